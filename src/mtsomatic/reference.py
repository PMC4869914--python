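"""Circular mitochondrial reference model.

Holds the reference sequence (light strand by convention), gene annotations,
excluded regions/sites; provides circular triplet counting on either strand
and codon-level consequence annotation under the vertebrate mitochondrial
genetic code (NCBI translation table 2 by default).

Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "GeneAnnotation",
    "MtReference",
    "TripletCensus",
    "load_reference",
    "count_triplets",
    "annotate_consequence",
    "revcomp",
    "complement",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

HEAVY = "heavy"
LIGHT = "light"

SYNONYMOUS = "synonymous"
MISSENSE = "missense"
NONSENSE = "nonsense"
NON_CODING = "non_coding"


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene on the circular genome.

    ``strand`` names the strand the gene is transcribed from. Genes
    transcribed from the heavy strand have a coding sequence equal to the
    reference (light) strand read forward; a light-strand-transcribed gene
    (the ND6 analogue) codes on the reverse complement.
    """

    name: str
    start: int
    end: int
    strand: str = HEAVY
    frame: int = 0
    coding: bool = True

    def __post_init__(self) -> None:
        if self.strand not in (HEAVY, LIGHT):
            raise ValueError(f"gene {self.name}: strand must be 'heavy' or 'light'")
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"gene {self.name}: invalid interval {self.start}-{self.end}")
        if self.frame not in (0, 1, 2):
            raise ValueError(f"gene {self.name}: frame must be 0, 1 or 2")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class TripletCensus:
    """Counts of the 64 triplets centred on each counted position of one strand."""

    strand: str
    counts: Mapping[str, int]
    n_counted: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_counted:
            raise ValueError("triplet census does not conserve position count")

    def count(self, triplet: str) -> int:
        return self.counts.get(triplet.upper(), 0)


@dataclass
class MtReference:
    """Circular mtDNA reference: sequence, genes, exclusions, genetic code."""

    sequence: str
    genes: Sequence[GeneAnnotation] = field(default_factory=list)
    excluded_regions: Sequence[tuple[int, int]] = field(default_factory=list)
    excluded_sites: Sequence[tuple[int, str]] = field(default_factory=list)
    translation_table: int = 2
    allow_incomplete_terminal_codon: bool = True

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        n = len(self.sequence)
        if n < 3:
            raise ValueError("reference sequence shorter than one triplet")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"non-nucleotide characters in reference: {sorted(bad)}")
        light_genes = [g for g in self.genes if g.strand == LIGHT]
        if len(light_genes) > 1:
            raise ValueError("at most one gene may be light-strand transcribed")
        for g in self.genes:
            if g.end > n:
                raise ValueError(f"gene {g.name} extends beyond sequence length {n}")
            if g.coding and (g.length - g.frame) % 3 != 0 and not self.allow_incomplete_terminal_codon:
                raise ValueError(f"gene {g.name}: coding length not divisible by 3")
        overlaps = []
        ordered = sorted(self.genes, key=lambda g: g.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.start <= a.end:
                overlaps.append((a.name, b.name))
        if overlaps:
            raise ValueError(f"overlapping gene annotations: {overlaps}")
        for s, e in self.excluded_regions:
            if not (1 <= s <= e <= n):
                raise ValueError(f"excluded region {s}-{e} outside [1, {n}]")
        for p, change in self.excluded_sites:
            if not 1 <= p <= n:
                raise ValueError(f"excluded site {p} outside [1, {n}]")
            if ">" not in change:
                raise ValueError(f"excluded site change {change!r} not of form 'REF>ALT'")
        self._codon_table = CodonTable.unambiguous_dna_by_id[self.translation_table]

    @property
    def length(self) -> int:
        return len(self.sequence)

    # -- positional access (circular, 1-based) ------------------------------
    def base(self, position: int) -> str:
        return self.sequence[(position - 1) % self.length]

    def triplet(self, position: int, strand: str = LIGHT) -> str:
        """Triplet centred on ``position``; wraps at the origin."""
        n = self.length
        i = position - 1
        t = self.sequence[(i - 1) % n] + self.sequence[i % n] + self.sequence[(i + 1) % n]
        if strand == LIGHT:
            return t
        if strand == HEAVY:
            return revcomp(t)
        raise ValueError(f"unknown strand {strand!r}")

    @property
    def excluded_positions(self) -> frozenset[int]:
        pos = set()
        for s, e in self.excluded_regions:
            pos.update(range(s, e + 1))
        pos.update(p for p, _ in self.excluded_sites)
        return frozenset(pos)

    def site_excluded(self, position: int, ref: str, alt: str) -> bool:
        return (position, f"{ref}>{alt}") in set(self.excluded_sites)

    def region_excluded(self, position: int) -> bool:
        return any(s <= position <= e for s, e in self.excluded_regions)

    def gene_at(self, position: int) -> GeneAnnotation | None:
        for g in self.genes:
            if g.contains(position):
                return g
        return None

    # -- codon machinery ----------------------------------------------------
    def codon_at(self, position: int) -> tuple[GeneAnnotation, str, int] | None:
        """Return (gene, codon, offset-within-codon) for a coding position.

        The codon is given on the gene's coding strand. Returns None for
        non-coding positions, positions before the reading-frame offset and
        incomplete terminal codons.
        """
        gene = self.gene_at(position)
        if gene is None or not gene.coding:
            return None
        if gene.strand == HEAVY:
            cds_index = (position - gene.start) - gene.frame
        else:
            cds_index = (gene.end - position) - gene.frame
        if cds_index < 0:
            return None
        n_codons = (gene.length - gene.frame) // 3
        codon_index = cds_index // 3
        if codon_index >= n_codons:
            return None  # incomplete terminal codon
        offset = cds_index % 3
        if gene.strand == HEAVY:
            first = gene.start + gene.frame + 3 * codon_index
            codon = self.sequence[first - 1 : first + 2]
        else:
            first = gene.end - gene.frame - 3 * codon_index
            codon = complement(self.sequence[first - 3 : first][::-1])
        return gene, codon, offset

    def translate_codon(self, codon: str) -> str:
        """Amino acid for a codon under the configured code; '*' for stop."""
        if codon in self._codon_table.stop_codons:
            return "*"
        return self._codon_table.forward_table[codon]


def count_triplets(ref: MtReference, strand: str) -> TripletCensus:
    """Census of triplets centred on each non-excluded position of a strand.

    Counting is circular: the triplets at positions 1 and ``length`` wrap
    around the origin. The heavy-strand census is the reverse-complement
    image of the light-strand census.
    """
    if strand not in (HEAVY, LIGHT):
        raise ValueError(f"unknown strand {strand!r}")
    excluded = ref.excluded_positions
    counts: Counter[str] = Counter()
    for position in range(1, ref.length + 1):
        if position in excluded:
            continue
        counts[ref.triplet(position, strand)] += 1
    return TripletCensus(strand=strand, counts=dict(counts), n_counted=sum(counts.values()))


def annotate_consequence(ref: MtReference, position: int, ref_base: str, alt_base: str) -> str:
    """Classify a substitution as synonymous / missense / nonsense / non_coding.

    ``ref_base``/``alt_base`` are given on the reference (light) strand and
    must match the reference sequence at ``position``.
    """
    ref_base = ref_base.upper()
    alt_base = alt_base.upper()
    if ref.base(position) != ref_base:
        raise ValueError(
            f"reference mismatch at {position}: expected {ref.base(position)}, got {ref_base}"
        )
    if ref_base == alt_base:
        raise ValueError("ref and alt bases are identical")
    hit = ref.codon_at(position)
    if hit is None:
        return NON_CODING
    gene, codon, offset = hit
    if gene.strand == HEAVY:
        new_base = alt_base
    else:
        new_base = complement(alt_base)
    new_codon = codon[:offset] + new_base + codon[offset + 1 :]
    aa_old = ref.translate_codon(codon)
    aa_new = ref.translate_codon(new_codon)
    if aa_old == aa_new:
        return SYNONYMOUS
    if aa_new == "*":
        return NONSENSE
    return MISSENSE  # includes stop-loss


def load_reference(
    fasta_path: str | Path,
    gene_table_path: str | Path | None = None,
    exclusions: Mapping | None = None,
    max_n_fraction: float = 0.01,
) -> MtReference:
    """Load an MtReference from a single-record FASTA plus a gene table.

    The gene table is tab-separated with columns
    ``name  start  end  strand  frame`` (header optional). Exclusions are a
    mapping with optional keys ``excluded_regions`` (list of [start, end])
    and ``excluded_sites`` (list of [position, "REF>ALT"]).
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{fasta_path}: expected exactly one FASTA record, found {len(records)}")
    sequence = str(records[0].seq).upper()
    if sequence.count("N") > max_n_fraction * len(sequence):
        raise ValueError(f"{fasta_path}: N fraction exceeds {max_n_fraction}")

    genes: list[GeneAnnotation] = []
    if gene_table_path is not None:
        with open(gene_table_path, newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#") or row[0] == "name":
                    continue
                name, start, end, strand = row[0], int(row[1]), int(row[2]), row[3]
                frame = int(row[4]) if len(row) > 4 and row[4] != "" else 0
                genes.append(GeneAnnotation(name, start, end, strand, frame))

    exclusions = exclusions or {}
    regions = [tuple(r) for r in exclusions.get("excluded_regions", [])]
    sites = [(int(p), c) for p, c in exclusions.get("excluded_sites", [])]
    return MtReference(
        sequence=sequence,
        genes=genes,
        excluded_regions=regions,
        excluded_sites=sites,
    )
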