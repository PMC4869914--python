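"""Synthetic cohort generator.

Produces reference genomes, clade structures, variant-call tables and
coverage summaries with the statistical structure the downstream analysis
assumes: clades founded from distinct donor haplotypes, Poisson somatic
accumulation under a strand-biased context spectrum, class-specific
selection (thinning plus heteroplasmy penalty for deleterious classes),
host-contamination mixing, and binomial read-support sampling.

Randomness is driven by a single global seed with named substreams per
stage, so individual stages are reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import defaults
from .calls import (
    DELETION,
    INSERTION,
    SUBSTITUTION,
    CoverageSummary,
    VariantCall,
    write_coverage_table,
    write_variant_table,
)
from .reference import (
    HEAVY,
    LIGHT,
    MISSENSE,
    NONSENSE,
    GeneAnnotation,
    MtReference,
    annotate_consequence,
)
from .spectrum import SUB_TYPES, SpectrumClass, classify_substitution

__all__ = [
    "SimulationConfig",
    "SimulatedTruth",
    "SimulatedCohort",
    "simulate_reference",
    "simulate_cohort",
    "draw_somatic_mutations",
    "default_spectrum_weights",
    "write_cohort",
    "substream",
]

Key = tuple[int, str, str]

LABEL_GERMLINE = "germline_clade_defining"
LABEL_POTENTIAL = "potential_somatic"
LABEL_SOMATIC = "somatic"
LABEL_CONTAMINATION = "contamination"


def substream(seed: int, *names: object) -> np.random.Generator:
    """Independent generator for a named simulation stage."""
    tags = [zlib.crc32(str(n).encode()) for n in names]
    return np.random.default_rng([int(seed), *tags])


def default_spectrum_weights() -> dict[tuple[str, str], float]:
    """Strand-biased default: heavy-strand C>T / T>C dominate."""
    weights = {(sub, strand): 0.0125 for sub in SUB_TYPES for strand in (HEAVY, LIGHT)}
    weights[("C>T", HEAVY)] = 0.35
    weights[("T>C", HEAVY)] = 0.35
    weights[("C>T", LIGHT)] = 0.1
    weights[("T>C", LIGHT)] = 0.1
    total = sum(weights.values())
    return {k: v / total for k, v in weights.items()}


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    # reference
    genome_length: int = 6000
    gc_weight: float = 0.45
    n_genes: int = 3
    include_light_gene: bool = True
    # cohort structure
    n_clades: int = 3
    tumours_per_clade: int = 4
    matched_host_fraction: float = 1.0
    donor_divergence: int = 8
    potential_somatic_per_clade: int = 1
    host_divergence: int = 6
    panel_extra_haplotypes: int = 5
    # mutational process
    mutation_rate_per_year: float = 0.03
    indel_rate_per_year: float = 0.0
    clade_ages: tuple[float, ...] | None = None
    spectrum_weights: Mapping[tuple[str, str], float] | None = None
    # selection
    w_mis: float = 1.0
    w_non: float = 1.0
    w_frameshift: float = 1.0
    deleterious_het_penalty: bool = True
    # heteroplasmy
    heteroplasmy_prob: float = 0.1
    heteroplasmy_alpha: float = 2.0
    heteroplasmy_beta: float = 2.0
    # sequencing / contamination
    contamination: float = 0.2
    mt_coverage: float = 70.0
    nucl_coverage: float = 0.3
    min_mutant_reads: int = 2

    def __post_init__(self) -> None:
        for name in ("matched_host_fraction", "contamination", "heteroplasmy_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("mutation_rate_per_year", "indel_rate_per_year",
                     "w_mis", "w_non", "w_frameshift", "mt_coverage", "nucl_coverage"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.spectrum_weights is not None:
            vals = list(self.spectrum_weights.values())
            if any(v < 0 for v in vals):
                raise ValueError("spectrum weights must be non-negative")
            if abs(sum(vals) - 1.0) > 1e-9:
                raise ValueError("spectrum weights must sum to 1")

    @property
    def ages(self) -> tuple[float, ...]:
        if self.clade_ages is not None:
            if len(self.clade_ages) != self.n_clades:
                raise ValueError("clade_ages length must equal n_clades")
            return self.clade_ages
        return tuple(300.0 + 250.0 * i for i in range(self.n_clades))

    @property
    def weights(self) -> dict[tuple[str, str], float]:
        if self.spectrum_weights is None:
            return default_spectrum_weights()
        return dict(self.spectrum_weights)


@dataclass
class SimulatedTruth:
    """Ground truth for every emitted variant plus generative parameters."""

    labels: dict[tuple[str, Key], str] = field(default_factory=dict)
    clade_of: dict[str, int] = field(default_factory=dict)
    tumour_fraction: dict[str, float] = field(default_factory=dict)
    donor_haplotypes: dict[int, set[Key]] = field(default_factory=dict)
    generated_somatic_counts: dict[str, int] = field(default_factory=dict)
    w_mis: float = 1.0
    w_non: float = 1.0
    w_frameshift: float = 1.0

    def validate(self) -> None:
        valid = {LABEL_GERMLINE, LABEL_POTENTIAL, LABEL_SOMATIC, LABEL_CONTAMINATION}
        for (sample, key), label in self.labels.items():
            if label not in valid:
                raise AssertionError(f"variant {sample}/{key} has bad label {label}")


@dataclass
class SimulatedCohort:
    reference: MtReference
    tumour_calls: dict[str, list[VariantCall]]
    host_calls: dict[str, list[VariantCall]]
    coverage: dict[str, CoverageSummary]
    clade_of: dict[str, int]
    host_of: dict[str, str | None]
    germline_panel: set[Key]
    truth: SimulatedTruth
    config: SimulationConfig


# ---------------------------------------------------------------------------
# reference simulation

def simulate_reference(config: SimulationConfig) -> MtReference:
    """Random circular genome with heavy-strand genes and optionally one
    light-strand gene standing in for ND6."""
    if config.genome_length < 60:
        raise ValueError("genome length must be >= 60")
    rng = substream(config.seed, "reference")
    p_gc = config.gc_weight
    probs = [(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2]
    seq = "".join(rng.choice(list("ACGT"), size=config.genome_length, p=probs))

    n_genes = config.n_genes + (1 if config.include_light_gene else 0)
    gap = 30
    head = 30
    usable = config.genome_length - head - gap * n_genes
    gene_len = (usable // n_genes) // 3 * 3
    if n_genes < 1 or gene_len < 30:
        raise ValueError("infeasible gene layout for requested length")
    genes = []
    cursor = head + 1
    for i in range(n_genes):
        strand = LIGHT if (config.include_light_gene and i == n_genes - 1) else HEAVY
        genes.append(
            GeneAnnotation(
                name=f"gene{i + 1}" if strand == HEAVY else "light_gene",
                start=cursor,
                end=cursor + gene_len - 1,
                strand=strand,
            )
        )
        cursor += gene_len + gap
    return MtReference(sequence=seq, genes=genes)


# ---------------------------------------------------------------------------
# mutation sampling

class CandidateSampler:
    """Samples (position, ref, alt) substitutions so that the realized
    class distribution matches configured class weights: a class is drawn
    by weight (renormalized over classes with at least one candidate site),
    then a site uniformly within the class."""

    def __init__(
        self,
        ref: MtReference,
        weights: Mapping[tuple[str, str], float],
    ):
        self.ref = ref
        by_class: dict[SpectrumClass, list[tuple[int, str, str]]] = {}
        excluded = ref.excluded_positions
        for pos in range(1, ref.length + 1):
            if pos in excluded:
                continue
            base = ref.base(pos)
            if base == "N":
                continue
            for alt in "ACGT":
                if alt == base:
                    continue
                cls = classify_substitution(ref, pos, base, alt)
                by_class.setdefault(cls, []).append((pos, base, alt))
        self.classes = sorted(by_class)
        self.candidates = [by_class[c] for c in self.classes]
        raw = np.array(
            [weights[(c.substitution, c.strand)] / 16.0 for c in self.classes]
        )
        if raw.sum() <= 0:
            raise ValueError("no spectrum weight on any achievable class")
        self.probs = raw / raw.sum()
        self.class_probs = {c: p for c, p in zip(self.classes, self.probs)}
        self._consequences: dict[tuple[int, str], str] = {}

    def draw(self, rng: np.random.Generator) -> tuple[int, str, str]:
        idx = rng.choice(len(self.classes), p=self.probs)
        sites = self.candidates[idx]
        return sites[rng.integers(len(sites))]

    def draw_many(self, n: int, rng: np.random.Generator) -> list[tuple[int, str, str]]:
        if n == 0:
            return []
        idxs = rng.choice(len(self.classes), size=n, p=self.probs)
        return [
            self.candidates[i][rng.integers(len(self.candidates[i]))] for i in idxs
        ]

    def consequence(self, pos: int, ref_base: str, alt: str) -> str:
        cached = self._consequences.get((pos, alt))
        if cached is None:
            cached = annotate_consequence(self.ref, pos, ref_base, alt)
            self._consequences[(pos, alt)] = cached
        return cached


def draw_somatic_mutations(
    ref: MtReference,
    n_candidates: int,
    rng: np.random.Generator,
    *,
    weights: Mapping[tuple[str, str], float] | None = None,
    w_mis: float = 1.0,
    w_non: float = 1.0,
    sampler: CandidateSampler | None = None,
) -> list[tuple[Key, str]]:
    """Draw candidate substitutions from the spectrum and thin them by
    class-specific selection. Returns (key, consequence) pairs for the
    accepted mutations."""
    if sampler is None:
        sampler = CandidateSampler(ref, weights or default_spectrum_weights())
    acceptance = {MISSENSE: w_mis, NONSENSE: w_non}
    out: list[tuple[Key, str]] = []
    for pos, base, alt in sampler.draw_many(n_candidates, rng):
        consequence = sampler.consequence(pos, base, alt)
        w = acceptance.get(consequence, 1.0)
        if w >= 1.0 or rng.random() < w:
            out.append(((pos, base, alt), consequence))
    return out


def _random_haplotype(
    ref: MtReference, n_variants: int, rng: np.random.Generator
) -> set[Key]:
    excluded = ref.excluded_positions
    allowed = [p for p in range(1, ref.length + 1) if p not in excluded]
    positions = rng.choice(allowed, size=min(n_variants, len(allowed)), replace=False)
    hap: set[Key] = set()
    for pos in sorted(int(p) for p in positions):
        base = ref.base(pos)
        alts = [b for b in "ACGT" if b != base]
        hap.add((pos, base, alts[rng.integers(3)]))
    return hap


def _heteroplasmy(
    rng: np.random.Generator,
    config: SimulationConfig,
    consequence: str,
    class_w: float,
) -> float:
    het_prob = config.heteroplasmy_prob
    alpha, beta = config.heteroplasmy_alpha, config.heteroplasmy_beta
    deleterious = consequence in (MISSENSE, NONSENSE, "frameshift") and class_w < 1.0
    if config.deleterious_het_penalty and deleterious:
        het_prob = max(het_prob, 1.0 - class_w)
        alpha, beta = 1.5, 3.0
    if rng.random() < het_prob:
        return float(rng.beta(alpha, beta))
    return 1.0


def _emit_call(
    sample_id: str,
    key: Key,
    expected_vaf: float,
    kind: str,
    rng: np.random.Generator,
    config: SimulationConfig,
) -> VariantCall | None:
    depth = int(rng.poisson(config.mt_coverage))
    if depth == 0:
        return None
    mutant = int(rng.binomial(depth, min(expected_vaf, 1.0)))
    if mutant < max(config.min_mutant_reads, 1):
        return None
    fwd_mut = int(rng.binomial(mutant, 0.5))
    ref_reads = depth - mutant
    fwd_ref = int(rng.binomial(ref_reads, 0.5)) if ref_reads else 0
    bq25 = int(rng.binomial(mutant, 0.98))
    pos, ref_allele, alt_allele = key
    return VariantCall(
        sample_id=sample_id,
        position=pos,
        ref=ref_allele,
        alt=alt_allele,
        kind=kind,
        mutant_reads=mutant,
        total_depth=depth,
        fwd_mutant=fwd_mut,
        rev_mutant=mutant - fwd_mut,
        fwd_ref=fwd_ref,
        rev_ref=ref_reads - fwd_ref,
        bq25_reads=bq25,
        mean_mq=60.0,
        rep=0,
        pindel_reads=mutant if kind != SUBSTITUTION else 0,
        bwa_reads=mutant if kind != SUBSTITUTION else 0,
    )


def _draw_indels(
    ref: MtReference,
    n_candidates: int,
    rng: np.random.Generator,
    config: SimulationConfig,
) -> list[tuple[Key, str, str]]:
    """Random small indels thinned by the frameshift selection coefficient.

    Returns (key, kind, consequence-class) with consequence-class in
    {"frameshift", "inframe"}.
    """
    excluded = ref.excluded_positions
    out = []
    for _ in range(n_candidates):
        pos = int(rng.integers(2, ref.length - 4))
        if pos in excluded:
            continue
        size = int(rng.integers(1, 4))
        frameshift = size % 3 != 0
        if frameshift and config.w_frameshift < 1.0 and rng.random() >= config.w_frameshift:
            continue
        anchor = ref.base(pos)
        if rng.random() < 0.5:
            inserted = "".join(rng.choice(list("ACGT"), size=size))
            key = (pos, anchor, anchor + inserted)
            kind = INSERTION
        else:
            removed = "".join(ref.base(pos + 1 + i) for i in range(size))
            key = (pos, anchor + removed, anchor)
            kind = DELETION
        out.append((key, kind, "frameshift" if frameshift else "inframe"))
    return out


# ---------------------------------------------------------------------------
# cohort simulation

def simulate_cohort(config: SimulationConfig, ref: MtReference) -> SimulatedCohort:
    truth = SimulatedTruth(
        w_mis=config.w_mis, w_non=config.w_non, w_frameshift=config.w_frameshift
    )
    weights = config.weights
    sampler = CandidateSampler(ref, weights)
    ages = config.ages

    # donor and panel haplotypes
    panel: set[Key] = set()
    donor_of: dict[int, set[Key]] = {}
    potential_of: dict[int, set[Key]] = {}
    used_positions: set[int] = set()
    for clade in range(1, config.n_clades + 1):
        rng = substream(config.seed, "donor", clade)
        hap = _random_haplotype(ref, config.donor_divergence, rng)
        hap = {k for k in hap if k[0] not in used_positions}
        used_positions |= {k[0] for k in hap}
        potential = _random_haplotype(ref, config.potential_somatic_per_clade, rng)
        potential = {k for k in potential if k[0] not in used_positions}
        used_positions |= {k[0] for k in potential}
        donor_of[clade] = hap
        potential_of[clade] = potential
        panel |= hap
        truth.donor_haplotypes[clade] = set(hap) | set(potential)
    rng = substream(config.seed, "panel")
    for _ in range(config.panel_extra_haplotypes):
        extra = _random_haplotype(ref, config.donor_divergence, rng)
        panel |= {k for k in extra if k[0] not in used_positions}

    tumour_calls: dict[str, list[VariantCall]] = {}
    host_calls: dict[str, list[VariantCall]] = {}
    coverage: dict[str, CoverageSummary] = {}
    clade_of: dict[str, int] = {}
    host_of: dict[str, str | None] = {}

    for clade in range(1, config.n_clades + 1):
        age = ages[clade - 1]
        for t in range(1, config.tumours_per_clade + 1):
            tumour_id = f"c{clade}t{t}T"
            host_id = f"c{clade}t{t}H"
            rng = substream(config.seed, "tumour", clade, t)
            has_host = rng.random() < config.matched_host_fraction

            f = 1.0 - config.contamination
            clade_positions = {k[0] for k in donor_of[clade] | potential_of[clade]}

            # host germline haplotype (a different dog)
            host_hap = _random_haplotype(ref, config.host_divergence, rng)
            host_hap = {
                k for k in host_hap if k[0] not in clade_positions
            }

            # somatic substitutions
            n_cand = int(rng.poisson(config.mutation_rate_per_year * age))
            somatic = draw_somatic_mutations(
                ref, n_cand, rng,
                w_mis=config.w_mis, w_non=config.w_non, sampler=sampler,
            )
            taken = clade_positions | {k[0] for k in host_hap}
            somatic_unique = []
            for key, consequence in somatic:
                if key[0] in taken:
                    continue
                taken.add(key[0])
                somatic_unique.append((key, consequence))
            truth.generated_somatic_counts[tumour_id] = len(somatic_unique)

            # somatic indels
            n_indel_cand = int(rng.poisson(config.indel_rate_per_year * age))
            indels = []
            for entry in _draw_indels(ref, n_indel_cand, rng, config):
                if entry[0][0] not in taken:
                    taken.add(entry[0][0])
                    indels.append(entry)

            calls: list[VariantCall] = []

            def emit(key, expected_vaf, kind, label):
                call = _emit_call(tumour_id, key, expected_vaf, kind, rng, config)
                if call is not None:
                    calls.append(call)
                    truth.labels[(tumour_id, key)] = label

            for key in sorted(donor_of[clade]):
                emit(key, f, SUBSTITUTION, LABEL_GERMLINE)
            for key in sorted(potential_of[clade]):
                emit(key, f, SUBSTITUTION, LABEL_POTENTIAL)
            for key, consequence in somatic_unique:
                class_w = {MISSENSE: config.w_mis, NONSENSE: config.w_non}.get(
                    consequence, 1.0
                )
                h = _heteroplasmy(rng, config, consequence, class_w)
                emit(key, h * f, SUBSTITUTION, LABEL_SOMATIC)
            for key, kind, klass in indels:
                class_w = config.w_frameshift if klass == "frameshift" else 1.0
                h = _heteroplasmy(rng, config, klass, class_w)
                emit(key, h * f, kind, LABEL_SOMATIC)
            if has_host and config.contamination > 0:
                for key in sorted(host_hap):
                    emit(key, 1.0 - f, SUBSTITUTION, LABEL_CONTAMINATION)

            tumour_calls[tumour_id] = calls
            clade_of[tumour_id] = clade
            truth.clade_of[tumour_id] = clade
            truth.tumour_fraction[tumour_id] = f
            coverage[tumour_id] = CoverageSummary(
                tumour_id, config.mt_coverage, config.nucl_coverage
            )

            if has_host:
                hcalls: list[VariantCall] = []
                for key in sorted(host_hap):
                    call = _emit_call(host_id, key, 0.995, SUBSTITUTION, rng, config)
                    if call is not None:
                        hcalls.append(call)
                host_calls[host_id] = hcalls
                host_of[tumour_id] = host_id
                coverage[host_id] = CoverageSummary(
                    host_id, config.mt_coverage, config.nucl_coverage
                )
                panel |= host_hap  # hosts are normal dogs: their germline joins the panel
            else:
                host_of[tumour_id] = None

    truth.validate()
    return SimulatedCohort(
        reference=ref,
        tumour_calls=tumour_calls,
        host_calls=host_calls,
        coverage=coverage,
        clade_of=clade_of,
        host_of=host_of,
        germline_panel=panel,
        truth=truth,
        config=config,
    )


# ---------------------------------------------------------------------------
# fixture output

def write_reference(ref: MtReference, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "reference.fasta", "w") as fh:
        fh.write(">MT simulated circular mtDNA\n")
        for i in range(0, ref.length, 70):
            fh.write(ref.sequence[i : i + 70] + "\n")
    with open(outdir / "genes.tsv", "w") as fh:
        fh.write("name\tstart\tend\tstrand\tframe\n")
        for g in ref.genes:
            fh.write(f"{g.name}\t{g.start}\t{g.end}\t{g.strand}\t{g.frame}\n")


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> None:
    """Write the cohort as plain-text fixture files (drop-in pipeline input)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_reference(cohort.reference, outdir)

    tumours = [c for s in sorted(cohort.tumour_calls) for c in cohort.tumour_calls[s]]
    hosts = [c for s in sorted(cohort.host_calls) for c in cohort.host_calls[s]]
    write_variant_table(tumours, outdir / "tumour_calls.tsv")
    write_variant_table(hosts, outdir / "host_calls.tsv")
    write_coverage_table(
        [cohort.coverage[s] for s in sorted(cohort.coverage)], outdir / "coverage.tsv"
    )
    with open(outdir / "clades.tsv", "w") as fh:
        fh.write("tumour_id\tclade\thost_id\n")
        for tumour in sorted(cohort.clade_of):
            host = cohort.host_of.get(tumour) or ""
            fh.write(f"{tumour}\t{cohort.clade_of[tumour]}\t{host}\n")
    with open(outdir / "panel.tsv", "w") as fh:
        fh.write("position\tref\talt\n")
        for pos, ref_a, alt_a in sorted(cohort.germline_panel):
            fh.write(f"{pos}\t{ref_a}\t{alt_a}\n")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("sample_id\tposition\tref\talt\tlabel\n")
        for (sample, key), label in sorted(cohort.truth.labels.items()):
            fh.write(f"{sample}\t{key[0]}\t{key[1]}\t{key[2]}\t{label}\n")
    with open(outdir / "config.json", "w") as fh:
        payload = dataclasses.asdict(cohort.config)
        if payload.get("spectrum_weights") is not None:
            payload["spectrum_weights"] = {
                f"{sub}|{strand}": w
                for (sub, strand), w in payload["spectrum_weights"].items()
            }
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
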