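"""Variant-call tables and coverage summaries.

The on-disk dialect is either a flat TSV (one row per call, stable column
order) or a VCF 4.2 file with reserved INFO keys carrying the same fields;
the format is selected by file extension (``.vcf`` vs anything else). Both
are lossless round-trips for every field of :class:`VariantCall`.
"""

from __future__ import annotations

import csv
import gzip
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "VariantCall",
    "CoverageSummary",
    "VariantTableError",
    "read_variant_table",
    "write_variant_table",
    "read_coverage_table",
    "write_coverage_table",
    "SUBSTITUTION",
    "INSERTION",
    "DELETION",
]

SUBSTITUTION = "substitution"
INSERTION = "insertion"
DELETION = "deletion"

VAF_TOLERANCE = 1e-6


class VariantTableError(ValueError):
    """Schema or invariant violation in a variant table."""


def _open(path: Path, mode: str):
    """Open a table file, transparently handling ``.gz`` compression."""
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t", encoding="utf-8", newline="")
    return open(path, mode, encoding="utf-8", newline="")


def _is_vcf(path: Path) -> bool:
    name = str(path)
    return name.endswith(".vcf") or name.endswith(".vcf.gz")


@dataclass(frozen=True)
class VariantCall:
    """One substitution or indel call in one sample, with filter evidence."""

    sample_id: str
    position: int
    ref: str
    alt: str
    kind: str
    mutant_reads: int
    total_depth: int
    vaf: float | None = None
    fwd_mutant: int = 0
    rev_mutant: int = 0
    fwd_ref: int = 0
    rev_ref: int = 0
    bq25_reads: int = 0
    mean_mq: float = 60.0
    read_end_only: bool = False
    rep: int = 0
    pindel_reads: int = 0
    bwa_reads: int = 0

    def __post_init__(self) -> None:
        if self.kind not in (SUBSTITUTION, INSERTION, DELETION):
            raise VariantTableError(f"unknown variant kind {self.kind!r}")
        if self.position < 1:
            raise VariantTableError(f"position {self.position} < 1")
        if self.total_depth < 0 or self.mutant_reads < 0:
            raise VariantTableError("negative read counts")
        if self.mutant_reads > self.total_depth:
            raise VariantTableError(
                f"mutant reads {self.mutant_reads} exceed depth {self.total_depth}"
            )
        if self.fwd_mutant + self.rev_mutant != self.mutant_reads:
            raise VariantTableError(
                "per-strand mutant counts do not sum to mutant_reads"
            )
        if self.bq25_reads > self.mutant_reads:
            raise VariantTableError("bq25_reads exceed mutant_reads")
        computed = self.mutant_reads / self.total_depth if self.total_depth else 0.0
        if self.vaf is None:
            object.__setattr__(self, "vaf", computed)
        elif abs(self.vaf - computed) > VAF_TOLERANCE:
            raise VariantTableError(
                f"stored VAF {self.vaf} inconsistent with {self.mutant_reads}/{self.total_depth}"
            )
        if not 0.0 <= self.vaf <= 1.0:
            raise VariantTableError(f"VAF {self.vaf} outside [0, 1]")

    @property
    def key(self) -> tuple[int, str, str]:
        """Sample-independent identity of the variant."""
        return (self.position, self.ref, self.alt)

    @property
    def change(self) -> str:
        return f"{self.ref}>{self.alt}"

    @property
    def is_indel(self) -> bool:
        return self.kind in (INSERTION, DELETION)

    @property
    def is_frameshift(self) -> bool:
        if not self.is_indel:
            return False
        return abs(len(self.ref) - len(self.alt)) % 3 != 0


@dataclass(frozen=True)
class CoverageSummary:
    """Per-sample mean mtDNA / nuclear coverage and ploidy."""

    sample_id: str
    mt_cov: float
    nucl_cov: float
    ploidy: int = 2
    low_coverage_x: float = 20.0
    high_coverage_x: float = 300.0

    def __post_init__(self) -> None:
        if self.mt_cov < 0 or self.nucl_cov < 0:
            raise VariantTableError("coverage must be non-negative")
        if self.ploidy < 1:
            raise VariantTableError("ploidy must be >= 1")

    @property
    def low_coverage(self) -> bool:
        return self.mt_cov < self.low_coverage_x

    @property
    def high_coverage(self) -> bool:
        return self.mt_cov > self.high_coverage_x


# ---------------------------------------------------------------------------
# TSV dialect

_COLUMNS = [
    "sample_id", "position", "ref", "alt", "kind", "mutant_reads",
    "total_depth", "vaf", "fwd_mutant", "rev_mutant", "fwd_ref", "rev_ref",
    "bq25_reads", "mean_mq", "read_end_only", "rep", "pindel_reads",
    "bwa_reads",
]

_INT_FIELDS = {
    "position", "mutant_reads", "total_depth", "fwd_mutant", "rev_mutant",
    "fwd_ref", "rev_ref", "bq25_reads", "rep", "pindel_reads", "bwa_reads",
}
_FLOAT_FIELDS = {"vaf", "mean_mq"}
_BOOL_FIELDS = {"read_end_only"}


def _format(value) -> str:
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return format(value, ".17g")
    return str(value)


def _parse_row(row: dict[str, str], line_no: int) -> VariantCall:
    kwargs = {}
    for name in _COLUMNS:
        raw = row.get(name)
        if raw is None:
            raise VariantTableError(f"line {line_no}: missing column {name!r}")
        try:
            if name in _INT_FIELDS:
                kwargs[name] = int(raw)
            elif name in _FLOAT_FIELDS:
                kwargs[name] = float(raw)
            elif name in _BOOL_FIELDS:
                kwargs[name] = raw in ("1", "True", "true")
            else:
                kwargs[name] = raw
        except ValueError as exc:
            raise VariantTableError(f"line {line_no}: bad value for {name}: {raw!r}") from exc
    try:
        return VariantCall(**kwargs)
    except VariantTableError as exc:
        raise VariantTableError(f"line {line_no}: {exc}") from exc


def _write_tsv(calls: Sequence[VariantCall], path: Path) -> None:
    with _open(path, "w") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_COLUMNS)
        for call in calls:
            writer.writerow([_format(getattr(call, c)) for c in _COLUMNS])


def _read_tsv(path: Path) -> list[VariantCall]:
    calls = []
    with _open(path, "r") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return []
        missing = set(_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise VariantTableError(f"{path}: missing columns {sorted(missing)}")
        for line_no, row in enumerate(reader, start=2):
            calls.append(_parse_row(row, line_no))
    return calls


# ---------------------------------------------------------------------------
# VCF dialect

_VCF_INFO_KEYS = [
    ("SM", "String", "Sample identifier"),
    ("KIND", "String", "Variant kind: substitution/insertion/deletion"),
    ("MR", "Integer", "Mutant read count"),
    ("DP", "Integer", "Total read depth"),
    ("VAF", "Float", "Variant allele fraction"),
    ("FMR", "Integer", "Forward-strand mutant reads"),
    ("RMR", "Integer", "Reverse-strand mutant reads"),
    ("FRR", "Integer", "Forward-strand reference reads"),
    ("RRR", "Integer", "Reverse-strand reference reads"),
    ("BQ25", "Integer", "Mutant reads with base quality >25"),
    ("MMQ", "Float", "Mean mapping quality of supporting reads"),
    ("ENDONLY", "Integer", "1 if supported only by first/last 15bp of reads"),
    ("REP", "Integer", "Adjacent repeat count of the indel unit"),
    ("PR", "Integer", "Pindel-supporting reads"),
    ("BR", "Integer", "BWA-supporting reads"),
]

_VCF_FIELD_BY_KEY = {
    "SM": "sample_id", "KIND": "kind", "MR": "mutant_reads", "DP": "total_depth",
    "VAF": "vaf", "FMR": "fwd_mutant", "RMR": "rev_mutant", "FRR": "fwd_ref",
    "RRR": "rev_ref", "BQ25": "bq25_reads", "MMQ": "mean_mq",
    "ENDONLY": "read_end_only", "REP": "rep", "PR": "pindel_reads",
    "BR": "bwa_reads",
}


def _write_vcf(calls: Sequence[VariantCall], path: Path, contig: str = "MT") -> None:
    with _open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig}>\n")
        for key, vtype, desc in _VCF_INFO_KEYS:
            fh.write(f'##INFO=<ID={key},Number=1,Type={vtype},Description="{desc}">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for call in calls:
            info = ";".join(
                f"{key}={_format(getattr(call, _VCF_FIELD_BY_KEY[key]))}"
                for key, _, _ in _VCF_INFO_KEYS
            )
            fh.write(
                f"{contig}\t{call.position}\t.\t{call.ref}\t{call.alt}\t.\t.\t{info}\n"
            )


def _read_vcf(path: Path) -> list[VariantCall]:
    calls = []
    with _open(path, "r") as fh:
        for line_no, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 8:
                raise VariantTableError(f"line {line_no}: malformed VCF row")
            _, pos, _, ref, alt, _, _, info = parts[:8]
            kv = {}
            for item in info.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    kv[k] = v
            kwargs = {"position": int(pos), "ref": ref, "alt": alt}
            for key, name in _VCF_FIELD_BY_KEY.items():
                if key not in kv:
                    raise VariantTableError(f"line {line_no}: missing INFO key {key}")
                raw = kv[key]
                if name in _INT_FIELDS:
                    kwargs[name] = int(raw)
                elif name in _FLOAT_FIELDS:
                    kwargs[name] = float(raw)
                elif name in _BOOL_FIELDS:
                    kwargs[name] = raw == "1"
                else:
                    kwargs[name] = raw
            try:
                calls.append(VariantCall(**kwargs))
            except VariantTableError as exc:
                raise VariantTableError(f"line {line_no}: {exc}") from exc
    return calls


# ---------------------------------------------------------------------------
# public API

def write_variant_table(calls: Sequence[VariantCall], path: str | Path) -> None:
    path = Path(path)
    if _is_vcf(path):
        _write_vcf(calls, path)
    else:
        _write_tsv(calls, path)


def read_variant_table(path: str | Path) -> list[VariantCall]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_vcf(path):
        return _read_vcf(path)
    return _read_tsv(path)


def write_coverage_table(summaries: Sequence[CoverageSummary], path: str | Path) -> None:
    with _open(path, "w") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", "mt_cov", "nucl_cov", "ploidy"])
        for s in summaries:
            writer.writerow([s.sample_id, _format(s.mt_cov), _format(s.nucl_cov), s.ploidy])


def read_coverage_table(path: str | Path) -> dict[str, CoverageSummary]:
    out: dict[str, CoverageSummary] = {}
    with _open(path, "r") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            s = CoverageSummary(
                sample_id=row["sample_id"],
                mt_cov=float(row["mt_cov"]),
                nucl_cov=float(row["nucl_cov"]),
                ploidy=int(row["ploidy"]),
            )
            out[s.sample_id] = s
    return out


def group_by_sample(calls: Iterable[VariantCall]) -> dict[str, list[VariantCall]]:
    grouped: dict[str, list[VariantCall]] = {}
    for call in calls:
        grouped.setdefault(call.sample_id, []).append(call)
    return grouped
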