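"""Somatic vs germline classification, tumour-fraction estimation and the
four tumour-substitution classes.

Tumours with a matched host are cleaned of host contamination using shared
calls and host VAF structure; host-less tumours use a per-tumour VAF cutoff.
Clade-level classes are then built across all tumours of a clade:

1. germline clade-defining  — shared by every tumour of the clade and
   present in the dog germline panel;
2. somatic                  — variable within the clade;
3. conservative-somatic     — somatic minus anything that could be germline
   (recombination-implicated, configured clades, ancestral-trunk groups,
   putative somatic calls from host-less tumours);
4. potential-somatic        — shared by every tumour of the clade but absent
   from the dog panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import fmean
from typing import Iterable, Mapping, Sequence

from . import defaults
from .calls import VariantCall, CoverageSummary

__all__ = [
    "SamplePair",
    "Label",
    "ClassifiedVariantSet",
    "classify_with_host",
    "classify_without_host",
    "estimate_tumour_fraction",
    "normalize_vaf",
    "build_variant_classes",
    "drop_tumour_contamination_from_host",
]

GERMLINE = "germline"
SOMATIC = "somatic"
DISCARDED = "discarded"

REASON_SHARED_LOW_VAF = "shared_with_host_low_vaf"
REASON_LOW_COV_HOST_SUPPORT = "supported_in_low_coverage_host"
REASON_LOW_COV_HOST_VAF = "low_vaf_with_low_coverage_host"
REASON_BELOW_CUTOFF = "below_vaf_cutoff"
REASON_IN_GERMLINE_PANEL = "in_dog_germline_panel"
NOTE_PUTATIVE = "putative_somatic"
NOTE_RELATED_TUMOURS = "present_in_related_tumours"
NOTE_TUMOUR_CONTAMINATED_HOST = "host_call_likely_tumour_contamination"

Key = tuple[int, str, str]


@dataclass(frozen=True)
class Label:
    label: str
    reason: str | None = None


@dataclass
class SamplePair:
    """A tumour with its optional matched host."""

    tumour_id: str
    host_id: str | None = None
    host_low_coverage: bool = False
    tumour_fraction: float | None = None
    vaf_cutoff: float = defaults.DEFAULT_VAF_CUTOFF

    def __post_init__(self) -> None:
        if self.tumour_fraction is not None and not 0 < self.tumour_fraction <= 1:
            raise ValueError("tumour fraction must be in (0, 1]")
        if not 0 <= self.vaf_cutoff <= 1:
            raise ValueError("VAF cutoff must be in [0, 1]")


def classify_with_host(
    tumour_calls: Sequence[VariantCall],
    host_calls: Sequence[VariantCall],
    host_coverage: CoverageSummary,
    *,
    germline_vaf: float = defaults.GERMLINE_VAF_THRESHOLD,
    low_coverage_tumour_vaf: float = defaults.LOW_COVERAGE_TUMOUR_VAF,
    host_support_by_key: Mapping[Key, int] | None = None,
) -> list[Label]:
    """Label each tumour call germline / somatic / discarded using the host.

    ``host_support_by_key`` optionally gives, for a low-coverage host, the
    number of host reads supporting each tumour variant position even where
    no host call was made; any support discards the tumour call.
    """
    if host_coverage is None:
        raise ValueError("matched-host classification requires a coverage summary")
    host_by_key = {c.key: c for c in host_calls}
    low_cov = host_coverage.low_coverage
    labels: list[Label] = []
    for call in tumour_calls:
        host_call = host_by_key.get(call.key)
        if host_call is not None:
            if call.vaf < germline_vaf:
                labels.append(Label(DISCARDED, REASON_SHARED_LOW_VAF))
                continue
            if host_call.vaf > germline_vaf:
                labels.append(Label(GERMLINE))
                continue
            # homoplasmic in tumour, subclonal in host: host call most
            # likely reflects tumour contamination of the host sample
            labels.append(Label(SOMATIC, NOTE_TUMOUR_CONTAMINATED_HOST))
            continue
        if low_cov:
            support = 0
            if host_support_by_key is not None:
                support = host_support_by_key.get(call.key, 0)
            if support >= 1:
                labels.append(Label(DISCARDED, REASON_LOW_COV_HOST_SUPPORT))
                continue
            if call.vaf < low_coverage_tumour_vaf:
                labels.append(Label(DISCARDED, REASON_LOW_COV_HOST_VAF))
                continue
        labels.append(Label(SOMATIC))
    return labels


def classify_without_host(
    tumour_calls: Sequence[VariantCall],
    cutoff: float = defaults.DEFAULT_VAF_CUTOFF,
    *,
    contamination_level: float | None = None,
    related_tumour_variants: Iterable[Key] = (),
    germline_panel: Iterable[Key] = (),
    heavy_contamination_level: float = defaults.HEAVY_CONTAMINATION_LEVEL,
) -> list[Label]:
    """Label calls from a tumour without a matched host.

    Below the per-tumour VAF cutoff calls are discarded. When contamination
    exceeds ``heavy_contamination_level`` the cutoff is unusable: calls
    present in phylogenetically related tumours are kept, calls in the dog
    germline panel dropped, and the remainder retained as putative somatic.
    """
    if not 0 <= cutoff <= 1:
        raise ValueError("cutoff outside [0, 1]")
    heavy = contamination_level is not None and contamination_level > heavy_contamination_level
    related = set(related_tumour_variants)
    panel = set(germline_panel)
    labels: list[Label] = []
    for call in tumour_calls:
        if heavy:
            if call.key in related:
                labels.append(Label(SOMATIC, NOTE_RELATED_TUMOURS))
            elif call.key in panel:
                labels.append(Label(DISCARDED, REASON_IN_GERMLINE_PANEL))
            else:
                labels.append(Label(SOMATIC, NOTE_PUTATIVE))
        elif call.vaf < cutoff:
            labels.append(Label(DISCARDED, REASON_BELOW_CUTOFF))
        else:
            labels.append(Label(SOMATIC))
    return labels


def estimate_tumour_fraction(
    tumour_calls: Sequence[VariantCall],
    host_calls: Sequence[VariantCall],
    *,
    homoplasmic_fraction: float = defaults.HOMOPLASMIC_CLASS_FRACTION,
) -> float:
    """Estimate the tumour mtDNA fraction from tumour-unique substitutions.

    The estimate is the mean raw VAF of tumour-unique, homoplasmic-class
    substitutions (those with VAF at least ``homoplasmic_fraction`` of the
    largest tumour-unique VAF, which screens out heteroplasmic variants).
    """
    host_keys = {c.key for c in host_calls}
    vafs = [
        c.vaf
        for c in tumour_calls
        if c.key not in host_keys and not c.is_indel
    ]
    if not vafs:
        raise ValueError("no tumour-unique substitutions: tumour fraction undefined")
    top = max(vafs)
    homoplasmic = [v for v in vafs if v >= homoplasmic_fraction * top]
    f = fmean(homoplasmic)
    return min(max(f, 1e-12), 1.0)


def normalize_vaf(raw_vaf: float, tumour_fraction: float) -> float:
    """Rescale a raw VAF by the tumour mtDNA fraction, capped at 1."""
    if tumour_fraction <= 0:
        raise ValueError("tumour fraction must be positive")
    if not 0 <= raw_vaf <= 1:
        raise ValueError("raw VAF outside [0, 1]")
    return min(raw_vaf / tumour_fraction, 1.0)


@dataclass(frozen=True)
class SomaticRecord:
    key: Key
    carriers: frozenset[str]
    mean_raw_vaf: float
    mean_normalized_vaf: float


@dataclass
class ClassifiedVariantSet:
    """Per-clade partition of tumour variants into the four classes."""

    clade_defining: dict[object, set[Key]] = field(default_factory=dict)
    potential_somatic: dict[object, set[Key]] = field(default_factory=dict)
    somatic: dict[object, dict[Key, SomaticRecord]] = field(default_factory=dict)
    conservative_somatic: dict[object, set[Key]] = field(default_factory=dict)
    tumours_by_clade: dict[object, tuple[str, ...]] = field(default_factory=dict)

    @property
    def clades(self) -> list:
        return sorted(self.clade_defining, key=str)

    def validate(self) -> None:
        for clade in self.clade_defining:
            defining = self.clade_defining[clade]
            potential = self.potential_somatic[clade]
            somatic = set(self.somatic[clade])
            conservative = self.conservative_somatic[clade]
            if not conservative <= somatic:
                raise AssertionError(f"clade {clade}: conservative not within somatic")
            pairs = [(defining, potential), (defining, somatic), (potential, somatic)]
            for a, b in pairs:
                if a & b:
                    raise AssertionError(f"clade {clade}: classes overlap: {a & b}")

    def conservative_records(self) -> list[SomaticRecord]:
        out = []
        for clade in self.clades:
            for key in sorted(self.conservative_somatic[clade]):
                out.append(self.somatic[clade][key])
        return out

    def somatic_records(self) -> list[SomaticRecord]:
        out = []
        for clade in self.clades:
            for key in sorted(self.somatic[clade]):
                out.append(self.somatic[clade][key])
        return out


def build_variant_classes(
    labelled_calls: Mapping[str, Sequence[tuple[VariantCall, Label]]],
    clade_of: Mapping[str, object],
    dog_germline_panel: Iterable[Key],
    *,
    tumour_fractions: Mapping[str, float] | None = None,
    excluded_clades: Iterable[object] = defaults.EXCLUDED_CLADES,
    trunk_groups: Mapping[str, Iterable[str]] | None = None,
    recombination_variants: Iterable[Key] = (),
) -> ClassifiedVariantSet:
    """Build the four variant classes per clade from per-tumour labels.

    ``trunk_groups`` maps an ancestral-trunk group name to the tumour ids it
    contains; a somatic variant carried by exactly the members of a trunk
    group is excluded from the conservative list.
    """
    panel = set(dog_germline_panel)
    recomb = set(recombination_variants)
    excluded_clades = set(excluded_clades)
    fractions = tumour_fractions or {}
    trunk_sets = {name: frozenset(members) for name, members in (trunk_groups or {}).items()}

    for tumour in labelled_calls:
        if tumour not in clade_of:
            raise ValueError(f"tumour {tumour} has no clade assignment")

    tumours_by_clade: dict[object, list[str]] = {}
    for tumour, clade in clade_of.items():
        tumours_by_clade.setdefault(clade, []).append(tumour)
    for clade in tumours_by_clade:
        tumours_by_clade[clade].sort()

    # kept (non-discarded) variant keys and somatic keys per tumour
    present: dict[str, set[Key]] = {}
    somatic_calls: dict[str, dict[Key, tuple[VariantCall, Label]]] = {}
    for tumour, pairs in labelled_calls.items():
        present[tumour] = set()
        somatic_calls[tumour] = {}
        for call, label in pairs:
            if call.is_indel or label.label == DISCARDED:
                continue
            present[tumour].add(call.key)
            if label.label == SOMATIC:
                somatic_calls[tumour][call.key] = (call, label)

    result = ClassifiedVariantSet()
    for clade, members in sorted(tumours_by_clade.items(), key=lambda kv: str(kv[0])):
        members = [m for m in members if m in labelled_calls]
        if not members:
            continue
        shared = set.intersection(*(present[m] for m in members))
        defining = shared & panel
        potential = shared - panel

        somatic: dict[Key, SomaticRecord] = {}
        carriers_by_key: dict[Key, set[str]] = {}
        for m in members:
            for key in somatic_calls[m]:
                if key in shared:
                    continue
                carriers_by_key.setdefault(key, set()).add(m)
        for key, carriers in carriers_by_key.items():
            raws, norms = [], []
            for m in sorted(carriers):
                call, _ = somatic_calls[m][key]
                raws.append(call.vaf)
                f = fractions.get(m)
                norms.append(normalize_vaf(call.vaf, f) if f else call.vaf)
            somatic[key] = SomaticRecord(
                key=key,
                carriers=frozenset(carriers),
                mean_raw_vaf=fmean(raws),
                mean_normalized_vaf=fmean(norms),
            )
        putative_keys = {
            key
            for m in members
            for key, (call, label) in somatic_calls[m].items()
            if label.reason == NOTE_PUTATIVE and key not in shared
        }

        conservative = set(somatic)
        conservative -= recomb
        conservative -= putative_keys
        if clade in excluded_clades:
            conservative = set()
        for group_members in trunk_sets.values():
            for key, carriers in carriers_by_key.items():
                if frozenset(carriers) == group_members:
                    conservative.discard(key)

        result.clade_defining[clade] = defining
        result.potential_somatic[clade] = potential
        result.somatic[clade] = somatic
        result.conservative_somatic[clade] = conservative
        result.tumours_by_clade[clade] = tuple(members)

    result.validate()
    return result


def drop_tumour_contamination_from_host(
    host_calls: Sequence[VariantCall],
    known_tumour_variants: Iterable[Key],
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Remove from a low-level tumour-contaminated host any subclonal calls
    matching known tumour variants. Returns (kept, dropped)."""
    known = set(known_tumour_variants)
    kept, dropped = [], []
    for call in host_calls:
        if call.key in known and call.vaf < defaults.GERMLINE_VAF_THRESHOLD:
            dropped.append(call)
        else:
            kept.append(call)
    return kept, dropped
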