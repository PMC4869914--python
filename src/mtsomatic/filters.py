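"""Post-processing filters for substitution and indel calls.

Rules are applied in a fixed, documented order so that the reasons attached
to each verdict are stable. The rescue list can only override the
indel-proximity rule; every other discard reason is terminal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from . import defaults
from .calls import VariantCall, CoverageSummary, group_by_sample
from .reference import MtReference

__all__ = [
    "FilterVerdict",
    "filter_substitutions",
    "filter_indels",
    "flag_recurrence",
    "kept_calls",
]

# substitution discard reasons
REASON_BASE_QUALITY = "base_quality"
REASON_MAPPING_QUALITY = "mapping_quality"
REASON_READ_END = "read_end_only"
REASON_INDEL_PROXIMITY = "indel_proximity"
REASON_REPEAT_REGION = "repeat_region"
REASON_STRAND_BIAS = "strand_bias"
REASON_EXCLUDED_SITE = "excluded_site"
NOTE_RESCUED = "rescued"

# indel discard reasons
REASON_STRAND_SUPPORT = "strand_support"
REASON_PINDEL_SUPPORT = "pindel_support"
REASON_HIGH_COVERAGE_SAMPLE = "high_coverage_sample"

# recurrence flags
FLAG_RECURRENT = "recurrent"
FLAG_BACK_MUTATION = "back_mutation"


@dataclass(frozen=True)
class FilterVerdict:
    variant: VariantCall
    kept: bool
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        discard = [r for r in self.reasons if r != NOTE_RESCUED]
        rescued = NOTE_RESCUED in self.reasons
        if self.kept and discard and not rescued:
            raise ValueError("kept verdict carries unrescued discard reasons")
        if not self.kept and not discard:
            raise ValueError("discarded verdict carries no reason")


def kept_calls(verdicts: Iterable[FilterVerdict]) -> list[VariantCall]:
    return [v.variant for v in verdicts if v.kept]


def _in_region(position: int, region: tuple[int, int]) -> bool:
    return region[0] <= position <= region[1]


def filter_substitutions(
    calls: Sequence[VariantCall],
    ref: MtReference,
    indel_calls: Sequence[VariantCall] = (),
    rescue_list: Iterable[tuple[int, str]] | None = None,
    *,
    excluded_sites: Iterable[tuple[int, str]] | None = None,
    bq_min_fraction: tuple[int, int] = defaults.BASE_QUALITY_FRACTION,
    min_mean_mq: float = defaults.MIN_MEAN_MAPPING_QUALITY,
    indel_proximity_bp: int = defaults.INDEL_PROXIMITY_BP,
    repeat_region: tuple[int, int] = defaults.REPEAT_REGION,
) -> list[FilterVerdict]:
    """Apply the substitution post-processing filters.

    ``indel_calls`` must be the *kept* indels for the same samples (the
    proximity rule is defined against surviving indel calls). The rescue
    list re-admits variants whose only discard reason is indel proximity.
    """
    rescue = set(rescue_list if rescue_list is not None else defaults.RESCUE_LIST)
    site_exclusions = set(
        excluded_sites if excluded_sites is not None else list(ref.excluded_sites)
    )
    indels_by_sample = group_by_sample(indel_calls)
    num, den = bq_min_fraction

    verdicts: list[FilterVerdict] = []
    for call in calls:
        if call.is_indel:
            raise ValueError(f"indel passed to filter_substitutions: {call.key}")
        reasons: list[str] = []

        # 1. base-quality rule: at least `num/den` of mutant reads with BQ>25,
        # compared exactly in integers so ties (e.g. 3 of 9) are kept
        if call.mutant_reads > 0 and call.bq25_reads * den < call.mutant_reads * num:
            reasons.append(REASON_BASE_QUALITY)

        # 2. mean mapping quality
        if call.mean_mq < min_mean_mq:
            reasons.append(REASON_MAPPING_QUALITY)

        # 3. supported only by read ends
        if call.read_end_only:
            reasons.append(REASON_READ_END)

        # 4. proximity to a surviving indel in the same sample
        for indel in indels_by_sample.get(call.sample_id, ()):
            window = indel_proximity_bp + (indel.rep if indel.rep > 0 else 0)
            if abs(call.position - indel.position) <= window:
                reasons.append(REASON_INDEL_PROXIMITY)
                break

        # 5. simple repeat region
        if _in_region(call.position, repeat_region):
            reasons.append(REASON_REPEAT_REGION)

        # 6. strand representation
        if call.fwd_ref >= 1 and call.rev_ref >= 1:
            if call.fwd_mutant < 1 or call.rev_mutant < 1:
                reasons.append(REASON_STRAND_BIAS)

        # 7. configured excluded sites
        if (call.position, call.change) in site_exclusions:
            reasons.append(REASON_EXCLUDED_SITE)

        # 8. rescue: overrides the indel-proximity rule only
        kept = not reasons
        if (
            not kept
            and set(reasons) == {REASON_INDEL_PROXIMITY}
            and (call.position, call.change) in rescue
        ):
            kept = True
            reasons.append(NOTE_RESCUED)

        verdicts.append(FilterVerdict(call, kept, tuple(reasons)))
    return verdicts


def filter_indels(
    indel_calls: Sequence[VariantCall],
    *,
    coverage: Mapping[str, CoverageSummary] | None = None,
    high_coverage_samples: Iterable[str] = (),
    min_strand_reads: int = defaults.INDEL_MIN_STRAND_READS,
    min_both_strand_reads: int = defaults.INDEL_MIN_BOTH_STRAND_READS,
    pindel_check_threshold: int = defaults.INDEL_PINDEL_CHECK_THRESHOLD,
    repeat_region: tuple[int, int] = defaults.REPEAT_REGION,
) -> list[FilterVerdict]:
    """Apply the indel filters.

    High-coverage samples can be supplied explicitly or derived from
    coverage summaries (mean mtDNA coverage above the exclusion threshold).
    """
    excluded_samples = set(high_coverage_samples)
    if coverage:
        excluded_samples |= {s for s, c in coverage.items() if c.high_coverage}

    verdicts: list[FilterVerdict] = []
    for call in indel_calls:
        if not call.is_indel:
            raise ValueError(f"substitution passed to filter_indels: {call.key}")
        reasons: list[str] = []

        fwd, rev = call.fwd_mutant, call.rev_mutant
        one_strand_ok = fwd >= min_strand_reads or rev >= min_strand_reads
        both_strands_ok = fwd >= min_both_strand_reads and rev >= min_both_strand_reads
        if not (one_strand_ok or both_strands_ok):
            reasons.append(REASON_STRAND_SUPPORT)

        if call.pindel_reads >= pindel_check_threshold:
            bwa_ok = call.bwa_reads >= 1
            fallback_ok = call.rep == 0 and fwd >= 1 and rev >= 1
            if not (bwa_ok or fallback_ok):
                reasons.append(REASON_PINDEL_SUPPORT)

        if _in_region(call.position, repeat_region):
            reasons.append(REASON_REPEAT_REGION)

        if call.sample_id in excluded_samples:
            reasons.append(REASON_HIGH_COVERAGE_SAMPLE)

        verdicts.append(FilterVerdict(call, not reasons, tuple(reasons)))
    return verdicts


def flag_recurrence(
    somatic_by_sample: Mapping[str, Iterable[tuple[int, str, str]]],
    group_of: Mapping[str, str | int],
    clade_defining: Mapping[str | int, Iterable[tuple[int, str, str]]] | None = None,
    reference: MtReference | None = None,
) -> dict[tuple[int, str, str], set[str]]:
    """Flag recurrent and back-mutations among somatic variants.

    A somatic variant observed in more than one group that is not
    clade-defining anywhere is flagged ``recurrent``. A somatic call that
    reverts a clade-defining allele of the sample's own group back to the
    reference base is flagged ``back_mutation``.
    """
    clade_defining = clade_defining or {}
    defining_all: set[tuple[int, str, str]] = set()
    for keys in clade_defining.values():
        defining_all.update(keys)

    groups_with: dict[tuple[int, str, str], set] = {}
    for sample, keys in somatic_by_sample.items():
        group = group_of[sample]
        for key in keys:
            groups_with.setdefault(key, set()).add(group)

    flags: dict[tuple[int, str, str], set[str]] = {}
    for key, groups in groups_with.items():
        if len(groups) > 1 and key not in defining_all:
            flags.setdefault(key, set()).add(FLAG_RECURRENT)

    for sample, keys in somatic_by_sample.items():
        group = group_of[sample]
        defining_here = {(p, r, a): (p, a, r) for p, r, a in clade_defining.get(group, ())}
        reversions = set(defining_here.values())
        for key in keys:
            if key in reversions:
                flags.setdefault(key, set()).add(FLAG_BACK_MUTATION)
    return flags
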