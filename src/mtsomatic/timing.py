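"""Clade-divergence timing from somatic mutation burden.

Three independent calibrations of the somatic mtDNA mutation rate turn a
mean per-clade burden into a (maximum) time since mtDNA capture:

* nuclear calibration — a reference clade of known maximum age;
* cell-division calibration — one homoplasmic mutation per ~1000 cell
  generations with bounding generation times;
* externally calibrated per-year rate.

All methods are linear in burden, so the age ordering of clades does not
depend on the method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import fmean
from typing import Mapping, Sequence

from . import defaults

__all__ = [
    "CladeBurden",
    "TimingEstimate",
    "rate_from_nuclear_calibration",
    "time_since_capture",
    "rate_from_cell_divisions",
    "rate_human_calibrated",
    "timing_report",
]

METHOD_NUCLEAR = "nuclear-calibration"
METHOD_CELL_DIVISIONS = "cell-divisions"
METHOD_PER_YEAR = "per-year-rate"


@dataclass(frozen=True)
class CladeBurden:
    """Per-clade somatic mutation counts and their mean."""

    clade: object
    per_tumour_counts: tuple[int, ...]
    burden_override: float | None = None  # e.g. recombination adjustment
    includes_potential_somatic: bool = False

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.per_tumour_counts):
            raise ValueError("somatic counts must be >= 0")
        if not self.per_tumour_counts and self.burden_override is None:
            raise ValueError("empty clade burden")

    @property
    def mean(self) -> float:
        if self.burden_override is not None:
            return self.burden_override
        return fmean(self.per_tumour_counts)


@dataclass(frozen=True)
class TimingEstimate:
    clade: object
    method: str
    rate: float  # mutations / year
    burden: float
    years: float

    def __post_init__(self) -> None:
        if self.years < 0:
            raise ValueError("time since capture must be >= 0")


def rate_from_nuclear_calibration(reference_clade_burden: float, calibration_age_years: float) -> float:
    """Mutations per year implied by a reference clade of known maximum age."""
    if reference_clade_burden <= 0 or calibration_age_years <= 0:
        raise ValueError("burden and calibration age must be positive")
    return reference_clade_burden / calibration_age_years


def time_since_capture(burden: float, rate: float) -> float:
    """Years since mtDNA capture for a given mean burden and rate."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    if burden < 0:
        raise ValueError("burden must be >= 0")
    return burden / rate


def rate_from_cell_divisions(
    generation_days: float,
    mutations_per_1000_generations: float = 1.0,
    days_per_year: float = defaults.DAYS_PER_YEAR,
) -> float:
    """Mutations per year from a cell-generation-time calibration."""
    if generation_days <= 0:
        raise ValueError("generation time must be positive")
    return (mutations_per_1000_generations / 1000.0) * (days_per_year / generation_days)


def rate_human_calibrated(rate: float = defaults.HUMAN_CALIBRATED_RATE) -> float:
    """Externally calibrated constant somatic mtDNA rate (mutations/year)."""
    return rate


def timing_report(
    burdens: Sequence[CladeBurden],
    *,
    reference_clade: object,
    calibration_age_years: float = defaults.NUCLEAR_CALIBRATION_YEARS,
    min_generation_days: float = defaults.MIN_GENERATION_DAYS,
    max_generation_days: float = defaults.MAX_GENERATION_DAYS,
) -> list[TimingEstimate]:
    """Timing of every clade under all three calibrations.

    The nuclear calibration rate is derived from ``reference_clade``'s own
    mean burden and the calibration age.
    """
    by_clade = {b.clade: b for b in burdens}
    if reference_clade not in by_clade:
        raise ValueError(f"reference clade {reference_clade!r} not among burdens")
    nuclear_rate = rate_from_nuclear_calibration(
        by_clade[reference_clade].mean, calibration_age_years
    )
    # generation-time bounds map to rate bounds in reverse order
    rate_slow = rate_from_cell_divisions(max_generation_days)
    rate_fast = rate_from_cell_divisions(min_generation_days)
    per_year = rate_human_calibrated()

    estimates: list[TimingEstimate] = []
    for b in burdens:
        for method, rate in (
            (METHOD_NUCLEAR, nuclear_rate),
            (f"{METHOD_CELL_DIVISIONS}-min-rate", rate_slow),
            (f"{METHOD_CELL_DIVISIONS}-max-rate", rate_fast),
            (METHOD_PER_YEAR, per_year),
        ):
            estimates.append(
                TimingEstimate(
                    clade=b.clade,
                    method=method,
                    rate=rate,
                    burden=b.mean,
                    years=time_since_capture(b.mean, rate),
                )
            )
    return estimates
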