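"""mtDNA copy-number estimation and qPCR standard-curve arithmetic."""

from __future__ import annotations

import math
from dataclasses import dataclass

from . import defaults
from .calls import CoverageSummary

__all__ = [
    "CopyNumberEstimate",
    "QpcrStandardCurve",
    "estimate_copy_number",
    "qpcr_relative_input",
]


@dataclass(frozen=True)
class CopyNumberEstimate:
    sample_id: str
    mt_cov: float
    nucl_cov: float
    ploidy: int
    copies_per_cell: float
    excluded: bool  # mean mtDNA coverage above the exclusion threshold


@dataclass(frozen=True)
class QpcrStandardCurve:
    """Ct = m * log10(input) + b for one qPCR target."""

    slope: float
    intercept: float
    target: str = ""

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("standard-curve slope must be non-zero")


def estimate_copy_number(
    cov: CoverageSummary,
    *,
    high_coverage_x: float = defaults.HIGH_COVERAGE_X,
    purity_correction: float | None = None,
) -> CopyNumberEstimate:
    """Copies per cell = (mtCOV / nuclCOV) * ploidy.

    Samples with mean mtDNA coverage above ``high_coverage_x`` are flagged
    excluded (kept out of cohort averages). Copy numbers are by default not
    corrected for host contamination; pass a tumour fraction as
    ``purity_correction`` to divide it out.
    """
    if cov.nucl_cov <= 0:
        raise ValueError("nuclear coverage must be positive")
    copies = (cov.mt_cov / cov.nucl_cov) * cov.ploidy
    if purity_correction is not None:
        if not 0 < purity_correction <= 1:
            raise ValueError("purity correction must be in (0, 1]")
        copies /= purity_correction
    return CopyNumberEstimate(
        sample_id=cov.sample_id,
        mt_cov=cov.mt_cov,
        nucl_cov=cov.nucl_cov,
        ploidy=cov.ploidy,
        copies_per_cell=copies,
        excluded=cov.mt_cov > high_coverage_x,
    )


def qpcr_relative_input(
    ct: float,
    curve: QpcrStandardCurve,
    normalizer_input: float = 1.0,
) -> float:
    """Relative DNA input from a threshold cycle and a standard curve.

    input = 10 ** ((ct - b) / m), normalized to the normalizer target's
    input amount.
    """
    if normalizer_input <= 0:
        raise ValueError("normalizer input must be positive")
    input_amount = 10.0 ** ((ct - curve.intercept) / curve.slope)
    return input_amount / normalizer_input
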