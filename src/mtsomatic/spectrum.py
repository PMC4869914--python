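"""Strand-specific 96-class mutation spectrum with triplet normalization.

Substitutions are expressed in pyrimidine context: pyrimidine changes on
the reference (light) strand stay as called with reference flanks, purine
changes are complemented onto the heavy strand with heavy-strand flanks.
Observed counts per class are normalized by expected counts derived from
the genome triplet census:

    expected(class with triplet t on strand s) = N * count_s(t) / L / 3

where L is the full genome length (the conventional denominator even when
positions are excluded from the census; ``denominator="included"`` uses the
number of counted positions instead, which makes the expected counts sum
exactly to N).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .calls import VariantCall
from .reference import HEAVY, LIGHT, MtReference, TripletCensus, count_triplets, revcomp, complement

__all__ = [
    "SpectrumClass",
    "SpectrumResult",
    "assign_class",
    "classify_substitution",
    "observed_counts",
    "expected_counts",
    "normalized_rates",
    "compute_spectrum",
    "all_classes",
    "worked_example",
]

PYRIMIDINES = ("C", "T")
BASES = ("A", "C", "G", "T")
SUB_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


@dataclass(frozen=True, order=True)
class SpectrumClass:
    """One of the 96 pyrimidine-context classes on one strand."""

    substitution: str  # e.g. "C>T"
    five_prime: str
    three_prime: str
    strand: str

    def __post_init__(self) -> None:
        if self.substitution not in SUB_TYPES:
            raise ValueError(f"not a pyrimidine substitution: {self.substitution}")
        if self.five_prime not in BASES or self.three_prime not in BASES:
            raise ValueError("flanking bases must be A/C/G/T")
        if self.strand not in (HEAVY, LIGHT):
            raise ValueError(f"unknown strand {self.strand!r}")

    @property
    def triplet(self) -> str:
        return self.five_prime + self.substitution[0] + self.three_prime

    @property
    def label(self) -> str:
        ref, alt = self.substitution.split(">")
        return f"{self.five_prime}[{ref}>{alt}]{self.three_prime}/{self.strand}"


def all_classes() -> list[SpectrumClass]:
    return [
        SpectrumClass(sub, five, three, strand)
        for strand in (HEAVY, LIGHT)
        for sub in SUB_TYPES
        for five in BASES
        for three in BASES
    ]


def assign_class(ref: MtReference, variant: VariantCall) -> SpectrumClass:
    """Assign a substitution call to its pyrimidine-context class and strand."""
    if variant.is_indel:
        raise ValueError("indels have no spectrum class")
    return classify_substitution(ref, variant.position, variant.ref, variant.alt)


def classify_substitution(
    ref: MtReference, position: int, ref_base: str, alt_base: str
) -> SpectrumClass:
    """Pyrimidine-context class for a bare (position, ref, alt) substitution."""
    ref_base, alt_base = ref_base.upper(), alt_base.upper()
    if ref.base(position) != ref_base:
        raise ValueError(
            f"reference mismatch at {position}: "
            f"{ref.base(position)} != {ref_base}"
        )
    light_triplet = ref.triplet(position, LIGHT)
    if ref_base in PYRIMIDINES:
        return SpectrumClass(
            substitution=f"{ref_base}>{alt_base}",
            five_prime=light_triplet[0],
            three_prime=light_triplet[2],
            strand=LIGHT,
        )
    heavy_triplet = revcomp(light_triplet)
    return SpectrumClass(
        substitution=f"{complement(ref_base)}>{complement(alt_base)}",
        five_prime=heavy_triplet[0],
        three_prime=heavy_triplet[2],
        strand=HEAVY,
    )


def observed_counts(
    ref: MtReference, variants: Iterable[VariantCall]
) -> Counter[SpectrumClass]:
    counts: Counter[SpectrumClass] = Counter()
    for v in variants:
        counts[assign_class(ref, v)] += 1
    return counts


def expected_counts(
    light_census: TripletCensus,
    heavy_census: TripletCensus,
    n_total: float,
    genome_length: int,
    *,
    presentation_rounding: bool = False,
    denominator: str = "genome_length",
) -> dict[SpectrumClass, float]:
    """Expected count per class: N * triplet frequency / 3.

    In presentation mode the triplet frequency is rounded to 3 decimal
    places before use, matching hand-calculated published values.
    """
    if n_total < 0:
        raise ValueError("n_total must be >= 0")
    census_of = {LIGHT: light_census, HEAVY: heavy_census}
    for census in census_of.values():
        if census.n_counted == 0:
            raise ValueError("empty triplet census")
    if denominator == "genome_length":
        denom = genome_length
    elif denominator == "included":
        denom = light_census.n_counted
    else:
        raise ValueError(f"unknown denominator mode {denominator!r}")
    out: dict[SpectrumClass, float] = {}
    for cls in all_classes():
        freq = census_of[cls.strand].count(cls.triplet) / denom
        if presentation_rounding:
            freq = round(freq, 3)
        out[cls] = n_total * freq / 3
    return out


@dataclass
class SpectrumResult:
    """Observed, expected and normalized rates for all 192 strand-classes."""

    observed: Mapping[SpectrumClass, int]
    expected: Mapping[SpectrumClass, float]
    rates: Mapping[SpectrumClass, float]
    infinite_classes: tuple[SpectrumClass, ...]
    n_total: int

    def rate(self, cls: SpectrumClass) -> float:
        return self.rates[cls]

    def top_class(self) -> SpectrumClass:
        return max(self.rates, key=lambda c: (self.rates[c], c.label))

    def to_rows(self) -> list[dict]:
        rows = []
        for cls in sorted(self.rates):
            rows.append(
                {
                    "class": cls.label,
                    "strand": cls.strand,
                    "substitution": cls.substitution,
                    "triplet": cls.triplet,
                    "observed": self.observed.get(cls, 0),
                    "expected": self.expected.get(cls, 0.0),
                    "normalized_rate": self.rates[cls],
                }
            )
        return rows


def normalized_rates(
    observed: Mapping[SpectrumClass, int],
    expected: Mapping[SpectrumClass, float],
    *,
    presentation_rounding: bool = False,
) -> SpectrumResult:
    """Observed/expected ratio per class.

    Classes with expected 0 and observed 0 get rate 0; expected 0 with
    observed > 0 is reported as infinite (and listed), never dropped. In
    presentation mode expected counts are rounded to 2 dp before dividing.
    """
    rates: dict[SpectrumClass, float] = {}
    infinite: list[SpectrumClass] = []
    for cls in expected:
        obs = observed.get(cls, 0)
        exp = expected[cls]
        if presentation_rounding:
            exp = round(exp, 2)
        if exp == 0:
            if obs == 0:
                rates[cls] = 0.0
            else:
                rates[cls] = float("inf")
                infinite.append(cls)
        else:
            rates[cls] = obs / exp
    return SpectrumResult(
        observed=dict(observed),
        expected=dict(expected),
        rates=rates,
        infinite_classes=tuple(infinite),
        n_total=sum(observed.values()),
    )


def compute_spectrum(
    ref: MtReference,
    variants: Sequence[VariantCall],
    *,
    presentation_rounding: bool = False,
    denominator: str = "genome_length",
) -> SpectrumResult:
    """Full spectrum for a set of substitutions (the conservative list)."""
    light = count_triplets(ref, LIGHT)
    heavy = count_triplets(ref, HEAVY)
    obs = observed_counts(ref, variants)
    exp = expected_counts(
        light,
        heavy,
        n_total=len(variants),
        genome_length=ref.length,
        presentation_rounding=presentation_rounding,
        denominator=denominator,
    )
    return normalized_rates(obs, exp, presentation_rounding=presentation_rounding)


def worked_example(
    n_total: int,
    triplet_count: int,
    genome_length: int,
    observed: int,
    *,
    presentation_rounding: bool = True,
) -> tuple[float, float, float]:
    """Frequency, expected count and normalized rate for a single class
    computed from printed census numbers.

    Returns (frequency, expected, rate); in presentation mode each stage is
    rounded as in hand calculation (3 dp, 2 dp, 2 dp).
    """
    freq = triplet_count / genome_length
    if presentation_rounding:
        freq = round(freq, 3)
    expected = n_total * freq / 3
    if presentation_rounding:
        expected = round(expected, 2)
    rate = observed / expected
    if presentation_rounding:
        rate = round(rate, 2)
    return freq, expected, rate
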