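"""Negative-selection inference.

Two complementary signals:

* VAF cumulative-distribution comparisons between truncating and
  non-truncating variants (two-sample Kolmogorov-Smirnov);
* a context-dependent Poisson dN/dS with 192 substitution-in-context rates
  and selection coefficients for missense and nonsense changes, tested for
  deviation from neutrality by likelihood-ratio tests, with
  profile-likelihood 95% confidence intervals.

Counts are modelled as n_{j,i} ~ Poisson(r_j * L_{j,i} * w_i) with
w_syn = 1; the context rates r_j profile out in closed form, leaving a
two-parameter concentrated likelihood in (w_mis, w_non).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .calls import VariantCall
from .classify import ClassifiedVariantSet
from .reference import (
    HEAVY,
    MISSENSE,
    NONSENSE,
    NON_CODING,
    SYNONYMOUS,
    MtReference,
    annotate_consequence,
)

__all__ = [
    "KsComparison",
    "DnDsFit",
    "ks_vaf_test",
    "truncating_vs_other_comparisons",
    "count_opportunities",
    "count_observed_by_context",
    "dnds_fit",
    "Context",
]

IMPACTS = (SYNONYMOUS, MISSENSE, NONSENSE)

Context = tuple[str, str, str]  # (substitution "X>Y", 5' base, 3' base), reference strand
Key = tuple[int, str, str]

_CHI2_95 = stats.chi2.ppf(0.95, 1)  # 3.841...; /2 on the log-likelihood scale


@dataclass(frozen=True)
class KsComparison:
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    statistic: float
    pvalue: float

    def __post_init__(self) -> None:
        if not 0 <= self.statistic <= 1 or not 0 <= self.pvalue <= 1:
            raise ValueError("KS statistic and p-value must be in [0, 1]")


def ks_vaf_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    label_a: str = "A",
    label_b: str = "B",
    *,
    exact_limit: int = 10_000,
) -> KsComparison:
    """Two-sided two-sample KS test; exact p-value for small samples."""
    if len(values_a) == 0 or len(values_b) == 0:
        raise ValueError("both groups must be non-empty")
    method = "exact" if len(values_a) * len(values_b) <= exact_limit else "asymp"
    res = stats.ks_2samp(values_a, values_b, alternative="two-sided", method=method)
    return KsComparison(
        label_a=label_a,
        label_b=label_b,
        n_a=len(values_a),
        n_b=len(values_b),
        statistic=float(res.statistic),
        pvalue=float(min(res.pvalue, 1.0)),
    )


def truncating_vs_other_comparisons(
    classified: ClassifiedVariantSet,
    ref: MtReference,
    somatic_indels: Sequence[tuple[VariantCall, float]] = (),
) -> dict[str, KsComparison | None]:
    """Truncating-vs-other VAF comparisons for substitutions and indels.

    Substitutions use mean normalized VAFs from the conservative-somatic
    list: nonsense vs missense+synonymous. Indels are supplied as
    (call, normalized VAF) pairs: frameshift vs non-frameshift. A missing
    group yields None for that comparison.
    """
    nonsense, other = [], []
    for record in classified.conservative_records():
        pos, ref_base, alt_base = record.key
        consequence = annotate_consequence(ref, pos, ref_base, alt_base)
        if consequence == NONSENSE:
            nonsense.append(record.mean_normalized_vaf)
        elif consequence in (MISSENSE, SYNONYMOUS):
            other.append(record.mean_normalized_vaf)

    out: dict[str, KsComparison | None] = {}
    if nonsense and other:
        out["substitutions"] = ks_vaf_test(
            nonsense, other, "nonsense", "missense+synonymous"
        )
    else:
        out["substitutions"] = None

    frameshift = [vaf for call, vaf in somatic_indels if call.is_frameshift]
    inframe = [vaf for call, vaf in somatic_indels if call.is_indel and not call.is_frameshift]
    if frameshift and inframe:
        out["indels"] = ks_vaf_test(frameshift, inframe, "frameshift", "non-frameshift")
    else:
        out["indels"] = None
    return out


# ---------------------------------------------------------------------------
# dN/dS

def _contexts() -> list[Context]:
    bases = "ACGT"
    return [
        (f"{b}>{a}", five, three)
        for b in bases
        for a in bases
        if a != b
        for five in bases
        for three in bases
    ]


def count_opportunities(
    ref: MtReference,
    *,
    respect_exclusions: bool = True,
) -> dict[Context, dict[str, int]]:
    """Opportunity counts L_{j,impact} over heavy-strand coding sites.

    Every possible substitution at every included coding position of every
    heavy-strand-transcribed gene is enumerated and classified; the single
    light-strand gene (the ND6 analogue) contributes nothing. Contexts are
    expressed on the reference strand.
    """
    excluded = ref.excluded_positions if respect_exclusions else frozenset()
    L: dict[Context, dict[str, int]] = {}
    any_coding = False
    for gene in ref.genes:
        if not gene.coding or gene.strand != HEAVY:
            continue
        for position in range(gene.start, gene.end + 1):
            if position in excluded:
                continue
            if ref.codon_at(position) is None:
                continue  # frame offset / incomplete terminal codon
            any_coding = True
            ref_base = ref.base(position)
            triplet = ref.triplet(position)
            for alt in "ACGT":
                if alt == ref_base:
                    continue
                impact = annotate_consequence(ref, position, ref_base, alt)
                context = (f"{ref_base}>{alt}", triplet[0], triplet[2])
                slot = L.setdefault(
                    context, {SYNONYMOUS: 0, MISSENSE: 0, NONSENSE: 0}
                )
                slot[impact] += 1
    if not any_coding:
        raise ValueError("reference has no included heavy-strand coding sites")
    return L


def count_observed_by_context(
    ref: MtReference,
    keys: Iterable[Key],
) -> dict[Context, dict[str, int]]:
    """Observed substitution counts by context and impact.

    Non-coding and light-strand-gene substitutions are ignored, mirroring
    the opportunity enumeration.
    """
    n: dict[Context, dict[str, int]] = {}
    for position, ref_base, alt_base in keys:
        gene = ref.gene_at(position)
        if gene is None or not gene.coding or gene.strand != HEAVY:
            continue
        impact = annotate_consequence(ref, position, ref_base, alt_base)
        if impact == NON_CODING:
            continue
        triplet = ref.triplet(position)
        context = (f"{ref_base}>{alt_base}", triplet[0], triplet[2])
        slot = n.setdefault(context, {SYNONYMOUS: 0, MISSENSE: 0, NONSENSE: 0})
        slot[impact] += 1
    return n


@dataclass
class DnDsFit:
    w_mis: float
    w_non: float
    loglik: float
    loglik_null_mis: float
    loglik_null_non: float
    lrt_mis: float
    lrt_non: float
    p_mis: float
    p_non: float
    ci_mis: tuple[float, float]
    ci_non: tuple[float, float]
    rates: dict[Context, float]
    n_contexts: int

    def __post_init__(self) -> None:
        if self.w_mis < 0 or self.w_non < 0:
            raise ValueError("selection coefficients must be >= 0")
        if self.lrt_mis < 0 or self.lrt_non < 0:
            raise ValueError("LRT statistics must be >= 0")


def _assemble(observed, opportunities):
    contexts = sorted(opportunities)
    L = np.array(
        [[opportunities[c][i] for i in IMPACTS] for c in contexts], dtype=float
    )
    n = np.zeros_like(L)
    for j, c in enumerate(contexts):
        slot = observed.get(c)
        if slot:
            n[j] = [slot[i] for i in IMPACTS]
    stray = set(observed) - set(contexts)
    for c in stray:
        if any(observed[c].values()):
            raise ValueError(f"observed counts in context {c} with zero opportunity")
    keep = L.sum(axis=1) > 0
    return [c for c, k in zip(contexts, keep) if k], L[keep], n[keep]


def _loglik(w: np.ndarray, L: np.ndarray, n: np.ndarray) -> float:
    """Exact Poisson log-likelihood with rates profiled out at given w."""
    weights = np.array([1.0, w[0], w[1]])
    denom = L @ weights
    n_tot = n.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, n_tot / np.where(denom > 0, denom, 1.0), 0.0)
    mean = r[:, None] * L * weights[None, :]
    mask = n > 0
    if np.any(mask & (mean == 0)):
        return -np.inf
    return float(
        np.sum(n[mask] * np.log(mean[mask]))
        - np.sum(mean)
        - np.sum(_log_factorial(n[mask]))
    )


def _log_factorial(x: np.ndarray) -> np.ndarray:
    from scipy.special import gammaln

    return gammaln(np.asarray(x, dtype=float) + 1.0)


def _profile_rates(w: np.ndarray, L: np.ndarray, n: np.ndarray) -> np.ndarray:
    weights = np.array([1.0, w[0], w[1]])
    denom = L @ weights
    n_tot = n.sum(axis=1)
    return np.where(denom > 0, n_tot / np.where(denom > 0, denom, 1.0), 0.0)


def _maximize(L, n, fixed: dict[int, float] | None = None) -> tuple[np.ndarray, float]:
    """Maximize the concentrated likelihood over free w components.

    ``fixed`` maps index (0 = mis, 1 = non) to a fixed value.
    """
    fixed = fixed or {}
    free = [i for i in (0, 1) if i not in fixed]

    def build(x):
        w = np.empty(2)
        for i, v in fixed.items():
            w[i] = v
        for i, v in zip(free, x):
            w[i] = math.exp(v)
        return w

    # boundary case: zero observed counts for a free impact => w_hat = 0
    totals = n.sum(axis=0)  # syn, mis, non
    boundary = {}
    for i in list(free):
        if totals[i + 1] == 0:
            boundary[i] = 0.0
            free.remove(i)

    def neg(x):
        w = build(x)
        for i, v in boundary.items():
            w[i] = v
        return -_loglik(w, L, n)

    if free:
        x0 = np.zeros(len(free))
        res = optimize.minimize(neg, x0, method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
        x = res.x
    else:
        x = np.empty(0)
    w = build(x)
    for i, v in boundary.items():
        w[i] = v
    return w, _loglik(w, L, n)


def _profile_ci(index: int, w_hat: np.ndarray, ll_hat: float, L, n) -> tuple[float, float]:
    """95% profile-likelihood interval for w[index]."""
    target = ll_hat - _CHI2_95 / 2.0

    def profile(value: float) -> float:
        _, ll = _maximize(L, n, fixed={index: value})
        return ll - target

    mle = w_hat[index]
    # lower bound
    if mle <= 0 or profile(max(mle * 1e-6, 1e-9)) > 0:
        lower = 0.0
    else:
        lower = optimize.brentq(profile, max(mle * 1e-6, 1e-9), mle, xtol=1e-6)
    # upper bound
    hi = max(mle, 1e-3) * 2
    for _ in range(60):
        if profile(hi) < 0:
            break
        hi *= 2
    else:
        return lower, math.inf
    upper = optimize.brentq(profile, max(mle, 1e-9), hi, xtol=1e-6)
    return lower, upper


def dnds_fit(
    observed: Mapping[Context, Mapping[str, int]],
    opportunities: Mapping[Context, Mapping[str, int]],
    *,
    compute_ci: bool = True,
) -> DnDsFit:
    """Fit the context-dependent Poisson selection model.

    Returns MLEs for (w_mis, w_non) with per-coefficient likelihood-ratio
    tests against w = 1 and profile-likelihood 95% CIs.
    """
    contexts, L, n = _assemble(observed, opportunities)
    if n.sum() == 0:
        raise ValueError("no observed substitutions in any context")

    w_hat, ll_hat = _maximize(L, n)
    _, ll0_mis = _maximize(L, n, fixed={0: 1.0})
    _, ll0_non = _maximize(L, n, fixed={1: 1.0})

    lrt_mis = max(2.0 * (ll_hat - ll0_mis), 0.0)
    lrt_non = max(2.0 * (ll_hat - ll0_non), 0.0)

    if compute_ci:
        ci_mis = _profile_ci(0, w_hat, ll_hat, L, n)
        ci_non = _profile_ci(1, w_hat, ll_hat, L, n)
    else:
        ci_mis = (math.nan, math.nan)
        ci_non = (math.nan, math.nan)

    rates = dict(zip(contexts, _profile_rates(w_hat, L, n)))
    return DnDsFit(
        w_mis=float(w_hat[0]),
        w_non=float(w_hat[1]),
        loglik=ll_hat,
        loglik_null_mis=ll0_mis,
        loglik_null_non=ll0_non,
        lrt_mis=lrt_mis,
        lrt_non=lrt_non,
        p_mis=float(stats.chi2.sf(lrt_mis, 1)),
        p_non=float(stats.chi2.sf(lrt_non, 1)),
        ci_mis=ci_mis,
        ci_non=ci_non,
        rates=rates,
        n_contexts=len(contexts),
    )
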