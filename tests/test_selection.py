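"""Selection inference: KS tests with combinatorial oracle, opportunity
enumeration with brute-force oracle, dN/dS closed form and recovery."""

from __future__ import annotations

import itertools
import math
import random

import numpy as np
import pytest

from mtsomatic.reference import (
    HEAVY,
    LIGHT,
    GeneAnnotation,
    MtReference,
    annotate_consequence,
)
from mtsomatic.selection import (
    IMPACTS,
    count_observed_by_context,
    count_opportunities,
    dnds_fit,
    ks_vaf_test,
    truncating_vs_other_comparisons,
)


class TestKs:
    def test_identical_samples(self):
        res = ks_vaf_test([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_disjoint_supports(self):
        res = ks_vaf_test([0.1, 0.2], [0.8, 0.9])
        assert res.statistic == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            ks_vaf_test([], [0.5])

    def test_exact_small_n_matches_enumeration(self):
        a = [0.11, 0.47, 0.62]
        b = [0.25, 0.33, 0.91]

        def ks_stat(x, y):
            pooled = sorted(set(x) | set(y))
            d = 0.0
            for v in pooled:
                fx = sum(1 for t in x if t <= v) / len(x)
                fy = sum(1 for t in y if t <= v) / len(y)
                d = max(d, abs(fx - fy))
            return d

        observed_d = ks_stat(a, b)
        pooled = a + b
        count = 0
        total = 0
        for combo in itertools.combinations(range(6), 3):
            x = [pooled[i] for i in combo]
            y = [pooled[i] for i in range(6) if i not in combo]
            total += 1
            if ks_stat(x, y) >= observed_d - 1e-12:
                count += 1
        res = ks_vaf_test(a, b)
        assert res.statistic == pytest.approx(observed_d)
        assert res.pvalue == pytest.approx(count / total)


class TestTruncatingComparisons:
    def test_empty_group_skipped(self, toy_reference):
        from mtsomatic.classify import ClassifiedVariantSet

        empty = ClassifiedVariantSet(
            clade_defining={1: set()},
            potential_somatic={1: set()},
            somatic={1: {}},
            conservative_somatic={1: set()},
            tumours_by_clade={1: ("t1",)},
        )
        out = truncating_vs_other_comparisons(empty, toy_reference)
        assert out["substitutions"] is None
        assert out["indels"] is None


def _toy_coding_reference(n_codons=9, seed=7, include_light=False):
    rng = random.Random(seed)
    cds = "".join(rng.choice("ACGT") for _ in range(3 * n_codons))
    pad = "".join(rng.choice("ACGT") for _ in range(12))
    genes = [GeneAnnotation("g", 13, 12 + 3 * n_codons, HEAVY)]
    seq = pad + cds
    if include_light:
        light_cds = "".join(rng.choice("ACGT") for _ in range(9))
        genes.append(
            GeneAnnotation("nd6ish", len(seq) + 4, len(seq) + 12, LIGHT))
        seq = seq + "AAA" + light_cds
    seq = seq + "".join(rng.choice("ACGT") for _ in range(9))
    return MtReference(seq, genes=genes)


class TestOpportunities:
    def test_conservation(self):
        ref = _toy_coding_reference()
        L = count_opportunities(ref)
        total = sum(sum(slot.values()) for slot in L.values())
        assert total == 3 * 27  # three alts per coding site

    def test_matches_bruteforce_oracle(self):
        ref = _toy_coding_reference()
        L = count_opportunities(ref)
        oracle: dict = {}
        gene = ref.genes[0]
        for pos in range(gene.start, gene.end + 1):
            base = ref.base(pos)
            for alt in "ACGT":
                if alt == base:
                    continue
                impact = annotate_consequence(ref, pos, base, alt)
                ctx = (f"{base}>{alt}", ref.base(pos - 1), ref.base(pos + 1))
                oracle.setdefault(ctx, dict.fromkeys(IMPACTS, 0))
                oracle[ctx][impact] += 1
        assert L == oracle

    def test_light_gene_excluded(self):
        ref = _toy_coding_reference(include_light=True)
        L = count_opportunities(ref)
        light = ref.genes[1]
        total = sum(sum(slot.values()) for slot in L.values())
        assert total == 3 * 27  # unchanged: light-gene sites contribute 0
        # and observed counting also skips the light gene
        pos = light.start + 1
        key = (pos, ref.base(pos), "A" if ref.base(pos) != "A" else "C")
        assert count_observed_by_context(ref, [key]) == {}

    def test_no_coding_sites_rejected(self):
        with pytest.raises(ValueError, match="coding"):
            count_opportunities(MtReference("ACGT" * 10))


def _single_context_tables(n_syn, n_mis, n_non, l_syn=100, l_mis=300, l_non=30):
    ctx = ("C>T", "A", "A")
    L = {ctx: {"synonymous": l_syn, "missense": l_mis, "nonsense": l_non}}
    n = {ctx: {"synonymous": n_syn, "missense": n_mis, "nonsense": n_non}}
    return n, L


class TestDnDsFit:
    def test_single_context_closed_form(self):
        n, L = _single_context_tables(20, 30, 2)
        fit = dnds_fit(n, L, compute_ci=False)
        w_mis_expected = (30 / 300) / (20 / 100)
        w_non_expected = (2 / 30) / (20 / 100)
        assert fit.w_mis == pytest.approx(w_mis_expected, rel=1e-4)
        assert fit.w_non == pytest.approx(w_non_expected, rel=1e-4)

    def test_zero_nonsense_boundary(self):
        n, L = _single_context_tables(20, 30, 0)
        fit = dnds_fit(n, L, compute_ci=False)
        assert fit.w_non == 0.0

    def test_lrt_nonnegative_and_null_below_alt(self):
        n, L = _single_context_tables(25, 10, 1)
        fit = dnds_fit(n, L)
        assert fit.lrt_mis >= 0 and fit.lrt_non >= 0
        assert fit.loglik_null_mis <= fit.loglik + 1e-9
        assert fit.loglik_null_non <= fit.loglik + 1e-9

    def test_local_optimality(self):
        from mtsomatic.selection import _assemble, _loglik

        n, L = _single_context_tables(25, 40, 3)
        fit = dnds_fit(n, L, compute_ci=False)
        _, Lm, nm = _assemble(n, L)
        best = _loglik(np.array([fit.w_mis, fit.w_non]), Lm, nm)
        for dm, dn in [(1.05, 1.0), (0.95, 1.0), (1.0, 1.1), (1.0, 0.9)]:
            perturbed = _loglik(
                np.array([fit.w_mis * dm, fit.w_non * dn]), Lm, nm)
            assert perturbed <= best + 1e-9

    def test_profile_ci_brackets_mle(self):
        n, L = _single_context_tables(40, 60, 5)
        fit = dnds_fit(n, L)
        assert fit.ci_mis[0] < fit.w_mis < fit.ci_mis[1]
        assert fit.ci_non[0] < fit.w_non < fit.ci_non[1]

    def test_all_zero_counts_rejected(self):
        n, L = _single_context_tables(0, 0, 0)
        with pytest.raises(ValueError, match="no observed"):
            dnds_fit(n, L)

    def test_observed_without_opportunity_rejected(self):
        n, L = _single_context_tables(5, 5, 1)
        n[("G>A", "C", "C")] = {"synonymous": 1, "missense": 0, "nonsense": 0}
        with pytest.raises(ValueError, match="zero opportunity"):
            dnds_fit(n, L)

    def test_pvalues_roughly_uniform_under_null(self):
        # Poisson-count-level null simulation over many contexts
        rng = np.random.default_rng(42)
        ref = _toy_coding_reference(n_codons=60, seed=3)
        L = count_opportunities(ref)
        pvals = []
        for _ in range(60):
            n = {}
            for ctx, slot in L.items():
                rate = rng.uniform(0.02, 0.2)
                n[ctx] = {
                    impact: int(rng.poisson(rate * slot[impact]))
                    for impact in IMPACTS
                }
            fit = dnds_fit(n, L, compute_ci=False)
            pvals.append(fit.p_mis)
        from scipy import stats as sps

        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestRecovery:
    def test_neutral_recovery_single_replicate(self, cohort):
        from mtsomatic.simulate import draw_somatic_mutations, substream

        ref = _toy_coding_reference(n_codons=600, seed=9)
        rng = substream(123, "neutral-recovery")
        mutations = draw_somatic_mutations(ref, 2500, rng)
        keys = [k for k, _ in mutations]
        observed = count_observed_by_context(ref, keys)
        fit = dnds_fit(observed, count_opportunities(ref), compute_ci=False)
        assert 0.8 <= fit.w_mis <= 1.25
        assert 0.8 <= fit.w_non <= 1.25
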