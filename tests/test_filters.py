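"""Substitution and indel filters: each rule, rescue, idempotence,
reason-count reconciliation, recurrence flagging."""

from __future__ import annotations

import pytest

from mtsomatic.calls import CoverageSummary, VariantCall
from mtsomatic.filters import (
    FLAG_BACK_MUTATION,
    FLAG_RECURRENT,
    REASON_BASE_QUALITY,
    REASON_EXCLUDED_SITE,
    REASON_HIGH_COVERAGE_SAMPLE,
    REASON_INDEL_PROXIMITY,
    REASON_MAPPING_QUALITY,
    REASON_PINDEL_SUPPORT,
    REASON_READ_END,
    REASON_REPEAT_REGION,
    REASON_STRAND_BIAS,
    REASON_STRAND_SUPPORT,
    FilterVerdict,
    filter_indels,
    filter_substitutions,
    flag_recurrence,
    kept_calls,
)
from mtsomatic.reference import MtReference

REF = MtReference("ACGT" * 5000)  # 20 kb, large enough for default regions


def sub(position=100, sample="t1", **kwargs):
    base = dict(
        sample_id=sample,
        position=position,
        ref=REF.base(position),
        alt={"A": "G", "C": "T", "G": "A", "T": "C"}[REF.base(position)],
        kind="substitution",
        mutant_reads=30,
        total_depth=70,
        fwd_mutant=15,
        rev_mutant=15,
        fwd_ref=20,
        rev_ref=20,
        bq25_reads=28,
        mean_mq=60.0,
    )
    base.update(kwargs)
    return VariantCall(**base)


def indel(position=500, sample="t1", **kwargs):
    base = dict(
        sample_id=sample,
        position=position,
        ref=REF.base(position),
        alt=REF.base(position) + "TT",
        kind="insertion",
        mutant_reads=10,
        total_depth=70,
        fwd_mutant=5,
        rev_mutant=5,
        pindel_reads=10,
        bwa_reads=8,
        bq25_reads=10,
    )
    base.update(kwargs)
    return VariantCall(**base)


def one(verdicts):
    assert len(verdicts) == 1
    return verdicts[0]


class TestSubstitutionRules:
    def test_clean_call_kept(self):
        v = one(filter_substitutions([sub()], REF))
        assert v.kept and v.reasons == ()

    def test_bq_rule_below_third(self):
        v = one(filter_substitutions(
            [sub(mutant_reads=9, fwd_mutant=5, rev_mutant=4, bq25_reads=2)], REF))
        assert not v.kept and REASON_BASE_QUALITY in v.reasons

    def test_bq_rule_exact_third_kept(self):
        v = one(filter_substitutions(
            [sub(mutant_reads=9, fwd_mutant=5, rev_mutant=4, bq25_reads=3)], REF))
        assert v.kept

    def test_mapping_quality(self):
        v = one(filter_substitutions([sub(mean_mq=20.9)], REF))
        assert not v.kept and REASON_MAPPING_QUALITY in v.reasons

    def test_read_end_only(self):
        v = one(filter_substitutions([sub(read_end_only=True)], REF))
        assert not v.kept and REASON_READ_END in v.reasons

    def test_repeat_region(self):
        v = one(filter_substitutions([sub(position=16200)], REF))
        assert not v.kept and REASON_REPEAT_REGION in v.reasons

    def test_repeat_region_boundaries(self):
        inside = [sub(position=16129), sub(position=16430)]
        outside = [sub(position=16128), sub(position=16431)]
        for v in filter_substitutions(inside, REF):
            assert REASON_REPEAT_REGION in v.reasons
        for v in filter_substitutions(outside, REF):
            assert REASON_REPEAT_REGION not in v.reasons

    def test_strand_rule(self):
        v = one(filter_substitutions(
            [sub(mutant_reads=30, fwd_mutant=30, rev_mutant=0)], REF))
        assert not v.kept and REASON_STRAND_BIAS in v.reasons

    def test_strand_rule_inactive_when_ref_one_sided(self):
        v = one(filter_substitutions(
            [sub(mutant_reads=30, fwd_mutant=30, rev_mutant=0,
                 fwd_ref=40, rev_ref=0)], REF))
        assert v.kept

    def test_indel_proximity_default_window(self):
        near = one(filter_substitutions([sub(position=508)], REF, [indel(500)]))
        far = one(filter_substitutions([sub(position=511)], REF, [indel(500)]))
        assert not near.kept and REASON_INDEL_PROXIMITY in near.reasons
        assert far.kept

    def test_indel_proximity_extended_by_rep(self):
        v = one(filter_substitutions([sub(position=513)], REF, [indel(500, rep=3)]))
        assert not v.kept and REASON_INDEL_PROXIMITY in v.reasons

    def test_indel_proximity_other_sample_ignored(self):
        v = one(filter_substitutions(
            [sub(position=505)], REF, [indel(500, sample="other")]))
        assert v.kept

    def test_excluded_site(self):
        call = sub(position=1000)
        ref = MtReference(REF.sequence, excluded_sites=[(1000, call.change)])
        v = one(filter_substitutions([call], ref))
        assert not v.kept and REASON_EXCLUDED_SITE in v.reasons

    def test_rescue_overrides_proximity_only(self):
        call = sub(position=505)
        rescued = one(filter_substitutions(
            [call], REF, [indel(500)], rescue_list=[(505, call.change)]))
        assert rescued.kept and REASON_INDEL_PROXIMITY in rescued.reasons

        bad = sub(position=505, mean_mq=10.0)
        not_rescued = one(filter_substitutions(
            [bad], REF, [indel(500)], rescue_list=[(505, bad.change)]))
        assert not not_rescued.kept

    def test_indel_input_rejected(self):
        with pytest.raises(ValueError, match="indel"):
            filter_substitutions([indel()], REF)


class TestIndelRules:
    def test_three_on_one_strand_kept(self):
        v = one(filter_indels([indel(mutant_reads=3, fwd_mutant=3, rev_mutant=0,
                                     pindel_reads=3, bq25_reads=3)]))
        assert v.kept

    def test_two_on_both_strands_kept(self):
        v = one(filter_indels([indel(mutant_reads=4, fwd_mutant=2, rev_mutant=2,
                                     pindel_reads=3, bq25_reads=4)]))
        assert v.kept

    def test_one_and_one_discarded(self):
        v = one(filter_indels([indel(mutant_reads=2, fwd_mutant=1, rev_mutant=1,
                                     pindel_reads=2, bq25_reads=2)]))
        assert not v.kept and REASON_STRAND_SUPPORT in v.reasons

    def test_pindel_rule_needs_bwa_or_fallback(self):
        no_bwa = one(filter_indels([indel(pindel_reads=5, bwa_reads=0, rep=2)]))
        assert not no_bwa.kept and REASON_PINDEL_SUPPORT in no_bwa.reasons
        fallback = one(filter_indels(
            [indel(pindel_reads=5, bwa_reads=0, rep=0,
                   mutant_reads=6, fwd_mutant=3, rev_mutant=3, bq25_reads=6)]))
        assert fallback.kept

    def test_repeat_region(self):
        v = one(filter_indels([indel(position=16200)]))
        assert not v.kept and REASON_REPEAT_REGION in v.reasons

    def test_high_coverage_sample_excluded(self):
        cov = {"t1": CoverageSummary("t1", 400.0, 0.3)}
        v = one(filter_indels([indel()], coverage=cov))
        assert not v.kept and REASON_HIGH_COVERAGE_SAMPLE in v.reasons

    def test_substitution_input_rejected(self):
        with pytest.raises(ValueError, match="substitution"):
            filter_indels([sub()])


class TestProperties:
    def _mixed_calls(self):
        return [
            sub(position=100),
            sub(position=505),
            sub(position=16200),
            sub(position=900, mean_mq=5.0),
            sub(position=1200, mutant_reads=9, fwd_mutant=5, rev_mutant=4,
                bq25_reads=1),
        ]

    def test_idempotent(self):
        indels = [indel(500)]
        first = filter_substitutions(self._mixed_calls(), REF, indels)
        second = filter_substitutions(kept_calls(first), REF, indels)
        assert all(v.kept for v in second)
        assert kept_calls(second) == kept_calls(first)

    def test_reason_counts_reconcile(self):
        verdicts = filter_substitutions(self._mixed_calls(), REF, [indel(500)])
        discarded = [v for v in verdicts if not v.kept]
        assert len(verdicts) - len(kept_calls(verdicts)) == len(discarded)
        assert all(v.reasons for v in discarded)

    def test_verdict_invariants_enforced(self):
        with pytest.raises(ValueError):
            FilterVerdict(sub(), kept=True, reasons=(REASON_REPEAT_REGION,))
        with pytest.raises(ValueError):
            FilterVerdict(sub(), kept=False, reasons=())


class TestRecurrence:
    def test_private_variant_unflagged(self):
        flags = flag_recurrence(
            {"t1": [(10, "A", "G")], "t2": []}, {"t1": 1, "t2": 2})
        assert flags == {}

    def test_recurrent_across_clades(self):
        flags = flag_recurrence(
            {"t1": [(10, "A", "G")], "t2": [(10, "A", "G")]},
            {"t1": 1, "t2": 2},
        )
        assert FLAG_RECURRENT in flags[(10, "A", "G")]

    def test_clade_defining_not_recurrent(self):
        flags = flag_recurrence(
            {"t1": [(10, "A", "G")], "t2": [(10, "A", "G")]},
            {"t1": 1, "t2": 2},
            clade_defining={1: [(10, "A", "G")]},
        )
        assert flags == {}

    def test_back_mutation(self):
        flags = flag_recurrence(
            {"t1": [(10, "G", "A")]},
            {"t1": 1},
            clade_defining={1: [(10, "A", "G")]},
        )
        assert FLAG_BACK_MUTATION in flags[(10, "G", "A")]
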