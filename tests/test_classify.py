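"""Somatic classification: host rules, tumour fraction, VAF normalization,
class building."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtsomatic.calls import CoverageSummary, VariantCall
from mtsomatic.classify import (
    DISCARDED,
    GERMLINE,
    SOMATIC,
    Label,
    NOTE_PUTATIVE,
    SamplePair,
    build_variant_classes,
    classify_with_host,
    classify_without_host,
    drop_tumour_contamination_from_host,
    estimate_tumour_fraction,
    normalize_vaf,
)


def call(sample, position, vaf, depth=100, ref="A", alt="G", kind="substitution"):
    mutant = round(vaf * depth)
    fwd = mutant // 2
    return VariantCall(
        sample_id=sample, position=position, ref=ref, alt=alt, kind=kind,
        mutant_reads=mutant, total_depth=depth,
        fwd_mutant=fwd, rev_mutant=mutant - fwd,
        fwd_ref=(depth - mutant) // 2, rev_ref=depth - mutant - (depth - mutant) // 2,
        bq25_reads=mutant,
    )


NORMAL_HOST_COV = CoverageSummary("h", 70.0, 0.3)
LOW_HOST_COV = CoverageSummary("h", 12.0, 0.3)


class TestWithHost:
    def test_shared_high_vaf_both_is_germline(self):
        labels = classify_with_host(
            [call("t", 5, 0.95)], [call("h", 5, 0.95)], NORMAL_HOST_COV)
        assert labels[0].label == GERMLINE

    def test_shared_low_tumour_vaf_discarded(self):
        labels = classify_with_host(
            [call("t", 5, 0.40)], [call("h", 5, 0.95)], NORMAL_HOST_COV)
        assert labels[0].label == DISCARDED

    def test_tumour_only_is_somatic(self):
        labels = classify_with_host([call("t", 5, 0.30)], [], NORMAL_HOST_COV)
        assert labels[0].label == SOMATIC

    def test_low_coverage_host_read_support_discards(self):
        labels = classify_with_host(
            [call("t", 5, 0.85)], [], LOW_HOST_COV,
            host_support_by_key={(5, "A", "G"): 1})
        assert labels[0].label == DISCARDED

    def test_low_coverage_host_vaf_floor(self):
        labels = classify_with_host(
            [call("t", 5, 0.45), call("t", 9, 0.55)], [], LOW_HOST_COV)
        assert labels[0].label == DISCARDED
        assert labels[1].label == SOMATIC

    def test_missing_coverage_is_error(self):
        with pytest.raises(ValueError, match="coverage"):
            classify_with_host([call("t", 5, 0.5)], [], None)


class TestWithoutHost:
    def test_below_cutoff_discarded(self):
        labels = classify_without_host([call("t", 5, 0.45)], cutoff=0.5)
        assert labels[0].label == DISCARDED

    def test_above_cutoff_kept(self):
        labels = classify_without_host([call("t", 5, 0.7)], cutoff=0.5)
        assert labels[0].label == SOMATIC

    def test_per_tumour_cutoff(self):
        labels = classify_without_host([call("t", 5, 0.55)], cutoff=0.6)
        assert labels[0].label == DISCARDED

    def test_heavy_contamination_uses_related_tumours(self):
        labels = classify_without_host(
            [call("t", 5, 0.2), call("t", 9, 0.2), call("t", 13, 0.2)],
            cutoff=0.5,
            contamination_level=0.5,
            related_tumour_variants=[(5, "A", "G")],
            germline_panel=[(9, "A", "G")],
        )
        assert labels[0].label == SOMATIC
        assert labels[1].label == DISCARDED
        assert labels[2] == Label(SOMATIC, NOTE_PUTATIVE)

    def test_bad_cutoff(self):
        with pytest.raises(ValueError):
            classify_without_host([], cutoff=1.5)


class TestTumourFraction:
    def test_mean_of_unique_vafs(self):
        tumour = [call("t", p, v) for p, v in ((1, 0.8), (5, 0.9), (9, 1.0))]
        assert estimate_tumour_fraction(tumour, []) == pytest.approx(0.9)

    def test_single_homoplasmic(self):
        assert estimate_tumour_fraction([call("t", 1, 1.0)], []) == 1.0

    def test_host_shared_variants_excluded(self):
        tumour = [call("t", 1, 0.8), call("t", 5, 0.2)]
        host = [call("h", 5, 0.9)]
        assert estimate_tumour_fraction(tumour, host) == pytest.approx(0.8)

    def test_no_unique_variants_flagged(self):
        with pytest.raises(ValueError, match="undefined"):
            estimate_tumour_fraction([call("t", 5, 0.5)], [call("h", 5, 0.5)])


class TestNormalizeVaf:
    def test_examples(self):
        assert normalize_vaf(0.45, 0.9) == pytest.approx(0.5)
        assert normalize_vaf(0.95, 0.9) == 1.0
        assert normalize_vaf(0.33, 1.0) == pytest.approx(0.33)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            normalize_vaf(0.5, 0.0)

    @settings(max_examples=50, deadline=None)
    @given(
        st.floats(0, 1), st.floats(0, 1),
        st.floats(0.05, 1.0),
    )
    def test_monotone_in_raw(self, a, b, f):
        lo, hi = sorted((a, b))
        assert normalize_vaf(lo, f) <= normalize_vaf(hi, f)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(0.0, 0.5), st.floats(0.1, 0.5), st.floats(1.0, 2.0))
    def test_scale_equivariant(self, raw, f, scale):
        # below the cap, scaling raw and f together leaves the result fixed
        if raw * scale <= 1 and f * scale <= 1:
            assert normalize_vaf(raw * scale, f * scale) == pytest.approx(
                normalize_vaf(raw, f)
            )


class TestBuildClasses:
    def _fixture(self):
        # clade 1: two tumours; clade 3: one tumour (conservative-excluded)
        defining = (10, "A", "G")
        potential = (20, "A", "G")
        private1 = (30, "A", "G")
        private2 = (40, "A", "G")
        recomb = (50, "A", "G")
        labelled = {
            "t1": [
                (call("t1", 10, 0.95), Label(GERMLINE)),
                (call("t1", 20, 0.95), Label(SOMATIC)),
                (call("t1", 30, 0.60), Label(SOMATIC)),
                (call("t1", 50, 0.80), Label(SOMATIC)),
            ],
            "t2": [
                (call("t2", 10, 0.92), Label(GERMLINE)),
                (call("t2", 20, 0.93), Label(SOMATIC)),
                (call("t2", 40, 0.70), Label(SOMATIC)),
            ],
            "t3": [
                (call("t3", 60, 0.9), Label(SOMATIC)),
            ],
            "t4": [
                (call("t4", 65, 0.9), Label(SOMATIC)),
            ],
        }
        clade_of = {"t1": 1, "t2": 1, "t3": 3, "t4": 3}
        panel = {defining}
        return labelled, clade_of, panel, locals()

    def test_classes(self):
        labelled, clade_of, panel, names = self._fixture()
        result = build_variant_classes(
            labelled, clade_of, panel,
            recombination_variants=[(50, "A", "G")],
        )
        assert result.clade_defining[1] == {(10, "A", "G")}
        assert result.potential_somatic[1] == {(20, "A", "G")}
        assert set(result.somatic[1]) == {(30, "A", "G"), (40, "A", "G"), (50, "A", "G")}
        # recombination-implicated variant excluded from conservative list
        assert result.conservative_somatic[1] == {(30, "A", "G"), (40, "A", "G")}
        # clade 3 entirely excluded from conservative list
        assert set(result.somatic[3]) == {(60, "A", "G"), (65, "A", "G")}
        assert result.conservative_somatic[3] == set()
        result.validate()

    def test_trunk_group_exclusion(self):
        labelled, clade_of, panel, _ = self._fixture()
        shared = (70, "A", "G")
        labelled["t1"].append((call("t1", 70, 0.8), Label(SOMATIC)))
        result = build_variant_classes(
            labelled, clade_of, panel,
            trunk_groups={"trunkA": {"t1"}},
        )
        assert shared in result.somatic[1]
        assert shared not in result.conservative_somatic[1]

    def test_putative_somatic_excluded_from_conservative(self):
        labelled, clade_of, panel, _ = self._fixture()
        labelled["t2"].append(
            (call("t2", 80, 0.8), Label(SOMATIC, NOTE_PUTATIVE)))
        result = build_variant_classes(labelled, clade_of, panel)
        assert (80, "A", "G") in result.somatic[1]
        assert (80, "A", "G") not in result.conservative_somatic[1]

    def test_normalized_vafs_recorded(self):
        labelled, clade_of, panel, _ = self._fixture()
        result = build_variant_classes(
            labelled, clade_of, panel, tumour_fractions={"t1": 0.8, "t2": 0.8})
        record = result.somatic[1][(30, "A", "G")]
        assert record.mean_raw_vaf == pytest.approx(0.6)
        assert record.mean_normalized_vaf == pytest.approx(0.75)

    def test_missing_clade_is_error(self):
        labelled, clade_of, panel, _ = self._fixture()
        del clade_of["t3"]
        with pytest.raises(ValueError, match="clade"):
            build_variant_classes(labelled, clade_of, panel)


def test_sample_pair_invariants():
    with pytest.raises(ValueError):
        SamplePair("t", tumour_fraction=1.5)
    with pytest.raises(ValueError):
        SamplePair("t", vaf_cutoff=2.0)
    assert SamplePair("t", host_id="h").vaf_cutoff == 0.5


def test_drop_tumour_contamination_from_host():
    host = [call("h", 5, 0.3), call("h", 9, 0.95), call("h", 13, 0.4)]
    kept, dropped = drop_tumour_contamination_from_host(
        host, [(5, "A", "G"), (9, "A", "G")])
    assert [c.position for c in dropped] == [5]  # homoplasmic host call stays
    assert [c.position for c in kept] == [9, 13]
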