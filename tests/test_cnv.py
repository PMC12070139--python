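import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meningrisk.cnv import (
    ArmDefinition,
    LocusDefinition,
    Segment,
    arm_loss_fraction,
    build_cnv_profile,
    call_arm_status,
    call_cdkn2ab,
)
from meningrisk.cnv import CnvConfigError

from .conftest import brute_force_fraction


class TestSegmentInvariants:
    def test_rejects_inverted_interval(self):
        with pytest.raises(ValueError):
            Segment("chr1", 100, 100, -0.5)

    def test_rejects_empty_chrom(self):
        with pytest.raises(ValueError):
            Segment("", 0, 10, 0.0)

    def test_rejects_non_finite_log2(self):
        with pytest.raises(ValueError):
            Segment("chr1", 0, 10, float("nan"))


class TestArmLossFraction:
    def test_single_segment_ten_percent(self, toy_arm):
        segs = [Segment("chrT", 0, 1_000, -0.5)]
        assert arm_loss_fraction(segs, toy_arm) == pytest.approx(0.10)

    def test_no_segment_below_threshold(self, toy_arm):
        segs = [Segment("chrT", 0, 9_000, 0.02), Segment("chrT", 9_000, 10_000, -0.05)]
        assert arm_loss_fraction(segs, toy_arm) == 0.0

    def test_overlapping_segments_union_seven_percent(self, toy_arm):
        # union of [1000,1500) and [1300,1700) is 700 bases of a 10 kb arm;
        # expected value frozen from the per-base oracle
        segs = [
            Segment("chrT", 1_000, 1_500, -0.4),
            Segment("chrT", 1_300, 1_700, -0.3),
        ]
        assert brute_force_fraction(segs, toy_arm) == 0.07
        assert arm_loss_fraction(segs, toy_arm) == 0.07

    def test_threshold_is_inclusive(self, toy_arm):
        # log2 == threshold counts as lost ("-0.1 indicates the loss of one copy")
        segs = [Segment("chrT", 0, 1_000, -0.1)]
        assert arm_loss_fraction(segs, toy_arm) == 0.10

    def test_segment_clipped_to_arm(self, toy_arm):
        segs = [Segment("chrT", 8_000, 20_000, -0.5)]
        assert arm_loss_fraction(segs, toy_arm) == pytest.approx(0.20)

    def test_other_chromosome_ignored(self, toy_arm):
        segs = [Segment("chrX", 0, 10_000, -0.5)]
        assert arm_loss_fraction(segs, toy_arm) == 0.0


segments_strategy = st.lists(
    st.tuples(
        st.integers(min_value=-5_000, max_value=99_999),
        st.integers(min_value=1, max_value=40_000),
        st.floats(min_value=-2.0, max_value=1.0, allow_nan=False),
    ),
    max_size=20,
)


def _build(raw):
    return [Segment("chrT", start, start + length, log2) for start, length, log2 in raw]


class TestUnionOracle:
    @given(raw=segments_strategy, arm_len=st.integers(min_value=1, max_value=100_000))
    @settings(max_examples=300, deadline=None)
    def test_matches_per_base_brute_force(self, raw, arm_len):
        arm = ArmDefinition("chrT", "p", 0, arm_len)
        segs = _build(raw)
        assert arm_loss_fraction(segs, arm) == brute_force_fraction(segs, arm)

    @given(raw=segments_strategy)
    @settings(max_examples=100, deadline=None)
    def test_fraction_in_unit_interval(self, raw):
        arm = ArmDefinition("chrT", "p", 0, 50_000)
        assert 0.0 <= arm_loss_fraction(_build(raw), arm) <= 1.0

    @given(
        raw=segments_strategy,
        extra_start=st.integers(min_value=0, max_value=49_000),
        extra_len=st.integers(min_value=1, max_value=10_000),
        extra_log2=st.floats(min_value=-2.0, max_value=1.0, allow_nan=False),
    )
    @settings(max_examples=150, deadline=None)
    def test_monotone_under_added_segment(self, raw, extra_start, extra_len, extra_log2):
        arm = ArmDefinition("chrT", "p", 0, 50_000)
        segs = _build(raw)
        before = arm_loss_fraction(segs, arm)
        extra = Segment("chrT", extra_start, extra_start + extra_len, extra_log2)
        after = arm_loss_fraction(segs + [extra], arm)
        if extra_log2 <= -0.1:
            assert after >= before
        else:
            assert after == before


class TestBoundaryClipping:
    def test_spanning_segment_equals_presplit(self):
        p = ArmDefinition("chrT", "p", 0, 6_000)
        q = ArmDefinition("chrT", "q", 6_000, 14_000)
        spanning = [Segment("chrT", 5_000, 9_000, -0.5)]
        split = [
            Segment("chrT", 5_000, 6_000, -0.5),
            Segment("chrT", 6_000, 9_000, -0.5),
        ]
        for arm in (p, q):
            assert arm_loss_fraction(spanning, arm) == arm_loss_fraction(split, arm)
        assert arm_loss_fraction(spanning, p) == pytest.approx(1_000 / 6_000)
        assert arm_loss_fraction(spanning, q) == pytest.approx(3_000 / 8_000)


class TestCallArmStatus:
    def test_just_over_five_percent_is_lost(self):
        assert call_arm_status("1p", 0.051).lost is True

    def test_exactly_five_percent_is_not_lost(self):
        assert call_arm_status("1p", 0.05).lost is False

    def test_zero_is_not_lost(self):
        assert call_arm_status("1p", 0.0).lost is False

    @pytest.mark.parametrize("bad", [-0.01, 1.01])
    def test_fraction_out_of_range_errors(self, bad):
        with pytest.raises(ValueError):
            call_arm_status("1p", bad)


class TestCallCdkn2ab:
    def test_deep_deletion_called(self, toy_locus):
        log2, deleted = call_cdkn2ab([Segment("chrT", 4_000, 4_200, -1.2)], toy_locus)
        assert deleted is True
        assert log2 == -1.2

    def test_neutral_not_deleted(self, toy_locus):
        log2, deleted = call_cdkn2ab([Segment("chrT", 3_000, 5_000, 0.0)], toy_locus)
        assert deleted is False
        assert log2 == 0.0

    def test_no_overlap_is_no_call(self, toy_locus):
        log2, deleted = call_cdkn2ab([Segment("chrT", 0, 1_000, -1.5)], toy_locus)
        assert log2 is None and deleted is None

    def test_minimum_over_overlapping_segments(self, toy_locus):
        segs = [
            Segment("chrT", 3_900, 4_100, -0.2),
            Segment("chrT", 4_100, 4_300, -0.9),
        ]
        log2, deleted = call_cdkn2ab(segs, toy_locus)
        assert log2 == -0.9 and deleted is True

    def test_threshold_is_strict(self, toy_locus):
        log2, deleted = call_cdkn2ab([Segment("chrT", 4_000, 4_200, -0.4)], toy_locus)
        assert deleted is False


class TestBuildCnvProfile:
    def test_only_planted_arm_called(self, arms, loci):
        arm_1p = next(a for a in arms if a.key == "1p")
        segs = [Segment("chr1", arm_1p.start, arm_1p.end, -0.5)]
        profile = build_cnv_profile("S1", segs, arms, loci)
        assert profile.lost("1p") is True
        assert not any(profile.lost(k) for k in ("6q", "14q", "22q"))

    def test_empty_segments(self, arms, loci):
        profile = build_cnv_profile("S1", [], arms, loci)
        assert all(s.fraction_lost == 0.0 and not s.lost for s in profile.statuses.values())
        assert profile.cdkn2ab_log2 is None and profile.cdkn2ab_deleted is None

    def test_missing_arm_definition_is_config_error(self, loci):
        arms = [ArmDefinition("chr1", "p", 0, 1_000)]
        with pytest.raises(CnvConfigError):
            build_cnv_profile("S1", [], arms, loci)

    def test_missing_locus_is_config_error(self, arms):
        with pytest.raises(CnvConfigError):
            build_cnv_profile("S1", [], arms, [])

    def test_simulator_planted_losses_recovered(self, arms, loci, rng):
        from meningrisk.simulate import SegmentNoise, emit_segments

        truth = {
            "sample_id": "S1",
            "lost_1p": True,
            "lost_14q": True,
            "lost_6q": False,
            "lost_22q": False,
            "cdkn2ab_deleted": False,
        }
        segs = emit_segments(truth, arms, loci, SegmentNoise(), rng)
        profile = build_cnv_profile("S1", segs, arms, loci)
        assert {k for k, s in profile.statuses.items() if s.lost} == {"1p", "14q"}
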