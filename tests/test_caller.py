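import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nlrpool.caller import (
    CallerParams,
    CallSet,
    NoCall,
    SnpCall,
    call_pileup,
    call_site,
    copy_class,
    detectability_threshold,
    filter_fixed_differences,
    intersect_callsets,
    validate_against_truth,
)
from nlrpool.io import SiteCounts

P = CallerParams()


def site(counts, pos=1, ref="A", contig="g1", indel=0):
    return SiteCounts(contig, pos, ref, counts, indel_evidence=indel)


class TestCallSite:
    def test_minor_at_threshold_called_with_copy_class(self):
        call = call_site(site({"A": 24, "C": 6}))
        assert isinstance(call, SnpCall)
        assert call.p_hat == pytest.approx(0.2) and call.k == 4
        assert call.minor_allele == "C" and call.alt_allele == "C"

    def test_depth_just_below_minimum_is_low_coverage(self):
        res = call_site(site({"A": 23, "C": 6}))
        assert res == NoCall("g1", 1, "low_coverage")

    def test_rare_minor_at_depth_is_low_count(self):
        res = call_site(site({"A": 295, "C": 5}))
        assert res == NoCall("g1", 1, "low_count")

    def test_balanced_site_called_at_half(self):
        call = call_site(site({"A": 20, "C": 20}))
        assert call.p_hat == 0.5 and call.k == 10

    def test_third_allele_at_threshold_is_multiallelic(self):
        res = call_site(site({"A": 20, "C": 10, "G": 6}))
        assert res.reason == "multiallelic"

    def test_pure_reference_site_is_monomorphic(self):
        assert call_site(site({"A": 50})).reason == "monomorphic"

    def test_nonreference_major_keeps_ref_as_alt_candidate(self):
        call = call_site(site({"T": 24, "A": 6}, ref="A"))
        assert call.major_allele == "T" and call.minor_allele == "A"
        assert call.alt_allele == "T"  # the non-reference allele

    def test_exhaustive_two_allele_oracle_up_to_depth_60(self):
        """The caller agrees with a brute-force restatement of the
        depth/count rules on every two-allele count vector."""
        for depth in range(1, 61):
            for minor in range(0, depth // 2 + 1):
                s = site({"A": depth - minor, "C": minor})
                got = call_site(s, P)
                # independent oracle: plain threshold logic
                if depth < 30:
                    expect = "low_coverage"
                elif minor == 0:
                    expect = "monomorphic"
                elif minor < 6:
                    expect = "low_count"
                else:
                    expect = "call"
                if expect == "call":
                    assert isinstance(got, SnpCall)
                    assert got.minor_count == minor and got.depth == depth
                else:
                    assert got.reason == expect


class TestCopyClass:
    def test_half_up_rounding_and_clamping(self):
        assert copy_class(0.2, 20) == 4
        assert copy_class(0.025, 20) == 1  # rounds to 0.5 -> half-up -> 1
        assert copy_class(0.01, 20) == 1  # class 0 promoted: a call segregates
        assert copy_class(0.99, 20) == 19


class TestCallPileup:
    def test_snp_inside_indel_window_masked(self):
        pile = [
            site({"A": 100}, pos=p) if p not in (50, 53) else
            site({"A": 80, "C": 20} if p == 50 else {"A": 100}, pos=p,
                 indel=2 if p == 53 else 0)
            for p in range(1, 201)
        ]
        calls, log = call_pileup(pile)
        assert len(calls) == 0
        assert NoCall("g1", 50, "indel_proximal") in log

    def test_snp_outside_indel_window_called(self):
        pile = [
            site({"A": 80, "C": 20} if p == 50 else {"A": 100}, pos=p,
                 indel=2 if p == 56 else 0)
            for p in range(1, 201)
        ]
        calls, _ = call_pileup(pile)
        assert len(calls) == 1 and next(iter(calls)).pos == 50

    def test_extreme_depth_site_masked_as_excess_coverage(self):
        pile = [
            site({"A": 4000, "C": 1000} if p == 10 else {"A": 100}, pos=p)
            for p in range(1, 201)
        ]
        calls, log = call_pileup(pile)
        assert len(calls) == 0
        assert NoCall("g1", 10, "excess_coverage") in log

    def test_unsorted_input_rejected(self):
        pile = [site({"A": 50}, pos=2), site({"A": 50}, pos=1)]
        with pytest.raises(ValueError, match="sorted"):
            call_pileup(pile)

    def test_raising_thresholds_never_adds_calls(self, study_pool):
        _, _, _, pileup = study_pool
        sub = pileup[:20000]
        baseline = len(call_pileup(sub, CallerParams())[0])
        for params in (
            CallerParams(min_cov=60),
            CallerParams(min_count=10),
            CallerParams(max_cov_quantile=0.90),
            CallerParams(indel_window=50),
        ):
            assert len(call_pileup(sub, params)[0]) <= baseline


class TestDetectability:
    @pytest.mark.parametrize("depth,expected", [(30, 4), (120, 1), (20, 6)])
    def test_smallest_detectable_copy_class(self, depth, expected):
        res = detectability_threshold(depth, P)
        assert res.k == expected and res.feasible

    def test_infeasible_depth_capped_at_half_pool(self):
        res = detectability_threshold(10, P)  # would need k=12 of 20
        assert res.k == 10 and not res.feasible


def mkcall(pos, minor="C", contig="g1", ref="A", mc=10, depth=50):
    major = ref if minor != ref else "T"
    return SnpCall(contig, pos, ref, major, minor, mc, depth)


class TestFilterFixedDifferences:
    def test_fixed_difference_to_reference_removed(self):
        calls = CallSet([SnpCall("g1", 5, "A", "T", "A", 0, 30)])
        sites = [site({"T": 30}, pos=5)]
        assert len(filter_fixed_differences(calls, sites)) == 0

    def test_genuinely_polymorphic_site_retained(self):
        calls = CallSet([SnpCall("g1", 5, "A", "T", "A", 6, 30)])
        sites = [site({"T": 24, "A": 6}, pos=5)]
        assert len(filter_fixed_differences(calls, sites)) == 1

    def test_empty_call_set_passes_through(self):
        assert len(filter_fixed_differences(CallSet(), [])) == 0

    def test_missing_site_is_an_error(self):
        calls = CallSet([mkcall(7)])
        with pytest.raises(KeyError):
            filter_fixed_differences(calls, [site({"A": 50}, pos=1)])


class TestIntersect:
    def test_shared_and_private_calls_partitioned(self):
        p1, p2, p3 = mkcall(1), mkcall(2), mkcall(3)
        both, only_a, only_b = intersect_callsets(CallSet([p1, p2]), CallSet([p2, p3]))
        assert both.keys() == {p2.key}
        assert only_a.keys() == {p1.key} and only_b.keys() == {p3.key}

    def test_same_position_different_minor_allele_not_shared(self):
        a = CallSet([mkcall(1, minor="C")])
        b = CallSet([mkcall(1, minor="G")])
        both, only_a, only_b = intersect_callsets(a, b)
        assert len(both) == 0 and len(only_a) == 1 and len(only_b) == 1
        both_pos, *_ = intersect_callsets(a, b, match_on="pos")
        assert len(both_pos) == 1

    def test_identical_sets_fully_shared(self):
        a = CallSet([mkcall(1), mkcall(2)])
        both, only_a, only_b = intersect_callsets(a, CallSet(iter(a)))
        assert both.keys() == a.keys() and not len(only_a) and not len(only_b)

    def test_both_keeps_first_arguments_frequency(self):
        a = CallSet([mkcall(1, mc=10, depth=50)])
        b = CallSet([mkcall(1, mc=20, depth=40)])
        both, _, _ = intersect_callsets(a, b)
        assert next(iter(both)).p_hat == pytest.approx(0.2)

    @given(
        a_pos=st.sets(st.integers(1, 40), max_size=20),
        b_pos=st.sets(st.integers(1, 40), max_size=20),
    )
    @settings(deadline=None, derandomize=True)
    def test_outputs_partition_the_union(self, a_pos, b_pos):
        a = CallSet(mkcall(p) for p in a_pos)
        b = CallSet(mkcall(p) for p in b_pos)
        both, only_a, only_b = intersect_callsets(a, b)
        parts = [both.keys(), only_a.keys(), only_b.keys()]
        union = set().union(*parts)
        assert union == a.keys() | b.keys()
        assert sum(len(p) for p in parts) == len(union)
        assert len(both) <= min(len(a), len(b))


class TestValidation:
    REGION = [("g1", 1, 1000)]

    def test_perfect_calls_have_zero_error_rates(self):
        truth = [("g1", p, "C") for p in (5, 10)]
        calls = CallSet([mkcall(5), mkcall(10)])
        rep = validate_against_truth(calls, truth, self.REGION)
        assert rep.fp_rate == 0.0 and rep.fn_rate == 0.0

    def test_one_missed_one_spurious_of_25(self):
        truth = [("g1", p, "C") for p in range(1, 26)]
        calls = CallSet([mkcall(p) for p in range(1, 25)] + [mkcall(500)])
        rep = validate_against_truth(calls, truth, self.REGION)
        assert rep.fn == 1 and rep.fp == 1 and rep.tp == 24
        assert rep.fn_rate == pytest.approx(1 / 25)
        assert rep.fp_rate == pytest.approx(1 / 25)

    def test_no_calls_leaves_fp_rate_undefined(self):
        truth = [("g1", 5, "C")]
        rep = validate_against_truth(CallSet(), truth, self.REGION)
        assert rep.fn_rate == 1.0 and rep.fp_rate is None

    def test_region_restricts_both_sides(self):
        truth = [("g1", 5, "C"), ("g1", 999, "C")]
        calls = CallSet([mkcall(5), mkcall(999)])
        rep = validate_against_truth(calls, truth, [("g1", 1, 10)])
        assert rep.tp == 1 and rep.fp == 0 and rep.fn == 0

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            validate_against_truth(CallSet(), [], [])
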