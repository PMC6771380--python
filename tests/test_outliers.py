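"""Robust outlier calling, stretch assembly, direction, overlap, frequency."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from gbscov import (
    DenoisedProfile,
    OutlierCalls,
    build_windows,
    call_outliers,
    classify_direction,
    find_stretches,
    frequency_summary,
    longest_stretch,
    overlap_fraction,
)
from gbscov.outliers import MAD_SCALE, OutlierStretch

from stretch_oracle import brute_force_stretches


def _profile(vals, sid="s"):
    return DenoisedProfile(sid, np.asarray(vals, float))


def _calls_from_flags(flags, sid="s"):
    flags = np.asarray(flags, bool)
    return OutlierCalls(sid, np.where(flags, 10.0, 0.0), flags, 3.719, "two_sided")


class TestCallOutliers:
    def test_constant_profile_warns_and_flags_nothing(self):
        with pytest.warns(UserWarning, match="MAD"):
            calls = call_outliers(_profile([1.0] * 100))
        assert not calls.flag.any()
        assert calls.mad_zero

    def test_spiked_normal_sample_is_flagged(self):
        rng = np.random.default_rng(42)
        p = rng.standard_normal(1000)
        p[500] = 50.0
        calls = call_outliers(_profile(p))
        assert calls.flag[500]
        # z matches a direct median/MAD computation on the drawn sample
        med = np.median(p)
        mad = MAD_SCALE * np.median(np.abs(p - med))
        assert calls.z[500] == pytest.approx((p[500] - med) / mad)
        assert abs(calls.z[500]) > 3.719

    def test_threshold_is_normal_quantile(self):
        calls = call_outliers(_profile(np.arange(10.0)), prob=0.975)
        assert calls.threshold == pytest.approx(norm.ppf(0.975))

    def test_upper_sidedness_ignores_low_tail(self):
        rng = np.random.default_rng(1)
        p = rng.standard_normal(500)
        p[10] = -40.0
        p[20] = 40.0
        two = call_outliers(_profile(p), sidedness="two_sided")
        up = call_outliers(_profile(p), sidedness="upper")
        assert two.flag[10] and two.flag[20]
        assert up.flag[20] and not up.flag[10]

    @settings(derandomize=True, max_examples=25)
    @given(alpha=st.floats(0.01, 100), beta=st.floats(-50, 50))
    def test_affine_invariance_of_flags(self, alpha, beta):
        rng = np.random.default_rng(9)
        p = rng.standard_normal(300)
        p[7] = 30.0
        base = call_outliers(_profile(p))
        scaled = call_outliers(_profile(alpha * p + beta))
        np.testing.assert_array_equal(base.flag, scaled.flag)

    def test_raising_prob_never_adds_flags(self):
        rng = np.random.default_rng(3)
        p = rng.standard_normal(2000)
        loose = call_outliers(_profile(p), prob=0.95)
        tight = call_outliers(_profile(p), prob=0.999)
        assert not (tight.flag & ~loose.flag).any()

    def test_short_profile_rejected(self):
        with pytest.raises(ValueError):
            call_outliers(_profile([1.0]))


class TestFindStretches:
    gw = build_windows([("c1", 7_000_000)], 500_000)  # 14 windows

    def _stretches(self, flags, min_outliers=3):
        calls = _calls_from_flags(list(flags) + [False] * (14 - len(flags)))
        return find_stretches(calls, self.gw, min_outliers)

    def test_simple_run(self):
        (s,) = self._stretches([True, True, True])
        assert (s.start_window, s.end_window, s.n_outliers) == (0, 2, 3)
        assert (s.start_bp, s.end_bp) == (0, 1_500_000)

    def test_single_gap_bridged(self):
        (s,) = self._stretches([True, False, True, True])
        assert (s.start_window, s.end_window, s.n_outliers) == (0, 3, 3)

    def test_double_gap_breaks(self):
        (s,) = self._stretches([True, False, False, True, True, True])
        assert (s.start_window, s.end_window, s.n_outliers) == (3, 5, 3)

    def test_min_outliers_counts_flagged_only(self):
        # T F T F T spans 5 windows but has 3 flagged
        (s,) = self._stretches([True, False, True, False, True], min_outliers=3)
        assert s.n_outliers == 3
        assert self._stretches([True, False, True], min_outliers=3) == []

    def test_stretch_never_crosses_chromosomes(self):
        gw = build_windows([("a", 1_000_000), ("b", 1_000_000)], 500_000)
        calls = _calls_from_flags([True, True, True, True])
        out = find_stretches(calls, gw, min_outliers=2)
        assert [(s.chrom, s.n_outliers) for s in out] == [("a", 2), ("b", 2)]

    def test_exhaustive_oracle_equivalence_short(self):
        """Implementation agrees with the literal brute-force enumerator on
        every flag vector of length 8."""
        gw = build_windows([("c", 4_000_000)], 500_000)
        for bits in itertools.product([False, True], repeat=8):
            calls = _calls_from_flags(list(bits))
            for m in (1, 2, 3):
                got = [(s.start_window, s.end_window, s.n_outliers)
                       for s in find_stretches(calls, gw, m)]
                assert got == brute_force_stretches(list(bits), m), (bits, m)

    def test_raising_min_outliers_never_adds_stretches(self):
        rng = np.random.default_rng(4)
        flags = rng.random(14) < 0.4
        lo = {(s.start_window, s.end_window)
              for s in self._stretches(flags, min_outliers=1)}
        hi = {(s.start_window, s.end_window)
              for s in self._stretches(flags, min_outliers=3)}
        assert hi <= lo

    def test_structural_invariants(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            flags = rng.random(14) < 0.5
            calls = _calls_from_flags(flags)
            for s in find_stretches(calls, self.gw, 2):
                assert flags[s.start_window] and flags[s.end_window]
                inside = flags[s.start_window:s.end_window + 1]
                assert not any(~inside[i] and ~inside[i + 1]
                               for i in range(len(inside) - 1))
                assert s.n_outliers >= 2


def _stretch(chrom="c1", sw=0, ew=2, n=3, start=0, end=1_500_000,
             direction="decreased", mean_p=-1.0):
    return OutlierStretch(chrom, sw, ew, start, end, n, direction, mean_p)


class TestLongestStretch:
    def test_empty_is_none(self):
        assert longest_stretch([]) is None

    def test_most_outliers_wins(self):
        a = _stretch(n=3)
        b = _stretch(n=7, sw=5, ew=12, start=2_500_000, end=6_500_000)
        assert longest_stretch([a, b]) is b

    def test_tie_breaks_by_span_then_position(self):
        short = _stretch(n=5, start=0, end=4_000_000)
        long = _stretch(n=5, start=10_000_000, end=16_000_000)
        assert longest_stretch([short, long]) is long
        first = _stretch(n=5, start=0, end=4_000_000)
        later = _stretch(n=5, start=8_000_000, end=12_000_000)
        assert longest_stretch([first, later]) is first


class TestClassifyDirection:
    def test_signs(self):
        p = _profile([-1, -1, -1, 0.8, 0.8, 0.8])
        assert classify_direction(_stretch(sw=0, ew=2), p) == "decreased"
        assert classify_direction(_stretch(sw=3, ew=5), p) == "increased"

    def test_mixed_mean_and_zero_tie(self):
        p = _profile([0.1, -0.2, -0.05, 1.0, -1.0])
        assert classify_direction(_stretch(sw=0, ew=2), p) == "decreased"
        assert classify_direction(_stretch(sw=3, ew=4), p) == "decreased"  # mean 0


class TestOverlapFraction:
    def test_identical(self):
        assert overlap_fraction(("c", 0, 10), ("c", 0, 10)) == (1.0, 1.0)

    def test_disjoint_and_other_chromosome(self):
        assert overlap_fraction(("c", 0, 10), ("c", 20, 30)) == (0.0, 0.0)
        assert overlap_fraction(("c1", 0, 10), ("c2", 0, 10)) == (0.0, 0.0)

    def test_partial(self):
        frac, jac = overlap_fraction(("c", 0, 10), ("c", 5, 15))
        assert frac == pytest.approx(0.5)
        assert jac == pytest.approx(5 / 15)

    def test_zero_length_annotated_rejected(self):
        with pytest.raises(ValueError):
            overlap_fraction(("c", 0, 10), ("c", 5, 5))


class TestFrequencySummary:
    def _collection(self, n_samples, flagged_at):
        out = []
        for i in range(n_samples):
            flags = np.zeros(10, bool)
            for w, sample_set in flagged_at.items():
                if i in sample_set:
                    flags[w] = True
            out.append(_calls_from_flags(flags, sid=f"s{i}"))
        return out

    def test_inclusive_boundary_at_3_percent(self):
        calls = self._collection(100, {0: set(range(3)), 1: set(range(2))})
        summary = frequency_summary(calls, 0.03)
        assert summary.fraction[0] == pytest.approx(0.03)
        assert 0 in summary.robust_windows
        assert 1 not in summary.robust_windows

    def test_empty_robust_set(self):
        summary = frequency_summary(self._collection(10, {}), 0.1)
        assert summary.robust_windows.size == 0
        assert (summary.n_flagged == 0).all()

    def test_inconsistent_grids_rejected(self):
        a = _calls_from_flags([True] * 5)
        b = _calls_from_flags([True] * 6)
        with pytest.raises(ValueError, match="inconsistent"):
            frequency_summary([a, b], 0.1)
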