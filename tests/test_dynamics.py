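"""Dominance dynamics: windowing, DiffIndex, trend fits, class comparison."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import msbdyn as m
import msbdyn.dynamics as dyn
from msbdyn.errors import ConfigError, InsufficientDataError
from msbdyn.records import SpineRecord


class TestTruncateSeries:
    def test_42_hourly_frames_keep_16(self):
        t = np.arange(42.0)
        kept, = dyn.truncate_series(t, window_h=15.0)[:1]
        assert len(kept) == 16 and kept[-1] == 15.0

    def test_short_series_kept_whole(self):
        t = np.arange(10.0)
        assert len(dyn.truncate_series(t, window_h=15.0)[0]) == 10

    def test_zero_window_keeps_first_frame_only(self):
        t = np.arange(5.0)
        assert len(dyn.truncate_series(t, window_h=0.0)[0]) == 1

    def test_window_measured_from_start_frame(self):
        t = np.arange(30.0)
        kept, = dyn.truncate_series(t, window_h=15.0, start_frame=5)[:1]
        assert kept[0] == 5.0 and kept[-1] == 20.0 and len(kept) == 16

    def test_empty_series_raises(self):
        with pytest.raises(ConfigError):
            dyn.truncate_series(np.array([]))


class TestPreselectDominant:
    def test_higher_mean_is_dominant(self):
        assert dyn.preselect_dominant([120.0] * 4, [80.0] * 4,
                                      "a", "b") == ("a", "b")

    def test_tie_goes_to_smaller_id(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="msbdyn.dynamics"):
            assert dyn.preselect_dominant([5.0, 5.0], [5.0, 5.0],
                                          "b", "a") == ("a", "b")
        assert any("tie" in r.message for r in caplog.records)

    def test_length_mismatch_raises(self):
        with pytest.raises(ConfigError):
            dyn.preselect_dominant([1.0, 2.0], [1.0])

    def test_agrees_with_direct_mean_comparison(self, rng):
        for _ in range(100):
            a = rng.uniform(0, 100, size=8)
            b = rng.uniform(0, 100, size=8)
            dom, _ = dyn.preselect_dominant(a, b, 0, 1)
            assert dom == (0 if a.mean() > b.mean() else 1)


class TestDifferenceIndex:
    @pytest.mark.parametrize("dom,non,expected", [
        (3.0, 1.0, 0.5), (2.0, 2.0, 0.0), (5.0, 0.0, 1.0)])
    def test_values(self, dom, non, expected):
        assert dyn.difference_index(dom, non) == expected

    def test_both_zero_is_missing_with_warning(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(dyn.difference_index(0.0, 0.0))

    @given(st.floats(0.01, 1e6), st.floats(0.01, 1e6))
    def test_antisymmetric_under_label_swap(self, a, b):
        assert dyn.difference_index(a, b) == pytest.approx(
            -dyn.difference_index(b, a))

    @given(st.floats(0.01, 1e4), st.floats(0.01, 1e4), st.floats(0.01, 100))
    def test_invariant_to_illumination_scale(self, a, b, scale):
        assert dyn.difference_index(a * scale, b * scale) == pytest.approx(
            dyn.difference_index(a, b), abs=1e-9)


def normal_equations_slope(t, y):
    """Oracle: solve [n Σt; Σt Σt²][b0 b1]ᵀ = [Σy; Σty] directly."""
    A = np.array([[len(t), t.sum()], [t.sum(), (t * t).sum()]])
    rhs = np.array([y.sum(), (t * y).sum()])
    return np.linalg.solve(A, rhs)[1]


class TestDominanceFit:
    def test_exact_linear_series(self):
        t = np.arange(16.0)
        rate, r2 = dyn.dominance_fit(t, 0.042 * t)
        assert rate == pytest.approx(0.042) and r2 == pytest.approx(1.0)

    def test_constant_series_rate_zero_r2_zero(self):
        rate, r2 = dyn.dominance_fit(np.arange(10.0), np.full(10, 0.3))
        assert rate == 0.0 and r2 == 0.0

    def test_missing_frames_skipped(self):
        t = np.arange(10.0)
        y = 0.01 * t
        y[3] = np.nan
        rate, _ = dyn.dominance_fit(t, y)
        assert rate == pytest.approx(0.01)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(100):
            t = np.sort(rng.uniform(0, 15, size=12))
            y = rng.uniform(-1, 1, size=12)
            rate, _ = dyn.dominance_fit(t, y)
            assert rate == pytest.approx(normal_equations_slope(t, y))

    def test_too_few_valid_frames_raises(self):
        with pytest.raises(InsufficientDataError):
            dyn.dominance_fit(np.array([0.0, 1.0]), np.array([np.nan, 0.5]))

    def test_zero_time_variance_raises(self):
        with pytest.raises(ConfigError):
            dyn.dominance_fit(np.array([2.0, 2.0]), np.array([0.1, 0.2]))

    def test_preselection_makes_rate_nonnegative_on_monotone_input(self):
        """Noise-free monotone competition: dominant preselected, slope >= 0."""
        t = np.arange(16.0)
        total = 1000.0
        for rate in (0.005, 0.02, 0.042):
            non = total / 2 * (1 - rate * t)
            dom = total - non
            pd = dyn.pair_dynamics(0, "msb", t, non, dom)  # arbitrary order
            assert pd.dominance_rate >= 0
            assert pd.dominance_rate == pytest.approx(rate)


class TestParameterRecovery:
    def test_median_rate_error_small_under_noise(self):
        """200 noisy pairs per truth rate: median |fit − truth| ≤ 0.005."""
        for truth in (0.002, 0.01, 0.042):
            cfg = m.SceneConfig(dominance_rate_mean_msb=truth,
                                dominance_rate_sd_msb=0.0,
                                intensity_noise_sd=0.05, seed=41)
            errors = []
            for s in m.sample_pair_dynamics(cfg, 200, "msb"):
                pd = dyn.pair_dynamics(s.pair_id, "msb", s.times,
                                       s.intden_a, s.intden_b)
                errors.append(abs(pd.dominance_rate - truth))
            assert np.median(errors) <= 0.005


class TestSsbPairing:
    def spine(self, x, sid):
        return SpineRecord(id=sid, frame=0, head_um=(x, 1.0, 0.0),
                           base_um=(x, 0.0, 0.0))

    def test_collinear_nearest_neighbor(self):
        s = [self.spine(0.0, 0), self.spine(1.0, 1), self.spine(3.0, 2)]
        pairs = dyn.pair_ssb_neighbors([s[1]], s)
        assert [(a.id, b.id) for a, b in pairs] == [(1, 0)]

    def test_single_spine_warns_and_skips(self):
        s = self.spine(0.0, 0)
        with pytest.warns(UserWarning, match="no neighbor"):
            assert dyn.pair_ssb_neighbors([s], [s]) == []

    def test_duplicate_pairs_emitted_once(self):
        s = [self.spine(0.0, 0), self.spine(1.0, 1)]
        assert len(dyn.pair_ssb_neighbors(s, s)) == 1

    def test_agrees_with_brute_force_search(self, rng):
        for _ in range(50):
            xs = rng.uniform(0, 30, size=8)
            spines = [self.spine(float(x), i) for i, x in enumerate(xs)]
            pairs = dyn.pair_ssb_neighbors(spines, spines)
            got = {frozenset((a.id, b.id)) for a, b in pairs}
            expected = set()
            for i, x in enumerate(xs):
                d = np.abs(xs - x)
                d[i] = np.inf
                expected.add(frozenset((i, int(d.argmin()))))
            assert got == expected


def fake_pair(pair_id, pair_class, rate, r2):
    t = np.arange(3.0)
    return dyn.PairDynamics(pair_id=pair_id, pair_class=pair_class, times=t,
                            intden_dom=np.ones(3), intden_nondom=np.ones(3),
                            diff_index=np.zeros(3), dominance_rate=rate,
                            r_squared=r2)


class TestCompareClasses:
    def test_fold_ratio_on_sampled_default_classes(self):
        """MSB vs single-bouton rates at defaults: ≈ 21-fold apart."""
        cfg = m.SceneConfig(seed=43)
        msb = [dyn.pair_dynamics(s.pair_id, "msb", s.times, s.intden_a,
                                 s.intden_b)
               for s in m.sample_pair_dynamics(cfg, 1000, "msb")]
        ssb = [dyn.pair_dynamics(s.pair_id, "ssb", s.times, s.intden_a,
                                 s.intden_b)
               for s in m.sample_pair_dynamics(cfg, 1000, "ssb")]
        report = dyn.compare_classes(msb, ssb)
        # 3σ band from error propagation of the two sample means
        assert 14 <= report["rate_fold"] <= 28
        assert report["rate_p_one_tailed"] < 0.05

    def test_identical_classes_fold_one_not_significant(self):
        a = [fake_pair(i, "msb", 0.01, 0.5) for i in range(3)]
        a[0].dominance_rate = 0.012  # avoid zero variance
        b = [fake_pair(i, "ssb", p.dominance_rate, p.r_squared)
             for i, p in enumerate(a)]
        report = dyn.compare_classes(a, b)
        assert report["rate_fold"] == pytest.approx(1.0)
        assert report["rate_p_one_tailed"] >= 0.05

    def test_single_pair_classes_not_computable(self):
        report = dyn.compare_classes([fake_pair(0, "msb", 0.04, 0.5)],
                                     [fake_pair(0, "ssb", 0.002, 0.1)])
        assert report["rate_p_one_tailed"] is None
        assert report["msb"]["rate_mean"] == 0.04
        assert "not computable" in report["rate_test"]

    def test_empty_class_raises(self):
        with pytest.raises(InsufficientDataError):
            dyn.compare_classes([], [fake_pair(0, "ssb", 0.0, 0.0)])
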