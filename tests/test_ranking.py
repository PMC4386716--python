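from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import camoband as cb
from camoband.ranking import D_CAP, select_peaks, smooth_curve


def exhaustive_two_means(values):
    """Independent oracle: exact-rational scan of every threshold partition,
    minimising the within-class sum of squares (first minimiser on ties)."""
    xs = sorted(int(v) for v in values)
    n = len(xs)
    sq = sum(Fraction(v) ** 2 for v in xs)
    best = None
    for k in range(1, n):
        if xs[k - 1] == xs[k]:
            continue
        s1, s2 = sum(xs[:k]), sum(xs[k:])
        wcss = sq - Fraction(s1**2, k) - Fraction(s2**2, n - k)
        if best is None or wcss < best[0]:
            best = (wcss, k)
    return best  # (min WCSS as Fraction, split size)


class TestFitTwoClasses:
    def test_perfectly_separated(self):
        fit = cb.fit_two_classes(np.array([0, 0, 0, 0, 10, 10, 10, 10]))
        assert (fit.mu1, fit.mu2, fit.sigma1, fit.sigma2) == (0, 10, 0, 0)
        assert not fit.degenerate

    def test_matches_exhaustive_partition(self):
        fit = cb.fit_two_classes(np.array([1, 2, 9, 10]))
        assert (fit.mu1, fit.mu2) == (1.5, 9.5)
        assert fit.sigma1 == fit.sigma2 == 0.5

    def test_constant_image_is_degenerate(self):
        fit = cb.fit_two_classes(np.full((3, 3), 5.0))
        assert fit.degenerate
        assert fit.mu1 == fit.mu2 == 5.0

    def test_lower_mean_reported_first(self):
        rng = np.random.default_rng(2)
        fit = cb.fit_two_classes(rng.normal(100, 5, size=(8, 8)))
        assert fit.mu1 <= fit.mu2

    def test_oracle_equivalence_on_small_images(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            n = int(rng.integers(2, 65))
            vals = rng.integers(0, 16, size=n)
            if vals.min() == vals.max():
                continue
            fit = cb.fit_two_classes(vals)
            w_min, k_oracle = exhaustive_two_means(vals)
            xs = np.sort(vals.astype(float))
            k_impl = int(np.sum(xs <= fit.threshold))
            n1, n2 = k_impl, n - k_impl
            wcss_impl = n1 * fit.sigma1**2 + n2 * fit.sigma2**2
            assert wcss_impl == pytest.approx(float(w_min), abs=1e-9)
            if k_impl == k_oracle:
                lo, hi = xs[:k_oracle], xs[k_oracle:]
                assert fit.mu1 == pytest.approx(lo.mean())
                assert fit.sigma2 == pytest.approx(hi.std())


class TestDiscriminability:
    def test_basic_ratio(self):
        assert cb.discriminability(10, 20, 2, 3) == 2.0

    def test_equal_means_give_zero(self):
        assert cb.discriminability(7.0, 7.0, 1.0, 2.0) == 0.0

    def test_zero_spread_is_capped_not_infinite(self):
        d = cb.discriminability(0, 10, 0, 0)
        assert d == D_CAP
        assert d > cb.discriminability(0, 1e5, 1.0, 0)  # ranks above any finite D
        assert cb.discriminability(0, 1e9, 1e-3, 0) == D_CAP  # overflow clipped too

    def test_non_finite_inputs_rejected(self):
        with pytest.raises(ValueError):
            cb.discriminability(np.nan, 1, 1, 1)

    @settings(derandomize=True, max_examples=40)
    @given(seed=st.integers(0, 2**31 - 1), c=st.floats(1e-3, 1e3), shift=st.floats(-1e4, 1e4))
    def test_scale_and_shift_invariance(self, seed, c, shift):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 4096, size=(6, 6)).astype(float)
        if img.min() == img.max():
            img[0, 0] += 1
        base = cb.fit_two_classes(img)
        trans = cb.fit_two_classes(c * img + shift)
        d0 = cb.discriminability(base.mu1, base.mu2, base.sigma1, base.sigma2)
        d1 = cb.discriminability(trans.mu1, trans.mu2, trans.sigma1, trans.sigma2)
        assert d1 == pytest.approx(d0, rel=1e-6)


class TestBuildCurve:
    def test_argmax_lies_in_planted_window(self, default_scene, default_cube):
        cube, _ = default_cube
        curve = cb.build_curve(cube)
        win = set(cb.planted_window(default_scene).tolist())
        assert int(np.argmax(curve.d_values)) in win
        assert set(curve.candidates) & win

    def test_pure_noise_yields_no_candidates(self):
        # empirical null: flat curve around the two-means-on-noise level
        for seed in range(10):
            rng = np.random.default_rng(seed)
            cube = cb.Hypercube(
                rng.normal(2000, 30, size=(32, 32, 40)).clip(0),
                np.linspace(400, 1000, 40),
            )
            curve = cb.build_curve(cube)
            assert curve.candidates == []

    def test_single_band_cube(self):
        rng = np.random.default_rng(0)
        cube = cb.Hypercube(rng.random((8, 8, 1)), np.array([500.0]))
        curve = cb.build_curve(cube)
        assert len(curve.stats) == 1

    def test_degenerate_band_gets_zero_d(self):
        data = np.ones((4, 4, 2))
        data[:, :2, 1] = 5.0
        cube = cb.Hypercube(data, np.array([500.0, 510.0]))
        curve = cb.build_curve(cube)
        assert curve.stats[0].d_value == 0.0
        assert curve.stats[0].degenerate

    def test_curve_csv_export_columns(self, default_cube):
        cube, _ = default_cube
        df = cb.build_curve(cube).to_frame()
        assert list(df.columns) == [
            "band_index", "wavelength_nm", "mu1", "mu2",
            "sigma1", "sigma2", "d_value", "is_candidate",
        ]
        assert len(df) == cube.n_bands


class TestSelectCandidates:
    def test_two_peaks_above_floor(self):
        # brute-force check on the 5-vector: peaks at 1 and 3, floor 0.2*5=1
        assert cb.select_candidates([1, 5, 1, 4, 1], smoothing_window=1,
                                    min_prominence_fraction=0.2) == [1, 3]

    def test_monotone_curve_peaks_at_last_band(self):
        assert cb.select_candidates([1, 2, 3, 4, 5], smoothing_window=1) == [4]

    def test_global_mode_returns_single_argmax_first_on_ties(self):
        assert cb.select_candidates([1, 4, 2, 4, 1], mode="global_maximum",
                                    smoothing_window=1) == [1]

    def test_plateau_reports_leftmost_index(self):
        assert cb.select_candidates([0, 3, 3, 3, 0], smoothing_window=1) == [1]

    def test_flat_curve_gives_empty_selection(self):
        assert cb.select_candidates([2.0, 2.0, 2.0, 2.0], smoothing_window=1) == []

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            cb.select_candidates([1, 2, 1], smoothing_window=2)

    def test_smoothing_is_truncated_moving_average(self):
        sm = smooth_curve(np.array([0.0, 3.0, 6.0, 9.0]), 3)
        assert sm == pytest.approx([1.5, 3.0, 6.0, 7.5])

    @settings(derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_peaks_are_sorted_unique_and_in_range(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.random(30)
        peaks = select_peaks(values, smoothing_window=5, min_prominence_fraction=0.05)
        assert peaks == sorted(set(peaks))
        assert all(0 <= p < 30 for p in peaks)
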