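"""Correlator stage: window sizing, Pearson oracle, surfaces, ranges."""

import math

import numpy as np
import pytest

import stereocorr as sc
from stereocorr.correlator import (
    CorrelatorGrid,
    SizeDisparityRelation,
    correlation_surface,
    disparity_range_in_window,
    window_sigma,
    windowed_correlation,
)
from stereocorr.stimgen import DisparityProfile, StereoPair


def brute_force_pearson(L, R, x, y, dx_px, sigma, pitch):
    """Independent oracle: explicit double loop + textbook Pearson."""
    k = math.ceil(2.0 * sigma / pitch) - 1
    a, b = [], []
    for oy in range(-k, k + 1):
        for ox in range(-k, k + 1):
            w = math.exp(-((ox * pitch) ** 2 + (oy * pitch) ** 2)
                         / (2.0 * sigma ** 2))
            a.append(w * L[y + oy, x + ox])
            b.append(w * R[y + oy, x + ox + dx_px])
    a, b = np.array(a), np.array(b)
    am, bm = a - a.mean(), b - b.mean()
    return float((am @ bm) / np.sqrt((am @ am) * (bm @ bm)))


@pytest.fixture(scope="module")
def random_pair():
    rng = np.random.default_rng(77)
    L = rng.standard_normal((90, 90))
    R = rng.standard_normal((90, 90))
    return StereoPair(left=L, right=R, pixel_pitch=0.6, extent=(0.9, 0.9))


class TestWindowSigma:
    def test_quadratic_values(self):
        rel = SizeDisparityRelation.quadratic()
        assert rel.sigma(0.0) == pytest.approx(3.0)
        assert rel.sigma(13.0) == pytest.approx(8.408)
        # the relation assigns 2*sigma ~ 10 arcmin to 7.6' detectors
        assert rel.sigma(7.6) == pytest.approx(4.85, abs=0.01)

    def test_constant_and_linear(self):
        assert SizeDisparityRelation.constant().sigma(99.0) == 3.0
        lin = SizeDisparityRelation.linear()
        assert lin.sigma(-10.0) == pytest.approx(3.0 + 2.4)

    def test_even_and_monotone(self):
        for rel in (SizeDisparityRelation.quadratic(),
                    SizeDisparityRelation.linear(),
                    SizeDisparityRelation.constant()):
            dx = np.linspace(0, 20, 50)
            s = rel.sigma(dx)
            assert np.all(np.diff(s) >= 0)
            np.testing.assert_allclose(rel.sigma(-dx), s)


class TestWindowedCorrelation:
    def test_identical_patches_give_one(self, random_pair):
        pair = StereoPair(left=random_pair.left,
                          right=random_pair.left.copy(),
                          pixel_pitch=0.6, extent=random_pair.extent)
        assert windowed_correlation(pair, 45, 45, 0.0, 3.0) == pytest.approx(
            1.0, abs=1e-12)

    def test_anticorrelated_patches_give_minus_one(self, random_pair):
        pair = StereoPair(left=random_pair.left,
                          right=-random_pair.left,
                          pixel_pitch=0.6, extent=random_pair.extent)
        assert windowed_correlation(pair, 45, 45, 0.0, 3.0) == pytest.approx(
            -1.0, abs=1e-12)

    def test_hand_computed_3x3_patch(self):
        """sigma spanning the patch; value checked against by-hand Pearson."""
        L = np.array([[1.0, 2.0, 0.0],
                      [0.5, -1.0, 1.5],
                      [0.0, 1.0, -0.5]])
        R = np.array([[0.5, 1.5, 0.5],
                      [1.0, -0.5, 1.0],
                      [0.5, 0.5, 0.0]])
        pair = StereoPair(left=L, right=R, pixel_pitch=1.0,
                          extent=(0.05, 0.05))
        got = windowed_correlation(pair, 1, 1, 0.0, 1.0)
        expected = brute_force_pearson(L, R, 1, 1, 0, 1.0, 1.0)
        assert got == pytest.approx(expected, abs=1e-14)

    def test_blank_region_flagged_undefined(self):
        L = np.zeros((21, 21))
        R = np.ones((21, 21))
        pair = StereoPair(left=L, right=R, pixel_pitch=0.6, extent=(0.21,) * 2)
        assert np.isnan(windowed_correlation(pair, 10, 10, 0.0, 2.0))

    def test_oracle_equivalence_100_random_windows(self, random_pair):
        """Max deviation from the brute-force oracle below 1e-10."""
        rng = np.random.default_rng(5)
        worst = 0.0
        for _ in range(100):
            x = int(rng.integers(25, 65))
            y = int(rng.integers(25, 65))
            ddx = int(rng.integers(-10, 11))
            sigma = float(rng.uniform(1.2, 6.0))
            got = windowed_correlation(random_pair, x, y, ddx * 0.6, sigma)
            ref = brute_force_pearson(random_pair.left, random_pair.right,
                                      x, y, ddx, sigma, 0.6)
            worst = max(worst, abs(got - ref))
        assert worst < 1e-10

    def test_non_grid_disparity_rejected(self, random_pair):
        with pytest.raises(ValueError):
            windowed_correlation(random_pair, 45, 45, 0.25, 3.0)


class TestCorrelationSurface:
    def test_matches_single_point_computation(self, random_pair):
        grid = CorrelatorGrid.standard(6.0)
        rel = SizeDisparityRelation.quadratic()
        surf = correlation_surface(random_pair, grid, rel, x=45)
        for j, dx in enumerate(grid.disparities):
            for y in (25, 45, 60):
                direct = windowed_correlation(random_pair, 45, y, dx,
                                              rel.sigma(dx))
                assert surf.C[y, j] == pytest.approx(direct, abs=1e-10)

    def test_scale_invariance(self, random_pair):
        grid = CorrelatorGrid.standard(6.0)
        rel = SizeDisparityRelation.quadratic()
        s1 = correlation_surface(random_pair, grid, rel)
        scaled = StereoPair(left=7.0 * random_pair.left,
                            right=7.0 * random_pair.right,
                            pixel_pitch=0.6, extent=random_pair.extent)
        s2 = correlation_surface(scaled, grid, rel)
        np.testing.assert_allclose(s1.C, s2.C, atol=1e-12)

    def test_eye_swap_disparity_negation_symmetry(self, random_pair):
        """Swapping eyes and negating the disparity axis preserves C."""
        grid = CorrelatorGrid.standard(6.0)
        rel = SizeDisparityRelation.quadratic()
        s1 = correlation_surface(random_pair, grid, rel, x=45)
        swapped = StereoPair(left=random_pair.right, right=random_pair.left,
                             pixel_pitch=0.6, extent=random_pair.extent)
        interior = slice(25, 65)
        for j, dx in enumerate(grid.disparities):
            ddx = int(round(dx / 0.6))
            # the swapped-eye correlator centred at x+dx with disparity -dx
            # sees the same two patches
            s_swap = correlation_surface(
                swapped, CorrelatorGrid(disparities=np.array([-dx])),
                rel, x=45 + ddx)
            np.testing.assert_allclose(s_swap.C[interior, 0],
                                       s1.C[interior, j], atol=1e-10)

    def test_edge_rows_flagged(self, random_pair):
        grid = CorrelatorGrid.standard(6.0)
        rel = SizeDisparityRelation.quadratic()
        surf = correlation_surface(random_pair, grid, rel)
        assert np.isnan(surf.C[0]).all()
        assert np.isnan(surf.C[-1]).all()
        assert np.isfinite(surf.C[45]).all()

    def test_values_bounded(self, random_pair):
        grid = CorrelatorGrid.standard(6.0)
        surf = correlation_surface(random_pair, grid,
                                   SizeDisparityRelation.quadratic())
        d = surf.C[np.isfinite(surf.C)]
        assert np.all(d >= -1.0) and np.all(d <= 1.0)

    def test_empty_grid_rejected(self, random_pair):
        with pytest.raises(ValueError):
            CorrelatorGrid(disparities=np.array([]))

    def test_uniform_disparity_peak_location(self):
        """An RDS of uniform disparity d peaks at dx = d (20 seeds)."""
        cfg = sc.PipelineConfig(extent=(1.0, 1.0),
                                grid=CorrelatorGrid.standard(6.0))
        prof = DisparityProfile("square", 2.4, frequency=0.25, phase=90.0)
        # frequency 0.25 cpd, phase 90: the entire 1-deg field sits on the
        # +2.4' plateau -> uniform disparity
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            surf = cfg.simulate_surface(prof, rng)
            m = np.nanmean(surf.C, axis=0)
            if surf.disparities[np.nanargmax(m)] == pytest.approx(2.4):
                hits += 1
        assert hits >= 19

    def test_uncorrelated_eyes_give_zero_mean_correlation(self):
        """Binocularly uncorrelated RDS: mean C is zero within 3 SE.

        Surface entries within one stimulus share windows and are heavily
        dependent, so the Monte-Carlo averages per-stimulus surface means
        over independent stimulus pairs.
        """
        cfg = sc.PipelineConfig(extent=(1.0, 1.0),
                                grid=CorrelatorGrid.standard(6.0))
        prof = DisparityProfile("sine", 0.0, frequency=1.0)
        means = []
        for seed in range(12):
            rng = np.random.default_rng(100 + seed)
            # independent dot fields per eye: take the left image of one
            # stimulus and the right image of another
            p1 = cfg.simulate_pair(prof, rng)
            p2 = cfg.simulate_pair(prof, rng)
            pair = StereoPair(left=p1.left, right=p2.right, pixel_pitch=0.6,
                              extent=p1.extent)
            surf = correlation_surface(pair, cfg.grid, cfg.relation)
            means.append(np.nanmean(surf.C))
        means = np.asarray(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean()) < 3.0 * se

    def test_heatmap_export(self, tmp_path, random_pair):
        surf = correlation_surface(random_pair, CorrelatorGrid.standard(6.0),
                                   SizeDisparityRelation.quadratic())
        out = tmp_path / "surface.png"
        surf.save_heatmap(out, title="debug")
        assert out.exists() and out.stat().st_size > 0

    def test_hdf5_roundtrip(self, tmp_path, random_pair):
        grid = CorrelatorGrid.standard(6.0)
        surf = correlation_surface(random_pair, grid,
                                   SizeDisparityRelation.quadratic())
        surf.to_hdf5(tmp_path / "surf.h5")
        back = sc.CorrelationSurface.from_hdf5(tmp_path / "surf.h5")
        np.testing.assert_array_equal(back.C, surf.C)
        assert back.meta["relation"] == "quadratic"


class TestDisparityRangeInWindow:
    @pytest.mark.parametrize("A,phase,h,expected", [
        (1.3, 90.0, 3.0, 0.8),    # peak-centred, low amplitude
        (1.3, 0.0, 3.0, 2.4),     # zero-crossing-centred, low amplitude
        (7.6, 0.0, 3.0, 14.1),    # zero-crossing-centred, high amplitude
        (7.6, 90.0, 3.0, 4.8),    # peak-centred, high amplitude
        (7.6, 90.0, 5.0, 10.7),   # enlarged window at the peak
    ])
    def test_sine_window_ranges(self, A, phase, h, expected):
        p = DisparityProfile("sine", A, frequency=3.8, phase=phase)
        assert disparity_range_in_window(p, 0.0, h) == pytest.approx(
            expected, abs=0.1)

    def test_matches_peak_centred_closed_form(self):
        # A (1 - cos(2 pi f h)) for a window centred on the peak
        for A, f, h in [(2.0, 1.3, 4.0), (5.0, 0.8, 2.5)]:
            p = DisparityProfile("sine", A, frequency=f, phase=90.0)
            expected = A * (1 - np.cos(2 * np.pi * f * h / 60.0))
            assert disparity_range_in_window(p, 0.0, h) == pytest.approx(
                expected, abs=1e-9)

    def test_zero_halfwidth_gives_zero(self):
        p = DisparityProfile("sine", 5.0, frequency=2.0)
        assert disparity_range_in_window(p, 0.123, 0.0) == 0.0

    def test_matches_dense_sampling(self, rng):
        """Closed-form extrema agree with brute-force dense evaluation."""
        for _ in range(20):
            A = float(rng.uniform(0.5, 10))
            f = float(rng.uniform(0.5, 4))
            ph = float(rng.uniform(0, 360))
            yc = float(rng.uniform(-0.3, 0.3))
            h = float(rng.uniform(0.5, 10))
            p = DisparityProfile("sine", A, frequency=f, phase=ph)
            ys = np.linspace(yc - h / 60, yc + h / 60, 20001)
            d = A * np.sin(2 * np.pi * f * ys + np.deg2rad(ph))
            assert disparity_range_in_window(p, yc, h) == pytest.approx(
                d.max() - d.min(), abs=1e-5)

    def test_square_wave_edge_vs_plateau(self):
        p = DisparityProfile("square", 3.0, frequency=1.0, phase=0.0)
        # window straddling the edge at y=0 sees both disparities
        assert disparity_range_in_window(p, 0.0, 2.0) == pytest.approx(6.0)
        # window wholly inside a half-cycle sees constant disparity
        assert disparity_range_in_window(p, 0.25, 2.0) == 0.0
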