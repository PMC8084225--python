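import numpy as np
import pytest

from eaa.smoothing import (Z_NULL_BAND, choose_k, fit_curve, fit_surface,
                           locate_extrema, surface_cross_sections)


class TestFitCurve:
    def test_reproduces_linear_data(self):
        x = np.linspace(0, 300, 60)
        y = 0.02 * x - 1.0
        for k in (4, 8, 12):
            fit = fit_curve(x, y, k=k, grid=x)
            assert np.allclose(fit.fitted, y, atol=1e-6)

    def test_constant_data(self):
        x = np.linspace(0, 10, 30)
        fit = fit_curve(x, np.full(30, 3.3), k=6, grid=x)
        assert np.allclose(fit.fitted, 3.3, atol=1e-8)
        assert np.all((fit.lower <= 3.3 + 1e-8) & (fit.upper >= 3.3 - 1e-8))

    def test_sine_recovery_and_band_coverage(self):
        rng = np.random.default_rng(0)
        x = np.sort(rng.uniform(0, 200, 200))
        truth = np.sin(x / 30.0)
        y = truth + rng.normal(0, 0.2, 200)
        fit = fit_curve(x, y, k=12, grid=x)
        rmse = np.sqrt(np.mean((fit.fitted - truth) ** 2))
        assert rmse < 0.15
        covered = np.mean((fit.lower <= truth) & (truth <= fit.upper))
        assert covered >= 0.90

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            fit_curve(np.arange(5.0), np.arange(5.0), k=5)

    def test_linearity_in_y(self):
        rng = np.random.default_rng(1)
        x = np.sort(rng.uniform(0, 100, 80))
        y = rng.normal(0, 1, 80)
        f1 = fit_curve(x, y, k=8, grid=x)
        f2 = fit_curve(x, 3.0 * y + 2.0, k=8, lam_grid=[f1.lam], grid=x)
        assert np.allclose(f2.fitted, 3.0 * f1.fitted + 2.0, atol=1e-8)

    def test_band_shrinks_with_more_replicates(self):
        rng = np.random.default_rng(2)
        xb = np.linspace(0, 100, 20)
        def width(reps):
            x = np.tile(xb, reps)
            y = np.sin(x / 25) + rng.normal(0, 0.5, x.size)
            fit = fit_curve(x, y, k=8, grid=xb)
            return np.median(fit.upper - fit.lower)
        assert width(40) < width(10)

    def test_significance_mask_uses_null_band(self):
        x = np.linspace(0, 10, 40)
        fit = fit_curve(x, np.full(40, 5.0), k=5)
        assert fit.significant.all()           # well outside +-1.96
        fit0 = fit_curve(x, np.zeros(40), k=5)
        assert not fit0.significant.any()
        assert Z_NULL_BAND == pytest.approx(1.959964, abs=1e-5)


class TestChooseK:
    def test_linear_data_selects_smallest(self):
        x = np.linspace(0, 100, 60)
        y = 0.1 * x
        assert choose_k(x, y, k_grid=range(4, 13)) == 4

    def test_wiggly_truth_needs_larger_basis(self):
        rng = np.random.default_rng(3)
        x = np.sort(rng.uniform(0, 100, 300))
        y = np.sin(x / 3.0) + rng.normal(0, 0.1, 300)
        assert choose_k(x, y, k_grid=range(4, 21)) >= 10

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        x = np.sort(rng.uniform(0, 50, 100))
        y = np.cos(x / 5) + rng.normal(0, 0.2, 100)
        assert choose_k(x, y) == choose_k(x, y)


class TestStatsmodelsOracle:
    def test_agrees_with_independent_gam_implementation(self):
        # statsmodels GLMGam (penalized B-splines, independent smoothing choice)
        # serves as the cross-check on a smooth truth
        from statsmodels.gam.api import BSplines, GLMGam

        rng = np.random.default_rng(5)
        x = np.sort(rng.uniform(0, 200, 300))
        truth = np.sin(x / 40.0) + 0.5 * np.cos(x / 90.0)
        y = truth + rng.normal(0, 0.1, 300)
        ours = fit_curve(x, y, k=12, grid=x)
        bs = BSplines(x[:, None], df=[12], degree=[3])
        gam = GLMGam(y, np.ones((x.size, 1)), smoother=bs, alpha=[1.0])
        res = gam.fit()
        theirs = res.predict(np.ones((x.size, 1)), exog_smooth=x[:, None])
        assert np.sqrt(np.mean((ours.fitted - truth) ** 2)) < 0.08
        assert np.sqrt(np.mean((theirs - truth) ** 2)) < 0.15
        assert np.corrcoef(ours.fitted, theirs)[0, 1] > 0.99


class TestFitSurface:
    def test_constant_along_physical_axis(self):
        rng = np.random.default_rng(6)
        ann = np.repeat(np.linspace(2, 12, 6), 30)
        phy = np.tile(np.linspace(0, 300, 30), 6)
        y = np.sin(phy / 60.0) + rng.normal(0, 0.1, phy.size)
        fit = fit_surface(ann, phy, y, k=(4, 8))
        secs = surface_cross_sections(fit)
        profiles = np.stack([v for _, v in secs.values()])
        spread = profiles.max(axis=0) - profiles.min(axis=0)
        assert np.median(spread) < 0.3  # constant in the physical direction

    def test_separable_signal_keeps_argmax_across_annuli(self):
        rng = np.random.default_rng(7)
        ann = np.repeat(np.linspace(2, 12, 8), 40)
        phy = np.tile(np.linspace(0, 300, 40), 8)
        truth = np.exp(-((phy - 120) ** 2) / (2 * 40**2)) * (1.5 - 0.08 * ann)
        y = truth + rng.normal(0, 0.1, phy.size)
        fit = fit_surface(ann, phy, y, k=(5, 9))
        bin_width = 300 / 40
        for g2, vals in surface_cross_sections(fit).items():
            xg, fg = vals
            assert abs(xg[np.argmax(fg)] - 120) <= 300 / 8 + bin_width

    def test_mask_gray_where_no_effect(self):
        rng = np.random.default_rng(8)
        ann = np.repeat(np.linspace(2, 12, 5), 25)
        phy = np.tile(np.linspace(0, 300, 25), 5)
        y = rng.normal(0, 0.3, phy.size)  # null everywhere
        fit = fit_surface(ann, phy, y, k=(4, 6))
        assert not fit.significant.any()

    def test_degenerate_grid_raises(self):
        with pytest.raises(ValueError):
            fit_surface([1, 1, 1], [0, 10, 20], [0.0, 0.1, 0.2])


class TestLocateExtrema:
    def test_monotone_curve_has_none(self):
        x = np.linspace(0, 100, 50)
        fit = fit_curve(x, 0.05 * x, k=5)
        assert locate_extrema(fit) == []

    def test_planted_valley_found_near_its_location(self):
        rng = np.random.default_rng(9)
        x = np.sort(rng.uniform(0, 300, 400))
        truth = -3.0 * np.exp(-((x - 100) ** 2) / (2 * 25**2))
        y = truth + rng.normal(0, 0.2, 400)
        fit = fit_curve(x, y, k=14)
        valleys = [e for e in locate_extrema(fit) if e["kind"] == "valley"]
        assert valleys and abs(valleys[0]["x"] - 100) < 30

    def test_two_features_ranked_by_prominence(self):
        rng = np.random.default_rng(10)
        x = np.sort(rng.uniform(0, 300, 500))
        truth = (-3.0 * np.exp(-((x - 80) ** 2) / (2 * 20**2))
                 + 1.5 * np.exp(-((x - 220) ** 2) / (2 * 20**2)))
        y = truth + rng.normal(0, 0.15, 500)
        fit = fit_curve(x, y, k=16)
        found = locate_extrema(fit)
        assert len(found) >= 2
        assert found[0]["kind"] == "valley" and abs(found[0]["x"] - 80) < 30
        peaks = [e for e in found if e["kind"] == "peak"]
        assert peaks and abs(peaks[0]["x"] - 220) < 30
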