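"""Spacing-curve, clipped-line and CSF fitting: recovery, algebra, oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from perifield import (critical_distance, clipped_line_model, csf_model,
                       fit_clipped_line, fit_csf, fit_spacing_curve,
                       minimum_contrast_per_eccentricity, spacing_model)


class TestSpacingCurve:
    def test_noiseless_recovery(self):
        x = np.array([0.6, 0.8, 1.0, 1.5, 2.5])
        y = spacing_model(x, 0.1, 5.0, 0.5)
        fit = fit_spacing_curve(x, y)
        assert fit.alpha == pytest.approx(0.1, abs=1e-4)
        assert fit.s == pytest.approx(5.0, abs=1e-3)
        assert fit.t == pytest.approx(0.5, abs=1e-4)
        assert fit.ybase == pytest.approx(0.1, abs=1e-4)
        assert fit.xcrit == pytest.approx(0.5 + math.log(10) / 5.0, abs=1e-3)

    def test_flat_data_pins_t_at_bound(self):
        x = np.array([0.7, 1.05, 1.4, 1.75, 2.1])
        fit = fit_spacing_curve(x, np.full(5, 0.08))
        assert fit.alpha == pytest.approx(0.08, abs=1e-6)
        assert fit.xcrit <= x.min()
        assert fit.at_bound["t"]

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_spacing_curve([1.0, 2.0, 3.0], [0.1, 0.1, 0.1])
        with pytest.raises(ValueError):
            fit_spacing_curve([1.0, 1.0, 2.0, 2.0], [0.1] * 4)

    def test_out_of_range_thresholds_rejected(self):
        with pytest.raises(ValueError):
            fit_spacing_curve([1, 2, 3, 4], [0.1, 0.2, 1.5, 0.1])

    def test_objective_matches_brute_force_grid(self):
        """Constrained optimizer reaches the dense grid-search objective on
        small instances (oracle equivalence)."""
        rng = np.random.default_rng(17)
        alphas = np.linspace(0.01, 0.4, 45)
        ss = np.logspace(np.log10(0.3), np.log10(25), 60)
        for _ in range(5):
            a0 = rng.uniform(0.02, 0.2)
            s0 = rng.uniform(1.0, 8.0)
            t0 = rng.uniform(0.0, 0.5)
            x = np.sort(rng.uniform(0.5, 3.0, 6))
            y = np.clip(spacing_model(x, a0, s0, t0)
                        * np.exp(rng.normal(0, 0.1, 6)), 1e-3, 1.0)
            fit = fit_spacing_curve(x, y)
            sse_fit = float(np.sum((spacing_model(x, fit.alpha, fit.s, fit.t)
                                    - y) ** 2))
            ts = np.linspace(0, x.min(), 40)
            best = np.inf
            for t in ts:
                pred = (alphas[:, None, None]
                        + (1 - alphas[:, None, None])
                        * np.exp(-ss[None, :, None]
                                 * np.maximum(x[None, None, :] - t, 0)))
                pred = np.where(x[None, None, :] >= t, pred, 1.0)
                sse = ((pred - y[None, None, :]) ** 2).sum(axis=-1)
                best = min(best, float(sse.min()))
            assert sse_fit <= best + 1e-6

    def test_critical_distance_formula(self):
        class F:
            s, t = 5.0, 0.5
        assert critical_distance(F) == pytest.approx(0.96052, abs=5e-6)
        F.s, F.t = 25.0, 0.0
        assert critical_distance(F) == pytest.approx(math.log(10) / 25, abs=1e-9)
        F.s = -1.0
        with pytest.raises(ValueError):
            critical_distance(F)

    def test_elevation_at_critical_distance_is_ten_percent(self):
        # y(xcrit) - alpha = 0.1 * (1 - alpha) exactly, by construction
        for alpha, s, t in [(0.05, 3.0, 0.2), (0.2, 10.0, 0.0)]:
            xc = t + math.log(10) / s
            assert spacing_model(xc, alpha, s, t) - alpha == pytest.approx(
                0.1 * (1 - alpha), abs=1e-12)


class TestClippedLine:
    def test_noiseless_recovery_and_critical_eccentricity(self):
        x = np.array([4.0, 6.0, 8.0, 9.5, 11.0, 13.0, 16.0, 18.0])
        y = clipped_line_model(x, 0.05, 0.04, 10.0)
        fit = fit_clipped_line(x, y)
        assert fit.b == pytest.approx(0.05, abs=1e-3)
        assert fit.m == pytest.approx(0.04, abs=1e-3)
        assert fit.x0 == pytest.approx(10.0, abs=1e-2)
        assert fit.xcrit_ecc == pytest.approx(10.0 + 0.1 * 0.05 / 0.04,
                                              abs=0.02)

    def test_flat_data_clamps_slope_and_undefined_critical_ecc(self):
        x = np.linspace(4, 9, 6)
        fit = fit_clipped_line(x, np.full(6, 0.06))
        assert fit.m == 0.0
        assert math.isnan(fit.xcrit_ecc)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_clipped_line([1, 2, 3, 4], [0.1] * 4)

    def test_threshold_at_critical_ecc_is_ten_percent_above_baseline(self):
        x = np.array([4.0, 6.0, 8.0, 9.5, 11.0, 13.0, 16.0, 18.0])
        y = clipped_line_model(x, 0.063, 0.042, 10.0)
        fit = fit_clipped_line(x, y)
        assert clipped_line_model(fit.xcrit_ecc, fit.b, fit.m, fit.x0) == \
            pytest.approx(1.1 * fit.b, rel=1e-6)


class TestMinimumContrast:
    def test_minimum_over_reliable_cells(self):
        df = pd.DataFrame({
            "participant_id": ["p"] * 3, "eccentricity_deg": [3.5] * 3,
            "threshold": [0.07, 0.06, 0.09], "reliable": [True] * 3})
        out = minimum_contrast_per_eccentricity(df)
        assert out["min_contrast"].iloc[0] == pytest.approx(0.06)

    def test_unreliable_cells_excluded(self):
        df = pd.DataFrame({
            "participant_id": ["p"] * 3, "eccentricity_deg": [7.0] * 3,
            "threshold": [0.01, 0.06, 0.09],
            "reliable": [False, True, True]})
        out = minimum_contrast_per_eccentricity(df)
        assert out["min_contrast"].iloc[0] == pytest.approx(0.06)

    def test_all_unreliable_yields_missing(self):
        df = pd.DataFrame({
            "participant_id": ["p"], "eccentricity_deg": [10.5],
            "threshold": [0.2], "reliable": [False]})
        out = minimum_contrast_per_eccentricity(df)
        assert math.isnan(out["min_contrast"].iloc[0])


class TestCSF:
    def test_closed_form_peak(self):
        f = np.array([0.3, 0.5, 1, 2, 4, 6, 8], dtype=float)
        thr = 1.0 / csf_model(f, 2.0, 30.0, 1.0)
        fit = fit_csf(f, thr)
        assert fit.fmax == pytest.approx(1 - 2 / 30, abs=1e-6)
        assert fit.smax == pytest.approx(30 * math.exp(-(1 - 2 / 30)),
                                         rel=1e-6)
        # derivative at the peak vanishes
        eps = 1e-6
        d = (csf_model(fit.fmax + eps, fit.a, fit.b, fit.c)
             - csf_model(fit.fmax - eps, fit.a, fit.b, fit.c)) / (2 * eps)
        assert abs(d) < 1e-6

    def test_half_height_root_matches_grid_search(self):
        fit = fit_csf(np.array([0.3, 0.5, 1, 2, 4, 6, 8]),
                      1.0 / csf_model(np.array([0.3, 0.5, 1, 2, 4, 6, 8]),
                                      2.0, 30.0, 1.0))
        grid = np.linspace(fit.fmax, 50, 4_000_001)
        vals = csf_model(grid, fit.a, fit.b, fit.c)
        brute = grid[np.argmin(np.abs(vals - fit.smax / 2))]
        assert fit.sf_cutoff == pytest.approx(brute, abs=1e-4)
        assert fit.sf_cutoff > fit.fmax
        assert fit.hbw_high == pytest.approx(fit.sf_cutoff - fit.fmax)

    def test_scale_invariance_of_peak_frequency(self):
        f = np.array([0.3, 0.5, 1, 2, 4, 6, 8], dtype=float)
        sens = csf_model(f, 2.0, 30.0, 1.0)
        fit1 = fit_csf(f, 1.0 / sens)
        fit3 = fit_csf(f, 1.0 / (3.0 * sens))
        assert fit3.fmax == pytest.approx(fit1.fmax, rel=1e-6)
        assert fit3.smax == pytest.approx(3 * fit1.smax, rel=1e-6)

    def test_nonpositive_thresholds_rejected(self):
        with pytest.raises(ValueError):
            fit_csf([1, 2, 3], [0.1, -0.2, 0.3])
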