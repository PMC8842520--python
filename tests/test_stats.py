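"""Normalization, exclusion bookkeeping, and correlation statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from perifield import (apply_exclusions, field_size_deg, normalize_measures,
                       pearson, rmcorr)


def _fits_frame(rows):
    defaults = {"condition": "none", "at_bound_alpha": False,
                "at_bound_s": False, "at_bound_t": False, "reliable": True}
    return pd.DataFrame([{**defaults, **r} for r in rows])


class TestFieldSize:
    def test_integration_field_examples(self):
        assert field_size_deg(0.2, 7.0) == pytest.approx(1.4)
        assert field_size_deg(0.17, 10.5) == pytest.approx(1.8)

    def test_relative_field_size_across_conditions(self):
        # twice as large for the stronger-interference condition
        assert field_size_deg(0.2, 7.0) / field_size_deg(0.1, 7.0) == \
            pytest.approx(2.0)


class TestNormalize:
    def test_baseline_divided_by_eccentricity_factor(self):
        fits = _fits_frame([
            {"participant_id": "p", "task": "masking",
             "eccentricity_deg": 7.0, "ybase": 0.12, "xcrit": 1.4},
            {"participant_id": "p", "task": "masking",
             "eccentricity_deg": 3.5, "ybase": 0.05, "xcrit": 0.7},
        ])
        m = normalize_measures(fits)
        b = m[m["kind"] == "baseline_contrast_norm"].set_index(
            "eccentricity_deg")["value"]
        assert b[7.0] == pytest.approx(0.06)
        assert b[3.5] == pytest.approx(0.05)

    def test_critical_distance_as_fraction_of_eccentricity(self):
        fits = _fits_frame([{"participant_id": "p", "task": "crowding",
                             "eccentricity_deg": 10.5, "ybase": 0.1,
                             "xcrit": 2.1}])
        m = normalize_measures(fits)
        frac = m[m["kind"] == "critical_distance_frac"]["value"].iloc[0]
        assert frac == pytest.approx(0.2)

    def test_unconfigured_eccentricity_rejected(self):
        fits = _fits_frame([{"participant_id": "p", "task": "masking",
                             "eccentricity_deg": 5.0, "ybase": 0.1,
                             "xcrit": 1.0}])
        with pytest.raises(ValueError):
            normalize_measures(fits)


class TestExclusions:
    def _setup(self, **overrides):
        row = {"participant_id": "p", "task": "masking",
               "eccentricity_deg": 7.0, "ybase": 0.1, "xcrit": 1.4}
        row.update(overrides)
        fits = _fits_frame([row])
        measures = normalize_measures(fits)
        return apply_exclusions(measures, fits)

    def test_clean_fit_fully_retained(self):
        retained, log = self._setup()
        assert len(retained) == 2 and len(log) == 0

    def test_baseline_at_fit_limit_dropped(self):
        retained, log = self._setup(ybase=0.01, at_bound_alpha=True)
        assert set(log["exclusion_reason"]) == {"at_fit_limit"}
        assert set(retained["kind"]) == {"critical_distance_frac"}

    def test_fraction_beyond_tested_range_dropped(self):
        retained, log = self._setup(xcrit=4.9)  # 0.7 of eccentricity
        assert set(log["exclusion_reason"]) == {"exceeds_tested_range"}
        assert set(retained["kind"]) == {"baseline_contrast_norm"}

    def test_unreliable_fit_drops_both_measures(self):
        retained, log = self._setup(reliable=False)
        assert len(retained) == 0
        assert set(log["exclusion_reason"]) == {"unreliable_fit"}


class TestRmcorr:
    def _pairs(self, subjects, x, y):
        return pd.DataFrame({"participant_id": subjects, "x": x, "y": y})

    def test_perfect_within_subject_correlation(self):
        pairs = self._pairs(list("aabbcc"), [1, 2, 4, 5, 7, 8],
                            [10, 11, 2, 3, 30, 31])
        res = rmcorr(pairs)
        assert res.r_rm == pytest.approx(1.0)
        assert res.p_value == pytest.approx(0.0, abs=1e-12)

    def test_perfect_negative_correlation(self):
        pairs = self._pairs(list("aabbcc"), [1, 2, 4, 5, 7, 8],
                            [11, 10, 3, 2, 31, 30])
        assert rmcorr(pairs).r_rm == pytest.approx(-1.0)

    def test_degrees_of_freedom_bookkeeping(self):
        # N subjects with k repeats: df = N*(k-1) - 1
        rng = np.random.default_rng(0)
        n, k = 10, 3
        subs = np.repeat([f"s{i}" for i in range(n)], k)
        pairs = self._pairs(subs, rng.normal(size=n * k),
                            rng.normal(size=n * k))
        res = rmcorr(pairs)
        assert res.df == n * (k - 1) - 1 == 19
        assert res.n_subjects == n and res.n_observations == n * k

    def test_translation_invariance_across_subjects(self):
        # adding a per-subject offset to either variable changes nothing
        rng = np.random.default_rng(1)
        subs = np.repeat(list("abcde"), 3)
        x = rng.normal(size=15)
        y = 0.5 * x + rng.normal(0, 0.3, 15)
        base = rmcorr(self._pairs(subs, x, y))
        offs = np.repeat(rng.normal(0, 50, 5), 3)
        shifted = rmcorr(self._pairs(subs, x + offs, y - 2 * offs))
        assert shifted.r_rm == pytest.approx(base.r_rm, abs=1e-12)
        assert shifted.p_value == pytest.approx(base.p_value, rel=1e-9)

    def test_matches_ancova_oracle(self):
        """Independent oracle: ANCOVA with subject indicator variables."""
        rng = np.random.default_rng(2)
        n, k = 8, 3
        subs = np.repeat([f"s{i}" for i in range(n)], k)
        x = rng.normal(size=n * k)
        y = 0.7 * x + np.repeat(rng.normal(0, 2, n), k) + \
            rng.normal(0, 0.5, n * k)
        res = rmcorr(self._pairs(subs, x, y))

        dummies = pd.get_dummies(subs).to_numpy(dtype=float)
        X_full = np.column_stack([x, dummies])
        X_null = dummies
        beta_f, *_ = np.linalg.lstsq(X_full, y, rcond=None)
        sse_f = float(np.sum((y - X_full @ beta_f) ** 2))
        beta_n, *_ = np.linalg.lstsq(X_null, y, rcond=None)
        sse_n = float(np.sum((y - X_null @ beta_n) ** 2))
        r_oracle = math.copysign(math.sqrt((sse_n - sse_f) / sse_n), beta_f[0])
        assert res.r_rm == pytest.approx(r_oracle, abs=1e-10)
        assert res.slope == pytest.approx(beta_f[0], abs=1e-10)

    def test_matches_reference_implementation(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        subs = np.repeat([f"s{i}" for i in range(12)], 3)
        df = pd.DataFrame({"participant_id": subs,
                           "x": rng.normal(size=36),
                           "y": rng.normal(size=36)})
        res = rmcorr(df)
        ref = pingouin.rm_corr(data=df, x="x", y="y", subject="participant_id")
        assert res.r_rm == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert res.df == int(ref["dof"].iloc[0])
        assert res.p_value == pytest.approx(float(ref["pval"].iloc[0]),
                                            rel=1e-8)

    def test_subjects_with_single_pair_dropped(self):
        pairs = self._pairs(list("aabbccd"), [1, 2, 4, 5, 7, 8, 9],
                            [1, 2, 4, 5, 7, 8, 0])
        res = rmcorr(pairs)
        assert res.n_subjects == 3 and res.n_observations == 6

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            rmcorr(self._pairs(list("aabb"), [1, 2, 3, 4], [1, 2, 3, 4]))

    def test_significance_uses_alpha_001(self):
        rng = np.random.default_rng(4)
        subs = np.repeat(list("abcdefgh"), 3)
        x = rng.normal(size=24)
        strong = rmcorr(self._pairs(subs, x, x + rng.normal(0, 0.05, 24)))
        assert strong.significant and strong.p_value < 0.01


class TestPearson:
    def test_hand_computed_five_pairs(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 5.0]
        # r = cov/(sx*sy) = 8 / sqrt(10*10) = 0.8
        res = pearson(x, y)
        assert res.r == pytest.approx(0.8, abs=1e-12)
        assert res.df == 3

    def test_df_is_n_minus_two(self):
        rng = np.random.default_rng(5)
        res = pearson(rng.normal(size=34), rng.normal(size=34))
        assert res.df == 32  # reported as r(32)

    def test_missing_values_dropped_before_df(self):
        x = [1, 2, 3, 4, 5, np.nan]
        y = [1, 2, 3, 5, 4, 2]
        assert pearson(x, y).df == 3

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 2, 3], [1, 2, 3])

    def test_constant_input_gives_nan(self):
        res = pearson([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(res.r) and not res.significant
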