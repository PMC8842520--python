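"""Normalization, exclusion rules, and correlation analyses.

Baseline contrasts and critical distances are normalized for eccentricity
before correlation: critical distance is expressed as a fraction of stimulus
eccentricity, and baseline contrast is divided by 1, 2 and 3 at 3.5, 7.0 and
10.5 degrees (contrast thresholds grow roughly linearly over that range).
Values are excluded when the exponential fit sat at its lower baseline bound
(alpha = 0.01), when the critical-distance fraction exceeds the largest
tested spread (0.6), or when upstream reliability screens failed.

The repeated-measures correlation is the common-slope analysis-of-covariance
association: each participant's means are removed from both variables, a
single shared slope is fitted, and

    r_rm = sign(slope) * sqrt(SS_measure / (SS_measure + SS_error)),

with error degrees of freedom n_obs - n_subjects - 1 and the p-value from
F(1, df).  With two to three eccentricities per participant this captures
within-observer covariation across retinal locations without inflating df.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "BASELINE_DIVISORS", "RmcorrResult", "PearsonResult",
    "normalize_measures", "apply_exclusions", "rmcorr", "pearson",
    "field_size_deg",
]

#: Eccentricity-proportional divisors for baseline contrast.
BASELINE_DIVISORS = {3.5: 1.0, 7.0: 2.0, 10.5: 3.0}

#: Largest tested spread; larger critical-distance fractions are extrapolation.
MAX_TESTED_FRACTION = 0.6

#: Exponential-fit lower bound on baseline contrast.
ALPHA_FIT_LIMIT = 0.01

ALPHA_LEVEL = 0.01


def field_size_deg(scaling_fraction: float, eccentricity: float,
                   ndigits: int = 1) -> float:
    """Convert an eccentricity-scaling fraction to a field size in degrees.

    E.g. a 0.2 critical-distance scaling at 7 degrees gives a 1.4 degree
    integration field; 0.17 at 10.5 degrees gives 1.8 degrees (one-decimal
    rounding).
    """
    return round(scaling_fraction * eccentricity, ndigits)


def normalize_measures(fits: pd.DataFrame,
                       divisors: dict | None = None) -> pd.DataFrame:
    """Eccentricity-normalized measures from a spacing-fit table.

    Expects columns ``participant_id, task, condition, eccentricity_deg,
    ybase, xcrit`` (plus any flags, which are carried through).  Emits a long
    table with ``kind`` in {baseline_contrast_norm, critical_distance_frac}.
    """
    divisors = divisors if divisors is not None else BASELINE_DIVISORS
    rows = []
    for _, r in fits.iterrows():
        ecc = float(r["eccentricity_deg"])
        if ecc not in divisors:
            raise ValueError(
                f"no baseline divisor configured for eccentricity {ecc}")
        base = {
            "participant_id": r["participant_id"], "task": r["task"],
            "condition": r["condition"], "eccentricity_deg": ecc,
        }
        rows.append({**base, "kind": "baseline_contrast_norm",
                     "value": float(r["ybase"]) / divisors[ecc]})
        rows.append({**base, "kind": "critical_distance_frac",
                     "value": float(r["xcrit"]) / ecc})
    return pd.DataFrame(rows)


def apply_exclusions(measures: pd.DataFrame,
                     fits: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the exclusion rules; returns (retained measures, exclusion log).

    Rules: baseline values from fits pinned at alpha = 0.01 are dropped
    (``at_fit_limit``); critical-distance fractions above 0.6 are dropped
    (``exceeds_tested_range``); measures from fits failing the adjusted-R^2
    screen are dropped (``unreliable_fit``).
    """
    key = ["participant_id", "task", "condition", "eccentricity_deg"]
    flags = fits[key + [c for c in ("at_bound_alpha", "reliable")
                        if c in fits.columns]].copy()
    merged = measures.merge(flags, on=key, how="left", validate="many_to_one")

    reasons = []
    for _, r in merged.iterrows():
        reason = ""
        if "reliable" in merged.columns and not bool(r.get("reliable", True)):
            reason = "unreliable_fit"
        elif (r["kind"] == "baseline_contrast_norm"
                and bool(r.get("at_bound_alpha", False))):
            reason = "at_fit_limit"
        elif (r["kind"] == "critical_distance_frac"
                and r["value"] > MAX_TESTED_FRACTION):
            reason = "exceeds_tested_range"
        elif not np.isfinite(r["value"]):
            reason = "non_finite"
        reasons.append(reason)

    merged = merged.assign(exclusion_reason=reasons,
                           included=[r == "" for r in reasons])
    retained = merged[merged["included"]][measures.columns.tolist()]
    log = merged[~merged["included"]][
        key + ["kind", "value", "exclusion_reason"]]
    return retained.reset_index(drop=True), log.reset_index(drop=True)


@dataclass
class RmcorrResult:
    """Repeated-measures (common-slope ANCOVA) correlation."""

    r_rm: float
    df: int
    p_value: float
    n_subjects: int
    n_observations: int
    slope: float

    @property
    def significant(self) -> bool:
        return bool(np.isfinite(self.p_value) and self.p_value < ALPHA_LEVEL)


@dataclass
class PearsonResult:
    """Product-moment correlation with its df = n - 2."""

    r: float
    df: int
    p_value: float

    @property
    def significant(self) -> bool:
        return bool(np.isfinite(self.p_value) and self.p_value < ALPHA_LEVEL)


def rmcorr(pairs: pd.DataFrame, subject: str = "participant_id",
           x: str = "x", y: str = "y") -> RmcorrResult:
    """Repeated-measures correlation over (subject, x, y) rows.

    Rows with missing x or y are dropped; subjects left with fewer than two
    complete pairs are dropped (they contribute no within-subject contrast).
    Requires at least three surviving subjects.
    """
    df_in = pairs[[subject, x, y]].dropna()
    counts = df_in.groupby(subject).size()
    keep = counts[counts >= 2].index
    df_in = df_in[df_in[subject].isin(keep)]
    n_sub = int(df_in[subject].nunique())
    n_obs = int(len(df_in))
    if n_sub < 3:
        raise ValueError(
            f"rmcorr needs >= 3 subjects with >= 2 complete pairs (got {n_sub})")

    g = df_in.groupby(subject)
    xc = (df_in[x] - g[x].transform("mean")).to_numpy(dtype=float)
    yc = (df_in[y] - g[y].transform("mean")).to_numpy(dtype=float)
    sxx = float(np.sum(xc ** 2))
    if sxx <= 0:
        return RmcorrResult(r_rm=math.nan, df=n_obs - n_sub - 1,
                            p_value=math.nan, n_subjects=n_sub,
                            n_observations=n_obs, slope=math.nan)
    slope = float(np.sum(xc * yc) / sxx)
    syy = float(np.sum(yc ** 2))
    ss_err = float(np.sum((yc - slope * xc) ** 2))
    ss_meas = syy - ss_err
    dof = n_obs - n_sub - 1
    r2 = ss_meas / syy if syy > 0 else math.nan
    r = math.copysign(math.sqrt(max(r2, 0.0)), slope) if np.isfinite(r2) else math.nan
    if np.isfinite(r) and dof >= 1 and abs(r) < 1:
        F = (r * r) / (1 - r * r) * dof
        p = float(sps.f.sf(F, 1, dof))
    elif np.isfinite(r) and abs(r) >= 1:
        p = 0.0
    else:
        p = math.nan
    return RmcorrResult(r_rm=r, df=int(dof), p_value=p, n_subjects=n_sub,
                        n_observations=n_obs, slope=slope)


def pearson(x, y) -> PearsonResult:
    """Plain product-moment correlation (one observation per participant)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 4:
        raise ValueError("pearson needs >= 4 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return PearsonResult(r=math.nan, df=int(x.size - 2), p_value=math.nan)
    res = sps.pearsonr(x, y)
    return PearsonResult(r=float(res.statistic), df=int(x.size - 2),
                         p_value=float(res.pvalue))
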