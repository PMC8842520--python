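"""Spacing-curve, clipped-line, and CSF fits with derived field-size metrics.

Threshold-versus-spacing data for detection (masking) and discrimination
(crowding) are fitted with the inverted exponential

    y(x) = alpha + (1 - alpha) * exp(-s * (x - t))   for x >= t,  1 below t

whose asymptote ``alpha`` is the baseline contrast (ybase) and whose
10%-elevation point ``xcrit = t + ln(10)/s`` is the critical distance: the
inter-element spacing at which the flanker-induced elevation has decayed to
10% of its range.  Grouping thresholds as a function of farthest-element
eccentricity are fitted with a continuous clipped ("broken-stick") line,
yielding a baseline contrast and a critical eccentricity at which the
threshold is 10% above baseline.  Contrast sensitivity functions are fitted
on the sensitivity scale with ``(a + b f) exp(-c f)`` and summarized by the
peak frequency, peak sensitivity, and the high-frequency half-height point.

Fits with adjusted R^2 below 0.7 are flagged unreliable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "SpacingFit", "ClippedLineFit", "CSFFit",
    "spacing_model", "fit_spacing_curve", "critical_distance",
    "clipped_line_model", "fit_clipped_line",
    "minimum_contrast_per_eccentricity",
    "csf_model", "fit_csf",
]

R2_RELIABILITY_LIMIT = 0.7
ALPHA_BOUNDS = (0.01, 1.0)
S_BOUNDS = (1e-6, 25.0)


def _r2_adjusted(y: np.ndarray, resid: np.ndarray, n_params: int) -> float:
    n = y.size
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot <= 0 or n - n_params - 1 <= 0:
        return math.nan
    r2 = 1.0 - ss_res / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)


# ---------------------------------------------------------------------------
# Spacing curve (masking / crowding).
# ---------------------------------------------------------------------------


@dataclass
class SpacingFit:
    """Fitted spacing curve with derived baseline contrast and critical distance."""

    alpha: float
    s: float
    t: float
    r2adj: float
    n_points: int
    at_bound: dict = field(default_factory=dict)
    converged: bool = True

    @property
    def ybase(self) -> float:
        return self.alpha

    @property
    def xcrit(self) -> float:
        return critical_distance(self)

    @property
    def reliable(self) -> bool:
        return bool(self.converged and np.isfinite(self.r2adj)
                    and self.r2adj >= R2_RELIABILITY_LIMIT)


def spacing_model(x, alpha: float, s: float, t: float):
    """Threshold contrast as a function of inter-element spacing (degrees)."""
    x = np.asarray(x, dtype=float)
    y = np.where(x >= t, alpha + (1.0 - alpha) * np.exp(-s * np.maximum(x - t, 0.0)),
                 1.0)
    return y if y.ndim else float(y)


def critical_distance(fit) -> float:
    """Spacing at which the threshold is 10% (of range) above baseline.

    ``xcrit = t - ln(0.1)/s = t + ln(10)/s``; requires s > 0.
    """
    s = fit.s if hasattr(fit, "s") else float(fit)
    t = fit.t if hasattr(fit, "t") else 0.0
    if s <= 0:
        raise ValueError("scaling factor s must be positive")
    return float(t + math.log(10.0) / s)


def _spacing_objective(params, x, y):
    a, s, t = params
    return spacing_model(x, a, s, t) - y


def fit_spacing_curve(x, y, n_restarts: int = 10) -> SpacingFit:
    """Constrained least-squares fit of the spacing curve.

    Bounds: alpha in [0.01, 1], s in (0, 25], t >= 0 (no upper limit).
    Multi-start optimization: a deterministic seed at
    (min(y), 5, min(x)-ish) plus jittered restarts; the best objective wins,
    ties broken toward the smallest s.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4 or np.unique(x).size < 4:
        raise ValueError("need >= 4 points with distinct spacings")
    if np.any((y <= 0) | (y > 1)):
        raise ValueError("thresholds must lie in (0, 1]")

    lo = [ALPHA_BOUNDS[0], S_BOUNDS[0], 0.0]
    hi = [ALPHA_BOUNDS[1], S_BOUNDS[1], np.inf]
    a0 = float(np.clip(y.min(), lo[0] + 1e-9, hi[0] - 1e-9))
    starts = [(a0, 5.0, 0.0), (a0, 5.0, float(x.min())),
              (a0, math.log(10.0) / max(x.min(), 1e-3), 0.0)]
    jit = np.random.default_rng(0)  # fixed: restarts are part of the algorithm
    for _ in range(n_restarts):
        starts.append((
            float(np.clip(a0 * np.exp(jit.normal(0, 0.3)), lo[0] + 1e-9, 1 - 1e-9)),
            float(np.exp(jit.uniform(np.log(0.3), np.log(20.0)))),
            float(jit.uniform(0.0, x.min())),
        ))

    best = None
    for start in starts:
        try:
            res = optimize.least_squares(
                _spacing_objective, start, args=(x, y), bounds=(lo, hi),
                method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        if best is None or res.cost < best.cost - 1e-12 or (
                abs(res.cost - best.cost) <= 1e-12 and res.x[1] < best.x[1]):
            best = res

    if best is None:
        return SpacingFit(alpha=math.nan, s=math.nan, t=math.nan,
                          r2adj=math.nan, n_points=int(x.size), converged=False)

    a, s, t = (float(v) for v in best.x)
    resid = _spacing_objective(best.x, x, y)
    tol = 1e-6
    at_bound = {
        "alpha": bool(a <= ALPHA_BOUNDS[0] + tol or a >= ALPHA_BOUNDS[1] - tol),
        "s": bool(s >= S_BOUNDS[1] - tol),
        "t": bool(t <= tol),
    }
    return SpacingFit(alpha=a, s=s, t=t,
                      r2adj=_r2_adjusted(y, resid, 3),
                      n_points=int(x.size), at_bound=at_bound,
                      converged=bool(best.success))


# ---------------------------------------------------------------------------
# Clipped line (grouping).
# ---------------------------------------------------------------------------


@dataclass
class ClippedLineFit:
    """Broken-stick fit: flat baseline out to x0, linear rise beyond."""

    b: float
    m: float
    x0: float
    r2adj: float
    n_points: int
    converged: bool = True

    @property
    def xcrit_ecc(self) -> float:
        """Eccentricity at which the threshold is 10% above baseline."""
        if not self.m > 0:
            return math.nan
        return float(self.x0 + 0.1 * self.b / self.m)

    @property
    def reliable(self) -> bool:
        return bool(self.converged and np.isfinite(self.r2adj)
                    and self.r2adj >= R2_RELIABILITY_LIMIT)


def clipped_line_model(x, b: float, m: float, x0: float):
    x = np.asarray(x, dtype=float)
    y = b + m * np.maximum(0.0, x - x0)
    return y if y.ndim else float(y)


def _clipped_sse(x0: float, x: np.ndarray, y: np.ndarray):
    """Profile out (b, m) at fixed breakpoint; m constrained >= 0."""
    z = np.maximum(0.0, x - x0)
    if np.ptp(z) > 0:
        A = np.column_stack([np.ones_like(x), z])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        b, m = float(coef[0]), float(coef[1])
        if m < 0:
            b, m = float(y.mean()), 0.0
    else:
        b, m = float(y.mean()), 0.0
    sse = float(np.sum((clipped_line_model(x, b, m, x0) - y) ** 2))
    return sse, b, m


def fit_clipped_line(x, y) -> ClippedLineFit:
    """Continuous broken-stick fit with profiled breakpoint search.

    The breakpoint is searched on a dense grid over the data range and
    refined locally; at each candidate the baseline and slope are the exact
    least-squares solution (slope clamped at 0 if the data are flat or
    decreasing).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.argsort(x)
    x, y = x[order], y[order]
    if x.size < 5:
        raise ValueError("need >= 5 points spanning the breakpoint region")

    grid = np.linspace(x.min(), x.max(), 201)
    sses = np.array([_clipped_sse(g, x, y)[0] for g in grid])
    k = int(np.argmin(sses))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid.size - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda g: _clipped_sse(g, x, y)[0], bounds=(lo, hi),
            method="bounded", options={"xatol": 1e-8})
        x0 = float(res.x) if res.fun <= sses[k] + 1e-15 else float(grid[k])
    else:
        x0 = float(grid[k])
    _, b, m = _clipped_sse(x0, x, y)
    resid = clipped_line_model(x, b, m, x0) - y
    n_params = 3 if m > 0 else 1
    return ClippedLineFit(b=b, m=m, x0=x0,
                          r2adj=_r2_adjusted(y, resid, n_params),
                          n_points=int(x.size))


def minimum_contrast_per_eccentricity(thresholds: pd.DataFrame) -> pd.DataFrame:
    """Minimum reliable grouping threshold at each stimulus eccentricity.

    Expects a thresholds table with columns ``participant_id``,
    ``eccentricity_deg``, ``threshold`` and ``reliable``; unreliable cells
    are ignored and eccentricities with no reliable cell yield NaN.
    """
    rows = []
    for (pid, ecc), sub in thresholds.groupby(["participant_id", "eccentricity_deg"]):
        ok = sub[sub["reliable"].astype(bool)]
        rows.append({
            "participant_id": pid, "eccentricity_deg": ecc,
            "min_contrast": float(ok["threshold"].min()) if len(ok) else math.nan,
            "n_reliable": int(len(ok)),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Contrast sensitivity function.
# ---------------------------------------------------------------------------


@dataclass
class CSFFit:
    """Exponential CSF fit ``y(f) = (a + b f) exp(-c f)`` on sensitivity scale."""

    a: float
    b: float
    c: float
    r2adj: float
    n_points: int
    scale: str = "sensitivity"
    converged: bool = True

    @property
    def fmax(self) -> float:
        """Peak spatial frequency, 1/c - a/b (cycles/degree)."""
        if self.b <= 0 or self.c <= 0:
            return math.nan
        return float(1.0 / self.c - self.a / self.b)

    @property
    def smax(self) -> float:
        """Fitted value at the peak frequency."""
        f = self.fmax
        if not np.isfinite(f) or f <= 0:
            return math.nan
        return float(csf_model(f, self.a, self.b, self.c))

    @property
    def sf_cutoff(self) -> float:
        """Frequency above the peak at which the curve falls to half height."""
        return _half_height_root(self.a, self.b, self.c)

    @property
    def hbw_high(self) -> float:
        """Half bandwidth at half height toward high frequencies (cpd)."""
        cut = self.sf_cutoff
        return float(cut - self.fmax) if np.isfinite(cut) else math.nan

    @property
    def reliable(self) -> bool:
        return bool(self.converged and np.isfinite(self.r2adj)
                    and self.r2adj >= R2_RELIABILITY_LIMIT
                    and np.isfinite(self.fmax) and self.fmax > 0)


def csf_model(f, a: float, b: float, c: float):
    f = np.asarray(f, dtype=float)
    y = (a + b * f) * np.exp(-c * f)
    return y if y.ndim else float(y)


def _half_height_root(a: float, b: float, c: float) -> float:
    if b <= 0 or c <= 0:
        return math.nan
    fmax = 1.0 / c - a / b
    if fmax <= 0:
        return math.nan
    half = 0.5 * csf_model(fmax, a, b, c)
    g = lambda f: csf_model(f, a, b, c) - half
    hi = fmax + 1.0
    while g(hi) > 0 and hi < 1e4:
        hi *= 2.0
    if g(hi) > 0:
        return math.nan
    return float(optimize.brentq(g, fmax, hi, xtol=1e-12, rtol=1e-14))


def fit_csf(freqs, thresholds, scale: str = "sensitivity") -> CSFFit:
    """Nonlinear least-squares CSF fit.

    Thresholds are converted to sensitivities (reciprocals) by default, the
    scale on which the rising-then-falling form has its natural reading as a
    peaked sensitivity curve; ``scale='threshold'`` fits thresholds directly.
    """
    f = np.asarray(freqs, dtype=float)
    thr = np.asarray(thresholds, dtype=float)
    if np.any(thr <= 0):
        raise ValueError("thresholds must be positive")
    if scale not in ("sensitivity", "threshold"):
        raise ValueError("scale must be 'sensitivity' or 'threshold'")
    y = 1.0 / thr if scale == "sensitivity" else thr

    def resid(p):
        return csf_model(f, *p) - y

    ymax = float(y.max())
    fpk = float(f[np.argmax(y)])
    starts = []
    for c0 in (0.3, 0.6, 1.0, 2.0):
        b0 = ymax * c0 * math.e  # peak of b*f*exp(-c f) at 1/c is b/(c e)
        starts.append((max(y[0] - 0.0, 1e-6), b0, c0))
        starts.append((1e-3, b0, c0))
    if fpk > 0:
        c0 = 1.0 / fpk
        starts.append((1e-3, ymax * c0 * math.e, c0))

    lo = [0.0, 1e-9, 1e-6]
    hi = [np.inf, np.inf, np.inf]
    best = None
    for start in starts:
        try:
            res = optimize.least_squares(resid, start, bounds=(lo, hi),
                                         xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return CSFFit(a=math.nan, b=math.nan, c=math.nan, r2adj=math.nan,
                      n_points=int(f.size), scale=scale, converged=False)
    a, b, c = (float(v) for v in best.x)
    return CSFFit(a=a, b=b, c=c,
                  r2adj=_r2_adjusted(y, resid(best.x), 3),
                  n_points=int(f.size), scale=scale,
                  converged=bool(best.success))
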