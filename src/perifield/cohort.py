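"""Synthetic observers for masking, crowding, grouping, and CSF measurement.

Simulated participants have known ground-truth condition structure:

* masking and crowding thresholds follow the spacing curve
  ``y(x) = alpha + (1 - alpha) * exp(-s * (x - t))`` (for spacing x >= t,
  and 1 below t), where x is the centre-to-centre inter-element distance in
  degrees; ``alpha`` is the baseline contrast and ``t + ln(10)/s`` the
  critical distance;
* grouping thresholds follow a clipped ("broken-stick") line in the
  eccentricity of the farthest grid element: flat at baseline ``b`` out to
  breakpoint ``x0``, rising with slope ``m_slope`` beyond it;
* contrast sensitivity follows ``(a + b * f) * exp(-c * f)`` on the
  sensitivity (reciprocal-threshold) scale over spatial frequency ``f``.

Each condition cell is measured by running the full adaptive staircase
procedure against a Weibull observer whose 81%-correct point equals the
ground-truth threshold, so the entire estimation pipeline can be exercised
end-to-end with a known answer.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .psychometric import WeibullPF
from .staircase import StaircaseConfig, run_running_fit, _m_from_threshold

__all__ = [
    "StimulusGeometry",
    "ObserverSpec",
    "CohortDesign",
    "threshold_at_spacing",
    "farthest_element_eccentricity",
    "make_observers",
    "simulate_cohort",
    "simulate_csf_table",
]

ECCENTRICITIES = (3.5, 7.0, 10.5)
SPREAD_FRACS = (0.2, 0.3, 0.4, 0.5, 0.6)
CSF_FREQS = (0.3, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0)
ELEMENT_SIZE_DEG = 0.8  # Gabor patch diameter; grids must not overlap


@dataclass(frozen=True)
class StimulusGeometry:
    """3x3 grid geometry: eccentricity of the central element and spread.

    ``spread_frac`` is the centre-to-centre inter-element distance along the
    cardinal axes expressed as a fraction of eccentricity.
    """

    eccentricity: float
    spread_frac: float

    def __post_init__(self) -> None:
        if self.spread_frac < 0 or self.spread_frac > 0.6:
            raise ValueError("spread_frac must lie in [0, 0.6]")
        if self.eccentricity <= 0:
            raise ValueError("eccentricity must be positive")

    @property
    def spacing_deg(self) -> float:
        """Centre-to-centre inter-element distance in degrees."""
        return self.spread_frac * self.eccentricity


def farthest_element_eccentricity(geometry: StimulusGeometry) -> float:
    """Eccentricity of the outer corner element of the top/bottom grid rows.

    With central-element eccentricity E and spacing d, the corner element of
    the top or bottom row sits at sqrt((E + d)^2 + d^2) degrees from
    fixation.  For the largest tested spread (0.6) this lands near 6, 12 and
    18 degrees at the three tested eccentricities.
    """
    E = geometry.eccentricity
    d = geometry.spacing_deg
    return float(math.hypot(E + d, d))


@dataclass(frozen=True)
class SpacingParams:
    """Generating spacing-curve parameters (alpha, s, t) for one cell family."""

    alpha: float
    s: float
    t: float

    def __post_init__(self) -> None:
        if not (0.01 <= self.alpha <= 1):
            raise ValueError("alpha must lie in [0.01, 1]")
        if not (0 < self.s <= 25):
            raise ValueError("s must lie in (0, 25]")
        if self.t < 0:
            raise ValueError("t must be non-negative")


@dataclass(frozen=True)
class ClippedLineParams:
    """Generating broken-stick parameters for the grouping task."""

    b: float
    m_slope: float
    x0: float

    def __post_init__(self) -> None:
        if not (0 < self.b <= 1):
            raise ValueError("baseline b must lie in (0, 1]")
        if self.m_slope < 0:
            raise ValueError("slope must be non-negative")
        if self.x0 < 0:
            raise ValueError("breakpoint must be non-negative")


@dataclass
class ObserverSpec:
    """One simulated participant's complete ground truth."""

    participant_id: str
    spacing: dict = field(default_factory=dict)   # (task, condition, ecc) -> SpacingParams
    grouping: ClippedLineParams | None = None
    csf: tuple[float, float, float] = (2.0, 60.0, 0.45)
    adjust_contrast: dict = field(default_factory=dict)  # ecc -> detection contrast
    beta: float = 3.5
    gamma: float = 0.5
    lam: float = 0.02


def threshold_at_spacing(spec: ObserverSpec, task: str, condition: str,
                         eccentricity: float, spread_frac: float) -> float:
    """Ground-truth contrast threshold for one condition cell.

    For masking/crowding this evaluates the spacing curve at
    x = spread_frac * eccentricity; for grouping it evaluates the clipped
    line at the farthest-element eccentricity of the grid.
    """
    if task == "grouping":
        if spec.grouping is None:
            raise ValueError("observer has no grouping parameters")
        g = spec.grouping
        x_far = farthest_element_eccentricity(
            StimulusGeometry(eccentricity, spread_frac))
        return float(g.b + g.m_slope * max(0.0, x_far - g.x0))
    key = (task, condition, eccentricity)
    if key not in spec.spacing:
        raise ValueError(f"no spacing parameters for cell {key}")
    p = spec.spacing[key]
    x = spread_frac * eccentricity
    if x < p.t:
        return 1.0
    return float(p.alpha + (1.0 - p.alpha) * math.exp(-p.s * (x - p.t)))


# ---------------------------------------------------------------------------
# Default generating values.  Baselines scale roughly linearly with
# eccentricity (so the divide-by-1/2/3 normalization flattens them);
# critical-distance fractions default to 0.17 (orthogonal masking) and 0.20
# (collinear masking and crowding); grouping uses a ~10 degree breakpoint
# with a 0.042 contrast-per-degree rise.  The spacing curves place the
# full-contrast intercept at t = 0.3 * xcrit with s = ln(10) / (0.7 * xcrit),
# which reproduces those fractions exactly while rising steeply near the
# critical distance and flattening within the tested spread range, the shape
# the threshold data show.
# ---------------------------------------------------------------------------

DEFAULT_BASELINES = {
    # task/condition -> baseline contrast at (3.5, 7.0, 10.5) degrees
    ("masking", "collinear"): (0.03, 0.06, 0.09),
    ("masking", "orthogonal"): (0.03, 0.06, 0.09),
    ("crowding", "none"): (0.058, 0.088, 0.118),
}
DEFAULT_CRIT_FRACTIONS = {
    ("masking", "collinear"): 0.20,
    ("masking", "orthogonal"): 0.17,
    ("crowding", "none"): 0.20,
}
DEFAULT_GROUPING = ClippedLineParams(b=0.063, m_slope=0.042, x0=10.0)
DEFAULT_CSF = (2.0, 60.0, 0.45)


@dataclass(frozen=True)
class CohortDesign:
    """Study design: tested eccentricities, spreads, tasks and conditions."""

    eccentricities: tuple = ECCENTRICITIES
    spread_fracs: tuple = SPREAD_FRACS
    tasks: tuple = (
        ("masking", "collinear"),
        ("masking", "orthogonal"),
        ("crowding", "none"),
        ("grouping", "none"),
    )


def make_observers(
    n_participants: int,
    rng: np.random.Generator,
    design: CohortDesign = CohortDesign(),
    *,
    baseline_log_sd: float = 0.15,
    fraction_log_sd: float = 0.10,
    grouping_slope_log_sd: float = 0.25,
    breakpoint_log_sd: float = 0.08,
) -> list[ObserverSpec]:
    """Draw a cohort of observers with multiplicative log-normal scatter.

    Each participant's baselines, critical-distance fractions, grouping
    parameters and CSF parameters are the defaults perturbed by log-normal
    factors with the given log-SDs (natural log).
    """
    observers = []
    for i in range(n_participants):
        pid = f"P{i + 1:03d}"
        spacing: dict = {}
        for (task, cond), baselines in DEFAULT_BASELINES.items():
            if (task, cond) not in [t for t in design.tasks]:
                continue
            frac = DEFAULT_CRIT_FRACTIONS[(task, cond)] * float(
                np.exp(rng.normal(0.0, fraction_log_sd)))
            base_factor = float(np.exp(rng.normal(0.0, baseline_log_sd)))
            for ecc, base in zip(ECCENTRICITIES, baselines):
                if ecc not in design.eccentricities:
                    continue
                alpha = min(1.0, max(0.011, base * base_factor))
                xcrit = frac * ecc
                t = 0.3 * xcrit
                s = min(25.0, math.log(10.0) / (xcrit - t))
                spacing[(task, cond, ecc)] = SpacingParams(alpha=alpha, s=s, t=t)
        grouping = None
        if any(t == "grouping" for t, _ in design.tasks):
            grouping = ClippedLineParams(
                b=DEFAULT_GROUPING.b * float(np.exp(rng.normal(0.0, baseline_log_sd))),
                m_slope=DEFAULT_GROUPING.m_slope
                * float(np.exp(rng.normal(0.0, grouping_slope_log_sd))),
                x0=DEFAULT_GROUPING.x0
                * float(np.exp(rng.normal(0.0, breakpoint_log_sd))),
            )
        a, b, c = DEFAULT_CSF
        csf = (
            a * float(np.exp(rng.normal(0.0, baseline_log_sd))),
            b * float(np.exp(rng.normal(0.0, baseline_log_sd))),
            c * float(np.exp(rng.normal(0.0, 0.05))),
        )
        # Peripheral contrast-adjustment proxy: detection contrast close to
        # the masking baseline at each eccentricity; seeds the staircases.
        adjust = {}
        for ecc, base in zip(ECCENTRICITIES, DEFAULT_BASELINES[("masking", "collinear")]):
            adjust[ecc] = base * float(np.exp(rng.normal(0.0, 0.1)))
        observers.append(ObserverSpec(
            participant_id=pid, spacing=spacing, grouping=grouping,
            csf=csf, adjust_contrast=adjust,
        ))
    return observers


def _records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([{
        "participant_id": r.participant_id, "task": r.task,
        "condition": r.condition, "eccentricity_deg": r.eccentricity_deg,
        "spread_frac": r.spread_frac, "staircase_id": r.staircase_id,
        "trial_index": r.trial_index, "contrast": r.contrast,
        "correct": int(r.correct), "scored": int(r.scored),
    } for r in records])


def ground_truth_frame(observers: list[ObserverSpec]) -> pd.DataFrame:
    """Ground-truth table: generating parameters per participant and cell."""
    rows = []
    for obs in observers:
        for (task, cond, ecc), p in obs.spacing.items():
            rows.append({
                "participant_id": obs.participant_id, "task": task,
                "condition": cond, "eccentricity_deg": ecc,
                "alpha_true": p.alpha, "s_true": p.s, "t_true": p.t,
                "b_true": math.nan, "m_true": math.nan, "x0_true": math.nan,
            })
        if obs.grouping is not None:
            rows.append({
                "participant_id": obs.participant_id, "task": "grouping",
                "condition": "none", "eccentricity_deg": math.nan,
                "alpha_true": math.nan, "s_true": math.nan, "t_true": math.nan,
                "b_true": obs.grouping.b, "m_true": obs.grouping.m_slope,
                "x0_true": obs.grouping.x0,
            })
    return pd.DataFrame(rows)


def simulate_cohort(
    n_participants: int,
    seed: int | np.random.SeedSequence,
    design: CohortDesign = CohortDesign(),
    staircase_template: StaircaseConfig | None = None,
    *,
    observers: list[ObserverSpec] | None = None,
    drop_largest_spread_frac: float = 0.0,
    initial_threshold_factor: float = 1.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate complete trial logs for a cohort; fully seed-reproducible.

    For every (participant, task, condition, eccentricity, spread) cell a
    Weibull observer whose target-probability point equals the ground-truth
    threshold is run through the paired adaptive staircases.  A configurable
    fraction of participants skips the largest spread for masking and
    crowding (mirroring sessions shortened once asymptotic performance was
    clear).  Returns ``(trials, ground_truth)`` DataFrames.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    obs_seed, trial_seed = ss.spawn(2)
    if observers is None:
        observers = make_observers(n_participants, np.random.default_rng(obs_seed),
                                   design)
    template = staircase_template or StaircaseConfig(initial_threshold=0.1)

    cell_rngs = np.random.default_rng(trial_seed)
    all_records: list[pd.DataFrame] = []
    max_spread = max(design.spread_fracs)
    n_drop = int(round(drop_largest_spread_frac * len(observers)))

    for i, obs in enumerate(observers):
        drops_largest = i < n_drop
        for task, cond in design.tasks:
            for ecc in design.eccentricities:
                for spread in design.spread_fracs:
                    if (drops_largest and spread == max_spread
                            and task in ("masking", "crowding")):
                        continue
                    thr = threshold_at_spacing(obs, task, cond, ecc, spread)
                    if thr > 1.0:
                        warnings.warn(
                            f"cell ({obs.participant_id},{task},{cond},{ecc},"
                            f"{spread}) has infeasible threshold {thr:.3f}; skipped")
                        continue
                    seed_c = float(np.clip(
                        initial_threshold_factor * obs.adjust_contrast[ecc],
                        1e-3, 1.0))
                    cfg = StaircaseConfig(
                        initial_threshold=seed_c,
                        n_trials_per_staircase=template.n_trials_per_staircase,
                        n_staircases=template.n_staircases,
                        target_p=template.target_p, beta=obs.beta,
                        lam=obs.lam, gamma=obs.gamma,
                        prior_sd_log10=template.prior_sd_log10,
                        discard_first=template.discard_first,
                        preview_trials=template.preview_trials,
                        threshold_criterion=template.threshold_criterion,
                        grid_points=template.grid_points,
                    )
                    m = _m_from_threshold(thr, cfg)
                    observer_pf = WeibullPF(m=m, beta=obs.beta,
                                            gamma=obs.gamma, lam=obs.lam)
                    records, _ = run_running_fit(
                        cfg, observer_pf, cell_rngs,
                        participant_id=obs.participant_id, task=task,
                        condition=cond, eccentricity_deg=ecc,
                        spread_frac=spread)
                    all_records.append(_records_to_frame(records))

    trials = pd.concat(all_records, ignore_index=True)
    return trials, ground_truth_frame(observers)


def simulate_csf_table(
    observers: list[ObserverSpec],
    rng: np.random.Generator,
    freqs=CSF_FREQS,
    noise_log_sd: float = 0.08,
) -> pd.DataFrame:
    """Per-participant CSF threshold tables with log-normal measurement noise."""
    rows = []
    for obs in observers:
        a, b, c = obs.csf
        for f in freqs:
            sens = (a + b * f) * math.exp(-c * f)
            thr = (1.0 / sens) * float(np.exp(rng.normal(0.0, noise_log_sd)))
            rows.append({"participant_id": obs.participant_id,
                         "spatial_freq_cpd": f, "threshold": min(1.0, thr)})
    return pd.DataFrame(rows)
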