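"""End-to-end orchestration: simulate -> estimate -> fit -> correlate -> report.

All randomness flows from one top-level seed through per-stage spawned
streams, so identical configurations produce identical outputs.  Every stage
writes a plain CSV and the reporter only aggregates stage outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as _cohort
from . import fits as _fits
from . import stats as _stats
from .staircase import StaircaseConfig, ThresholdEstimate, TrialRecord, \
    bootstrap_se, reestimate_threshold

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "read_trials",
           "write_results", "estimate_thresholds", "fit_all", "correlate"]

log = logging.getLogger("perifield")

TRIAL_COLUMNS = ["participant_id", "task", "condition", "eccentricity_deg",
                 "spread_frac", "staircase_id", "trial_index", "contrast",
                 "correct", "scored"]


@dataclass
class RunConfig:
    """Complete configuration of a seeded pipeline run.

    Every screening threshold defaults to the analysis constants: bootstrap
    SE limit 0.2, adjusted-R^2 limit 0.7, critical-distance fraction limit
    0.6, baseline fit bound 0.01, significance level 0.01.
    """

    seed: int = 1
    n_participants: int = 10
    eccentricities: tuple = _cohort.ECCENTRICITIES
    spread_fracs: tuple = _cohort.SPREAD_FRACS
    tasks: tuple = (("masking", "collinear"), ("masking", "orthogonal"),
                    ("crowding", "none"), ("grouping", "none"))
    n_trials_per_staircase: int = 40
    n_staircases: int = 2
    target_p: float = 0.81
    beta: float = 3.5
    lam: float = 0.02
    gamma: float = 0.5
    prior_sd_log10: float = 0.2
    bootstrap_B: int = 500
    drop_largest_spread_frac: float = 0.0
    se_limit: float = 0.2
    r2adj_limit: float = 0.7
    fraction_limit: float = 0.6
    alpha_fit_limit: float = 0.01
    alpha_level: float = 0.01
    baseline_divisors: dict = field(
        default_factory=lambda: dict(_stats.BASELINE_DIVISORS))
    include_csf: bool = True
    output_dir: str | None = None

    def staircase_template(self) -> StaircaseConfig:
        return StaircaseConfig(
            initial_threshold=0.1,
            n_trials_per_staircase=self.n_trials_per_staircase,
            n_staircases=self.n_staircases, target_p=self.target_p,
            beta=self.beta, lam=self.lam, gamma=self.gamma,
            prior_sd_log10=self.prior_sd_log10)

    def design(self) -> _cohort.CohortDesign:
        return _cohort.CohortDesign(
            eccentricities=tuple(self.eccentricities),
            spread_fracs=tuple(self.spread_fracs),
            tasks=tuple(tuple(t) for t in self.tasks))

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["tasks"] = [list(t) for t in self.tasks]
        d["eccentricities"] = list(self.eccentricities)
        d["spread_fracs"] = list(self.spread_fracs)
        d["baseline_divisors"] = {str(k): v for k, v in
                                  self.baseline_divisors.items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["tasks"] = tuple(tuple(t) for t in d.get("tasks", cls().tasks))
        d["eccentricities"] = tuple(d.get("eccentricities",
                                          cls().eccentricities))
        d["spread_fracs"] = tuple(d.get("spread_fracs", cls().spread_fracs))
        if "baseline_divisors" in d:
            d["baseline_divisors"] = {float(k): float(v) for k, v in
                                      d["baseline_divisors"].items()}
        return cls(**d)


# ---------------------------------------------------------------------------
# Trial-log IO.
# ---------------------------------------------------------------------------


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial-log CSV (schema of ``TRIAL_COLUMNS``).

    Raises ``ValueError`` naming missing columns, or listing offending line
    numbers for malformed rows (non-binary correctness, contrast outside
    (0, 1]).
    """
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial log missing column(s): {', '.join(missing)}")
    bad: list[str] = []
    lines = df.index + 2  # header is line 1
    contrast = pd.to_numeric(df["contrast"], errors="coerce")
    bad_contrast = lines[~((contrast > 0) & (contrast <= 1))]
    if len(bad_contrast):
        bad.append(f"contrast outside (0, 1] on line(s) "
                   f"{list(map(int, bad_contrast[:10]))}")
    correct = pd.to_numeric(df["correct"], errors="coerce")
    bad_correct = lines[~correct.isin([0, 1])]
    if len(bad_correct):
        bad.append(f"non-binary correct flag on line(s) "
                   f"{list(map(int, bad_correct[:10]))}")
    if bad:
        raise ValueError("; ".join(bad))
    df["correct"] = correct.astype(int)
    df["scored"] = pd.to_numeric(df["scored"], errors="coerce").fillna(1).astype(int)
    return df


def _records_from_frame(sub: pd.DataFrame) -> list[TrialRecord]:
    return [TrialRecord(
        participant_id=str(r.participant_id), task=str(r.task),
        condition=str(r.condition), eccentricity_deg=float(r.eccentricity_deg),
        spread_frac=float(r.spread_frac), staircase_id=int(r.staircase_id),
        trial_index=int(r.trial_index), contrast=float(r.contrast),
        correct=bool(r.correct), scored=bool(r.scored))
        for r in sub.itertuples()]


# ---------------------------------------------------------------------------
# Stages.
# ---------------------------------------------------------------------------

CELL_KEY = ["participant_id", "task", "condition", "eccentricity_deg",
            "spread_frac"]


def estimate_thresholds(trials: pd.DataFrame, config: RunConfig,
                        seed: int | np.random.SeedSequence = 0) -> pd.DataFrame:
    """Pooled re-estimation plus bootstrap SE for every condition cell.

    The prior centre for each cell's re-fit is taken from the cell's own
    unscored orienting trial (the staircase's starting contrast), matching
    the procedure that collected the data.
    """
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    rng = np.random.default_rng(ss)
    template = config.staircase_template()
    rows = []
    for key, sub in trials.groupby(CELL_KEY, sort=True):
        sub = sub.sort_values("trial_index")
        preview = sub[sub["scored"] == 0]
        init = (float(preview["contrast"].iloc[0]) if len(preview)
                else float(sub["contrast"].median()))
        cfg = dataclasses.replace(template,
                                  initial_threshold=float(np.clip(init, 1e-3, 1.0)))
        records = _records_from_frame(sub)
        try:
            est = reestimate_threshold(records, cfg)
            est.se_boot = bootstrap_se(records, cfg, B=config.bootstrap_B,
                                       rng=rng)
        except ValueError as exc:
            log.warning("estimate: skipping cell %s: %s", key, exc)
            continue
        rows.append({
            **dict(zip(CELL_KEY, key)), "threshold": est.threshold,
            "se_boot": est.se_boot, "n_trials": est.n_trials,
            "degenerate": est.degenerate,
            "reliable": bool(np.isfinite(est.se_boot)
                             and est.se_boot <= config.se_limit
                             and not est.degenerate),
        })
    return pd.DataFrame(rows)


def fit_all(thresholds: pd.DataFrame, config: RunConfig) -> dict:
    """Spacing fits, grouping clipped-line fits, and minimum contrasts."""
    spacing_rows = []
    reliable = thresholds[thresholds["reliable"].astype(bool)]
    spacing_tasks = reliable[reliable["task"].isin(["masking", "crowding"])]
    for (pid, task, cond, ecc), sub in spacing_tasks.groupby(
            ["participant_id", "task", "condition", "eccentricity_deg"]):
        x = sub["spread_frac"].to_numpy() * float(ecc)
        y = sub["threshold"].to_numpy()
        if np.unique(x).size < 4:
            log.warning("fit: <4 reliable points for %s/%s/%s/%s; skipped",
                        pid, task, cond, ecc)
            continue
        f = _fits.fit_spacing_curve(x, y)
        spacing_rows.append({
            "participant_id": pid, "task": task, "condition": cond,
            "eccentricity_deg": float(ecc), "alpha": f.alpha, "s": f.s,
            "t": f.t, "r2adj": f.r2adj, "ybase": f.ybase,
            "xcrit": f.xcrit if f.s > 0 else math.nan,
            "at_bound_alpha": f.at_bound.get("alpha", False),
            "at_bound_s": f.at_bound.get("s", False),
            "at_bound_t": f.at_bound.get("t", False),
            "reliable": f.reliable, "n_points": f.n_points,
        })
    spacing_fits = pd.DataFrame(spacing_rows)

    grouping = reliable[reliable["task"] == "grouping"]
    grouping_rows = []
    for pid, sub in grouping.groupby("participant_id"):
        x = np.array([_cohort.farthest_element_eccentricity(
            _cohort.StimulusGeometry(e, s))
            for e, s in zip(sub["eccentricity_deg"], sub["spread_frac"])])
        y = sub["threshold"].to_numpy()
        if x.size < 5:
            log.warning("fit: <5 reliable grouping points for %s; skipped", pid)
            continue
        f = _fits.fit_clipped_line(x, y)
        grouping_rows.append({
            "participant_id": pid, "b": f.b, "m": f.m, "x0": f.x0,
            "r2adj": f.r2adj, "xcrit_ecc": f.xcrit_ecc,
            "reliable": f.reliable, "n_points": f.n_points,
        })
    grouping_fits = pd.DataFrame(grouping_rows)

    min_contrast = (_fits.minimum_contrast_per_eccentricity(grouping)
                    if len(grouping) else pd.DataFrame(
                        columns=["participant_id", "eccentricity_deg",
                                 "min_contrast", "n_reliable"]))
    return {"spacing_fits": spacing_fits, "grouping_fits": grouping_fits,
            "min_contrast": min_contrast}


def fit_csf_tables(csf_table: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for pid, sub in csf_table.groupby("participant_id"):
        f = _fits.fit_csf(sub["spatial_freq_cpd"].to_numpy(),
                          sub["threshold"].to_numpy())
        rows.append({"participant_id": pid, "a": f.a, "b": f.b, "c": f.c,
                     "r2adj": f.r2adj, "fmax": f.fmax, "smax": f.smax,
                     "hbw_high": f.hbw_high, "sf_cutoff": f.sf_cutoff,
                     "reliable": f.reliable})
    return pd.DataFrame(rows)


def _measure_frame(measures: pd.DataFrame, task: str, condition: str,
                   kind: str) -> pd.DataFrame:
    sub = measures[(measures["task"] == task)
                   & (measures["condition"] == condition)
                   & (measures["kind"] == kind)]
    return sub[["participant_id", "eccentricity_deg", "value"]]


def _rm_pairs(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    m = a.merge(b, on=["participant_id", "eccentricity_deg"],
                suffixes=("_x", "_y"))
    return m.rename(columns={"value_x": "x", "value_y": "y"})


def correlate(fit_bundle: dict, config: RunConfig) -> dict:
    """Normalization, exclusions, and the full correlation table."""
    spacing_fits = fit_bundle["spacing_fits"]
    measures = _stats.normalize_measures(spacing_fits,
                                         config.baseline_divisors)
    retained, exclusion_log = _stats.apply_exclusions(measures, spacing_fits)

    mc = fit_bundle["min_contrast"].dropna(subset=["min_contrast"]).copy()
    mc["task"], mc["condition"], mc["kind"] = "grouping", "none", "min_contrast_norm"
    mc["value"] = [v / config.baseline_divisors[e] for v, e in
                   zip(mc["min_contrast"], mc["eccentricity_deg"])]
    mc = mc[["participant_id", "task", "condition", "eccentricity_deg",
             "kind", "value"]]

    B, X = "baseline_contrast_norm", "critical_distance_frac"
    sel = lambda t, c, k: _measure_frame(retained, t, c, k)
    gsel = mc[["participant_id", "eccentricity_deg", "value"]]
    analyses = [
        ("mask_baseline_coll_vs_orth", sel("masking", "collinear", B),
         sel("masking", "orthogonal", B)),
        ("mask_xcrit_coll_vs_orth", sel("masking", "collinear", X),
         sel("masking", "orthogonal", X)),
        ("mask_coll_baseline_vs_xcrit", sel("masking", "collinear", B),
         sel("masking", "collinear", X)),
        ("mask_orth_baseline_vs_xcrit", sel("masking", "orthogonal", B),
         sel("masking", "orthogonal", X)),
        ("crowd_baseline_vs_xcrit", sel("crowding", "none", B),
         sel("crowding", "none", X)),
        ("crowd_vs_mask_coll_baseline", sel("crowding", "none", B),
         sel("masking", "collinear", B)),
        ("crowd_vs_mask_orth_baseline", sel("crowding", "none", B),
         sel("masking", "orthogonal", B)),
        ("crowd_vs_mask_coll_xcrit", sel("crowding", "none", X),
         sel("masking", "collinear", X)),
        ("crowd_vs_mask_orth_xcrit", sel("crowding", "none", X),
         sel("masking", "orthogonal", X)),
        ("group_vs_mask_coll_baseline", gsel, sel("masking", "collinear", B)),
        ("group_vs_mask_orth_baseline", gsel, sel("masking", "orthogonal", B)),
        ("group_vs_crowd_baseline", gsel, sel("crowding", "none", B)),
    ]
    corr_rows = []
    for name, a, b in analyses:
        pairs = _rm_pairs(a, b)
        try:
            res = _stats.rmcorr(pairs)
        except ValueError as exc:
            log.warning("correlate: %s skipped: %s", name, exc)
            continue
        corr_rows.append({
            "analysis": name, "method": "rmcorr", "r": res.r_rm,
            "df": res.df, "p": res.p_value, "n_subjects": res.n_subjects,
            "n_obs": res.n_observations, "significant": res.significant,
        })

    gfits = fit_bundle["grouping_fits"]
    ok = gfits[gfits["reliable"].astype(bool)].dropna(subset=["xcrit_ecc"]) \
        if len(gfits) else gfits
    if len(ok) >= 4:
        pr = _stats.pearson(ok["b"], ok["xcrit_ecc"])
        corr_rows.append({
            "analysis": "group_baseline_vs_critical_ecc", "method": "pearson",
            "r": pr.r, "df": pr.df, "p": pr.p_value, "n_subjects": len(ok),
            "n_obs": len(ok), "significant": pr.significant,
        })
    return {"measures": retained, "exclusions": exclusion_log,
            "correlations": pd.DataFrame(corr_rows)}


@dataclass
class PipelineResult:
    config: RunConfig
    trials: pd.DataFrame
    ground_truth: pd.DataFrame
    thresholds: pd.DataFrame
    spacing_fits: pd.DataFrame
    grouping_fits: pd.DataFrame
    min_contrast: pd.DataFrame
    csf_fits: pd.DataFrame
    measures: pd.DataFrame
    exclusions: pd.DataFrame
    correlations: pd.DataFrame
    summary: dict


def _summarize(result_parts: dict, config: RunConfig) -> dict:
    spacing = result_parts["spacing_fits"]
    agg = []
    if len(spacing):
        ok = spacing[spacing["reliable"].astype(bool)]
        for (task, cond, ecc), sub in ok.groupby(
                ["task", "condition", "eccentricity_deg"]):
            agg.append({"task": task, "condition": cond,
                        "eccentricity_deg": float(ecc),
                        "mean_ybase": float(sub["ybase"].mean()),
                        "mean_xcrit": float(sub["xcrit"].mean()),
                        "mean_xcrit_frac": float((sub["xcrit"] / ecc).mean()),
                        "n": int(len(sub))})
    gf = result_parts["grouping_fits"]
    grouping_summary = {}
    if len(gf):
        ok = gf[gf["reliable"].astype(bool)]
        if len(ok):
            grouping_summary = {
                "mean_baseline": float(ok["b"].mean()),
                "median_slope": float(ok["m"].median()),
                "mean_critical_ecc": float(ok["xcrit_ecc"].mean()),
                "n": int(len(ok))}
    thr = result_parts["thresholds"]
    return {
        "seed": config.seed,
        "n_participants": config.n_participants,
        "n_cells": int(len(thr)),
        "n_reliable_cells": int(thr["reliable"].sum()) if len(thr) else 0,
        "spacing_aggregates": agg,
        "grouping": grouping_summary,
        "n_exclusions": int(len(result_parts["exclusions"])),
        "correlations": result_parts["correlations"].to_dict("records"),
    }


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all stages in order; identical outputs for identical config."""
    ss = np.random.SeedSequence(config.seed)
    sim_ss, est_ss, csf_ss = ss.spawn(3)

    log.info("stage simulate: %d participants", config.n_participants)
    observers = _cohort.make_observers(
        config.n_participants, np.random.default_rng(sim_ss.spawn(1)[0]),
        config.design())
    trials, ground_truth = _cohort.simulate_cohort(
        config.n_participants, sim_ss, design=config.design(),
        staircase_template=config.staircase_template(), observers=observers,
        drop_largest_spread_frac=config.drop_largest_spread_frac)

    log.info("stage estimate: %d trials", len(trials))
    thresholds = estimate_thresholds(trials, config, est_ss)

    log.info("stage fit")
    bundle = fit_all(thresholds, config)
    csf_fits = pd.DataFrame()
    if config.include_csf:
        csf_table = _cohort.simulate_csf_table(
            observers, np.random.default_rng(csf_ss))
        csf_fits = fit_csf_tables(csf_table)

    log.info("stage correlate")
    corr = correlate(bundle, config)

    parts = {"thresholds": thresholds, **bundle, **corr}
    summary = _summarize(parts, config)
    result = PipelineResult(
        config=config, trials=trials, ground_truth=ground_truth,
        thresholds=thresholds, spacing_fits=bundle["spacing_fits"],
        grouping_fits=bundle["grouping_fits"],
        min_contrast=bundle["min_contrast"], csf_fits=csf_fits,
        measures=corr["measures"], exclusions=corr["exclusions"],
        correlations=corr["correlations"], summary=summary)
    if config.output_dir:
        write_results(result, config.output_dir)
    return result


def write_results(result: PipelineResult, outdir) -> None:
    """Write every stage output as CSV plus a JSON summary."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.trials.to_csv(out / "trials.csv", index=False)
    result.ground_truth.to_csv(out / "ground_truth.csv", index=False)
    result.thresholds.to_csv(out / "thresholds.csv", index=False)
    result.spacing_fits.to_csv(out / "fits.csv", index=False)
    result.grouping_fits.to_csv(out / "grouping_fits.csv", index=False)
    result.min_contrast.to_csv(out / "min_contrast.csv", index=False)
    result.csf_fits.to_csv(out / "csf_fits.csv", index=False)
    result.measures.to_csv(out / "measures.csv", index=False)
    result.exclusions.to_csv(out / "exclusions.csv", index=False)
    result.correlations.to_csv(out / "correlations.csv", index=False)
    (out / "summary.json").write_text(json.dumps(result.summary, indent=2,
                                                 sort_keys=True))
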