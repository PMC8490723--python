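"""End-to-end orchestration: simulate -> prepare -> metrics -> statistics.

``analyze_trial`` applies the identical preparation chain to every trial
(zero-phase low-pass filtering, kinetic event detection, step labelling)
and extracts the per-step outcomes; ``run_pipeline`` composes the whole
study analysis and returns a ``ResultsBundle`` of plain tables that can be
written to CSV/JSON deterministically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import stats0d
from .config import AnalysisConfig, StudyConfig
from .signal_prep import (
    detect_gait_events,
    label_steps,
    lowpass_filter,
    normalize_stance,
)
from .spm import SPMResult, roi_average, spm_contrast
from .stability import (
    BaselineStats,
    baseline_stats,
    grf_angle,
    margin_of_stability,
    n_steps,
    step_length_pct,
    xcom,
)
from .synthetic import SIDES, StudyDataset, TrialTimeSeries, simulate_study

logger = logging.getLogger("slipgait")

__all__ = ["StepMetrics", "ResultsBundle", "analyze_trial", "run_pipeline",
           "compute_study_metrics"]

CURVE_CHANNELS = ("grf_theta", "moment_knee", "moment_ankle", "moment_hip")


@dataclass
class StepMetrics:
    step_label: str
    side: str
    hs_time: float
    to_time: float
    mos_cm: float
    step_len_pctbh: float
    curves: dict[str, np.ndarray]  # 101-node stance curves per channel


@dataclass
class ResultsBundle:
    metrics: pd.DataFrame  # participant, age_group, slip, step_label, ...
    outcomes: pd.DataFrame  # participant, slip, n_steps, capped
    baselines: pd.DataFrame  # participant, mos_mean, mos_sd, n_cycles
    events: pd.DataFrame  # participant, slip, side, type, time_s, step_label
    spm: list[SPMResult]
    clusters: pd.DataFrame
    roi: pd.DataFrame
    tests: pd.DataFrame
    correlations: pd.DataFrame
    manifest: dict[str, Any] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in (
            ("metrics", self.metrics),
            ("outcomes", self.outcomes),
            ("baselines", self.baselines),
            ("events", self.events),
            ("clusters", self.clusters),
            ("roi", self.roi),
            ("tests", self.tests),
            ("correlations", self.correlations),
        ):
            df.to_csv(out / f"{name}.csv", index=False, float_format="%.10g")
        bundle = {
            "spm": [
                {
                    "channel": r.channel,
                    "contrast": r.contrast,
                    "alpha": r.alpha,
                    "threshold": r.threshold,
                    "n_permutations": r.n_permutations,
                    "clusters": [list(c) for c in r.clusters],
                }
                for r in self.spm
            ],
            "manifest": self.manifest,
        }
        with open(out / "bundle.json", "w") as fh:
            json.dump(bundle, fh, indent=1, sort_keys=True)


def _nearest(t: np.ndarray, value: float) -> int:
    return int(np.argmin(np.abs(t - value)))


def analyze_trial(
    trial: TrialTimeSeries,
    height: float,
    pert_side: str | None,
    acfg: AnalysisConfig,
    n_recovery: int = 15,
) -> list[StepMetrics]:
    """Filter, detect events, label steps and extract per-step outcomes.

    The CoM velocity is obtained by central differences of the filtered
    position (filter-then-differentiate).
    """
    mrate, frate = trial.marker_rate, trial.force_rate
    f = lambda x, rate: lowpass_filter(x, acfg.filter_cutoff_hz,
                                       acfg.filter_order, rate)
    com = f(trial.com_ap, mrate)
    com_vel = np.gradient(com, 1.0 / mrate)
    foot = {s: f(trial.foot_com_ap[s], mrate) for s in SIDES}
    toe2 = {s: f(trial.toe2_ap[s], mrate) for s in SIDES}
    moments = {
        "moment_hip": {s: f(trial.moment_hip[s], mrate) for s in SIDES},
        "moment_knee": {s: f(trial.moment_knee[s], mrate) for s in SIDES},
        "moment_ankle": {s: f(trial.moment_ankle[s], mrate) for s in SIDES},
    }
    grf_v = {s: f(trial.grf_vert[s], frate) for s in SIDES}
    grf_a = {s: f(trial.grf_ap[s], frate) for s in SIDES}
    theta = {s: grf_angle(grf_a[s], grf_v[s]) for s in SIDES}

    # events from the raw vertical GRF: the zero-phase 8 Hz filter smears the
    # contact transient by tens of ms, which would bias heel-strike timing
    events = detect_gait_events(
        trial.grf_vert, frate, acfg.event_threshold_n,
        acfg.event_min_contact_s, time=trial.time_force,
    )
    events = label_steps(events, trial.pert_hs_time, pert_side,
                         n_recovery=n_recovery)

    leg = acfg.leg_length_factor * height
    omega0 = np.sqrt(acfg.gravity / leg)
    tm = trial.time_marker

    out: list[StepMetrics] = []
    for label, (side, idx) in sorted(
        events.labels.items(), key=lambda kv: events.contacts[kv[1][0]][kv[1][1]]
    ):
        hs, to = events.contacts[side][idx]
        i_hs = _nearest(tm, hs)
        other = "left" if side == "right" else "right"
        mos = float(
            margin_of_stability(
                toe2[side][i_hs], xcom(com[i_hs], com_vel[i_hs], omega0)
            )
        )
        length = float(step_length_pct(foot[side][i_hs], foot[other][i_hs],
                                       height))
        curves: dict[str, np.ndarray] = {}
        curves["grf_theta"] = normalize_stance(
            theta[side], hs, to, frate, t0=trial.time_force[0],
            channel="grf_theta", units="deg",
        ).values
        for name in ("moment_hip", "moment_knee", "moment_ankle"):
            curves[name] = normalize_stance(
                moments[name][side], hs, to, mrate, t0=tm[0],
                channel=name, units="N.m/kg",
            ).values
        out.append(StepMetrics(step_label=label, side=side, hs_time=hs,
                               to_time=to, mos_cm=mos,
                               step_len_pctbh=length, curves=curves))
    return out


def _events_rows(participant: str, slip: int, steps: list[StepMetrics]):
    for sm in steps:
        yield (participant, slip, sm.side, "heel_strike", sm.hs_time,
               sm.step_label)
        yield (participant, slip, sm.side, "toe_off", sm.to_time, sm.step_label)


def compute_study_metrics(
    dataset: StudyDataset, acfg: AnalysisConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Run the preparation and outcome stages on every trial of a study.

    Returns (metrics, outcomes, baselines, events, curves) where ``curves``
    maps (participant, slip, step_label, channel) to a 101-node array.
    The Normal-trial baseline of each participant is the mean and sample SD
    of the MoS over ``n_baseline_cycles`` consecutive steps of the (future)
    perturbed side, skipping warm-up steps.
    """
    profiles = {p.id: p for p in dataset.participants}
    n_slips = max(s for (_, s) in dataset.trials) if dataset.trials else 0
    gcfg = dataset.config_echo.get("generator", {})
    n_recovery = int(gcfg.get("n_recovery_steps", 15))

    metric_rows = []
    outcome_rows = []
    baseline_rows = []
    event_rows = []
    curves: dict[tuple[str, int, str, str], np.ndarray] = {}
    baselines: dict[str, BaselineStats] = {}

    for profile in dataset.participants:
        pid = profile.id
        # --- Normal trial & baseline -----------------------------------
        trial = dataset.trials[(pid, 0)]
        steps = analyze_trial(trial, profile.height, None, acfg,
                              n_recovery=n_recovery)
        own = [sm for sm in steps if sm.side == profile.perturbed_side]
        cycles = own[
            acfg.baseline_skip_steps : acfg.baseline_skip_steps
            + acfg.n_baseline_cycles
        ]
        if len(cycles) < acfg.n_baseline_cycles:
            raise ValueError(
                f"{pid}: Normal trial has fewer than "
                f"{acfg.n_baseline_cycles} usable gait cycles"
            )
        base = baseline_stats([sm.mos_cm for sm in cycles])
        baselines[pid] = base
        baseline_rows.append((pid, base.mos_mean, base.mos_sd, base.n_cycles))
        event_rows.extend(_events_rows(pid, 0, steps))
        # Normal condition summaries: per-cycle mean
        for ch in CURVE_CHANNELS:
            curves[(pid, 0, "Normal", ch)] = np.mean(
                [sm.curves[ch] for sm in cycles], axis=0
            )
        metric_rows.append(
            (pid, profile.age_group, 0, "Normal",
             float(np.mean([sm.mos_cm for sm in cycles])),
             float(np.mean([sm.step_len_pctbh for sm in cycles])))
        )

        # --- slip trials -------------------------------------------------
        for s in range(1, n_slips + 1):
            trial = dataset.trials[(pid, s)]
            steps = analyze_trial(trial, profile.height,
                                  profile.perturbed_side, acfg,
                                  n_recovery=n_recovery)
            event_rows.extend(_events_rows(pid, s, steps))
            by_label = {sm.step_label: sm for sm in steps}
            for sm in steps:
                metric_rows.append((pid, profile.age_group, s, sm.step_label,
                                    sm.mos_cm, sm.step_len_pctbh))
                for ch in CURVE_CHANNELS:
                    curves[(pid, s, sm.step_label, ch)] = sm.curves[ch]
            rec = [by_label[f"Rec{k}"].mos_cm for k in range(1, n_recovery + 1)]
            outcome = n_steps(rec, base, slip_index=s, n_recovery=n_recovery)
            if outcome.capped:
                logger.warning("%s slip %d: recovery capped (n_steps=16)",
                               pid, s)
            outcome_rows.append((pid, profile.age_group, s, outcome.n_steps,
                                 outcome.capped))

    metrics = pd.DataFrame(
        metric_rows,
        columns=["participant", "age_group", "slip", "step_label", "mos_cm",
                 "step_len_pctbh"],
    )
    outcomes = pd.DataFrame(
        outcome_rows,
        columns=["participant", "age_group", "slip", "n_steps", "capped"],
    )
    baseline_df = pd.DataFrame(
        baseline_rows, columns=["participant", "mos_mean", "mos_sd", "n_cycles"]
    )
    events_df = pd.DataFrame(
        event_rows,
        columns=["participant", "slip", "side", "type", "time_s", "step_label"],
    )
    return metrics, outcomes, baseline_df, events_df, curves


def _curve_matrix(curves, participants, slip, label, channel):
    rows = [curves[(p, slip, label, channel)] for p in participants]
    return np.vstack(rows)


def run_pipeline(
    config: StudyConfig,
    dataset: StudyDataset | None = None,
    seed: int | None = None,
) -> ResultsBundle:
    """Simulate (unless given a dataset) and analyse a full study."""
    seed = config.seed if seed is None else int(seed)
    if dataset is None:
        dataset = simulate_study(config, seed)
    acfg = config.analysis
    metrics, outcomes, baselines, events_df, curves = compute_study_metrics(
        dataset, acfg
    )
    participants = [p.id for p in dataset.participants]
    age = {p.id: p.age_group for p in dataset.participants}
    n_slips = int(outcomes["slip"].max()) if len(outcomes) else 0
    first, last = 1, n_slips

    def mos_series(slip, label):
        sel = metrics[(metrics["slip"] == slip)
                      & (metrics["step_label"] == label)]
        return sel.set_index("participant")["mos_cm"].reindex(participants)

    def len_series(slip, label):
        sel = metrics[(metrics["slip"] == slip)
                      & (metrics["step_label"] == label)]
        return sel.set_index("participant")["step_len_pctbh"].reindex(
            participants)

    # ------------------------------------------------------------------ SPM
    spm_results: list[SPMResult] = []
    roi_rows = []
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5B3]))
    spm_conditions = [(first, "Pert"), (first, "Rec1")]
    if last > first:
        spm_conditions += [(last, "Pert"), (last, "Rec1")]
    for channel in ("grf_theta", "moment_knee", "moment_ankle"):
        normal = _curve_matrix(curves, participants, 0, "Normal", channel)
        for slip, label in spm_conditions:
            cond = _curve_matrix(curves, participants, slip, label, channel)
            name = f"Slip{slip:02d}_{label}~Normal"
            res = spm_contrast(
                cond, normal, paired=True, alpha=acfg.spm_alpha,
                n_perm=acfg.n_permutations,
                seed=int(rng.integers(2**31 - 1)),
                channel=channel, contrast=name,
            )
            spm_results.append(res)
            for (cs, ce) in res.clusters:
                for pid in participants:
                    roi_rows.append(
                        (pid, channel, name, slip, label, cs, ce,
                         roi_average(curves[(pid, slip, label, channel)],
                                     (cs, ce)))
                    )
        if last > first:
            for label in ("Pert", "Rec1"):
                a = _curve_matrix(curves, participants, first, label, channel)
                b = _curve_matrix(curves, participants, last, label, channel)
                res = spm_contrast(
                    a, b, paired=True, alpha=acfg.spm_alpha,
                    n_perm=acfg.n_permutations,
                    seed=int(rng.integers(2**31 - 1)),
                    channel=channel,
                    contrast=f"Slip{first:02d}_{label}~Slip{last:02d}_{label}",
                )
                spm_results.append(res)

    roi = pd.DataFrame(
        roi_rows,
        columns=["participant", "channel", "contrast", "slip", "step_label",
                 "start_pct", "end_pct", "value"],
    )
    cluster_rows = [
        (r.channel, r.contrast, cs, ce, r.threshold, r.alpha, r.n_permutations)
        for r in spm_results
        for (cs, ce) in r.clusters
    ]
    clusters = pd.DataFrame(
        cluster_rows,
        columns=["channel", "contrast", "start_pct", "end_pct", "threshold",
                 "alpha", "n_perm"],
    )

    # ------------------------------------------------------- scalar families
    tests: list[stats0d.TestResult] = []

    # n_steps across slips: Friedman + Wilcoxon post-hocs, Age via M-W
    ns_wide = outcomes.pivot(index="participant", columns="slip",
                             values="n_steps")
    ns_wide.columns = [f"Slip{int(c):02d}" for c in ns_wide.columns]
    if n_slips >= 3:
        fam = 45 if n_slips == 10 else None
        tests += stats0d.compare_conditions(ns_wide, "friedman",
                                            family_size=fam)
    ns_age = ns_wide.copy()
    ns_age["age_group"] = [age[p] for p in ns_age.index]
    tests += stats0d.compare_conditions(ns_age, "mann_whitney",
                                        between="age_group",
                                        family_size=n_slips)

    # anticipatory MoS family: Normal, Pre2/Pre1 of first and last slip
    pre = pd.DataFrame(index=pd.Index(participants, name="participant"))
    pre["Normal"] = mos_series(0, "Normal")
    for slip in {first, last}:
        for lbl in ("Pre2", "Pre1"):
            pre[f"Slip{slip:02d}_{lbl}"] = mos_series(slip, lbl)
    fam_pre = 8 if n_slips == 10 else None
    tests += stats0d.compare_conditions(pre.dropna(), "friedman",
                                        family_size=fam_pre)

    # recovery MoS vs Normal: one mixed ANOVA per slip (alpha 0.005)
    n_recovery = int(dataset.config_echo.get("generator", {})
                     .get("n_recovery_steps", 15))
    for slip in range(1, n_slips + 1):
        rec = pd.DataFrame(index=pd.Index(participants, name="participant"))
        rec["Normal"] = mos_series(0, "Normal")
        for k in range(1, n_recovery + 1):
            rec[f"Rec{k}"] = mos_series(slip, f"Rec{k}")
        rec["age_group"] = [age[p] for p in rec.index]
        aov = stats0d.compare_conditions(rec.dropna(), "mixed_anova",
                                         between="age_group")
        for t in aov:
            if t.test == "mixed_anova":
                t.alpha_adjusted = acfg.alpha_mos_anova
                t.contrast = f"Slip{slip:02d}_MoS:{t.contrast}"
                tests.append(t)

    # step-length family: Normal vs Pert/Rec1/Rec2 of first & last slip,
    # plus first-vs-last, at the nine-contrast alpha
    sl = pd.DataFrame(index=pd.Index(participants, name="participant"))
    sl["Normal"] = len_series(0, "Normal")
    for slip in {first, last}:
        for lbl in ("Pert", "Rec1", "Rec2"):
            sl[f"Slip{slip:02d}_{lbl}"] = len_series(slip, lbl)
    sl = sl.dropna()
    sl_pairs = [("Normal", c) for c in sl.columns if c != "Normal"]
    if last > first:
        sl_pairs += [
            (f"Slip{first:02d}_{lbl}", f"Slip{last:02d}_{lbl}")
            for lbl in ("Pert", "Rec1", "Rec2")
        ]
    sig_scalar: list[tuple[str, int, str, pd.Series]] = []
    for ca, cb in sl_pairs:
        res = stats0d.compare_conditions(sl[[ca, cb]], "wilcoxon_posthoc",
                                         family_size=9)
        tests += res
        if res[0].significant and ca == "Normal":
            slip = int(cb[4:6])
            lbl = cb.split("_", 1)[1]
            sig_scalar.append(
                (f"step_length[{cb}]", slip, lbl, len_series(slip, lbl))
            )

    # ------------------------------------------------------- correlations
    out_long = outcomes.rename(columns={"n_steps": "n_steps"})
    correlations = stats0d.correlation_plan(
        metrics, out_long, roi=roi, scalar_sources=sig_scalar,
        normality_alpha=acfg.normality_alpha,
    )

    tests_df = pd.DataFrame(
        [
            (t.test, t.contrast, t.statistic, t.p_value, t.alpha_adjusted,
             t.significant)
            for t in tests
        ],
        columns=["test", "contrast", "statistic", "p_value", "alpha_adjusted",
                 "significant"],
    )
    corr_df = pd.DataFrame(
        [
            (c.pair, c.method, c.coefficient, c.p_value, c.n, c.excluded_capped)
            for c in correlations
        ],
        columns=["pair", "method", "coefficient", "p_value", "n",
                 "excluded_capped"],
    )
    manifest = {
        "seed": seed,
        "config_hash": config.config_hash(),
        "n_participants": len(participants),
        "n_slips": n_slips,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    return ResultsBundle(
        metrics=metrics, outcomes=outcomes,
        baselines=baselines, events=events_df, spm=spm_results,
        clusters=clusters, roi=roi, tests=tests_df, correlations=corr_df,
        manifest=manifest,
    )
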