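"""End-to-end orchestration: simulate -> detect -> classify -> SDT -> stats.

A run emulates the study design: 7 control and 7 perturbation sessions per
arm, ~1000 trials each over the 13 display configurations, followed by
per-hemifield signal-detection analysis and session-level inference.  All
randomness derives from a single seed via a counter scheme (session k of
arm a uses ``seed * 1000 + a * 500 + k``), so adding sessions never
perturbs existing ones and a fixed seed is fully reproducible.

Every downstream artifact is re-derivable from the tidy per-trial tables
alone; ``reanalyze`` takes a trial table and recomputes counts, metrics and
statistics without touching the generator.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from . import outcome_classification as oc
from . import scenario_simulation as sim
from . import sdt_metrics as sdt
from . import stats_inference as si
from .saccade_detection import DetectionParams, detect_saccades
from .synthetic_data import (
    GazeKinematics,
    InactivationEffect,
    LatencyModel,
    SessionParams,
    generate_gaze_trace,
    generate_session,
    trials_to_frame,
)
from .task_model import Side

__all__ = ["RunConfig", "run_pipeline", "reanalyze", "write_report", "load_config"]

log = logging.getLogger("saccsdt.pipeline")

_MEASURES = ("hit_rate", "fa_rate", "dprime", "criterion")


@dataclass
class RunConfig:
    """Configuration of one full pipeline run (defaults mirror the design)."""

    seed: int = 0
    n_sessions: int = 7  # per arm
    n_trials_per_condition: int = 75
    inactivated_side: Side = Side.LEFT
    effect: InactivationEffect = field(
        default_factory=lambda: InactivationEffect(criterion_shift=0.2)
    )
    control_latency: LatencyModel = field(default_factory=LatencyModel)
    inactivation_latency: LatencyModel = field(
        default_factory=lambda: LatencyModel(mean_contra=220.0, mean_ipsi=180.0)
    )
    detection: DetectionParams = field(default_factory=DetectionParams)
    correction: str = "log_linear"
    detect_sample_size: int = 10  # gaze-trace round-trip check per run
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_sessions < 2:
            raise ValueError("need >= 2 sessions per arm for inference")
        self.inactivated_side = Side(self.inactivated_side)

    def session_params(self, arm: str, index: int) -> SessionParams:
        arm_offset = 0 if arm == "control" else 500
        return SessionParams(
            latency=self.control_latency if arm == "control" else self.inactivation_latency,
            n_trials_per_condition=self.n_trials_per_condition,
            seed=(int(self.seed) * 1000 + arm_offset + index) % (2**31),
            perturbation=arm,
            effect=self.effect,
            inactivated_side=self.inactivated_side,
        )


def load_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file (flat keys; nested for models)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = dict(raw)
    for key, cls in (
        ("effect", InactivationEffect),
        ("control_latency", LatencyModel),
        ("inactivation_latency", LatencyModel),
        ("detection", DetectionParams),
    ):
        if key in kwargs and isinstance(kwargs[key], dict):
            kwargs[key] = cls(**kwargs[key])
    return RunConfig(**kwargs)


def simulate_sessions(config: RunConfig) -> pd.DataFrame:
    """Generate all sessions of both arms as one tidy trial table."""
    frames = []
    session_id = 0
    for arm in ("control", "inactivation"):
        for k in range(config.n_sessions):
            params = config.session_params(arm, k)
            trials = generate_session(params)
            frames.append(trials_to_frame(trials, session_id=session_id, perturbation=arm))
            session_id += 1
    return pd.concat(frames, ignore_index=True)


def detection_check(config: RunConfig) -> pd.DataFrame:
    """Round-trip a sample of selection trials through the gaze generator
    and the velocity-threshold detector; reports latency/amplitude errors."""
    params = config.session_params("control", 0)
    trials = generate_session(params)
    rows = []
    for t in trials:
        if len(rows) >= config.detect_sample_size:
            break
        if t.selected_side is None:
            continue
        trace = generate_gaze_trace(t, GazeKinematics(), seed=config.seed)
        found = detect_saccades(trace, reference_t=t.go_time, params=config.detection)
        if found:
            s = found[0]
            rows.append(
                {
                    "true_latency_ms": t.latency,
                    "detected_latency_ms": s.latency,
                    "latency_error_ms": s.latency - t.latency,
                    "amplitude_deg": s.amplitude,
                    "peak_velocity": s.peak_velocity,
                    "n_detected": len(found),
                }
            )
        else:
            rows.append(
                {
                    "true_latency_ms": t.latency,
                    "detected_latency_ms": np.nan,
                    "latency_error_ms": np.nan,
                    "amplitude_deg": np.nan,
                    "peak_velocity": np.nan,
                    "n_detected": 0,
                }
            )
    return pd.DataFrame(rows)


def session_metrics(
    trials: pd.DataFrame, inactivated_side: Side, correction: str = "log_linear"
) -> pd.DataFrame:
    """Per-session, per-cell SDT metrics (hemifield x stimulus type x difficulty)."""
    tally = oc.tally_counts(trials, inactivated_side)
    cells = oc.sdt_cells(tally)
    return sdt.metrics_table(cells, correction=correction)


def latency_summary(trials: pd.DataFrame, inactivated_side: Side) -> pd.DataFrame:
    """Mean latency of completed saccades to targets, per session cell.

    Hemifield refers to the side of the selected target relative to the
    inactivated hemisphere; difficulty levels are pooled.
    """
    side = Side(inactivated_side)
    contra = side.opposite.value
    sel = trials[trials["response"].isin(["select_left", "select_right"])].copy()
    sel["sel_side"] = np.where(sel["response"] == "select_left", "left", "right")
    role = np.where(
        sel["sel_side"] == "left", sel["left_role"], sel["right_role"]
    )
    sel = sel[role == "target"]
    sel["hemifield"] = np.where(sel["sel_side"] == contra, "contra", "ipsi")
    out = (
        sel.groupby(["session_id", "perturbation", "stimulus_type", "hemifield"],
                    observed=True)["latency_ms"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "latency_ms", "count": "n_saccades"})
    )
    return out


def _arm_values(df: pd.DataFrame, value: str) -> Dict[str, np.ndarray]:
    return {
        arm: df.loc[df["perturbation"] == arm, value].to_numpy()
        for arm in ("control", "inactivation")
    }


def sdt_ttest_table(metrics: pd.DataFrame) -> pd.DataFrame:
    """Control vs. inactivation t-tests per cell and measure (Table 2 layout)."""
    rows = []
    keys = ["stimulus_type", "difficulty", "hemifield"]
    for cell, part in metrics.groupby(keys, observed=True):
        for measure in _MEASURES:
            vals = _arm_values(part, measure)
            if min(len(v) for v in vals.values()) < 2:
                continue
            t_res = si.independent_t_test(vals["inactivation"], vals["control"])
            r_res = si.ranksum_test(vals["inactivation"], vals["control"])
            rows.append(
                {
                    **dict(zip(keys, cell)),
                    "measure": measure,
                    "mean_control": float(np.mean(vals["control"])),
                    "mean_inactivation": float(np.mean(vals["inactivation"])),
                    "t": t_res.statistic,
                    "df": t_res.df,
                    "p": t_res.p_value,
                    "p_ranksum": r_res.p_value,
                }
            )
    return pd.DataFrame(rows)


def latency_ttest_table(latency: pd.DataFrame) -> pd.DataFrame:
    """Control vs. inactivation latency t-tests (Table 1 layout)."""
    rows = []
    for (stype, hemi), part in latency.groupby(["stimulus_type", "hemifield"],
                                               observed=True):
        vals = _arm_values(part, "latency_ms")
        if min(len(v) for v in vals.values()) < 2:
            continue
        res = si.independent_t_test(vals["inactivation"], vals["control"])
        rows.append(
            {
                "stimulus_type": stype,
                "hemifield": hemi,
                "mean_control_ms": float(np.mean(vals["control"])),
                "mean_inactivation_ms": float(np.mean(vals["inactivation"])),
                "t": res.statistic,
                "df": res.df,
                "p": res.p_value,
            }
        )
    return pd.DataFrame(rows)


def mixed_anova_table(metrics: pd.DataFrame) -> pd.DataFrame:
    """Two-way mixed ANOVA (hemifield x perturbation) per cell and measure."""
    rows = []
    for (stype, diff), part in metrics.groupby(["stimulus_type", "difficulty"],
                                               observed=True):
        for measure in ("dprime", "criterion"):
            table = part.rename(columns={measure: "value"})
            aov = si.mixed_anova_2way(table)
            for _, arow in aov.iterrows():
                rows.append(
                    {
                        "stimulus_type": stype,
                        "difficulty": diff,
                        "measure": measure,
                        **arow.to_dict(),
                    }
                )
    return pd.DataFrame(rows)


def scenario_panels(correction: str = "log_linear") -> pd.DataFrame:
    """Hypothesis-prediction panels for every stimulus type x difficulty."""
    rows = []
    for stype in ("single", "double_same", "double_different"):
        for diff in ("difficult", "easy"):
            for hypo in ("response_bias", "perceptual_deficit"):
                for hemi in ("contra", "ipsi"):
                    if stype == "single" and hemi == "ipsi":
                        continue
                    scen = sim.hypothesis_template(stype, diff, hypo, hemifield=hemi)
                    res = sim.apply_scenario(scen, correction=correction)
                    rows.append(
                        {
                            "stimulus_type": stype,
                            "difficulty": diff,
                            "hypothesis": hypo,
                            "hemifield": hemi,
                            "hit_before": res.before.hit_rate,
                            "hit_after": res.after.hit_rate,
                            "fa_before": res.before.fa_rate,
                            "fa_after": res.after.fa_rate,
                            "criterion_before": res.before.criterion,
                            "criterion_after": res.after.criterion,
                            "dprime_before": res.before.dprime,
                            "dprime_after": res.after.dprime,
                        }
                    )
    return pd.DataFrame(rows)


def reanalyze(trials: pd.DataFrame, config: RunConfig) -> Dict[str, object]:
    """Everything downstream of the trial table (no generator state needed)."""
    t0 = time.perf_counter()
    metrics = session_metrics(trials, config.inactivated_side, config.correction)
    latency = latency_summary(trials, config.inactivated_side)
    acc = oc.accuracy_table(trials)
    ttests = sdt_ttest_table(metrics)
    lat_tests = latency_ttest_table(latency)
    anova = mixed_anova_table(metrics)

    # go/stay bias per session and stimulus type (hemifields pooled)
    # pool the raw tally (not the per-difficulty cells, which would count
    # the shared target-only trials twice)
    tally = oc.tally_counts(trials, config.inactivated_side)
    pooled = oc.pooled_counts(tally, over=("hemifield", "difficulty"))
    bias_rows = []
    for _, row in pooled.iterrows():
        counts = sdt.SDTCounts(
            int(row["hits"]), int(row["misses"]),
            int(row["correct_rejections"]), int(row["false_alarms"]),
        )
        value, label = sdt.go_stay_bias(counts, row["stimulus_type"], config.correction)
        bias_rows.append(
            {
                "session_id": row["session_id"],
                "perturbation": row["perturbation"],
                "stimulus_type": row["stimulus_type"],
                "bias": value,
                "label": label,
            }
        )
    bias = pd.DataFrame(bias_rows)

    # accuracy differences between stimulus types in control sessions
    rm_results = {}
    control_acc = acc[acc["perturbation"] == "control"]
    for diff, part in control_acc.groupby("difficulty", observed=True):
        table = part.rename(columns={"accuracy": "value"})
        aov, post = si.rm_anova_1way(table)
        rm_results[diff] = {"anova": aov, "posthoc": post}

    log.info("analysis stage done in %.2fs", time.perf_counter() - t0)
    return {
        "metrics": metrics,
        "latency": latency,
        "accuracy": acc,
        "ttests": ttests,
        "latency_ttests": lat_tests,
        "mixed_anova": anova,
        "go_stay_bias": bias,
        "rm_anova_accuracy": rm_results,
    }


def _summarize(bundle: Dict[str, object], config: RunConfig) -> Dict[str, object]:
    ttests: pd.DataFrame = bundle["ttests"]
    contra = ttests[ttests["hemifield"] == "contra"]

    def _sig(measure: str) -> Dict[str, object]:
        part = contra[contra["measure"] == measure]
        return {
            "n_cells": int(len(part)),
            "n_significant": int((part["p"] < config.alpha).sum()),
            "mean_change": float(
                (part["mean_inactivation"] - part["mean_control"]).mean()
            ) if len(part) else None,
        }

    table3 = sim.apply_scenario(
        sim.Scenario(before={"hit": 0.70, "fa": 0.40}, effect={"hit": -0.2, "fa": -0.2})
    )
    return {
        "seed": int(config.seed),
        "design": {
            "n_sessions_per_arm": config.n_sessions,
            "n_trials_per_condition": config.n_trials_per_condition,
            "inactivated_side": config.inactivated_side.value,
            "criterion_shift": config.effect.criterion_shift,
            "sensitivity_change": config.effect.sensitivity_change,
        },
        "contra_criterion": _sig("criterion"),
        "contra_dprime": _sig("dprime"),
        "worked_example": {
            "criterion_before": sdt.round_report(table3.before.criterion),
            "criterion_after": sdt.round_report(table3.after.criterion),
            "dprime_after": sdt.round_report(table3.after.dprime),
        },
    }


def run_pipeline(config: RunConfig, out_dir: Optional[Path] = None) -> Dict[str, object]:
    """Full run: simulate both arms, analyze, and (optionally) write a report.

    Returns a bundle of dataframes plus a JSON-serializable ``summary``;
    idempotent for a fixed seed.
    """
    t0 = time.perf_counter()
    trials = simulate_sessions(config)
    log.info("simulated %d trials in %.2fs", len(trials), time.perf_counter() - t0)
    bundle: Dict[str, object] = {"trials": trials}
    bundle["detection_check"] = detection_check(config)
    bundle.update(reanalyze(trials, config))
    bundle["scenarios"] = scenario_panels(config.correction)
    bundle["summary"] = _summarize(bundle, config)
    if out_dir is not None:
        write_report(bundle, out_dir)
    return bundle


def write_report(bundle: Dict[str, object], out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in (
        "trials",
        "detection_check",
        "metrics",
        "latency",
        "accuracy",
        "ttests",
        "latency_ttests",
        "mixed_anova",
        "go_stay_bias",
        "scenarios",
    ):
        obj = bundle.get(name)
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(out / f"{name}.csv", index=False)
    rm = bundle.get("rm_anova_accuracy") or {}
    for diff, res in rm.items():
        res["anova"].to_csv(out / f"rm_anova_accuracy_{diff}.csv", index=False)
        if res["posthoc"] is not None:
            res["posthoc"].to_csv(out / f"rm_posthoc_accuracy_{diff}.csv", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(bundle["summary"], fh, indent=2)
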