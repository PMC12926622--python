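"""End-to-end pipeline: simulate -> segment -> filter -> fit -> analyze -> report.

Each stage is a plain function over data frames so it can be re-run from the
CSV artifacts of the previous stage; ``run_pipeline`` chains them in memory
and writes every stage's artifact plus a run manifest.  Re-running with an
identical configuration (hash in the manifest) reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import kinematics as kin
from . import psychometrics as psy
from . import stats as st
from .config import PipelineConfig, Thresholds
from .population import sample_population
from .study import SessionDataset, simulate_study
from .trials import ContractViolation, RejectionParams, reject_trials, rule_counts

REACHING_GROUPS = ("early25", "mid50", "late75", "target")


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    row_counts: dict[str, int] = field(default_factory=dict)
    started: float = 0.0
    finished: float = 0.0

    def to_json(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# stages

def stage_simulate(config: PipelineConfig) -> dict[str, SessionDataset]:
    population = sample_population(
        config.n_participants,
        seed=config.seed,
        params=config.population,
        attenuation=config.attenuation,
    )
    datasets = {}
    for session in config.sessions:
        observers = {pid: models[session][0] for pid, models in population.items()}
        kins = {pid: models[session][1] for pid, models in population.items()}
        fingers = {pid: models["stimulated_finger"] for pid, models in population.items()}
        datasets[session] = simulate_study(
            config.design,
            observers,
            kins,
            seed=config.seed,
            stimulated_fingers=fingers,
        )
    return datasets


def stage_segment(
    datasets: dict[str, SessionDataset], thresholds: Thresholds = Thresholds()
) -> pd.DataFrame:
    frames = []
    for dataset in datasets.values():
        rows = []
        for rec in dataset.trials.itertuples(index=False):
            trace = dataset.traces[rec.trace_ref]
            row = kin.segment_trace(
                trace,
                rec.instructed_finger,
                rec.block,
                onset_threshold=thresholds.onset_speed,
                onset_hold_ms=thresholds.onset_hold_ms,
                offset_threshold=thresholds.offset_force,
                peak_window_fraction=thresholds.peak_window_fraction,
                dip_speed_threshold=thresholds.dip_speed,
                dip_max_ms=thresholds.dip_max_ms,
                retreat_threshold_cm=thresholds.retreat_cm,
            )
            row["trial_id"] = rec.trial_id
            row["participant_id"] = rec.participant_id
            row["session"] = rec.session
            row["scheduled_group"] = rec.scheduled_group
            rows.append(row)
        frames.append(pd.DataFrame(rows, columns=list(kin.SEGMENTATION_COLUMNS)))
    return pd.concat(frames, ignore_index=True)


def stage_filter(
    trials: pd.DataFrame,
    segmentation: pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    params = RejectionParams(
        test_force_min=thresholds.test_force_min,
        test_force_max=thresholds.test_force_max,
        baseline_speed_threshold=thresholds.onset_speed,
        bin_edges=thresholds.bin_edges,
    )
    return reject_trials(trials, segmentation, params)


def stage_fit(
    kept: pd.DataFrame, config: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Fits, post-exclusion fits, exclusion report, and normalized PSEs."""
    fits = psy.fit_dataset(kept, intensities=config.design.comparison_intensities)
    kept_fits, exclusions = psy.exclude_poor_fits(
        fits, r2_threshold=config.thresholds.r2_threshold
    )
    norm = psy.normalize_pse(kept_fits)
    return fits, kept_fits, exclusions, norm


def participant_endpoint_variability(
    kept: pd.DataFrame, segmentation: pd.DataFrame
) -> pd.DataFrame:
    """Root-total-variance endpoint dispersion per participant x session."""
    seg = segmentation.set_index("trial_id")
    reach = kept[kept["block"] == "reaching"]
    rows = []
    for (pid, session), cell in reach.groupby(["participant_id", "session"]):
        s = seg.loc[cell["trial_id"]]
        by_finger = {}
        for finger, grp in s.groupby("instructed_finger"):
            pts = grp[["endpoint_x", "endpoint_y", "endpoint_z"]].to_numpy(dtype=float)
            by_finger[finger] = pts[np.isfinite(pts).all(axis=1)]
        rows.append(
            {
                "participant_id": pid,
                "session": session,
                "endpoint_variability": kin.endpoint_variability(by_finger),
            }
        )
    return pd.DataFrame(rows)


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _as_jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _paired_frame(norm: pd.DataFrame, session: str) -> pd.DataFrame:
    cell = norm[norm["session"] == session]
    return cell.pivot_table(index="participant_id", columns="group", values="delta_pse")


def stage_analyze(
    norm: pd.DataFrame,
    regressions: pd.DataFrame,
    variability: pd.DataFrame,
    alpha: float = 0.05,
) -> dict:
    """The study's inferential battery on the fitted quantities."""
    report: dict = {}

    # trial-group ANOVAs per session, and the groups x session ANOVA
    for session in sorted(norm["session"].unique()):
        cell = norm[norm["session"] == session]
        res = st.rm_anova(cell, dv="delta_pse", within=["group"], subject="participant_id", alpha=alpha)
        report[f"anova_trial_group_{session}"] = res[0]
    if norm["session"].nunique() == 2:
        res = st.rm_anova(
            norm, dv="delta_pse", within=["group", "session"], subject="participant_id", alpha=alpha
        )
        report["anova_group_by_session"] = res
        jnd = st.rm_anova(
            norm, dv="delta_jnd", within=["group", "session"], subject="participant_id", alpha=alpha
        )
        report["anova_jnd_group_by_session"] = jnd

    # pairwise trial-group comparisons within each session, FDR-corrected
    for session in sorted(norm["session"].unique()):
        wide = _paired_frame(norm, session).dropna()
        pairs = [
            (a, b) for a, b in combinations(REACHING_GROUPS, 2)
            if a in wide.columns and b in wide.columns
        ]
        results = {
            f"{b}_vs_{a}": st.paired_compare(wide[b], wide[a], alpha=alpha)
            for a, b in pairs
        }
        adj = st.fdr_adjust([r.p_raw for r in results.values()])
        for r, q in zip(results.values(), adj):
            r.p_fdr = float(q)
        report[f"pairwise_{session}"] = results

    # between-session comparison of the same trial group, FDR-corrected
    if norm["session"].nunique() == 2:
        s1, s2 = sorted(norm["session"].unique())
        w1, w2 = _paired_frame(norm, s1), _paired_frame(norm, s2)
        common = w1.index.intersection(w2.index)
        results = {}
        for g in REACHING_GROUPS:
            if g in w1.columns and g in w2.columns:
                results[g] = st.paired_compare(
                    w1.loc[common, g], w2.loc[common, g], alpha=alpha
                )
        adj = st.fdr_adjust([r.p_raw for r in results.values()])
        for r, q in zip(results.values(), adj):
            r.p_fdr = float(q)
        report["between_sessions_by_group"] = results

    # slope / intercept analyses
    reg = regressions[regressions["valid"]]
    slopes = reg.pivot_table(index="participant_id", columns="session", values="slope")
    intercepts = reg.pivot_table(index="participant_id", columns="session", values="intercept")
    slope_block: dict = {}
    for session in slopes.columns:
        v = slopes[session].dropna()
        slope_block[f"slope_vs_zero_{session}"] = st.one_sample_against_zero(v, alpha=alpha)
        slope_block[f"mean_slope_{session}"] = float(v.mean())
        slope_block[f"sd_slope_{session}"] = float(v.std(ddof=1))
        iv = intercepts[session].dropna()
        slope_block[f"mean_intercept_{session}"] = float(iv.mean())
    if slopes.shape[1] == 2:
        s1, s2 = sorted(slopes.columns)  # no_vision, vision
        both = slopes.dropna()
        slope_block["slope_vision_vs_no_vision"] = st.paired_compare(
            both["vision"], both["no_vision"], alpha=alpha
        )
        bothi = intercepts.dropna()
        slope_block["intercept_vision_vs_no_vision"] = st.paired_compare(
            bothi["vision"], bothi["no_vision"], alpha=alpha
        )
    report["time_regressions"] = slope_block

    # endpoint variability and its relation to the temporal tuning
    var_wide = variability.pivot_table(
        index="participant_id", columns="session", values="endpoint_variability"
    )
    var_block: dict = {
        f"mean_variability_{s}": float(var_wide[s].mean()) for s in var_wide.columns
    }
    if var_wide.shape[1] == 2:
        both = var_wide.dropna()
        var_block["no_vision_vs_vision"] = st.paired_compare(
            both["no_vision"], both["vision"], alpha=alpha
        )
        merged = (
            slopes.join(intercepts, lsuffix="_slope", rsuffix="_intercept")
            .join(var_wide.add_suffix("_var"))
            .dropna()
        )
        var_block["slope_vs_variability_no_vision_partial"] = st.partial_correlation(
            merged["no_vision_var"],
            merged["no_vision_slope"],
            merged["vision_var"],
            covariate_name="vision endpoint variability",
        )
        var_block["intercept_vs_variability_no_vision_partial"] = st.partial_correlation(
            merged["no_vision_var"],
            merged["no_vision_intercept"],
            merged["vision_var"],
            covariate_name="vision endpoint variability",
        )
        var_block["slope_vs_variability_vision"] = st.correlation(
            merged["vision_var"], merged["vision_slope"], method="kendall"
        )
        var_block["intercept_vs_variability_vision"] = st.correlation(
            merged["vision_var"], merged["vision_intercept"], method="pearson"
        )
    report["endpoint_variability"] = var_block
    return report


# ---------------------------------------------------------------------------
# orchestration

def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> RunManifest:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config.config_hash(), seed=config.seed, started=time.time()
    )
    config.to_yaml(out / "config.yaml")

    datasets = stage_simulate(config)
    trials = pd.concat([d.trials for d in datasets.values()], ignore_index=True)
    for session, dataset in datasets.items():
        dataset.save(out, write_traces=config.write_traces)
    manifest.row_counts["trials"] = len(trials)

    segmentation = stage_segment(datasets, config.thresholds)
    segmentation.to_csv(out / "segmentation.csv", index=False)
    manifest.row_counts["segmentation"] = len(segmentation)

    kept, log = stage_filter(trials, segmentation, config.thresholds)
    kept.to_csv(out / "kept_trials.csv", index=False)
    log.to_csv(out / "rejection_log.csv", index=False)
    with open(out / "rule_counts.json", "w") as fh:
        json.dump(rule_counts(log), fh, indent=1)
    if len(kept) + int((log["rule_fired"] != "none").sum()) != len(trials):
        raise ContractViolation("kept + rejected != administered")
    manifest.row_counts["kept_trials"] = len(kept)
    manifest.row_counts["rejected_trials"] = int((log["rule_fired"] != "none").sum())

    fits, kept_fits, exclusions, norm = stage_fit(kept, config)
    fits.to_csv(out / "fits.csv", index=False)
    exclusions.to_csv(out / "excluded_fits.csv", index=False)
    norm.to_csv(out / "normalized_pse.csv", index=False)
    manifest.row_counts["fits"] = len(fits)
    manifest.row_counts["participants_excluded"] = int(
        fits["participant_id"].nunique() - kept_fits["participant_id"].nunique()
    )

    fracs = st.group_mean_fractions(kept)
    regressions = st.fit_time_regression(norm, fracs)
    regressions.to_csv(out / "time_regressions.csv", index=False)
    variability = participant_endpoint_variability(kept, segmentation)
    # restrict to participants surviving the fit exclusion
    variability = variability[
        variability["participant_id"].isin(kept_fits["participant_id"].unique())
    ]
    variability.to_csv(out / "endpoint_variability.csv", index=False)

    report = stage_analyze(norm, regressions, variability, alpha=config.thresholds.alpha)
    with open(out / "stats_report.json", "w") as fh:
        json.dump(_as_jsonable(report), fh, indent=1)

    manifest.finished = time.time()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest.to_json(), fh, indent=1)
    return manifest
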