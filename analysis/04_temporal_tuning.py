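"""Test the temporal tuning of somatosensory attenuation in each session.

Runs the categorical analysis (trial-group ANOVAs per session, the 4 x 2
group x session ANOVA, FDR-corrected pairwise comparisons) and the
continuous analysis (per-participant OLS of normalized PSE on the group mean
test fraction; slopes and intercepts tested against zero and between
sessions).  Writes results/time_regressions.csv and results/stats_report.json.
"""

import argparse
import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _paths import DEFAULT_SEED, RESULTS, SCRATCH, study_config

import selftouch.stats as st
from selftouch.pipeline import _as_jsonable, participant_endpoint_variability, stage_analyze


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=DEFAULT_SEED)
    args = parser.parse_args()
    cfg = study_config(args.seed)

    kept = pd.read_csv(SCRATCH / "kept_trials.csv")
    seg = pd.read_csv(SCRATCH / "segmentation.csv")
    norm = pd.read_csv(RESULTS / "normalized_pse.csv")

    fracs = st.group_mean_fractions(kept)
    regressions = st.fit_time_regression(norm, fracs)
    regressions.to_csv(RESULTS / "time_regressions.csv", index=False)

    variability = participant_endpoint_variability(kept, seg)
    variability = variability[
        variability["participant_id"].isin(norm["participant_id"].unique())
    ]
    variability.to_csv(RESULTS / "endpoint_variability.csv", index=False)

    report = stage_analyze(norm, regressions, variability, alpha=cfg.thresholds.alpha)
    with open(RESULTS / "stats_report.json", "w") as fh:
        json.dump(_as_jsonable(report), fh, indent=1)

    for session in ("vision", "no_vision"):
        a = report[f"anova_trial_group_{session}"]
        print(
            f"{session}: trial-group ANOVA F({a.df_num:.2f}, {a.df_den:.2f}) = {a.F:.2f}, "
            f"p = {a.p:.4f}, partial eta^2 = {a.partial_eta_sq:.3f}"
        )
    tr = report["time_regressions"]
    for session in ("vision", "no_vision"):
        t = tr[f"slope_vs_zero_{session}"]
        print(
            f"{session}: mean slope {tr[f'mean_slope_{session}']:.3e} N/% "
            f"({t.test_used}, statistic {t.statistic:.2f}, p = {t.p_raw:.4f})"
        )
    cmp_ = tr["slope_vision_vs_no_vision"]
    print(
        f"slopes vision vs no-vision: {cmp_.test_used} statistic {cmp_.statistic:.2f}, "
        f"p = {cmp_.p_raw:.4f}, effect = {cmp_.effect:.2f}"
    )
    icmp = tr["intercept_vision_vs_no_vision"]
    print(
        f"intercepts vision vs no-vision: {icmp.test_used} statistic {icmp.statistic:.2f}, "
        f"p = {icmp.p_raw:.4f}"
    )


if __name__ == "__main__":
    main()
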