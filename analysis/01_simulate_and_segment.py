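"""Simulate the two-session study and segment every reaching movement.

Generates 28 participants x 2 sessions x 336 trials with the linked
population model (steeper attenuation slopes and lower endpoint noise with
vision), then runs the kinematic segmentation: 5-point position smoothing,
3D speed, velocity-threshold onset (5 cm/s held 100 ms), force-threshold
offset (0.2 N), windowed peak velocity and realized test-force fractions.

Writes the per-trial tables to scratch/analysis/ for the downstream stages.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _paths import DEFAULT_SEED, SCRATCH, study_config

from selftouch.pipeline import stage_segment, stage_simulate


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=DEFAULT_SEED)
    args = parser.parse_args()

    cfg = study_config(args.seed)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(SCRATCH / "config.yaml")

    datasets = stage_simulate(cfg)
    trials = pd.concat([d.trials for d in datasets.values()], ignore_index=True)
    trials.to_csv(SCRATCH / "trials.csv", index=False)

    seg = stage_segment(datasets, cfg.thresholds)
    seg.to_csv(SCRATCH / "segmentation.csv", index=False)

    reach = seg[seg["block"] == "reaching"]
    print(f"simulated {len(trials)} trials ({cfg.n_participants} participants x 2 sessions)")
    print(
        "reaching movements: duration %.0f +- %.0f ms, peak velocity %.1f +- %.1f cm/s"
        % (
            1000 * reach["duration"].mean(),
            1000 * reach["duration"].std(),
            reach["peak_velocity"].mean(),
            reach["peak_velocity"].std(),
        )
    )
    by_group = reach.groupby("scheduled_group")["test_fraction"].mean()
    print("mean realized test fraction per scheduled group (%):")
    print(by_group.round(1).to_string())


if __name__ == "__main__":
    main()
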