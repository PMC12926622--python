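"""Apply the five rejection rules and rebin the surviving trials.

Rules fire in order: (a) test force outside [1.85, 2.15] N, (b) movement in
a baseline trial, (c) press-pattern failures, (d) movement-conduct failures,
(e) test force outside the (12.5, 87.5]% timing window.  Kept early/mid/late
trials are rebinned from their realized test fraction.
"""

import argparse
import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _paths import DEFAULT_SEED, RESULTS, SCRATCH, study_config

from selftouch.pipeline import stage_filter
from selftouch.trials import rule_counts


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=DEFAULT_SEED)
    args = parser.parse_args()
    cfg = study_config(args.seed)

    trials = pd.read_csv(SCRATCH / "trials.csv")
    seg = pd.read_csv(SCRATCH / "segmentation.csv")
    kept, log = stage_filter(trials, seg, cfg.thresholds)
    kept.to_csv(SCRATCH / "kept_trials.csv", index=False)
    log.to_csv(SCRATCH / "rejection_log.csv", index=False)

    RESULTS.mkdir(parents=True, exist_ok=True)
    counts = rule_counts(log)
    with open(RESULTS / "rule_counts.json", "w") as fh:
        json.dump(counts, fh, indent=1)

    rejected = len(trials) - counts["none"]
    print(f"administered {len(trials)}, rejected {rejected} ({100*rejected/len(trials):.1f}%)")
    print("per-rule counts:", counts)
    timed = kept[kept["final_group"].isin(("early25", "mid50", "late75"))]
    print(
        f"rebinned {int(timed['rebinned'].sum())} of {len(timed)} timed trials "
        f"({100*timed['rebinned'].mean():.1f}%)"
    )


if __name__ == "__main__":
    main()
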