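"""Fit the psychometric functions and baseline-normalize the PSEs.

One logistic fit per participant x session x trial group (responses pooled
across press locations, comparison forces rebinned to the seven-level grid).
Participants with any poor (McFadden R^2 < 0.2) or non-converged fit are
excluded, mirroring the study's exclusion gate.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _paths import DEFAULT_SEED, RESULTS, SCRATCH, study_config

from selftouch.pipeline import stage_fit


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=DEFAULT_SEED)
    args = parser.parse_args()
    cfg = study_config(args.seed)

    kept = pd.read_csv(SCRATCH / "kept_trials.csv")
    fits, kept_fits, exclusions, norm = stage_fit(kept, cfg)

    RESULTS.mkdir(parents=True, exist_ok=True)
    fits.to_csv(RESULTS / "fits.csv", index=False)
    norm.to_csv(RESULTS / "normalized_pse.csv", index=False)
    exclusions.to_csv(RESULTS / "excluded_fits.csv", index=False)

    ok = fits[fits["converged"]]
    print(f"fitted {len(fits)} cells; median McFadden R^2 = {ok['mcfadden_r2'].median():.2f}")
    n_excl = fits["participant_id"].nunique() - kept_fits["participant_id"].nunique()
    print(f"excluded {n_excl} participant(s) for poor fits; {kept_fits['participant_id'].nunique()} remain")
    means = norm.groupby(["session", "group"])["delta_pse"].mean().unstack()
    print("mean baseline-normalized PSE (N):")
    print(means.round(3).to_string())


if __name__ == "__main__":
    main()
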