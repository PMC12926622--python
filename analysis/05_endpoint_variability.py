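"""Relate reach endpoint variability to the temporal tuning of attenuation.

Endpoint variability is the root-total-variance of the 3D reach endpoints
per target finger, averaged over fingers.  The script compares it between
sessions and correlates it with the no-vision attenuation slopes and
intercepts, partialling out the vision-session variability to isolate the
component attributable to the missing visual input.
"""

import argparse
import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _paths import DEFAULT_SEED, RESULTS

def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=DEFAULT_SEED)
    args = parser.parse_args()

    with open(RESULTS / "stats_report.json") as fh:
        report = json.load(fh)
    ev = report["endpoint_variability"]

    print(
        "endpoint variability: vision %.3f cm, no-vision %.3f cm"
        % (ev["mean_variability_vision"], ev["mean_variability_no_vision"])
    )
    cmp_ = ev["no_vision_vs_vision"]
    print(
        f"no-vision vs vision: {cmp_['test_used']} statistic {cmp_['statistic']:.2f}, "
        f"p = {cmp_['p_raw']:.2e}, effect = {cmp_['effect']:.2f}"
    )
    for key, label in (
        ("slope_vs_variability_no_vision_partial", "slope ~ variability (no vision, vision partialled out)"),
        ("intercept_vs_variability_no_vision_partial", "intercept ~ variability (no vision, vision partialled out)"),
        ("slope_vs_variability_vision", "slope ~ variability (vision)"),
        ("intercept_vs_variability_vision", "intercept ~ variability (vision)"),
    ):
        c = ev[key]
        print(f"{label}: {c['method']} r = {c['coefficient']:.3f}, p = {c['p']:.4f}")


if __name__ == "__main__":
    main()
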