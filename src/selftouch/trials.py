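"""Trial rejection rules and rebinning.

Five rejection rules are applied in a fixed order, and a trial is logged
under the first rule that fires:

(a) the measured test force left the calibration band (< 1.85 N or > 2.15 N);
(b) a baseline trial in which the right hand moved (any speed sample above
    the onset threshold);
(c) a press-pattern failure on a reaching trial: no press on the instructed
    sensor, multiple presses, or a press on both sensors;
(d) a movement-conduct failure: non-continuous movement, motion during the
    comparison force, or a horizontal retreat of more than 5 cm before the
    comparison force;
(e) an early/mid/late trial whose test force fell at <= 12.5% or > 87.5% of
    that trial's own movement duration.

Surviving early/mid/late trials are rebinned from their realized test
fraction into half-open intervals (12.5, 37.5], (37.5, 62.5], (62.5, 87.5];
target trials keep their label.  Measured comparison forces are rebinned to
the nearest intensity of the design grid before psychometric fitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .design import DEFAULT_INTENSITIES

TEST_FORCE_MIN = 1.85  # N
TEST_FORCE_MAX = 2.15  # N
BIN_EDGES = (12.5, 37.5, 62.5, 87.5)  # % of movement duration
BIN_LABELS = ("early25", "mid50", "late75")

RULE_LABELS = (
    "a_test_force",
    "b_baseline_motion",
    "c_press_pattern",
    "d_movement_conduct",
    "e_timing_window",
)


class ContractViolation(RuntimeError):
    """An upstream stage delivered data that violates a pipeline contract."""


@dataclass(frozen=True)
class RejectionParams:
    test_force_min: float = TEST_FORCE_MIN
    test_force_max: float = TEST_FORCE_MAX
    baseline_speed_threshold: float = 5.0  # cm/s, reused onset threshold
    bin_edges: tuple[float, float, float, float] = BIN_EDGES


@dataclass(frozen=True)
class BinnedTrial:
    trial_id: str
    final_group: str
    test_fraction: float
    rebinned: bool


def rebin_trial(
    test_fraction: float,
    scheduled_group: str,
    edges: Sequence[float] = BIN_EDGES,
) -> BinnedTrial:
    """Assign an early/mid/late trial to its realized bin; target bypasses."""
    if scheduled_group == "target":
        return BinnedTrial("", "target", float(test_fraction), False)
    lo, *inner, hi = edges
    if not (lo < test_fraction <= hi):
        raise ContractViolation(
            f"test fraction {test_fraction:.2f}% outside ({lo}, {hi}]: "
            "should have been rejected under rule (e)"
        )
    bounds = list(edges)
    for label, left, right in zip(BIN_LABELS, bounds[:-1], bounds[1:]):
        if left < test_fraction <= right:
            return BinnedTrial(
                "", label, float(test_fraction), label != scheduled_group
            )
    raise AssertionError("unreachable: bins partition the interval")


def rebin_comparison(
    measured: float, intensities: Sequence[float] = DEFAULT_INTENSITIES
) -> float:
    """Nearest design intensity to the measured comparison force.

    Ties (equidistant between two grid values) break toward the lower
    intensity.
    """
    if measured <= 0:
        raise ValueError("measured comparison force must be positive")
    grid = np.asarray(intensities, dtype=float)
    dist = np.abs(grid - measured)
    return float(grid[int(np.argmin(dist))])  # argmin takes the first (lower) tie


def reject_trials(
    trials: pd.DataFrame,
    segmentations: pd.DataFrame,
    params: RejectionParams = RejectionParams(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply rules (a)-(e) and rebin the kept trials.

    Returns ``(kept, log)``: ``kept`` is the trial table restricted to
    surviving trials with ``final_group``, ``test_fraction`` and ``rebinned``
    columns appended; ``log`` has one row per trial with the rule that fired
    (or ``none``) and a human-readable detail.
    """
    seg = segmentations.set_index("trial_id")
    missing = set(trials["trial_id"]) - set(seg.index)
    if missing:
        raise ContractViolation(
            f"{len(missing)} trial(s) lack a segmentation row, e.g. {sorted(missing)[:3]}"
        )

    log_rows = []
    kept_rows = []
    for rec in trials.itertuples(index=False):
        s = seg.loc[rec.trial_id]
        rule, detail = _first_firing_rule(rec, s, params)
        log_rows.append(
            {"trial_id": rec.trial_id, "rule_fired": rule, "detail": detail}
        )
        if rule != "none":
            continue
        row = rec._asdict()
        if rec.block == "reaching" and rec.scheduled_group != "target":
            binned = rebin_trial(float(s["test_fraction"]), rec.scheduled_group, params.bin_edges)
            row["final_group"] = binned.final_group
            row["test_fraction"] = binned.test_fraction
            row["rebinned"] = binned.rebinned
        elif rec.scheduled_group == "target":
            row["final_group"] = "target"
            row["test_fraction"] = float(s["test_fraction"])
            row["rebinned"] = False
        else:
            row["final_group"] = "baseline"
            row["test_fraction"] = np.nan
            row["rebinned"] = False
        kept_rows.append(row)

    kept = pd.DataFrame(kept_rows)
    log = pd.DataFrame(log_rows, columns=["trial_id", "rule_fired", "detail"])
    return kept, log


def _first_firing_rule(rec, s, params: RejectionParams) -> tuple[str, str]:
    f = rec.test_force_measured
    if f < params.test_force_min or f > params.test_force_max:
        return "a_test_force", f"test force {f:.3f} N outside [{params.test_force_min}, {params.test_force_max}]"

    if rec.block == "baseline":
        if s["max_speed"] > params.baseline_speed_threshold:
            return (
                "b_baseline_motion",
                f"max speed {s['max_speed']:.1f} cm/s during baseline trial",
            )
        return "none", ""

    # reaching trials -------------------------------------------------------
    n_own = s["n_presses_instructed"]
    if not np.isfinite(n_own) or n_own == 0:
        return "c_press_pattern", "no press on the instructed sensor"
    if n_own > 1:
        return "c_press_pattern", f"{int(n_own)} presses on the instructed sensor"
    if s["n_presses_other"] > 0:
        return "c_press_pattern", "pressed both sensors"

    if not s["segmentation_ok"]:
        # pressed the sensor but produced no analyzable movement
        return "d_movement_conduct", str(s["segmentation_note"])
    if not s["continuous_movement"]:
        return "d_movement_conduct", "movement not continuous"
    if s["moved_during_comparison"]:
        return "d_movement_conduct", "moved during the comparison force"
    if s["retreat_cm"] > 5.0:
        return (
            "d_movement_conduct",
            f"retreated {s['retreat_cm']:.1f} cm horizontally before the comparison",
        )

    if rec.scheduled_group != "target":
        frac = float(s["test_fraction"])
        lo, hi = params.bin_edges[0], params.bin_edges[-1]
        if frac <= lo or frac > hi:
            return (
                "e_timing_window",
                f"test force at {frac:.1f}% of movement duration",
            )
    return "none", ""


def rule_counts(log: pd.DataFrame) -> dict[str, int]:
    counts = log["rule_fired"].value_counts().to_dict()
    return {rule: int(counts.get(rule, 0)) for rule in (*RULE_LABELS, "none")}
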