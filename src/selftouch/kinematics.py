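"""Kinematic preprocessing and movement segmentation.

Positions are smoothed with a centered 5-point moving average (~21 ms at
240 Hz), 3D speed is the Euclidean norm of the first derivative of the
smoothed positions, movement onset is the first sample at which the speed
exceeds 5 cm/s and stays above it for the next 100 ms, and movement offset is
the first sample at which the instructed finger's sensor force exceeds 0.2 N.
Peak velocity is taken within the first 67% of the movement so the terminal
tap transient is excluded.  Endpoint variability is the root-total-variance
of the 3D reach endpoints per target finger, averaged across fingers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .traces import KinematicTrace

ONSET_SPEED_THRESHOLD = 5.0  # cm/s
ONSET_HOLD_MS = 100.0
OFFSET_FORCE_THRESHOLD = 0.2  # N
PEAK_WINDOW_FRACTION = 0.67
SMOOTHING_WINDOW = 5  # samples


@dataclass
class MovementSegmentation:
    """Per-trial movement summary used by trial filtering and the stats."""

    onset_index: int
    onset_time: float
    offset_time: float
    duration: float
    peak_velocity: float
    endpoint: np.ndarray  # 3D cm relative to the trial-onset position
    test_fraction: float  # % of movement duration at test-force onset

    def validate(self) -> None:
        if not self.onset_time < self.offset_time:
            raise ValueError("onset must precede offset")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


def smooth_array(a: np.ndarray, window: int = SMOOTHING_WINDOW) -> np.ndarray:
    """Centered moving average; edge samples average the in-window samples."""
    a = np.asarray(a, dtype=float)
    if a.shape[0] < window:
        raise ValueError(f"need at least {window} samples to smooth")
    return (
        pd.DataFrame(a)
        .rolling(window=window, center=True, min_periods=1)
        .mean()
        .to_numpy()
        .reshape(a.shape)
    )


def smooth_positions(trace: KinematicTrace, window: int = SMOOTHING_WINDOW) -> KinematicTrace:
    """Return a copy of the trace with smoothed positions; forces untouched."""
    smoothed = smooth_array(trace.position, window)
    return KinematicTrace(
        t=trace.t,
        position=smoothed,
        force_start=trace.force_start,
        force_index=trace.force_index,
        force_ring=trace.force_ring,
        force_probe=trace.force_probe,
        events=dict(trace.events),
        sampling_rate=trace.sampling_rate,
        trace_ref=trace.trace_ref,
        truth=trace.truth,
    )


def compute_speed(trace: KinematicTrace) -> np.ndarray:
    """Per-sample 3D speed (cm/s): central differences, one-sided at ends."""
    dt = np.diff(trace.t)
    period = 1.0 / trace.sampling_rate
    if np.any(np.abs(dt - period) > period):
        raise ValueError("non-uniform timestamps exceed one sample period")
    vel = np.gradient(trace.position, trace.t, axis=0)
    return np.linalg.norm(vel, axis=1)


def detect_onset(
    speed: np.ndarray,
    sampling_rate: float,
    threshold: float = ONSET_SPEED_THRESHOLD,
    hold_ms: float = ONSET_HOLD_MS,
) -> Optional[int]:
    """First index where speed exceeds ``threshold`` for the next ``hold_ms``.

    "Exceeds" is strict, and the sample at the end of the hold window is
    included, so a window of ``hold_samples + 1`` consecutive supra-threshold
    samples is required.  Returns ``None`` when no such index exists (or the
    trace is shorter than the hold window).
    """
    speed = np.asarray(speed, dtype=float)
    hold = int(round(hold_ms / 1000.0 * sampling_rate))
    win = hold + 1
    if speed.size < win:
        return None
    above = (speed > threshold).astype(int)
    # runs of consecutive supra-threshold samples of length >= win
    csum = np.concatenate([[0], np.cumsum(above)])
    window_full = csum[win:] - csum[:-win] == win
    hits = np.flatnonzero(window_full)
    return int(hits[0]) if hits.size else None


def detect_offset(
    force: np.ndarray, threshold: float = OFFSET_FORCE_THRESHOLD
) -> Optional[int]:
    """First sample where the sensor force strictly exceeds ``threshold``."""
    hits = np.flatnonzero(np.asarray(force, dtype=float) > threshold)
    return int(hits[0]) if hits.size else None


def press_segments(
    force: np.ndarray, threshold: float = OFFSET_FORCE_THRESHOLD
) -> list[tuple[int, int]]:
    """Contiguous supra-threshold episodes as (start, stop) index pairs."""
    above = np.asarray(force, dtype=float) > threshold
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    stops = list(np.flatnonzero(edges == -1) + 1)
    if above.size and above[0]:
        starts.insert(0, 0)
    if above.size and above[-1]:
        stops.append(above.size)
    return list(zip(starts, stops))


def movement_metrics(
    trace: KinematicTrace,
    onset_index: int,
    offset_index: int,
    speed: Optional[np.ndarray] = None,
    peak_window_fraction: float = PEAK_WINDOW_FRACTION,
) -> MovementSegmentation:
    """Duration, windowed peak velocity, endpoint and test fraction."""
    if offset_index <= onset_index:
        raise ValueError("movement offset must come after onset")
    if speed is None:
        speed = compute_speed(trace)
    onset_time = float(trace.t[onset_index])
    offset_time = float(trace.t[offset_index])
    duration = offset_time - onset_time
    window_end = onset_time + peak_window_fraction * duration
    in_window = (trace.t >= onset_time) & (trace.t <= window_end)
    peak_velocity = float(np.max(speed[in_window]))
    endpoint = trace.position[offset_index] - trace.position[0]
    test_time = float(trace.t[trace.events["test_on"]])
    seg = MovementSegmentation(
        onset_index=int(onset_index),
        onset_time=onset_time,
        offset_time=offset_time,
        duration=duration,
        peak_velocity=peak_velocity,
        endpoint=np.asarray(endpoint, dtype=float),
        test_fraction=100.0 * (test_time - onset_time) / duration,
    )
    seg.validate()
    return seg


def endpoint_variability(endpoints_by_finger: Mapping[str, np.ndarray]) -> float:
    """Mean over fingers of the 3D endpoint dispersion sqrt(var_x+var_y+var_z).

    Per-axis variances use the n-1 convention.  Fingers with fewer than two
    endpoints are excluded with a warning; an error is raised if no finger has
    enough data.
    """
    dispersions = []
    for finger, pts in endpoints_by_finger.items():
        pts = np.asarray(pts, dtype=float).reshape(-1, 3)
        if pts.shape[0] < 2:
            warnings.warn(
                f"finger {finger!r} has {pts.shape[0]} endpoint(s); excluded",
                stacklevel=2,
            )
            continue
        dispersions.append(float(np.sqrt(np.var(pts, axis=0, ddof=1).sum())))
    if not dispersions:
        raise ValueError("no finger has at least two endpoints")
    return float(np.mean(dispersions))


# ---------------------------------------------------------------------------
# dataset-level segmentation

SEGMENTATION_COLUMNS = (
    "trial_id",
    "participant_id",
    "session",
    "block",
    "scheduled_group",
    "instructed_finger",
    "onset_time",
    "offset_time",
    "duration",
    "peak_velocity",
    "max_speed",
    "endpoint_x",
    "endpoint_y",
    "endpoint_z",
    "test_fraction",
    "n_presses_instructed",
    "n_presses_other",
    "continuous_movement",
    "moved_during_comparison",
    "retreat_cm",
    "segmentation_ok",
    "segmentation_note",
)


def segment_trace(
    trace: KinematicTrace,
    instructed_finger: Optional[str],
    block: str,
    onset_threshold: float = ONSET_SPEED_THRESHOLD,
    onset_hold_ms: float = ONSET_HOLD_MS,
    offset_threshold: float = OFFSET_FORCE_THRESHOLD,
    peak_window_fraction: float = PEAK_WINDOW_FRACTION,
    dip_speed_threshold: float = 1.0,
    dip_max_ms: float = 150.0,
    retreat_threshold_cm: float = 5.0,
) -> dict:
    """Full segmentation of one trial; returns one row of the segmentation table.

    Baseline trials only report the maximum speed (used by the baseline-motion
    rejection rule).  Reaching trials additionally carry the press-pattern and
    movement-conduct features consumed by the trial filter.
    """
    smoothed = smooth_positions(trace)
    speed = compute_speed(smoothed)
    row: dict = {
        "trial_id": trace.trace_ref,
        "block": block,
        "instructed_finger": instructed_finger,
        "max_speed": float(np.max(speed)),
        "segmentation_ok": True,
        "segmentation_note": "",
    }
    for key in SEGMENTATION_COLUMNS:
        row.setdefault(key, np.nan)
    if block == "baseline":
        return row

    onset = detect_onset(speed, trace.sampling_rate, onset_threshold, onset_hold_ms)
    own = trace.force_channel(instructed_finger)
    other = trace.force_channel("ring" if instructed_finger == "index" else "index")
    presses = press_segments(own, offset_threshold)
    row["n_presses_instructed"] = len(presses)
    row["n_presses_other"] = len(press_segments(other, offset_threshold))

    if onset is None or not presses:
        row["segmentation_ok"] = False
        row["segmentation_note"] = (
            "no movement onset" if onset is None else "no sensor press"
        )
        return row
    offset_index = presses[0][0]
    if offset_index <= onset:
        row["segmentation_ok"] = False
        row["segmentation_note"] = "sensor press before movement onset"
        return row

    seg = movement_metrics(
        smoothed, onset, offset_index, speed=speed, peak_window_fraction=peak_window_fraction
    )
    row.update(
        onset_time=seg.onset_time,
        offset_time=seg.offset_time,
        duration=seg.duration,
        peak_velocity=seg.peak_velocity,
        endpoint_x=seg.endpoint[0],
        endpoint_y=seg.endpoint[1],
        endpoint_z=seg.endpoint[2],
        test_fraction=seg.test_fraction,
    )

    # movement-conduct features for rejection rule (d)
    dip_samples = int(round(dip_max_ms / 1000.0 * trace.sampling_rate))
    transport = speed[onset:offset_index]
    below = transport < dip_speed_threshold
    longest = _longest_run(below)
    row["continuous_movement"] = bool(longest <= dip_samples)

    comp_on, comp_off = trace.events["comparison_on"], trace.events["comparison_off"]
    row["moved_during_comparison"] = bool(
        np.any(speed[comp_on : comp_off + 1] > onset_threshold)
    )
    x = smoothed.position[:, 0]
    between = x[offset_index:comp_on]
    row["retreat_cm"] = (
        float(np.max(x[offset_index] - between)) if between.size else 0.0
    )
    return row


def _longest_run(mask: np.ndarray) -> int:
    best = run = 0
    for m in mask:
        run = run + 1 if m else 0
        best = max(best, run)
    return best


def segment_dataset(dataset) -> pd.DataFrame:
    """Segment every trace of a simulated (or loaded) session dataset."""
    rows = []
    trials = dataset.trials
    for rec in trials.itertuples(index=False):
        trace = dataset.traces[rec.trace_ref]
        row = segment_trace(trace, rec.instructed_finger, rec.block)
        row["trial_id"] = rec.trial_id
        row["participant_id"] = rec.participant_id
        row["session"] = rec.session
        row["scheduled_group"] = rec.scheduled_group
        rows.append(row)
    return pd.DataFrame(rows, columns=list(SEGMENTATION_COLUMNS))
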