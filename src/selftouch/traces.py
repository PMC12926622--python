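"""Synthetic kinematic and force traces for single trials.

Reaches are generated from a minimum-jerk transport profile

    s(tau) = 10 tau^3 - 15 tau^4 + 6 tau^5,   tau = (t - t_move) / T

from the start sensor to the instructed finger sensor (reach distance d along
the x axis, a small lateral offset along y distinguishing the two fingers, and
a vertical arc along z), plus a per-trial Gaussian endpoint offset.  The
transport speed peaks at 1.875 d / T midway through the movement.

Force channels reproduce the event structure the segmentation stage relies
on: the start-sensor hold force drops below 0.2 N at movement start, the
instructed finger's sensor shows a brief tap pulse crossing 0.2 N at arrival,
and the probe channel carries the 100 ms test and comparison pulses.

Each simulated trace also records its generative ground truth (movement
window, analytic velocity-threshold crossing, realized test fraction) in
``KinematicTrace.truth`` so recovery tests can compare detector output with
the quantities that generated the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .design import SCHEDULED_FRACTION, SessionDesign, TrialRecord

#: y positions (cm) of the two target sensors relative to the start sensor
FINGER_OFFSET_CM = {"index": 1.0, "ring": -1.0}


@dataclass(frozen=True)
class KinematicsModel:
    """Generator parameters for one participant's reaches in one session."""

    reach_distance: float = 25.0  # cm
    duration_mean: float = 1.0  # s
    duration_sd: float = 0.08  # s
    endpoint_noise_sd: float = 0.1  # cm per axis; 0.1 with vision, 0.4 without
    start_hold_force: float = 1.0  # N held on the start sensor
    tap_force_peak: float = 3.0  # N
    tap_width: float = 0.08  # s, half-sine tap pulse
    reaction_time_mean: float = 0.25  # s from go cue to movement start
    reaction_time_sd: float = 0.03  # s
    arc_height: float = 2.0  # cm, vertical hump of the reach
    position_noise_sd: float = 0.005  # cm, sensor jitter per axis
    target_system_delay: float = 0.02  # s, tap-triggered stimulus latency
    onset_speed_threshold: float = 5.0  # cm/s, defines the movement phase

    def validate(self) -> None:
        if self.reach_distance <= 0 or self.duration_mean <= 0:
            raise ValueError("reach_distance and duration_mean must be positive")
        if self.endpoint_noise_sd < 0 or self.duration_sd < 0:
            raise ValueError("noise parameters must be non-negative")
        if not (0 < self.tap_force_peak):
            raise ValueError("tap_force_peak must be positive")


@dataclass
class KinematicTrace:
    """Uniformly sampled 3D position and four force channels for one trial."""

    t: np.ndarray  # s, uniform at sampling_rate
    position: np.ndarray  # (n, 3) cm: x toward the left hand, y lateral, z up
    force_start: np.ndarray  # N, start-position sensor
    force_index: np.ndarray  # N, sensor above the left index finger
    force_ring: np.ndarray  # N, sensor above the left ring finger
    force_probe: np.ndarray  # N, probe delivering test/comparison forces
    events: dict[str, int]  # labelled sample indices
    sampling_rate: float
    trace_ref: str = ""
    truth: dict = field(default_factory=dict)

    def validate(self) -> None:
        n = len(self.t)
        if self.position.shape != (n, 3):
            raise ValueError("position must be (n, 3)")
        dt = np.diff(self.t)
        if not np.allclose(dt, 1.0 / self.sampling_rate, rtol=1e-6):
            raise ValueError("trace must be uniformly sampled")
        for name in ("force_start", "force_index", "force_ring", "force_probe"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} must be non-negative")
        idx = [self.events[k] for k in sorted(self.events, key=self.events.get)]
        if any(j < 0 or j >= n for j in idx):
            raise ValueError("event indices must lie within the trace")
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("event indices must be strictly increasing")

    def force_channel(self, finger: str) -> np.ndarray:
        return self.force_index if finger == "index" else self.force_ring


def minimum_jerk_progress(tau: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk position profile on tau in [0, 1]."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def minimum_jerk_rate(tau: np.ndarray) -> np.ndarray:
    """d s / d tau of the minimum-jerk profile (peaks at 1.875 at tau=0.5)."""
    tau = np.clip(tau, 0.0, 1.0)
    return 30 * tau**2 - 60 * tau**3 + 30 * tau**4


def _speed_profile(tau: float, T: float, straight_len: float, arc_height: float) -> float:
    """Continuous 3D speed (cm/s) of the generated reach at phase tau."""
    s = minimum_jerk_progress(np.array(tau))[()]
    ds = minimum_jerk_rate(np.array(tau))[()] / T
    lateral = 4.0 * arc_height * (1.0 - 2.0 * s)
    return float(ds * math.hypot(straight_len, lateral))


def speed_threshold_crossing(
    T: float, straight_len: float, arc_height: float, threshold: float
) -> float:
    """Time after movement start at which 3D speed first exceeds ``threshold``.

    Solved on the continuous generative speed profile; used both to place the
    observer's movement phase and as the analytic oracle for onset detection.
    """
    peak = _speed_profile(0.5, T, straight_len, arc_height)
    if peak <= threshold:
        raise ValueError("reach never exceeds the speed threshold")
    f = lambda tau: _speed_profile(tau, T, straight_len, arc_height) - threshold
    return T * brentq(f, 1e-9, 0.5, xtol=1e-12)


def _half_sine_pulse(
    t: np.ndarray, onset: float, width: float, peak: float
) -> np.ndarray:
    u = (t - onset) / width
    pulse = np.where((u >= 0) & (u <= 1), np.sin(np.pi * np.clip(u, 0, 1)), 0.0)
    return peak * pulse


def simulate_kinematics(
    stub: TrialRecord,
    model: KinematicsModel,
    history: Sequence[float],
    rng: np.random.Generator,
    design: Optional[SessionDesign] = None,
) -> KinematicTrace:
    """Simulate one trial's trace.

    ``history`` holds the online movement durations (start-sensor release to
    tap) of the most recent reaching trials; the test force of early/mid/late
    trials is scheduled at 25/50/75% of the mean of the last five.  An empty
    history falls back to ``model.duration_mean``.  Baseline trials produce a
    static hold trace with the test force 100 ms after trial onset.
    """
    model.validate()
    design = design or SessionDesign()
    fs = design.sampling_rate
    dt = 1.0 / fs
    pulse = design.force_pulse_duration_ms / 1000.0
    comp_delay = design.comparison_delay_ms / 1000.0

    if stub.block == "baseline":
        test_time = design.baseline_test_onset_s
        comp_time = test_time + comp_delay
        t_end = comp_time + pulse + 0.2
        n = int(round(t_end * fs)) + 1
        t = np.arange(n) * dt
        position = rng.normal(0.0, model.position_noise_sd, size=(n, 3))
        force_start = np.full(n, model.start_hold_force) + rng.normal(0, 0.005, n)
        force_index = np.abs(rng.normal(0, 0.003, n))
        force_ring = np.abs(rng.normal(0, 0.003, n))
        truth = {"movement_start": None, "duration": None, "realized_fraction": None,
                 "online_duration": None}
    else:
        if stub.instructed_finger is None:
            raise ValueError("reaching trial requires an instructed finger")
        T = float(
            np.clip(
                rng.normal(model.duration_mean, model.duration_sd),
                0.5 * model.duration_mean,
                1.6 * model.duration_mean,
            )
        )
        reaction = float(
            max(0.05, rng.normal(model.reaction_time_mean, model.reaction_time_sd))
        )
        recent = list(history)[-5:]
        mean_recent = float(np.mean(recent)) if recent else model.duration_mean

        t_move = reaction
        t_arrive = t_move + T

        # endpoint offset: direction-preserving, norm clipped at 3 sd
        offset = rng.normal(0.0, model.endpoint_noise_sd, size=3)
        if model.endpoint_noise_sd > 0:
            norm = float(np.linalg.norm(offset))
            cap = 3.0 * model.endpoint_noise_sd
            if norm > cap:
                offset *= cap / norm
        target = np.array(
            [model.reach_distance, FINGER_OFFSET_CM[stub.instructed_finger], 0.0]
        )
        endpoint = target + offset
        straight_len = float(np.linalg.norm(endpoint))

        if stub.scheduled_group == "target":
            # tap-triggered: crossing of the 0.2 N tap threshold plus latency
            tap_delay = (model.tap_width / math.pi) * math.asin(
                min(1.0, 0.2 / model.tap_force_peak)
            )
            test_time = t_arrive + tap_delay + model.target_system_delay
        else:
            frac = SCHEDULED_FRACTION[stub.scheduled_group] / 100.0
            test_time = t_move + frac * mean_recent
        comp_time = test_time + comp_delay
        t_end = comp_time + pulse + 0.2
        n = int(round(t_end * fs)) + 1
        t = np.arange(n) * dt

        tau = (t - t_move) / T
        s = minimum_jerk_progress(tau)
        position = np.outer(s, endpoint)
        position[:, 2] += model.arc_height * 4.0 * s * (1.0 - s)
        position += rng.normal(0.0, model.position_noise_sd, size=(n, 3))

        force_start = np.where(t < t_move, model.start_hold_force, 0.0)
        force_start = np.abs(force_start + rng.normal(0, 0.005, n))
        tap = _half_sine_pulse(t, t_arrive, model.tap_width, model.tap_force_peak)
        noise_a = np.abs(rng.normal(0, 0.003, n))
        noise_b = np.abs(rng.normal(0, 0.003, n))
        if stub.instructed_finger == "index":
            force_index, force_ring = tap + noise_a, noise_b
        else:
            force_index, force_ring = noise_a, tap + noise_b

        # ground truth of the movement phase, on the analysis's definition:
        # velocity-threshold onset to tap-force offset
        t5 = speed_threshold_crossing(
            T, straight_len, model.arc_height, model.onset_speed_threshold
        )
        tap_delay = (model.tap_width / math.pi) * math.asin(
            min(1.0, 0.2 / model.tap_force_peak)
        )
        onset_true = t_move + t5
        offset_true = t_arrive + tap_delay
        duration_true = offset_true - onset_true
        truth = {
            "movement_start": t_move,
            "movement_duration": T,
            "online_duration": T,  # release-to-tap, as timed online
            "onset_true": onset_true,
            "offset_true": offset_true,
            "duration": duration_true,
            "realized_fraction": 100.0 * (test_time - onset_true) / duration_true,
            "endpoint": endpoint,
        }

    test_amp = stub.test_force_measured
    comp_amp = stub.comparison_measured
    if test_amp is None or comp_amp is None:
        raise ValueError("stub must carry measured test and comparison forces")
    force_probe = (
        0.1
        + _half_sine_pulse(t, test_time, pulse, test_amp - 0.1)
        + _half_sine_pulse(t, comp_time, pulse, comp_amp - 0.1)
    )

    events = {
        "trial_onset": 0,
        "test_on": int(np.searchsorted(t, test_time)),
        "test_off": int(np.searchsorted(t, test_time + pulse)),
        "comparison_on": int(np.searchsorted(t, comp_time)),
        "comparison_off": int(np.searchsorted(t, comp_time + pulse)),
    }
    trace = KinematicTrace(
        t=t,
        position=position,
        force_start=force_start,
        force_index=force_index,
        force_ring=force_ring,
        force_probe=force_probe,
        events=events,
        sampling_rate=fs,
        trace_ref=stub.trial_id,
        truth=truth,
    )
    trace.validate()
    return trace
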