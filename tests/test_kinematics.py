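import numpy as np
import pytest
from hypothesis import given, settings, strategies as st_h

from conftest import noise_free_trace
from selftouch.kinematics import (
    compute_speed,
    detect_offset,
    detect_onset,
    endpoint_variability,
    movement_metrics,
    press_segments,
    smooth_array,
    smooth_positions,
)
from selftouch.traces import KinematicTrace


def trace_from_position(pos: np.ndarray, fs: float = 240.0, events=None) -> KinematicTrace:
    n = len(pos)
    zeros = np.zeros(n)
    return KinematicTrace(
        t=np.arange(n) / fs,
        position=np.asarray(pos, dtype=float),
        force_start=zeros,
        force_index=zeros,
        force_ring=zeros,
        force_probe=zeros,
        events=events or {"trial_onset": 0, "test_on": n // 2},
        sampling_rate=fs,
        trace_ref="synthetic",
    )


class TestSmoothing:
    def test_constant_signal_unchanged(self):
        a = np.full((50, 3), 7.0)
        assert smooth_array(a) == pytest.approx(a)

    def test_linear_ramp_interior_unchanged(self):
        a = np.arange(50, dtype=float)[:, None] * np.array([1.0, -2.0, 0.5])
        sm = smooth_array(a)
        assert sm[2:-2] == pytest.approx(a[2:-2])

    def test_impulse_spreads_to_plateau(self):
        # direct convolution oracle: impulse of 5 -> plateau of 1 over 5 samples
        a = np.zeros(41)
        a[20] = 5.0
        sm = smooth_array(a)
        expected = np.convolve(a, np.ones(5) / 5, mode="same")
        assert sm == pytest.approx(expected)
        assert sm[18:23] == pytest.approx(np.ones(5))

    def test_edges_average_available_samples(self):
        a = np.arange(10, dtype=float)
        sm = smooth_array(a)
        assert sm[0] == pytest.approx(np.mean(a[:3]))
        assert sm[1] == pytest.approx(np.mean(a[:4]))

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            smooth_array(np.zeros(4))

    def test_forces_untouched(self):
        trace = noise_free_trace()
        sm = smooth_positions(trace)
        assert sm.force_probe is trace.force_probe


class TestSpeed:
    def test_stationary_trace_has_zero_speed(self):
        trace = trace_from_position(np.full((30, 3), 2.0))
        assert compute_speed(trace) == pytest.approx(np.zeros(30))

    def test_affine_motion_exact_everywhere(self):
        fs = 240.0
        t = np.arange(60) / fs
        pos = np.column_stack([10.0 * t, np.zeros_like(t), np.zeros_like(t)])
        assert compute_speed(trace_from_position(pos)) == pytest.approx(np.full(60, 10.0))

    def test_nonuniform_timestamps_rejected(self):
        trace = trace_from_position(np.zeros((30, 3)))
        trace.t = trace.t.copy()
        trace.t[10] += 0.02
        with pytest.raises(ValueError):
            compute_speed(trace)


def brute_force_onset(speed, hold_samples):
    """Reference scan: first t with speed > threshold on every sample of [t, t+hold]."""
    n = len(speed)
    for t in range(n - hold_samples):
        if all(speed[t + j] > 5.0 for j in range(hold_samples + 1)):
            return t
    return None


class TestOnsetDetection:
    def test_all_zero_speed_gives_none(self):
        assert detect_onset(np.zeros(500), 240.0) is None

    def test_step_function_onset_at_step(self):
        speed = np.concatenate([np.zeros(100), np.full(200, 10.0)])
        assert detect_onset(speed, 240.0) == 100

    def test_short_spike_skipped_sustained_rise_found(self):
        # 42 ms (10-sample) spike at 50 is shorter than the 100 ms hold
        speed = np.zeros(400)
        speed[50:60] = 10.0
        speed[200:] = 10.0
        assert detect_onset(speed, 240.0) == 200

    def test_trace_shorter_than_hold_gives_none(self):
        assert detect_onset(np.full(10, 99.0), 240.0) is None

    def test_boundary_sample_must_exceed_threshold(self):
        # 24 supra-threshold samples + sub-threshold boundary sample: no onset
        speed = np.zeros(200)
        speed[100:124] = 10.0
        assert detect_onset(speed, 240.0) is None
        speed[124] = 10.0
        assert detect_onset(speed, 240.0) == 100

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st_h.lists(st_h.sampled_from([0.0, 4.9, 5.1, 20.0]), min_size=30, max_size=120))
    def test_matches_brute_force_scan(self, speeds):
        speed = np.array(speeds)
        assert detect_onset(speed, 240.0) == brute_force_onset(speed, 24)

    def test_invariant_to_appending_samples(self):
        speed = np.concatenate([np.zeros(50), np.full(100, 8.0)])
        onset = detect_onset(speed, 240.0)
        extended = np.concatenate([speed, np.zeros(300)])
        assert detect_onset(extended, 240.0) == onset


class TestOffsetDetection:
    def test_subthreshold_force_gives_none(self):
        assert detect_offset(np.full(100, 0.1)) is None

    def test_threshold_is_strict(self):
        force = np.full(50, 0.2)
        assert detect_offset(force) is None
        force[30] = 0.2001
        assert detect_offset(force) == 30

    def test_two_pulses_first_crossing_and_multipress_flag(self):
        force = np.zeros(200)
        force[40:60] = 1.0
        force[120:140] = 1.0
        assert detect_offset(force) == 40
        assert len(press_segments(force)) == 2


class TestMovementMetrics:
    def test_peak_velocity_excludes_late_tap(self):
        # transport at 10 cm/s then a faster tap spike after 67% of the movement
        fs = 240.0
        n = 240
        t = np.arange(n) / fs
        x = 10.0 * t
        x[200:] += np.linspace(0, 3, 40)  # fast spike near the end
        trace = trace_from_position(
            np.column_stack([x, np.zeros(n), np.zeros(n)]),
            events={"trial_onset": 0, "test_on": 100},
        )
        speed = compute_speed(trace)
        seg = movement_metrics(trace, onset_index=0, offset_index=230, speed=speed)
        assert seg.peak_velocity < speed.max()
        assert seg.peak_velocity == pytest.approx(10.0, rel=0.05)

    def test_test_fraction_boundaries(self):
        trace = trace_from_position(np.zeros((200, 3)) + np.arange(200)[:, None])
        trace.events["test_on"] = 150
        seg = movement_metrics(trace, onset_index=50, offset_index=150)
        assert seg.test_fraction == pytest.approx(100.0)
        trace.events["test_on"] = 50
        seg = movement_metrics(trace, onset_index=50, offset_index=150)
        assert seg.test_fraction == pytest.approx(0.0)

    def test_offset_before_onset_rejected(self):
        trace = trace_from_position(np.zeros((100, 3)))
        with pytest.raises(ValueError):
            movement_metrics(trace, onset_index=50, offset_index=40)

    def test_noise_free_reach_onset_and_duration_match_truth(self):
        from selftouch.kinematics import detect_onset as onset_fn

        trace = noise_free_trace(T=1.0)
        speed = compute_speed(smooth_positions(trace))
        onset = onset_fn(speed, trace.sampling_rate)
        assert onset is not None
        dt = 1.0 / trace.sampling_rate
        assert abs(trace.t[onset] - trace.truth["onset_true"]) <= 1.5 * dt
        offset = detect_offset(trace.force_index)
        duration = trace.t[offset] - trace.t[onset]
        assert abs(duration - trace.truth["duration"]) <= 2.5 * dt


class TestEndpointVariability:
    def test_identical_endpoints_give_zero(self):
        pts = np.tile([1.0, 2.0, 3.0], (10, 1))
        assert endpoint_variability({"index": pts, "ring": pts}) == 0.0

    def test_hand_computed_dispersion(self):
        # x = +-1 cm, n-1 variance 2 -> dispersion sqrt(2)
        pts = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        assert endpoint_variability({"index": pts}) == pytest.approx(np.sqrt(2.0))

    def test_mean_of_per_finger_dispersions(self):
        f1 = np.array([[0.0, 0, 0], [np.sqrt(2.0), 0, 0]])  # dispersion 1
        f2 = np.array([[0.0, 0, 0], [3 * np.sqrt(2.0), 0, 0]])  # dispersion 3
        assert endpoint_variability({"index": f1, "ring": f2}) == pytest.approx(2.0)

    def test_single_endpoint_finger_excluded_with_warning(self):
        pts = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        with pytest.warns(UserWarning):
            v = endpoint_variability({"index": pts, "ring": pts[:1]})
        assert v == pytest.approx(np.sqrt(2.0))

    def test_both_fingers_short_is_an_error(self):
        with pytest.warns(UserWarning), pytest.raises(ValueError):
            endpoint_variability({"index": np.zeros((1, 3))})

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st_h.integers(0, 10_000))
    def test_translation_and_axis_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        pts = {f: rng.normal(size=(6, 3)) for f in ("index", "ring")}
        base = endpoint_variability(pts)
        shift = rng.normal(size=3)
        shifted = {f: p + shift for f, p in pts.items()}
        assert endpoint_variability(shifted) == pytest.approx(base)
        perm = rng.permutation(3)
        permuted = {f: p[:, perm] for f, p in pts.items()}
        assert endpoint_variability(permuted) == pytest.approx(base)
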