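"""Session design and trial scheduling for the two-block force-discrimination task.

A session consists of a *baseline* block, in which both forces are delivered
with the hands at rest, and a *reaching* block, in which the 2 N test force is
delivered during a reach of the right hand towards a force sensor above the
left index or ring finger.  Reaching trials belong to one of four groups
defined by when the test force is scheduled: at 25%, 50% or 75% of the recent
average movement time, or synchronously with the terminal tap (*target*).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

DEFAULT_INTENSITIES: tuple[float, ...] = (1.0, 1.5, 1.75, 2.0, 2.25, 2.5, 3.0)
REACHING_GROUPS: tuple[str, ...] = ("early25", "mid50", "late75", "target")
FINGERS: tuple[str, ...] = ("index", "ring")

#: nominal test-force delivery point, as % of the recent mean movement time
SCHEDULED_FRACTION: dict[str, float] = {"early25": 25.0, "mid50": 50.0, "late75": 75.0}

#: column order of the per-trial table (the package's CSV interchange format)
TRIAL_COLUMNS: tuple[str, ...] = (
    "trial_id",
    "participant_id",
    "session",
    "block",
    "scheduled_group",
    "instructed_finger",
    "stimulated_finger",
    "test_force_measured",
    "comparison_nominal",
    "comparison_measured",
    "test_onset",
    "response_comparison_stronger",
    "trace_ref",
)


class DesignError(ValueError):
    """Raised when a session design violates one of its balance constraints."""


@dataclass(frozen=True)
class SessionDesign:
    """Trial-count structure and timing constants of one experimental session.

    Defaults reproduce the study design: 7 comparison intensities x 8
    baseline repetitions = 56 baseline trials, and 7 x 10 x 4 groups = 280
    reaching trials (70 per group, 35 per instructed finger per group),
    336 trials in total.
    """

    comparison_intensities: tuple[float, ...] = DEFAULT_INTENSITIES
    baseline_reps_per_intensity: int = 8
    reaching_reps_per_intensity_per_group: int = 10
    trial_groups: tuple[str, ...] = REACHING_GROUPS
    fingers: tuple[str, ...] = FINGERS
    test_force_nominal: float = 2.0  # N
    sampling_rate: float = 240.0  # Hz
    reach_distance: float = 25.0  # cm
    force_pulse_duration_ms: float = 100.0
    comparison_delay_ms: float = 1200.0
    baseline_test_onset_s: float = 0.1  # test force 100 ms after trial onset

    def validate(self) -> None:
        ints = np.asarray(self.comparison_intensities, dtype=float)
        if ints.size < 1 or np.any(np.diff(ints) <= 0):
            raise DesignError("comparison_intensities must be strictly increasing")
        if np.any(ints <= 0):
            raise DesignError("comparison_intensities must be positive forces")
        if self.baseline_reps_per_intensity < 1:
            raise DesignError("baseline_reps_per_intensity must be >= 1")
        if self.reaching_reps_per_intensity_per_group < 1:
            raise DesignError("reaching_reps_per_intensity_per_group must be >= 1")
        if len(self.fingers) not in (1, 2):
            raise DesignError("one or two instructed fingers are required")
        per_group = self.reaching_reps_per_intensity_per_group * len(
            self.comparison_intensities
        )
        if len(self.fingers) == 2 and per_group % 2 != 0:
            raise DesignError(
                "instructed-finger counts cannot be balanced: "
                f"{per_group} reaching trials per group is odd"
            )
        if self.sampling_rate <= 0:
            raise DesignError("sampling_rate must be positive")
        if self.test_force_nominal <= 0:
            raise DesignError("test_force_nominal must be positive")

    @property
    def n_baseline(self) -> int:
        return len(self.comparison_intensities) * self.baseline_reps_per_intensity

    @property
    def n_reaching(self) -> int:
        return (
            len(self.comparison_intensities)
            * self.reaching_reps_per_intensity_per_group
            * len(self.trial_groups)
        )

    @property
    def n_trials(self) -> int:
        return self.n_baseline + self.n_reaching

    def with_(self, **kwargs) -> "SessionDesign":
        return replace(self, **kwargs)


@dataclass
class TrialRecord:
    """One two-interval force-discrimination trial.

    ``response_comparison_stronger`` codes the binary judgement: 1 when the
    second (comparison) force was reported stronger than the first (test)
    force, 0 otherwise.  Fields that are only known after simulation or
    measurement (forces, onset, response) start as ``None``.
    """

    trial_id: str
    participant_id: str
    session: str
    block: str  # {"baseline", "reaching"}
    scheduled_group: str  # {"baseline", "early25", "mid50", "late75", "target"}
    instructed_finger: Optional[str]  # None for baseline trials
    stimulated_finger: str
    comparison_nominal: float
    test_force_measured: Optional[float] = None
    comparison_measured: Optional[float] = None
    test_onset: Optional[float] = None  # s from trial onset
    response_comparison_stronger: Optional[int] = None
    trace_ref: Optional[str] = None


def _balanced_fingers(design: SessionDesign, n: int) -> list[str]:
    """A length-``n`` list with the instructed fingers in equal counts."""
    if len(design.fingers) == 1:
        return [design.fingers[0]] * n
    return list(design.fingers) * (n // 2)


def generate_schedule(
    design: SessionDesign,
    seed: int,
    participant_id: str = "P00",
    session: str = "vision",
    stimulated_finger: str = "index",
    block_order: Sequence[str] = ("baseline", "reaching"),
) -> list[TrialRecord]:
    """Build the randomized trial order for one session.

    Trial counts per block / group / intensity / finger follow the design
    exactly; ordering is randomized independently within each block and is
    reproducible under ``seed``.
    """
    design.validate()
    if sorted(block_order) != ["baseline", "reaching"]:
        raise DesignError("block_order must be a permutation of (baseline, reaching)")
    rng = np.random.default_rng(seed)

    baseline: list[tuple] = []
    for intensity in design.comparison_intensities:
        for _ in range(design.baseline_reps_per_intensity):
            baseline.append(("baseline", "baseline", None, intensity))

    reaching: list[tuple] = []
    for group in design.trial_groups:
        cells = [
            intensity
            for intensity in design.comparison_intensities
            for _ in range(design.reaching_reps_per_intensity_per_group)
        ]
        fingers = _balanced_fingers(design, len(cells))
        # pair intensities with fingers before shuffling so each group is
        # exactly half index / half ring
        for intensity, finger in zip(cells, fingers):
            reaching.append(("reaching", group, finger, intensity))

    blocks = {"baseline": baseline, "reaching": reaching}
    stubs: list[TrialRecord] = []
    for block_name in block_order:
        rows = blocks[block_name]
        order = rng.permutation(len(rows))
        for j in order:
            block, group, finger, intensity = rows[j]
            idx = len(stubs)
            stubs.append(
                TrialRecord(
                    trial_id=f"{participant_id}_{session}_t{idx:04d}",
                    participant_id=participant_id,
                    session=session,
                    block=block,
                    scheduled_group=group,
                    instructed_finger=finger,
                    stimulated_finger=stimulated_finger,
                    comparison_nominal=float(intensity),
                )
            )
    return stubs


def trials_to_frame(stubs: Sequence[TrialRecord]) -> pd.DataFrame:
    """Convert trial records to the canonical per-trial table."""
    rows = []
    for s in stubs:
        rows.append(
            {
                "trial_id": s.trial_id,
                "participant_id": s.participant_id,
                "session": s.session,
                "block": s.block,
                "scheduled_group": s.scheduled_group,
                "instructed_finger": s.instructed_finger,
                "stimulated_finger": s.stimulated_finger,
                "test_force_measured": s.test_force_measured,
                "comparison_nominal": s.comparison_nominal,
                "comparison_measured": s.comparison_measured,
                "test_onset": s.test_onset,
                "response_comparison_stronger": s.response_comparison_stronger,
                "trace_ref": s.trace_ref,
            }
        )
    return pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))
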