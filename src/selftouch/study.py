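"""Whole-study simulation: schedules, traces, and observer responses.

``simulate_study`` assembles one full session per participant: it draws the
randomized schedule, simulates each reaching trial's trace sequentially so the
online test-force scheduling can use the running mean of the last five
movement durations, and draws each 2AFC response from the participant's
observer model at the trial's realized movement fraction.  Ground-truth
generator parameters are kept alongside the data for recovery tests.

Randomness is split per (study seed, participant, trial) through a
counter-based ``SeedSequence`` scheme, so regenerating any single trial is
reproducible independently of the rest of the study.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .design import SessionDesign, TrialRecord, generate_schedule, trials_to_frame
from .observer import ObserverModel, simulate_response
from .traces import KinematicsModel, KinematicTrace, simulate_kinematics

#: measurement noise (N) of the delivered test and comparison forces
TEST_FORCE_SD = 0.05
COMPARISON_FORCE_SD = 0.05


@dataclass
class SessionDataset:
    """One simulated session: trial table, traces, and generative truth."""

    session: str
    design: SessionDesign
    trials: pd.DataFrame
    traces: dict[str, KinematicTrace]
    ground_truth: dict

    def save(self, out_dir: str | Path, write_traces: bool = False) -> None:
        out = Path(out_dir)
        try:
            out.mkdir(parents=True, exist_ok=True)
            self.trials.to_csv(out / f"trials_{self.session}.csv", index=False)
            with open(out / f"ground_truth_{self.session}.json", "w") as fh:
                json.dump(self.ground_truth, fh, indent=1, default=_jsonable)
            if write_traces:
                tdir = out / "traces" / self.session
                tdir.mkdir(parents=True, exist_ok=True)
                for ref, trace in self.traces.items():
                    save_trace(trace, tdir / ref)
        except OSError as err:
            raise OSError(f"failed writing session dataset under {out}: {err}") from err


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def save_trace(trace: KinematicTrace, stem: Path) -> None:
    df = pd.DataFrame(
        {
            "t": trace.t,
            "x": trace.position[:, 0],
            "y": trace.position[:, 1],
            "z": trace.position[:, 2],
            "f_start": trace.force_start,
            "f_index": trace.force_index,
            "f_ring": trace.force_ring,
            "f_probe": trace.force_probe,
        }
    )
    df.to_csv(stem.with_suffix(".csv"), index=False)
    with open(stem.with_suffix(".events.json"), "w") as fh:
        json.dump(
            {"events": trace.events, "sampling_rate": trace.sampling_rate}, fh
        )


def load_trace(stem: Path) -> KinematicTrace:
    df = pd.read_csv(stem.with_suffix(".csv"))
    with open(stem.with_suffix(".events.json")) as fh:
        meta = json.load(fh)
    return KinematicTrace(
        t=df["t"].to_numpy(),
        position=df[["x", "y", "z"]].to_numpy(),
        force_start=df["f_start"].to_numpy(),
        force_index=df["f_index"].to_numpy(),
        force_ring=df["f_ring"].to_numpy(),
        force_probe=df["f_probe"].to_numpy(),
        events={k: int(v) for k, v in meta["events"].items()},
        sampling_rate=float(meta["sampling_rate"]),
        trace_ref=stem.name,
    )


def _trial_rng(
    seed: int, session: str, participant_index: int, trial_index: int
) -> np.random.Generator:
    session_key = zlib.crc32(session.encode())
    return np.random.default_rng(
        np.random.SeedSequence([seed, session_key, participant_index, trial_index])
    )


def simulate_participant_session(
    design: SessionDesign,
    observer: ObserverModel,
    kinematics: KinematicsModel,
    seed: int,
    participant_index: int,
    participant_id: str,
    stimulated_finger: str = "index",
    keep_traces: bool = True,
) -> tuple[list[TrialRecord], dict[str, KinematicTrace]]:
    schedule_rng = _trial_rng(seed, observer.session, participant_index, 0)
    stubs = generate_schedule(
        design,
        seed=int(schedule_rng.integers(2**31)),
        participant_id=participant_id,
        session=observer.session,
        stimulated_finger=stimulated_finger,
    )
    traces: dict[str, KinematicTrace] = {}
    history: list[float] = []
    for j, stub in enumerate(stubs):
        rng = _trial_rng(seed, observer.session, participant_index, j + 1)
        stub.test_force_measured = float(
            rng.normal(design.test_force_nominal, TEST_FORCE_SD)
        )
        stub.comparison_measured = float(
            max(0.1, rng.normal(stub.comparison_nominal, COMPARISON_FORCE_SD))
        )
        trace = simulate_kinematics(stub, kinematics, history, rng, design)
        stub.test_onset = float(trace.t[trace.events["test_on"]])
        if stub.block == "reaching":
            history.append(trace.truth["online_duration"])
            fraction = float(np.clip(trace.truth["realized_fraction"], 0.0, 120.0))
        else:
            fraction = None
        stub.response_comparison_stronger = simulate_response(
            stub.comparison_measured, observer, fraction, rng
        )
        stub.trace_ref = trace.trace_ref
        if keep_traces:
            traces[trace.trace_ref] = trace
    return stubs, traces


def simulate_study(
    design: SessionDesign,
    observers: Mapping[str, ObserverModel],
    kinematics: Mapping[str, KinematicsModel],
    seed: int,
    stimulated_fingers: Optional[Mapping[str, str]] = None,
    out_dir: Optional[str | Path] = None,
    write_traces: bool = False,
) -> SessionDataset:
    """Simulate one session for every participant in ``observers``.

    All observers must share the same session label.  Returns the dataset in
    memory; pass ``out_dir`` to also write the trial table, ground-truth
    metadata and (optionally) the per-trial trace files.
    """
    sessions = {obs.session for obs in observers.values()}
    if len(sessions) != 1:
        raise ValueError("all observers in one study call must share a session label")
    session = sessions.pop()
    if set(observers) != set(kinematics):
        raise ValueError("observers and kinematics must cover the same participants")

    all_stubs: list[TrialRecord] = []
    traces: dict[str, KinematicTrace] = {}
    truth: dict = {"seed": seed, "session": session, "participants": {}}
    for pidx, pid in enumerate(sorted(observers)):
        finger = (
            stimulated_fingers[pid]
            if stimulated_fingers is not None
            else ("index" if pidx % 2 == 0 else "ring")
        )
        stubs, ptraces = simulate_participant_session(
            design,
            observers[pid],
            kinematics[pid],
            seed=seed,
            participant_index=pidx + 1,
            participant_id=pid,
            stimulated_finger=finger,
        )
        all_stubs.extend(stubs)
        traces.update(ptraces)
        truth["participants"][pid] = {
            "observer": asdict(observers[pid]),
            "kinematics": asdict(kinematics[pid]),
            "stimulated_finger": finger,
        }

    dataset = SessionDataset(
        session=session,
        design=design,
        trials=trials_to_frame(all_stubs),
        traces=traces,
        ground_truth=truth,
    )
    if out_dir is not None:
        dataset.save(out_dir, write_traces=write_traces)
    return dataset
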