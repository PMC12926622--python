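import numpy as np
import pandas as pd
import pytest

from selftouch.config import PipelineConfig
from selftouch.design import SessionDesign, TrialRecord
from selftouch.pipeline import stage_filter, stage_segment, stage_simulate
from selftouch.traces import KinematicsModel, simulate_kinematics


def make_stub(
    block: str = "reaching",
    group: str = "mid50",
    finger: str = "index",
    test_force: float = 2.0,
    comparison: float = 2.25,
    trial_id: str = "T0",
) -> TrialRecord:
    return TrialRecord(
        trial_id=trial_id,
        participant_id="P00",
        session="vision",
        block=block,
        scheduled_group=group,
        instructed_finger=None if block == "baseline" else finger,
        stimulated_finger="index",
        comparison_nominal=comparison,
        test_force_measured=test_force,
        comparison_measured=comparison,
    )


def noise_free_model(**kwargs) -> KinematicsModel:
    defaults = dict(
        duration_sd=0.0,
        endpoint_noise_sd=0.0,
        position_noise_sd=0.0,
        reaction_time_sd=0.0,
    )
    defaults.update(kwargs)
    return KinematicsModel(**defaults)


def noise_free_trace(T: float = 1.0, group: str = "mid50", history=None, seed: int = 0,
                     arc_height: float = 2.0, d: float = 25.0):
    model = noise_free_model(duration_mean=T, reach_distance=d, arc_height=arc_height)
    rng = np.random.default_rng(seed)
    return simulate_kinematics(
        make_stub(group=group), model, history if history is not None else [T] * 5, rng
    )


@pytest.fixture(scope="session")
def small_study():
    """Two participants, both sessions, full default design; segmented and filtered."""
    cfg = PipelineConfig(n_participants=2, seed=123)
    datasets = stage_simulate(cfg)
    trials = pd.concat([d.trials for d in datasets.values()], ignore_index=True)
    seg = stage_segment(datasets, cfg.thresholds)
    kept, log = stage_filter(trials, seg, cfg.thresholds)
    return dict(config=cfg, datasets=datasets, trials=trials, seg=seg, kept=kept, log=log)
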