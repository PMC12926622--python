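"""Population model linking observers and kinematics across the two sessions.

Each simulated participant completes a *vision* and a *no_vision* session.
The sampler encodes the between-subject structure the analysis is designed to
detect:

* attenuation slopes are on average steeper (more negative) with vision than
  without, with a participant-level shared component so the within-subject
  session contrast is more precise than the marginal spread;
* attenuation intercepts are on average closer to zero with vision;
* reach endpoint noise is larger without vision, and a participant's
  no-vision endpoint noise is coupled to their no-vision slope (noisier
  reaches, flatter slope) and intercept (noisier reaches, lower intercept),
  producing the positive slope-variability and negative intercept-variability
  partial correlations in the no-vision session;
* baseline PSE, JND and movement tempo are shared across sessions, since the
  study design matches movement execution and task difficulty between them.

Mean slopes/intercepts and their spreads follow the reported group values;
endpoint-noise levels and couplings are generator choices (see docs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .observer import ObserverModel
from .traces import KinematicsModel


@dataclass(frozen=True)
class PopulationParams:
    # psychometric level
    baseline_pse_mean: float = 2.0  # N
    baseline_pse_sd: float = 0.15
    jnd_log_mean: float = float(np.log(0.25))  # lognormal JND around 0.25 N
    jnd_log_sd: float = 0.2
    jnd_bounds: tuple[float, float] = (0.12, 0.5)
    lapse_rate: float = 0.0
    # attenuation slopes, N per % movement duration
    slope_mean_vision: float = -2.512e-3
    slope_mean_no_vision: float = -1.101e-3
    slope_shared_sd: float = 2.2e-3
    slope_resid_sd_vision: float = 2.4e-3
    slope_resid_sd_no_vision: float = 1.6e-3
    slope_noise_coupling: float = 0.028  # (N/%) per cm of endpoint noise
    # attenuation intercepts, N
    intercept_mean_vision: float = -0.054
    intercept_mean_no_vision: float = -0.150
    intercept_shared_sd: float = 0.07
    intercept_resid_sd_vision: float = 0.06
    intercept_resid_sd_no_vision: float = 0.05
    intercept_noise_coupling: float = 0.7  # N per cm of endpoint noise
    # kinematics
    endpoint_noise_mean_vision: float = 0.1  # cm per axis
    endpoint_noise_sd_vision: float = 0.02
    endpoint_noise_mean_no_vision: float = 0.4
    endpoint_noise_sd_no_vision: float = 0.06
    duration_mean: float = 1.0  # s
    duration_between_sd: float = 0.1
    duration_within_sd: float = 0.08


def sample_population(
    n_participants: int,
    seed: int,
    params: PopulationParams = PopulationParams(),
    attenuation: bool = True,
) -> dict[str, dict]:
    """Draw linked per-participant models for both sessions.

    Returns ``{pid: {"vision": (observer, kinematics),
    "no_vision": (observer, kinematics), "stimulated_finger": str}}``.
    With ``attenuation=False`` all slopes and intercepts are zero (null
    observers), everything else unchanged.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 915]))
    p = params
    out: dict[str, dict] = {}
    for i in range(n_participants):
        pid = f"P{i + 1:02d}"
        base_pse = float(np.clip(rng.normal(p.baseline_pse_mean, p.baseline_pse_sd), 1.5, 2.5))
        jnd = float(np.clip(np.exp(rng.normal(p.jnd_log_mean, p.jnd_log_sd)), *p.jnd_bounds))
        dur = float(np.clip(rng.normal(p.duration_mean, p.duration_between_sd), 0.7, 1.4))

        noise_v = float(max(0.03, rng.normal(p.endpoint_noise_mean_vision, p.endpoint_noise_sd_vision)))
        noise_nv = float(max(0.1, rng.normal(p.endpoint_noise_mean_no_vision, p.endpoint_noise_sd_no_vision)))

        slope_shared = rng.normal(0.0, p.slope_shared_sd)
        slope_v = p.slope_mean_vision + slope_shared + rng.normal(0.0, p.slope_resid_sd_vision)
        slope_nv = (
            p.slope_mean_no_vision
            + slope_shared
            + p.slope_noise_coupling * (noise_nv - p.endpoint_noise_mean_no_vision)
            + rng.normal(0.0, p.slope_resid_sd_no_vision)
        )
        int_shared = rng.normal(0.0, p.intercept_shared_sd)
        int_v = p.intercept_mean_vision + int_shared + rng.normal(0.0, p.intercept_resid_sd_vision)
        int_nv = (
            p.intercept_mean_no_vision
            + int_shared
            - p.intercept_noise_coupling * (noise_nv - p.endpoint_noise_mean_no_vision)
            + rng.normal(0.0, p.intercept_resid_sd_no_vision)
        )
        if not attenuation:
            slope_v = slope_nv = int_v = int_nv = 0.0

        sessions = {}
        for session, slope, intercept, noise in (
            ("vision", slope_v, int_v, noise_v),
            ("no_vision", slope_nv, int_nv, noise_nv),
        ):
            observer = ObserverModel(
                baseline_pse=base_pse,
                jnd=jnd,
                attenuation_intercept=float(intercept),
                attenuation_slope=float(slope),
                lapse_rate=p.lapse_rate,
                session=session,
            )
            kin = KinematicsModel(
                duration_mean=dur,
                duration_sd=p.duration_within_sd,
                endpoint_noise_sd=noise,
            )
            sessions[session] = (observer, kin)
        sessions["stimulated_finger"] = "index" if i % 2 == 0 else "ring"
        out[pid] = sessions
    return out
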