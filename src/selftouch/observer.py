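"""Two-alternative forced-choice observer model.

The observer judges whether the second (comparison) force feels stronger than
the first (test) force.  Responses follow a logistic psychometric function

    P(comparison stronger | x) = exp(b0 + b1 x) / (1 + exp(b0 + b1 x))

parameterized here by its point of subjective equality (PSE = -b0/b1, the
comparison intensity judged stronger with probability 0.5) and just noticeable
difference (JND = ln(3)/b1, the distance between the 0.5 and 0.75 points).

Somatosensory attenuation during the reach is modelled as a linear drift of
the effective PSE with movement-time fraction f (in % of movement duration):

    PSE(f) = baseline_pse + attenuation_intercept + attenuation_slope * f

Baseline (resting) trials use ``baseline_pse`` alone.  An optional lapse rate
mixes in stimulus-independent guessing; it is a robustness stressor for the
fitting stage and defaults to zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

LOG3 = float(np.log(3.0))


@dataclass(frozen=True)
class ObserverModel:
    baseline_pse: float = 2.0  # N
    jnd: float = 0.25  # N
    attenuation_intercept: float = 0.0  # N, shift at movement onset
    attenuation_slope: float = 0.0  # N per % movement duration
    lapse_rate: float = 0.0
    session: str = "vision"

    def validate(self) -> None:
        if self.jnd <= 0:
            raise ValueError("jnd must be positive")
        if not (0.0 <= self.lapse_rate < 0.1):
            raise ValueError("lapse_rate must lie in [0, 0.1)")

    def pse_at(self, movement_fraction: Optional[float]) -> float:
        """Effective PSE for a trial; ``None`` marks a baseline trial."""
        if movement_fraction is None:
            return self.baseline_pse
        return (
            self.baseline_pse
            + self.attenuation_intercept
            + self.attenuation_slope * movement_fraction
        )

    def response_probability(
        self, comparison: float, movement_fraction: Optional[float] = None
    ) -> float:
        """P(respond "comparison stronger") at a comparison intensity in N."""
        self.validate()
        if comparison <= 0:
            raise ValueError("comparison intensity must be positive")
        beta1 = LOG3 / self.jnd
        beta0 = -beta1 * self.pse_at(movement_fraction)
        p = 1.0 / (1.0 + np.exp(-(beta0 + beta1 * comparison)))
        return float((1.0 - self.lapse_rate) * p + self.lapse_rate / 2.0)


def simulate_response(
    comparison: float,
    observer: ObserverModel,
    movement_fraction: Optional[float],
    rng: np.random.Generator,
) -> int:
    """Draw one binary judgement (1 = comparison felt stronger)."""
    if movement_fraction is not None and not (0.0 <= movement_fraction <= 120.0):
        raise ValueError("movement_fraction must lie in [0, 120] percent")
    p = observer.response_probability(comparison, movement_fraction)
    return int(rng.random() < p)
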