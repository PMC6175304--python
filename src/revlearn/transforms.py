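"""Monotone maps between the unconstrained (sampling) and constrained
(model) parameter scales.

Learning rates live on (0, 1) and the inverse temperature on (0, BETA_MAX);
both use a scaled logistic, the convention of hierarchical fits of bounded
decision-model parameters.  The finite upper bound on beta stabilizes the
hierarchy when choices are near-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

BETA_MAX = 10.0


@dataclass(frozen=True)
class ParamTransform:
    """Strictly increasing map of the real line onto (lower, upper)."""

    name: str
    lower: float
    upper: float

    def forward(self, x):
        return self.lower + (self.upper - self.lower) * expit(np.asarray(x, dtype=float))

    def inverse(self, y):
        y = np.asarray(y, dtype=float)
        return logit((y - self.lower) / (self.upper - self.lower))


def default_transforms(beta_max: float = BETA_MAX) -> dict[str, ParamTransform]:
    return {
        "eta": ParamTransform("eta", 0.0, 1.0),
        "eta_pos": ParamTransform("eta_pos", 0.0, 1.0),
        "eta_neg": ParamTransform("eta_neg", 0.0, 1.0),
        "beta": ParamTransform("beta", 0.0, beta_max),
    }
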