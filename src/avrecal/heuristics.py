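"""Non-Bayesian recalibration rules.

Two heuristic alternatives to the causal-inference update:

* asynchrony-contingent — the bias is shifted against the measured SOA at
  a rate scaled by the likelihood that the stimuli were physically
  simultaneous, evaluated under the observer's double-exponential
  measurement distribution.  The update vanishes exponentially as the
  measurement leaves the plausible-simultaneity region.
* asynchrony-correction — the bias is shifted by a fixed proportion of
  the measured SOA whenever its magnitude exceeds the simultaneity
  criterion ``c``, and left untouched otherwise.  Beyond the criterion
  the update grows linearly with the measurement, the qualitative
  opposite of the contingent rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .measurement import MeasurementModel, simultaneity_likelihood

__all__ = ["HeuristicParams", "contingent_bias_update", "correction_bias_update"]


@dataclass(frozen=True)
class HeuristicParams:
    """Learning rate and (for the correction rule) simultaneity criterion."""

    alpha: float
    criterion: float = 0.1

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.criterion <= 0:
            raise ValueError("criterion must be positive")


def contingent_bias_update(model: MeasurementModel, delta, m, alpha: float,
                           normalized: bool = False):
    """Asynchrony-contingent update of the cumulative bias shift.

    Returns ``delta - P(m | SOA=0) * alpha * m`` where the simultaneity
    likelihood is the measurement density at stimulus SOA zero under the
    current bias.  By default the raw density (units 1/s) multiplies the
    rate, exactly as the rule is defined, so ``alpha`` carries units of
    seconds; with ``normalized=True`` the density is divided by its peak
    ``1/(tau_a + tau_v)``, giving a dimensionless factor in [0, 1].
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    like = simultaneity_likelihood(model, m)
    if normalized:
        like = like * model.tau_sum
    out = np.asarray(delta, dtype=float) - like * alpha * np.asarray(m, dtype=float)
    return out if out.ndim else float(out)


def correction_bias_update(delta, m, params: HeuristicParams):
    """Asynchrony-correction update of the cumulative bias shift.

    If ``|m| > c`` (strictly) the bias shifts by ``-alpha * m``;
    otherwise the measured asynchrony is attributed to sensory noise and
    no recalibration occurs.
    """
    m = np.asarray(m, dtype=float)
    out = np.asarray(delta, dtype=float) - np.where(
        np.abs(m) > params.criterion, params.alpha * m, 0.0
    )
    return out if out.ndim else float(out)
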