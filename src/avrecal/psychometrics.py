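"""Ternary temporal-order-judgment response probabilities.

The observer compares an internal SOA estimate ``s_hat`` to a symmetric
pair of criteria ``±c``: responses are "visual first" when ``s_hat > c``,
"auditory first" when ``s_hat < -c`` and "simultaneous" otherwise (ties at
the criteria count as simultaneous — a measure-zero convention fixed for
determinism).  A lapse occurs with probability ``lapse`` and distributes
uniformly over the three responses.

For the asynchrony-contingent and asynchrony-correction observers the
estimate equals the measurement, so the three probabilities follow in
closed form from the double-exponential measurement CDF.  For the
causal-inference observer the estimate distribution has no closed form
and is approximated by Monte Carlo: sample measurements, push each
through the causal-inference read-out, and count the fractions falling in
the three response regions.  Measurements are produced by inverse-CDF
transform of a fixed uniform-deviate array, so that with a fixed seed the
simulated probabilities are a deterministic function of the parameters
(common random numbers, required for stable optimization).

Response probabilities are returned in the fixed column order
(auditory-first, simultaneous, visual-first).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .causal import CausalPrior, _estimate_from_d
from .measurement import MeasurementModel, _cdf, _ppf
from .models import ModelSpec, ObserverParams

__all__ = [
    "TernaryProbabilities",
    "DecisionParams",
    "toj_probs_measurement_readout",
    "toj_probs_causal_inference",
    "psychometric_curve",
    "RESPONSES",
]

#: Canonical response codes in column order.
RESPONSES = ("A", "S", "V")


@dataclass(frozen=True)
class TernaryProbabilities:
    """Probabilities of the three TOJ responses at one test SOA."""

    p_auditory_first: float
    p_simultaneous: float
    p_visual_first: float

    def __post_init__(self) -> None:
        total = self.p_auditory_first + self.p_simultaneous + self.p_visual_first
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"probabilities must sum to 1, got {total}")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_auditory_first, self.p_simultaneous,
                         self.p_visual_first])


@dataclass(frozen=True)
class DecisionParams:
    """Simultaneity criterion ``c`` (s) and lapse rate."""

    criterion: float
    lapse: float = 0.0

    def __post_init__(self) -> None:
        if self.criterion <= 0:
            raise ValueError("criterion must be positive")
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError("lapse must lie in [0, 1]")


def _apply_lapse(raw: np.ndarray, lapse: float) -> np.ndarray:
    return lapse / 3.0 + (1.0 - lapse) * raw


def _readout_probs(u, tau_a: float, tau_v: float, criterion: float,
                   lapse: float) -> np.ndarray:
    """Closed-form ternary probabilities for estimate = measurement.

    ``u = s + bias`` is the peak location of the measurement density;
    returns an array of shape ``(len(u), 3)`` in (A, S, V) order.
    """
    u = np.atleast_1d(np.asarray(u, dtype=float))
    p_a = _cdf(-criterion - u, tau_a, tau_v)
    p_v = 1.0 - _cdf(criterion - u, tau_a, tau_v)
    out = np.stack([p_a, 1.0 - p_a - p_v, p_v], axis=-1)
    return _apply_lapse(out, lapse)


def _ci_fractions(u, eps: np.ndarray, prior: CausalPrior, tau_a: float,
                  tau_v: float, criterion: float, estimator=None) -> np.ndarray:
    """Monte-Carlo response fractions for the causal-inference observer.

    ``u`` are peak locations ``s + bias``; ``eps`` is a fixed array of
    centered measurement-noise deviates.  The observer infers from the raw
    measurement ``m = u + eps`` (no correction for the own bias).  Shape
    of the result: ``(len(u), 3)`` in (A, S, V) order, no lapse applied.
    A tabulated estimate function may be supplied in place of the exact
    causal-inference read-out.
    """
    u = np.atleast_1d(np.asarray(u, dtype=float))
    d = u[:, None] + eps[None, :]
    if estimator is None:
        s_hat = _estimate_from_d(d, prior, tau_a, tau_v)
    else:
        s_hat = estimator(d)
    p_v = np.mean(s_hat > criterion, axis=1)
    p_a = np.mean(s_hat < -criterion, axis=1)
    return np.stack([p_a, 1.0 - p_a - p_v, p_v], axis=-1)


def _noise_deviates(n_samples: int, tau_a: float, tau_v: float,
                    rng_seed) -> np.ndarray:
    rng = np.random.default_rng(rng_seed)
    return _ppf(rng.uniform(size=n_samples), tau_a, tau_v)


def toj_probs_measurement_readout(model: MeasurementModel, s: float,
                                  dec: DecisionParams) -> TernaryProbabilities:
    """Exact ternary probabilities when the estimate equals the measurement."""
    if not np.isfinite(s):
        raise ValueError("s must be finite")
    row = _readout_probs(s + model.bias, model.tau_a, model.tau_v,
                         dec.criterion, dec.lapse)[0]
    return TernaryProbabilities(*row)


def toj_probs_causal_inference(model: MeasurementModel, s: float,
                               prior: CausalPrior, dec: DecisionParams,
                               n_samples: int = 10_000,
                               rng_seed=0) -> TernaryProbabilities:
    """Monte-Carlo ternary probabilities for the causal-inference observer.

    Draws ``n_samples`` measurements at stimulus SOA ``s`` (default
    10,000), maps each through the causal-inference read-out and applies
    the lapse mixture.  Deterministic given ``rng_seed``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if not np.isfinite(s):
        raise ValueError("s must be finite")
    eps = _noise_deviates(n_samples, model.tau_a, model.tau_v, rng_seed)
    raw = _ci_fractions(s + model.bias, eps, prior, model.tau_a,
                        model.tau_v, dec.criterion)[0]
    return TernaryProbabilities(*_apply_lapse(raw, dec.lapse))


def psychometric_curve(spec: ModelSpec, params: ObserverParams, test_soas,
                       shift: float = 0.0, n_samples: int = 10_000,
                       rng_seed=0) -> np.ndarray:
    """Ternary response probabilities over a grid of test SOAs.

    Dispatches to the closed-form read-out (contingent and correction
    observers) or the Monte-Carlo causal-inference computation.  ``shift``
    is an additional bias offset (the accumulated recalibration shift for
    post-test curves).  Returns an array of shape ``(len(test_soas), 3)``
    in (A, S, V) column order; rows sum to one.
    """
    test_soas = np.atleast_1d(np.asarray(test_soas, dtype=float))
    if test_soas.size == 0:
        raise ValueError("test_soas must be nonempty")
    u = test_soas + params.beta_pre + shift
    if spec.update_rule.is_causal:
        eps = _noise_deviates(n_samples, params.tau_a, params.tau_v, rng_seed)
        raw = _ci_fractions(u, eps, params.causal_prior(), params.tau_a,
                            params.tau_v, params.criterion)
    else:
        raw = _readout_probs(u, params.tau_a, params.tau_v,
                             params.criterion, 0.0)
    return _apply_lapse(raw, params.lapse)
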