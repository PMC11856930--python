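"""Exposure-phase dynamics: trial-by-trial bias updates and their distribution.

During an exposure session the observer experiences ``n_trials`` (default
250) audiovisual stimulus pairs at a fixed adapter SOA.  After each trial
the cumulative shift of the audiovisual bias is updated according to the
observer model's rule; the measurement on trial ``i`` is drawn with the
CURRENT bias ``beta_pre + shift_i``, so the dynamics feed back on
themselves.

The post-test likelihood requires the distribution of the cumulative
shift after the full exposure phase.  Following the fitting procedure,
the exposure phase is simulated ``n_reps`` times (default 1000), the
final shifts are summarized by a Gaussian with the empirical mean and
standard deviation, and that Gaussian is discretized into 100 equally
spaced bins spanning triple the range of the Monte-Carlo sample:
``lb = min - (max - min)`` and ``ub = max + (max - min)``.  Bin weights
are the Gaussian density at the bin centers; the likelihood integrates
against them with a uniform-bin-width Riemann sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .causal import _estimate_from_d, _posterior_c1_from_d, build_estimator
from .measurement import _logpdf, _ppf
from .models import ModelSpec, ObserverParams, UpdateRule

__all__ = ["BiasTrajectory", "ShiftDistribution", "simulate_exposure",
           "approximate_shift_distribution"]


@dataclass(frozen=True)
class BiasTrajectory:
    """Cumulative bias shifts over one exposure session, including trial 0."""

    shifts: np.ndarray

    def __post_init__(self) -> None:
        shifts = np.asarray(self.shifts, dtype=float)
        if shifts.ndim != 1 or shifts.size < 1 or shifts[0] != 0.0:
            raise ValueError("shifts must be a 1-d array starting at exactly 0")
        object.__setattr__(self, "shifts", shifts)

    @property
    def final(self) -> float:
        return float(self.shifts[-1])

    def __len__(self) -> int:
        return self.shifts.size


@dataclass(frozen=True)
class ShiftDistribution:
    """Gaussian + binned approximation of the final cumulative shift.

    A degenerate Monte-Carlo sample (zero spread, e.g. with a zero
    learning rate) collapses to a point mass: a single bin of weight one
    at the sample mean with ``lower == upper``.
    """

    mean: float
    sd: float
    bin_centers: np.ndarray
    bin_weights: np.ndarray
    lower: float
    upper: float

    @property
    def is_point_mass(self) -> bool:
        return self.bin_centers.size == 1

    @property
    def bin_width(self) -> float:
        return (self.upper - self.lower) / self.bin_centers.size

    @classmethod
    def from_samples(cls, samples, n_bins: int = 100) -> "ShiftDistribution":
        samples = np.asarray(samples, dtype=float)
        if samples.size < 1:
            raise ValueError("need at least one sample")
        mean = float(np.mean(samples))
        sd = float(np.std(samples))
        lo, hi = float(np.min(samples)), float(np.max(samples))
        span = hi - lo
        if span <= 0.0 or sd <= 0.0:
            return cls(mean=mean, sd=0.0, bin_centers=np.array([mean]),
                       bin_weights=np.array([1.0]), lower=mean, upper=mean)
        lower, upper = lo - span, hi + span
        width = (upper - lower) / n_bins
        centers = lower + (np.arange(n_bins) + 0.5) * width
        weights = norm.pdf(centers, loc=mean, scale=sd)
        return cls(mean=mean, sd=sd, bin_centers=centers, bin_weights=weights,
                   lower=lower, upper=upper)


def _step(spec: ModelSpec, params: ObserverParams, shifts: np.ndarray,
          eps: np.ndarray, adapter: np.ndarray, estimator=None) -> np.ndarray:
    """One vectorized exposure trial; returns the updated cumulative shifts.

    ``shifts`` and ``eps`` broadcast together; ``adapter`` broadcasts
    against them (one adapter SOA per row for batched sessions).  For the
    causal-inference rule a tabulated estimate function may be supplied
    to avoid recomputing the scenario marginals per trial.
    """
    bias = params.beta_pre + shifts
    m = adapter + bias + eps
    rule = spec.update_rule
    if rule is UpdateRule.CAUSAL_INFERENCE:
        if estimator is None:
            est = _estimate_from_d(m, params.causal_prior(),
                                   params.tau_a, params.tau_v)
        else:
            est = estimator(m)
        return shifts + params.alpha * (est - m)
    if rule is UpdateRule.CAUSAL_INFERENCE_POSTERIOR:
        w = _posterior_c1_from_d(m, params.causal_prior(), params.tau_a, params.tau_v)
        return shifts - params.alpha * w * m
    if rule is UpdateRule.ASYNCHRONY_CONTINGENT:
        like = np.exp(_logpdf(m - bias, params.tau_a, params.tau_v))
        return shifts - like * params.alpha * m
    if rule is UpdateRule.ASYNCHRONY_CORRECTION:
        return shifts - np.where(np.abs(m) > params.criterion,
                                 params.alpha * m, 0.0)
    raise ValueError(f"unknown update rule {rule!r}")


def _final_shifts(spec: ModelSpec, params: ObserverParams,
                  adapter_soas: np.ndarray, uniforms: np.ndarray,
                  estimator=None) -> np.ndarray:
    """Final cumulative shifts for batched sessions × repetitions.

    ``uniforms`` has shape ``(J, R, T)``; the same deviates are reused
    across likelihood evaluations (common random numbers), with the
    inverse-CDF transform applied under the current time constants.
    ``adapter_soas`` has shape ``(J,)``.  Returns shape ``(J, R)``.
    """
    J, R, T = uniforms.shape
    adapter = np.asarray(adapter_soas, dtype=float)[:, None]
    eps = _ppf(uniforms, params.tau_a, params.tau_v)
    if estimator is None and spec.update_rule is UpdateRule.CAUSAL_INFERENCE:
        lo = float(adapter.min() + params.beta_pre + eps.min()) - 1.0
        hi = float(adapter.max() + params.beta_pre + eps.max()) + 1.0
        estimator = build_estimator(params.causal_prior(), params.tau_a,
                                    params.tau_v, lo, hi)
    shifts = np.zeros((J, R))
    for i in range(T):
        shifts = _step(spec, params, shifts, eps[:, :, i], adapter, estimator)
    return shifts


def simulate_exposure(spec: ModelSpec, params: ObserverParams,
                      adapter_soa: float, n_trials: int = 250,
                      rng_seed=0) -> BiasTrajectory:
    """Simulate one exposure session, returning the full shift trajectory."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(rng_seed)
    uniforms = rng.uniform(size=n_trials)
    shifts = np.zeros(n_trials + 1)
    adapter = np.asarray(adapter_soa, dtype=float)
    for i in range(n_trials):
        eps = _ppf(uniforms[i], params.tau_a, params.tau_v)
        shifts[i + 1] = _step(spec, params, shifts[i], eps, adapter)
    return BiasTrajectory(shifts=shifts)


def approximate_shift_distribution(spec: ModelSpec, params: ObserverParams,
                                   adapter_soa: float, n_reps: int = 1000,
                                   n_trials: int = 250, rng_seed=0,
                                   n_bins: int = 100) -> ShiftDistribution:
    """Gaussian + binned approximation of the final shift for one session.

    Runs ``n_reps`` independent exposure simulations and summarizes the
    final cumulative shifts; see module docstring for the binning rule.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    rng = np.random.default_rng(rng_seed)
    uniforms = rng.uniform(size=(1, n_reps, n_trials))
    finals = _final_shifts(spec, params, np.array([adapter_soa]), uniforms)[0]
    return ShiftDistribution.from_samples(finals, n_bins=n_bins)
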