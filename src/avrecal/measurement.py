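"""Double-exponential model of the measured audiovisual SOA.

An auditory and a visual stimulus presented with stimulus-onset asynchrony
(SOA) ``s = t_A - t_V`` (negative: auditory lead; positive: visual lead)
trigger internal signals whose arrival latencies are modeled as shifted
exponential distributions with time constants ``tau_a`` and ``tau_v``.
The measured SOA ``m`` is the difference of the two arrival times, so

    m = s + bias + E_A - E_V,    E_A ~ Exp(tau_a),  E_V ~ Exp(tau_v),

where ``bias`` is the observer's audiovisual temporal bias (the difference
of the fixed processing delays).  The density of ``m`` is a two-sided
("double") exponential that peaks at ``s + bias`` with value
``1 / (tau_a + tau_v)``: the left flank decays with constant ``tau_v``,
the right flank with ``tau_a``.  All times are in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "MeasurementModel",
    "measurement_density",
    "measurement_cdf",
    "measurement_quantile",
    "sample_measurements",
    "simultaneity_likelihood",
]


@dataclass(frozen=True)
class MeasurementModel:
    """Parameters of the double-exponential SOA measurement distribution.

    Parameters
    ----------
    bias : float
        Current audiovisual temporal bias in seconds (``beta_pre`` plus any
        accumulated recalibration shift).  Negative values indicate faster
        auditory processing.
    tau_a, tau_v : float
        Exponential time constants (seconds) of the auditory and visual
        arrival-latency distributions.  Must be strictly positive.
    """

    bias: float
    tau_a: float
    tau_v: float

    def __post_init__(self) -> None:
        for name in ("bias", "tau_a", "tau_v"):
            value = getattr(self, name)
            if not np.isfinite(value):
                raise ValueError(f"{name} must be finite, got {value!r}")
        if self.tau_a <= 0 or self.tau_v <= 0:
            raise ValueError(
                f"time constants must be positive, got tau_a={self.tau_a}, "
                f"tau_v={self.tau_v}"
            )

    @property
    def tau_sum(self) -> float:
        return self.tau_a + self.tau_v

    def with_bias(self, bias: float) -> "MeasurementModel":
        """Copy of the model with a different audiovisual bias."""
        return replace(self, bias=bias)


def _check_finite(name: str, x: np.ndarray) -> None:
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} must be finite")


def _logpdf(x, tau_a: float, tau_v: float):
    """Log density of the centered measurement noise at ``x = m - peak``.

    The point ``x = 0`` belongs to the left branch; both branches agree
    there, the assignment only fixes a deterministic convention.
    """
    x = np.asarray(x, dtype=float)
    left = x / tau_v
    right = -x / tau_a
    return np.where(x <= 0.0, left, right) - np.log(tau_a + tau_v)


def _cdf(x, tau_a: float, tau_v: float):
    x = np.asarray(x, dtype=float)
    p_left = tau_v / (tau_a + tau_v)
    with np.errstate(over="ignore"):
        left = p_left * np.exp(np.minimum(x, 0.0) / tau_v)
        right = 1.0 - (1.0 - p_left) * np.exp(-np.maximum(x, 0.0) / tau_a)
    return np.where(x <= 0.0, left, right)


def _ppf(q, tau_a: float, tau_v: float):
    """Inverse CDF of the centered noise; vectorized over ``q`` in (0, 1)."""
    q = np.asarray(q, dtype=float)
    p_left = tau_v / (tau_a + tau_v)
    with np.errstate(divide="ignore"):
        left = tau_v * np.log(q / p_left)
        right = -tau_a * np.log((1.0 - q) / (1.0 - p_left))
    return np.where(q <= p_left, left, right)


def measurement_density(model: MeasurementModel, m, s):
    """Probability density (1/s) of measuring ``m`` at stimulus SOA ``s``.

    Two-branch double exponential peaking at ``s + model.bias`` with value
    ``1 / (tau_a + tau_v)``; strictly positive everywhere.
    """
    m = np.asarray(m, dtype=float)
    s = np.asarray(s, dtype=float)
    _check_finite("m", m)
    _check_finite("s", s)
    out = np.exp(_logpdf(m - (s + model.bias), model.tau_a, model.tau_v))
    return out if out.ndim else float(out)


def measurement_cdf(model: MeasurementModel, m, s):
    """P(measured SOA <= m) at stimulus SOA ``s`` (piecewise exponential)."""
    m = np.asarray(m, dtype=float)
    s = np.asarray(s, dtype=float)
    _check_finite("m", m)
    _check_finite("s", s)
    out = _cdf(m - (s + model.bias), model.tau_a, model.tau_v)
    return out if out.ndim else float(out)


def measurement_quantile(model: MeasurementModel, q, s):
    """Inverse of :func:`measurement_cdf` in ``m`` for ``q`` in (0, 1)."""
    q = np.asarray(q, dtype=float)
    if np.any((q <= 0.0) | (q >= 1.0)):
        raise ValueError("quantile levels must lie strictly inside (0, 1)")
    out = np.asarray(s, dtype=float) + model.bias + _ppf(q, model.tau_a, model.tau_v)
    return out if out.ndim else float(out)


def sample_measurements(model: MeasurementModel, s, n: int, rng_seed) -> np.ndarray:
    """Draw ``n`` SOA measurements at stimulus SOA ``s``.

    Samples ``m = s + bias + E_A - E_V`` with independent exponential
    latencies.  ``rng_seed`` may be an integer seed or a
    ``numpy.random.Generator``; a fixed seed yields identical samples on
    repeated calls.  ``n = 0`` returns an empty array.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(rng_seed)
    _check_finite("s", np.asarray(s, dtype=float))
    e_a = rng.exponential(model.tau_a, size=n)
    e_v = rng.exponential(model.tau_v, size=n)
    return np.asarray(s, dtype=float) + model.bias + e_a - e_v


def simultaneity_likelihood(model: MeasurementModel, m):
    """Likelihood that the stimuli were physically simultaneous, p(m | SOA=0).

    This is the measurement density evaluated at stimulus SOA zero; the
    asynchrony-contingent observer uses it to scale bias updates.
    """
    return measurement_density(model, m, 0.0)
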