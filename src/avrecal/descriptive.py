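"""Model-agnostic behavioral analysis of recalibration.

Pre- and post-test responses of one session are fitted jointly with the
closed-form ternary psychometric functions (measurement read-out), with a
shared shape — time constants, simultaneity criterion and lapse rate —
and separate pre/post biases, so any pre-to-post change appears as a
lateral shift of the curves.  This is a reconstruction of the
atheoretical analysis from its description (shared shape, shifted bias,
fixed criteria); no criterion-shift variant is provided.

The point of subjective simultaneity (PSS) is the physical SOA at which
the probability of reporting "simultaneous" is maximal, located by a
1 ms grid search with local refinement.  For a symmetric measurement
distribution (equal time constants) the PSS equals minus the bias.

The recalibration effect of a session is PSS_post - PSS_pre; the
asymmetry index is the sum of effects across all nine adapter SOAs
(positive: greater recalibration for visual-lead adapters).  Confidence
intervals come from a percentile bootstrap that resamples responses with
replacement within each (session, phase, test SOA) cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .data import Dataset
from .likelihood import _minimize_nm
from .psychometrics import _readout_probs

__all__ = ["DescriptiveFit", "fit_descriptive", "pss",
           "asymmetry_index", "recalibration_summary", "RecalibrationSummary"]

_NAMES = ["beta_pre", "beta_post", "tau_a", "tau_v", "criterion", "lapse"]
_LO = np.array([-0.4, -0.4, 0.005, 0.005, 0.001, 1e-4])
_HI = np.array([0.4, 0.4, 0.5, 0.5, 0.5, 0.2])


@dataclass(frozen=True)
class DescriptiveFit:
    """Shared psychometric shape plus separate pre/post biases."""

    beta_pre: float
    beta_post: float
    tau_a: float
    tau_v: float
    criterion: float
    lapse: float
    loglik: float

    @property
    def pss_pre(self) -> float:
        return pss(self.tau_a, self.tau_v, self.criterion, self.lapse,
                   self.beta_pre)

    @property
    def pss_post(self) -> float:
        return pss(self.tau_a, self.tau_v, self.criterion, self.lapse,
                   self.beta_post)

    @property
    def effect(self) -> float:
        """Recalibration effect, PSS_post - PSS_pre (s)."""
        return self.pss_post - self.pss_pre


def _cell_ll(counts, probs) -> float:
    with np.errstate(divide="ignore"):
        logp = np.log(probs)
    mask = counts > 0
    if np.any(np.isneginf(logp) & mask):
        return -np.inf
    return float(np.sum(counts[mask] * logp[mask]))


def _fit_counts(soas: np.ndarray, pre: np.ndarray, post: np.ndarray,
                n_starts: int = 2, rng_seed: int = 0,
                maxfev: int = 2000) -> DescriptiveFit:
    def objective(x):
        v = _LO + np.clip(x, 0.0, 1.0) * (_HI - _LO)
        beta_pre, beta_post, tau_a, tau_v, crit, lapse = v
        ll = (_cell_ll(pre, _readout_probs(soas + beta_pre, tau_a, tau_v,
                                           crit, lapse))
              + _cell_ll(post, _readout_probs(soas + beta_post, tau_a, tau_v,
                                              crit, lapse)))
        return -ll if np.isfinite(ll) else 1e12

    def center_guess(counts):
        return (-float(soas[np.argmax(counts[:, 1])])
                if counts[:, 1].sum() else 0.0)

    x0 = (np.array([center_guess(pre), center_guess(post),
                    0.07, 0.07, 0.1, 0.02]) - _LO) / (_HI - _LO)
    rng = np.random.default_rng(rng_seed)
    starts = [np.clip(x0, 0.0, 1.0)]
    starts += [np.clip(x0 + rng.normal(0, 0.08, size=6), 0.0, 1.0)
               for _ in range(n_starts - 1)]
    best = None
    for s in starts:
        res = _minimize_nm(objective, s, maxfev, xatol=1e-4, fatol=1e-4)
        if best is None or res.fun < best.fun:
            best = res
    v = _LO + np.clip(best.x, 0.0, 1.0) * (_HI - _LO)
    return DescriptiveFit(*v.tolist(), loglik=-float(best.fun))


def fit_descriptive(session_data: Dataset, n_starts: int = 2,
                    rng_seed: int = 0, maxfev: int = 2000) -> DescriptiveFit:
    """Joint pre/post psychometric fit of one session.

    Requires both phases; invariant to trial order (only per-cell counts
    enter the likelihood).
    """
    pre = session_data.counts("pre")
    post = session_data.counts("post")
    if pre.sum() == 0 or post.sum() == 0:
        raise ValueError("session must contain trials in both phases")
    if pre.shape[0] != 1:
        raise ValueError("fit_descriptive expects a single session")
    return _fit_counts(session_data.test_soas, pre[0], post[0],
                       n_starts=n_starts, rng_seed=rng_seed, maxfev=maxfev)


def pss(tau_a: float, tau_v: float, criterion: float, lapse: float,
        bias: float, half_range: float = 0.6) -> float:
    """Physical SOA maximizing the probability of reporting simultaneity.

    Grid search (1 ms step over ``±half_range``) with golden-section
    refinement.  The lapse rate rescales the curve without moving the
    argmax; for ``tau_a == tau_v`` the PSS equals ``-bias``.
    """
    grid = np.arange(-half_range, half_range + 1e-3, 1e-3)
    p_s = _readout_probs(grid + bias, tau_a, tau_v, criterion, lapse)[:, 1]
    i = int(np.argmax(p_s))
    lo = grid[max(i - 2, 0)]
    hi = grid[min(i + 2, grid.size - 1)]
    res = optimize.minimize_scalar(
        lambda s: -_readout_probs(np.array([s + bias]), tau_a, tau_v,
                                  criterion, lapse)[0, 1],
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-6})
    return float(res.x)


def asymmetry_index(effects: dict, n_sessions: int = 9) -> float:
    """Sum of per-session recalibration effects (s).

    ``effects`` maps session id to PSS shift.  Raises if any of the
    expected sessions is missing.
    """
    if len(effects) != n_sessions:
        missing = sorted(set(range(1, n_sessions + 1)) - set(effects))
        raise ValueError(f"missing sessions: {missing}")
    return float(sum(effects.values()))


@dataclass
class RecalibrationSummary:
    """Per-session PSS shifts and the asymmetry index with bootstrap CIs."""

    table: pd.DataFrame
    asymmetry: float
    asymmetry_ci: tuple
    n_boot: int
    rng_seed: int

    def to_json_dict(self) -> dict:
        return {"asymmetry_index_s": self.asymmetry,
                "asymmetry_ci95_s": list(self.asymmetry_ci),
                "n_boot": self.n_boot, "rng_seed": self.rng_seed}


def _resample_counts(counts: np.ndarray, rng) -> np.ndarray:
    """Multinomial resample within each (SOA) cell, preserving cell sizes."""
    out = np.zeros_like(counts)
    for s in range(counts.shape[0]):
        n = counts[s].sum()
        if n == 0:
            continue
        out[s] = rng.multinomial(n, counts[s] / n)
    return out


def recalibration_summary(data: Dataset, n_boot: int = 1000,
                          rng_seed: int = 0, require_full_design: bool = True,
                          fit_kwargs: dict | None = None) -> RecalibrationSummary:
    """Descriptive recalibration analysis of a full experiment.

    Fits every session, extracts PSS_pre/PSS_post and the per-session
    effect, sums effects into the asymmetry index, and attaches 95%
    percentile bootstrap CIs obtained by resampling responses within each
    (session, phase, test SOA) cell and refitting.
    """
    fit_kwargs = fit_kwargs or {}
    sessions = data.sessions
    if require_full_design and len(sessions) != 9:
        missing = sorted(set(range(1, 10)) - set(int(j) for j in sessions))
        raise ValueError(f"missing sessions: {missing}")
    soas = data.test_soas
    pre_all = data.counts("pre")
    post_all = data.counts("post")

    rows = []
    for idx, j in enumerate(sessions):
        fit = _fit_counts(soas, pre_all[idx], post_all[idx], **fit_kwargs)
        rows.append({"session": int(j), "adapter_soa_s": data.adapter_soa(j),
                     "pss_pre": fit.pss_pre, "pss_post": fit.pss_post,
                     "effect": fit.effect})
    table = pd.DataFrame(rows)
    asym = float(table["effect"].sum())

    rng = np.random.default_rng(rng_seed)
    boot_effects = np.empty((n_boot, len(sessions)))
    for b in range(n_boot):
        for idx in range(len(sessions)):
            fit = _fit_counts(soas, _resample_counts(pre_all[idx], rng),
                              _resample_counts(post_all[idx], rng),
                              **fit_kwargs)
            boot_effects[b, idx] = fit.effect
    lo, hi = np.percentile(boot_effects, [2.5, 97.5], axis=0)
    table["effect_ci_low"] = lo
    table["effect_ci_high"] = hi
    boot_index = boot_effects.sum(axis=1)
    ci = tuple(np.percentile(boot_index, [2.5, 97.5]).tolist())
    return RecalibrationSummary(table=table, asymmetry=asym,
                                asymmetry_ci=ci, n_boot=n_boot,
                                rng_seed=rng_seed)
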