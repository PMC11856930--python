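"""Joint pre/post-test likelihood, multistart fitting and model comparison.

The pre-test log-likelihood is the multinomial log-likelihood of the
ternary responses under the model's psychometric functions evaluated at
the pre-exposure bias, identical across sessions.  The post-test
log-likelihood integrates, per session, the product of trial likelihoods
over the unknown cumulative bias shift produced by the exposure phase:
the shift distribution is approximated by a Gaussian fitted to Monte-
Carlo exposure simulations, discretized into 100 equally spaced bins, and
the integral is taken as a uniform-width Riemann sum.  Products over
trials and sums over bins are computed in log space (log-sum-exp).

All Monte-Carlo elements (exposure simulations and, for the causal-
inference observer, the psychometric simulation) reuse a fixed array of
uniform deviates drawn once per engine from the seed, transformed by the
inverse measurement CDF under the current parameters.  The joint
log-likelihood is therefore a deterministic function of (parameters,
seed) across optimizer iterations (common random numbers).

For the causal-inference observer the response probabilities depend on
the test SOA and the bias only through their sum ``u = s + bias``, so the
engine evaluates the Monte-Carlo psychometric once on a fine grid of
``u`` (default 5 ms spacing) and interpolates linearly for the hundreds
of (shift bin × test SOA) combinations the post-test integral requires.
The standalone :func:`avrecal.psychometrics.toj_probs_causal_inference`
performs the direct per-SOA simulation; grid and direct computation agree
to within Monte-Carlo error (tested).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp
from scipy.stats import qmc

from .causal import build_estimator, uniform_interp
from .data import Dataset
from .exposure import ShiftDistribution, _final_shifts
from .measurement import _ppf
from .models import ModelSpec, ObserverParams, UpdateRule
from .psychometrics import _apply_lapse, _ci_fractions, _readout_probs

__all__ = [
    "JointLikelihoodEngine",
    "pretest_loglik",
    "posttest_loglik",
    "joint_loglik",
    "fit_model",
    "FitResult",
    "compare_models",
]

_BIG = 1e12  # penalty value standing in for -inf log-likelihoods


def _minimize_nm(objective, x0, maxfev: int, step: float = 0.15,
                 xatol: float = 1e-3, fatol: float = 1e-3):
    """Nelder-Mead in unit-cube coordinates with an absolute-step simplex.

    scipy's default initial simplex perturbs coordinates multiplicatively,
    which freezes parameters sitting near zero (e.g. a lapse rate at its
    lower bound); an explicit simplex with absolute steps keeps every
    coordinate mobile.
    """
    x0 = np.clip(np.asarray(x0, dtype=float), 0.0, 1.0)
    d = x0.size
    simplex = np.repeat(x0[None, :], d + 1, axis=0)
    for i in range(d):
        simplex[i + 1, i] += step if x0[i] <= 1.0 - step else -step
    return optimize.minimize(objective, x0, method="Nelder-Mead",
                             options={"maxfev": maxfev, "xatol": xatol,
                                      "fatol": fatol, "adaptive": True,
                                      "initial_simplex": simplex})


class JointLikelihoodEngine:
    """Reusable joint-likelihood evaluator with common random numbers.

    Parameters
    ----------
    data : Dataset
        Trial-level ternary TOJ data.
    spec : ModelSpec
        Observer model to evaluate.
    rng_seed : int
        Seed for the fixed uniform-deviate arrays.
    n_samples : int
        Monte-Carlo sample size per psychometric evaluation point
        (causal-inference observer only); 10,000 by default.
    n_reps : int
        Exposure simulations per session for the shift distribution
        (1000 by default).
    n_trials : int
        Exposure trials per simulation (250 by default).
    n_bins : int
        Bins discretizing the Gaussian shift distribution (100).
    grid_step : float
        Spacing (s) of the ``u = s + bias`` grid for the causal-inference
        psychometric.
    """

    def __init__(self, data: Dataset, spec: ModelSpec, rng_seed: int = 0,
                 n_samples: int = 10_000, n_reps: int = 1000,
                 n_trials: int = 250, n_bins: int = 100,
                 grid_step: float = 0.005):
        if data.n_trials == 0:
            raise ValueError("dataset is empty")
        self.data = data
        self.spec = spec
        self.rng_seed = int(rng_seed)
        self.n_samples = int(n_samples)
        self.n_reps = int(n_reps)
        self.n_trials = int(n_trials)
        self.n_bins = int(n_bins)
        self.grid_step = float(grid_step)

        self.test_soas = data.test_soas
        self.sessions = data.sessions
        self.adapter_soas = data.adapter_soas
        self.pre_counts = data.counts("pre")          # (J, S, 3)
        self.post_counts = data.counts("post")
        # pre-test curves are shared across sessions: total counts suffice
        self.pre_counts_total = self.pre_counts.sum(axis=0)

        seq_psy, seq_exp = np.random.SeedSequence(self.rng_seed).spawn(2)
        self._u_psy = np.random.default_rng(seq_psy).uniform(size=self.n_samples)
        self._u_exp = np.random.default_rng(seq_exp).uniform(
            size=(len(self.sessions), self.n_reps, self.n_trials))
        self._u_min = float(self._u_exp.min())
        self._u_max = float(self._u_exp.max())
        self._u_psy_min = float(self._u_psy.min())
        self._u_psy_max = float(self._u_psy.max())

    # ------------------------------------------------------------------
    def _estimator(self, params: ObserverParams):
        """Shared tabulated causal-inference estimate covering all phases."""
        if self.spec.update_rule is not UpdateRule.CAUSAL_INFERENCE:
            return None
        eps_lo = min(_ppf(self._u_min, params.tau_a, params.tau_v),
                     _ppf(self._u_psy_min, params.tau_a, params.tau_v))
        eps_hi = max(_ppf(self._u_max, params.tau_a, params.tau_v),
                     _ppf(self._u_psy_max, params.tau_a, params.tau_v))
        lo = (params.beta_pre + min(self.test_soas.min(), self.adapter_soas.min())
              + eps_lo - 1.0)
        hi = (params.beta_pre + max(self.test_soas.max(), self.adapter_soas.max())
              + eps_hi + 1.0)
        return build_estimator(params.causal_prior(), params.tau_a,
                               params.tau_v, float(lo), float(hi))

    def shift_distributions(self, params: ObserverParams,
                            estimator=None) -> list[ShiftDistribution]:
        """Per-session binned shift distributions under ``params``."""
        finals = _final_shifts(self.spec, params, self.adapter_soas,
                               self._u_exp, estimator=estimator)
        return [ShiftDistribution.from_samples(f, n_bins=self.n_bins)
                for f in finals]

    def _prob_fn(self, params: ObserverParams,
                 dists: Optional[Sequence[ShiftDistribution]],
                 estimator=None):
        """Callable mapping peak locations ``u = s + bias`` to (A,S,V) probs."""
        if not self.spec.update_rule.is_causal:
            def prob_fn(u):
                return _readout_probs(u, params.tau_a, params.tau_v,
                                      params.criterion, params.lapse)
            return prob_fn

        eps = _ppf(self._u_psy, params.tau_a, params.tau_v)
        lo = float(self.test_soas.min() + params.beta_pre)
        hi = float(self.test_soas.max() + params.beta_pre)
        if dists is not None:
            lo += min(0.0, *(d.bin_centers.min() for d in dists))
            hi += max(0.0, *(d.bin_centers.max() for d in dists))
        step = self.grid_step
        grid = np.arange(lo - step, hi + 2 * step, step)
        raw = _ci_fractions(grid, eps, params.causal_prior(),
                            params.tau_a, params.tau_v, params.criterion,
                            estimator=estimator)
        interp = uniform_interp(float(grid[0]), step, raw[:, [0, 2]])

        def prob_fn(u):
            u = np.atleast_1d(np.asarray(u, dtype=float))
            p_av = interp(u)
            p_a, p_v = p_av[..., 0], p_av[..., 1]
            out = np.stack([p_a, 1.0 - p_a - p_v, p_v], axis=-1)
            return _apply_lapse(out, params.lapse)

        return prob_fn

    @staticmethod
    def _cell_loglik(counts: np.ndarray, probs: np.ndarray) -> float:
        """Sum of counts × log-probabilities; -inf when impossible."""
        with np.errstate(divide="ignore"):
            logp = np.log(probs)
        mask = counts > 0
        if np.any(np.isneginf(logp) & mask):
            return -np.inf
        return float(np.sum(counts[mask] * logp[mask]))

    # ------------------------------------------------------------------
    def pretest_loglik(self, params: ObserverParams,
                       prob_fn=None, counts: Optional[np.ndarray] = None) -> float:
        """Eq.-style multinomial log-likelihood of the pre-test responses."""
        if prob_fn is None:
            prob_fn = self._prob_fn(params, None)
        if counts is None:
            counts = self.pre_counts_total
        probs = prob_fn(self.test_soas + params.beta_pre)
        return self._cell_loglik(counts, probs)

    def posttest_loglik(self, params: ObserverParams,
                        dists: Sequence[ShiftDistribution],
                        prob_fn=None) -> float:
        """Post-test log-likelihood integrating over the shift per session."""
        if len(dists) != len(self.sessions):
            raise ValueError("need one shift distribution per session")
        if prob_fn is None:
            prob_fn = self._prob_fn(params, dists)
        total = 0.0
        for j, dist in enumerate(dists):
            counts = self.post_counts[j]
            if dist.is_point_mass:
                probs = prob_fn(self.test_soas + params.beta_pre + dist.mean)
                total += self._cell_loglik(counts, probs)
                continue
            u = (self.test_soas[None, :] + params.beta_pre
                 + dist.bin_centers[:, None])            # (n_bins, S)
            probs = prob_fn(u.ravel()).reshape(u.shape + (3,))
            with np.errstate(divide="ignore"):
                logp = np.log(probs)
                log_w = np.log(dist.bin_weights)
            lp_bins = np.einsum("sr,nsr->n", counts, np.nan_to_num(
                logp, neginf=-_BIG))
            # restore hard -inf for bins containing impossible responses
            bad = np.any(np.isneginf(logp) & (counts[None] > 0), axis=(1, 2))
            lp_bins[bad] = -np.inf
            session_ll = logsumexp(lp_bins + log_w) + np.log(dist.bin_width)
            if np.isneginf(session_ll):
                return -np.inf
            total += session_ll
        return total

    def loglik(self, params: ObserverParams) -> float:
        """Joint pre + post log-likelihood (deterministic given the seed)."""
        estimator = self._estimator(params)
        dists = self.shift_distributions(params, estimator=estimator)
        prob_fn = self._prob_fn(params, dists, estimator=estimator)
        pre = self.pretest_loglik(params, prob_fn=prob_fn)
        if np.isneginf(pre):
            return -np.inf
        return pre + self.posttest_loglik(params, dists, prob_fn=prob_fn)


# ----------------------------------------------------------------------
# module-level convenience wrappers


def pretest_loglik(data: Dataset, spec: ModelSpec, params: ObserverParams,
                   rng_seed: int = 0, n_samples: int = 10_000) -> float:
    """Log-likelihood of all pre-test responses under one parameter set."""
    engine = JointLikelihoodEngine(data, spec, rng_seed=rng_seed,
                                   n_samples=n_samples, n_reps=2, n_trials=1)
    return engine.pretest_loglik(params)


def posttest_loglik(data: Dataset, spec: ModelSpec, params: ObserverParams,
                    shift_dists: Sequence[ShiftDistribution],
                    rng_seed: int = 0, n_samples: int = 10_000) -> float:
    """Post-test log-likelihood given per-session shift distributions."""
    engine = JointLikelihoodEngine(data, spec, rng_seed=rng_seed,
                                   n_samples=n_samples, n_reps=2, n_trials=1)
    return engine.posttest_loglik(params, shift_dists)


def joint_loglik(data: Dataset, spec: ModelSpec, params: ObserverParams,
                 rng_seed: int = 0, n_samples: int = 10_000,
                 n_reps: int = 1000, n_trials: int = 250,
                 n_bins: int = 100) -> float:
    """Joint pre/post log-likelihood, regenerating shift distributions."""
    engine = JointLikelihoodEngine(data, spec, rng_seed=rng_seed,
                                   n_samples=n_samples, n_reps=n_reps,
                                   n_trials=n_trials, n_bins=n_bins)
    return engine.loglik(params)


# ----------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    """Outcome of a multistart maximum-likelihood fit."""

    model: str
    params: ObserverParams
    loglik: float
    n_params: int
    aic: float
    bic: float
    n_trials: int
    starts: list = field(default_factory=list)
    rng_seed: int = 0
    settings: dict = field(default_factory=dict)
    data_fingerprint: str = ""

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": self.params.to_dict(),
            "loglik": self.loglik,
            "n_params": self.n_params,
            "aic": self.aic,
            "bic": self.bic,
            "n_trials": self.n_trials,
            "starts": self.starts,
            "rng_seed": self.rng_seed,
            "settings": self.settings,
            "data_fingerprint": self.data_fingerprint,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        d = dict(d)
        d["params"] = ObserverParams.from_dict(d["params"])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "FitResult":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _moment_init(data: Dataset, spec: ModelSpec) -> dict:
    """Cheap data-driven initial values for the shared psychometric shape."""
    counts = data.counts("pre").sum(axis=0)
    soas = data.test_soas
    beta0 = -float(soas[np.argmax(counts[:, 1])]) if counts[:, 1].sum() else 0.0
    return {"beta_pre": float(np.clip(beta0, -0.25, 0.25)),
            "tau": 0.07, "criterion": 0.1, "lapse": 0.02}


def _fit_pretest_readout(data: Dataset, spec: ModelSpec,
                         maxfev: int = 1200) -> dict:
    """Quick closed-form fit of the pre-test curves (warm-start helper).

    Fits the measurement-readout psychometric (bias, time constants,
    criterion, lapse) to the pooled pre-test counts; used to seed the full
    joint fit for every model family, since those parameters dominate the
    pre-test likelihood in all of them.
    """
    counts = data.counts("pre").sum(axis=0)
    soas = data.test_soas
    ms = spec.is_modality_specific
    names = (["beta_pre", "tau_a", "tau_v", "criterion", "lapse"] if ms
             else ["beta_pre", "tau", "criterion", "lapse"])
    lo = np.array([{"beta_pre": -0.3, "tau_a": 0.005, "tau_v": 0.005,
                    "tau": 0.005, "criterion": 0.001, "lapse": 1e-4}[n]
                   for n in names])
    hi = np.array([{"beta_pre": 0.3, "tau_a": 0.5, "tau_v": 0.5, "tau": 0.5,
                    "criterion": 0.5, "lapse": 0.2}[n] for n in names])
    init = _moment_init(data, spec)

    def unpack(x):
        d = dict(zip(names, lo + x * (hi - lo)))
        if "tau" in d:
            d["tau_a"] = d["tau_v"] = d.pop("tau")
        return d

    def objective(x):
        d = unpack(np.clip(x, 0.0, 1.0))
        probs = _readout_probs(soas + d["beta_pre"], d["tau_a"], d["tau_v"],
                               d["criterion"], d["lapse"])
        ll = JointLikelihoodEngine._cell_loglik(counts, probs)
        return -ll if np.isfinite(ll) else _BIG

    x0_map = dict(init)
    if ms:
        x0_map["tau_a"] = x0_map["tau_v"] = x0_map.pop("tau")
    x0 = (np.array([x0_map[n] for n in names]) - lo) / (hi - lo)
    res = _minimize_nm(objective, x0, maxfev, xatol=1e-4, fatol=1e-4)
    return unpack(np.clip(res.x, 0.0, 1.0))


_WARM_DEFAULTS = {"sigma_c1": 0.06, "sigma_c2": 0.8, "p_common": 0.5}


def _warm_start_vector(data: Dataset, spec: ModelSpec) -> np.ndarray:
    shape = _fit_pretest_readout(data, spec)
    values = {}
    for name in spec.param_names:
        if name in shape:
            values[name] = shape[name]
        elif name == "tau":
            values[name] = shape.get("tau", shape.get("tau_a", 0.07))
        elif name in _WARM_DEFAULTS:
            values[name] = _WARM_DEFAULTS[name]
        elif name == "alpha":
            values[name] = (0.003 if spec.update_rule
                            is UpdateRule.ASYNCHRONY_CONTINGENT else 0.01)
        else:  # pragma: no cover - all names handled above
            raise KeyError(name)
    return np.array([values[n] for n in spec.param_names])


def _block_descent(engine: JointLikelihoodEngine, spec: ModelSpec,
                   vector: np.ndarray, lo: np.ndarray, hi: np.ndarray,
                   maxfev_per_block: int = 120) -> np.ndarray:
    """Block-coordinate refinement of a warm start for the causal models.

    The pre-test read-out fit mislocates the criterion and lapse for
    causal-inference data (the estimate distribution is compressed toward
    zero relative to the measurement distribution), leaving a full
    9-parameter search in a long curved valley where Nelder-Mead stalls.
    Alternating low-dimensional searches over a causal block (priors,
    learning rate, criterion) and a shape block (bias, time constants,
    criterion, lapse) are far more reliable per function evaluation; the
    result seeds the subsequent full-dimensional polish.
    """
    names = spec.param_names
    idx = {n: i for i, n in enumerate(names)}
    causal = [idx[n] for n in ("sigma_c1", "sigma_c2", "p_common", "alpha")]
    causal_c = causal + [idx["criterion"]]
    shape = [idx[n] for n in names
             if n in ("beta_pre", "tau", "tau_a", "tau_v", "criterion",
                      "lapse")]
    i_s1 = idx["sigma_c1"]
    v = vector.copy()

    def block_objective(free):
        free = np.asarray(free)

        def objective(x_sub):
            trial = v.copy()
            trial[free] = lo[free] + np.clip(x_sub, 0.0, 1.0) \
                * (hi[free] - lo[free])
            if trial[i_s1] >= trial[i_s1 + 1]:
                return _BIG
            ll = engine.loglik(spec.unpack(trial))
            return -ll if np.isfinite(ll) else _BIG

        return objective, free

    for free_names in (causal, shape, causal_c, shape):
        objective, free = block_objective(free_names)
        x0 = (v[free] - lo[free]) / (hi[free] - lo[free])
        res = _minimize_nm(objective, x0, maxfev_per_block)
        v[free] = lo[free] + np.clip(res.x, 0.0, 1.0) * (hi[free] - lo[free])
    return v


def fit_model(data: Dataset, spec: ModelSpec, n_starts: int = 20,
              rng_seed: int = 0, n_samples: int = 10_000, n_reps: int = 1000,
              n_trials: int = 250, n_bins: int = 100,
              maxfev: Optional[int] = None, warm_start: bool = True,
              grid_step: float = 0.005,
              block_maxfev: int = 120) -> FitResult:
    """Multistart bound-constrained maximum-likelihood fit of one model.

    Starting points are Latin-hypercube draws within the documented
    fitting bounds (optimized in unit-cube coordinates with Nelder-Mead);
    when ``warm_start`` is set, the first start is replaced by a cheap
    closed-form fit of the pre-test curves.  All starts are logged; the
    best is returned.  Refitting with the same seed reproduces identical
    results.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    engine = JointLikelihoodEngine(data, spec, rng_seed=rng_seed,
                                   n_samples=n_samples, n_reps=n_reps,
                                   n_trials=n_trials, n_bins=n_bins,
                                   grid_step=grid_step)
    bounds = np.asarray(spec.bounds(), dtype=float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    d = spec.n_params
    names = spec.param_names
    i_s1 = names.index("sigma_c1") if "sigma_c1" in names else None

    def objective(x):
        x = np.clip(x, 0.0, 1.0)
        vec = lo + x * (hi - lo)
        if i_s1 is not None and vec[i_s1] >= vec[i_s1 + 1]:
            return _BIG  # separate-causes prior must be the wider one
        ll = engine.loglik(spec.unpack(vec))
        return -ll if np.isfinite(ll) else _BIG

    sampler = qmc.LatinHypercube(
        d=d, seed=np.random.default_rng(np.random.SeedSequence(rng_seed).spawn(1)[0]))
    starts_unit = sampler.random(n=n_starts)
    if warm_start:
        warm = _warm_start_vector(data, spec)
        if spec.update_rule.is_causal:
            warm = _block_descent(engine, spec, warm, lo, hi,
                                  maxfev_per_block=block_maxfev)
        starts_unit[0] = np.clip((warm - lo) / (hi - lo), 0.0, 1.0)

    maxfev = maxfev or 400 * d
    log, best = [], None
    for x0 in starts_unit:
        res = _minimize_nm(objective, x0, maxfev)
        x_best = np.clip(res.x, 0.0, 1.0)
        ll = -res.fun
        log.append({"x0": (lo + x0 * (hi - lo)).tolist(),
                    "x": (lo + x_best * (hi - lo)).tolist(),
                    "loglik": float(ll), "nfev": int(res.nfev)})
        if best is None or ll > best[0]:
            best = (ll, x_best)
    if best is None or not np.isfinite(best[0]):
        raise RuntimeError(
            "no start converged to a finite log-likelihood; start log: "
            f"{log}"
        )
    ll, x_best = best
    params = spec.unpack(lo + x_best * (hi - lo))
    n_obs = data.n_trials
    return FitResult(
        model=spec.code, params=params, loglik=float(ll), n_params=d,
        aic=2 * d - 2 * ll, bic=d * np.log(n_obs) - 2 * ll, n_trials=n_obs,
        starts=log, rng_seed=rng_seed,
        settings={"n_starts": n_starts, "n_samples": n_samples,
                  "n_reps": n_reps, "n_trials": n_trials, "n_bins": n_bins,
                  "maxfev": maxfev, "warm_start": warm_start,
                  "grid_step": grid_step, "block_maxfev": block_maxfev},
        data_fingerprint=data.fingerprint(),
    )


def compare_models(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Comparison table of several fits of the same dataset.

    Reports maximized log-likelihood, parameter count and AIC/BIC, plus a
    log-Bayes-factor analogue ``0.5 * (AIC_worst - AIC)`` relative to the
    weakest model (by AIC), mirroring comparisons stated against the
    worst-performing model.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    prints = {f.data_fingerprint for f in fits}
    if len(prints) > 1:
        raise ValueError("fits were computed on different datasets")
    rows = [{"model": f.model, "n_params": f.n_params, "loglik": f.loglik,
             "aic": f.aic, "bic": f.bic} for f in fits]
    table = pd.DataFrame(rows)
    worst_aic = table["aic"].max()
    table["log_bf_vs_worst"] = 0.5 * (worst_aic - table["aic"])
    return table
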