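"""Parameter- and model-recovery harnesses on synthetic experiments.

Recovery studies close the loop on the fitting pipeline: simulate
experiments from known ground-truth observers, refit, and check that
parameters come back (parameter recovery) and that the generating model
wins the comparison (model recovery).  Both run at configurable,
reduced Monte-Carlo scale so they stay tractable on a single CPU.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .likelihood import fit_model
from .models import MODEL_CODES, ModelSpec
from .synthetic import ExperimentDesign, generate_observer, simulate_experiment

__all__ = ["parameter_recovery", "model_recovery", "family_confusion"]

#: Fit settings used by default in recovery runs (reduced Monte-Carlo
#: sizes; a warm start from the pre-test curves plus one Latin-hypercube
#: start, with a capped function-evaluation budget).
REDUCED_FIT = {"n_starts": 2, "n_samples": 800, "n_reps": 60,
               "n_bins": 100, "maxfev": 150, "grid_step": 0.0075}


def parameter_recovery(spec: ModelSpec, n_observers: int = 20, rng_seed: int = 0,
                       design: ExperimentDesign | None = None,
                       fit_kwargs: dict | None = None,
                       sim_n_samples: int = 10_000) -> pd.DataFrame:
    """Simulate-and-refit study for one model.

    Returns a tidy frame with one row per (observer, parameter) holding
    the generating and the recovered value.
    """
    design = design or ExperimentDesign()
    kwargs = dict(REDUCED_FIT)
    kwargs.update(fit_kwargs or {})
    root = np.random.SeedSequence(rng_seed)
    rows = []
    for i, seq in enumerate(root.spawn(n_observers)):
        seq_obs, seq_sim, seq_fit = seq.spawn(3)
        observer = generate_observer(spec, rng_seed=seq_obs)
        data = simulate_experiment(spec, observer, design, rng_seed=seq_sim,
                                   n_samples=sim_n_samples)
        fit = fit_model(data, spec,
                        rng_seed=int(seq_fit.generate_state(1)[0] % (2**31)),
                        **kwargs)
        truth = spec.pack(observer)
        est = spec.pack(fit.params)
        for name, t, e in zip(spec.param_names, truth, est):
            rows.append({"observer": i, "param": name, "truth": float(t),
                         "estimate": float(e), "loglik": fit.loglik})
    return pd.DataFrame(rows)


def recovery_correlations(table: pd.DataFrame) -> pd.Series:
    """Pearson correlation truth vs estimate per parameter."""
    return table.groupby("param").apply(
        lambda g: float(np.corrcoef(g["truth"], g["estimate"])[0, 1]),
        include_groups=False)


def model_recovery(generating_codes=MODEL_CODES, candidate_codes=MODEL_CODES,
                   n_observers: int = 5, rng_seed: int = 0,
                   design: ExperimentDesign | None = None,
                   fit_kwargs: dict | None = None,
                   sim_n_samples: int = 10_000,
                   criterion: str = "aic") -> pd.DataFrame:
    """Confusion study: which candidate model wins on data from each generator.

    Returns a frame with one row per synthetic dataset listing the
    generating model and the winner by the penalized-likelihood
    criterion (``aic`` or ``bic``).
    """
    design = design or ExperimentDesign()
    kwargs = dict(REDUCED_FIT)
    kwargs.update(fit_kwargs or {})
    root = np.random.SeedSequence(rng_seed)
    rows = []
    for g, gen_code in enumerate(generating_codes):
        gen_spec = ModelSpec.from_code(gen_code)
        for i, seq in enumerate(root.spawn(len(generating_codes) * n_observers)
                                [g * n_observers:(g + 1) * n_observers]):
            seq_obs, seq_sim, seq_fit = seq.spawn(3)
            observer = generate_observer(gen_spec, rng_seed=seq_obs)
            data = simulate_experiment(gen_spec, observer, design,
                                       rng_seed=seq_sim,
                                       n_samples=sim_n_samples)
            fit_seed = int(seq_fit.generate_state(1)[0] % (2**31))
            scores = {}
            for code in candidate_codes:
                fit = fit_model(data, ModelSpec.from_code(code),
                                rng_seed=fit_seed, **kwargs)
                scores[code] = getattr(fit, criterion)
            winner = min(scores, key=scores.get)
            rows.append({"generating": gen_code, "observer": i,
                         "winner": winner, **{f"{c}_{criterion}": s
                                              for c, s in scores.items()}})
    return pd.DataFrame(rows)


def family_confusion(recovery_table: pd.DataFrame) -> pd.DataFrame:
    """Collapse a model-recovery table to the three update-rule families."""
    def family(code: str) -> str:
        return code.split("_")[0]

    table = recovery_table.assign(
        gen_family=recovery_table["generating"].map(family),
        win_family=recovery_table["winner"].map(family))
    return pd.crosstab(table["gen_family"], table["win_family"])
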