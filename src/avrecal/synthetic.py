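"""Synthetic ternary TOJ experiments with the nine-session study design.

Generates complete pre/exposure/post experiments from any of the observer
models with known ground-truth parameters.  Defaults reproduce the study
design: nine sessions with adapter SOAs ±0.7, ±0.3, ±0.2, ±0.1 and 0 s;
fifteen test SOAs (±0.5 s and -0.3 … 0.3 s in 0.05 s steps), each
repeated 20 times per phase (300 TOJ trials per phase, 5400 per
experiment); 250 exposure trials per session.

Each session simulates ONE realized exposure trajectory — what a single
participant experiences — and generates the post-test at the resulting
shifted bias, while the fitted likelihood integrates over the trajectory
distribution.  This asymmetry is intentional: the generator mimics a
participant, the likelihood mimics the experimenter's uncertainty.  The
bias resets to ``beta_pre`` at the start of every session.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import COLUMNS, Dataset
from .exposure import simulate_exposure
from .models import ModelSpec, ObserverParams, UpdateRule
from .psychometrics import RESPONSES, psychometric_curve

__all__ = ["ExperimentDesign", "generate_observer", "simulate_experiment",
           "PLAUSIBLE_RANGES"]


def _default_test_soas() -> tuple:
    inner = np.round(np.arange(-0.3, 0.3001, 0.05), 10)
    return tuple([-0.5, *inner.tolist(), 0.5])


@dataclass(frozen=True)
class ExperimentDesign:
    """Session structure of the recalibration experiment."""

    adapter_soas: tuple = (-0.7, -0.3, -0.2, -0.1, 0.0, 0.1, 0.2, 0.3, 0.7)
    test_soas: tuple = field(default_factory=_default_test_soas)
    n_repeats: int = 20
    n_exposure_trials: int = 250

    def __post_init__(self) -> None:
        if self.n_repeats < 1 or self.n_exposure_trials < 1:
            raise ValueError("repeat and trial counts must be positive")

    @property
    def n_sessions(self) -> int:
        return len(self.adapter_soas)

    @property
    def trials_per_phase(self) -> int:
        return len(self.test_soas) * self.n_repeats


#: Ground-truth sampling ranges for recovery studies; all inside the
#: fitting bounds, with the separate-causes spread strictly above the
#: common-cause spread.  The contingent-rule learning rate is in seconds
#: (it multiplies a density).
PLAUSIBLE_RANGES = {
    "beta_pre": (-0.15, 0.15),
    "tau_a": (0.02, 0.15),
    "tau_v": (0.02, 0.15),
    "tau": (0.02, 0.15),
    "sigma_c1": (0.01, 0.1),
    "sigma_c2": (0.3, 1.5),
    "p_common": (0.2, 0.9),
    "criterion": (0.04, 0.2),
    "lapse": (0.005, 0.06),
    "alpha": (0.002, 0.02),
    "alpha_contingent": (0.001, 0.01),
}


def generate_observer(spec: ModelSpec, rng_seed=0,
                      plausible_ranges: dict | None = None) -> ObserverParams:
    """Draw ground-truth observer parameters uniformly within plausible ranges."""
    ranges = dict(PLAUSIBLE_RANGES)
    ranges.update(plausible_ranges or {})
    rng = np.random.default_rng(rng_seed)
    values = []
    for name in spec.param_names:
        key = name
        if (name == "alpha"
                and spec.update_rule is UpdateRule.ASYNCHRONY_CONTINGENT):
            key = "alpha_contingent"
        lo, hi = ranges[key]
        if not hi > lo:
            raise ValueError(f"empty range for {key}: ({lo}, {hi})")
        values.append(rng.uniform(lo, hi))
    return spec.unpack(np.array(values))


def _draw_responses(probs: np.ndarray, n_repeats: int, rng) -> list:
    """Multinomial response draws, expanded to per-trial response codes."""
    responses = []
    for row in probs:
        counts = rng.multinomial(n_repeats, row / row.sum())
        codes = sum(([RESPONSES[r]] * int(c) for r, c in enumerate(counts)), [])
        rng.shuffle(codes)
        responses.extend(codes)
    return responses


def simulate_experiment(spec: ModelSpec, observer: ObserverParams,
                        design: ExperimentDesign | None = None, rng_seed=0,
                        n_samples: int = 10_000, participant: str = "synthetic",
                        return_info: bool = False):
    """Simulate a complete experiment from a ground-truth observer.

    Per session: draw pre-test responses from the model's ternary
    probabilities at ``beta_pre``, run one exposure phase to obtain the
    realized cumulative shift, then draw post-test responses at the
    shifted bias.  Returns a :class:`Dataset` (and, with
    ``return_info=True``, a dict with the realized shifts and seeds).
    """
    design = design or ExperimentDesign()
    root = (rng_seed if isinstance(rng_seed, np.random.SeedSequence)
            else np.random.SeedSequence(rng_seed))
    session_seqs = root.spawn(design.n_sessions)
    soas = np.asarray(design.test_soas, dtype=float)

    records = []
    shifts = {}
    for j, (adapter, seq) in enumerate(zip(design.adapter_soas, session_seqs),
                                       start=1):
        seq_pre, seq_exp, seq_post, seq_curve = seq.spawn(4)
        rng_pre = np.random.default_rng(seq_pre)
        rng_post = np.random.default_rng(seq_post)

        pre_probs = psychometric_curve(spec, observer, soas, shift=0.0,
                                       n_samples=n_samples, rng_seed=seq_curve)
        trajectory = simulate_exposure(spec, observer, adapter,
                                       n_trials=design.n_exposure_trials,
                                       rng_seed=seq_exp)
        shift = trajectory.final
        shifts[j] = shift
        post_probs = psychometric_curve(spec, observer, soas, shift=shift,
                                        n_samples=n_samples,
                                        rng_seed=seq_curve)
        for phase, probs, rng in (("pre", pre_probs, rng_pre),
                                  ("post", post_probs, rng_post)):
            responses = _draw_responses(probs, design.n_repeats, rng)
            for t, response in enumerate(responses):
                soa = float(soas[t // design.n_repeats])
                records.append((participant, j, adapter, phase, t + 1,
                                soa, response))

    df = pd.DataFrame(records, columns=COLUMNS)
    data = Dataset(df)
    if return_info:
        info = {"model": spec.code, "observer": observer.to_dict(),
                "realized_shifts": shifts,
                "rng_seed": rng_seed if isinstance(rng_seed, int) else str(rng_seed),
                "n_samples": n_samples}
        return data, info
    return data
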