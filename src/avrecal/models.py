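"""Model specifications and observer parameters for the six observer models.

Three bias-update rules (causal inference, asynchrony-contingent,
asynchrony-correction) crossed with two arrival-latency precision
assumptions (modality-specific: separate ``tau_a``/``tau_v``;
modality-independent: a single shared ``tau``) give six observer models,
identified by the short codes ``ci_ms``, ``ci_mi``, ``ac_ms``, ``ac_mi``,
``corr_ms`` and ``corr_mi``.

``ModelSpec`` owns the free-parameter list and fitting bounds of each
model and converts between flat parameter vectors (for optimizers) and
``ObserverParams``.  Parameter roles:

=============  ==========================================================
``beta_pre``   audiovisual temporal bias before exposure (s)
``tau_a/v``    auditory / visual latency time constants (s)
``sigma_c1``   spread of the common-cause SOA prior (s), causal model only
``sigma_c2``   spread of the separate-causes SOA prior (s), causal only
``p_common``   prior probability of a common cause, causal only
``criterion``  simultaneity criterion c (s) for the ternary judgment and
               the asynchrony-correction exposure rule (shared)
``lapse``      lapse rate, uniform over the three responses
``alpha``      learning rate of the bias update (dimensionless for the
               causal and correction rules; seconds for the contingent
               rule, where it multiplies a density)
=============  ==========================================================
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .causal import CausalPrior
from .measurement import MeasurementModel

__all__ = ["UpdateRule", "Precision", "ModelSpec", "ObserverParams", "MODEL_CODES"]


class UpdateRule(str, Enum):
    CAUSAL_INFERENCE = "causal_inference"
    CAUSAL_INFERENCE_POSTERIOR = "causal_inference_posterior"  # recovery-study variant
    ASYNCHRONY_CONTINGENT = "asynchrony_contingent"
    ASYNCHRONY_CORRECTION = "asynchrony_correction"

    @property
    def is_causal(self) -> bool:
        return self in (UpdateRule.CAUSAL_INFERENCE,
                        UpdateRule.CAUSAL_INFERENCE_POSTERIOR)


class Precision(str, Enum):
    MODALITY_SPECIFIC = "modality_specific"
    MODALITY_INDEPENDENT = "modality_independent"


_RULE_CODE = {
    UpdateRule.CAUSAL_INFERENCE: "ci",
    UpdateRule.CAUSAL_INFERENCE_POSTERIOR: "cip",
    UpdateRule.ASYNCHRONY_CONTINGENT: "ac",
    UpdateRule.ASYNCHRONY_CORRECTION: "corr",
}
_PRECISION_CODE = {
    Precision.MODALITY_SPECIFIC: "ms",
    Precision.MODALITY_INDEPENDENT: "mi",
}

#: The six canonical model identifiers (the posterior-variant causal model
#: is available in addition under ``cip_ms`` / ``cip_mi``).
MODEL_CODES = ("ci_ms", "ci_mi", "ac_ms", "ac_mi", "corr_ms", "corr_mi")

# Fitting bounds.  The alpha bound for the contingent rule is wider on the
# effective-rate scale because alpha multiplies a density there (units s).
_BOUNDS = {
    "beta_pre": (-0.3, 0.3),
    "tau_a": (0.005, 0.5),
    "tau_v": (0.005, 0.5),
    "tau": (0.005, 0.5),
    "sigma_c1": (0.001, 0.3),
    "sigma_c2": (0.05, 3.0),
    "p_common": (0.0, 1.0),
    "criterion": (0.001, 0.5),
    "lapse": (1e-4, 0.2),
    "alpha": (0.0, 0.1),
    "alpha_contingent": (0.0, 0.05),
}


@dataclass(frozen=True)
class ObserverParams:
    """Full parameter set of one observer; fields unused by the model are None."""

    beta_pre: float
    tau_a: float
    tau_v: float
    criterion: float
    lapse: float
    alpha: float
    sigma_c1: Optional[float] = None
    sigma_c2: Optional[float] = None
    p_common: Optional[float] = None

    def measurement_model(self, shift: float = 0.0) -> MeasurementModel:
        """Generative measurement model at bias ``beta_pre + shift``."""
        return MeasurementModel(bias=self.beta_pre + shift,
                                tau_a=self.tau_a, tau_v=self.tau_v)

    def causal_prior(self) -> CausalPrior:
        if self.sigma_c1 is None or self.sigma_c2 is None or self.p_common is None:
            raise ValueError("observer has no causal-prior parameters")
        return CausalPrior(self.sigma_c1, self.sigma_c2, self.p_common)

    def to_dict(self) -> dict:
        return {k: v for k, v in asdict(self).items() if v is not None}

    @classmethod
    def from_dict(cls, d: dict) -> "ObserverParams":
        return cls(**d)

    def replace(self, **kw) -> "ObserverParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class ModelSpec:
    """One of the observer models: update rule × precision assumption."""

    update_rule: UpdateRule
    precision: Precision

    @property
    def code(self) -> str:
        return f"{_RULE_CODE[self.update_rule]}_{_PRECISION_CODE[self.precision]}"

    @classmethod
    def from_code(cls, code: str) -> "ModelSpec":
        rules = {v: k for k, v in _RULE_CODE.items()}
        precisions = {v: k for k, v in _PRECISION_CODE.items()}
        try:
            rule_code, prec_code = code.split("_")
            return cls(rules[rule_code], precisions[prec_code])
        except (ValueError, KeyError):
            raise ValueError(
                f"unknown model code {code!r}; valid codes are "
                f"{', '.join(MODEL_CODES)}"
            ) from None

    @property
    def is_modality_specific(self) -> bool:
        return self.precision is Precision.MODALITY_SPECIFIC

    @property
    def param_names(self) -> tuple[str, ...]:
        names = ["beta_pre"]
        names += ["tau_a", "tau_v"] if self.is_modality_specific else ["tau"]
        if self.update_rule.is_causal:
            names += ["sigma_c1", "sigma_c2", "p_common"]
        names += ["criterion", "lapse", "alpha"]
        return tuple(names)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def bounds(self) -> list[tuple[float, float]]:
        out = []
        for name in self.param_names:
            if name == "alpha" and self.update_rule is UpdateRule.ASYNCHRONY_CONTINGENT:
                out.append(_BOUNDS["alpha_contingent"])
            else:
                out.append(_BOUNDS[name])
        return out

    def pack(self, params: ObserverParams) -> np.ndarray:
        """Flatten an ``ObserverParams`` to the model's free-parameter vector."""
        values = []
        for name in self.param_names:
            if name == "tau":
                if params.tau_a != params.tau_v:
                    raise ValueError(
                        "modality-independent model requires tau_a == tau_v"
                    )
                values.append(params.tau_a)
            else:
                value = getattr(params, name)
                if value is None:
                    raise ValueError(f"parameter {name} missing from observer")
                values.append(value)
        return np.asarray(values, dtype=float)

    def unpack(self, vector: Sequence[float]) -> ObserverParams:
        """Build an ``ObserverParams`` from a free-parameter vector."""
        vector = np.asarray(vector, dtype=float)
        if vector.shape != (self.n_params,):
            raise ValueError(
                f"expected {self.n_params} parameters for {self.code}, "
                f"got shape {vector.shape}"
            )
        d = dict(zip(self.param_names, vector.tolist()))
        if "tau" in d:
            tau = d.pop("tau")
            d["tau_a"] = d["tau_v"] = tau
        return ObserverParams(**d)
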