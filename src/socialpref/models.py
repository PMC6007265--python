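"""Social-utility models of responder behavior.

Nine competing accounts of how a responder values post-punishment payoffs
``X_resp`` (own) and ``X_prop`` (proposer's):

* ``FS_unconstrained`` / ``FS_standard`` — Fehr–Schmidt inequity aversion,
  ``U = P_reward·X_resp − α·max(X_prop−X_resp, 0) − β·max(X_resp−X_prop, 0)``;
  the standard variant imposes ``α ≥ β`` and ``0 ≤ β < 1``, the unconstrained
  variant allows inequality *seeking* (negative weights).
* ``TotalReward``, ``RewardDifference``, ``ProposerReward``,
  ``LinearCombination`` — component models built from payoff sums,
  differences or single payoffs.
* ``CharnessRabin`` — efficiency/reciprocity weighting,
  ``U = (ρr + σs + θq)·X_prop + (1 − ρr − σs − θq)·X_resp`` with indicators
  r = AI, s = DI, and q = −1 when the proposer misbehaved (transfer < 50).
* ``FS_RT`` — Fehr–Schmidt extended with a response-time term ``− P_RT·RT``
  (RT as a proxy for choice difficulty); ``RT_only`` keeps just that term.

Every model is linear in its parameters, so each is represented by a design
row (regressor values per trial) plus, for Charness–Rabin, a fixed offset
``X_resp`` whose coefficient is pinned at 1 by the functional form.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Mapping, Sequence, Tuple

import numpy as np

from .task import Trial

__all__ = [
    "ModelSpec",
    "PreferenceParams",
    "MODEL_REGISTRY",
    "BEHAVIORAL_MODELS",
    "NEURAL_MODELS",
    "get_model",
    "utility",
    "design_row",
    "design_matrix",
    "offsets",
    "is_nested",
]

FAIR_TRANSFER = 50  # transfer below this counts as proposer misbehavior (q = −1)


def _fs_regressors(t: Trial) -> Tuple[float, ...]:
    xr, xp = float(t.payoff_responder), float(t.payoff_proposer)
    return (xr, -max(xp - xr, 0.0), -max(xr - xp, 0.0))


def _cr_regressors(t: Trial) -> Tuple[float, ...]:
    xr, xp = float(t.payoff_responder), float(t.payoff_proposer)
    r = 1.0 if xr > xp else 0.0
    s = 1.0 if xr < xp else 0.0
    q = -1.0 if t.transfer < FAIR_TRANSFER else 0.0
    return (r * (xp - xr), s * (xp - xr), q * (xp - xr))


@dataclass(frozen=True)
class ModelSpec:
    """A utility model as a named, ordered set of linear regressors."""

    model_id: str
    param_names: Tuple[str, ...]
    regressor_names: Tuple[str, ...]
    design_fn: Callable[[Trial], Tuple[float, ...]]
    offset_name: str | None = None  # regressor with coefficient fixed at 1
    constrained: bool = False  # Standard FS bounds

    @property
    def k(self) -> int:
        """Number of free parameters."""
        return len(self.param_names)

    def offset(self, t: Trial) -> float:
        if self.offset_name == "x_resp":
            return float(t.payoff_responder)
        return 0.0


def _spec(model_id: str, params: Sequence[str], regs: Sequence[str],
          fn: Callable[[Trial], Tuple[float, ...]],
          offset: str | None = None, constrained: bool = False) -> ModelSpec:
    return ModelSpec(model_id, tuple(params), tuple(regs), fn, offset, constrained)


def _cr_restricted(keep: Tuple[int, ...]) -> Callable[[Trial], Tuple[float, ...]]:
    def fn(t: Trial) -> Tuple[float, ...]:
        full = _cr_regressors(t)
        return tuple(full[i] for i in keep)
    return fn


MODEL_REGISTRY: Dict[str, ModelSpec] = {
    m.model_id: m for m in [
        _spec("FS_unconstrained", ("p_reward_responder", "alpha", "beta"),
              ("x_resp", "neg_di", "neg_ai"), _fs_regressors),
        _spec("FS_standard", ("p_reward_responder", "alpha", "beta"),
              ("x_resp", "neg_di", "neg_ai"), _fs_regressors, constrained=True),
        _spec("TotalReward", ("p_reward_total",), ("total",),
              lambda t: (float(t.payoff_responder + t.payoff_proposer),)),
        _spec("RewardDifference", ("p_reward_difference",), ("diff",),
              lambda t: (float(t.payoff_responder - t.payoff_proposer),)),
        _spec("ProposerReward", ("p_reward_proposer",), ("x_prop",),
              lambda t: (float(t.payoff_proposer),)),
        _spec("LinearCombination", ("p_reward_responder", "p_reward_proposer"),
              ("x_resp", "x_prop"),
              lambda t: (float(t.payoff_responder), float(t.payoff_proposer))),
        _spec("CharnessRabin", ("rho", "sigma", "theta"),
              ("cr_r", "cr_s", "cr_q"), _cr_regressors, offset="x_resp"),
        _spec("FS_RT", ("p_reward_responder", "alpha", "beta", "p_rt"),
              ("x_resp", "neg_di", "neg_ai", "neg_rt"),
              lambda t: _fs_regressors(t) + (-float(t.rt),)),
        _spec("RT_only", ("p_rt",), ("neg_rt",), lambda t: (-float(t.rt),)),
        # Two-parameter Charness–Rabin restrictions (one weight pinned to 0);
        # available for exploratory fits, excluded from default comparisons.
        _spec("CharnessRabin_theta0", ("rho", "sigma"), ("cr_r", "cr_s"),
              _cr_restricted((0, 1)), offset="x_resp"),
        _spec("CharnessRabin_sigma0", ("rho", "theta"), ("cr_r", "cr_q"),
              _cr_restricted((0, 2)), offset="x_resp"),
        _spec("CharnessRabin_rho0", ("sigma", "theta"), ("cr_s", "cr_q"),
              _cr_restricted((1, 2)), offset="x_resp"),
    ]
}

#: Models entering the default behavioral comparison (registry order fixes ties).
BEHAVIORAL_MODELS: Tuple[str, ...] = (
    "FS_unconstrained", "FS_standard", "TotalReward", "RewardDifference",
    "ProposerReward", "LinearCombination", "CharnessRabin", "FS_RT", "RT_only")

#: Standard FS fits the behavioral data so poorly it is dropped for neural data.
NEURAL_MODELS: Tuple[str, ...] = tuple(
    m for m in BEHAVIORAL_MODELS if m != "FS_standard")


def get_model(model_id: str) -> ModelSpec:
    try:
        return MODEL_REGISTRY[model_id]
    except KeyError:
        raise KeyError(f"unknown model id {model_id!r}; "
                       f"known: {sorted(MODEL_REGISTRY)}") from None


@dataclass(frozen=True)
class PreferenceParams:
    """A parameter vector tagged with the model it belongs to."""

    model_id: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        spec = get_model(self.model_id)
        missing = set(spec.param_names) - set(self.values)
        extra = set(self.values) - set(spec.param_names)
        if missing or extra:
            raise ValueError(
                f"params for {self.model_id} must be exactly {spec.param_names}; "
                f"missing={sorted(missing)}, extra={sorted(extra)}")
        if spec.constrained:
            a, b = self.values["alpha"], self.values["beta"]
            if not (a >= b and 0.0 <= b < 1.0):
                raise ValueError(
                    f"Standard FS requires alpha >= beta and 0 <= beta < 1, "
                    f"got alpha={a}, beta={b}")

    def as_vector(self) -> np.ndarray:
        spec = get_model(self.model_id)
        return np.array([self.values[p] for p in spec.param_names], dtype=float)

    def __getitem__(self, name: str) -> float:
        return float(self.values[name])


def design_row(trial: Trial, model_id: str) -> np.ndarray:
    """Regressor values of one trial under one model (offset excluded)."""
    return np.asarray(get_model(model_id).design_fn(trial), dtype=float)


def design_matrix(trials: Sequence[Trial], model_id: str) -> np.ndarray:
    """Stacked design rows, shape ``(n_trials, k)``."""
    spec = get_model(model_id)
    return np.array([spec.design_fn(t) for t in trials], dtype=float)


def offsets(trials: Sequence[Trial], model_id: str) -> np.ndarray:
    """Fixed-coefficient offset per trial (zero for all but Charness–Rabin)."""
    spec = get_model(model_id)
    return np.array([spec.offset(t) for t in trials], dtype=float)


def utility(trial: Trial, params: PreferenceParams) -> float:
    """Scalar utility of one trial under the parameterized model."""
    row = design_row(trial, params.model_id)
    spec = get_model(params.model_id)
    return float(row @ params.as_vector() + spec.offset(trial))


def is_nested(reduced: str, full: str) -> bool:
    """True when the reduced model's regressors are a subset of the full's.

    Nesting also requires identical fixed offsets, so Charness–Rabin variants
    nest only within the Charness–Rabin family.
    """
    r, f = get_model(reduced), get_model(full)
    return (set(r.regressor_names) <= set(f.regressor_names)
            and r.offset_name == f.offset_name)
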