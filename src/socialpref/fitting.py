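"""Model fitting: behavioral least squares and robust neural regression.

Behavioral punishment amounts and per-window hemodynamic values are first
standardized to [-1, 1] per participant (behavior) or per participant-
channel (neural), then regressed on each utility model's design.  All
models except Standard FS are linear in their parameters, so the default
behavioral solver is closed-form least squares; a multi-start nonlinear
least-squares path exists for every model (and is the only solver that can
honor Standard FS's ``alpha >= beta``, ``0 <= beta < 1`` constraints, via
the reparametrization ``alpha = beta + delta`` with ``delta >= 0``).  The
two solvers agree to numerical precision on linear models and the test
suite pins that equivalence.

Neural fits use iteratively reweighted least squares with the "fair"
weight function ``w(r) = 1 / (1 + |r / (c*s)|)``, c = 1.3998, where s is
the median absolute deviation of the residuals divided by 0.6745.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .models import (PreferenceParams, design_matrix, get_model, offsets)
from .nirs import REGION_CHANNELS
from .task import TaskConfig, Trial

__all__ = [
    "FitOptions",
    "FitResult",
    "standardize",
    "fit_behavior",
    "fit_neural_cell",
    "fit_neural",
    "average_hemispheres",
    "fit_results_frame",
]

#: Multi-start sampling ranges per parameter name.
START_RANGES: Mapping[str, Tuple[float, float]] = {
    "alpha": (-2.0, 2.0), "beta": (-2.0, 2.0),
    "rho": (-2.0, 2.0), "sigma": (-2.0, 2.0), "theta": (-2.0, 2.0),
    "p_reward_responder": (-1.0, 1.0), "p_reward_total": (-1.0, 1.0),
    "p_reward_difference": (-1.0, 1.0), "p_reward_proposer": (-1.0, 1.0),
    "p_rt": (-1.0, 1.0),
}

BETA_UPPER = 1.0 - 1e-6  # strict beta < 1 bound for Standard FS


@dataclass(frozen=True)
class FitOptions:
    n_starts: int = 20
    seed: int = 0
    solver: str = "auto"  # "auto" | "ols" | "nls"
    xtol: float = 1e-10
    max_irls_iter: int = 50
    irls_tol: float = 1e-8
    fair_c: float = 1.3998


@dataclass
class FitResult:
    """One fitted model on one dataset (per channel/window for neural)."""

    participant_id: int | str
    model_id: str
    params: PreferenceParams
    rss: float
    mse: float
    n: int
    k: int
    converged: bool = True
    n_starts_used: int = 1
    channel: int | None = None
    window: int | None = None

    def __post_init__(self) -> None:
        assert abs(self.mse - self.rss / self.n) < 1e-9 * max(1.0, self.rss)


def standardize(values: Sequence[float]) -> np.ndarray:
    """Affinely map values to [-1, 1]; a constant vector maps to zeros."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("standardize requires at least one value")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return 2.0 * (x - lo) / (hi - lo) - 1.0


def _ols(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    return coef


def _multistart_nls(x: np.ndarray, y: np.ndarray, param_names: Sequence[str],
                    opts: FitOptions, constrained: bool,
                    ) -> Tuple[np.ndarray, bool, int]:
    """Best-of-N nonlinear least squares; returns (theta, converged, n_used)."""
    rng = np.random.default_rng(opts.seed)
    k = len(param_names)
    best_cost, best_theta, any_ok = np.inf, np.zeros(k), False

    if constrained:
        # theta = (p_reward, delta, beta); alpha = beta + delta
        def resid(th):
            p, delta, beta = th
            alpha = beta + delta
            return x @ np.array([p, alpha, beta]) - y
        lb = np.array([-np.inf, 0.0, 0.0])
        ub = np.array([np.inf, np.inf, BETA_UPPER])
    else:
        def resid(th):
            return x @ th - y
        lb, ub = -np.inf, np.inf

    n_used = 0
    for _ in range(opts.n_starts):
        th0 = np.array([rng.uniform(*START_RANGES.get(p, (-1.0, 1.0)))
                        for p in param_names])
        if constrained:
            # map a raw (p, alpha, beta) draw into the feasible box
            beta0 = float(np.clip(th0[2], 0.0, BETA_UPPER))
            delta0 = max(th0[1] - beta0, 0.0)
            th0 = np.array([th0[0], delta0, beta0])
        n_used += 1
        try:
            sol = least_squares(resid, th0, bounds=(lb, ub),
                                xtol=opts.xtol, ftol=opts.xtol, gtol=None)
        except Exception:
            continue
        if sol.cost < best_cost:
            best_cost, best_theta, any_ok = sol.cost, sol.x, sol.success or any_ok
            any_ok = any_ok or sol.success
    if constrained:
        p, delta, beta = best_theta
        best_theta = np.array([p, beta + delta, beta])
    return best_theta, any_ok, n_used


def _as_trials(trials, cfg: TaskConfig | None) -> List[Trial]:
    if isinstance(trials, pd.DataFrame):
        from .cohort import trials_from_frame
        return trials_from_frame(trials, cfg)
    return list(trials)


def fit_behavior(trials, model_id: str, options: FitOptions | None = None,
                 participant_id: int | str = 0,
                 cfg: TaskConfig | None = None) -> FitResult:
    """Fit one model to one participant's standardized punishments."""
    opts = options or FitOptions()
    tlist = _as_trials(trials, cfg)
    spec = get_model(model_id)
    if len(tlist) < spec.k + 2:
        raise ValueError(f"need at least {spec.k + 2} trials to fit {model_id}")
    y = standardize([t.punishment for t in tlist])
    x = design_matrix(tlist, model_id)
    target = y - offsets(tlist, model_id)

    solver = opts.solver
    if solver == "auto":
        solver = "nls" if spec.constrained else "ols"
    if solver == "ols" and spec.constrained:
        raise ValueError("Standard FS requires the NLS solver")

    if solver == "ols":
        theta, ok, n_used = _ols(x, target), True, 1
    else:
        theta, ok, n_used = _multistart_nls(x, target, spec.param_names, opts,
                                            spec.constrained)
    resid = x @ theta - target
    rss = float(resid @ resid)
    return FitResult(
        participant_id=participant_id, model_id=model_id,
        params=PreferenceParams(model_id, dict(zip(spec.param_names, theta))),
        rss=rss, mse=rss / len(tlist), n=len(tlist), k=spec.k,
        converged=bool(ok), n_starts_used=n_used)


def _irls_fair(x: np.ndarray, y: np.ndarray, opts: FitOptions,
               ) -> Tuple[np.ndarray, bool]:
    """Robust linear regression with the fair weight function."""
    if np.linalg.matrix_rank(x) < x.shape[1]:
        return _ols(x, y), False
    theta = _ols(x, y)
    for _ in range(opts.max_irls_iter):
        resid = y - x @ theta
        s = np.median(np.abs(resid - np.median(resid))) / 0.6745
        if s < 1e-12:
            return theta, True
        w = 1.0 / (1.0 + np.abs(resid / (opts.fair_c * s)))
        sw = np.sqrt(w)
        new = _ols(x * sw[:, None], y * sw)
        if np.max(np.abs(new - theta)) < opts.irls_tol:
            return new, True
        theta = new
    return theta, False


def fit_neural_cell(y: Sequence[float], trials, model_id: str,
                    options: FitOptions | None = None,
                    participant_id: int | str = 0,
                    channel: int | None = None, window: int | None = None,
                    cfg: TaskConfig | None = None,
                    prestandardized: bool = False) -> FitResult:
    """Robust fit of one model to one channel-window's values across trials.

    ``y`` should already be standardized per channel when
    ``prestandardized=True``; otherwise it is standardized here.
    """
    opts = options or FitOptions()
    tlist = _as_trials(trials, cfg)
    spec = get_model(model_id)
    if spec.constrained:
        raise ValueError("Standard FS is not fitted to neural data")
    if len(tlist) < spec.k + 2:
        raise ValueError(f"need at least {spec.k + 2} trials to fit {model_id}")
    yv = np.asarray(y, dtype=float)
    if not prestandardized:
        yv = standardize(yv)
    x = design_matrix(tlist, model_id)
    target = yv - offsets(tlist, model_id)
    theta, ok = _irls_fair(x, target, opts)
    resid = x @ theta - target
    rss = float(resid @ resid)
    return FitResult(
        participant_id=participant_id, model_id=model_id,
        params=PreferenceParams(model_id, dict(zip(spec.param_names, theta))),
        rss=rss, mse=rss / len(tlist), n=len(tlist), k=spec.k,
        converged=ok, channel=channel, window=window)


def fit_neural(windows: np.ndarray, trials, model_ids: Sequence[str],
               options: FitOptions | None = None,
               participant_id: int | str = 0,
               cfg: TaskConfig | None = None,
               channel_labels: Sequence[int | str] | None = None,
               ) -> List[FitResult]:
    """Fit models per channel x window on a ``(n_trials, n_ch, n_win)`` array.

    The dependent variable of each regression (one channel, one window,
    values across trials) is standardized to [-1, 1], so residual scales -
    and hence AIC - are comparable across windows regardless of where the
    hemodynamic response places its energy.
    """
    windows = np.asarray(windows, dtype=float)
    n_trials, n_ch, n_win = windows.shape
    labels = list(channel_labels) if channel_labels is not None \
        else list(range(1, n_ch + 1))
    out: List[FitResult] = []
    for c in range(n_ch):
        z = np.column_stack([standardize(windows[:, c, w])
                             for w in range(n_win)])
        for w in range(n_win):
            for mid in model_ids:
                out.append(fit_neural_cell(
                    z[:, w], trials, mid, options,
                    participant_id=participant_id, channel=labels[c],
                    window=w, cfg=cfg, prestandardized=True))
    return out


def average_hemispheres(windows: np.ndarray,
                        regions: Mapping[str, Sequence[int]] | None = None,
                        ) -> Dict[str, np.ndarray]:
    """Average channels within each region (pooling both hemispheres).

    Input ``(n_trials, n_channels, n_windows)``; output maps region name to
    ``(n_trials, 1, n_windows)`` so the result feeds directly into
    :func:`fit_neural`.
    """
    regions = dict(regions) if regions is not None else dict(REGION_CHANNELS)
    n_ch = windows.shape[1]
    for name, chans in regions.items():
        bad = [c for c in chans if not (0 <= c < n_ch)]
        if bad:
            raise ValueError(f"region {name!r} maps unknown channels {bad}")
    return {name: windows[:, list(chans), :].mean(axis=1, keepdims=True)
            for name, chans in regions.items()}


def fit_results_frame(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Tidy one-row-per-fit table (parameters expanded into columns)."""
    rows = []
    for f in fits:
        row = {"participant_id": f.participant_id, "model_id": f.model_id,
               "rss": f.rss, "mse": f.mse, "n": f.n, "k": f.k,
               "converged": f.converged, "n_starts_used": f.n_starts_used,
               "channel": f.channel, "window": f.window}
        row.update({f"param_{k}": v for k, v in f.params.values.items()})
        rows.append(row)
    return pd.DataFrame(rows)
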