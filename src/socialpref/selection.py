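"""Model comparison: AIC on least-squares fits, nested F-tests, null model.

AIC is computed in its least-squares form, ``AIC = n*ln(RSS/n) + 2*(k+1)``,
counting the residual variance as one extra fitted quantity; the same
formula is applied to behavioral and neural fits so rankings are
comparable.  Nested models (regressor subsets) are compared with the
standard extra-sum-of-squares F-test.  A null reference "model" draws
uniform values on [-1, 1] and scores their MSE against the standardized
data.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .fitting import FitResult
from .models import MODEL_REGISTRY, is_nested

__all__ = [
    "ModelComparison",
    "aic",
    "nested_f",
    "null_model_mse",
    "compare_models",
]

_AIC_FLOOR = -1e12  # sentinel for a perfect (zero-RSS) fit


def aic(rss: float, n: int, k: int) -> float:
    """Least-squares AIC; smaller is better."""
    if n <= k:
        raise ValueError(f"AIC requires n > k, got n={n}, k={k}")
    if rss <= 0.0:
        warnings.warn("zero RSS: returning sentinel minimal AIC",
                      RuntimeWarning, stacklevel=2)
        return _AIC_FLOOR
    return float(n * np.log(rss / n) + 2 * (k + 1))


def nested_f(fit_reduced: FitResult, fit_full: FitResult,
             ) -> Tuple[float, int, int, float]:
    """Extra-sum-of-squares F-test of the full against the reduced model."""
    if not is_nested(fit_reduced.model_id, fit_full.model_id):
        raise ValueError(
            f"{fit_reduced.model_id} is not nested in {fit_full.model_id}")
    if fit_reduced.n != fit_full.n:
        raise ValueError("nested F-test requires fits on the same data")
    df1 = fit_full.k - fit_reduced.k
    df2 = fit_full.n - fit_full.k
    if df1 <= 0 or df2 <= 0:
        raise ValueError(f"invalid degrees of freedom df1={df1}, df2={df2}")
    num = (fit_reduced.rss - fit_full.rss) / df1
    den = fit_full.rss / df2
    f = num / den if den > 0 else np.inf
    p = float(sps.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    return float(f), df1, df2, p


def null_model_mse(values: Sequence[float], rng: np.random.Generator) -> float:
    """MSE of the standardized data against uniform(-1, 1) random guesses."""
    y = np.asarray(values, dtype=float)
    draws = rng.uniform(-1.0, 1.0, size=y.shape)
    return float(np.mean((y - draws) ** 2))


_REGISTRY_ORDER = {m: i for i, m in enumerate(MODEL_REGISTRY)}


@dataclass
class ModelComparison:
    """Cross-model comparison over a cohort of fits."""

    table: pd.DataFrame  # per participant x model (x window): aic, mse, rank
    mean_aic: pd.Series  # per model (behavioral) / best-window mean (neural)
    mean_mse: pd.Series
    anova: Dict[str, float]
    pairwise: pd.DataFrame
    window_profile: pd.DataFrame | None = None  # neural: mean AIC per window
    best_model: str = ""


def compare_models(fits: Sequence[FitResult], scope: str = "behavioral",
                   null_mses: Dict[int | str, float] | None = None,
                   ) -> ModelComparison:
    """Build AIC/MSE comparison tables from a collection of fits.

    Behavioral scope expects one fit per participant x model; neural scope
    one per participant x model x window (single channel/region).  The
    neural mean-AIC ranking is taken at each model's AIC-vs-window profile,
    and ``window_profile`` records the full profile.  A missing model simply
    does not appear.  ``null_mses`` (participant -> MSE from
    :func:`null_model_mse`) joins the MSE ANOVA as model "Null".
    """
    rows = []
    for f in fits:
        rows.append({"participant_id": f.participant_id,
                     "model_id": f.model_id, "window": f.window,
                     "rss": f.rss, "mse": f.mse,
                     "aic": aic(f.rss, f.n, f.k) if f.rss > 0 else _AIC_FLOOR})
    table = pd.DataFrame(rows)

    if scope == "neural":
        profile = (table.groupby(["model_id", "window"])["aic"]
                   .mean().rename("mean_aic").reset_index())
        best_win = profile.loc[profile.groupby("model_id")["mean_aic"].idxmin()]
        mean_aic = best_win.set_index("model_id")["mean_aic"]
        per_pm = (table.groupby(["participant_id", "model_id"])
                  .agg(aic=("aic", "mean"), mse=("mse", "mean")).reset_index())
    else:
        profile = None
        per_pm = table.copy()
        mean_aic = per_pm.groupby("model_id")["aic"].mean()

    per_pm["_reg"] = per_pm.model_id.map(_REGISTRY_ORDER).fillna(99)
    per_pm = per_pm.sort_values(["participant_id", "aic", "_reg"])
    per_pm["rank"] = per_pm.groupby("participant_id").cumcount() + 1
    per_pm = (per_pm.drop(columns="_reg")
              .sort_values(["participant_id", "model_id"])
              .reset_index(drop=True))
    mean_mse = per_pm.groupby("model_id")["mse"].mean()

    # one-way ANOVA of per-participant MSEs across models (+ optional null)
    mse_groups = {m: g["mse"].to_numpy()
                  for m, g in per_pm.groupby("model_id")}
    if null_mses:
        mse_groups["Null"] = np.asarray(list(null_mses.values()), dtype=float)
    anova: Dict[str, float] = {}
    if len(mse_groups) >= 2 and all(len(v) >= 2 for v in mse_groups.values()):
        fstat, pval = sps.f_oneway(*mse_groups.values())
        k_groups = len(mse_groups)
        n_total = sum(len(v) for v in mse_groups.values())
        anova = {"F": float(fstat), "p": float(pval),
                 "df1": k_groups - 1, "df2": n_total - k_groups}

    pairs = list(itertools.combinations(sorted(mse_groups), 2))
    prows = []
    for a, b in pairs:
        with np.errstate(invalid="ignore"):
            t, p = sps.ttest_ind(mse_groups[a], mse_groups[b])
        prows.append({"model_a": a, "model_b": b, "t": float(t),
                      "p_bonferroni": min(1.0, float(p) * len(pairs))})
    pairwise = pd.DataFrame(prows)

    order = mean_aic.sort_values().index
    best = min(order[mean_aic[order] == mean_aic.min()],
               key=lambda m: _REGISTRY_ORDER.get(m, 99))
    return ModelComparison(table=per_pm, mean_aic=mean_aic, mean_mse=mean_mse,
                           anova=anova, pairwise=pairwise,
                           window_profile=profile, best_model=best)
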