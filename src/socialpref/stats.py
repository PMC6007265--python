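"""Psychometric–neurometric statistics.

Robust correlation between behaviorally and neurally estimated preference
parameters (percentage-bend correlation, Wilcox's estimator with bending
constant 0.2), Fisher r-to-z comparison of correlations, factorial ANOVA
with Bonferroni post-hocs, and linear support-vector regression predicting
the behavioral utility series from the neural one on a 50% holdout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PBCorrResult",
    "PredictionResult",
    "percentage_bend_correlation",
    "compare_correlations",
    "factorial_anova",
    "predict_behavior_from_neural",
]


@dataclass(frozen=True)
class PBCorrResult:
    r: float
    n: int
    bending_constant: float
    p: float


def _pb_psi_scores(x: np.ndarray, beta: float) -> np.ndarray:
    """Winsorized standardized scores Psi(U) for one margin."""
    n = x.size
    med = np.median(x)
    m = int(np.floor((1.0 - beta) * n + 0.5))
    omega = np.sort(np.abs(x - med))[m - 1]
    if omega <= 0:
        raise ValueError("degenerate margin: bend scale omega is zero")
    z = (x - med) / omega
    i1 = int(np.sum(z < -1.0))
    i2 = int(np.sum(z > 1.0))
    sx = float(np.sum(x[(z >= -1.0) & (z <= 1.0)]))
    phi = (omega * (i2 - i1) + sx) / (n - i1 - i2)
    u = (x - phi) / omega
    return np.clip(u, -1.0, 1.0)


def percentage_bend_correlation(x: Sequence[float], y: Sequence[float],
                                beta: float = 0.2) -> PBCorrResult:
    """Wilcox's percentage-bend correlation.

    Robust to marginal outliers: each margin is recentred at a bend-
    winsorized location and scores beyond the (1-beta) quantile of absolute
    deviations are clamped before correlating.  p-value from the usual
    t(n-2) reference.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    if not (0.0 < beta <= 0.5):
        raise ValueError("bending constant must be in (0, 0.5]")
    a = _pb_psi_scores(x, beta)
    b = _pb_psi_scores(y, beta)
    r = float(np.sum(a * b) / np.sqrt(np.sum(a * a) * np.sum(b * b)))
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return PBCorrResult(r=r, n=n, bending_constant=beta, p=p)


def compare_correlations(r1: float, n1: int, r2: float, n2: int,
                         method: str = "independent",
                         r_shared: float | None = None,
                         ) -> Tuple[float, float]:
    """Compare two correlation coefficients after Fisher's r-to-z transform.

    ``method="independent"`` (default): two-sample z-test,
    ``z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3))``.
    ``method="steiger"``: Steiger's test for two dependent correlations
    sharing one variable within a single sample (``n1 == n2``); requires
    ``r_shared``, the correlation between the two non-shared variables.
    Returns ``(z, two_sided_p)``.
    """
    for n in (n1, n2):
        if n <= 3:
            raise ValueError("need n > 3 per sample")
    for r in (r1, r2):
        if not -1.0 < r < 1.0:
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    if method == "independent":
        z = (z1 - z2) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    elif method == "steiger":
        if n1 != n2:
            raise ValueError("steiger requires a single sample (n1 == n2)")
        if r_shared is None:
            raise ValueError("steiger requires r_shared")
        n = n1
        rbar2 = ((r1 + r2) / 2.0) ** 2
        cov = (r_shared * (1.0 - 2.0 * rbar2)
               - 0.5 * rbar2 * (1.0 - 2.0 * rbar2 - r_shared ** 2))
        cov /= (1.0 - rbar2) ** 2
        z = (z1 - z2) * np.sqrt((n - 3) / (2.0 - 2.0 * cov))
    else:
        raise ValueError(f"unknown method {method!r}")
    p = float(2.0 * sps.norm.sf(abs(z)))
    return float(z), p


def factorial_anova(data: pd.DataFrame, dv: str, factors: Sequence[str],
                    posthoc_factor: str | None = None,
                    ) -> Dict[str, pd.DataFrame]:
    """Fully-crossed factorial ANOVA (type-II SS) with Bonferroni post-hocs.

    Returns ``{"anova": table, "posthoc": pairwise}`` where the post-hoc
    table compares levels of ``posthoc_factor`` (default: last factor) with
    two-sample t-tests, p-values multiplied by the number of pairs.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    cells = data.groupby(list(factors), observed=True).size()
    full = itertools.product(*[data[f].unique() for f in factors])
    for cell in full:
        if cell not in cells.index:
            raise ValueError(f"empty design cell {dict(zip(factors, cell))}")

    d = data.rename(columns={dv: "_dv"})
    rhs = " * ".join(f"C({f})" for f in factors)
    model = smf.ols(f"_dv ~ {rhs}", data=d).fit()
    table = sm.stats.anova_lm(model, typ=2)

    pf = posthoc_factor or factors[-1]
    levels = list(pd.unique(data[pf]))
    pairs = list(itertools.combinations(levels, 2))
    rows = []
    for a, b in pairs:
        va = data.loc[data[pf] == a, dv].to_numpy()
        vb = data.loc[data[pf] == b, dv].to_numpy()
        t, p = sps.ttest_ind(va, vb)
        rows.append({"level_a": a, "level_b": b, "t": float(t),
                     "p_bonferroni": min(1.0, float(p) * len(pairs))})
    return {"anova": table, "posthoc": pd.DataFrame(rows)}


@dataclass(frozen=True)
class PredictionResult:
    participant_id: int | str
    region: str
    r_squared: float
    window_index: int
    holdout_fraction: float = 0.5


def predict_behavior_from_neural(
        behavior_utilities: Sequence[float],
        neural_utilities: Mapping[str, np.ndarray],
        window_starts: Sequence[float],
        participant_id: int | str = 0,
        punishment_onset: float = 5.0,
        holdout: float = 0.5,
        seed: int = 0) -> List[PredictionResult]:
    """Linear SVR prediction of the behavioral utility series per region.

    ``neural_utilities[region]`` has shape ``(n_trials, n_windows)``.  For
    each window starting at or after the punishment-phase onset (5 s after
    transfer onset), a linear support-vector regression (C=1, epsilon=0.1)
    is trained on a seeded 50% split and scored by holdout R-squared; the
    per-region result keeps the best window.  Holdout R-squared can be
    negative for uninformative predictors; the maximum over windows is
    reported as computed.
    """
    from sklearn.metrics import r2_score
    from sklearn.model_selection import train_test_split
    from sklearn.svm import SVR

    y = np.asarray(behavior_utilities, dtype=float)
    n = y.size
    if n < 8:
        raise ValueError("need at least 8 trials for holdout prediction")
    starts = np.asarray(window_starts, dtype=float)
    win_idx = np.flatnonzero(starts >= punishment_onset - 1e-9)
    if win_idx.size == 0:
        raise ValueError("no windows start inside the punishment phase")
    idx_train, idx_test = train_test_split(
        np.arange(n), test_size=holdout, random_state=seed, shuffle=True)

    out: List[PredictionResult] = []
    for region, series in neural_utilities.items():
        series = np.asarray(series, dtype=float)
        best_r2, best_w = -np.inf, int(win_idx[0])
        for w in win_idx:
            xw = series[:, w].reshape(-1, 1)
            model = SVR(kernel="linear", C=1.0, epsilon=0.1)
            model.fit(xw[idx_train], y[idx_train])
            r2 = r2_score(y[idx_test], model.predict(xw[idx_test]))
            if r2 > best_r2:
                best_r2, best_w = float(r2), int(w)
        out.append(PredictionResult(participant_id=participant_id,
                                    region=region, r_squared=best_r2,
                                    window_index=best_w,
                                    holdout_fraction=holdout))
    return out
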