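"""Robust correlation, correlation comparison, factorial ANOVA, SVR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from socialpref.stats import (compare_correlations, factorial_anova,
                              percentage_bend_correlation,
                              predict_behavior_from_neural)


class TestPercentageBend:
    def test_identity_gives_one(self, rng):
        x = rng.normal(size=30)
        assert percentage_bend_correlation(x, x).r == pytest.approx(1.0)

    def test_sign_flip_gives_minus_one(self, rng):
        x = rng.normal(size=30)
        assert percentage_bend_correlation(x, -x).r == pytest.approx(-1.0)

    def test_matches_reference_implementation(self, rng):
        """Independent oracle: pingouin's published percentage-bend estimator
        agrees to 1e-10 on random data."""
        import pingouin as pg
        for _ in range(10):
            x = rng.normal(size=50)
            y = 0.4 * x + rng.normal(size=50)
            mine = percentage_bend_correlation(x, y)
            ref = pg.corr(x, y, method="percbend")
            assert mine.r == pytest.approx(float(ref["r"].iloc[0]),
                                           abs=1e-10)
            assert mine.p == pytest.approx(float(ref["p_val"].iloc[0]),
                                           abs=1e-8)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        base = percentage_bend_correlation(x, y).r
        shifted = percentage_bend_correlation(3.0 * x + 7.0, 0.5 * y - 2.0).r
        assert shifted == pytest.approx(base, abs=1e-12)

    def test_close_to_pearson_on_clean_gaussian_data(self, rng):
        x = rng.normal(size=4000)
        y = 0.6 * x + 0.8 * rng.normal(size=4000)
        r_pb = percentage_bend_correlation(x, y).r
        r_p = np.corrcoef(x, y)[0, 1]
        assert r_pb == pytest.approx(r_p, abs=0.05)

    def test_degenerate_margin_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            percentage_bend_correlation([1.0] * 10, list(range(10)))

    def test_short_input_raises(self):
        with pytest.raises(ValueError, match="at least 4"):
            percentage_bend_correlation([1, 2, 3], [1, 2, 3])


class TestCompareCorrelations:
    def test_equal_correlations_give_zero(self):
        z, p = compare_correlations(0.5, 40, 0.5, 40)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_antisymmetry(self):
        z1, _ = compare_correlations(0.7, 48, 0.38, 48)
        z2, _ = compare_correlations(0.38, 48, 0.7, 48)
        assert z1 == pytest.approx(-z2)

    def test_direct_formula_oracle(self):
        """z for r = 0.70 vs 0.38 at n = 48 each, against a hand evaluation
        of (atanh r1 - atanh r2) / sqrt(1/45 + 1/45)."""
        z, p = compare_correlations(0.70, 48, 0.38, 48)
        expected = (np.arctanh(0.70) - np.arctanh(0.38)) / np.sqrt(2 / 45)
        assert z == pytest.approx(expected, rel=1e-12)
        assert p == pytest.approx(2 * sps.norm.sf(abs(expected)), rel=1e-12)
        assert p < 0.05  # the difference is significant at these values

    def test_steiger_requires_shared_correlation(self):
        with pytest.raises(ValueError, match="r_shared"):
            compare_correlations(0.5, 30, 0.3, 30, method="steiger")
        z, p = compare_correlations(0.5, 30, 0.3, 30, method="steiger",
                                    r_shared=0.2)
        assert np.isfinite(z) and 0 <= p <= 1

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="n > 3"):
            compare_correlations(0.5, 3, 0.3, 30)


class TestFactorialAnova:
    @staticmethod
    def _toy(rng, effect_a=0.0, effect_b=0.0, interaction=0.0, reps=8):
        rows = []
        for a in ("x", "y"):
            for b in ("u", "v"):
                mu = (effect_a * (a == "y") + effect_b * (b == "v")
                      + interaction * (a == "y") * (b == "v"))
                for _ in range(reps):
                    rows.append({"A": a, "B": b,
                                 "value": mu + rng.normal()})
        return pd.DataFrame(rows)

    def test_equal_means_give_zero_f(self):
        """Identical value distributions in every cell: all between-group
        sums of squares vanish, so every F is ~0 and every p ~1."""
        rows = [{"A": a, "B": b, "value": v}
                for a in ("x", "y") for b in ("u", "v")
                for v in (-1.0, 0.0, 1.0, 2.0)]
        out = factorial_anova(pd.DataFrame(rows), "value", ["A", "B"])
        table = out["anova"].drop(index="Residual")
        assert np.all(np.abs(table["F"].to_numpy()) < 1e-12)
        assert np.all(table["PR(>F)"].to_numpy() > 0.999)

    def test_balanced_design_matches_brute_force_ss(self, rng):
        """Sums of squares decompose exactly on a balanced 2x2 table."""
        data = self._toy(rng, effect_a=1.0, effect_b=0.5, interaction=0.3)
        out = factorial_anova(data, "value", ["A", "B"])
        table = out["anova"]
        v = data.value.to_numpy().reshape(2, 2, -1)  # A x B x reps
        reps = v.shape[2]
        grand = v.mean()
        ss_a = 2 * reps * ((v.mean(axis=(1, 2)) - grand) ** 2).sum()
        ss_b = 2 * reps * ((v.mean(axis=(0, 2)) - grand) ** 2).sum()
        cell = v.mean(axis=2)
        ss_int = reps * ((cell - v.mean(axis=(1, 2))[:, None]
                          - v.mean(axis=(0, 2))[None, :] + grand) ** 2).sum()
        assert table.loc["C(A)", "sum_sq"] == pytest.approx(ss_a, rel=1e-10)
        assert table.loc["C(B)", "sum_sq"] == pytest.approx(ss_b, rel=1e-10)
        assert table.loc["C(A):C(B)", "sum_sq"] == pytest.approx(
            ss_int, rel=1e-10)

    def test_posthoc_bonferroni_capped(self, rng):
        data = self._toy(rng, effect_b=2.0)
        out = factorial_anova(data, "value", ["A", "B"], posthoc_factor="B")
        assert (out["posthoc"].p_bonferroni <= 1.0).all()

    def test_empty_cell_raises_naming_cell(self, rng):
        data = self._toy(rng)
        data = data[~((data.A == "y") & (data.B == "v"))]
        with pytest.raises(ValueError, match="empty design cell"):
            factorial_anova(data, "value", ["A", "B"])


class TestPrediction:
    def test_perfect_predictor(self, rng):
        y = rng.normal(size=60)
        series = {"dlPFC": np.tile(y[:, None], (1, 40))}
        starts = np.arange(40) * 0.18
        res = predict_behavior_from_neural(y, series, starts, seed=0)
        assert res[0].r_squared >= 0.99
        assert res[0].holdout_fraction == 0.5

    def test_pure_noise_predictor_near_zero(self):
        scores = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            y = rng.normal(size=60)
            series = {"dlPFC": rng.normal(size=(60, 40))}
            starts = np.arange(40) * 0.18
            res = predict_behavior_from_neural(y, series, starts, seed=seed)
            scores.append(res[0].r_squared)
        assert np.mean(scores) <= 0.15

    def test_deterministic_given_seed(self, rng):
        y = rng.normal(size=40)
        series = {"dlPFC": rng.normal(size=(40, 40))}
        starts = np.arange(40) * 0.18
        a = predict_behavior_from_neural(y, series, starts, seed=5)
        b = predict_behavior_from_neural(y, series, starts, seed=5)
        assert a[0].r_squared == b[0].r_squared
        assert a[0].window_index == b[0].window_index

    def test_too_few_trials_rejected(self, rng):
        y = rng.normal(size=5)
        with pytest.raises(ValueError, match="at least 8"):
            predict_behavior_from_neural(
                y, {"dlPFC": rng.normal(size=(5, 40))},
                np.arange(40) * 0.18)
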