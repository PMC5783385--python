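"""Call-type validation statistics: z-scores, LDA, MANOVA, LOO-CV, GLM, W."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.linalg
import scipy.stats

from pacavoc import repertoire, synth


def make_two_class(n=40, gap=10.0, sd=1.0, seed=0, features=("duration", "dominant_freq")):
    rng = np.random.default_rng(seed)
    rows = []
    for c, mu in (("a", 0.0), ("b", gap)):
        for _ in range(n):
            rows.append({"call_type": c, **{f: mu + rng.normal(0, sd) for f in features}})
    return pd.DataFrame(rows)


class TestZscore:
    def test_hand_values(self):
        df = pd.DataFrame({"duration": [1.0, 2.0, 3.0]})
        out, _, _ = repertoire.zscore(df, ["duration"], ddof=1)
        assert np.allclose(out["duration"], [-1.0, 0.0, 1.0])
        out0, _, _ = repertoire.zscore(df, ["duration"], ddof=0)
        assert np.allclose(out0["duration"], [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_idempotent_on_standardized_data(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"x": rng.normal(size=50)})
        once, _, _ = repertoire.zscore(df, ["x"])
        twice, _, _ = repertoire.zscore(once, ["x"])
        pd.testing.assert_frame_equal(once, twice)

    def test_constant_feature_raises(self):
        df = pd.DataFrame({"x": [3.0, 3.0, 3.0]})
        with pytest.raises(repertoire.ConstantFeatureError, match="no variation"):
            repertoire.zscore(df, ["x"])


class TestLda:
    def test_two_class_axis_matches_fisher_direction(self):
        """Closed-form oracle: pooled-covariance-inverse x mean difference."""
        df = make_two_class(gap=3.0, sd=1.0, seed=2)
        feats = ["duration", "dominant_freq"]
        model = repertoire.fit_lda(df, feats)
        assert model.n_axes == 1
        std, _, _ = repertoire.zscore(df, feats)
        xa = std.loc[std.call_type == "a", feats].to_numpy()
        xb = std.loc[std.call_type == "b", feats].to_numpy()
        sp = ((len(xa) - 1) * np.cov(xa.T) + (len(xb) - 1) * np.cov(xb.T)) / (
            len(xa) + len(xb) - 2
        )
        fisher = np.linalg.solve(sp, xb.mean(axis=0) - xa.mean(axis=0))
        cos = fisher @ model.functions[0] / (
            np.linalg.norm(fisher) * np.linalg.norm(model.functions[0])
        )
        assert abs(cos) == pytest.approx(1.0, abs=1e-8)
        # symmetric centroids on the single axis
        assert model.centroids.to_numpy().sum() == pytest.approx(0.0, abs=1e-8)

    def test_matches_sklearn_eigenvalue_ratios(self, element_table):
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        model = repertoire.fit_lda(element_table)
        std, _, _ = repertoire.zscore(element_table)
        sk = sklearn.LinearDiscriminantAnalysis(solver="eigen").fit(
            std[list(repertoire.FEATURES)].to_numpy(), std["call_type"].to_numpy()
        )
        assert np.allclose(
            model.explained_variance, sk.explained_variance_ratio_, atol=1e-8
        )

    def test_axes_invariant_to_feature_rescaling(self, element_table):
        scaled = element_table.copy()
        scaled["dominant_freq"] = scaled["dominant_freq"] / 1000.0 + 5.0
        m1 = repertoire.fit_lda(element_table)
        m2 = repertoire.fit_lda(scaled)
        assert np.allclose(np.abs(m1.explained_variance), np.abs(m2.explained_variance))
        pred1 = repertoire.classify(m1, element_table)
        pred2 = repertoire.classify(m2, scaled)
        assert (pred1 == pred2).all()

    def test_explained_variance_sums_to_one(self, element_table):
        model = repertoire.fit_lda(element_table)
        assert model.explained_variance.sum() == pytest.approx(1.0)
        assert model.n_axes == min(len(repertoire.FEATURES), 8 - 1)


class TestManova:
    def test_identical_class_distributions_lambda_one(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=(30, 2))
        df = pd.DataFrame(
            np.vstack([base, base]), columns=["duration", "dominant_freq"]
        )
        df["call_type"] = ["a"] * 30 + ["b"] * 30
        res = repertoire.manova_wilks(df, ["duration", "dominant_freq"])
        assert res["wilks_lambda"] == pytest.approx(1.0)

    def test_two_class_agrees_with_hotelling_t2(self):
        df = make_two_class(n=25, gap=1.5, seed=5)
        feats = ["duration", "dominant_freq"]
        res = repertoire.manova_wilks(df, feats)
        std, _, _ = repertoire.zscore(df, feats)
        xa = std.loc[std.call_type == "a", feats].to_numpy()
        xb = std.loc[std.call_type == "b", feats].to_numpy()
        na, nb, p = len(xa), len(xb), 2
        sp = ((na - 1) * np.cov(xa.T) + (nb - 1) * np.cov(xb.T)) / (na + nb - 2)
        d = xa.mean(axis=0) - xb.mean(axis=0)
        t2 = (na * nb) / (na + nb) * d @ np.linalg.solve(sp, d)
        f_oracle = (na + nb - p - 1) / (p * (na + nb - 2)) * t2
        assert res["F"] == pytest.approx(f_oracle, rel=1e-9)

    def test_matches_statsmodels_on_full_table(self, element_table):
        from statsmodels.multivariate.manova import MANOVA

        res = repertoire.manova_wilks(element_table)
        std, _, _ = repertoire.zscore(element_table)
        mv = MANOVA.from_formula(
            "duration + dominant_freq + min_freq + max_freq ~ call_type", data=std
        )
        stat = mv.mv_test().results["call_type"]["stat"].loc["Wilks' lambda"]
        assert res["wilks_lambda"] == pytest.approx(float(stat["Value"]), rel=1e-6)
        assert res["F"] == pytest.approx(float(stat["F Value"]), rel=1e-6)
        assert 0 < res["wilks_lambda"] <= 1

    def test_lambda_decreases_with_separation(self):
        lams = [
            repertoire.manova_wilks(
                make_two_class(gap=g, seed=6), ["duration", "dominant_freq"]
            )["wilks_lambda"]
            for g in (0.0, 1.0, 3.0, 8.0)
        ]
        assert lams == sorted(lams, reverse=True)


class TestLooCrossValidation:
    def test_separated_classes_perfect_accuracy(self):
        df = make_two_class(n=12, gap=50.0, sd=0.5, seed=7)
        cm = repertoire.loo_crossvalidate(df, ["duration", "dominant_freq"])
        assert cm.overall_accuracy == 1.0
        assert cm.counts.to_numpy().sum() == 24
        assert (cm.counts.sum(axis=1) == 12).all()

    def test_matches_literal_refit_oracle(self, element_table):
        """Bit-equal to an independent numpy reimplementation of the
        per-fold standardize + eigensolve + nearest-centroid chain."""
        from conftest import loo_refit_oracle

        sub = (
            element_table.groupby("call_type", group_keys=False)
            .head(8)
            .reset_index(drop=True)
        )
        cm = repertoire.loo_crossvalidate(sub, repertoire.FEATURES)
        oracle = loo_refit_oracle(sub, repertoire.FEATURES)
        pd.testing.assert_frame_equal(cm.counts, oracle)

    def test_single_sample_class_rejected(self):
        df = make_two_class(n=5, seed=8)
        df = pd.concat(
            [df, pd.DataFrame([{"call_type": "c", "duration": 0.0, "dominant_freq": 0.0}])],
            ignore_index=True,
        )
        with pytest.raises(ValueError, match="single sample"):
            repertoire.loo_crossvalidate(df, ["duration", "dominant_freq"])


class TestBinomial:
    def test_three_of_three_at_half(self):
        assert repertoire.binomial_vs_chance(3, 3, 0.5) == pytest.approx(0.125)

    def test_reference_accuracy_beats_chance(self):
        assert repertoire.binomial_vs_chance(264, 400, 0.125) < 1e-4

    def test_at_expectation_matches_exact_sum_oracle(self):
        p = repertoire.binomial_vs_chance(50, 400, 0.125)
        oracle = sum(
            math.comb(400, k) * 0.125**k * 0.875 ** (400 - k) for k in range(50, 401)
        )
        assert p == pytest.approx(oracle, rel=1e-10)
        assert 0.4 < p < 0.6

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            repertoire.binomial_vs_chance(5, 3, 0.5)
        with pytest.raises(ValueError):
            repertoire.binomial_vs_chance(1, 3, 0.0)


class TestAgeTypeModel:
    def test_null_age_effect_calibrated(self):
        rej = 0
        n_rep = 300
        for r in range(n_rep):
            df = synth.generate_individual_means(
                age_effect=0.0,
                type_effects={"roar": 1.0, "growl": 0.0, "bark": -1.0, "groan": 0.5},
                seed=r,
            )
            tab = repertoire.age_type_linear_model(df)
            if tab.loc["age_class", "PR(>F)"] < 0.05:
                rej += 1
        assert abs(rej / n_rep - 0.05) < 0.03

    def test_injected_interaction_detected(self):
        hits = 0
        for r in range(60):
            df = synth.generate_individual_means(
                age_effect=0.5,
                interaction={"roar": 1.5, "bark": -1.5},
                seed=10_000 + r,
            )
            tab = repertoire.age_type_linear_model(df)
            if tab.loc["interaction", "PR(>F)"] < 0.05:
                hits += 1
        assert hits / 60 > 0.8

    def test_single_age_class_rejected(self):
        df = synth.generate_individual_means(n_juveniles=0, seed=0)
        with pytest.raises(ValueError, match="at least 2 levels"):
            repertoire.age_type_linear_model(df)

    def test_empty_cell_reported(self):
        df = synth.generate_individual_means(seed=1)
        df = df[~((df.age_class == "juvenile") & (df.call_type == "roar"))]
        with pytest.raises(ValueError, match="empty cells"):
            repertoire.age_type_linear_model(df)


class TestKendallW:
    def test_identical_rankings(self):
        ratings = np.tile(np.arange(6, dtype=float), (3, 1))
        assert repertoire.kendall_w(ratings) == pytest.approx(1.0)

    def test_hand_worked_example(self):
        """3 observers x 4 items, W from the rank-sum formula by hand."""
        ranks = np.array([[1, 2, 3, 4], [2, 1, 3, 4], [1, 3, 2, 4]], dtype=float)
        r = ranks.sum(axis=0)
        s = ((r - r.mean()) ** 2).sum()
        oracle = 12 * s / (3**2 * (4**3 - 4))
        assert repertoire.kendall_w(ranks) == pytest.approx(oracle)

    def test_independent_rankings_near_zero(self):
        # under independence E[W] = 1/m, so use many observers
        rng = np.random.default_rng(9)
        m = 25
        ratings = np.vstack([rng.permutation(120).astype(float) for _ in range(m)])
        assert repertoire.kendall_w(ratings) < 2.5 / m

    def test_degenerate_input(self):
        with pytest.raises(ValueError):
            repertoire.kendall_w(np.array([[1.0, 2.0]]))
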