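import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from broilerne import datasets
from broilerne.model import fit_published_equation, published_panel
from broilerne.stats_inference import (duncan_groups, one_way_anova,
                                       pearson_matrix, predict_ne,
                                       stepwise_fit, validate)

WHEAT_AME = [12.93, 13.10, 13.09, 13.75, 13.32]
WHEAT_NE = [9.34, 10.02, 10.27, 11.33, 10.49]


class TestPearsonMatrix:
    def test_self_correlation_is_one(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [2.0, 1, 4, 3]})
        cm = pearson_matrix(df)
        assert cm.r.loc["x", "x"] == 1.0
        assert cm.p.loc["x", "x"] == 0.0

    def test_perfect_linearity(self):
        x = np.array([1.0, 2, 3, 4, 5])
        cm = pearson_matrix(pd.DataFrame({"x": x, "y": 2 * x + 1}))
        assert cm.r.loc["x", "y"] == pytest.approx(1.0)

    def test_wheat_ame_ne_pairs(self):
        cm = pearson_matrix(pd.DataFrame({"ame": WHEAT_AME, "ne": WHEAT_NE}))
        assert cm.r.loc["ame", "ne"] == pytest.approx(0.96, abs=0.005)

    def test_zero_variance_column_gives_nan(self):
        cm = pearson_matrix(pd.DataFrame({"x": [1.0, 1, 1], "y": [1.0, 2, 3]}))
        assert np.isnan(cm.r.loc["x", "y"])

    def test_symmetry_and_bounds(self, rng):
        df = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        cm = pearson_matrix(df)
        assert np.allclose(cm.r, cm.r.T)
        assert (cm.r.abs() <= 1 + 1e-12).all().all()


class TestDuncan:
    def test_equal_means_share_a_letter(self):
        letters = duncan_groups([5.0, 5.0], mse=1.0, df_error=10,
                                n_per_group=4)
        assert letters[0] == letters[1]

    def test_clear_separation(self):
        letters = duncan_groups([10.0, 5.0], mse=1e-8, df_error=10,
                                n_per_group=4)
        assert letters == ["a", "b"]

    def test_intermediate_grouping(self):
        letters = duncan_groups([10.0, 9.9, 5.0], mse=0.05, df_error=12,
                                n_per_group=5)
        assert letters[0] == letters[1] == "a"
        assert letters[2] == "b"

    def test_alpha_to_zero_single_letter(self):
        letters = duncan_groups([10.0, 7.0, 5.0], mse=1.0, df_error=10,
                                n_per_group=4, alpha=1e-12)
        assert len(set(letters)) == 1

    def test_zero_mse_distinct_means_distinct_letters(self):
        letters = duncan_groups([10.0, 9.0, 5.0], mse=0.0, df_error=10,
                                n_per_group=4)
        assert len(set(letters)) == 3


class TestAnova:
    def test_identical_groups_degenerate(self):
        res = one_way_anova({"a": [1.0, 1.0], "b": [1.0, 1.0]})
        assert res.degenerate

    def test_separated_groups_significant(self):
        res = one_way_anova({"a": [10.0, 10.1, 9.9],
                             "b": [5.0, 5.1, 4.9]})
        assert res.p_value < 0.001
        assert res.duncan_letters["a"] != res.duncan_letters["b"]

    def test_matches_scipy_f_oneway(self, rng):
        groups = {k: rng.normal(loc=i, size=6)
                  for i, k in enumerate("abcd")}
        res = one_way_anova(groups)
        from scipy.stats import f_oneway
        f, p = f_oneway(*groups.values())
        assert res.f_stat == pytest.approx(f)
        assert res.p_value == pytest.approx(p)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova({"a": [1.0], "b": [1.0, 2.0]})

    def test_power_on_study_scale_effects(self, rng):
        """Groups separated as the bran-diet AME contrasts (means ~11.2
        vs 13.3, between-replicate CV ~2%) should essentially always be
        detected at alpha=0.05 with 6 replicates."""
        hits = 0
        for _ in range(200):
            ref = rng.normal(13.29, 0.25, size=6)
            test = rng.normal(11.2, 0.25, size=6)
            if one_way_anova({"ref": ref, "test": test}).p_value < 0.05:
                hits += 1
        assert hits >= 195


class TestStepwise:
    def test_noise_free_single_predictor_recovery(self, rng):
        x = rng.normal(size=30)
        noise = pd.DataFrame(rng.normal(size=(30, 3)),
                             columns=["n1", "n2", "n3"])
        cands = noise.assign(x=x)
        eq = stepwise_fit(3.0 * x + 1.0, cands)
        assert eq.predictors() == ["x"]
        assert eq.r2 == pytest.approx(1.0)
        assert dict(eq.terms)["x"] == pytest.approx(3.0)
        assert eq.intercept == pytest.approx(1.0)

    def test_published_wheat_panel_selects_ame_and_adf(self):
        eq = fit_published_equation("wheat", stepwise=True)
        assert sorted(eq.predictors()) == ["adf", "ame"]
        coefs = dict(eq.terms)
        assert coefs["ame"] == pytest.approx(1.968, abs=0.02)
        assert coefs["adf"] == pytest.approx(-0.411, abs=0.02)
        assert eq.intercept == pytest.approx(-14.227, abs=0.02)

    def test_open_entry_equals_full_ols(self, rng):
        """With alpha_enter=1 and no screens, stepwise must coincide with
        the normal-equations solution on the full design."""
        X = pd.DataFrame(rng.normal(size=(25, 3)), columns=["a", "b", "c"])
        y = 1.0 + 2 * X["a"] - X["b"] + 0.5 * X["c"] + rng.normal(
            scale=0.1, size=25)
        eq = stepwise_fit(y, X, alpha_enter=1.0, alpha_remove=1.0,
                          collinearity_alpha=0.0)
        A = np.column_stack([np.ones(25), X.to_numpy()])
        beta = np.linalg.solve(A.T @ A, A.T @ y.to_numpy())
        assert eq.intercept == pytest.approx(beta[0], rel=1e-8)
        got = dict(eq.terms)
        for j, name in enumerate(X.columns):
            assert got[name] == pytest.approx(beta[j + 1], rel=1e-8)
        # residual orthogonality of the least-squares fit
        resid = y.to_numpy() - A @ beta
        assert np.max(np.abs(A.T @ resid)) < 1e-8

    def test_collinearity_screen_blocks_second_latent_twin(self, rng):
        latent = rng.normal(size=40)
        cands = pd.DataFrame({
            "p1": latent + rng.normal(scale=0.05, size=40),
            "p2": latent + rng.normal(scale=0.05, size=40)})
        y = latent + rng.normal(scale=0.05, size=40)
        eq = stepwise_fit(y, cands)
        assert len(eq.predictors()) == 1

    def test_no_entry_gives_intercept_only(self, rng):
        cands = pd.DataFrame({"x": rng.normal(size=20)})
        y = rng.normal(size=20)
        eq = stepwise_fit(y, cands, alpha_enter=1e-9)
        assert eq.terms == []
        assert eq.intercept == pytest.approx(np.mean(y))


class TestPredictAndValidate:
    def test_printed_bran_equation_on_bran4(self):
        eq = datasets.printed_equations()["wheat_bran"]
        ne = predict_ne(eq, dict(cp=18.30, cf=13.96, adf=15.78))
        assert ne == pytest.approx(5.062, abs=0.001)

    def test_printed_wheat_equation_on_wheat4(self):
        eq = datasets.printed_equations()["wheat"]
        ne = predict_ne(eq, dict(ame=13.75, adf=3.73))
        assert ne == pytest.approx(11.30, abs=0.01)

    def test_missing_predictor_named(self):
        eq = datasets.printed_equations()["wheat"]
        with pytest.raises(KeyError, match="adf"):
            predict_ne(eq, dict(ame=13.0))

    def test_holdout_on_fitted_plane_gives_r_one(self):
        eq = fit_published_equation("wheat", stepwise=False)
        pts = [(dict(ame=a, adf=d),
                predict_ne(eq, dict(ame=a, adf=d)))
               for a, d in [(13.0, 4.0), (13.5, 3.5), (12.9, 4.5)]]
        res = validate(eq, pts)
        assert res.pearson_r == pytest.approx(1.0)

    def test_wheat_pooled_validation_r(self):
        """5 training samples + the held-out validation wheat
        (AME 13.79, ADF 4.78, measured NE 10.48): pooled r ~ 0.96."""
        eq = fit_published_equation("wheat")
        panel = published_panel("wheat")
        training = [(r.to_dict(), r["ne"]) for _, r in panel.iterrows()]
        res = validate(eq, [(dict(ame=13.79, adf=4.78), 10.48)],
                       training=training)
        assert res.pearson_r == pytest.approx(0.96, abs=0.01)

    def test_anticorrelated_pairs(self):
        eq = datasets.printed_equations()["wheat"]
        pts = [(dict(ame=14.0, adf=3.0), 5.0), (dict(ame=12.0, adf=5.0), 12.0)]
        res = validate(eq, pts)
        assert res.pearson_r == pytest.approx(-1.0)
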