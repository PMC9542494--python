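"""Linear-model battery: OLS oracle equivalence, ANOVA identities, LRT
selection, marginal slopes and Bonferroni post-hocs."""

import json
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from invasionlab.inference import (
    AnalysisReport,
    ModelSpec,
    anova_table,
    fit_linear_model,
    likelihood_ratio_select,
    likelihood_ratio_test,
    marginal_pairwise,
    resource_specific_slopes,
)
from invasionlab.synthetic import (
    DEFAULT_SLOPES,
    ParametricConfig,
    generate_parametric,
)


def ols_normal_equations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Brute-force oracle: solve X'X b = X'y directly."""
    return np.linalg.solve(X.T @ X, X.T @ y)


class TestFitLinearModel:
    def test_coefficients_match_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        n = 30
        df = pd.DataFrame(
            {c: rng.normal(size=n) for c in ("a", "b", "c")}
        )
        df["y"] = rng.normal(size=n)
        fit = fit_linear_model(
            ModelSpec(response="y", disturbance_degree=0,
                      covariates=("a", "b", "c")),
            df,
        )
        X = np.column_stack([np.ones(n), df["a"], df["b"], df["c"]])
        expected = ols_normal_equations(X, df["y"].to_numpy())
        np.testing.assert_allclose(fit.params.to_numpy(), expected, rtol=1e-8)

    def test_exact_line_recovered_with_zero_rss(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        df["y"] = 2.0 * df["x"]
        fit = fit_linear_model(
            ModelSpec(response="y", disturbance_degree=0, covariates=("x",)), df
        )
        assert fit.params["x"] == pytest.approx(2.0)
        assert fit.rss == pytest.approx(0.0, abs=1e-20)

    def test_intercept_only_equals_sample_mean(self):
        df = pd.DataFrame({"y": [1.0, 4.0, 7.0, 8.0]})
        fit = fit_linear_model(ModelSpec(response="y", disturbance_degree=0), df)
        assert fit.params["Intercept"] == pytest.approx(df["y"].mean())

    def test_rank_deficient_design_is_an_error(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"a": rng.normal(size=10)})
        df["b"] = 2 * df["a"]  # aliased
        df["y"] = rng.normal(size=10)
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_linear_model(
                ModelSpec(response="y", disturbance_degree=0,
                          covariates=("a", "b")),
                df,
            )


class TestAnova:
    def test_identical_group_means_give_zero_f(self):
        df = pd.DataFrame(
            {"resource": ["low"] * 3 + ["high"] * 3,
             "y": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]}
        )
        fit = fit_linear_model(
            ModelSpec(response="y", disturbance_degree=0,
                      factors=("resource",)), df
        )
        tab = anova_table(fit, "II")
        assert tab.loc["resource", "F"] == pytest.approx(0.0, abs=1e-12)

    def test_two_group_f_equals_t_squared(self):
        a = [3.1, 2.8, 3.6, 3.0, 2.5]
        b = [4.0, 4.4, 3.9, 4.8, 4.1]
        df = pd.DataFrame({"resource": ["low"] * 5 + ["high"] * 5, "y": a + b})
        fit = fit_linear_model(
            ModelSpec(response="y", disturbance_degree=0,
                      factors=("resource",)), df
        )
        f = anova_table(fit, "II").loc["resource", "F"]
        t, _ = stats.ttest_ind(a, b, equal_var=True)
        assert f == pytest.approx(t ** 2, rel=1e-10)

    def test_balanced_two_way_type_ii_equals_iii_without_interaction(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {"resource": ["low", "low", "high", "high"] * 4,
             "invader_type": (["SM"] * 4 + ["WS"] * 4) * 2}
        )
        df["y"] = rng.normal(size=len(df))
        fit = fit_linear_model(
            ModelSpec(response="y", disturbance_degree=0,
                      factors=("resource", "invader_type")), df
        )
        t2, t3 = anova_table(fit, "II"), anova_table(fit, "III")
        for term in ("resource", "invader_type"):
            assert t2.loc[term, "F"] == pytest.approx(t3.loc[term, "F"],
                                                      rel=1e-10)

    def test_invalid_ss_type(self, sim_small):
        df = pd.DataFrame({"y": [1.0, 2.0]})
        fit = fit_linear_model(ModelSpec(response="y", disturbance_degree=0), df)
        with pytest.raises(ValueError):
            anova_table(fit, "I")


class TestLikelihoodRatio:
    def test_model_against_itself_is_null(self):
        df = pd.DataFrame({"y": np.arange(10.0),
                           "x": np.arange(10.0) ** 0.5})
        fit = fit_linear_model(
            ModelSpec(response="y", disturbance_degree=0, covariates=("x",)), df
        )
        stat, dof, p = likelihood_ratio_test(fit, fit)
        assert stat == 0.0 and p == 1.0

    def test_closed_form_on_ten_point_fixture(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"x": np.linspace(0, 1, 10)})
        df["y"] = 1.0 + 0.5 * df["x"] + rng.normal(0, 0.2, 10)
        full = fit_linear_model(
            ModelSpec(response="y", disturbance_degree=0, covariates=("x",)), df
        )
        reduced = fit_linear_model(
            ModelSpec(response="y", disturbance_degree=0), df
        )
        stat, dof, p = likelihood_ratio_test(full, reduced)
        # independent closed form from raw residual sums of squares
        y = df["y"].to_numpy()
        rss0 = np.sum((y - y.mean()) ** 2)
        X = np.column_stack([np.ones(10), df["x"]])
        beta = ols_normal_equations(X, y)
        rss1 = np.sum((y - X @ beta) ** 2)
        assert stat == pytest.approx(10 * math.log(rss0 / rss1), rel=1e-10)
        assert dof == 1
        assert p == pytest.approx(stats.chi2.sf(stat, 1))

    def test_non_nested_comparison_rejected(self):
        df = pd.DataFrame({"y": np.arange(8.0), "x": np.arange(8.0) ** 2,
                           "z": np.cos(np.arange(8.0))})
        fx = fit_linear_model(
            ModelSpec(response="y", disturbance_degree=0, covariates=("x",)), df
        )
        fz = fit_linear_model(
            ModelSpec(response="y", disturbance_degree=0, covariates=("z",)), df
        )
        with pytest.raises(ValueError, match="nested"):
            likelihood_ratio_test(fx, fz)

    def test_selection_respects_marginality_and_drops_noise(self):
        # strong dist x resource interaction, plus a pure-noise covariate
        rng = np.random.default_rng(99)
        tab, _ = generate_parametric(ParametricConfig(residual_sd=0.1), seed=8)
        tab = tab[tab["invader_type"] == "SM"].copy()
        tab["noise"] = rng.normal(size=len(tab))
        spec = ModelSpec(response="success_score", factors=("resource",),
                         covariates=("noise",),
                         interactions=(("dist", "resource"),))
        final, trace = likelihood_ratio_select(spec, tab, alpha=0.05)
        labels = {":".join(t) for t in final.terms}
        assert "dist:resource" in labels
        assert "dist" in labels and "resource" in labels  # marginality kept
        assert "noise" not in labels
        dropped = [t.term for t in trace if t.action == "dropped"]
        assert dropped == ["noise"]
        # main effects were never tested while their interaction remained
        assert all(t.term not in ("dist", "resource") or t.action == "kept"
                   for t in trace)

    def test_null_lrt_pvalues_are_uniform(self):
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(500):
            n = 80
            df = pd.DataFrame(
                {"disturbance_interval": np.resize([1, 2, 4, 8, 16], n),
                 "y": rng.normal(size=n)}
            )
            full = fit_linear_model(ModelSpec(response="y"), df)
            red = fit_linear_model(
                ModelSpec(response="y", disturbance_degree=0), df
            )
            ps.append(likelihood_ratio_test(full, red)[2])
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01


class TestSlopes:
    def test_no_interaction_gives_common_slope(self):
        tab, _ = generate_parametric(
            ParametricConfig(slopes={k: 0.1 for k in DEFAULT_SLOPES},
                             residual_sd=0.2),
            seed=3,
        )
        fit = fit_linear_model(
            ModelSpec(response="success_score", factors=("resource",),
                      data_filter={"invader_type": "SM"}),
            tab,
        )
        slopes = resource_specific_slopes(fit)
        vals = [s.slope for s in slopes]
        assert max(vals) - min(vals) < 1e-10

    def test_noiseless_recovery_of_generating_slopes(self):
        tab, _ = generate_parametric(ParametricConfig(residual_sd=0.0), seed=0)
        fit = fit_linear_model(
            ModelSpec(response="success_score", factors=("resource",),
                      interactions="all",
                      data_filter={"invader_type": "SM"}),
            tab,
        )
        for s in resource_specific_slopes(fit):
            truth = DEFAULT_SLOPES[("SM", s.resource_level)]
            assert s.slope == pytest.approx(truth, abs=1e-9)
            assert s.ci95[1] - s.ci95[0] == pytest.approx(0.0, abs=1e-9)
            assert s.significant

    def test_quadratic_model_refuses_slopes(self):
        tab, _ = generate_parametric(ParametricConfig(residual_sd=0.1), seed=1)
        fit = fit_linear_model(
            ModelSpec(response="success_score", disturbance_degree=2,
                      factors=("resource",),
                      data_filter={"invader_type": "SM"}),
            tab,
        )
        with pytest.raises(ValueError, match="degree-1"):
            resource_specific_slopes(fit)

    def test_slope_estimates_unbiased_at_low_noise(self):
        # mean slope-estimation error across many replicate experiments
        cfg = ParametricConfig(residual_sd=0.1)
        errors = {res: [] for res in ("low", "medium", "high")}
        for s in range(500):
            tab, _ = generate_parametric(cfg, seed=60_000 + s)
            fit = fit_linear_model(
                ModelSpec(response="success_score", factors=("resource",),
                          interactions="all",
                          data_filter={"invader_type": "SM"}),
                tab,
            )
            for sl in resource_specific_slopes(fit):
                errors[sl.resource_level].append(
                    sl.slope - DEFAULT_SLOPES[("SM", sl.resource_level)]
                )
        for res, errs in errors.items():
            assert abs(np.mean(errs)) < 0.01


class TestMarginalMeans:
    def test_bonferroni_arithmetic(self):
        rng = np.random.default_rng(12)
        tab, _ = generate_parametric(ParametricConfig(residual_sd=0.3), seed=12)
        fit = fit_linear_model(
            ModelSpec(response="success_score", factors=("resource",),
                      data_filter={"invader_type": "SM"}),
            tab,
        )
        pairs = marginal_pairwise(fit, "resource")
        assert len(pairs) == 3
        for p in pairs:
            assert p.p_adjusted == pytest.approx(min(1.0, 3 * p.p_raw))
            assert p.method == "bonferroni"

    def test_duplicated_levels_have_zero_difference(self):
        df = pd.DataFrame(
            {"resource": ["low"] * 4 + ["high"] * 4,
             "y": [1.0, 2.0, 3.0, 4.0] * 2}
        )
        fit = fit_linear_model(
            ModelSpec(response="y", disturbance_degree=0,
                      factors=("resource",)), df
        )
        (pair,) = marginal_pairwise(fit, "resource")
        assert pair.estimate == pytest.approx(0.0, abs=1e-12)

    def test_balanced_marginal_mean_equals_group_mean(self):
        df = pd.DataFrame(
            {"resource": ["low"] * 4 + ["high"] * 4,
             "y": [1.0, 2.0, 3.0, 4.0, 10.0, 11.0, 12.0, 13.0]}
        )
        fit = fit_linear_model(
            ModelSpec(response="y", disturbance_degree=0,
                      factors=("resource",)), df
        )
        (pair,) = marginal_pairwise(fit, "resource")
        diff = df[df.resource == pair.level_a]["y"].mean() - \
            df[df.resource == pair.level_b]["y"].mean()
        assert pair.estimate == pytest.approx(diff)

    def test_absent_factor_rejected(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0]})
        fit = fit_linear_model(ModelSpec(response="y", disturbance_degree=0), df)
        with pytest.raises(ValueError):
            marginal_pairwise(fit, "resource")


class TestAnalysisReport:
    def test_report_contains_three_way_and_branches(self, full_report):
        s = full_report.sections
        assert s["success_three_way"]["three_way"] is not None
        assert s["three_way_significant"] is True
        assert set(s["per_morph_success"]) == {"SM", "WS"}
        for entry in s["per_morph_success"].values():
            assert len(entry["slopes"]) == 3
            assert len(entry["resource_posthoc"]) == 3
        assert set(s["diversity"]) == {"SM", "WS"}
        assert set(s["resident_effects"]) == {"SM", "WS"}

    def test_every_reported_test_carries_df_and_p(self, full_report):
        s = full_report.sections

        def check(node):
            if isinstance(node, dict):
                if "F" in node:
                    assert {"df_num", "df_den", "p"} <= set(node) or \
                        {"df"} <= set(node)
                for v in node.values():
                    check(v)
            elif isinstance(node, list):
                for item in node:
                    check(item)

        check(s)

    def test_json_roundtrip(self, full_report):
        text = full_report.to_json()
        back = AnalysisReport.from_json(text)
        assert back.sections == json.loads(text)
        assert back.to_json() == text
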