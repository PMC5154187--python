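"""Wald/LRT inference and the PRISM, RERI and gamma estimands."""

import math

import numpy as np
import pandas as pd
import pytest

from perilreg import (
    FittedModel,
    ModelDesign,
    SimulationDesign,
    SufficientCauseSpec,
    confint_transformed,
    fit_complementary_log,
    gamma_from_beta,
    likelihood_ratio_test,
    make_fixture_table,
    prism_test,
    reri,
    simulate_cohort,
    wald_test,
)

from conftest import HYPERTENSION_TABLE, random_2x2_table

Z95 = 1.959964


def manual_model(betas: dict, ses: dict, nll=0.0, n=100, cases=10) -> FittedModel:
    """A FittedModel assembled from given estimates and standard errors."""
    terms = list(betas)
    cov = pd.DataFrame(
        np.diag([ses[t] ** 2 for t in terms]), index=terms, columns=terms
    )
    design = ModelDesign.intercept_only()
    return FittedModel(
        params=pd.Series(betas),
        cov=cov,
        nll=nll,
        deviance=0.0,
        n_iter=1,
        converged=True,
        design=design,
        n_total=n,
        cases_total=cases,
    )


def se_from_ci(lo: float, hi: float) -> float:
    return (hi - lo) / (2 * Z95)


class TestWald:
    def test_p_value_reconstructed_from_published_ci(self):
        beta, lo, hi, printed_p = HYPERTENSION_TABLE["Age:BMI"]
        model = manual_model({"Age:BMI": beta}, {"Age:BMI": se_from_ci(lo, hi)})
        _, p = wald_test(model, "Age:BMI")
        assert round(p, 4) == printed_p

    def test_zero_beta_gives_p_one(self):
        model = manual_model({"t": 0.0}, {"t": 0.1})
        z, p = wald_test(model, "t")
        assert (z, p) == (0.0, 1.0)

    def test_quantile_identity(self):
        model = manual_model({"t": Z95 * 0.2}, {"t": 0.2})
        _, p = wald_test(model, "t")
        assert p == pytest.approx(0.05, abs=1e-6)

    def test_degenerate_se_raises(self):
        model = manual_model({"t": 0.5}, {"t": 0.0})
        with pytest.raises(ValueError, match="degenerate"):
            wald_test(model, "t")

    def test_unknown_term(self):
        model = manual_model({"t": 0.5}, {"t": 0.1})
        with pytest.raises(KeyError):
            wald_test(model, "nope")


class TestConfintTransformed:
    @pytest.mark.parametrize(
        "term, transformed, tlo, thi",
        [
            ("Age", 0.8921, 0.8634, 0.9217),
            ("Age:BMI", 0.9170, 0.8696, 0.9671),
        ],
    )
    def test_published_transforms_with_endpoint_swap(self, term, transformed, tlo, thi):
        beta, lo, hi, _ = HYPERTENSION_TABLE[term]
        model = manual_model({term: beta}, {term: se_from_ci(lo, hi)})
        est = confint_transformed(model, term)
        assert round(est.transformed, 4) == transformed
        assert round(est.transformed_ci_lower, 4) == tlo
        assert round(est.transformed_ci_upper, 4) == thi
        # swap: lower transformed bound comes from the upper coefficient bound
        assert est.transformed_ci_lower == pytest.approx(math.exp(-est.ci_upper))
        assert est.transformed_ci_upper == pytest.approx(math.exp(-est.ci_lower))

    def test_null_beta_symmetric_on_log_scale(self):
        model = manual_model({"t": 0.0}, {"t": 0.3})
        est = confint_transformed(model, "t")
        assert est.transformed == 1.0
        assert est.transformed_ci_lower * est.transformed_ci_upper == pytest.approx(1.0)

    def test_transformed_estimate_inside_its_ci(self, rng):
        model = fit_complementary_log(random_2x2_table(rng))
        for term in model.terms:
            est = confint_transformed(model, term)
            assert est.transformed_ci_lower <= est.transformed <= est.transformed_ci_upper

    def test_bad_level(self, rng):
        model = fit_complementary_log(random_2x2_table(rng))
        with pytest.raises(ValueError, match="level"):
            confint_transformed(model, "x", level=1.5)


class TestPrismTest:
    def test_single_term_matches_wald_and_transform(self):
        beta, lo, hi, _ = HYPERTENSION_TABLE["Age:BMI"]
        model = manual_model({"Age:BMI": beta}, {"Age:BMI": se_from_ci(lo, hi)})
        res = prism_test(model, ["Age:BMI"])
        _, p_wald = wald_test(model, "Age:BMI")
        est = confint_transformed(model, "Age:BMI")
        assert res.p_value == p_wald
        assert res.prism == pytest.approx(math.exp(beta))
        assert res.inverse_prism == est.transformed
        assert res.prism * res.inverse_prism == pytest.approx(1.0, abs=1e-12)
        assert res.df == 1

    def test_joint_test_df_and_null(self):
        terms = [f"age[{k}]:personality" for k in (1, 2, 3, 4)]
        model = manual_model({t: 0.0 for t in terms}, {t: 0.1 for t in terms})
        res = prism_test(model, terms)
        assert res.df == 4
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.prism is None  # no single-index summary for joint tests

    def test_empty_term_set_rejected(self, rng):
        model = fit_complementary_log(random_2x2_table(rng))
        with pytest.raises(ValueError):
            prism_test(model, [])

    def test_default_terms_from_design(self, rng):
        model = fit_complementary_log(random_2x2_table(rng))
        res = prism_test(model)
        assert res.terms == ("x:z",)


class TestLikelihoodRatio:
    def test_published_lrt_arithmetic(self):
        full_terms = {f"t{i}": 0.0 for i in range(10)}
        red_terms = {f"t{i}": 0.0 for i in range(6)}
        full = manual_model(full_terms, {t: 1.0 for t in full_terms}, nll=851.0780)
        reduced = manual_model(red_terms, {t: 1.0 for t in red_terms}, nll=854.3623)
        res = likelihood_ratio_test(full, reduced)
        assert res.statistic == pytest.approx(6.5686, abs=1e-10)
        assert res.df == 4
        assert round(res.p_value, 4) == 0.1605

    def test_identical_models_give_zero(self, rng):
        model = fit_complementary_log(random_2x2_table(rng))
        res = likelihood_ratio_test(model, model)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_chi_square_quantile_identity(self):
        full = manual_model({"a": 0.0, "b": 0.0}, {"a": 1.0, "b": 1.0}, nll=0.0)
        reduced = manual_model({"a": 0.0}, {"a": 1.0}, nll=3.841459 / 2)
        res = likelihood_ratio_test(full, reduced)
        assert res.p_value == pytest.approx(0.05, abs=1e-6)

    def test_non_nested_rejected(self):
        full = manual_model({"a": 0.0}, {"a": 1.0})
        other = manual_model({"b": 0.0}, {"b": 1.0})
        with pytest.raises(ValueError, match="nested"):
            likelihood_ratio_test(full, other)

    def test_negative_statistic_rejected(self):
        full = manual_model({"a": 0.0, "b": 0.0}, {"a": 1.0, "b": 1.0}, nll=10.0)
        reduced = manual_model({"a": 0.0}, {"a": 1.0}, nll=5.0)
        with pytest.raises(ValueError, match="negative|nested"):
            likelihood_ratio_test(full, reduced)

    def test_wald_and_lrt_agree_asymptotically(self):
        # a large cohort with a genuine interaction class present
        spec = SufficientCauseSpec({"U1": 0.05, "U2": 0.03, "U6": 0.04})
        design = SimulationDesign(spec=spec, n=400_000, seed=11)
        cohort = simulate_cohort(design)
        full = fit_complementary_log(cohort)
        reduced = fit_complementary_log(
            cohort, design=ModelDesign.from_data(cohort, interaction_order=1)
        )
        z, _ = wald_test(full, "x:z")
        lrt = likelihood_ratio_test(full, reduced)
        assert lrt.statistic == pytest.approx(z**2, rel=0.05)


class TestReri:
    @pytest.mark.parametrize(
        "v11, v10, v01, expected",
        [
            (2.0, 1.5, 1.2, 0.3),
            (1.7, 1.5, 1.2, 0.0),  # exact additivity v11 = v10 + v01 - 1
            (1.0, 1.0, 1.0, 0.0),
        ],
    )
    def test_reri_arithmetic(self, v11, v10, v01, expected):
        assert reri(v11, v10, v01).reri == pytest.approx(expected, abs=1e-12)

    def test_one_sided_test_against_threshold(self):
        res0 = reri(3.0, 1.2, 1.1, se=0.5, null_threshold=0.0)
        res1 = reri(3.0, 1.2, 1.1, se=0.5, null_threshold=1.0)
        assert res0.reri == res1.reri == pytest.approx(1.7)
        assert res0.p_value < res1.p_value  # threshold 1 is more stringent

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError, match="v10"):
            reri(1.0, 0.0, 1.0)


class TestGamma:
    def test_elementwise_ratio(self):
        model = manual_model(
            {"Intercept": 0.10, "x": 0.05, "z": 0.02, "x:z": 0.01},
            {t: 0.1 for t in ("Intercept", "x", "z", "x:z")},
        )
        res = gamma_from_beta(model)
        assert res.gamma == pytest.approx({"x": 0.5, "z": 0.2, "x:z": 0.1})

    def test_null_effects_give_zero_gamma(self):
        model = manual_model(
            {"Intercept": 0.10, "x": 0.0}, {"Intercept": 0.1, "x": 0.1}
        )
        assert gamma_from_beta(model).gamma == {"x": 0.0}

    def test_nonpositive_intercept_rejected(self):
        model = manual_model({"Intercept": -0.1, "x": 0.05}, {"Intercept": 1, "x": 1})
        with pytest.raises(ValueError, match="rare-disease|positive"):
            gamma_from_beta(model)

    def test_rare_disease_gamma_approximates_excess_odds_ratio(self):
        # all cell risks < 0.01: gamma_1 should track OR(1,0) - 1 computed
        # directly from the simulated cell counts
        spec = SufficientCauseSpec({"U1": 0.002, "U2": 0.004})
        design = SimulationDesign(spec=spec, n=2_000_000, seed=5)
        cohort = simulate_cohort(design)
        model = fit_complementary_log(cohort)
        gamma1 = gamma_from_beta(model).gamma["x"]

        tab = cohort.table.set_index(["x", "z"])
        odds = {
            c: tab.loc[c, "cases"] / (tab.loc[c, "n"] - tab.loc[c, "cases"])
            for c in ((0, 0), (1, 0))
        }
        excess_or = odds[(1, 0)] / odds[(0, 0)] - 1
        assert gamma1 == pytest.approx(excess_or, rel=0.10)
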