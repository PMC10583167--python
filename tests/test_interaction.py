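"""Relative- and absolute-scale interaction surfaces: within-group RRs,
interaction ratios, RERI -> interaction contrast -> excess cases."""

import numpy as np
import pandas as pd
import pytest

from acehealth.glm import ModelSpec, SurveyDesign, fit_modified_poisson
from acehealth.interaction import (
    excess_cases,
    interaction_ratio_from_within,
    interaction_rr,
    reri,
    within_group_rr,
)
from acehealth.pool import PooledFit

from conftest import saturated_two_group_frame

GROUPS = ("White", "Black", "Asian", "AI/NA")


def make_pooled(params: dict[str, float], cov: np.ndarray | None = None,
                referent: str = "Multiracial", outcome: str = "asthma") -> PooledFit:
    labels = list(params)
    beta = pd.Series([params[k] for k in labels], index=labels)
    if cov is None:
        cov = 1e-4 * np.eye(len(labels))
    cov_df = pd.DataFrame(cov, index=labels, columns=labels)
    return PooledFit(
        params=beta, within=cov_df, between=0 * cov_df, cov=cov_df,
        df=pd.Series(np.full(len(labels), 1e12), index=labels), m=2,
        spec=ModelSpec(outcome=outcome, referent_race=referent),
    )


def interaction_labels(referent="Multiracial"):
    labels = {"Intercept": np.log(0.15)}
    for g in GROUPS:
        labels[f"race[{g}]"] = 0.0
    labels["elevated_aces"] = 0.0
    for g in GROUPS:
        labels[f"elevated_aces:race[{g}]"] = 0.0
    return labels


class TestWithinGroupRR:
    def test_null_model_gives_rr_one_everywhere(self):
        pooled = make_pooled(interaction_labels())
        for g in (*GROUPS, "Multiracial"):
            assert within_group_rr(pooled, g).estimate == pytest.approx(1.0)

    def test_published_style_linear_combination(self):
        """Referent RR 1.13 and interaction 0.92 compose to a White RR of
        1.04 at two decimals."""
        params = interaction_labels()
        params["elevated_aces"] = np.log(1.13)
        params["elevated_aces:race[White]"] = np.log(0.92)
        pooled = make_pooled(params)
        rr = within_group_rr(pooled, "White")
        assert rr.estimate == pytest.approx(1.13 * 0.92, abs=1e-12)
        assert round(rr.estimate, 2) == 1.04

    def test_unknown_group_rejected(self):
        pooled = make_pooled(interaction_labels())
        with pytest.raises(ValueError, match="does not contain term"):
            within_group_rr(pooled, "Martian")

    def test_ci_matches_independent_delta_recomputation(self):
        """CI from the pooled covariance equals an independently coded
        linear-combination computation on a random 5-term covariance."""
        rng = np.random.default_rng(17)
        a = rng.normal(size=(5, 5))
        cov = a @ a.T / 10
        labels = ["Intercept", "race[White]", "elevated_aces",
                  "elevated_aces:race[White]", "age"]
        beta = rng.normal(size=5)
        pooled = make_pooled(dict(zip(labels, beta)), cov=cov)
        rr = within_group_rr(pooled, "White")
        c = np.array([0.0, 0.0, 1.0, 1.0, 0.0])
        est = c @ beta
        se = np.sqrt(c @ cov @ c)
        from scipy.stats import norm

        crit = norm.ppf(0.975)
        assert rr.estimate == pytest.approx(np.exp(est), abs=1e-10)
        assert rr.ci_low == pytest.approx(np.exp(est - crit * se), abs=1e-10)
        assert rr.ci_high == pytest.approx(np.exp(est + crit * se), abs=1e-10)


class TestInteractionRR:
    def test_ratio_identity_on_published_values(self):
        assert round(interaction_ratio_from_within(1.04, 1.13), 2) == 0.92
        assert round(interaction_ratio_from_within(1.30, 1.13), 2) == 1.15

    def test_referent_returns_reference_marker(self):
        pooled = make_pooled(interaction_labels())
        ref = interaction_rr(pooled, "Multiracial")
        assert ref.is_referent and ref.estimate == 1.0

    def test_exponentiated_interaction_term(self):
        params = interaction_labels()
        params["elevated_aces:race[Asian]"] = np.log(0.89)
        pooled = make_pooled(params)
        assert interaction_rr(pooled, "Asian").estimate == pytest.approx(0.89)

    def test_model_identity_rr_ratio(self):
        """interaction RR x referent within-RR == group within-RR."""
        rng = np.random.default_rng(2)
        params = interaction_labels()
        params["elevated_aces"] = rng.normal()
        for g in GROUPS:
            params[f"elevated_aces:race[{g}]"] = rng.normal(scale=0.3)
        pooled = make_pooled(params)
        ref_rr = within_group_rr(pooled, "Multiracial").estimate
        for g in GROUPS:
            lhs = interaction_rr(pooled, g).estimate * ref_rr
            assert lhs == pytest.approx(within_group_rr(pooled, g).estimate, abs=1e-12)


def saturated_fit(risks: dict[tuple[int, int], float], group="White") -> PooledFit:
    """Fit the saturated two-group interaction model on an exact risk table."""
    frame = saturated_two_group_frame(risks, group=group)
    spec = ModelSpec(outcome="y", referent_race="Multiracial", covariates=())
    fit = fit_modified_poisson(frame, spec, SurveyDesign.from_frame(frame))
    pooled = PooledFit(
        params=fit.params, within=fit.cov, between=0 * fit.cov, cov=fit.cov,
        df=pd.Series(np.full(len(fit.params), 1e12), index=fit.params.index), m=1,
        spec=spec,
    )
    return pooled


class TestExcessCases:
    def test_null_model_gives_zero_excess_with_ci_covering_zero(self):
        pooled = make_pooled(interaction_labels())
        res = excess_cases(pooled, "White", n_resamples=4000, seed=1)
        assert res.excess_per_1000.estimate == pytest.approx(0.0, abs=1e-9)
        assert res.excess_per_1000.ci_low < 0 < res.excess_per_1000.ci_high

    def test_enumerated_risk_table_gives_150_per_1000(self):
        """R00=.10, R01=.20, R10=.15, R11=.40: IC = .15, so 150 per 1000
        via the RERI x R00 route on the saturated model."""
        pooled = saturated_fit({(0, 0): 0.10, (0, 1): 0.20, (1, 0): 0.15, (1, 1): 0.40})
        res = excess_cases(pooled, "White", n_resamples=2000, seed=3)
        assert res.excess_per_1000.estimate == pytest.approx(150.0, abs=1e-6)
        assert res.r00 == pytest.approx(0.10, abs=1e-9)
        assert res.reri * res.r00 * 1000 == pytest.approx(res.excess_per_1000.estimate)

    def test_resampling_ci_width_agrees_with_delta_method(self):
        """Percentile and delta-method widths agree within 10% on a toy fit
        with 10,000 resamples."""
        pooled = saturated_fit({(0, 0): 0.10, (0, 1): 0.20, (1, 0): 0.15, (1, 1): 0.40})
        res = excess_cases(pooled, "White", n_resamples=10_000, seed=7)
        beta = pooled.params.to_numpy()
        T = pooled.cov.to_numpy()

        def functional(b):
            from acehealth.interaction import _cell_log_risks

            rows = _cell_log_risks(pooled, "White", "Multiracial", {})
            r = np.exp(rows @ b)
            return 1000.0 * (r[3] - r[2] - r[1] + r[0])

        eps = 1e-6
        grad = np.array([
            (functional(beta + eps * np.eye(len(beta))[i])
             - functional(beta - eps * np.eye(len(beta))[i])) / (2 * eps)
            for i in range(len(beta))
        ])
        delta_width = 2 * 1.959964 * np.sqrt(grad @ T @ grad)
        pct_width = res.excess_per_1000.ci_high - res.excess_per_1000.ci_low
        assert pct_width == pytest.approx(delta_width, rel=0.10)

    def test_sign_coherence_follows_reri_not_interaction_rr(self):
        """Excess cases are negative iff RERI is negative; a multiplicative
        interaction below 1 can coexist with positive additive interaction
        and vice versa."""
        # interaction ratio 0.9 < 1 but RERI > 0
        params = interaction_labels()
        params["race[White]"] = np.log(2.0)
        params["elevated_aces"] = np.log(3.0)
        params["elevated_aces:race[White]"] = np.log(0.9)
        pooled = make_pooled(params)
        res = excess_cases(pooled, "White", n_resamples=500, seed=1)
        assert interaction_rr(pooled, "White").estimate < 1
        assert res.reri > 0 and res.excess_per_1000.estimate > 0
        # interaction ratio 1.2 > 1 but RERI < 0
        params = interaction_labels()
        params["race[White]"] = np.log(3.0)
        params["elevated_aces"] = np.log(0.1)
        params["elevated_aces:race[White]"] = np.log(1.2)
        pooled = make_pooled(params)
        res = excess_cases(pooled, "White", n_resamples=500, seed=1)
        assert interaction_rr(pooled, "White").estimate > 1
        assert res.reri < 0 and res.excess_per_1000.estimate < 0

    def test_resampling_seed_reproducible_and_stable_in_size(self):
        pooled = saturated_fit({(0, 0): 0.10, (0, 1): 0.20, (1, 0): 0.15, (1, 1): 0.40})
        a = excess_cases(pooled, "White", n_resamples=10_000, seed=11)
        b = excess_cases(pooled, "White", n_resamples=10_000, seed=11)
        assert (a.excess_per_1000.ci_low, a.excess_per_1000.ci_high) == (
            b.excess_per_1000.ci_low, b.excess_per_1000.ci_high)
        c = excess_cases(pooled, "White", n_resamples=20_000, seed=11)
        for lo_hi in ("ci_low", "ci_high"):
            x = getattr(a.excess_per_1000, lo_hi)
            y = getattr(c.excess_per_1000, lo_hi)
            assert abs(x - y) / max(abs(x), abs(y)) < 0.02

    def test_non_psd_covariance_rejected(self):
        params = interaction_labels()
        labels = list(params)
        bad = -np.eye(len(labels))
        pooled = make_pooled(params, cov=bad)
        with pytest.raises(ValueError, match="positive semi-definite"):
            excess_cases(pooled, "White", n_resamples=100, seed=0)

    def test_r00_above_one_rejected(self):
        params = interaction_labels()
        params["Intercept"] = 0.5  # exp(0.5) > 1
        pooled = make_pooled(params)
        with pytest.raises(ValueError, match="R00"):
            excess_cases(pooled, "White", n_resamples=100, seed=0)

    def test_marginal_standardization_route(self):
        """With r00 rows from the doubly-unexposed cell of a saturated
        table, marginal standardization reproduces the cell R00."""
        pooled = saturated_fit({(0, 0): 0.10, (0, 1): 0.20, (1, 0): 0.15, (1, 1): 0.40})
        p = len(pooled.params)
        row = np.zeros(p)
        row[list(pooled.params.index).index("Intercept")] = 1.0
        res = excess_cases(pooled, "White", n_resamples=1000, seed=2,
                           r00_rows=row[None, :], r00_weights=np.array([1.0]))
        assert res.r00 == pytest.approx(0.10, abs=1e-9)
        assert res.excess_per_1000.estimate == pytest.approx(150.0, abs=1e-6)


def test_point_estimate_unbiased_on_simulated_cohorts():
    """Excess cases per 1000 from the saturated model are unbiased for the
    generating interaction contrast over 200 replicates."""
    from acehealth import SimulationConfig
    from acehealth.derive import derive_all
    from acehealth.simulate import generate_cohort

    # cells: R00=.20, R01=.30, R10=.25, R11=.45 -> IC x 1000 = 100
    base = SimulationConfig()
    estimates = []
    for r in range(200):
        config = SimulationConfig(
            n_individuals=3000, seed=70_000 + r,
            race_proportions={"Multiracial": 0.5, "White": 0.5},
            ace_prevalence_by_race={"Multiracial": 0.35, "White": 0.25},
            baseline_risk_by_outcome={**base.baseline_risk_by_outcome, "asthma": 0.20},
            true_rr={"asthma": {"Multiracial": 1.5, "White": 1.8}},
            race_main_rr={"asthma": {"Multiracial": 1.0, "White": 1.25}},
        )
        cohort = generate_cohort(config)
        frame = derive_all(cohort)
        spec = ModelSpec(outcome="asthma", referent_race="Multiracial", covariates=())
        fit = fit_modified_poisson(frame, spec, SurveyDesign.from_frame(frame))
        pooled = PooledFit(
            params=fit.params, within=fit.cov, between=0 * fit.cov, cov=fit.cov,
            df=pd.Series(np.full(len(fit.params), 1e12), index=fit.params.index),
            m=1, spec=spec,
        )
        estimates.append(excess_cases(pooled, "White", n_resamples=200,
                                      seed=r).excess_per_1000.estimate)
    truth = 1000 * (0.45 - 0.25 - 0.30 + 0.20)
    mc_se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
    assert abs(np.mean(estimates) - truth) <= 3 * mc_se
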