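"""Scenario mechanisms: marginals, dependence, coefficient recovery,
theoretical ACE."""

import dataclasses

import numpy as np
import pytest
from scipy.special import expit

from gcompml import (CovariateSpec, EffectTerm, OutcomeModel, ScenarioConfig,
                     generate_replicates, get_scenario, oracle_cohort,
                     realistic_scenario, simplistic_scenario, simulate_cohort,
                     theoretical_ace)


def flat_scenario(intercept=0.0, exposure_coef=0.0, out_intercept=0.0):
    """One inert covariate; all covariate effects zero."""
    return ScenarioConfig(
        name="flat",
        covariates=(CovariateSpec("X1"),),
        exposure_intercept=intercept, exposure_coefs={},
        outcome=OutcomeModel(intercept=out_intercept,
                             exposure_coef=exposure_coef, terms=()),
    )


class TestSimulateCohort:
    def test_zero_coefficients_give_half_half_bernoullis(self):
        ds = simulate_cohort(flat_scenario(), 10000, seed=0)
        assert abs(ds.cohort.exposure.mean() - 0.5) < 0.015
        assert abs(ds.cohort.outcome.mean() - 0.5) < 0.015

    def test_realistic_preset_has_22_covariates(self):
        ds = simulate_cohort(realistic_scenario(), 100, seed=1)
        assert ds.cohort.k == 22

    def test_simplistic_covariates_mutually_independent(self):
        ds = simulate_cohort(simplistic_scenario(), 10000, seed=2)
        corr = np.corrcoef(ds.cohort.covariates.to_numpy().T)
        off = corr[~np.eye(9, dtype=bool)]
        assert np.max(np.abs(off)) < 0.05

    def test_realistic_covariates_actually_correlated(self):
        ds = simulate_cohort(realistic_scenario(), 10000, seed=3)
        corr = np.corrcoef(ds.cohort.covariates.to_numpy().T)
        off = corr[~np.eye(22, dtype=bool)]
        assert np.max(np.abs(off)) > 0.2

    def test_reproducible_given_seed(self):
        a = simulate_cohort(simplistic_scenario(), 100, seed=5)
        b = simulate_cohort(simplistic_scenario(), 100, seed=5)
        np.testing.assert_array_equal(a.cohort.outcome, b.cohort.outcome)
        np.testing.assert_array_equal(a.cohort.covariates.to_numpy(),
                                      b.cohort.covariates.to_numpy())

    def test_unknown_scenario_name_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            get_scenario("galactic")

    def test_acyclic_dependence_enforced(self):
        with pytest.raises(ValueError, match="not-yet-generated"):
            ScenarioConfig(
                name="bad",
                covariates=(CovariateSpec("A", depends={"B": 1.0}),
                            CovariateSpec("B")),
                exposure_intercept=0.0, exposure_coefs={},
                outcome=OutcomeModel(intercept=0.0, exposure_coef=0.0, terms=()),
            )


class TestCoefficientRecovery:
    """A correctly specified logistic regression on simulated data must
    recover the generating coefficients within 3 SEs (n = 50,000)."""

    def test_exposure_model_alpha(self):
        import statsmodels.api as sm
        sc = simplistic_scenario()
        ds = simulate_cohort(sc, 50000, seed=11)
        X = ds.cohort.covariates[list(sc.exposure_coefs)].to_numpy()
        res = sm.GLM(ds.cohort.exposure, sm.add_constant(X),
                     family=sm.families.Binomial()).fit()
        truth = np.array([sc.exposure_intercept, *sc.exposure_coefs.values()])
        np.testing.assert_array_less(np.abs(res.params - truth), 3 * res.bse)

    def test_outcome_model_beta(self):
        import statsmodels.api as sm
        sc = simplistic_scenario()
        ds = simulate_cohort(sc, 50000, seed=12)
        oc = oracle_cohort(sc, ds)
        X = np.column_stack([ds.cohort.exposure, oc.covariates.to_numpy()])
        res = sm.GLM(ds.cohort.outcome, sm.add_constant(X),
                     family=sm.families.Binomial()).fit()
        truth = np.array([sc.outcome.intercept, sc.outcome.exposure_coef,
                          *[t.coef for t in sc.outcome.terms]])
        np.testing.assert_array_less(np.abs(res.params - truth), 3 * res.bse)


class TestTheoreticalAce:
    def test_closed_form_when_covariate_effects_are_zero(self):
        """With no covariate effects, the truth is expit(a+b) - expit(a)."""
        sc = flat_scenario(exposure_coef=1.0, out_intercept=-1.0)
        res = theoretical_ace(sc, n_datasets=200, n_per_dataset=4000, seed=0)
        expected = expit(0.0) - expit(-1.0)        # 0.23106
        assert expected == pytest.approx(0.23106, abs=1e-4)
        assert abs(res.ace - expected) < 3 * res.mc_se

    def test_null_exposure_effect_gives_zero(self):
        sc = flat_scenario(exposure_coef=0.0)
        res = theoretical_ace(sc, n_datasets=200, n_per_dataset=2000, seed=1)
        assert abs(res.ace) < 3 * res.mc_se

    def test_invariant_to_randomization_probability(self):
        sc = simplistic_scenario()
        values = [theoretical_ace(sc, n_datasets=150, n_per_dataset=4000,
                                  z_prob=p, seed=2) for p in (0.3, 0.5, 0.7)]
        for a in values[1:]:
            tol = 3 * np.hypot(a.mc_se, values[0].mc_se)
            assert abs(a.ace - values[0].ace) < tol

    def test_mc_se_shrinks_like_root_n_datasets(self):
        sc = simplistic_scenario()
        se100 = theoretical_ace(sc, n_datasets=100, n_per_dataset=1000, seed=3).mc_se
        se400 = theoretical_ace(sc, n_datasets=400, n_per_dataset=1000, seed=3).mc_se
        assert se100 / se400 == pytest.approx(2.0, rel=0.35)

    def test_closed_form_mle_agrees_with_iterative_glm(self):
        """Dual route: the arm-mean contrast equals the fitted univariate
        logistic contrast expit(b0+b1) - expit(b0)."""
        import statsmodels.api as sm
        sc = simplistic_scenario()
        ds = simulate_cohort(sc, 5000, seed=4)
        z, y = ds.cohort.exposure, ds.cohort.outcome
        res = sm.GLM(y, sm.add_constant(z.astype(float)),
                     family=sm.families.Binomial()).fit()
        b0, b1 = res.params
        closed = y[z == 1].mean() - y[z == 0].mean()
        assert expit(b0 + b1) - expit(b0) == pytest.approx(closed, abs=1e-10)


class TestReplicates:
    def test_stream_is_deterministic_and_seeds_distinct(self):
        sc = simplistic_scenario()
        a = list(generate_replicates(sc, 50, 3, master_seed=9))
        b = list(generate_replicates(sc, 50, 3, master_seed=9))
        seeds = [d.seed for d in a]
        assert len(set(seeds)) == 3
        for x, y in zip(a, b):
            assert x.seed == y.seed
            np.testing.assert_array_equal(x.cohort.outcome, y.cohort.outcome)

    def test_prefix_stable_under_longer_streams(self):
        """Replicate r depends only on (master_seed, r), not on n_reps."""
        sc = simplistic_scenario()
        short = list(generate_replicates(sc, 40, 2, master_seed=4))
        long = list(generate_replicates(sc, 40, 5, master_seed=4))
        for x, y in zip(short, long):
            np.testing.assert_array_equal(x.cohort.outcome, y.cohort.outcome)

    def test_schema_constant_across_replicates(self):
        sc = realistic_scenario()
        reps = list(generate_replicates(sc, 60, 3, master_seed=1))
        names = {r.cohort.covariate_names for r in reps}
        assert len(names) == 1


class TestScenarioFiles:
    def test_yaml_round_trip_preserves_scenario(self, tmp_path):
        from gcompml import load_scenario, save_scenario
        for preset in (simplistic_scenario(), realistic_scenario()):
            path = tmp_path / f"{preset.name}.yaml"
            save_scenario(preset, path)
            assert load_scenario(path) == preset

    def test_shipped_files_match_code_presets(self):
        from importlib import resources
        from gcompml import load_scenario
        for preset in (simplistic_scenario(), realistic_scenario()):
            ref = resources.files("gcompml") / "scenarios" / f"{preset.name}.yaml"
            assert load_scenario(ref) == preset


class TestOracleCohort:
    def test_term_columns_and_binary_tags(self):
        sc = realistic_scenario()
        ds = simulate_cohort(sc, 200, seed=6)
        oc = oracle_cohort(sc, ds)
        # 9 term columns; the interaction covariate X5 already appears as a
        # linear term so no extra column is added
        assert oc.k == 9
        step_cols = [c for c in oc.covariate_names if c.endswith("_step")]
        assert len(step_cols) == 2
        assert set(step_cols) <= set(oc.binary_covariates)
        quad = oc.covariates["X1_quadratic"].to_numpy()
        np.testing.assert_allclose(
            quad, ds.cohort.covariates["X1"].to_numpy() ** 2)
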