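"""DSEM specification, sampler behaviour and diagnostics."""

import numpy as np
import pandas as pd
import pytest

from somnus import dsem
from somnus.dsem import (
    DsemModel,
    ModelSpec,
    Priors,
    build_design,
    loo_compare,
    ppc_mean,
    rhat,
    significance,
    vif,
)
from somnus.panel import decompose, impute


@pytest.fixture(scope="module")
def small_dp(small_panel):
    return decompose(small_panel, variables=dsem.MODEL1_VARIABLES)


@pytest.fixture(scope="module")
def small_fit(small_panel):
    """One reduced-size fit shared by several diagnostics tests."""
    dp = decompose(small_panel, variables=dsem.MODEL1_VARIABLES)
    spec = ModelSpec.model1(seed=3, iterations=2000)
    return dsem.fit(spec, dp)


class TestModelSpec:
    def test_model1_timings(self):
        spec = ModelSpec.model1()
        assert set(spec.outcomes) == {"tsu", "suib", "sleep_total"}
        paths = dict(spec.paths["sleep_total"])
        assert paths["tsu"] == "current" and paths["suib"] == "current"
        assert paths["sleep_total"] == "lagged"
        assert dict(spec.paths["tsu"]) == {
            "tsu": "lagged", "suib": "lagged", "sleep_total": "lagged"}
        assert dict(spec.paths["suib"])["tsu"] == "current"

    def test_model2_has_five_outcomes(self):
        spec = ModelSpec.model2()
        assert len(spec.outcomes) == 5
        assert dict(spec.paths["deep"])["suib"] == "current"
        assert dict(spec.paths["tsu"])["rem"] == "lagged"

    def test_cyclic_current_paths_rejected(self):
        with pytest.raises(ValueError, match="recursive order"):
            ModelSpec(outcomes=["a", "b"],
                      paths={"a": [("b", "current")], "b": [("a", "current")]})


class TestBuildDesign:
    def test_model1_sleep_outcome_columns(self, small_dp):
        spec = ModelSpec.model1()
        y, X, cols, pid, rows = build_design(spec, small_dp, "sleep_total")
        within = [(c["predictor"], c["timing"]) for c in cols if c["level"] == "within"]
        assert ("sleep_total", "lagged") in within
        assert ("tsu", "current") in within and ("suib", "current") in within
        assert sum(c["level"] == "between" for c in cols) == 3

    def test_rows_per_participant(self, small_dp, small_panel):
        spec = ModelSpec.model1()
        y, X, cols, pid, rows = build_design(spec, small_dp, "tsu")
        n = small_panel["participant_id"].nunique()
        assert len(y) == n * 13  # T=14 gives 13 lag-complete rows

    def test_unknown_outcome_rejected(self, small_dp):
        spec = ModelSpec.from_variables(["tsu", "suib", "sleep_total", "deep"])
        with pytest.raises(ValueError):
            build_design(spec, small_dp, "deep")


class TestSignificance:
    def test_point_mass_is_significant(self):
        assert significance(np.full(2000, 0.5))

    def test_symmetric_draws_not_significant(self):
        rng = np.random.default_rng(0)
        assert not significance(rng.standard_normal(4000))

    def test_narrow_positive_interval_significant(self):
        rng = np.random.default_rng(1)
        assert significance(rng.uniform(0.01, 0.02, size=2000))

    def test_matches_percentile_oracle_on_random_sets(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            draws = rng.standard_normal(500) + rng.uniform(-1, 1)
            lo, hi = np.percentile(draws, [2.5, 97.5])
            assert significance(draws) == (lo > 0 or hi < 0)


class TestRhat:
    def test_identical_iid_chains_near_one(self):
        rng = np.random.default_rng(3)
        chains = rng.standard_normal((2, 4000))
        assert abs(rhat(chains) - 1.0) < 0.005

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(4)
        chains = np.stack([rng.standard_normal(500), rng.standard_normal(500) + 10])
        assert rhat(chains) > 1.01

    def test_constant_chain_gives_nan(self):
        chains = np.stack([np.zeros(100), np.zeros(100)])
        assert np.isnan(rhat(chains))

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="2 chains"):
            rhat(np.zeros((1, 100)))


class TestVif:
    def test_orthogonal_columns(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((500, 3))
        X, _ = np.linalg.qr(X)
        np.testing.assert_allclose(vif(X), 1.0, atol=1e-4)

    def test_duplicated_column_flagged(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(200)
        X = np.column_stack([x, x, rng.standard_normal(200)])
        assert vif(X)[0] >= 1e6

    def test_known_correlation_closed_form(self):
        """Two columns with correlation 0.6 give VIF = 1/(1-0.36)."""
        rng = np.random.default_rng(7)
        n = 200_000
        a = rng.standard_normal(n)
        b = 0.6 * a + np.sqrt(1 - 0.36) * rng.standard_normal(n)
        np.testing.assert_allclose(vif(np.column_stack([a, b])), 1.5625, atol=0.01)


class TestFit:
    def test_null_data_yields_no_significant_within_paths(self):
        """With all generating coefficients zero, spurious significance
        stays near the nominal 5% rate."""
        from dataclasses import replace

        from somnus.synth import SynthConfig, simulate_panel

        n_sig = n_paths = 0
        for rep in range(6):
            cfg = SynthConfig(
                variables=list(dsem.MODEL1_VARIABLES),
                lag={v: {} for v in dsem.MODEL1_VARIABLES},
                current={}, n_participants=30, missing_rate=0.0,
                trait_var={v: 0.5 for v in dsem.MODEL1_VARIABLES},
            )
            panel, _ = simulate_panel(cfg, seed=100 + rep)
            dp = decompose(panel, variables=dsem.MODEL1_VARIABLES)
            res = dsem.fit(ModelSpec.model1(seed=rep, iterations=600), dp)
            for p in res.paths:
                if p.level == "within":
                    n_paths += 1
                    n_sig += p.significant
        assert n_sig / n_paths < 0.2

    def test_single_imputation_complete_data_equals_direct_fit(self, small_panel):
        dp = decompose(small_panel, variables=dsem.MODEL1_VARIABLES)
        spec = ModelSpec.model1(seed=5, iterations=400)
        direct = dsem.fit(spec, dp)
        imps = impute(small_panel, m=1, seed=5, variables=dsem.MODEL1_VARIABLES)
        pooled = dsem.fit(spec, imps)
        for a, b in zip(direct.paths, pooled.paths):
            assert a.beta == pytest.approx(b.beta, abs=1e-12)

    def test_pooling_invariant_to_imputation_order(self, holey_panel):
        from somnus.panel import ImputationSet

        imps = impute(holey_panel, m=3, seed=2, variables=dsem.MODEL1_VARIABLES)
        spec = ModelSpec.model1(seed=2, iterations=400)
        res_a = dsem.fit(spec, imps, debias=False)
        flipped = ImputationSet(imps.completed[::-1], imps.decomposed[::-1], seed=2)
        res_b = dsem.fit(spec, flipped, debias=False)
        for a, b in zip(res_a.paths, res_b.paths):
            # pooled means are order-free up to chain seeding per imputation
            assert a.beta == pytest.approx(b.beta, abs=0.02)

    def test_convergence_flag_and_rhat_reported(self, small_fit):
        tab = small_fit.path_table()
        assert tab["rhat"].notna().all()
        assert small_fit.converged

    def test_single_person_reduces_to_plain_regression(self):
        """With one participant the hierarchical fit collapses to an
        ordinary Bayesian regression; the posterior mean should match the
        (ridge-like) penalized least-squares solution within MC error."""
        from somnus.dsem import _gibbs

        rng = np.random.default_rng(8)
        n, p = 400, 3
        X = rng.standard_normal((n, p))
        beta_true = np.array([0.5, -0.3, 0.0])
        y = X @ beta_true + 0.7 * rng.standard_normal(n)
        draws = _gibbs(y, X, np.zeros(n, dtype=int), 2000, Priors(),
                       np.random.default_rng(9))
        post_mean = draws["beta"][:, 1:].mean(axis=0)
        sigma2 = float(np.mean(draws["sigma"] ** 2))
        ridge = np.linalg.solve(X.T @ X + sigma2 / 100.0 * np.eye(p), X.T @ y)
        np.testing.assert_allclose(post_mean, ridge, atol=0.05)


class TestDiagnostics:
    def test_ppc_typical_for_true_model(self, small_fit):
        p = ppc_mean(small_fit, max_draws=400, seed=0)
        for outcome, val in p.items():
            assert 0.1 < val < 0.9

    def test_ppc_limits_under_shifted_data(self, small_fit):
        import copy

        shifted = copy.deepcopy(small_fit)
        for of in shifted.outcome_fits.values():
            for des in of.designs:
                des["y"] = des["y"] + 10.0  # observed mean 10 SD above model
        p_low = ppc_mean(shifted, max_draws=200, seed=0)
        assert all(v < 0.01 for v in p_low.values())
        shifted2 = copy.deepcopy(small_fit)
        for of in shifted2.outcome_fits.values():
            for des in of.designs:
                des["y"] = des["y"] - 10.0
        p_high = ppc_mean(shifted2, max_draws=200, seed=0)
        assert all(v > 0.99 for v in p_high.values())

    def test_loo_self_comparison_is_zero(self, small_fit):
        diff, se = loo_compare(small_fit, small_fit, max_draws=300, seed=1)
        assert diff == pytest.approx(0.0, abs=1e-9)

    def test_loo_mismatched_observations_rejected(self, small_fit, holey_panel):
        subset = holey_panel[holey_panel.participant_id != "sim001"]
        imps = impute(subset, m=1, seed=0, variables=dsem.MODEL1_VARIABLES)
        other = dsem.fit(ModelSpec.model1(seed=1, iterations=300), imps)
        with pytest.raises(ValueError, match="observation sets"):
            loo_compare(small_fit, other, max_draws=200, seed=1)


class TestEstimatorApi:
    def test_sklearn_params_roundtrip(self):
        model = DsemModel(chains=2, iterations=500, seed=1)
        params = model.get_params()
        clone = DsemModel(**{k: v for k, v in params.items()})
        assert clone.get_params() == params

    def test_fitted_attributes(self, small_panel):
        model = DsemModel(model=1, iterations=400, seed=6)
        model.fit(decompose(small_panel, variables=dsem.MODEL1_VARIABLES))
        assert isinstance(model.paths_, pd.DataFrame)
        assert set(model.vif_) == set(dsem.MODEL1_VARIABLES)
        assert model.predict("tsu").shape[0] > 0
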