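import warnings

import numpy as np
import pytest

from prevmap import standardize as stz
from prevmap import synthetic as syn
from prevmap.geography import icar_structure_matrix
from prevmap.models import (
    ModelConfig,
    fit_model,
    fitted_relative_risks,
    icar_full_conditional,
    write_draws,
)


def small_fit(Y, E, graph, seed=1, **kw):
    defaults = dict(
        model_form="spatial", n_iterations=1200, n_burnin=600, n_chains=1, seed=seed
    )
    defaults.update(kw)
    cfg = ModelConfig(**defaults)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_model(Y, E, kw.get("X"), graph, None, cfg)


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            ModelConfig(model_form="bogus")
        with pytest.raises(ValueError):
            ModelConfig(n_iterations=100, n_burnin=100)
        with pytest.raises(ValueError):
            ModelConfig(hyperprior="jeffreys")
        with pytest.raises(ValueError):
            ModelConfig(interaction_type="V")


class TestIcarFullConditional:
    def test_hand_case_path(self, path3):
        mean, var = icar_full_conditional([1.0, 0.0, 3.0], "B", path3, 2.0)
        assert mean == pytest.approx(2.0)
        assert var == pytest.approx(1.0)

    def test_all_neighbors_zero(self, path3):
        mean, _ = icar_full_conditional([0.0, 5.0, 0.0], "B", path3, 1.0)
        assert mean == 0.0

    def test_variance_formula(self, grid4):
        # interior cell of a rook 4x4 grid has 4 neighbors
        counts = grid4.neighbor_counts()
        i = int(np.argmax(counts == 4))
        _, var = icar_full_conditional(np.zeros(16), i, grid4, 1.0)
        assert var == pytest.approx(0.25)

    def test_island_error(self):
        from prevmap.geography import IslandRegionError, adjacency_from_edges

        with pytest.warns(UserWarning):
            g = adjacency_from_edges([("A", "B")], region_ids=["A", "B", "C"])
        with pytest.raises(IslandRegionError):
            icar_full_conditional([0, 0, 0], "C", g, 1.0)


class TestDegenerateAndNull:
    def test_degenerate_intercept_matches_poisson_mle(self, lattice96):
        rng = np.random.default_rng(0)
        E = rng.uniform(50, 150, size=96)
        Y = rng.poisson(E * 1.3)
        fit = small_fit(
            Y, E, lattice96, seed=5,
            n_iterations=2000, n_burnin=1000, n_chains=2,
            sigma2_fixed={"u": 0.0, "v": 0.0},
        )
        target = np.log(Y.sum() / E.sum())
        assert fit.draws["alpha"].mean() == pytest.approx(target, abs=0.01)

    def test_null_data_rr_near_one(self, grid4):
        E = np.full(16, 400.0)
        Y = E.copy()  # Y = E exactly
        fit = small_fit(
            Y, E, grid4, seed=2,
            sigma2_fixed={"u": 1e-4, "v": 1e-4},
        )
        rr = fitted_relative_risks(fit)
        assert rr.rr_median.between(0.9, 1.1).all()

    def test_zero_population_cells_excluded(self, grid4):
        E = np.full(16, 100.0)
        E[3] = 0.0
        Y = np.random.default_rng(1).poisson(E)
        fit = small_fit(Y, E, grid4, seed=3)
        assert not fit.mask[3, 0]
        assert fit.mask.sum() == 15


class TestSamplerCorrectness:
    def test_prior_only_icar_covariance(self):
        g = syn.generate_lattice(1, 5, 0.0, seed=0)
        K = icar_structure_matrix(g)
        cfg = ModelConfig(
            model_form="spatial", n_iterations=55_000, n_burnin=5_000,
            n_chains=1, seed=7, prior_only=True,
            sigma2_fixed={"u": 2.0, "v": 0.0},
        )
        fit = fit_model(np.zeros(5), np.ones(5), None, g, None, cfg)
        emp = np.cov(fit.draws["u"].T)
        target = 2.0 * np.linalg.pinv(K.entries)
        rel = np.linalg.norm(emp - target) / np.linalg.norm(target)
        assert rel < 0.1

    def test_glm_limit_matches_ml(self, lattice96):
        import statsmodels.api as sm

        rng = np.random.default_rng(10)
        x = rng.standard_normal(96)
        E = rng.uniform(80, 120, size=96)
        Y = rng.poisson(E * np.exp(0.3 * x))
        cfg = ModelConfig(
            model_form="spatial", covariates=("x",),
            n_iterations=4000, n_burnin=2000, n_chains=2, seed=11,
            sigma2_fixed={"u": 0.0, "v": 0.0},
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_model(Y, E, x, lattice96, None, cfg)
        glm = sm.GLM(
            Y, sm.add_constant(x), family=sm.families.Poisson(),
            offset=np.log(E),
        ).fit()
        from prevmap._mcmc import ess_geyer

        bd = fit.draws["beta"][:, 0]
        chains = bd.reshape(2, -1)
        mcse = bd.std() / np.sqrt(max(ess_geyer(chains), 1.0))
        assert abs(bd.mean() - glm.params[1]) < 2 * mcse + 1e-4

    def test_exchangeability_region_relabeling(self, grid4):
        from prevmap.geography import sample_intrinsic_gmrf

        rng = np.random.default_rng(4)
        E = rng.uniform(200, 400, 16)
        u_true = sample_intrinsic_gmrf(
            icar_structure_matrix(grid4), 0.3, 1, rng
        )[0]
        Y = rng.poisson(E * np.exp(u_true))
        # invariance holds in distribution (the realized chain depends on
        # label-dependent update ordering), so compare posterior means at
        # Monte Carlo tolerance
        kw = dict(n_iterations=6000, n_burnin=3000, n_chains=1)
        fit1 = small_fit(Y, E, grid4, seed=100, **kw)
        perm = rng.permutation(16)
        from prevmap.geography import AdjacencyGraph

        g2 = AdjacencyGraph(
            tuple(grid4.region_ids[i] for i in perm), grid4.edges
        )
        idx = [grid4.region_ids.index(r) for r in g2.region_ids]
        fit2 = small_fit(Y[idx], E[idx], g2, seed=200, **kw)
        u1 = fit1.draws["u"].mean(axis=0)
        u2 = fit2.draws["u"].mean(axis=0)
        assert np.corrcoef(u1[idx], u2)[0, 1] > 0.97
        nrmse = np.sqrt(np.mean((u1[idx] - u2) ** 2)) / u1.std()
        assert nrmse < 0.25

    def test_st_main_is_interaction_with_tiny_variance(self):
        # fixing the interaction variance near zero reproduces the
        # main-effects fit (checked on posterior mean linear predictors)
        b = syn.make_bundle(4, 4, years=range(2000, 2004), seed=20,
                            model_form="st_main",
                            truth=syn.TrueParams(
                                sigma2={"u": 0.05, "v": 0.01, "gamma": 0.01,
                                        "phi": 0.02},
                                seed=20,
                            ))
        exp = stz.expected_counts(b.cube, pool_time=False)
        Y = b.cube.case_totals()
        common = dict(n_iterations=1500, n_burnin=750, n_chains=1, seed=21)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit_main = fit_model(
                Y, exp, None, b.graph, 4,
                ModelConfig(model_form="st_main", **common),
            )
            fit_tiny = fit_model(
                Y, exp, None, b.graph, 4,
                ModelConfig(
                    model_form="st_interaction",
                    sigma2_fixed={"delta": 1e-8},
                    **common,
                ),
            )
        eta_main = fit_main.log_rr_draws().mean(axis=0)
        eta_tiny = fit_tiny.log_rr_draws().mean(axis=0)
        assert np.abs(eta_main - eta_tiny).mean() < 0.05


class TestConstraintsAndDraws:
    def test_sum_to_zero_constraints(self):
        b = syn.make_bundle(4, 4, years=range(2000, 2004), seed=30)
        exp = stz.expected_counts(b.cube, pool_time=False)
        Y = b.cube.case_totals()
        cfg = ModelConfig(
            model_form="st_interaction", n_iterations=600, n_burnin=300,
            n_chains=1, seed=31,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_model(Y, exp, None, b.graph, 4, cfg)
        assert np.abs(fit.draws["u"].sum(axis=1)).max() < 1e-8
        assert np.abs(fit.draws["phi"].sum(axis=1)).max() < 1e-8
        d = fit.draws["delta"]
        assert np.abs(d.sum(axis=1)).max() < 1e-8  # over space per time
        assert np.abs(d.sum(axis=2)).max() < 1e-8  # over time per space

    def test_draw_count_and_determinism(self, grid4):
        rng = np.random.default_rng(5)
        E = rng.uniform(50, 100, 16)
        Y = rng.poisson(E)
        cfg = dict(n_iterations=800, n_burnin=400, n_chains=2, thinning=2, seed=77)
        f1 = small_fit(Y, E, grid4, **cfg)
        f2 = small_fit(Y, E, grid4, **cfg)
        assert f1.n_draws == 2 * (800 - 400) // 2
        np.testing.assert_array_equal(f1.draws["alpha"], f2.draws["alpha"])
        np.testing.assert_array_equal(f1.draws["u"], f2.draws["u"])

    def test_lambda_positive(self, grid4):
        rng = np.random.default_rng(6)
        E = rng.uniform(50, 100, 16)
        fit = small_fit(rng.poisson(E), E, grid4, seed=8)
        assert (fit.lambda_draws() > 0).all()

    def test_island_rejected(self):
        from prevmap.geography import IslandRegionError, adjacency_from_edges

        with pytest.warns(UserWarning):
            g = adjacency_from_edges([("A", "B")], region_ids=["A", "B", "C"])
        with pytest.raises(IslandRegionError):
            small_fit(np.ones(3), np.ones(3), g)

    def test_uniform_hyperprior_runs(self, grid4):
        rng = np.random.default_rng(9)
        E = rng.uniform(50, 100, 16)
        Y = rng.poisson(E * np.exp(0.2 * rng.standard_normal(16)))
        fit = small_fit(Y, E, grid4, seed=13, hyperprior="uniform",
                        n_iterations=600, n_burnin=300)
        assert np.all(fit.draws["sigma2_u"] > 0)
        assert np.all(fit.draws["sigma2_u"] <= 100.0 + 1e-9)


class TestRelativeRisks:
    def test_rr_identity_when_lambda_equals_e(self, grid4):
        E = np.full(16, 300.0)
        fit = small_fit(E.copy(), E, grid4, seed=14,
                        sigma2_fixed={"u": 1e-6, "v": 1e-6})
        rr = fitted_relative_risks(fit)
        assert rr.rr_median.between(0.95, 1.05).all()

    def test_median_of_three(self):
        assert float(np.median([0.8, 1.0, 1.25])) == 1.0

    def test_covariate_rr_scaling(self):
        # RR for a 0.1-proportion step equals exp(0.1 * beta_per_unit)
        beta_raw_per_unit = 0.7
        step = 0.1
        assert np.exp(step * beta_raw_per_unit) == pytest.approx(
            np.exp(beta_raw_per_unit * step)
        )
        # and the design-scale coefficient (per 0.1 step) is 0.1*beta_raw
        from prevmap.covariates import assemble_covariates
        from test_covariates import factor_model_census

        tbl, _ = factor_model_census(n=10, seed=15)
        cov = assemble_covariates(tbl)
        X = cov.design_matrix(("indigenous",), tbl["region_id"])
        np.testing.assert_allclose(
            X[:, 0] * cov.scaling["indigenous_step"],
            tbl["prop_indigenous"],
        )

    def test_write_draws(self, tmp_path, grid4):
        rng = np.random.default_rng(16)
        E = rng.uniform(50, 100, 16)
        fit = small_fit(rng.poisson(E), E, grid4, seed=17,
                        n_iterations=300, n_burnin=150)
        p = tmp_path / "draws.csv"
        write_draws(fit, p, parameters=["alpha", "sigma2_u"])
        lines = p.read_text().splitlines()
        assert lines[0] == "parameter,chain,iteration,value"
        assert len(lines) == 1 + 2 * 150
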