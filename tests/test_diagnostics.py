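import warnings

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.stats import poisson as pois

from prevmap import standardize as stz
from prevmap import synthetic as syn
from prevmap.diagnostics import (
    build_report,
    cpo,
    dic,
    exceedance_probabilities,
    export_geojson_choropleth,
    pit,
    rr_interval_ranking,
    variance_shares,
)
from prevmap.models import FitResult, ModelConfig, fit_model


def manual_fit(Y, E, eta_draws, u_draws=None):
    """FitResult with hand-chosen log-RR draws (stored in the u field)."""
    eta_draws = np.asarray(eta_draws, dtype=float)
    S, n = eta_draws.shape
    draws = {
        "alpha": np.zeros(S),
        "beta": np.zeros((S, 0)),
        "u": eta_draws if u_draws is None else u_draws,
        "v": np.zeros((S, n)),
        "sigma2_u": np.ones(S),
        "sigma2_v": np.ones(S),
    }
    E = np.asarray(E, dtype=float)[:, None]
    return FitResult(
        draws=draws,
        chain_id=np.zeros(S, dtype=int),
        config=ModelConfig(model_form="spatial", seed=1, n_chains=1),
        region_ids=tuple(f"r{i}" for i in range(n)),
        years=(0,),
        Y=np.asarray(Y, dtype=float)[:, None],
        E=E,
        X=None,
        mask=E > 0,
        effects=("v", "u"),
    )


def quick_fit(Y, E, graph, seed=1, **kw):
    defaults = dict(
        model_form="spatial", n_iterations=1500, n_burnin=750, n_chains=1,
        seed=seed,
    )
    defaults.update(kw)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_model(Y, E, None, graph, None, ModelConfig(**defaults))


class TestDic:
    def test_point_mass_posterior_has_zero_pd(self):
        Y = np.array([3.0, 7.0, 5.0])
        E = np.ones(3)
        eta = np.log(np.array([[4.0, 6.0, 5.0]])).repeat(10, axis=0)
        d, p_eff = dic(manual_fit(Y, E, eta))
        assert p_eff == pytest.approx(0.0, abs=1e-9)
        lam = np.array([4.0, 6.0, 5.0])
        dev = -2 * pois.logpmf(Y, lam).sum()
        assert d == pytest.approx(dev)

    def test_saturated_beats_constant_on_heterogeneous_counts(self):
        rng = np.random.default_rng(1)
        Y = rng.poisson(np.linspace(2, 40, 10)).astype(float)
        Y = np.maximum(Y, 1.0)
        E = np.ones(10)
        eta_sat = np.log(Y)[None, :].repeat(5, axis=0)
        eta_const = np.full((5, 10), np.log(Y.mean()))
        d_sat, _ = dic(manual_fit(Y, E, eta_sat))
        d_const, _ = dic(manual_fit(Y, E, eta_const))
        assert d_sat < d_const

    def test_noise_covariate_penalty_is_small(self, grid4):
        deltas = []
        for s in range(10):
            rng = np.random.default_rng(s)
            E = rng.uniform(80, 120, 16)
            Y = rng.poisson(E)
            x = rng.standard_normal(16)
            common = dict(
                n_iterations=1500, n_burnin=750,
                sigma2_fixed={"u": 0.0, "v": 0.0},
            )
            f0 = quick_fit(Y, E, grid4, seed=s + 1, **common)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f1 = fit_model(
                    Y, E, x, grid4, None,
                    ModelConfig(
                        model_form="spatial", covariates=("x",),
                        n_iterations=1500, n_burnin=750, n_chains=1,
                        seed=s + 1, sigma2_fixed={"u": 0.0, "v": 0.0},
                    ),
                )
            deltas.append(dic(f1)[0] - dic(f0)[0])
        # soft check: one pure-noise covariate costs about one pD unit
        assert -1.0 < np.mean(deltas) < 3.0
        assert np.max(np.abs(deltas)) < 6.0

    def test_region_relabeling_invariance(self):
        Y = np.array([3.0, 9.0, 4.0, 6.0])
        E = np.full(4, 5.0)
        eta = 0.1 * np.random.default_rng(0).standard_normal((20, 4))
        d1, _ = dic(manual_fit(Y, E, eta))
        perm = [2, 0, 3, 1]
        d2, _ = dic(manual_fit(Y[perm], E[perm], eta[:, perm]))
        assert d1 == pytest.approx(d2, abs=1e-9)


class TestCpo:
    def test_single_draw_equals_likelihood(self):
        Y = np.array([2.0, 4.0])
        E = np.ones(2)
        lam = np.array([3.0, 3.5])
        fit = manual_fit(Y, E, np.log(lam)[None, :])
        cpo_i, s = cpo(fit)
        np.testing.assert_allclose(cpo_i, pois.pmf(Y, lam))
        assert s == pytest.approx(np.log(pois.pmf(Y, lam)).sum())

    def test_harmonic_mean_matches_loo_refit_oracle(self):
        # brute-force leave-one-out refits are the gold standard
        rng = np.random.default_rng(42)
        y = rng.poisson(5.0, size=50).astype(float)
        E = np.ones(50)
        g = syn.generate_lattice(5, 10, 0.0, seed=1)
        common = dict(
            n_iterations=3000, n_burnin=1000,
            sigma2_fixed={"u": 0.0, "v": 0.0},
        )
        fit_full = quick_fit(y, E, g, seed=7, **common)
        _, sum_log = cpo(fit_full)
        oracle = []
        for i in range(50):
            Ei = E.copy()
            Ei[i] = 0.0  # excluded from the likelihood -> LOO posterior
            f = quick_fit(y, Ei, g, seed=100 + i, **common)
            lam_i = np.exp(f.draws["alpha"])
            oracle.append(pois.pmf(y[i], lam_i).mean())
        oracle_sum = np.log(np.array(oracle)).sum()
        assert abs(sum_log - oracle_sum) / abs(oracle_sum) < 0.05

    def test_misspecified_model_has_lower_sum_log_cpo(self):
        rng = np.random.default_rng(3)
        Y = rng.poisson(10.0, size=30).astype(float)
        E = np.ones(30)
        good = manual_fit(Y, E, np.full((50, 30), np.log(10.0)))
        bad = manual_fit(Y, E, np.full((50, 30), np.log(25.0)))  # mean shift
        assert cpo(bad)[1] < cpo(good)[1]

    def test_zero_likelihood_draw_warns(self):
        Y = np.array([400.0])
        E = np.ones(1)
        eta = np.array([[-800.0], [np.log(400.0)]])
        with pytest.warns(UserWarning, match="zero-likelihood"):
            cpo_i, _ = cpo(manual_fit(Y, E, eta))
        assert np.isfinite(cpo_i).all()


class TestPit:
    def test_upper_tail(self):
        Y = np.array([300.0])
        E = np.ones(1)
        fit = manual_fit(Y, E, np.zeros((10, 1)))  # predictive is Poisson(1)
        assert pit(fit, randomize=False)[0] == pytest.approx(1.0, abs=1e-9)

    def test_midpoint_at_predictive_median(self):
        # choose lambda so that F(0) + F(1) = 1: the midpoint PIT of the
        # observation y=1 is then exactly 0.5
        lam = brentq(lambda l: pois.cdf(0, l) + pois.cdf(1, l) - 1.0, 0.5, 5.0)
        fit = manual_fit(np.array([1.0]), np.ones(1), np.log([[lam]]))
        assert pit(fit, randomize=False)[0] == pytest.approx(0.5, abs=1e-9)

    def test_randomized_within_bracket_and_deterministic(self):
        rng = np.random.default_rng(8)
        Y = rng.poisson(6.0, 20).astype(float)
        E = np.ones(20)
        fit = manual_fit(Y, E, np.full((30, 20), np.log(6.0)))
        u1 = pit(fit, randomize=True, seed=5)
        u2 = pit(fit, randomize=True, seed=5)
        np.testing.assert_array_equal(u1, u2)
        lo = pois.cdf(Y - 1, 6.0)
        hi = pois.cdf(Y, 6.0)
        assert ((u1 >= lo) & (u1 <= hi)).all()


class TestVarianceShares:
    def test_only_one_effect_nonzero(self):
        Y = np.ones(4)
        E = np.ones(4)
        eta = np.tile([0.5, -0.5, 0.25, -0.25], (10, 1))
        fit = manual_fit(Y, E, eta)  # u nonzero, v zero
        shares = variance_shares(fit)
        assert shares["structured_spatial"] == pytest.approx(100.0)
        assert shares["unstructured_spatial"] == pytest.approx(0.0)

    def test_equal_split(self):
        Y = np.ones(4)
        E = np.ones(4)
        field = np.tile([1.0, -1.0, 2.0, -2.0], (10, 1))
        fit = manual_fit(Y, E, field)
        fit.draws["v"] = field.copy()
        shares = variance_shares(fit)
        assert shares["structured_spatial"] == pytest.approx(50.0)
        assert shares["unstructured_spatial"] == pytest.approx(50.0)

    def test_sums_to_100(self):
        b = syn.make_bundle(4, 4, years=range(2000, 2004), seed=3)
        exp = stz.expected_counts(b.cube, pool_time=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_model(
                b.cube.case_totals(), exp, None, b.graph, 4,
                ModelConfig(
                    model_form="st_interaction", n_iterations=600,
                    n_burnin=300, n_chains=1, seed=4,
                ),
            )
        shares = variance_shares(fit)
        assert sum(shares.values()) == pytest.approx(100.0, abs=1e-6)
        assert len(shares) == 5

    def test_all_zero_errors(self):
        fit = manual_fit(np.ones(4), np.ones(4), np.zeros((5, 4)))
        with pytest.raises(ValueError, match="shares undefined"):
            variance_shares(fit)


class TestExceedance:
    def test_all_above(self):
        fit = manual_fit(np.ones(2), np.ones(2), np.full((10, 2), 0.3))
        assert (exceedance_probabilities(fit).exceedance == 1.0).all()

    def test_half_above(self):
        eta = np.log(np.array([0.8, 0.9, 1.1, 1.2]))[:, None]
        fit = manual_fit(np.ones(1), np.ones(1), eta)
        assert exceedance_probabilities(fit).exceedance[0] == pytest.approx(0.5)

    def test_threshold_zero_and_monotone(self):
        rng = np.random.default_rng(1)
        eta = 0.3 * rng.standard_normal((40, 6))
        fit = manual_fit(np.ones(6), np.ones(6), eta)
        assert (exceedance_probabilities(fit, threshold=0.0).exceedance == 1).all()
        prev = np.ones(6)
        for thr in (0.5, 0.9, 1.0, 1.1, 2.0):
            cur = exceedance_probabilities(fit, threshold=thr).exceedance.to_numpy()
            assert (cur <= prev + 1e-12).all()
            prev = cur


class TestRanking:
    def _fit_with_intervals(self):
        rng = np.random.default_rng(2)
        eta = np.stack(
            [
                rng.normal(np.log(1.08), 0.007, 400),  # interval above 1
                rng.normal(np.log(1.06), 0.03, 400),  # interval covers 1
                rng.normal(np.log(0.87), 0.02, 400),  # interval below 1
            ],
            axis=1,
        )
        return manual_fit(np.ones(3), np.ones(3), eta)

    def test_classes(self):
        df = rr_interval_ranking(self._fit_with_intervals())
        by_region = df.set_index("region")["class"]
        assert by_region["r0"] == "above"
        assert by_region["r1"] == "null"
        assert by_region["r2"] == "below"

    def test_sorted_by_median_desc(self):
        df = rr_interval_ranking(self._fit_with_intervals())
        assert (df.rr_median.diff().dropna() <= 1e-12).all()


class TestReportAndExport:
    def test_build_and_write(self, tmp_path):
        b = syn.make_bundle(4, 4, years=[2000], model_form="spatial", seed=5)
        exp = stz.expected_counts(b.cube, pool_time=True)
        fit = quick_fit(b.cube.case_totals()[:, 0], exp.E, b.graph, seed=6)
        report = build_report(fit, pit_seed=3)
        files = report.write(tmp_path, prefix="diag")
        assert all(f.exists() for f in files)
        assert report.cpo_i.min() > 0
        assert ((report.pit_i >= 0) & (report.pit_i <= 1)).all()

    def test_geojson_export(self, tmp_path):
        b = syn.make_bundle(2, 3, years=[2000], model_form="spatial", seed=7)
        exp = stz.expected_counts(b.cube, pool_time=True)
        fit = quick_fit(
            b.cube.case_totals()[:, 0], exp.E, b.graph, seed=8,
            n_iterations=400, n_burnin=200,
        )
        features = []
        for rid in b.graph.region_ids:
            r, c = b.graph.coords[rid]
            features.append(
                {
                    "type": "Feature",
                    "properties": {"region_id": rid},
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [[
                            [c, r], [c + 1, r], [c + 1, r + 1], [c, r + 1], [c, r]
                        ]],
                    },
                }
            )
        gj = {"type": "FeatureCollection", "features": features}
        out = tmp_path / "map.geojson"
        export_geojson_choropleth(fit, gj, out)
        import json

        back = json.loads(out.read_text())
        props = back["features"][0]["properties"]
        assert {"rr_median", "rr_lo", "rr_hi", "exceedance", "class"} <= set(props)
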