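"""BYM2 engine: ICAR scaling, sampler correctness, exceedance rules."""

import numpy as np
import pytest
from scipy import stats

import enwas
from enwas.spatial import (
    PriorConfig,
    exceedance,
    fit_bym2,
    sample_structured_field,
    scaled_icar,
    structured_share,
)


def eigen_oracle_scaling(L):
    """Geometric mean of constrained-pseudo-inverse marginal variances."""
    w, U = np.linalg.eigh(L)
    keep = w > w[-1] * 1e-9
    var = (U[:, keep] ** 2 / w[keep]).sum(axis=1)
    return float(np.exp(np.mean(np.log(var))))


class TestScaledIcar:
    def test_path_graph_matches_eigendecomposition_oracle(self, path3):
        st3 = scaled_icar(path3)
        L = np.array([[1, -1, 0], [-1, 2, -1], [0, -1, 1]], dtype=float)
        assert st3.scaling_factors[0] == pytest.approx(eigen_oracle_scaling(L), abs=1e-12)

    def test_cycle_graph_all_marginal_variances_one(self):
        g = enwas.AreaGraph.from_edges(
            list("abcde"), [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"), ("e", "a")]
        )
        Q = scaled_icar(g).Q.toarray()
        w, U = np.linalg.eigh(Q)
        keep = w > w[-1] * 1e-9
        var = (U[:, keep] ** 2 / w[keep]).sum(axis=1)
        np.testing.assert_allclose(var, 1.0, atol=1e-10)

    def test_post_scaling_geometric_mean_is_one(self, planar60):
        Q = scaled_icar(planar60).Q.toarray()
        assert eigen_oracle_scaling(Q) == pytest.approx(1.0, abs=1e-6)

    def test_identical_components_get_identical_factors(self):
        g = enwas.AreaGraph.from_edges(
            list("abcdef"), [("a", "b"), ("b", "c"), ("d", "e"), ("e", "f")]
        )
        st2 = scaled_icar(g)
        assert st2.scaling_factors[0] == pytest.approx(st2.scaling_factors[1], rel=1e-12)

    def test_island_carries_no_structured_effect(self):
        g = enwas.AreaGraph.from_edges(list("abc"), [("a", "b")])
        st2 = scaled_icar(g)
        assert st2.island_mask.tolist() == [False, False, True]
        rng = np.random.default_rng(0)
        u = sample_structured_field(st2, rng)
        assert u[2] == 0.0


@pytest.fixture(scope="module")
def fitted_small():
    """One moderate BYM2 fit shared across read-only assertions."""
    g = enwas.simulate_graph(80, "random-planar", seed=5)
    truth = enwas.sample_truth(g, [0.4], 0.3, 0.7, seed=8)
    X = enwas.simulate_exposures(g, 1, seed=2)
    E = np.full(80, 40.0)
    O = enwas.simulate_counts(E, X, truth, g)
    fit = fit_bym2(O, E, X.values.to_numpy(), graph=g, chains=2, iterations=2000, seed=3)
    return g, truth, O, E, X, fit


class TestFitBym2:
    def test_recovers_covariate_effect(self, fitted_small):
        *_, fit = fitted_small
        pr = fit.params.loc["beta_x0"]
        assert pr["cri_lo"] < 0.4 < pr["cri_hi"]

    def test_area_summaries_are_coherent(self, fitted_small):
        *_, fit = fitted_small
        a = fit.areas
        assert ((a["rr_lo"] <= a["rr_mean"]) & (a["rr_mean"] <= a["rr_hi"])).mean() >= 0.99
        np.testing.assert_allclose(a["prob_above_1"] + a["prob_below_1"], 1.0, atol=1e-12)

    def test_retained_structured_draws_sum_to_zero(self, fitted_small):
        *_, fit = fitted_small
        u = fit.draws["u"]
        assert np.abs(u.sum(axis=-1)).max() < 1e-8

    def test_phi_draws_in_unit_interval(self, fitted_small):
        *_, fit = fitted_small
        phi = fit.phi_draws()
        assert phi.min() >= 0.0 and phi.max() <= 1.0

    def test_deterministic_given_seed(self):
        g = enwas.simulate_graph(25, "lattice", seed=0)
        E = np.full(25, 30.0)
        O = np.random.default_rng(1).poisson(E)
        f1 = fit_bym2(O, E, None, graph=g, chains=2, iterations=400, seed=9)
        f2 = fit_bym2(O, E, None, graph=g, chains=2, iterations=400, seed=9)
        np.testing.assert_array_equal(f1.draws["sigma"], f2.draws["sigma"])
        np.testing.assert_array_equal(f1.draws["b"], f2.draws["b"])

    def test_flat_data_intercept_near_offset_mle(self):
        g = enwas.simulate_graph(100, "lattice", seed=0)
        E = np.full(100, 600.0)
        O = np.round(E * 1.2)
        fit = fit_bym2(O, E, None, graph=g, chains=2, iterations=1500, seed=2)
        assert fit.params.loc["intercept", "mean"] == pytest.approx(np.log(1.2), abs=0.02)

    def test_large_counts_tight_prior_gives_unit_rr(self):
        g = enwas.simulate_graph(36, "lattice", seed=0)
        E = np.full(36, 800.0)
        O = np.round(E)
        tight = PriorConfig(sigma_rate=np.log(100) / 0.05)  # Pr(sigma > 0.05) = 1%
        fit = fit_bym2(O, E, None, graph=g, priors=tight, chains=2, iterations=1500, seed=4)
        assert (fit.areas["rr_mean"].between(0.95, 1.05)).all()

    def test_nonconvergence_is_flagged_not_hidden(self):
        g = enwas.simulate_graph(40, "lattice", seed=0)
        E = np.full(40, 20.0)
        O = np.random.default_rng(0).poisson(E)
        fit = fit_bym2(O, E, None, graph=g, chains=2, iterations=120, seed=1)
        # far too few draws for ESS > 400: must be flagged
        assert not fit.converged
        assert fit.diagnostics["min_ess_bulk"] <= 400

    def test_input_validation(self, planar60):
        E = np.full(60, 10.0)
        with pytest.raises(ValueError, match="positive"):
            fit_bym2(np.ones(60), np.zeros(60), None, graph=planar60)
        with pytest.raises(ValueError, match="chains"):
            fit_bym2(np.ones(60), E, None, graph=planar60, chains=1)
        with pytest.raises(ValueError, match="rank-deficient"):
            x = np.arange(60.0)
            fit_bym2(np.ones(60), E, np.column_stack([x, x]), graph=planar60)


class TestPriorSampling:
    def test_prior_only_reproduces_sigma_and_phi_priors(self):
        g = enwas.simulate_graph(16, "lattice", seed=0)
        E = np.full(16, 10.0)
        fit = fit_bym2(
            np.ones(16), E, None, graph=g, chains=2, iterations=5000,
            seed=12, prior_only=True,
        )
        phi = fit.phi_draws()
        sig = fit.sigma_draws()
        assert len(phi) == 5000
        ks_phi = stats.kstest(phi, "uniform")
        ks_sig = stats.kstest(sig, "expon", args=(0, 1 / np.log(100)))
        assert ks_phi.pvalue > 0.01
        assert ks_sig.pvalue > 0.01


class TestReduction:
    def test_sigma_zero_matches_frequentist_screen(self):
        g = enwas.simulate_graph(60, "random-planar", seed=1)
        r = np.random.default_rng(3)
        E = r.uniform(20, 60, 60)
        x = r.normal(size=60)
        O = r.poisson(E * np.exp(0.1 + 0.3 * x))
        freq = enwas.fit_poisson_offset(O, E, x)
        bayes = fit_bym2(
            O, E, x, graph=g, priors=PriorConfig(sigma_fixed=0.0),
            chains=2, iterations=3000, seed=6,
        )
        a = bayes.params.loc["intercept"]
        b = bayes.params.loc["beta_x0"]
        assert abs(a["mean"] - freq.intercept) < 2 * a["sd"]
        assert abs(b["mean"] - freq.beta) < 2 * b["sd"]
        # posterior sd close to the Wald standard error
        assert b["sd"] == pytest.approx(freq.se, rel=0.25)


class TestExceedance:
    def test_forced_classifications(self):
        draws = np.full((1000, 3), 1.2)
        draws[:, 1] = 0.5
        draws[:200, 2] = 0.9
        draws[200:, 2] = 1.1  # exactly 800/1000 above 1
        out = exceedance(draws)
        assert list(out["classification"]) == ["elevated", "lowered", "elevated"]
        assert out.loc[0, "prob_above"] == 1.0

    def test_symmetric_draws_uncertain(self, rng):
        draws = np.exp(rng.normal(0, 0.2, size=(2000, 1)))
        out = exceedance(draws)
        assert out.loc[0, "classification"] == "uncertain"
        assert out.loc[0, "prob_above"] == pytest.approx(0.5, abs=0.05)

    def test_monotone_in_probability_threshold(self, rng):
        draws = np.exp(rng.normal(0, 0.3, size=(1000, 40)))
        previous = None
        for thr in [0.6, 0.7, 0.8, 0.9, 0.99]:
            cls = exceedance(draws, prob_threshold=thr)["classification"]
            decided = set(np.where(cls != "uncertain")[0])
            if previous is not None:
                assert decided <= previous  # raising the bar never decides more areas
            previous = decided

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError, match="100"):
            exceedance(np.ones((50, 2)))


class TestStructuredShare:
    def test_degenerate_point_mass(self):
        mean, (lo, hi) = structured_share(np.full(500, 0.78))
        assert mean == pytest.approx(0.78)
        assert lo == pytest.approx(0.78) and hi == pytest.approx(0.78)

    def test_uniform_draws(self, rng):
        mean, (lo, hi) = structured_share(rng.uniform(size=20_000))
        assert mean == pytest.approx(0.5, abs=0.02)
        assert lo == pytest.approx(0.025, abs=0.02)
        assert hi == pytest.approx(0.975, abs=0.02)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            structured_share(np.array([]))
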