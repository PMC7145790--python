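"""Poisson-offset screen: IRLS against independent maximisers, FWER plumbing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

import enwas
from enwas.screen import (
    ConvergenceFailure,
    DegenerateDataError,
    bonferroni_threshold,
    fit_poisson_offset,
    manhattan_values,
    qq_points,
    screen_exposures,
)


def newton_oracle(O, E, x):
    """Independent maximiser of the Poisson-offset log-likelihood."""

    def nll(theta):
        eta = theta[0] + theta[1] * x + np.log(E)
        return -(O @ eta - np.exp(eta).sum())

    def grad(theta):
        mu = np.exp(theta[0] + theta[1] * x + np.log(E))
        return -np.array([(O - mu).sum(), (O - mu) @ x])

    res = optimize.minimize(nll, np.zeros(2), jac=grad, method="BFGS",
                            options={"gtol": 1e-12, "maxiter": 500})
    return res.x


class TestFitPoissonOffset:
    def test_observed_equal_expected_gives_zero_coefficients(self, rng):
        E = rng.uniform(5, 50, 15)
        x = rng.normal(size=15)
        fit = fit_poisson_offset(E.copy(), E, x)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)
        assert fit.beta == pytest.approx(0.0, abs=1e-9)

    def test_offset_only_closed_form(self):
        fit = fit_poisson_offset([2, 4], [1, 1])
        assert fit.beta is None
        assert fit.intercept == pytest.approx(np.log(3), rel=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_independent_newton_maximiser(self, seed):
        r = np.random.default_rng(seed)
        n = 20
        E = r.uniform(2, 80, n)
        x = r.normal(size=n)
        O = r.poisson(E * np.exp(0.2 + 0.4 * x))
        if O.sum() == 0:
            pytest.skip("degenerate draw")
        fit = fit_poisson_offset(O, E, x)
        a_hat, b_hat = newton_oracle(O.astype(float), E, x)
        assert fit.beta == pytest.approx(b_hat, abs=1e-6)
        assert fit.intercept == pytest.approx(a_hat, abs=1e-6)

    def test_agrees_with_reference_glm_implementation(self, rng):
        import statsmodels.api as sm

        E = rng.uniform(3, 90, 40)
        x = rng.normal(size=40)
        O = rng.poisson(E * np.exp(-0.2 + 0.3 * x)).astype(float)
        fit = fit_poisson_offset(O, E, x)
        ref = sm.GLM(
            O, sm.add_constant(x), family=sm.families.Poisson(), offset=np.log(E)
        ).fit()
        assert fit.beta == pytest.approx(ref.params[1], abs=1e-8)
        assert fit.se == pytest.approx(ref.bse[1], rel=1e-6)
        assert fit.p == pytest.approx(ref.pvalues[1], abs=1e-8)

    def test_missing_covariate_areas_dropped(self, rng):
        E = rng.uniform(5, 20, 30)
        x = rng.normal(size=30)
        O = rng.poisson(E)
        x_miss = x.copy()
        x_miss[5:10] = np.nan
        fit = fit_poisson_offset(O, E, x_miss)
        keep = np.ones(30, bool)
        keep[5:10] = False
        ref = fit_poisson_offset(O[keep], E[keep], x[keep])
        assert fit.beta == pytest.approx(ref.beta, rel=1e-12)
        assert fit.n_areas == 25

    def test_all_zero_counts_degenerate(self):
        with pytest.raises(DegenerateDataError):
            fit_poisson_offset([0, 0, 0], [1.0, 2.0, 3.0], [0.1, 0.2, 0.3])

    def test_non_convergence_reports_diagnostics(self):
        # absurdly tight tolerance with one iteration allowed
        with pytest.raises(ConvergenceFailure) as exc:
            fit_poisson_offset([3, 9, 2], [1.0, 1.0, 1.0], [0.0, 1.0, 2.0], max_iter=1)
        assert exc.value.iterations == 1

    @given(shift=st.floats(-50, 50), seed=st.integers(0, 30))
    @settings(max_examples=20, deadline=None)
    def test_covariate_shift_invariance(self, shift, seed):
        r = np.random.default_rng(seed)
        E = r.uniform(5, 40, 25)
        x = r.normal(size=25)
        O = r.poisson(E * np.exp(0.1 * x))
        if O.sum() == 0:
            return
        f1 = fit_poisson_offset(O, E, x)
        f2 = fit_poisson_offset(O, E, x + shift)
        assert f2.beta == pytest.approx(f1.beta, abs=1e-7)
        assert f2.se == pytest.approx(f1.se, rel=1e-6)
        assert f2.p == pytest.approx(f1.p, abs=1e-7)


class TestBonferroni:
    @pytest.mark.parametrize("m,alpha,expect", [(1, 0.05, 0.05), (10, 0.05, 0.005)])
    def test_simple_cases(self, m, alpha, expect):
        assert bonferroni_threshold(m, alpha) == pytest.approx(expect)

    def test_53_tests_printed_threshold(self):
        # 0.05/53 rounds to 0.0009 at one significant figure
        t = bonferroni_threshold(53, 0.05)
        assert t == pytest.approx(9.434e-4, rel=1e-3)
        assert float(f"{t:.1g}") == 0.0009

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0)


class TestManhattanAndQQ:
    def test_manhattan_trivial_values(self):
        df = pd.DataFrame(
            {"p": [0.01, 1.0, 1e-4], "beta_hat": [-1.0, 0.5, 2.0]},
            index=["a", "b", "c"],
        )
        got = manhattan_values(df)
        assert got["a"] == pytest.approx(-2.0)
        assert got["b"] == pytest.approx(0.0)
        assert got["c"] == pytest.approx(4.0)

    def test_qq_single_midpoint(self):
        expected, observed = qq_points([0.5])
        assert expected[0] == pytest.approx(np.log10(2))
        assert observed[0] == pytest.approx(np.log10(2))

    def test_qq_uniform_grid_near_diagonal(self):
        m = 200
        p = (np.arange(1, m + 1)) / m
        expected, observed = qq_points(p)
        # grid k/m against midpoints (k-0.5)/m: off by at most log10(2)
        diff = np.abs(expected - observed)
        assert diff.max() <= np.log10(2) + 1e-9
        assert np.median(diff) < 0.01

    def test_qq_uniform_draws_within_kolmogorov_band(self, rng):
        m = 1000
        p = rng.uniform(size=m)
        expected, observed = qq_points(p)
        # compare on the p scale: KS distance against the 99th pct band
        d = np.max(np.abs(10.0**-observed - 10.0**-expected))
        band = stats.ksone.ppf(0.995, m)
        assert d < band * 1.5  # order-statistic midpoints vs KS band, slack 1.5

    def test_qq_empty_rejected(self):
        with pytest.raises(ValueError):
            qq_points([])


class TestScreenExposures:
    def test_screen_flags_true_signal(self, small_region):
        r = small_region
        O = r.observed().to_numpy(float)
        E = enwas.expected_counts(r.counts).expected.to_numpy()
        out = screen_exposures(O, E, r.exposures)
        assert set(out.index) == set(r.exposures.variables)
        assert (out["p"].dropna() <= 1).all()
        # significance flag consistent with the Bonferroni rule
        thr = bonferroni_threshold(r.exposures.n_variables)
        assert (out["significant"] == (out["p"] < thr)).all()
        # CI brackets the point estimate
        ok = out.dropna()
        assert ((ok["rr_lo"] <= ok["rr"]) & (ok["rr"] <= ok["rr_hi"])).all()

    def test_empty_exposures(self, planar60):
        X = enwas.simulate_exposures(planar60, 0, seed=0)
        out = screen_exposures(np.ones(60), np.ones(60), X)
        assert out.empty
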