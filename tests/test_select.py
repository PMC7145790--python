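"""Covariate selection, correlation clustering, temporal consistency."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import enwas
from enwas.containers import ExposureMatrix
from enwas.select import (
    ecological_regression,
    select_covariates,
    spearman_matrix,
    temporal_split_correlation,
)


def expo(df):
    return ExposureMatrix(df)


class TestSpearmanMatrix:
    def test_monotone_transform_gives_unit_correlation(self, rng):
        x = rng.normal(size=50)
        C = spearman_matrix(expo(pd.DataFrame({"x": x, "x3": x**3, "neg": -x})))
        assert C.loc["x", "x3"] == pytest.approx(1.0)
        assert C.loc["x", "neg"] == pytest.approx(-1.0)

    def test_tied_data_matches_midrank_pearson_oracle(self, rng):
        x = rng.integers(0, 4, size=80).astype(float)  # heavy ties
        y = rng.integers(0, 4, size=80).astype(float)
        C = spearman_matrix(expo(pd.DataFrame({"x": x, "y": y})))
        rx = stats.rankdata(x)  # midranks
        ry = stats.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert C.loc["x", "y"] == pytest.approx(oracle, abs=1e-12)

    def test_constant_variable_is_missing_with_warning(self, caplog, rng):
        df = pd.DataFrame({"x": rng.normal(size=30), "c": np.ones(30)})
        with caplog.at_level("WARNING"):
            C = spearman_matrix(expo(df))
        assert np.isnan(C.loc["c", "x"])
        assert "constant" in caplog.text


def make_screen(variables, p, adjusted_p):
    return pd.DataFrame({"p": p, "adjusted_p": adjusted_p}, index=pd.Index(variables, name="variable"))


def make_mapping(variables, lo, hi):
    return pd.DataFrame({"rr_lo": lo, "rr_hi": hi}, index=pd.Index(variables, name="variable"))


class TestSelectCovariates:
    def test_no_candidate_gives_empty_selection(self):
        sc = make_screen(["a", "b"], [0.5, 0.9], [1.0, 1.0])
        mp = make_mapping(["a", "b"], [0.9, 0.8], [1.1, 1.2])
        corr = pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"])
        out = select_covariates(sc, mp, corr)
        assert not out["selected"].any()
        assert (out["reason"] == "failed screen(s)").all()

    def test_highly_correlated_pair_keeps_exactly_one(self):
        sc = make_screen(["a", "b"], [1e-5, 1e-4], [0.001, 0.01])
        mp = make_mapping(["a", "b"], [1.01, 1.02], [1.2, 1.3])
        corr = pd.DataFrame([[1.0, 0.95], [0.95, 1.0]], index=["a", "b"], columns=["a", "b"])
        out = select_covariates(sc, mp, corr, rho_max=0.7)
        assert out["selected"].sum() == 1
        assert out.loc["a", "selected"]  # smallest screen p wins

    def test_screen_significant_but_cri_spans_one_is_excluded(self):
        # e.g. a pollutant with screen p < 0.001 but mapping CrI 0.942-1.005
        sc = make_screen(["pm", "ok"], [1e-6, 1e-6], [1e-4, 1e-4])
        mp = make_mapping(["pm", "ok"], [0.942, 1.01], [1.005, 1.10])
        corr = pd.DataFrame(np.eye(2), index=["pm", "ok"], columns=["pm", "ok"])
        out = select_covariates(sc, mp, corr)
        assert not out.loc["pm", "selected"]
        assert not out.loc["pm", "passed_mapping"]
        assert out.loc["ok", "selected"]

    def test_deterministic_under_variable_reordering(self, rng):
        variables = [f"v{k}" for k in range(8)]
        p = rng.uniform(1e-8, 1e-3, 8)
        sc = make_screen(variables, p, p * 8)
        mp = make_mapping(variables, np.full(8, 1.01), np.full(8, 1.2))
        M = rng.uniform(-1, 1, (8, 8))
        C = (M + M.T) / 2
        np.fill_diagonal(C, 1.0)
        corr = pd.DataFrame(C, index=variables, columns=variables)
        base = select_covariates(sc, mp, corr)
        perm = list(rng.permutation(variables))
        shuffled = select_covariates(
            sc.loc[perm], mp.loc[perm], corr.loc[perm, perm]
        )
        pd.testing.assert_frame_equal(base, shuffled)

    def test_selected_pairs_below_rho_max(self, rng):
        variables = [f"v{k}" for k in range(10)]
        p = rng.uniform(1e-8, 1e-4, 10)
        sc = make_screen(variables, p, p * 10)
        mp = make_mapping(variables, np.full(10, 1.01), np.full(10, 1.3))
        M = rng.uniform(0, 1, (10, 10))
        C = (M + M.T) / 2
        np.fill_diagonal(C, 1.0)
        corr = pd.DataFrame(C, index=variables, columns=variables)
        out = select_covariates(sc, mp, corr, rho_max=0.7)
        chosen = list(out.index[out["selected"]])
        for i, a in enumerate(chosen):
            for b in chosen[i + 1 :]:
                assert abs(corr.loc[a, b]) < 0.7

    def test_manual_override_representative(self):
        sc = make_screen(["a", "b"], [1e-5, 1e-4], [0.001, 0.01])
        mp = make_mapping(["a", "b"], [1.01, 1.02], [1.2, 1.3])
        corr = pd.DataFrame([[1.0, 0.95], [0.95, 1.0]], index=["a", "b"], columns=["a", "b"])
        out = select_covariates(sc, mp, corr, representatives={0: "b"})
        assert out.loc["b", "selected"] and not out.loc["a", "selected"]


class TestEcologicalRegression:
    def test_duplicate_covariate_rejected(self, small_region):
        r = small_region
        E = enwas.expected_counts(r.counts).expected.to_numpy()
        with pytest.raises(ValueError, match="duplicate"):
            ecological_regression(
                r.observed().to_numpy(float), E, r.exposures,
                [r.exposures.variables[0]] * 2, r.graph,
            )

    def test_collinear_covariates_rejected(self, small_region):
        r = small_region
        E = enwas.expected_counts(r.counts).expected.to_numpy()
        X = r.exposures.values.copy()
        X["dup"] = X[r.exposures.variables[0]]
        with pytest.raises(ValueError, match="rank-deficient"):
            ecological_regression(
                r.observed().to_numpy(float), E, ExposureMatrix(X),
                [r.exposures.variables[0], "dup"], r.graph,
                chains=2, iterations=300, seed=0,
            )

    def test_empty_selection_reduces_to_disease_mapping(self, small_region):
        r = small_region
        E = enwas.expected_counts(r.counts).expected.to_numpy()
        O = r.observed().to_numpy(float)
        fit = ecological_regression(O, E, r.exposures, [], r.graph,
                                    chains=2, iterations=600, seed=1)
        assert set(fit.params.index) == {"intercept", "sigma", "phi"}
        assert len(fit.areas) == r.graph.n_areas

    def test_two_true_effects_detected_jointly(self):
        # power check at moderate effect size on one seeded replicate
        g = enwas.simulate_graph(150, "random-planar", seed=20)
        X = enwas.simulate_exposures(g, 6, seed=21)
        beta = np.zeros(6)
        beta[[1, 4]] = [0.5, -0.5]
        truth = enwas.sample_truth(g, beta, 0.2, 0.5, seed=22)
        E = np.full(150, 40.0)
        O = enwas.simulate_counts(E, X, truth, g)
        fit = ecological_regression(
            O, E, X, X.variables, g, chains=2, iterations=1500, seed=23
        )
        b1 = fit.params.loc[f"beta_{X.variables[1]}"]
        b4 = fit.params.loc[f"beta_{X.variables[4]}"]
        assert b1["cri_lo"] > 0
        assert b4["cri_hi"] < 0


class TestTemporalSplit:
    def test_identical_periods_correlate_perfectly(self):
        x = np.array([3.0, 9.0, 1.0, 7.0])
        assert temporal_split_correlation(x, x) == pytest.approx(1.0)

    def test_scale_invariance(self):
        x = np.array([3.0, 9.0, 1.0, 7.0])
        assert temporal_split_correlation(x, 2 * x) == pytest.approx(1.0)

    def test_matches_covariance_formula_oracle(self, rng):
        a = rng.poisson(30, 50).astype(float)
        b = rng.poisson(30, 50).astype(float)
        got = temporal_split_correlation(a, b)
        oracle = ((a - a.mean()) @ (b - b.mean())) / (
            np.sqrt(((a - a.mean()) ** 2).sum()) * np.sqrt(((b - b.mean()) ** 2).sum())
        )
        assert got == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_is_missing(self, caplog):
        with caplog.at_level("WARNING"):
            out = temporal_split_correlation(np.ones(5), np.arange(5.0))
        assert np.isnan(out)
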