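"""Bayesian disease mapping with a BYM2 convolution random effect.

The model for observed area counts ``O_i`` with expected counts ``E_i`` and
optional covariates ``x_i`` is

    O_i ~ Poisson(E_i * exp(a + x_i' beta + b_i))
    b_i = sigma * (sqrt(phi) * u*_i + sqrt(1 - phi) * v_i)

where ``u*`` is an intrinsic CAR (ICAR) field scaled so the geometric mean of
its marginal variances is 1, ``v`` is iid standard normal over-dispersion,
``sigma >= 0`` is the marginal standard deviation of the combined effect and
``phi`` in [0, 1] is the mixing parameter: the share of random-effect
variability attributed to the spatially structured component.

Inference is MCMC: Metropolis-within-Gibbs with vectorised colour-group
updates for the latent fields and adaptive random-walk scales (adaptation
frozen after warm-up).  Convergence is assessed with split-R-hat and bulk
effective sample size; a fit that misses the thresholds is returned with an
explicit non-convergence flag, never silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .graph import AreaGraph, greedy_colouring

__all__ = [
    "PriorConfig",
    "ScaledStructure",
    "PosteriorSummary",
    "scaled_icar",
    "sample_structured_field",
    "fit_bym2",
    "exceedance",
    "structured_share",
]


@dataclass(frozen=True)
class PriorConfig:
    """Priors for the BYM2 model.

    ``sigma`` has an exponential prior with rate chosen so that
    ``Pr(sigma > 1) = 0.01`` by default (a penalised-complexity-style
    shrinkage prior); ``phi`` is uniform on [0, 1]; the intercept and
    covariate coefficients have vague zero-mean normals.  ``sigma_fixed``
    and ``phi_fixed`` pin a parameter instead of sampling it (``sigma_fixed=0``
    switches the random effect off entirely).
    """

    intercept_sd: float = 10.0
    beta_sd: float = 10.0
    sigma_rate: float = math.log(100.0)  # Pr(sigma > 1) = 0.01
    sigma_fixed: float | None = None
    phi_fixed: float | None = None


@dataclass
class ScaledStructure:
    """Scaled ICAR precision structure for an areal graph.

    ``Q`` is the graph Laplacian with each connected component multiplied by
    its scaling factor, so that the geometric mean of the marginal variances
    of the constrained field is 1 within every (multi-node) component.
    Single-node components (islands) carry no structured effect.
    """

    graph: AreaGraph
    Q: sparse.csr_matrix
    scaling_factors: tuple[float, ...]
    components: list[np.ndarray] = field(repr=False)
    island_mask: np.ndarray = field(repr=False)

    @property
    def n_areas(self) -> int:
        return self.graph.n_areas


def _geomean(x: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(x))))


def scaled_icar(graph: AreaGraph) -> ScaledStructure:
    """Build the scaled ICAR structure for ``graph``.

    Per component, the marginal variances of the sum-to-zero-constrained ICAR
    field are the diagonal of the Moore-Penrose pseudo-inverse of the
    component Laplacian; the scaling factor is their geometric mean, and the
    component block of ``Q`` is multiplied by it so the scaled field has unit
    typical (geometric-mean) marginal variance.
    """
    n = graph.n_areas
    A = graph.adjacency()
    deg = graph.degrees()
    L = sparse.diags(deg) - A
    comps = graph.components()
    island = np.zeros(n, dtype=bool)
    factors: list[float] = []
    Q = L.tolil().astype(float)
    for comp in comps:
        if len(comp) == 1:
            island[comp[0]] = True
            factors.append(float("nan"))
            continue
        Lc = L[np.ix_(comp, comp)].toarray()
        # constrained generalised inverse: drop the null (constant) mode
        # explicitly rather than trusting a generic pseudo-inverse cutoff
        w, U = np.linalg.eigh(Lc)
        keep = w > w[-1] * 1e-9
        var = (U[:, keep] ** 2 / w[keep]).sum(axis=1)
        g = _geomean(var)
        factors.append(g)
        Q[np.ix_(comp, comp)] = g * Lc
    return ScaledStructure(graph, Q.tocsr(), tuple(factors), comps, island)


def sample_structured_field(struct: ScaledStructure, rng: np.random.Generator) -> np.ndarray:
    """Draw one scaled ICAR field: N(0, Q^+) with sum-to-zero per component.

    Sampling is by eigendecomposition of each scaled component Laplacian,
    placing independent normals on the non-null eigenvectors.  Islands get 0.
    """
    n = struct.n_areas
    u = np.zeros(n)
    for comp in struct.components:
        m = len(comp)
        if m == 1:
            continue
        Qc = struct.Q[np.ix_(comp, comp)].toarray()
        w, U = np.linalg.eigh(Qc)
        keep = w > w[-1] * 1e-10
        z = rng.standard_normal(int(keep.sum()))
        u[comp] = U[:, keep] @ (z / np.sqrt(w[keep]))
    return u


@dataclass
class PosteriorSummary:
    """Posterior summaries from a BYM2 fit.

    ``areas``: per-area relative-risk summaries (rr_mean, rr_lo, rr_hi,
    prob_above_1, prob_below_1), indexed by area_id.  ``params``: posterior
    mean / 95% CrI / split-R-hat / bulk ESS for the intercept, each
    coefficient, sigma and phi.  ``draws``: retained samples keyed by
    parameter name (chains x draws [x dim]).  ``converged`` is False when any
    monitored split-R-hat >= 1.01 or bulk ESS <= 400.
    """

    areas: pd.DataFrame
    params: pd.DataFrame
    draws: dict[str, np.ndarray]
    converged: bool
    diagnostics: dict

    def rr_draws(self) -> np.ndarray:
        """Flattened per-area relative-risk draws, shape (total_draws, n_areas)."""
        b = self.draws["b"]
        return np.exp(b.reshape(-1, b.shape[-1]))

    def phi_draws(self) -> np.ndarray:
        return self.draws["phi"].reshape(-1)

    def sigma_draws(self) -> np.ndarray:
        return self.draws["sigma"].reshape(-1)


class ConvergenceError(RuntimeError):
    pass


def _validate_inputs(O, E, X, graph):
    O = np.asarray(O, dtype=float)
    E = np.asarray(E, dtype=float)
    n = graph.n_areas
    if O.shape != (n,) or E.shape != (n,):
        raise ValueError("O and E must have one entry per graph area")
    if np.any(E <= 0):
        raise ValueError("all expected counts E must be strictly positive")
    if np.any(O < 0):
        raise ValueError("observed counts must be non-negative")
    if X is None:
        Xm = np.empty((n, 0))
    else:
        Xm = np.asarray(X, dtype=float)
        if Xm.ndim == 1:
            Xm = Xm[:, None]
        if Xm.shape[0] != n:
            raise ValueError("covariate matrix must have one row per area")
        if np.isnan(Xm).any():
            raise ValueError("covariates passed to fit_bym2 must be complete")
    return O, E, Xm


_ACC_TARGET = 0.44  # canonical optimum for component-wise random walks


def _run_chain(
    O: np.ndarray,
    E: np.ndarray,
    X: np.ndarray,
    struct: ScaledStructure,
    colours: np.ndarray,
    priors: PriorConfig,
    iterations: int,
    warmup: int,
    thin: int,
    rng: np.random.Generator,
    prior_only: bool,
    eig: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> dict[str, np.ndarray]:
    n = len(O)
    p = X.shape[1]
    lik_scale = 0.0 if prior_only else 1.0

    Q = struct.Q
    qdiag = Q.diagonal()
    W = (sparse.diags(qdiag) - Q).tocsr()  # scaled adjacency (positive weights)
    island = struct.island_mask
    comps = [c for c in struct.components if len(c) > 1]
    free = ~island
    groups = [np.where((colours == c) & free)[0] for c in np.unique(colours)]
    groups = [g for g in groups if len(g)]
    W_rows = [W[g] for g in groups]  # per-group neighbour-sum operators

    sigma_fixed = priors.sigma_fixed
    phi_fixed = priors.phi_fixed
    no_field = sigma_fixed is not None and sigma_fixed == 0.0

    # centre covariates internally: decorrelates the intercept and the
    # coefficients, which speeds mixing; draws are mapped back on save
    xbar = X.mean(axis=0) if p else np.zeros(0)
    X = X - xbar

    # initial values, mildly over-dispersed across chains
    a = math.log(max(O.sum(), 0.5) / E.sum()) + 0.1 * rng.standard_normal()
    beta = 0.05 * rng.standard_normal(p)
    sigma = sigma_fixed if sigma_fixed is not None else float(abs(0.2 + 0.1 * rng.standard_normal()))
    phi = phi_fixed if phi_fixed is not None else float(rng.uniform(0.2, 0.8))
    u = np.zeros(n)
    v = np.zeros(n)

    def weights(phi_):
        wu = np.where(island, 0.0, math.sqrt(phi_))
        wv = np.where(island, 1.0, math.sqrt(1.0 - phi_))
        return wu, wv

    wu, wv = weights(phi)

    def linpred(a_, beta_, sigma_, wu_, wv_, u_, v_):
        return a_ + X @ beta_ + sigma_ * (wu_ * u_ + wv_ * v_)

    eta = linpred(a, beta, sigma, wu, wv, u, v)
    lam = E * np.exp(eta)

    # adaptive RW scales (frozen after warm-up)
    s_u = np.full(n, 0.5)
    s_v = np.full(n, 0.5)
    s_a, s_sig, s_phi = 0.1, 0.3, 0.5
    s_sig_c, s_phi_c = 0.3, 0.8
    s_beta = np.full(p, 0.1)

    keep = (iterations - warmup) // thin
    out = {
        "a": np.empty(keep),
        "beta": np.empty((keep, p)),
        "sigma": np.empty(keep),
        "phi": np.empty(keep),
        "b": np.empty((keep, n)),
        "u": np.empty((keep, n)),
    }
    k = 0

    for t in range(iterations):
        adapting = t < warmup
        gamma = min(0.25, (t + 1) ** -0.6) if adapting else 0.0

        if not no_field:
            # --- structured field u, one colour group at a time ---------
            su_coef = sigma * wu
            for g, Wg in zip(groups, W_rows):
                m = len(g)
                Wu_g = Wg @ u
                delta = s_u[g] * rng.standard_normal(m)
                ug = u[g]
                un = ug + delta
                d_eta = su_coef[g] * delta
                dlik = lik_scale * (O[g] * d_eta - lam[g] * np.expm1(d_eta))
                dpri = -0.5 * qdiag[g] * (un * un - ug * ug) + delta * Wu_g
                acc = -rng.standard_exponential(m) < dlik + dpri
                if acc.any():
                    gi = g[acc]
                    u[gi] = un[acc]
                    eta[gi] += d_eta[acc]
                    lam[gi] = E[gi] * np.exp(eta[gi])
                if adapting:
                    s_u[g] *= np.exp(gamma * (acc - _ACC_TARGET))
            # sum-to-zero per component, centring on the fly
            shift = np.zeros(n)
            for comp in comps:
                shift[comp] = u[comp].mean()
            u -= shift
            d_eta = -su_coef * shift
            eta += d_eta
            lam *= np.exp(d_eta)

            # --- unstructured field v, all sites at once ----------------
            sv_coef = sigma * wv
            delta = s_v * rng.standard_normal(n)
            vn = v + delta
            d_eta = sv_coef * delta
            dlik = lik_scale * (O * d_eta - lam * np.expm1(d_eta))
            dpri = -0.5 * (vn * vn - v * v)
            acc = -rng.standard_exponential(n) < dlik + dpri
            if acc.any():
                v[acc] = vn[acc]
                eta[acc] += d_eta[acc]
                lam[acc] = E[acc] * np.exp(eta[acc])
            if adapting:
                s_v *= np.exp(gamma * (acc - _ACC_TARGET))

        # --- intercept and coefficients (repeated cheap sweeps) -----------
        for _ in range(3):
            delta = s_a * rng.standard_normal()
            dlik = lik_scale * (O.sum() * delta - math.expm1(delta) * lam.sum())
            dpri = -0.5 * ((a + delta) ** 2 - a**2) / priors.intercept_sd**2
            if -rng.standard_exponential() < dlik + dpri:
                a += delta
                eta += delta
                lam *= math.exp(delta)
                acc_a = 1.0
            else:
                acc_a = 0.0
            if adapting:
                s_a *= math.exp(gamma * (acc_a - _ACC_TARGET))

            for j in range(p):
                delta = s_beta[j] * rng.standard_normal()
                d_eta = X[:, j] * delta
                dlik = lik_scale * (O @ d_eta - lam @ np.expm1(d_eta))
                bj = beta[j]
                dpri = -0.5 * ((bj + delta) ** 2 - bj**2) / priors.beta_sd**2
                if -rng.standard_exponential() < dlik + dpri:
                    beta[j] = bj + delta
                    eta += d_eta
                    lam *= np.exp(d_eta)
                    acc_b = 1.0
                else:
                    acc_b = 0.0
                if adapting:
                    s_beta[j] *= math.exp(gamma * (acc_b - _ACC_TARGET))

        # --- sigma: non-centred RW against the likelihood -----------------
        if sigma_fixed is None:
            if prior_only:
                sigma = float(rng.exponential(1.0 / priors.sigma_rate))
                eta = linpred(a, beta, sigma, wu, wv, u, v)
                lam = E * np.exp(eta)
            else:
                ls = math.log(sigma) if sigma > 0 else -10.0
                lsn = ls + s_sig * rng.standard_normal()
                sig_n = math.exp(lsn)
                d_eta = (sig_n - sigma) * (wu * u + wv * v)
                dlik = O @ d_eta - lam @ np.expm1(d_eta)
                dpri = -priors.sigma_rate * (sig_n - sigma) + (lsn - ls)
                if -rng.standard_exponential() < dlik + dpri:
                    sigma = sig_n
                    eta += d_eta
                    lam *= np.exp(d_eta)
                    acc_s = 1.0
                else:
                    acc_s = 0.0
                if adapting:
                    s_sig *= math.exp(gamma * (acc_s - _ACC_TARGET))

        # --- phi: non-centred RW against the likelihood -------------------
        if phi_fixed is None and not no_field:
            if prior_only:
                phi = float(rng.random())
                wu, wv = weights(phi)
                eta = linpred(a, beta, sigma, wu, wv, u, v)
                lam = E * np.exp(eta)
            else:
                lp = math.log(phi / (1.0 - phi))
                lpn = lp + s_phi * rng.standard_normal()
                phi_n = 1.0 / (1.0 + math.exp(-lpn))
                wu_n, wv_n = weights(phi_n)
                d_eta = sigma * ((wu_n - wu) * u + (wv_n - wv) * v)
                dlik = O @ d_eta - lam @ np.expm1(d_eta)
                dpri = math.log(phi_n * (1.0 - phi_n)) - math.log(phi * (1.0 - phi))
                if -rng.standard_exponential() < dlik + dpri:
                    phi, wu, wv = phi_n, wu_n, wv_n
                    eta += d_eta
                    lam *= np.exp(d_eta)
                    acc_p = 1.0
                else:
                    acc_p = 0.0
                if adapting:
                    s_phi *= math.exp(gamma * (acc_p - _ACC_TARGET))

        # --- partially collapsed block: (sigma, phi) | b, then (u, v) | b -
        # Given the combined effect b, (u, v) can be marginalised: in the
        # eigenbasis of the scaled Laplacian, b's free coordinates are
        # independent N(0, sigma^2 (phi/lambda_k + 1 - phi)) (null modes and
        # islands: pure unstructured variance).  (sigma, phi) are updated by
        # Metropolis sweeps on this collapsed conditional, after which the
        # decomposition (u, v) is redrawn exactly from its conditional given
        # b — its posterior is diagonal in the same basis, and the
        # sum-to-zero constraint is just zeroing the null modes.  The
        # likelihood never changes (b is fixed), but phi and sigma stop
        # being anchored to one particular (u, v) split.
        if (
            eig is not None
            and not no_field
            and not prior_only
            and sigma > 0
            and 1e-9 < phi < 1.0 - 1e-9
        ):
            Uq, lam_q, null_mode = eig
            bfield = sigma * (wu * u + wv * v)
            z2 = (Uq.T @ bfield[free]) ** 2
            b_isl2 = float(bfield[island] @ bfield[island])
            n_isl = int(island.sum())
            with np.errstate(divide="ignore"):
                inv_lam = np.where(null_mode, 0.0, 1.0 / np.where(null_mode, 1.0, lam_q))

            def collapsed(ls_, lp_):
                sig = math.exp(ls_)
                ph = 1.0 / (1.0 + math.exp(-lp_))
                s = ph * inv_lam + (1.0 - ph)
                val = -0.5 * float(np.sum(z2 / s)) / sig**2 - 0.5 * float(np.sum(np.log(s)))
                val -= len(z2) * ls_
                if n_isl:
                    val += -0.5 * b_isl2 / sig**2 - n_isl * ls_
                # priors + parameterisation Jacobians
                val += -priors.sigma_rate * sig + ls_
                val += math.log(ph * (1.0 - ph))
                return val

            ls = math.log(sigma)
            lp = math.log(phi / (1.0 - phi))
            cur = collapsed(ls, lp)
            for _ in range(5):
                if sigma_fixed is None:
                    lsn = ls + s_sig_c * rng.standard_normal()
                    lsn = min(5.0, max(-12.0, lsn))
                    new = collapsed(lsn, lp)
                    acc_c = 1.0 if -rng.standard_exponential() < new - cur else 0.0
                    if acc_c:
                        ls, cur = lsn, new
                    if adapting:
                        s_sig_c *= math.exp(gamma * (acc_c - _ACC_TARGET))
                if phi_fixed is None:
                    lpn = lp + s_phi_c * rng.standard_normal()
                    lpn = min(30.0, max(-30.0, lpn))
                    new = collapsed(ls, lpn)
                    acc_c = 1.0 if -rng.standard_exponential() < new - cur else 0.0
                    if acc_c:
                        lp, cur = lpn, new
                    if adapting:
                        s_phi_c *= math.exp(gamma * (acc_c - _ACC_TARGET))
            sigma = math.exp(ls)
            phi = 1.0 / (1.0 + math.exp(-lp))
            wu, wv = weights(phi)

            # exact redraw of the decomposition under the new (sigma, phi)
            cpar = phi / (1.0 - phi)
            r = Uq.T @ (bfield[free] / (sigma * math.sqrt(phi)))
            prec = lam_q + cpar
            w = (cpar * r) / prec + rng.standard_normal(len(r)) / np.sqrt(prec)
            w[null_mode] = 0.0
            u_free = Uq @ w
            v[free] = (bfield[free] / sigma - math.sqrt(phi) * u_free) / math.sqrt(1.0 - phi)
            u[free] = u_free
            if n_isl:
                v[island] = bfield[island] / sigma

        if t >= warmup and (t - warmup) % thin == 0 and k < keep:
            out["a"][k] = a - (xbar @ beta if p else 0.0)
            out["beta"][k] = beta
            out["sigma"][k] = sigma
            out["phi"][k] = phi
            out["b"][k] = sigma * (wu * u + wv * v)
            out["u"][k] = u
            k += 1

    return out


def fit_bym2(
    O,
    E,
    X=None,
    graph: AreaGraph | None = None,
    priors: PriorConfig | None = None,
    chains: int = 4,
    iterations: int = 5000,
    warmup: int | None = None,
    thin: int = 1,
    seed: int = 0,
    covariate_names: list[str] | None = None,
    prior_only: bool = False,
    struct: ScaledStructure | None = None,
    keep_field_draws: bool = True,
) -> PosteriorSummary:
    """Fit the BYM2 disease-mapping model by adaptive MCMC.

    Parameters
    ----------
    O, E
        Observed and (strictly positive) expected counts per area, in graph
        order.
    X
        Optional area-by-covariate matrix (complete cases only).
    graph
        Areal adjacency; ``struct`` may be passed to reuse a precomputed
        scaled ICAR structure.
    chains, iterations, warmup, thin
        MCMC schedule; at least 2 chains are required for split-R-hat.
        ``warmup`` defaults to half the iterations.
    prior_only
        Switch the likelihood off; used to verify the sampler reproduces its
        priors.

    Returns
    -------
    PosteriorSummary
        Always returned; ``converged`` is False (with diagnostics) when
        split-R-hat or bulk ESS thresholds are missed.
    """
    if graph is None:
        raise ValueError("graph is required")
    if chains < 2:
        raise ValueError("at least 2 chains are required for split-R-hat")
    priors = priors or PriorConfig()
    O, E, Xm = _validate_inputs(O, E, X, graph)
    p = Xm.shape[1]
    if p and np.linalg.matrix_rank(np.column_stack([np.ones(len(O)), Xm])) < p + 1:
        raise ValueError("rank-deficient design: covariates are collinear (or constant)")
    if warmup is None:
        warmup = iterations // 2
    if iterations <= warmup:
        raise ValueError("iterations must exceed warmup")
    struct = struct if struct is not None else scaled_icar(graph)
    colours = greedy_colouring(graph)

    # one-time eigendecomposition of the scaled Laplacian on non-island
    # nodes, used by the exact decomposition-refresh Gibbs step
    free = ~struct.island_mask
    eig = None
    if free.any() and not (priors.sigma_fixed == 0.0):
        Qf = struct.Q[np.ix_(np.where(free)[0], np.where(free)[0])].toarray()
        lam_q, Uq = np.linalg.eigh(Qf)
        null_mode = lam_q < max(lam_q[-1], 1.0) * 1e-9
        lam_q = np.where(null_mode, 0.0, lam_q)
        eig = (Uq, lam_q, null_mode)

    ss = np.random.SeedSequence(seed)
    chain_rngs = [np.random.default_rng(s) for s in ss.spawn(chains)]
    results = [
        _run_chain(
            O, E, Xm, struct, colours, priors, iterations, warmup, thin, rng, prior_only, eig
        )
        for rng in chain_rngs
    ]

    names = covariate_names or [f"x{j}" for j in range(p)]
    stacked = {key: np.stack([r[key] for r in results]) for key in results[0]}

    monitored: dict[str, np.ndarray] = {"intercept": stacked["a"]}
    for j, nm in enumerate(names):
        monitored[f"beta_{nm}"] = stacked["beta"][:, :, j]
    if priors.sigma_fixed is None:
        monitored["sigma"] = stacked["sigma"]
    if priors.phi_fixed is None and not (priors.sigma_fixed == 0.0):
        monitored["phi"] = stacked["phi"]

    import arviz as az

    rows = []
    all_ok = True
    for nm, arr in monitored.items():
        flat = arr.reshape(-1)
        rhat = float(az.rhat(arr)) if arr.shape[0] >= 2 else float("nan")
        ess = float(az.ess(arr))
        ok = (rhat < 1.01) and (ess > 400)
        all_ok &= ok
        rows.append(
            {
                "param": nm,
                "mean": float(flat.mean()),
                "sd": float(flat.std(ddof=1)),
                "cri_lo": float(np.quantile(flat, 0.025)),
                "cri_hi": float(np.quantile(flat, 0.975)),
                "rhat": rhat,
                "ess_bulk": ess,
            }
        )
    params = pd.DataFrame(rows).set_index("param")

    b = stacked["b"]
    rr = np.exp(b.reshape(-1, b.shape[-1]))
    areas = pd.DataFrame(
        {
            "rr_mean": rr.mean(axis=0),
            "rr_lo": np.quantile(rr, 0.025, axis=0),
            "rr_hi": np.quantile(rr, 0.975, axis=0),
            "prob_above_1": (rr > 1.0).mean(axis=0),
            "prob_below_1": (rr < 1.0).mean(axis=0),
        },
        index=pd.Index(graph.area_ids, name="area_id"),
    )

    draws = {
        "intercept": stacked["a"],
        "beta": stacked["beta"],
        "sigma": stacked["sigma"],
        "phi": stacked["phi"],
    }
    if keep_field_draws:
        draws["b"] = stacked["b"]
        draws["u"] = stacked["u"]

    diagnostics = {
        "chains": chains,
        "iterations": iterations,
        "warmup": warmup,
        "thin": thin,
        "seed": seed,
        "max_rhat": float(np.nanmax(params["rhat"])),
        "min_ess_bulk": float(np.nanmin(params["ess_bulk"])),
        "covariates": names,
    }
    return PosteriorSummary(areas, params, draws, bool(all_ok), diagnostics)


def exceedance(
    rr_draws: np.ndarray,
    rr_threshold: float = 1.0,
    prob_threshold: float = 0.8,
) -> pd.DataFrame:
    """Classify areas by posterior exceedance probability.

    ``rr_draws`` has one column per area.  An area is ``elevated`` when the
    fraction of draws with RR above ``rr_threshold`` is at least
    ``prob_threshold``, ``lowered`` symmetrically, otherwise ``uncertain``.
    """
    rr = np.asarray(rr_draws, dtype=float)
    if rr.ndim != 2:
        raise ValueError("rr_draws must be draws x areas")
    if rr.shape[0] < 100:
        raise ValueError("at least 100 retained draws per area are required")
    if not (0.5 < prob_threshold <= 1.0):
        raise ValueError("prob_threshold must be in (0.5, 1]")
    p_above = (rr > rr_threshold).mean(axis=0)
    p_below = (rr < rr_threshold).mean(axis=0)
    cls = np.where(
        p_above >= prob_threshold, "elevated", np.where(p_below >= prob_threshold, "lowered", "uncertain")
    )
    return pd.DataFrame(
        {"prob_above": p_above, "prob_below": p_below, "classification": cls}
    )


def structured_share(phi_draws: np.ndarray) -> tuple[float, tuple[float, float]]:
    """Posterior mean and central 95% CrI of the mixing parameter phi."""
    phi = np.asarray(phi_draws, dtype=float).reshape(-1)
    if phi.size == 0:
        raise ValueError("empty phi draws")
    if np.any((phi < 0) | (phi > 1)):
        raise ValueError("phi draws must lie in [0, 1]")
    return float(phi.mean()), (float(np.quantile(phi, 0.025)), float(np.quantile(phi, 0.975)))
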