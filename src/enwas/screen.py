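"""Stage 1: the frequentist environment-wide association screen.

One univariable Poisson regression per exposure, with the log expected count
as offset:

    O_i ~ Poisson(E_i * exp(a + b * x_i))

fitted by iteratively reweighted least squares (IRLS).  The family-wise
error rate over the m screened exposures is controlled by Bonferroni
(per-test level alpha/m), and the screen's plotted quantities — the signed
-log10 p of the Manhattan plot and uniform-quantile QQ pairs — are computed
here so drivers only have to draw them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExposureMatrix

log = logging.getLogger(__name__)

__all__ = [
    "GlmFit",
    "ConvergenceFailure",
    "DegenerateDataError",
    "fit_poisson_offset",
    "bonferroni_threshold",
    "screen_exposures",
    "manhattan_values",
    "qq_points",
]

P_FLOOR = 1e-300  # plotting floor only; inference keeps the raw value


class ConvergenceFailure(RuntimeError):
    def __init__(self, msg: str, iterations: int, last_change: float):
        super().__init__(f"{msg} (iterations={iterations}, last relative change={last_change:.3g})")
        self.iterations = iterations
        self.last_change = last_change


class DegenerateDataError(ValueError):
    pass


@dataclass(frozen=True)
class GlmFit:
    """Poisson-offset GLM fit for one covariate (or offset-only)."""

    intercept: float
    beta: float | None
    se: float | None
    p: float | None
    n_areas: int
    n_iter: int
    deviance: float

    @property
    def rr(self) -> float | None:
        return None if self.beta is None else float(np.exp(self.beta))

    def rr_ci(self, level: float = 0.95) -> tuple[float, float] | None:
        if self.beta is None or self.se is None:
            return None
        z = stats.norm.ppf(0.5 + level / 2)
        return float(np.exp(self.beta - z * self.se)), float(np.exp(self.beta + z * self.se))


def fit_poisson_offset(
    O,
    E,
    x=None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> GlmFit:
    """Maximum-likelihood Poisson regression with log-offset by IRLS.

    Areas with missing ``x`` are dropped (complete-case per covariate).
    Converges on relative change in coefficients below ``tol``; failure to
    converge within ``max_iter`` raises :class:`ConvergenceFailure` with
    diagnostics.  All-zero counts raise :class:`DegenerateDataError` (the
    intercept MLE diverges).
    """
    O = np.asarray(O, dtype=float)
    E = np.asarray(E, dtype=float)
    if O.shape != E.shape:
        raise ValueError("O and E must have matching shapes")
    if np.any(E <= 0):
        raise ValueError("all expected counts E must be strictly positive")
    if np.any(O < 0):
        raise ValueError("observed counts must be non-negative")
    if x is not None:
        x = np.asarray(x, dtype=float)
        keep = ~np.isnan(x)
        O, E, x = O[keep], E[keep], x[keep]
        if len(np.unique(x)) < 2:
            raise ValueError("covariate needs at least 2 distinct values after dropping missing")
    n = len(O)
    if n == 0:
        raise ValueError("no areas left to fit")
    if O.sum() == 0:
        raise DegenerateDataError("all observed counts are zero; intercept MLE is -infinity")

    offset = np.log(E)
    X = np.ones((n, 1)) if x is None else np.column_stack([np.ones(n), x])
    theta = np.zeros(X.shape[1])
    theta[0] = np.log(O.sum() / E.sum())

    last_change = np.inf
    for it in range(1, max_iter + 1):
        eta = X @ theta + offset
        mu = np.exp(eta)
        # working response for the log link
        z = (eta - offset) + (O - mu) / mu
        XtW = X.T * mu
        theta_new = np.linalg.solve(XtW @ X, XtW @ z)
        denom = max(1.0, float(np.abs(theta).max()))
        last_change = float(np.abs(theta_new - theta).max()) / denom
        theta = theta_new
        if last_change < tol:
            break
    else:
        raise ConvergenceFailure("IRLS failed to converge", max_iter, last_change)

    mu = np.exp(X @ theta + offset)
    info = (X.T * mu) @ X
    cov = np.linalg.inv(info)
    with np.errstate(divide="ignore", invalid="ignore"):
        dev_terms = np.where(O > 0, O * np.log(O / mu), 0.0) - (O - mu)
    deviance = float(2 * dev_terms.sum())
    if x is None:
        return GlmFit(float(theta[0]), None, None, None, n, it, deviance)
    se = float(np.sqrt(cov[1, 1]))
    zstat = theta[1] / se
    p = float(2 * stats.norm.sf(abs(zstat)))
    return GlmFit(float(theta[0]), float(theta[1]), se, p, n, it, deviance)


def bonferroni_threshold(m: int, alpha: float = 0.05) -> float:
    """Per-test significance threshold alpha/m controlling the FWER at alpha."""
    if m < 1:
        raise ValueError("m must be at least 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / m


def screen_exposures(
    O,
    E,
    exposures: ExposureMatrix,
    alpha: float = 0.05,
    level: float = 0.95,
    standardise: bool = False,
) -> pd.DataFrame:
    """Run the univariable screen over every exposure variable.

    Returns one row per variable: ``beta_hat, se, rr, rr_lo, rr_hi, p,
    adjusted_p, significant, signed_log10p, n_areas``.  ``significant`` is the
    Bonferroni flag at family-wise level ``alpha`` over the m screened
    variables; ``adjusted_p`` is min(1, m*p).  Covariates enter in native
    units unless ``standardise`` (z-scores) is requested.  Variables whose
    fit fails (degenerate or non-convergent) are recorded with NaN estimates
    and a warning rather than aborting the screen.
    """
    m = exposures.n_variables
    if m == 0:
        return pd.DataFrame(
            columns=[
                "beta_hat", "se", "rr", "rr_lo", "rr_hi", "p", "adjusted_p",
                "significant", "signed_log10p", "n_areas",
            ]
        )
    thresh = bonferroni_threshold(m, alpha)
    rows = {}
    for var in exposures.variables:
        xv = exposures.values[var].to_numpy(dtype=float)
        if standardise:
            mu, sd = np.nanmean(xv), np.nanstd(xv)
            xv = (xv - mu) / sd if sd > 0 else xv
        try:
            fit = fit_poisson_offset(O, E, xv)
        except (ValueError, ConvergenceFailure) as err:
            log.warning("screen: variable %s not fitted: %s", var, err)
            rows[var] = dict.fromkeys(
                ["beta_hat", "se", "rr", "rr_lo", "rr_hi", "p", "adjusted_p", "signed_log10p"],
                np.nan,
            ) | {"significant": False, "n_areas": np.nan}
            continue
        lo, hi = fit.rr_ci(level)
        rows[var] = {
            "beta_hat": fit.beta,
            "se": fit.se,
            "rr": fit.rr,
            "rr_lo": lo,
            "rr_hi": hi,
            "p": fit.p,
            "adjusted_p": min(1.0, m * fit.p),
            "significant": fit.p < thresh,
            "signed_log10p": _signed_log10p(fit.p, fit.beta),
            "n_areas": fit.n_areas,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "variable"
    return out


def _signed_log10p(p: float, beta: float) -> float:
    if p <= 0:
        log.warning("p-value underflow; clamping to %.0e for plotting", P_FLOOR)
        p = P_FLOOR
    return float(-np.log10(p) * np.sign(beta))


def manhattan_values(results: pd.DataFrame) -> pd.Series:
    """Signed -log10 p per variable: -log10(p) * sign(beta_hat)."""
    if not {"p", "beta_hat"} <= set(results.columns):
        raise ValueError("results must carry 'p' and 'beta_hat' columns")
    vals = {
        var: _signed_log10p(row["p"], row["beta_hat"])
        for var, row in results.iterrows()
        if np.isfinite(row["p"])
    }
    s = pd.Series(vals, name="signed_log10p")
    return s.reindex(results.index)


def qq_points(pvalues) -> tuple[np.ndarray, np.ndarray]:
    """QQ pairs of -log10 p against uniform order-statistic quantiles.

    Expected quantiles use the midpoint rule (k - 0.5)/m; observed are the
    sorted -log10 p.  Both arrays are ascending in the expected value.
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)[::-1]
    observed = np.sort(-np.log10(p))
    return expected, observed
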