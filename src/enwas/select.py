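"""Stage 3: covariate selection and multivariable spatial regression.

Candidates must pass both earlier stages: Bonferroni-adjusted p < alpha in
the frequentist screen, and a 95% credible interval excluding 1 in the
disease mapping.  Because exposure variables come in highly intercorrelated
groups (air pollutants, deprivation domains, ...), candidates are clustered
by thresholded absolute Spearman correlation and one representative per
cluster enters the final multivariable spatial ecological regression.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from .containers import ExposureMatrix
from .graph import AreaGraph
from .spatial import PosteriorSummary, PriorConfig, fit_bym2

log = logging.getLogger(__name__)

__all__ = [
    "spearman_matrix",
    "select_covariates",
    "ecological_regression",
    "temporal_split_correlation",
]


def spearman_matrix(exposures: ExposureMatrix | pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman rank correlations (midrank ties, pairwise-complete).

    Constant variables get NaN correlations (with a warning); the diagonal
    is 1 for every non-constant variable.
    """
    X = exposures.values if isinstance(exposures, ExposureMatrix) else exposures
    n_ok = X.notna().sum(axis=0)
    if ((n_ok >= 3).sum()) == 0:
        raise ValueError("need at least 3 complete observations for correlations")
    constant = [c for c in X.columns if X[c].dropna().nunique() <= 1]
    if constant:
        log.warning("constant variable(s) %s: correlations recorded as missing", constant)
    C = X.corr(method="spearman", min_periods=3)
    for c in constant:
        C.loc[c, :] = np.nan
        C.loc[:, c] = np.nan
    for c in C.columns:
        if c not in constant:
            C.loc[c, c] = 1.0
    return C


def select_covariates(
    screen: pd.DataFrame,
    mapping: pd.DataFrame,
    corr: pd.DataFrame,
    rho_max: float = 0.7,
    alpha: float = 0.05,
    representatives: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Dual-screen selection with correlation clustering.

    ``screen`` needs columns ``adjusted_p`` (Bonferroni-adjusted p) and ``p``;
    ``mapping`` needs ``rr_lo``/``rr_hi`` (95% CrI of the exposure RR from
    disease mapping); all three inputs are indexed by variable name.

    A variable passes when adjusted_p < alpha AND the mapping CrI excludes 1.
    Passing variables are clustered as connected components of the graph
    joining pairs with |Spearman rho| >= rho_max; the representative of each
    cluster (default: smallest screen p, ties broken by name; overridable by
    cluster id through ``representatives``) is selected.  Deterministic under
    reordering of the input variables.
    """
    variables = sorted(screen.index)
    if sorted(mapping.index) != variables:
        raise ValueError("screen and mapping must cover the same variables")
    passed_enwas = screen["adjusted_p"] < alpha
    passed_mapping = (mapping["rr_lo"] > 1.0) | (mapping["rr_hi"] < 1.0)
    candidates = [v for v in variables if passed_enwas[v] and passed_mapping[v]]

    g = nx.Graph()
    g.add_nodes_from(candidates)
    for i, vi in enumerate(candidates):
        for vj in candidates[i + 1 :]:
            rho = corr.loc[vi, vj]
            if np.isfinite(rho) and abs(rho) >= rho_max:
                g.add_edge(vi, vj)
    clusters = sorted((sorted(c) for c in nx.connected_components(g)), key=lambda c: c[0])

    cluster_id = {}
    selected = {}
    reason = {}
    for cid, members in enumerate(clusters):
        for v in members:
            cluster_id[v] = cid
        if representatives and cid in representatives:
            rep = representatives[cid]
            if rep not in members:
                raise ValueError(f"override {rep!r} is not a member of cluster {cid}")
            why = "manual override"
        else:
            rep = min(members, key=lambda v: (screen.loc[v, "p"], v))
            why = "smallest screen p in cluster" if len(members) > 1 else "sole member of cluster"
        for v in members:
            selected[v] = v == rep
            reason[v] = why if v == rep else f"correlated with selected {rep}"

    out = pd.DataFrame(
        {
            "passed_enwas": passed_enwas,
            "passed_mapping": passed_mapping,
            "cluster_id": pd.Series(cluster_id, dtype="Int64").reindex(variables),
            "selected": pd.Series(selected, dtype=bool).reindex(variables, fill_value=False),
            "reason": pd.Series(reason).reindex(
                variables, fill_value="failed screen(s)"
            ),
        },
        index=pd.Index(variables, name="variable"),
    )
    out.loc[~(passed_enwas & passed_mapping), "reason"] = "failed screen(s)"
    return out


def ecological_regression(
    O,
    E,
    exposures: ExposureMatrix,
    selected: list[str],
    graph: AreaGraph,
    priors: PriorConfig | None = None,
    **mcmc,
) -> PosteriorSummary:
    """Multivariable spatial ecological regression over selected covariates.

    Delegates to the BYM2 engine with the selected covariate columns entered
    jointly (complete rows required; missing values are not imputed).
    Duplicate or collinear covariates raise a rank-deficiency error.
    """
    if len(set(selected)) != len(selected):
        raise ValueError("duplicate covariates in selection")
    X = exposures.values[list(selected)] if selected else None
    if X is not None and X.isna().any().any():
        raise ValueError("selected covariates contain missing values; restrict to complete areas first")
    return fit_bym2(
        O,
        E,
        X=None if X is None else X.to_numpy(dtype=float),
        graph=graph,
        priors=priors,
        covariate_names=list(selected),
        **mcmc,
    )


def temporal_split_correlation(counts_a, counts_b) -> float:
    """Pearson correlation between per-area counts from two sub-periods.

    A consistency check that the spatial pattern is stable over time.
    Returns NaN (with a warning) when either vector has zero variance.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("count vectors must cover the same areas")
    if a.size < 3:
        raise ValueError("need at least 3 areas")
    if a.std() == 0 or b.std() == 0:
        log.warning("zero variance in a count vector; correlation undefined")
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])
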