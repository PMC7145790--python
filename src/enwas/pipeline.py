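"""End-to-end pipeline orchestration.

The staged analysis — synthesise (optional), standardise, frequentist
screen, Bayesian disease mapping, dual-screen selection, multivariable
ecological regression — run from a single :class:`RunConfig`.  Every output
is a plain-text format readable by the package's own readers, every writer
is deterministic, and a manifest records the configuration and SHA-256
hashes of all inputs and outputs, so a fixed seed yields byte-identical
artefacts across runs.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .containers import ExposureMatrix, StratifiedCounts
from .graph import AreaGraph
from .screen import screen_exposures
from .select import ecological_regression, select_covariates, spearman_matrix
from .spatial import PriorConfig, exceedance, fit_bym2, scaled_icar, structured_share
from .standardize import expected_counts
from .synthesize import synthesize_region

log = logging.getLogger(__name__)

STAGES = ("simulate", "standardize", "screen", "map", "select", "ecoreg")

__all__ = ["RunConfig", "run_pipeline", "split_area_table", "PipelineError"]


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    When ``simulate`` is enabled the synthetic region is written to
    ``out_dir`` and used downstream; otherwise ``areas_csv`` and ``adj_gal``
    must point at existing inputs.  Stage dependencies are validated before
    anything executes.
    """

    out_dir: str
    areas_csv: str | None = None
    adj_gal: str | None = None
    seed: int = 0
    alpha: float = 0.05
    rho_max: float = 0.7
    prob_threshold: float = 0.8
    chains: int = 2
    iterations: int = 2000
    thin: int = 1
    n_areas: int = 354
    n_vars: int = 53
    stages: tuple[str, ...] = STAGES

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise PipelineError(f"unknown stages: {sorted(unknown)}")
        on = set(self.stages)
        deps = {
            "screen": {"standardize"},
            "map": {"standardize"},
            "select": {"screen", "map"},
            "ecoreg": {"select"},
        }
        for stage, req in deps.items():
            if stage in on and not req <= on:
                raise PipelineError(f"stage '{stage}' requires stage(s) {sorted(req - on)}")
        if "simulate" not in on and (self.areas_csv is None or self.adj_gal is None):
            raise PipelineError("without the simulate stage, areas_csv and adj_gal are required")
        if self.chains < 2:
            raise PipelineError("at least 2 chains are required")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def split_area_table(df: pd.DataFrame) -> tuple[StratifiedCounts, ExposureMatrix, pd.Series | None]:
    df = df.set_index("area_id")
    pop_cols = [c for c in df.columns if c.startswith("pop_")]
    case_cols = [c for c in df.columns if c.startswith("cases_")]
    strata = [c[len("pop_"):] for c in pop_cols]
    if [c[len("cases_"):] for c in case_cols] != strata:
        raise PipelineError("pop_*/cases_* columns must describe identical strata")
    counts = StratifiedCounts(
        df[pop_cols].rename(columns=dict(zip(pop_cols, strata))),
        df[case_cols].rename(columns=dict(zip(case_cols, strata))),
    )
    reserved = set(pop_cols) | set(case_cols) | {"O", "E"}
    exp_cols = [c for c in df.columns if c not in reserved]
    exposures = ExposureMatrix(df[exp_cols].astype(float))
    E = df["E"] if "E" in df.columns else None
    return counts, exposures, E


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dict.

    A stage failure raises :class:`PipelineError` after writing a
    machine-readable error report; outputs of completed stages are retained.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "stages": {},
        "outputs": {},
    }
    written: list[Path] = []

    def record(stage: str, paths: list[Path], t0: float) -> None:
        manifest["stages"][stage] = {"outputs": [p.name for p in paths]}
        written.extend(paths)
        log.info("stage=%s seed=%d wall_s=%.2f outputs=%s",
                 stage, config.seed, time.perf_counter() - t0, [p.name for p in paths])

    try:
        # ---------------- inputs / simulate -----------------------------
        t0 = time.perf_counter()
        if "simulate" in config.stages:
            region = synthesize_region(
                n_areas=config.n_areas, n_vars=config.n_vars, seed=config.seed
            )
            graph = region.graph
            counts, exposures = region.counts, region.exposures
            areas_path = out / "areas.csv"
            gal_path = out / "graph.gal"
            eio.write_area_table(region.area_table(), areas_path)
            eio.write_gal(graph, gal_path)
            eio.write_json(region.truth.to_dict(), out / "truth.json")
            record("simulate", [areas_path, gal_path, out / "truth.json"], t0)
        else:
            areas_path = Path(config.areas_csv)
            gal_path = Path(config.adj_gal)
            graph = eio.read_gal(gal_path)
            counts, exposures, _ = split_area_table(eio.read_area_table(areas_path))
        manifest["inputs"] = {
            "areas_csv": _sha256(areas_path),
            "adj_gal": _sha256(gal_path),
        }
        if list(counts.population.index) != list(graph.area_ids):
            raise PipelineError("area table and adjacency file disagree on areas/order")
        O = counts.observed().to_numpy(dtype=float)

        # ---------------- standardize -----------------------------------
        E = None
        if "standardize" in config.stages:
            t0 = time.perf_counter()
            ec = expected_counts(counts)
            E = ec.expected.to_numpy(dtype=float)
            tab = eio.read_area_table(areas_path)
            tab["E"] = ec.expected.to_numpy()
            tab["O"] = counts.observed().to_numpy()
            eio.write_area_table(tab, areas_path)
            eio.write_json(
                {"reference_rates": ec.reference_rates.to_dict()}, out / "standardization.json"
            )
            record("standardize", [areas_path, out / "standardization.json"], t0)

        # ---------------- screen ----------------------------------------
        screen_df = None
        if "screen" in config.stages:
            t0 = time.perf_counter()
            screen_df = screen_exposures(O, E, exposures, alpha=config.alpha)
            screen_path = out / "screen.csv"
            screen_df.to_csv(screen_path, float_format="%.12g", lineterminator="\n")
            eio.write_json(
                {
                    "alpha": config.alpha,
                    "m": int(exposures.n_variables),
                    "threshold": config.alpha / max(1, exposures.n_variables),
                    "n_significant": int(screen_df["significant"].sum()),
                },
                out / "screen_log.json",
            )
            record("screen", [screen_path, out / "screen_log.json"], t0)

        # ---------------- map -------------------------------------------
        mapping_df = None
        null_fit = None
        if "map" in config.stages:
            t0 = time.perf_counter()
            struct = scaled_icar(graph)
            mcmc = dict(chains=config.chains, iterations=config.iterations, thin=config.thin)
            null_fit = fit_bym2(O, E, None, graph=graph, struct=struct,
                                seed=config.seed + 1, **mcmc)
            rr = null_fit.rr_draws()
            exc = exceedance(rr, prob_threshold=config.prob_threshold)
            area_summary = null_fit.areas.copy()
            area_summary["classification"] = exc["classification"].to_numpy()
            area_summary.to_csv(out / "map_areas.csv", float_format="%.12g", lineterminator="\n")
            share, share_ci = structured_share(null_fit.phi_draws())
            rows = {}
            for k, var in enumerate(exposures.variables):
                fitv = fit_bym2(
                    O, E, exposures.values[var].to_numpy(dtype=float), graph=graph,
                    struct=struct, covariate_names=[var], keep_field_draws=False,
                    seed=config.seed + 10_000 + k, **mcmc,
                )
                pr = fitv.params.loc[f"beta_{var}"]
                rows[var] = {
                    "rr": float(np.exp(pr["mean"])),
                    "rr_lo": float(np.exp(pr["cri_lo"])),
                    "rr_hi": float(np.exp(pr["cri_hi"])),
                    "converged": bool(fitv.converged),
                }
            mapping_df = pd.DataFrame.from_dict(rows, orient="index")
            mapping_df.index.name = "variable"
            mapping_df.to_csv(out / "map_variables.csv", float_format="%.12g", lineterminator="\n")
            eio.write_json(
                {
                    "structured_share_mean": share,
                    "structured_share_cri": list(share_ci),
                    "null_fit_converged": bool(null_fit.converged),
                    "n_elevated": int((exc["classification"] == "elevated").sum()),
                    "n_lowered": int((exc["classification"] == "lowered").sum()),
                    "params": null_fit.params.reset_index().to_dict(orient="records"),
                },
                out / "map_summary.json",
            )
            record("map", [out / "map_areas.csv", out / "map_variables.csv",
                           out / "map_summary.json"], t0)

        # ---------------- select ----------------------------------------
        selection = None
        if "select" in config.stages:
            t0 = time.perf_counter()
            corr = spearman_matrix(exposures)
            corr.to_csv(out / "spearman.csv", float_format="%.12g", lineterminator="\n")
            selection = select_covariates(
                screen_df, mapping_df, corr, rho_max=config.rho_max, alpha=config.alpha
            )
            selection.to_csv(out / "selection.csv", lineterminator="\n")
            eio.write_json(
                {"selected": sorted(selection.index[selection["selected"]])},
                out / "selection.json",
            )
            record("select", [out / "spearman.csv", out / "selection.csv",
                              out / "selection.json"], t0)

        # ---------------- ecoreg ----------------------------------------
        if "ecoreg" in config.stages:
            t0 = time.perf_counter()
            chosen = sorted(selection.index[selection["selected"]])
            fit = ecological_regression(
                O, E, exposures, chosen, graph,
                chains=config.chains, iterations=config.iterations, thin=config.thin,
                seed=config.seed + 2,
            )
            rows = []
            for var in chosen:
                pr = fit.params.loc[f"beta_{var}"]
                rows.append(
                    {
                        "variable": var,
                        "rr": float(np.exp(pr["mean"])),
                        "rr_lo": float(np.exp(pr["cri_lo"])),
                        "rr_hi": float(np.exp(pr["cri_hi"])),
                    }
                )
            pd.DataFrame(rows, columns=["variable", "rr", "rr_lo", "rr_hi"]).to_csv(
                out / "ecoreg.csv", index=False, float_format="%.12g", lineterminator="\n"
            )
            share, share_ci = structured_share(fit.phi_draws())
            exc = exceedance(fit.rr_draws(), prob_threshold=config.prob_threshold)
            eio.write_json(
                {
                    "covariates": chosen,
                    "structured_share_mean": share,
                    "structured_share_cri": list(share_ci),
                    "converged": bool(fit.converged),
                    "n_elevated": int((exc["classification"] == "elevated").sum()),
                    "n_lowered": int((exc["classification"] == "lowered").sum()),
                },
                out / "ecoreg_summary.json",
            )
            record("ecoreg", [out / "ecoreg.csv", out / "ecoreg_summary.json"], t0)

    except PipelineError:
        raise
    except Exception as err:
        eio.write_json({"error": str(err), "type": type(err).__name__}, out / "error.json")
        raise PipelineError(f"pipeline stage failed: {err}") from err

    import enwas

    manifest["version"] = enwas.__version__
    manifest["outputs"] = {p.name: _sha256(p) for p in written}
    eio.write_json(manifest, out / "manifest.json")
    return manifest
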