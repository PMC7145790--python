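#!/usr/bin/env python
"""Stage 1: the frequentist environment-wide association screen.

Fits one univariable Poisson regression per exposure with the expected
count as offset, applies the Bonferroni correction over the 53 tests, and
writes the screen table plus the Manhattan and QQ plot quantities (and the
plots themselves).
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from enwas.io import read_area_table, write_json
from enwas.pipeline import split_area_table
from enwas.screen import bonferroni_threshold, manhattan_values, qq_points, screen_exposures

ROOT = Path(__file__).resolve().parents[1] / "results"
REGION = ROOT / "region"
OUT = ROOT / "screen"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    tab = read_area_table(REGION / "areas.csv")
    counts, exposures, E = split_area_table(tab)
    O = counts.observed().to_numpy(float)

    screen = screen_exposures(O, E.to_numpy(), exposures)
    screen.to_csv(OUT / "screen.csv", float_format="%.12g", lineterminator="\n")
    m = exposures.n_variables
    thr = bonferroni_threshold(m)
    n_sig = int(screen["significant"].sum())
    n_neg = int((screen.loc[screen["significant"], "beta_hat"] < 0).sum())
    print(f"{n_sig} of {m} exposures pass the Bonferroni threshold p < {thr:.1g}")
    print(f"of those, {n_neg} are inversely associated")

    # Manhattan quantities
    man = manhattan_values(screen)
    man.to_csv(OUT / "manhattan.csv", lineterminator="\n")
    fig, ax = plt.subplots(figsize=(10, 4))
    colors = np.where(man > 0, "tab:red", "tab:blue")
    ax.bar(range(len(man)), man.to_numpy(), color=colors)
    for y in (-np.log10(thr), np.log10(thr)):
        ax.axhline(-y, color="k", lw=0.8)
    ax.set_xticks(range(len(man)))
    ax.set_xticklabels(man.index, rotation=90, fontsize=5)
    ax.set_ylabel("-log10(p) x sign")
    fig.tight_layout()
    fig.savefig(OUT / "manhattan.png", dpi=150)

    # QQ quantities
    expected, observed = qq_points(screen["p"].dropna())
    pd.DataFrame({"expected": expected, "observed": observed}).to_csv(
        OUT / "qq.csv", index=False, lineterminator="\n"
    )
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(expected, observed, "o", ms=3)
    lim = max(expected.max(), observed.max())
    ax.plot([0, lim], [0, lim], "k--", lw=0.8)
    ax.set_xlabel("expected -log10(p)")
    ax.set_ylabel("observed -log10(p)")
    fig.tight_layout()
    fig.savefig(OUT / "qq.png", dpi=150)

    write_json({"m": m, "threshold": thr, "n_significant": n_sig}, OUT / "screen_log.json")
    print(f"wrote {OUT}/screen.csv, manhattan.csv/png, qq.csv/png")


if __name__ == "__main__":
    main()
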