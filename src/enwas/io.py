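"""Plain-text I/O: GAL neighbour lists, area tables, truth JSON, GeoJSON.

All formats round-trip through the package's own readers, and all writers are
deterministic (fixed float formatting, fixed key order) so that a seeded
pipeline run is byte-identical across repeats.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .graph import AreaGraph, GraphError


def write_gal(graph: AreaGraph, path: str | Path) -> None:
    """Write a GAL neighbour list (GeoDa dialect).

    Header line with the area count, then per area one line ``id n_neighbours``
    followed by one line of neighbour ids.
    """
    lines = [str(graph.n_areas)]
    for a in graph.area_ids:
        nbrs = graph.neighbours[a]
        lines.append(f"{a} {len(nbrs)}")
        lines.append(" ".join(nbrs))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gal(path: str | Path) -> AreaGraph:
    """Read a GAL neighbour list, rejecting asymmetric adjacency."""
    tokens_by_line = [ln.split() for ln in Path(path).read_text().splitlines()]
    lines = [t for t in tokens_by_line if t]
    header = lines[0]
    n = int(header[-1]) if len(header) > 1 else int(header[0])
    area_ids: list[str] = []
    nbrs: dict[str, list[str]] = {}
    pos = 1
    for _ in range(n):
        ident, count = lines[pos][0], int(lines[pos][1])
        if count > 0:
            neigh = lines[pos + 1]
            if len(neigh) != count:
                raise GraphError(f"area {ident!r}: expected {count} neighbours, got {len(neigh)}")
            pos += 2
        else:
            neigh = []
            pos += 1
        area_ids.append(ident)
        nbrs[ident] = neigh
    for i, ns in nbrs.items():
        for j in ns:
            if j not in nbrs:
                raise GraphError(f"unknown neighbour {j!r} of area {i!r}")
            if i not in nbrs[j]:
                raise GraphError(f"asymmetric adjacency in GAL file: {i!r}~{j!r} but not {j!r}~{i!r}")
    return AreaGraph(tuple(area_ids), {a: tuple(v) for a, v in nbrs.items()})


def write_area_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write the area table CSV.  Requires an ``area_id`` column."""
    if "area_id" not in df.columns:
        raise ValueError("area table requires an 'area_id' column")
    df.to_csv(path, index=False, float_format="%.12g", lineterminator="\n")


def read_area_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "area_id" not in df.columns:
        raise ValueError("area table requires an 'area_id' column")
    df["area_id"] = df["area_id"].astype(str)
    return df


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonify(x):
    try:
        import numpy as np

        if isinstance(x, np.generic):
            return x.item()
        if isinstance(x, np.ndarray):
            return x.tolist()
    except ImportError:  # pragma: no cover
        pass
    raise TypeError(f"not JSON serialisable: {type(x)}")


def lattice_geojson(graph: AreaGraph, values: dict[str, dict] | None = None) -> dict:
    """Synthetic unit-square polygons for a lattice graph, as a GeoJSON dict.

    ``values`` maps area_id to a property dict (e.g. rr_mean, classification).
    Only meaningful for graphs produced by the lattice layout.
    """
    from .graph import _lattice_dims

    n = graph.n_areas
    _, cols = _lattice_dims(n)
    feats = []
    for k, a in enumerate(graph.area_ids):
        r, c = divmod(k, cols)
        ring = [[c, -r], [c + 1, -r], [c + 1, -r - 1], [c, -r - 1], [c, -r]]
        props = {"area_id": a}
        if values and a in values:
            props.update(values[a])
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": props,
            }
        )
    return {"type": "FeatureCollection", "features": feats}
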