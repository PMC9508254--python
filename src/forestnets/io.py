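"""Reading and writing stem maps, patterns, networks and curves.

All formats are plain text: CSV for stem maps, simulated patterns, metric
tables and radial curves (with `#`-prefixed metadata lines), and GraphML or
edge-list CSV for networks.  Writers and their paired readers round-trip
losslessly.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError
from .network_build import CompetitionNetwork
from .point_process import MarkedPattern, Window
from .spatial_stats import EnvelopeResult

__all__ = [
    "read_stem_map", "write_pattern", "read_pattern",
    "write_network", "read_network", "write_envelope",
    "DEFAULT_ALIASES",
]

#: Accepted column spellings in external stem-map tables, checked
#: case-insensitively; extend via the ``aliases`` argument.
DEFAULT_ALIASES = {
    "id": ("id", "tree", "tree_id", "treeid", "tag", "stem_id"),
    "x": ("x", "x_m", "xcoord", "x_coord", "easting", "gx", "utm_x"),
    "y": ("y", "y_m", "ycoord", "y_coord", "northing", "gy", "utm_y"),
    "crown_radius": ("crown_radius", "crownradius", "cr", "radius", "r_crown"),
    "crown_area": ("crown_area", "crownarea", "ca", "area_crown", "crown_area_m2"),
    "plot": ("plot", "plot_id", "plotid", "label", "plot_label", "site"),
}


def _resolve(columns, wanted, aliases):
    lower = {c.lower(): c for c in columns}
    for name in aliases[wanted]:
        if name in lower:
            return lower[name]
    return None


def read_stem_map(path, plot_filter: Optional[str] = None,
                  aliases: Optional[dict] = None) -> pd.DataFrame:
    """Load a stem-map CSV into the canonical id/x/y/crown_radius table.

    Column names are matched case-insensitively against common spellings
    (configurable through ``aliases``); unknown columns are ignored.  Crown
    radius is derived as R = sqrt(A / pi) from a crown-area column when no
    radius column exists.  ``plot_filter`` keeps a single plot label.
    """
    amap = dict(DEFAULT_ALIASES)
    if aliases:
        amap.update({k: tuple(v) for k, v in aliases.items()})
    df = pd.read_csv(path, comment="#")
    if df.empty:
        import warnings

        warnings.warn(f"{path}: empty stem map", stacklevel=2)
        return pd.DataFrame(columns=["id", "x", "y", "crown_radius"])
    cols = {}
    for key in ("x", "y"):
        found = _resolve(df.columns, key, amap)
        if found is None:
            raise DataError(f"{path}: no '{key}' coordinate column "
                            f"(accepted names: {', '.join(amap[key])})")
        cols[key] = found
    plot_col = _resolve(df.columns, "plot", amap)
    if plot_filter is not None:
        if plot_col is None:
            raise DataError(f"{path}: plot filter requested but no plot column found")
        df = df[df[plot_col].astype(str) == str(plot_filter)]
    id_col = _resolve(df.columns, "id", amap)
    out = pd.DataFrame({
        "id": df[id_col].to_numpy() if id_col else np.arange(len(df)),
        "x": pd.to_numeric(df[cols["x"]]),
        "y": pd.to_numeric(df[cols["y"]]),
    })
    r_col = _resolve(df.columns, "crown_radius", amap)
    a_col = _resolve(df.columns, "crown_area", amap)
    if r_col is not None:
        out["crown_radius"] = pd.to_numeric(df[r_col])
    elif a_col is not None:
        area = pd.to_numeric(df[a_col])
        if (area < 0).any():
            raise DataError(f"{path}: negative crown areas")
        out["crown_radius"] = np.sqrt(area / math.pi)
    else:
        out["crown_radius"] = np.nan
    if plot_col is not None:
        out["plot"] = df[plot_col].to_numpy()
    if not np.isfinite(out[["x", "y"]].to_numpy()).all():
        raise DataError(f"{path}: non-finite coordinates")
    return out.reset_index(drop=True)


def write_pattern(pattern: MarkedPattern, path) -> None:
    """Pattern CSV: header id,x,y,crown_radius with a window comment line."""
    w = pattern.window
    ids = pattern.ids if pattern.ids is not None else np.arange(pattern.n)
    radii = pattern.radii if pattern.radii is not None else np.full(pattern.n, np.nan)
    with open(path, "w") as fh:
        fh.write(f"# window {w.xmin:.6f} {w.xmax:.6f} {w.ymin:.6f} {w.ymax:.6f}\n")
        fh.write(f"# provenance {pattern.provenance}\n")
        fh.write("id,x,y,crown_radius\n")
        for i in range(pattern.n):
            r = "" if np.isnan(radii[i]) else f"{radii[i]:.6f}"
            fh.write(f"{ids[i]},{pattern.x[i]:.6f},{pattern.y[i]:.6f},{r}\n")


def read_pattern(path) -> MarkedPattern:
    """Inverse of :func:`write_pattern`."""
    window = None
    provenance = "empirical"
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            parts = line[1:].split()
            if parts and parts[0] == "window":
                window = Window(*map(float, parts[1:5]))
            elif parts and parts[0] == "provenance":
                provenance = parts[1]
    df = pd.read_csv(path, comment="#")
    if window is None:
        window = Window.from_points(df["x"].to_numpy(), df["y"].to_numpy())
    radii = df["crown_radius"].to_numpy(float) if "crown_radius" in df else None
    if radii is not None and np.all(np.isnan(radii)):
        radii = None
    return MarkedPattern(df["x"].to_numpy(float), df["y"].to_numpy(float), window,
                         radii=radii, provenance=provenance,
                         ids=df["id"].to_numpy())


def write_network(net: CompetitionNetwork, path, fmt: Optional[str] = None) -> None:
    """Write a network as GraphML (nodes keep x, y, crown_radius) or
    edge-list CSV (``source,target,weight``)."""
    path = Path(path)
    fmt = fmt or ("graphml" if path.suffix == ".graphml" else "edgelist-csv")
    if fmt == "graphml":
        import networkx as nx

        g = net.to_networkx()
        g.graph["net_type"] = net.net_type
        nx.write_graphml(g, path)
    elif fmt == "edgelist-csv":
        ids = net.nodes["id"].to_numpy()
        with open(path, "w") as fh:
            fh.write(f"# net_type {net.net_type} directed {int(net.directed)}\n")
            fh.write("source,target,weight\n")
            for k in range(net.n_edges):
                i, j = net.edges[k]
                wgt = f"{net.weights[k]:.9g}" if net.weights is not None else ""
                fh.write(f"{ids[i]},{ids[j]},{wgt}\n")
    else:
        raise ParameterError(f"unsupported network format {fmt!r}")


def read_network(path) -> CompetitionNetwork:
    """Read back a GraphML network written by :func:`write_network`."""
    import networkx as nx

    path = Path(path)
    if path.suffix != ".graphml":
        raise ParameterError("only GraphML round-trip reading is supported")
    g = nx.read_graphml(path)
    net_type = g.graph.get("net_type", "CS")
    ids = list(g.nodes)
    index = {node: i for i, node in enumerate(ids)}
    nodes = pd.DataFrame({
        "id": ids,
        "x": [g.nodes[n].get("x", np.nan) for n in ids],
        "y": [g.nodes[n].get("y", np.nan) for n in ids],
        "crown_radius": [g.nodes[n].get("crown_radius", np.nan) for n in ids],
    })
    directed = g.is_directed()
    edges = np.array([[index[u], index[v]] for u, v in g.edges], dtype=int)
    if edges.size == 0:
        edges = np.empty((0, 2), dtype=int)
    weights = None
    if any("weight" in g.edges[e] for e in g.edges):
        weights = np.array([g.edges[e].get("weight", np.nan) for e in g.edges])
    if not directed and edges.size:
        edges = np.sort(edges, axis=1)
    return CompetitionNetwork(net_type, nodes, edges, weights=weights,
                              directed=directed)


def write_envelope(env: EnvelopeResult, path) -> None:
    """Envelope CSV: metadata comments then r, observed, lo, hi columns."""
    with open(path, "w") as fh:
        fh.write(f"# statistic {env.statistic} n_sim {env.n_sim} "
                 f"null {env.null_model.model}\n")
        fh.write("r,observed,lo,hi\n")
        obs = env.observed.values if env.observed is not None else np.full(env.r.size, np.nan)
        for r, o, lo, hi in zip(env.r, obs, env.lo, env.hi):
            fh.write(f"{r:.6f},{o:.9g},{lo:.9g},{hi:.9g}\n")
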