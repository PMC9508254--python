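"""Individual-tree competition networks.

Three graphs are built from a stem map, each with trees as nodes:

* **CS** (competition for space): undirected; trees are linked when their
  treetop distance is below a fixed interaction range (default 10 m).
* **CL** (competition for light): undirected; trees are linked when their
  crown discs overlap, i.e. distance < R_i + R_j.
* **WCL** (weighted competition for light): the CL edges, directed both
  ways, each direction weighted by the crown competition index

      CI_ij = R_ij * R_i / R_j,   R_ij = (R_i + R_j) - ||P_i - P_j||,

  so the overlap depth R_ij is scaled up for the larger-crowned competitor
  and down for the smaller one (CI_ij * CI_ji = R_ij**2).

Boundary ties are not connected: the comparisons are strict (< threshold),
so tangent crowns or a pair at exactly the CS range are unlinked.  Trees
lacking a crown radius are kept in CS but dropped (with a log message) from
CL/WCL.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import DataError, ParameterError
from .point_process import MarkedPattern

__all__ = ["TreeTable", "CompetitionNetwork", "competition_index",
           "build_cs", "build_cl", "build_wcl"]

logger = logging.getLogger(__name__)

TreeTable = pd.DataFrame  # columns: id, x, y, crown_radius (may be NaN)


def as_tree_table(trees) -> pd.DataFrame:
    """Normalize a stem map to a DataFrame with id/x/y/crown_radius columns."""
    if isinstance(trees, MarkedPattern):
        ids = trees.ids if trees.ids is not None else np.arange(trees.n)
        radii = trees.radii if trees.radii is not None else np.full(trees.n, np.nan)
        return pd.DataFrame({"id": ids, "x": trees.x, "y": trees.y, "crown_radius": radii})
    df = pd.DataFrame(trees).copy()
    if "x" not in df.columns or "y" not in df.columns:
        raise DataError("tree table needs 'x' and 'y' columns")
    if "id" not in df.columns:
        df.insert(0, "id", np.arange(len(df)))
    if "crown_radius" not in df.columns:
        df["crown_radius"] = np.nan
    return df[["id", "x", "y", "crown_radius"]].reset_index(drop=True)


@dataclass
class CompetitionNetwork:
    """A competition graph over a set of trees.

    ``edges`` holds positional node indices into ``nodes``; undirected
    networks store each pair once with ``edges[:, 0] < edges[:, 1]``,
    the directed WCL stores both orientations with per-edge ``weights``.
    """

    net_type: str
    nodes: pd.DataFrame
    edges: np.ndarray
    weights: Optional[np.ndarray] = None
    directed: bool = False
    dropped_nodes: int = field(default=0, repr=False)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        """Edge count: unordered pairs if undirected, ordered pairs if directed."""
        return len(self.edges)

    def adjacency(self):
        """Boolean sparse adjacency of the undirected skeleton (CSR)."""
        from scipy import sparse

        n = self.n_nodes
        if self.n_edges == 0:
            return sparse.csr_matrix((n, n), dtype=np.int8)
        i, j = self.edges[:, 0], self.edges[:, 1]
        data = np.ones(i.size, dtype=np.int8)
        a = sparse.coo_matrix((data, (i, j)), shape=(n, n))
        a = a + a.T
        a.data[:] = 1  # collapse the two orientations of directed edges
        return a.tocsr()

    def undirected_skeleton(self) -> "CompetitionNetwork":
        """CL-style undirected view of a WCL network (weights discarded)."""
        if not self.directed:
            return self
        und = np.sort(self.edges, axis=1)
        und = np.unique(und, axis=0)
        return CompetitionNetwork("CL", self.nodes, und, directed=False,
                                  dropped_nodes=self.dropped_nodes)

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph() if self.directed else nx.Graph()
        ids = self.nodes["id"].to_numpy()
        xs = self.nodes["x"].to_numpy(float)
        ys = self.nodes["y"].to_numpy(float)
        rs = self.nodes["crown_radius"].to_numpy(float)
        for i in range(len(ids)):
            g.add_node(ids[i], x=xs[i], y=ys[i], crown_radius=rs[i])
        for k in range(self.n_edges):
            i, j = self.edges[k]
            if self.weights is not None:
                g.add_edge(ids[i], ids[j], weight=float(self.weights[k]))
            else:
                g.add_edge(ids[i], ids[j])
        return g


def competition_index(r_i, r_j, dist):
    """Directed crown competition indices ``(CI_ij, CI_ji)`` for one overlap.

    Accepts scalars or arrays.  Requires actual overlap, ``dist < r_i + r_j``.
    """
    r_i = np.asarray(r_i, dtype=float)
    r_j = np.asarray(r_j, dtype=float)
    dist = np.asarray(dist, dtype=float)
    if np.any(r_i <= 0) or np.any(r_j <= 0):
        raise ParameterError("crown radii must be positive")
    overlap = (r_i + r_j) - dist
    if np.any(overlap <= 0):
        raise ParameterError("competition_index requires overlapping crowns (dist < R_i + R_j)")
    ci_ij = overlap * r_i / r_j
    ci_ji = overlap * r_j / r_i
    if ci_ij.ndim == 0:
        return float(ci_ij), float(ci_ji)
    return ci_ij, ci_ji


def _pairs_within(x, y, r_max):
    tree = cKDTree(np.column_stack([x, y]))
    pairs = tree.query_pairs(r_max, output_type="ndarray")
    if pairs.size == 0:
        return pairs.reshape(0, 2), np.empty(0)
    d = np.hypot(x[pairs[:, 0]] - x[pairs[:, 1]], y[pairs[:, 0]] - y[pairs[:, 1]])
    return pairs, d


def build_cs(trees, d_max: float = 10.0) -> CompetitionNetwork:
    """Competition-for-space network: link pairs closer than ``d_max`` metres.

    Crown radii are not needed; coincident trees (distance 0) are linked.
    """
    if not d_max > 0:
        raise ParameterError(f"d_max must be positive, got {d_max}")
    nodes = as_tree_table(trees)
    if len(nodes) == 0:
        raise DataError("no trees")
    x = nodes["x"].to_numpy(float)
    y = nodes["y"].to_numpy(float)
    # query_pairs uses d <= r; shrink by epsilon-free filter for the strict rule
    pairs, d = _pairs_within(x, y, d_max)
    keep = d < d_max
    return CompetitionNetwork("CS", nodes, pairs[keep])


def _crown_nodes(trees):
    nodes = as_tree_table(trees)
    if len(nodes) == 0:
        raise DataError("no trees")
    has_crown = nodes["crown_radius"].to_numpy(float) > 0
    dropped = int((~has_crown).sum())
    if dropped:
        logger.info("dropping %d trees without a crown radius from the crown-overlap network",
                    dropped)
    nodes = nodes[has_crown].reset_index(drop=True)
    if len(nodes) == 0:
        import warnings

        warnings.warn("no trees carry a crown radius: crown-overlap network is empty",
                      stacklevel=3)
    return nodes, dropped


def _overlap_pairs(nodes):
    x = nodes["x"].to_numpy(float)
    y = nodes["y"].to_numpy(float)
    r = nodes["crown_radius"].to_numpy(float)
    if len(nodes) < 2:
        return np.empty((0, 2), dtype=int), np.empty(0), r
    pairs, d = _pairs_within(x, y, 2.0 * r.max() if r.size else 0.0)
    keep = d < r[pairs[:, 0]] + r[pairs[:, 1]]
    return pairs[keep], d[keep], r


def build_cl(trees) -> CompetitionNetwork:
    """Competition-for-light network: link pairs with overlapping crown discs."""
    nodes, dropped = _crown_nodes(trees)
    pairs, _, _ = _overlap_pairs(nodes)
    return CompetitionNetwork("CL", nodes, pairs, dropped_nodes=dropped)


def build_wcl(trees) -> CompetitionNetwork:
    """Weighted, directed competition-for-light network.

    Every crown overlap contributes the two directed edges (i→j, j→i) with
    competition-index weights, so the directed edge count is exactly twice
    the CL edge count on the same trees.
    """
    nodes, dropped = _crown_nodes(trees)
    pairs, d, r = _overlap_pairs(nodes)
    if len(pairs) == 0:
        edges = np.empty((0, 2), dtype=int)
        weights = np.empty(0)
    else:
        ci_ij, ci_ji = competition_index(r[pairs[:, 0]], r[pairs[:, 1]], d)
        edges = np.vstack([pairs, pairs[:, ::-1]])
        weights = np.concatenate([ci_ij, ci_ji])
    return CompetitionNetwork("WCL", nodes, edges, weights=weights,
                              directed=True, dropped_nodes=dropped)
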