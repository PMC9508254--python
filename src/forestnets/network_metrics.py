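"""Graph characteristics of competition networks.

The four summary statistics used throughout the validation workflow are

* density             D = 2E / (N (N-1))
* average node degree k = 2E / N
* average path length L = mean shortest-path hop count over connected pairs
* clustering coeff.   C = (1/N) * sum_i 2 e_i / (k_i (k_i - 1))

computed on the *undirected, unweighted* skeleton — for the directed WCL
this means C, D and L equal those of the CL network on the same trees, and
only the weighted average degree uses the competition-index weights.
Disconnected node pairs are excluded from L (the connected-pair count is
reported alongside); nodes with fewer than two neighbours contribute 0 to C.

Degree-like statistics are computed directly on the sparse adjacency;
betweenness centrality is delegated to networkx (unnormalized shortest-path
betweenness, endpoints excluded).  Spatial fields of node metrics are
interpolated with a thin-plate spline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from numba import njit
from scipy import sparse
from scipy.sparse import csgraph

from .errors import DataError, ParameterError
from .network_build import CompetitionNetwork
from .point_process import Window

__all__ = [
    "MetricSet", "FieldGrid", "density", "average_degree",
    "weighted_average_degree", "average_path_length", "clustering_coefficient",
    "degree_distribution", "betweenness", "interpolate_field", "metric_set",
]


@dataclass(frozen=True)
class MetricSet:
    """One network's summary bundle (Table-style row)."""

    net_type: str
    N: int
    E: int          # unordered edges (CS/CL); ordered/directed edges (WCL)
    k: float
    C: float
    D: float
    L: float
    k_weighted: Optional[float] = None
    n_connected_pairs: int = 0

    def as_dict(self) -> dict:
        return {
            "net_type": self.net_type, "N": self.N, "E": self.E, "k": self.k,
            "C": self.C, "D": self.D, "L": self.L, "k_weighted": self.k_weighted,
        }


def _skeleton_counts(net: CompetitionNetwork):
    """(N, undirected edge count) of the skeleton."""
    if net.directed:
        skel = net.undirected_skeleton()
        return skel.n_nodes, skel.n_edges, skel
    return net.n_nodes, net.n_edges, net


def density(net: CompetitionNetwork) -> float:
    """Fraction of realized links among all possible pairs, 2E/(N(N-1))."""
    n, e, _ = _skeleton_counts(net)
    if n < 2:
        raise DataError(f"density undefined for N={n}")
    return 2.0 * e / (n * (n - 1))


def average_degree(net: CompetitionNetwork) -> float:
    """Mean number of competitors per tree, 2E/N (undirected skeleton)."""
    n, e, _ = _skeleton_counts(net)
    if n < 1:
        raise DataError("empty network")
    return 2.0 * e / n


def weighted_average_degree(net: CompetitionNetwork, factor: float = 2.0) -> float:
    """Weighted variant for WCL: the edge count is replaced by the total
    competition-index weight, ``k_w = factor * sum(CI) / N``.

    The literal replacement keeps the undirected factor 2 (default); pass
    ``factor=1`` for the per-directed-edge convention.  Both are exposed
    because the printed value for the reference plot does not disambiguate.
    """
    if net.weights is None:
        raise DataError("network has no edge weights")
    if net.n_nodes < 1:
        raise DataError("empty network")
    return factor * float(np.sum(net.weights)) / net.n_nodes


@njit(cache=True)
def _bfs_hop_sum(indptr, indices, n):
    """Sum of shortest-path hop counts and count over connected unordered pairs."""
    total = 0
    pairs = 0
    dist = np.empty(n, np.int32)
    queue = np.empty(n, np.int32)
    for s in range(n):
        for i in range(n):
            dist[i] = -1
        dist[s] = 0
        queue[0] = s
        head = 0
        tail = 1
        while head < tail:
            u = queue[head]
            head += 1
            du = dist[u]
            for ptr in range(indptr[u], indptr[u + 1]):
                v = indices[ptr]
                if dist[v] < 0:
                    dist[v] = du + 1
                    queue[tail] = v
                    tail += 1
        for t in range(s + 1, n):
            if dist[t] > 0:
                total += dist[t]
                pairs += 1
    return total, pairs


def average_path_length(net: CompetitionNetwork, directed: bool = False,
                        return_pairs: bool = False):
    """Mean shortest-path hop count over connected node pairs.

    Pairs in different components are excluded.  With ``directed=True`` the
    mean runs over ordered reachable pairs of the directed graph (only
    meaningful for WCL, where mutual edges make it coincide with the
    skeleton value; exposed for completeness).
    """
    n, e, skel = _skeleton_counts(net)
    if net.n_edges == 0:
        raise DataError("average path length undefined on an edgeless network")
    if directed and net.directed:
        i, j = net.edges[:, 0], net.edges[:, 1]
        adj = sparse.coo_matrix((np.ones(i.size), (i, j)), shape=(n, n)).tocsr()
        dmat = csgraph.shortest_path(adj, method="D", directed=True, unweighted=True)
        d = dmat[~np.eye(n, dtype=bool)]
        finite = np.isfinite(d)
        n_pairs = int(finite.sum())
        if n_pairs == 0:
            raise DataError("no connected pairs")
        value = float(d[finite].mean())
    else:
        a = skel.adjacency()
        total, n_pairs = _bfs_hop_sum(a.indptr, a.indices, n)
        if n_pairs == 0:
            raise DataError("no connected pairs")
        value = total / n_pairs
    if return_pairs:
        return value, n_pairs
    return value


def clustering_coefficient(net: CompetitionNetwork) -> float:
    """Mean local transitivity; isolated and degree-1 nodes contribute 0."""
    n, _, skel = _skeleton_counts(net)
    if n < 1:
        raise DataError("empty network")
    a = skel.adjacency().astype(np.int64)
    deg = np.asarray(a.sum(axis=1)).ravel()
    # wedge count through each node: (A @ A) .* A row sums = 2 * e_i
    two_e = np.asarray((a @ a).multiply(a).sum(axis=1)).ravel()
    denom = deg * (deg - 1)
    local = np.divide(two_e, denom, out=np.zeros(n, dtype=float), where=denom > 0)
    return float(local.mean())


def degree_distribution(net: CompetitionNetwork, weighted: bool = False, bins=None):
    """Per-node degrees (or strengths) plus a histogram.

    Returns ``(values, (counts, bin_edges))``.  ``weighted=True`` sums the
    incident competition-index weights (in + out for the directed WCL).
    """
    n = net.n_nodes
    if weighted:
        if net.weights is None:
            raise DataError("weighted degrees need edge weights")
        values = np.zeros(n)
        np.add.at(values, net.edges[:, 0], net.weights)   # out-strength
        np.add.at(values, net.edges[:, 1], net.weights)   # in-strength
    else:
        _, _, skel = _skeleton_counts(net)
        values = np.asarray(skel.adjacency().sum(axis=1), dtype=float).ravel()
    if bins is None:
        hi = max(1.0, float(values.max()) if n else 1.0)
        bins = np.arange(0.0, np.ceil(hi) + 2.0) if not weighted else 20
    counts, edges = np.histogram(values, bins=bins)
    return values, (counts, edges)


def betweenness(net: CompetitionNetwork) -> dict:
    """Unnormalized shortest-path betweenness (endpoints excluded) per node id.

    Computed on the undirected unweighted skeleton via networkx.
    """
    import networkx as nx

    _, _, skel = _skeleton_counts(net)
    g = nx.Graph()
    ids = skel.nodes["id"].tolist()
    g.add_nodes_from(ids)
    arr = skel.nodes["id"].to_numpy()
    g.add_edges_from((arr[i], arr[j]) for i, j in skel.edges)
    return nx.betweenness_centrality(g, normalized=False)


@dataclass
class FieldGrid:
    """A node metric interpolated onto a regular spatial grid."""

    x: np.ndarray        # (nx,) grid abscissae
    y: np.ndarray        # (ny,) grid ordinates
    values: np.ndarray   # (ny, nx)
    spacing: float

    def to_frame(self):
        import pandas as pd

        xx, yy = np.meshgrid(self.x, self.y)
        return pd.DataFrame({"x": xx.ravel(), "y": yy.ravel(),
                             "value": self.values.ravel()})


_CV_SMOOTHING_GRID = (0.0, 1e-3, 1e-2, 1e-1, 1.0, 10.0, 100.0)


def _cv_smoothing(coords, values, rng=None):
    """Pick thin-plate smoothing by 5-fold cross-validation over a log grid."""
    from scipy.interpolate import RBFInterpolator

    rng = np.random.default_rng(0 if rng is None else rng)
    n = len(coords)
    perm = rng.permutation(n)
    folds = np.array_split(perm, 5)
    best, best_err = 0.0, np.inf
    for s in _CV_SMOOTHING_GRID:
        err = 0.0
        ok = True
        for f in folds:
            train = np.setdiff1d(perm, f)
            if train.size < 4:
                ok = False
                break
            try:
                interp = RBFInterpolator(coords[train], values[train],
                                         kernel="thin_plate_spline", smoothing=s)
                err += float(np.sum((interp(coords[f]) - values[f]) ** 2))
            except np.linalg.LinAlgError:
                ok = False
                break
        if ok and err < best_err:
            best, best_err = s, err
    return best


def interpolate_field(x, y, values, window: Window, grid_spacing: float = 2.0,
                      smoothing="cv") -> FieldGrid:
    """Thin-plate spline surface of a node metric on a regular grid.

    ``smoothing`` is the spline smoothing parameter: 0 interpolates the node
    values exactly, larger values smooth; the default ``"cv"`` picks it by
    5-fold cross-validation.
    """
    from scipy.interpolate import RBFInterpolator

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    values = np.asarray(values, float)
    if x.size < 4:
        raise DataError("need at least 4 nodes to interpolate a surface")
    if not grid_spacing > 0:
        raise ParameterError("grid_spacing must be positive")
    coords = np.column_stack([x, y])
    span = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(span) < 2:
        raise DataError("degenerate (collinear) node geometry")
    if smoothing == "cv":
        smoothing = _cv_smoothing(coords, values)
    interp = RBFInterpolator(coords, values, kernel="thin_plate_spline",
                             smoothing=float(smoothing))
    gx = np.arange(window.xmin, window.xmax + 0.5 * grid_spacing, grid_spacing)
    gy = np.arange(window.ymin, window.ymax + 0.5 * grid_spacing, grid_spacing)
    xx, yy = np.meshgrid(gx, gy)
    grid_vals = interp(np.column_stack([xx.ravel(), yy.ravel()])).reshape(len(gy), len(gx))
    return FieldGrid(gx, gy, grid_vals, grid_spacing)


def metric_set(net: CompetitionNetwork, path_length: bool = True,
               weighted_factor: float = 2.0) -> MetricSet:
    """The full (N, E, k, C, D, L) bundle for one network.

    ``path_length=False`` skips the all-pairs shortest-path computation and
    reports ``L = nan`` (useful in large parameter sweeps).
    """
    n = net.n_nodes
    e = net.n_edges
    k = average_degree(net)
    c = clustering_coefficient(net)
    d = density(net)
    if path_length and net.n_edges > 0:
        length, pairs = average_path_length(net, return_pairs=True)
    else:
        length, pairs = float("nan"), 0
    kw = None
    if net.weights is not None:
        kw = weighted_average_degree(net, factor=weighted_factor)
    return MetricSet(net.net_type, n, e, k, c, d, length, k_weighted=kw,
                     n_connected_pairs=pairs)
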