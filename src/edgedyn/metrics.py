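"""Graph-theoretical metrics on binary undirected networks.

Global: clustering coefficient (Cp), characteristic path length (Lp),
global and local efficiency (Eglob, Eloc), and small-world indices gamma,
lambda, sigma obtained by normalizing Cp and Lp against degree-preserving
(Maslov-Sneppen rewired) random graphs.  Nodal: degree centrality (Dc),
unnormalized shortest-path betweenness (Bc, Brandes), and nodal efficiency
(Ne).  Values computed per sparsity threshold are summarized with a
trapezoidal area under the curve.

Conventions for degenerate cases: nodes with degree < 2 contribute 0 to Cp
and Eloc; Lp averages over reachable distinct pairs only (disconnected
graphs are routine at low sparsity) and the unreachable fraction is logged;
an empty graph yields all-zero metrics with a warning.
"""

from __future__ import annotations

import dataclasses
import logging

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

logger = logging.getLogger(__name__)

GLOBAL_METRIC_NAMES = ("Cp", "Lp", "gamma", "lambda", "sigma", "Eglob", "Eloc")
NODAL_METRIC_NAMES = ("Ne", "Dc", "Bc")


def _as_adj(adj) -> np.ndarray:
    a = np.asarray(adj)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    a = (a != 0).astype(np.uint8)
    if np.any(np.diag(a)):
        raise ValueError("self-loops are not allowed")
    if not np.array_equal(a, a.T):
        raise ValueError("adjacency must be symmetric")
    return a


def _distances(adj: np.ndarray) -> np.ndarray:
    if adj.sum() == 0:
        n = adj.shape[0]
        d = np.full((n, n), np.inf)
        np.fill_diagonal(d, 0.0)
        return d
    return shortest_path(csr_matrix(adj), method="D", unweighted=True, directed=False)


def clustering_coefficient(adj) -> float:
    """Mean over nodes of 2*triangles / (k*(k-1)); degree < 2 counts as 0."""
    a = _as_adj(adj).astype(float)
    deg = a.sum(axis=1)
    tri = np.diag(a @ a @ a) / 2.0
    denom = deg * (deg - 1)
    local = np.where(denom > 0, 2.0 * tri / np.where(denom > 0, denom, 1.0), 0.0)
    return float(local.mean()) if a.shape[0] else 0.0


def characteristic_path_length(adj) -> float:
    """Mean shortest-path length over reachable distinct pairs."""
    a = _as_adj(adj)
    d = _distances(a)
    n = a.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    n_pairs = int(off.sum())
    n_reach = int(finite.sum())
    if n_reach == 0:
        logger.warning("no reachable pairs; Lp set to 0")
        return 0.0
    if n_reach < n_pairs:
        logger.debug("Lp over %d/%d reachable pairs", n_reach, n_pairs)
    return float(d[finite].mean())


def _global_efficiency_from_dist(d: np.ndarray) -> float:
    n = d.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    return float(inv[off].mean())


def global_efficiency(adj) -> float:
    """Mean of 1/d over all distinct pairs, with 1/inf = 0."""
    a = _as_adj(adj)
    return _global_efficiency_from_dist(_distances(a))


def local_efficiency(adj) -> float:
    """Mean over nodes of the global efficiency of the neighbor subgraph."""
    a = _as_adj(adj)
    n = a.shape[0]
    if n == 0:
        return 0.0
    vals = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(a[i])
        if nb.size < 2:
            continue
        vals[i] = global_efficiency(a[np.ix_(nb, nb)])
    return float(vals.mean())


def global_metrics(adj) -> dict:
    """Cp, Lp, Eglob, Eloc of one binary graph (small-world terms excluded)."""
    a = _as_adj(adj)
    if a.sum() == 0:
        logger.warning("empty graph; global metrics all zero")
        return {"Cp": 0.0, "Lp": 0.0, "Eglob": 0.0, "Eloc": 0.0}
    d = _distances(a)
    n = a.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    lp = float(d[finite].mean()) if finite.any() else 0.0
    return {
        "Cp": clustering_coefficient(a),
        "Lp": lp,
        "Eglob": _global_efficiency_from_dist(d),
        "Eloc": local_efficiency(a),
    }


def nodal_metrics(adj) -> dict:
    """Per-node Ne, Dc, Bc arrays.

    Dc is the raw degree; Bc is unnormalized Brandes betweenness with
    fractional credit over equal-length shortest paths, each unordered pair
    counted once; Ne(i) = mean over j != i of 1/d(i, j).
    """
    a = _as_adj(adj)
    n = a.shape[0]
    d = _distances(a)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    ne = inv.sum(axis=1) / max(n - 1, 1)
    dc = a.sum(axis=1).astype(float)
    g = nx.from_numpy_array(a)
    bc_map = nx.betweenness_centrality(g, normalized=False)
    bc = np.array([bc_map[i] for i in range(n)])
    return {"Ne": ne, "Dc": dc, "Bc": bc}


def degree_preserving_rewire(adj, n_swaps: int, rng: np.random.Generator, max_tries: int | None = None):
    """Maslov-Sneppen double-edge swaps; returns a rewired adjacency matrix.

    Performs ``n_swaps`` accepted swaps, rejecting any proposal that would
    create a self-loop or duplicate edge.  If no swap is possible (e.g. too
    few edges), the original graph is returned with a warning.
    """
    a = _as_adj(adj)
    iu = np.triu_indices(a.shape[0], k=1)
    ei, ej = iu[0][a[iu] != 0], iu[1][a[iu] != 0]
    m = ei.size
    if m < 2:
        logger.warning("fewer than 2 edges; rewiring impossible, returning original graph")
        return a.copy()
    edges = {(int(i), int(j)) for i, j in zip(ei, ej)}
    elist = [(int(i), int(j)) for i, j in zip(ei, ej)]
    if max_tries is None:
        max_tries = 100 * max(n_swaps, 1)
    accepted = 0
    tries = 0
    while accepted < n_swaps and tries < max_tries:
        tries += 1
        u, v = rng.integers(0, m, size=2)
        if u == v:
            continue
        a1, b1 = elist[u]
        c1, d1 = elist[v]
        if rng.random() < 0.5:
            c1, d1 = d1, c1
        # propose (a1, d1) and (c1, b1)
        if a1 == d1 or c1 == b1:
            continue
        e1 = (min(a1, d1), max(a1, d1))
        e2 = (min(c1, b1), max(c1, b1))
        if e1 in edges or e2 in edges or e1 == e2:
            continue
        edges.discard(elist[u])
        edges.discard(elist[v])
        edges.add(e1)
        edges.add(e2)
        elist[u] = e1
        elist[v] = e2
        accepted += 1
    if accepted == 0 and n_swaps > 0:
        logger.warning("no feasible swap found; null equals original graph")
    out = np.zeros_like(a)
    for i, j in elist:
        out[i, j] = 1
        out[j, i] = 1
    return out


@dataclasses.dataclass(frozen=True)
class NullEnsemble:
    n_nulls: int
    rewires_per_edge: int
    seed: int
    null_cp_mean: float
    null_lp_mean: float


def null_normalize(
    adj,
    n_nulls: int = 100,
    rewires_per_edge: int = 10,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[dict, NullEnsemble]:
    """gamma = Cp/<Cp_null>, lambda = Lp/<Lp_null>, sigma = gamma/lambda.

    Nulls are degree-preserving rewired copies (``rewires_per_edge * E``
    accepted swaps each).  ``rewires_per_edge=0`` makes every null the graph
    itself, which pins gamma = lambda = sigma = 1 (useful as a calibration
    case).
    """
    a = _as_adj(adj)
    m = int(a.sum()) // 2
    if m < 2:
        raise ValueError("null normalization requires at least 2 edges")
    if n_nulls < 1:
        raise ValueError("need at least 1 null graph")
    if rng is None:
        rng = np.random.default_rng(seed)
    cp = clustering_coefficient(a)
    lp = characteristic_path_length(a)
    n_swaps = rewires_per_edge * m
    null_cp = np.empty(n_nulls)
    null_lp = np.empty(n_nulls)
    for k in range(n_nulls):
        null = degree_preserving_rewire(a, n_swaps, rng) if n_swaps > 0 else a
        null_cp[k] = clustering_coefficient(null)
        null_lp[k] = characteristic_path_length(null)
    cp_bar = float(null_cp.mean())
    lp_bar = float(null_lp.mean())
    gamma = cp / cp_bar if cp_bar > 0 else 0.0
    lam = lp / lp_bar if lp_bar > 0 else 0.0
    sigma = gamma / lam if lam > 0 else 0.0
    ensemble = NullEnsemble(
        n_nulls=n_nulls,
        rewires_per_edge=rewires_per_edge,
        seed=seed,
        null_cp_mean=cp_bar,
        null_lp_mean=lp_bar,
    )
    return {"gamma": gamma, "lambda": lam, "sigma": sigma}, ensemble


def auc_over_grid(values, grid) -> float:
    """Trapezoidal integral of metric values over the sorted sparsity grid."""
    values = np.asarray(values, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if values.shape != grid.shape:
        raise ValueError("values and grid must have the same length")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    return float(np.trapezoid(values, grid))
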