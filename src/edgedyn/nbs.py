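"""Network-based statistic (NBS).

Edge-wise two-sample pooled-variance t statistics are thresholded (default
T > 2.105, upper tail) and the surviving edges grouped into connected
components; the size of a component is its edge count.  Significance is
assessed against the max-component-size null distribution obtained by
permuting group labels, with the +1-corrected permutation p-value
``p = (1 + #{null max >= observed}) / (n_permutations + 1)``.
"""

from __future__ import annotations

import dataclasses
import logging
from itertools import combinations
from math import comb

import numpy as np

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class NbsConfig:
    t_threshold: float = 2.105
    n_permutations: int = 5000
    alpha: float = 0.05
    seed: int = 0
    tail: str = "greater"

    def __post_init__(self) -> None:
        if not (self.t_threshold > 0):
            raise ValueError("t_threshold must be positive")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be at least 100")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.tail not in ("greater", "less", "both"):
            raise ValueError("tail must be 'greater', 'less' or 'both'")


@dataclasses.dataclass(frozen=True)
class NbsComponent:
    nodes: tuple
    edges: tuple  # tuples of (i, j) node indices, i < j
    size: int  # edge count


@dataclasses.dataclass(frozen=True)
class NbsResult:
    edge_t: np.ndarray
    suprathreshold_edges: tuple
    components: tuple  # of NbsComponent
    max_component_null: np.ndarray
    p_per_component: tuple
    config: NbsConfig


def edge_group_t(fc_stack_a: np.ndarray, fc_stack_b: np.ndarray) -> np.ndarray:
    """Per-edge pooled-variance two-sample t (A minus B), df = nA + nB - 2."""
    a = np.asarray(fc_stack_a, dtype=float)
    b = np.asarray(fc_stack_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("stacks must be 2-D (subjects x edges) with matching edge count")
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 subjects per group")
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(axis=0, ddof=1) + (nb - 1) * b.var(axis=0, ddof=1)) / df
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    diff = a.mean(axis=0) - b.mean(axis=0)
    zero = denom == 0
    if zero.any():
        logger.warning("%d edges have zero pooled variance; t set to 0", int(zero.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero, 0.0, diff / np.where(zero, 1.0, denom))
    return t


def _supra_mask(edge_t: np.ndarray, t_threshold: float, tail: str) -> np.ndarray:
    if tail == "greater":
        return edge_t > t_threshold
    if tail == "less":
        return edge_t < -t_threshold
    return np.abs(edge_t) > t_threshold


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self) -> None:
        self.parent: dict = {}

    def find(self, x):
        p = self.parent.setdefault(x, x)
        while p != x:
            self.parent[x] = self.parent[p]
            x = p
            p = self.parent[x]
        return x

    def union(self, x, y) -> None:
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[ry] = rx


def extract_components(
    edge_t: np.ndarray, t_threshold: float, tail: str, edge_index: np.ndarray
) -> tuple:
    """Connected components of the suprathreshold-edge graph.

    Returns a tuple of :class:`NbsComponent`, sorted by decreasing size then
    by smallest node index; nodes and edges within a component are sorted.
    """
    mask = _supra_mask(np.asarray(edge_t, dtype=float), t_threshold, tail)
    pairs = np.asarray(edge_index)[mask]
    if pairs.size == 0:
        return ()
    uf = _UnionFind()
    for i, j in pairs:
        uf.union(int(i), int(j))
    groups: dict = {}
    for i, j in pairs:
        groups.setdefault(uf.find(int(i)), []).append((int(i), int(j)))
    comps = []
    for edges in groups.values():
        edges = tuple(sorted(edges))
        nodes = tuple(sorted({n for e in edges for n in e}))
        comps.append(NbsComponent(nodes=nodes, edges=edges, size=len(edges)))
    comps.sort(key=lambda c: (-c.size, c.nodes[0]))
    return tuple(comps)


def _max_component_size(mask: np.ndarray, edge_index: np.ndarray) -> int:
    pairs = edge_index[mask]
    if pairs.size == 0:
        return 0
    uf = _UnionFind()
    for i, j in pairs:
        uf.union(int(i), int(j))
    counts: dict = {}
    for i, j in pairs:
        r = uf.find(int(i))
        counts[r] = counts.get(r, 0) + 1
    return max(counts.values())


def permutation_p(
    fc_stack_a: np.ndarray,
    fc_stack_b: np.ndarray,
    edge_index: np.ndarray,
    config: NbsConfig = NbsConfig(),
) -> NbsResult:
    """Full NBS: observed components plus max-component permutation null.

    When the number of distinct label assignments is no larger than the
    requested permutation count the null is enumerated exactly instead
    (logged); p-values keep the +1 correction in both modes.
    """
    a = np.asarray(fc_stack_a, dtype=float)
    b = np.asarray(fc_stack_b, dtype=float)
    edge_index = np.asarray(edge_index)
    na, nb = a.shape[0], b.shape[0]
    observed_t = edge_group_t(a, b)
    components = extract_components(observed_t, config.t_threshold, config.tail, edge_index)

    pooled = np.vstack([a, b])
    n = na + nb
    n_assign = comb(n, na)
    rng = np.random.default_rng(config.seed)
    if n_assign <= config.n_permutations:
        logger.warning(
            "only %d distinct assignments (< %d permutations); enumerating exactly",
            n_assign,
            config.n_permutations,
        )
        index_sets = [np.array(c) for c in combinations(range(n), na)]
    else:
        index_sets = [rng.permutation(n)[:na] for _ in range(config.n_permutations)]

    null = np.empty(len(index_sets), dtype=int)
    all_idx = np.arange(n)
    for k, idx_a in enumerate(index_sets):
        sel = np.zeros(n, dtype=bool)
        sel[idx_a] = True
        t = edge_group_t(pooled[sel], pooled[~sel])
        null[k] = _max_component_size(_supra_mask(t, config.t_threshold, config.tail), edge_index)

    n_perm = len(index_sets)
    p_values = tuple(
        float((1 + int(np.sum(null >= c.size))) / (n_perm + 1)) for c in components
    )
    supra = tuple(
        (int(i), int(j))
        for i, j in edge_index[_supra_mask(observed_t, config.t_threshold, config.tail)]
    )
    return NbsResult(
        edge_t=observed_t,
        suprathreshold_edges=supra,
        components=components,
        max_component_null=null,
        p_per_component=p_values,
        config=config,
    )


def result_to_dict(result: NbsResult, roi_labels=None) -> dict:
    """JSON-serializable summary of an NBS result."""
    def _lab(i: int):
        return roi_labels[i] if roi_labels is not None else int(i)

    return {
        "config": dataclasses.asdict(result.config),
        "n_suprathreshold_edges": len(result.suprathreshold_edges),
        "components": [
            {
                "nodes": [_lab(i) for i in c.nodes],
                "edges": [[_lab(i), _lab(j)] for i, j in c.edges],
                "size": c.size,
                "p_value": p,
            }
            for c, p in zip(result.components, result.p_per_component)
        ],
        "null_max_component_sizes": result.max_component_null.tolist(),
    }
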