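"""Amplitude-state frame networks.

Frames are ranked by RSS and split into a high-amplitude set (the top
``fraction`` of frames, default 10%, k = ceil(fraction * T), ties at the
cutoff broken toward the earlier frame) and a low-amplitude set (the rest).
Each state gets a functional connectivity matrix — by default the mean
co-fluctuation over the retained frames; optionally the Pearson correlation
of the raw ROI rows restricted to those frames — which is then binarized
over a sparsity grid by keeping the largest (signed) off-diagonal values.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .ets import EdgeTimeSeries, RssTrace, edges_to_matrix, matrix_to_edges

DEFAULT_SPARSITY_GRID = tuple(np.round(np.arange(0.05, 0.501, 0.05), 2))


@dataclasses.dataclass(frozen=True)
class FrameMask:
    """Membership of frames in one amplitude state."""

    state: str  # "high" or "low"
    keep: np.ndarray  # boolean, length T
    fraction: float

    @property
    def n_kept(self) -> int:
        return int(np.count_nonzero(self.keep))


@dataclasses.dataclass(frozen=True)
class FrameFcNetwork:
    """State-labelled FC matrix plus binary graphs over the sparsity grid."""

    state: str
    fc: np.ndarray  # N x N symmetric, zero diagonal
    graphs: dict  # sparsity -> N x N binary adjacency (uint8)
    sparsity_grid: tuple

    @property
    def n_roi(self) -> int:
        return self.fc.shape[0]


def split_frames(rss: RssTrace, fraction: float = 0.10) -> tuple[FrameMask, FrameMask]:
    """Partition frames into high- (top ``fraction`` by RSS) and low-amplitude sets."""
    if not (0 < fraction < 1):
        raise ValueError("fraction must lie in (0, 1)")
    values = np.asarray(rss.values, dtype=float)
    T = values.size
    if T < 1 / fraction:
        raise ValueError(f"need at least {math.ceil(1 / fraction)} frames for fraction {fraction}")
    k = math.ceil(fraction * T)
    # stable sort on -rss keeps earlier frames first among ties
    order = np.argsort(-values, kind="stable")
    keep_high = np.zeros(T, dtype=bool)
    keep_high[order[:k]] = True
    high = FrameMask(state="high", keep=keep_high, fraction=fraction)
    low = FrameMask(state="low", keep=~keep_high, fraction=1 - fraction)
    return high, low


def build_state_fc(
    ets: EdgeTimeSeries,
    mask: FrameMask,
    method: str = "mean_cofluctuation",
    raw_data: np.ndarray | None = None,
) -> np.ndarray:
    """State FC matrix (N x N, symmetric, zero diagonal) from retained frames.

    ``mean_cofluctuation``: fc_ij = mean over retained frames of e_ij(t).
    ``frame_pearson``: Pearson correlation of the raw ROI rows restricted to
    the retained frames (requires ``raw_data``, the ROI x T matrix).
    """
    keep = np.asarray(mask.keep, dtype=bool)
    if keep.size != ets.n_frames:
        raise ValueError("mask length does not match frame count")
    n_kept = int(keep.sum())
    if method == "mean_cofluctuation":
        if n_kept < 2:
            raise ValueError("mean_cofluctuation needs at least 2 retained frames")
        edge_means = ets.data[:, keep].mean(axis=1)
        return edges_to_matrix(edge_means, ets.n_roi)
    if method == "frame_pearson":
        if raw_data is None:
            raise ValueError("frame_pearson requires the raw ROI x T matrix")
        if n_kept < 3:
            raise ValueError("frame_pearson needs at least 3 retained frames")
        fc = np.corrcoef(np.asarray(raw_data, dtype=float)[:, keep])
        np.fill_diagonal(fc, 0.0)
        return fc
    raise ValueError(f"unknown FC method {method!r}")


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def threshold_proportional(fc: np.ndarray, sparsity_grid) -> dict:
    """Binary adjacency at each sparsity: keep the round(S*E) largest values.

    Ranking is by signed value, descending, ties broken by canonical edge
    index, so graphs at larger S are strict supersets of graphs at smaller S.
    """
    grid = [float(s) for s in sparsity_grid]
    if any(not (0 < s < 1) for s in grid):
        raise ValueError("sparsity values must lie in (0, 1)")
    fc = np.asarray(fc, dtype=float)
    n = fc.shape[0]
    vec = matrix_to_edges(fc)
    E = vec.size
    order = np.argsort(-vec, kind="stable")
    graphs: dict = {}
    for s in grid:
        k = min(_round_half_away(s * E), E)
        keep = np.zeros(E, dtype=bool)
        keep[order[:k]] = True
        adj = edges_to_matrix(keep.astype(np.uint8), n)
        graphs[s] = adj.astype(np.uint8)
    return graphs


def build_frame_network(
    ets: EdgeTimeSeries,
    mask: FrameMask,
    sparsity_grid=DEFAULT_SPARSITY_GRID,
    method: str = "mean_cofluctuation",
    raw_data: np.ndarray | None = None,
) -> FrameFcNetwork:
    """FC matrix plus thresholded graphs for one amplitude state."""
    fc = build_state_fc(ets, mask, method=method, raw_data=raw_data)
    graphs = threshold_proportional(fc, sparsity_grid)
    return FrameFcNetwork(
        state=mask.state, fc=fc, graphs=graphs, sparsity_grid=tuple(float(s) for s in sparsity_grid)
    )
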