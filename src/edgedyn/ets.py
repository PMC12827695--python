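"""Edge time series (co-fluctuation) construction.

The co-fluctuation value of an ROI pair (i, j) at frame t is the product of
the two z-scored BOLD signals, ``e_ij(t) = z_i(t) * z_j(t)``.  Standardizing
with the sample standard deviation (T - 1 denominator) makes the time average
of an edge row, multiplied by ``T / (T - 1)``, exactly the Pearson
correlation of the raw signals — the usual "un-averaged correlation" reading
of edge time series.

Edges are indexed canonically: all unordered pairs (i, j) with i < j in
lexicographic order, so ``E = N * (N - 1) / 2`` rows.

The module also provides the edge-by-edge similarity matrix (eFC), with a
cosine-type normalization onto [-1, 1], and the per-frame RSS trace
``RSS(t) = sqrt(sum_edges e(t)^2)`` that summarizes global co-fluctuation
magnitude.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: refuse to build an E x E eFC matrix beyond this many edges unless overridden
DEFAULT_MAX_EFC_EDGES = 25_000


class ZeroVarianceError(ValueError):
    """An ROI row has zero variance and cannot be z-scored."""


def edge_pairs(n_roi: int) -> np.ndarray:
    """Canonical edge index: (E, 2) array of pairs (i, j), i < j, lexicographic."""
    if n_roi < 2:
        raise ValueError("need at least 2 ROIs to form edges")
    iu = np.triu_indices(n_roi, k=1)
    return np.column_stack(iu)


def n_edges(n_roi: int) -> int:
    return n_roi * (n_roi - 1) // 2


def edges_to_matrix(edge_values: np.ndarray, n_roi: int, diagonal: float = 0.0) -> np.ndarray:
    """Expand a length-E edge vector into a symmetric N x N matrix."""
    edge_values = np.asarray(edge_values)
    if edge_values.shape != (n_edges(n_roi),):
        raise ValueError(
            f"expected {n_edges(n_roi)} edge values for {n_roi} ROIs, got {edge_values.shape}"
        )
    mat = np.full((n_roi, n_roi), diagonal, dtype=float)
    iu = np.triu_indices(n_roi, k=1)
    mat[iu] = edge_values
    mat[iu[1], iu[0]] = edge_values
    return mat


def matrix_to_edges(mat: np.ndarray) -> np.ndarray:
    """Extract the canonical edge vector (upper triangle, i < j) of a square matrix."""
    mat = np.asarray(mat)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("expected a square matrix")
    return mat[np.triu_indices(mat.shape[0], k=1)]


@dataclasses.dataclass(frozen=True)
class RoiTimeSeries:
    """One subject's parcellated BOLD signal, ROI x T."""

    subject_id: str
    data: np.ndarray
    roi_labels: tuple[str, ...]
    tr_seconds: float = 1.0

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "roi_labels", tuple(str(l) for l in self.roi_labels))
        if data.ndim != 2:
            raise ValueError("data must be a 2-D ROI x T matrix")
        if data.shape[0] < 2:
            raise ValueError("need at least 2 ROIs")
        if data.shape[1] < 3:
            raise ValueError("need at least 3 frames")
        if not np.all(np.isfinite(data)):
            raise ValueError("data contains NaN or infinite values")
        if len(self.roi_labels) != data.shape[0]:
            raise ValueError("roi_labels length does not match ROI count")
        if len(set(self.roi_labels)) != len(self.roi_labels):
            raise ValueError("duplicate ROI labels")
        if not (self.tr_seconds > 0):
            raise ValueError("tr_seconds must be positive")

    @property
    def n_roi(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]


@dataclasses.dataclass(frozen=True)
class ZScoredSeries:
    """Per-ROI standardized signal; sample SD (T - 1) convention."""

    data: np.ndarray
    roi_labels: tuple[str, ...]
    tr_seconds: float = 1.0
    dof_convention: str = "sample (T-1)"

    @property
    def n_roi(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]


@dataclasses.dataclass(frozen=True)
class EdgeTimeSeries:
    """Co-fluctuation series, E x T, with the canonical (i, j) edge index."""

    data: np.ndarray
    edge_index: np.ndarray
    roi_labels: tuple[str, ...]
    tr_seconds: float = 1.0

    @property
    def n_edges(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def n_roi(self) -> int:
        return len(self.roi_labels)


@dataclasses.dataclass(frozen=True)
class EfcMatrix:
    """Edge-by-edge co-fluctuation similarity matrix (E x E)."""

    data: np.ndarray
    normalized: bool


@dataclasses.dataclass(frozen=True)
class RssTrace:
    """Per-frame global co-fluctuation magnitude, length T."""

    values: np.ndarray
    tr_seconds: float = 1.0

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


def zscore(series: RoiTimeSeries) -> ZScoredSeries:
    """Standardize each ROI row to mean 0 and sample SD 1.

    Raises :class:`ZeroVarianceError` naming the offending ROI if any row is
    constant.
    """
    data = series.data
    mean = data.mean(axis=1, keepdims=True)
    sd = data.std(axis=1, ddof=1, keepdims=True)
    flat = np.flatnonzero(sd[:, 0] == 0)
    if flat.size:
        label = series.roi_labels[flat[0]]
        raise ZeroVarianceError(f"ROI {label!r} (row {flat[0]}) has zero variance")
    z = (data - mean) / sd
    return ZScoredSeries(data=z, roi_labels=series.roi_labels, tr_seconds=series.tr_seconds)


def compute_ets(z: ZScoredSeries) -> EdgeTimeSeries:
    """Build the E x T edge time series from a z-scored ROI x T matrix."""
    pairs = edge_pairs(z.n_roi)
    data = z.data[pairs[:, 0]] * z.data[pairs[:, 1]]
    return EdgeTimeSeries(
        data=data, edge_index=pairs, roi_labels=z.roi_labels, tr_seconds=z.tr_seconds
    )


def compute_efc(
    ets: EdgeTimeSeries,
    normalize: bool = True,
    max_edges: int = DEFAULT_MAX_EFC_EDGES,
) -> EfcMatrix:
    """Edge-by-edge similarity: entry (u, v) = sum_t e_u(t) e_v(t).

    When ``normalize`` is set, each entry is divided by the geometric mean of
    the two edges' energies, which maps the matrix onto [-1, 1] with a unit
    diagonal.  Identically-zero edge rows get a zeroed row/column and a
    warning.  Refuses to allocate beyond ``max_edges`` edges (E x E floats)
    unless the cap is raised explicitly.
    """
    E = ets.n_edges
    if E > max_edges:
        raise MemoryError(
            f"eFC matrix would be {E} x {E}; raise max_edges (currently {max_edges}) to override"
        )
    if ets.n_frames < 2:
        raise ValueError("need at least 2 frames for eFC")
    gram = ets.data @ ets.data.T
    if not normalize:
        return EfcMatrix(data=gram, normalized=False)
    energy = np.diag(gram).copy()
    zero = energy == 0
    if zero.any():
        logger.warning("%d edge rows are identically zero; zeroing their eFC rows", zero.sum())
        energy[zero] = 1.0  # avoid division by zero; rows zeroed below
    norm = np.sqrt(np.outer(energy, energy))
    out = gram / norm
    out[zero, :] = 0.0
    out[:, zero] = 0.0
    np.fill_diagonal(out, np.where(zero, 0.0, 1.0))
    return EfcMatrix(data=out, normalized=True)


def compute_rss(ets: EdgeTimeSeries) -> RssTrace:
    """RSS(t) = sqrt(sum over edges of e(t)^2), one value per frame."""
    values = np.sqrt(np.sum(ets.data**2, axis=0))
    return RssTrace(values=values, tr_seconds=ets.tr_seconds)


def pearson_from_ets(ets: EdgeTimeSeries) -> np.ndarray:
    """Recover the length-E Pearson correlation vector from the edge series.

    Uses the identity r_ij = (1 / (T - 1)) * sum_t z_i(t) z_j(t), i.e. the
    time mean of each edge row scaled by T / (T - 1).
    """
    T = ets.n_frames
    return ets.data.mean(axis=1) * (T / (T - 1))


def ets_pipeline(series: RoiTimeSeries) -> tuple[ZScoredSeries, EdgeTimeSeries, RssTrace]:
    """Convenience: z-score, edge series, and RSS trace in one call."""
    z = zscore(series)
    ets = compute_ets(z)
    return z, ets, compute_rss(ets)
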