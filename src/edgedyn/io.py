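"""Delimited-text I/O for ROI time series, matrices and tables.

Subject files are laid out rows = frames, columns = ROI, with a header row
of ROI labels; they are transposed to ROI x T on read.  Floats are written
with 17 significant digits so a write/read round trip is exact.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .ets import RoiTimeSeries

FLOAT_FMT = "%.17g"


class ParseError(ValueError):
    """Malformed input file; the message carries the line number."""


def read_roi_series(
    path,
    tr_seconds: float = 1.0,
    subject_id: str | None = None,
    delimiter: str = ",",
    check_variance: bool = True,
) -> RoiTimeSeries:
    """Parse a frames x ROI delimited-text file into a RoiTimeSeries.

    Ragged rows, non-numeric or NaN cells, and duplicate ROI labels raise
    :class:`ParseError` with a line (and column) number.  Zero-variance ROI
    rows are rejected at load unless ``check_variance`` is disabled.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip() != ""]
    if len(lines) < 2:
        raise ParseError(f"{path}: need a header and at least one data row")
    labels = [c.strip() for c in lines[0].split(delimiter)]
    if len(set(labels)) != len(labels):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise ParseError(f"{path}: line 1: duplicate ROI labels {dup}")
    n_roi = len(labels)
    rows = []
    for lineno, ln in enumerate(lines[1:], start=2):
        cells = ln.split(delimiter)
        if len(cells) != n_roi:
            raise ParseError(
                f"{path}: line {lineno}: expected {n_roi} columns, found {len(cells)}"
            )
        row = []
        for col, cell in enumerate(cells, start=1):
            try:
                v = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}, column {col}: non-numeric cell {cell.strip()!r}"
                ) from None
            if math.isnan(v) or math.isinf(v):
                raise ParseError(f"{path}: line {lineno}, column {col}: non-finite cell")
            row.append(v)
        rows.append(row)
    data = np.asarray(rows, dtype=float).T  # ROI x T
    if check_variance:
        sd = data.std(axis=1, ddof=1)
        flat = np.flatnonzero(sd == 0)
        if flat.size:
            raise ParseError(f"{path}: ROI {labels[flat[0]]!r} has zero variance")
    sid = subject_id if subject_id is not None else path.stem
    return RoiTimeSeries(subject_id=sid, data=data, roi_labels=tuple(labels), tr_seconds=tr_seconds)


def write_roi_series(series: RoiTimeSeries, path, delimiter: str = ",") -> None:
    """Write frames x ROI text with a header row of ROI labels."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(delimiter.join(series.roi_labels) + "\n")
        for frame in series.data.T:
            fh.write(delimiter.join(FLOAT_FMT % v for v in frame) + "\n")


def write_matrix(mat: np.ndarray, labels, path, delimiter: str = ",") -> None:
    """Square matrix as delimited text with a label header row."""
    mat = np.asarray(mat)
    with open(Path(path), "w") as fh:
        fh.write(delimiter.join(str(l) for l in labels) + "\n")
        for row in mat:
            fh.write(delimiter.join(FLOAT_FMT % v for v in row) + "\n")


def read_metadata(path) -> pd.DataFrame:
    """Cohort metadata CSV with the fixed column set."""
    from .synthetic import METADATA_COLUMNS

    df = pd.read_csv(path)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: metadata is missing columns {missing}")
    return df
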