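"""Per-subject connectivity network construction.

Functional networks are Pearson correlations of ROI-averaged time series;
structural networks are streamline counts normalized by the summed volumes
of the two end regions. Proportional (sparsity) thresholding retains a
fixed number of strongest undirected edges with a deterministic tie-break.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .atlas import RegionAtlas

__all__ = [
    "ConnectivityMatrix",
    "ROITimeSeries",
    "StreamlineCounts",
    "build_functional_network",
    "build_structural_network",
    "apply_sparsity_threshold",
    "sparsity_edge_count",
    "read_timeseries",
    "read_streamlines",
    "write_matrix_tsv",
    "read_matrix_tsv",
]

SYMMETRY_TOL = 1e-12


@dataclass(frozen=True)
class ROITimeSeries:
    """ROI-averaged time series: timepoints x regions, in atlas order."""

    subject_id: str
    data: np.ndarray = field(repr=False)
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError("time series must be 2-D (timepoints x regions)")
        if data.shape[0] < 2:
            raise ValueError("time series needs at least 2 timepoints")
        if data.shape[1] != len(self.labels):
            raise ValueError(
                f"time series has {data.shape[1]} columns but {len(self.labels)} labels"
            )
        if not np.all(np.isfinite(data)):
            raise ValueError("time series contains non-finite values")
        object.__setattr__(self, "data", data)


@dataclass(frozen=True)
class StreamlineCounts:
    """Symmetric nonnegative integer streamline-count matrix, zero diagonal."""

    subject_id: str
    counts: np.ndarray = field(repr=False)
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("streamline counts must be square")
        if counts.shape[0] != len(self.labels):
            raise ValueError("streamline matrix size disagrees with labels")
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("streamline counts must be integer-valued")
        counts = counts.astype(np.int64)
        if (counts < 0).any():
            raise ValueError("streamline counts must be nonnegative")
        if not np.array_equal(counts, counts.T):
            raise ValueError("streamline counts must be symmetric")
        if np.any(np.diagonal(counts) != 0):
            raise ValueError("streamline count diagonal must be zero")
        object.__setattr__(self, "counts", counts)


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric nonnegative weighted network for one subject and modality."""

    subject_id: str
    modality: Literal["functional", "structural"]
    weights: np.ndarray = field(repr=False)
    labels: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if w.shape[0] != len(self.labels):
            raise ValueError("matrix size disagrees with labels")
        if not np.all(np.isfinite(w)):
            raise ValueError("connectivity weights must be finite")
        if np.abs(w - w.T).max(initial=0.0) > SYMMETRY_TOL:
            raise ValueError("connectivity matrix not symmetric within 1e-12")
        if np.any(np.diagonal(w) != 0):
            raise ValueError("connectivity diagonal must be exactly zero")
        if (w < 0).any():
            raise ValueError("connectivity weights must be nonnegative")
        if self.modality == "functional" and w.max(initial=0.0) > 1 + 1e-12:
            raise ValueError("functional weights cannot exceed 1")
        if self.modality not in ("functional", "structural"):
            raise ValueError(f"unknown modality {self.modality!r}")
        object.__setattr__(self, "weights", w)

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    def n_edges(self) -> int:
        iu = np.triu_indices(self.n_regions, k=1)
        return int((self.weights[iu] > 0).sum())

    def replace_weights(self, weights: np.ndarray, **meta) -> "ConnectivityMatrix":
        return ConnectivityMatrix(
            subject_id=self.subject_id,
            modality=self.modality,
            weights=weights,
            labels=self.labels,
            meta={**self.meta, **meta},
        )


def build_functional_network(
    ts: ROITimeSeries,
    negative_policy: Literal["zero", "absolute"] = "zero",
) -> ConnectivityMatrix:
    """Pearson-correlation network from ROI time series.

    Negative correlations are zeroed (default) or absolute-valued before
    any downstream thresholding; the diagonal is set to zero.
    """
    if negative_policy not in ("zero", "absolute"):
        raise ValueError(f"unknown negative_policy {negative_policy!r}")
    data = ts.data
    sd = data.std(axis=0)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        names = [ts.labels[i] for i in flat[:5]]
        raise ValueError(f"zero-variance time series for region(s): {names}")
    r = np.corrcoef(data, rowvar=False)
    if negative_policy == "zero":
        r = np.where(r < 0, 0.0, r)
    else:
        r = np.abs(r)
    r = np.clip(r, 0.0, 1.0)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix(
        subject_id=ts.subject_id,
        modality="functional",
        weights=r,
        labels=ts.labels,
        meta={"negative_policy": negative_policy},
    )


def build_structural_network(
    counts: StreamlineCounts, atlas: RegionAtlas
) -> ConnectivityMatrix:
    """Volume-normalized streamline network: w_ij = counts_ij / (vol_i + vol_j)."""
    n = len(counts.labels)
    if n != atlas.n_regions:
        raise ValueError(
            f"streamline matrix is {n}x{n} but atlas has {atlas.n_regions} regions"
        )
    if tuple(counts.labels) != tuple(atlas.labels):
        raise ValueError("streamline labels do not match atlas order")
    vols = atlas.volumes
    if not np.all(vols > 0):
        raise ValueError("all atlas volumes must be positive")
    denom = vols[:, None] + vols[None, :]
    w = counts.counts / denom
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(
        subject_id=counts.subject_id,
        modality="structural",
        weights=w,
        labels=counts.labels,
        meta={"normalization": "volume_sum"},
    )


def sparsity_edge_count(n_regions: int, sparsity: float) -> int:
    """Number of retained edges: round(sparsity * N(N-1)/2), half away from zero."""
    n_possible = n_regions * (n_regions - 1) // 2
    return int(math.floor(sparsity * n_possible + 0.5))


def apply_sparsity_threshold(
    net: ConnectivityMatrix, sparsity: float
) -> ConnectivityMatrix:
    """Keep the K strongest undirected edges, zero the rest.

    K = round(sparsity * N(N-1)/2). Ties are broken by ascending
    (row, column) index so the surviving edge sets are nested across
    sparsity levels.
    """
    if not 0 < sparsity <= 1:
        raise ValueError(f"sparsity must be in (0, 1], got {sparsity}")
    if sparsity == 1.0:
        return net.replace_weights(net.weights, sparsity=1.0)
    n = net.n_regions
    k = sparsity_edge_count(n, sparsity)
    rows, cols = np.triu_indices(n, k=1)
    w = net.weights[rows, cols]
    # lexsort: last key is primary -> sort by descending weight, then row, col
    order = np.lexsort((cols, rows, -w))
    keep = order[:k]
    out = np.zeros_like(net.weights)
    out[rows[keep], cols[keep]] = w[keep]
    out = out + out.T
    return net.replace_weights(out, sparsity=float(sparsity))


# ---------------------------------------------------------------------------
# Plain-text I/O


def read_timeseries(path: str | Path, atlas: RegionAtlas, subject_id: str | None = None) -> ROITimeSeries:
    """Read a TSV of timepoints x regions with atlas labels as header."""
    df = pd.read_csv(path, sep="\t")
    if tuple(df.columns) != tuple(atlas.labels):
        raise ValueError(f"time-series columns in {path} do not match atlas labels")
    sid = subject_id if subject_id is not None else Path(path).stem
    return ROITimeSeries(subject_id=sid, data=df.to_numpy(dtype=float), labels=tuple(atlas.labels))


def read_streamlines(path: str | Path, atlas: RegionAtlas, subject_id: str | None = None) -> StreamlineCounts:
    """Read a dense labelled TSV of streamline counts."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if tuple(df.columns) != tuple(atlas.labels) or tuple(df.index) != tuple(atlas.labels):
        raise ValueError(f"streamline labels in {path} do not match atlas order")
    sid = subject_id if subject_id is not None else Path(path).stem
    return StreamlineCounts(subject_id=sid, counts=df.to_numpy(), labels=tuple(atlas.labels))


def write_matrix_tsv(matrix: np.ndarray, labels: tuple[str, ...], path: str | Path) -> None:
    pd.DataFrame(matrix, index=list(labels), columns=list(labels)).to_csv(path, sep="\t")


def read_matrix_tsv(path: str | Path) -> tuple[np.ndarray, tuple[str, ...]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), tuple(df.columns)
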