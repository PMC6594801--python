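"""Hemispheric asymmetry: intra-hemispheric subnetworks and the laterality
index (X_L - X_R) / (X_L + X_R) for any global metric. Positive = leftward.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .atlas import RegionAtlas
from .metrics import GLOBAL_METRIC_NAMES, compute_global_metrics, sweep_and_integrate
from .networks import ConnectivityMatrix

__all__ = [
    "HemispherePair",
    "AsymmetryIndex",
    "UndefinedAsymmetryError",
    "split_hemispheres",
    "asymmetry_index",
    "metric_asymmetries",
]


class UndefinedAsymmetryError(ValueError):
    """Raised when X_L + X_R == 0 and the index is undefined."""


@dataclass(frozen=True)
class HemispherePair:
    left: ConnectivityMatrix
    right: ConnectivityMatrix


@dataclass(frozen=True)
class AsymmetryIndex:
    metric: str
    x_left: float
    x_right: float
    index: float  # NaN when undefined (propagated as missing, never 0)


def split_hemispheres(net: ConnectivityMatrix, atlas: RegionAtlas) -> HemispherePair:
    """Induced left and right intra-hemispheric subnetworks, in atlas order.

    Inter-hemispheric entries are discarded. Hemisphere sizes must match.
    """
    if len(net.labels) != atlas.n_regions or tuple(net.labels) != tuple(atlas.labels):
        raise ValueError("network labels do not match atlas")
    li = atlas.left_indices
    ri = atlas.right_indices
    if li.size + ri.size != atlas.n_regions:
        raise ValueError("atlas contains regions without a hemisphere label")
    if li.size != ri.size:
        raise ValueError(
            f"unequal hemisphere sizes: {li.size} left vs {ri.size} right"
        )
    def induced(idx: np.ndarray, side: str) -> ConnectivityMatrix:
        return ConnectivityMatrix(
            subject_id=net.subject_id,
            modality=net.modality,
            weights=net.weights[np.ix_(idx, idx)],
            labels=tuple(net.labels[i] for i in idx),
            meta={**net.meta, "hemisphere": side},
        )
    return HemispherePair(left=induced(li, "L"), right=induced(ri, "R"))


def asymmetry_index(x_left: float, x_right: float) -> float:
    """(X_L - X_R) / (X_L + X_R); raises when the denominator is zero."""
    denom = x_left + x_right
    if denom == 0:
        raise UndefinedAsymmetryError("asymmetry undefined: X_L + X_R == 0")
    return (x_left - x_right) / denom


def metric_asymmetries(
    net: ConnectivityMatrix,
    atlas: RegionAtlas,
    sweep: bool = False,
    s_min: float = 0.1,
    s_max: float = 0.4,
    step: float = 0.01,
    clustering: Literal["onnela", "barrat"] = "onnela",
) -> dict[str, AsymmetryIndex]:
    """Asymmetry index for each global metric on one subject's network.

    With ``sweep=True`` (functional networks), each 45-node subnetwork is
    proportionally thresholded across the grid (K computed from its own
    edge budget) and the integrated metric values are compared; otherwise
    metrics are computed on the unthresholded subnetworks.
    """
    pair = split_hemispheres(net, atlas)
    if sweep:
        left = sweep_and_integrate(pair.left, s_min, s_max, step, clustering).integrated
        right = sweep_and_integrate(pair.right, s_min, s_max, step, clustering).integrated
    else:
        left = compute_global_metrics(pair.left, clustering=clustering).as_dict()
        right = compute_global_metrics(pair.right, clustering=clustering).as_dict()
    out: dict[str, AsymmetryIndex] = {}
    for name in GLOBAL_METRIC_NAMES:
        xl, xr = left[name], right[name]
        try:
            idx = asymmetry_index(xl, xr)
        except UndefinedAsymmetryError:
            idx = float("nan")
        out[name] = AsymmetryIndex(metric=name, x_left=xl, x_right=xr, index=idx)
    return out
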