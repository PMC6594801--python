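"""Region atlas: ordered node labels with hemisphere, DMN membership, and volume.

The atlas is the single source of truth for node ordering. All connectivity
matrices, time series, and reports index regions in atlas order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["RegionAtlas", "aal90", "AAL90_BASE_LABELS", "DMN_LABELS"]

# 45 cerebral parcel short codes per hemisphere, in standard template order.
AAL90_BASE_LABELS: tuple[str, ...] = (
    "PreCG", "SFGdor", "ORBsup", "MFG", "ORBmid", "IFGoperc", "IFGtriang",
    "ORBinf", "ROL", "SMA", "OLF", "SFGmed", "ORBsupmed", "REC", "INS",
    "ACG", "DCG", "PCG", "HIP", "PHG", "AMYG", "CAL", "CUN", "LING",
    "SOG", "MOG", "IOG", "FFG", "PoCG", "SPG", "IPL", "SMG", "ANG",
    "PCUN", "PCL", "CAU", "PUT", "PAL", "THA", "HES", "STG", "TPOsup",
    "MTG", "TPOmid", "ITG",
)

# The 14 default-mode-network parcels.
DMN_LABELS: frozenset[str] = frozenset({
    "SFGdor.L", "SFGdor.R", "SFGmed.L", "SFGmed.R", "ACG.L", "ACG.R",
    "PCG.L", "PCG.R", "PHG.L", "PHG.R", "ANG.L", "ANG.R", "MTG.R", "ITG.L",
})


@dataclass(frozen=True)
class RegionAtlas:
    """Ordered region specification.

    Parameters
    ----------
    labels : tuple of str
        Unique short codes, e.g. ``"SFGdor.L"``.
    hemispheres : tuple of str
        ``"L"`` or ``"R"`` per region.
    dmn : tuple of bool
        Default-mode-network membership flag per region.
    volumes : numpy.ndarray
        Positive region volumes (voxel count or mm^3).
    """

    labels: tuple[str, ...]
    hemispheres: tuple[str, ...]
    dmn: tuple[bool, ...]
    volumes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("atlas labels must be unique")
        if len(self.hemispheres) != n or len(self.dmn) != n:
            raise ValueError("atlas field lengths disagree")
        bad = sorted(set(self.hemispheres) - {"L", "R"})
        if bad:
            raise ValueError(f"invalid hemisphere codes: {bad}")
        vols = np.asarray(self.volumes, dtype=float)
        if vols.shape != (n,):
            raise ValueError("volumes must be a 1-D array matching labels")
        if not np.all(vols > 0):
            raise ValueError("all region volumes must be positive")
        object.__setattr__(self, "volumes", vols)

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    @property
    def left_indices(self) -> np.ndarray:
        return np.array([i for i, h in enumerate(self.hemispheres) if h == "L"])

    @property
    def right_indices(self) -> np.ndarray:
        return np.array([i for i, h in enumerate(self.hemispheres) if h == "R"])

    @property
    def dmn_indices(self) -> np.ndarray:
        return np.array([i for i, d in enumerate(self.dmn) if d])

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"region {label!r} not in atlas") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "label": self.labels,
            "hemisphere": self.hemispheres,
            "dmn": [int(d) for d in self.dmn],
            "volume": self.volumes,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RegionAtlas":
        required = {"label", "hemisphere", "dmn", "volume"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"atlas table missing columns: {sorted(missing)}")
        return cls(
            labels=tuple(df["label"].astype(str)),
            hemispheres=tuple(df["hemisphere"].astype(str)),
            dmn=tuple(bool(int(v)) for v in df["dmn"]),
            volumes=df["volume"].to_numpy(dtype=float),
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "RegionAtlas":
        return cls.from_frame(pd.read_csv(path))


def _default_volumes(n_per_hemisphere: int) -> np.ndarray:
    # Deterministic, heterogeneous, mirror-symmetric (same value for .L/.R).
    base = 2500.0 + 175.0 * ((7 * np.arange(n_per_hemisphere)) % 45)
    return np.repeat(base, 2)


def aal90(n_regions: int = 90) -> RegionAtlas:
    """Build the 90-parcel cerebral atlas (or a leading even-sized subset).

    Regions are interleaved ``.L``/``.R`` in template order, 45 per
    hemisphere at full size. ``n_regions`` must be even; a smaller value
    keeps the first ``n_regions // 2`` parcels of each hemisphere (useful
    for fast synthetic fixtures).
    """
    if n_regions % 2 != 0 or not 2 <= n_regions <= 90:
        raise ValueError("n_regions must be an even number in [2, 90]")
    n_half = n_regions // 2
    labels: list[str] = []
    hemis: list[str] = []
    for base in AAL90_BASE_LABELS[:n_half]:
        labels.extend([f"{base}.L", f"{base}.R"])
        hemis.extend(["L", "R"])
    dmn = tuple(lab in DMN_LABELS for lab in labels)
    return RegionAtlas(
        labels=tuple(labels),
        hemispheres=tuple(hemis),
        dmn=dmn,
        volumes=_default_volumes(n_half),
    )
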