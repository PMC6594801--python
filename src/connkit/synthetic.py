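"""Synthetic connectome cohorts with known planted group effects.

Functional time series come from a latent-factor construction: every
region loads sqrt(base_correlation) on a shared factor, and DMN regions in
the tea group additionally load sqrt(dmn_effect) on a DMN factor, so the
implied DMN-pair population correlation is exactly base + effect (before
measurement-noise attenuation) and positive definiteness is guaranteed
whenever base + effect < 1.

Structural streamline counts are Poisson draws around a mirror-symmetric
distance-decay template (index distance within hemisphere as a proxy for
spatial distance). The tea group's template is scaled by
(1 + sc_global_effect); the non-tea group's left-intra-hemispheric
long-range entries are scaled by (1 + asym_effect), planting leftward
asymmetry in clustering and efficiency. A uniform left scaling would be
invisible to the max-normalized clustering coefficient, hence the
long-range restriction.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import RegionAtlas, aal90
from .cohort import NEUROPSYCH_COLUMNS
from .networks import ROITimeSeries, StreamlineCounts

__all__ = [
    "SyntheticCohortConfig",
    "GroundTruth",
    "SyntheticCohort",
    "generate_cohort",
    "generate_null_cohort",
    "write_cohort",
]

# template constants for the structural distance-decay model
_SC_SCALE = 60.0
_SC_DECAY = 10.0
_SC_INTER_FACTOR = 0.3
_ASYM_MIN_LABEL_DISTANCE = 6  # asym boost applies to left pairs at least this far apart


@dataclass(frozen=True)
class SyntheticCohortConfig:
    n_tea: int = 15
    n_nontea: int = 21
    n_regions: int = 90
    n_timepoints: int = 200
    base_correlation: float = 0.1
    dmn_effect: float = 0.0
    sc_global_effect: float = 0.0
    asym_effect: float = 0.0
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tea < 2 or self.n_nontea < 2:
            raise ValueError("group sizes must be at least 2")
        if self.n_regions % 2 != 0:
            raise ValueError("n_regions must be even")
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be at least 2")
        if not 0 < self.base_correlation < 1:
            raise ValueError("base_correlation must be in (0, 1)")
        if self.dmn_effect < 0 or not np.isfinite(self.dmn_effect):
            raise ValueError("dmn_effect must be finite and nonnegative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.base_correlation + self.dmn_effect >= 1:
            raise ValueError(
                "implied correlation matrix not positive definite: "
                "base_correlation + dmn_effect must be < 1; use smaller effects"
            )


@dataclass(frozen=True)
class GroundTruth:
    """Planted effects and the regions/edges they touch."""

    dmn_regions: tuple[str, ...]
    dmn_edges: tuple[tuple[str, str], ...]
    implied_base_correlation: float
    implied_dmn_correlation_delta: float  # group T minus NT, after attenuation
    sc_global_effect: float
    sc_effect_group: str
    asym_effect: float
    asym_target_group: str
    asym_boosted_pairs: tuple[tuple[str, str], ...]


@dataclass(frozen=True)
class SyntheticCohort:
    config: SyntheticCohortConfig
    atlas: RegionAtlas
    cohort_table: pd.DataFrame = field(repr=False)
    timeseries: tuple[ROITimeSeries, ...] = field(repr=False)
    streamlines: tuple[StreamlineCounts, ...] = field(repr=False)
    ground_truth: GroundTruth


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    # independent substream per pipeline stage, derived from one master seed
    return np.random.default_rng([seed, zlib.crc32(stage.encode())])


def _structural_template(atlas: RegionAtlas) -> np.ndarray:
    n = atlas.n_regions
    hemi = np.array(atlas.hemispheres)
    # label index within hemisphere (mirror pairs share an index)
    label_idx = np.empty(n, dtype=int)
    label_idx[atlas.left_indices] = np.arange(atlas.left_indices.size)
    label_idx[atlas.right_indices] = np.arange(atlas.right_indices.size)
    dist = np.abs(label_idx[:, None] - label_idx[None, :])
    mu = _SC_SCALE * np.exp(-dist / _SC_DECAY)
    inter = hemi[:, None] != hemi[None, :]
    mu[inter] *= _SC_INTER_FACTOR
    np.fill_diagonal(mu, 0.0)
    return mu


def _left_longrange_mask(atlas: RegionAtlas) -> np.ndarray:
    n = atlas.n_regions
    label_idx = np.empty(n, dtype=int)
    label_idx[atlas.left_indices] = np.arange(atlas.left_indices.size)
    label_idx[atlas.right_indices] = np.arange(atlas.right_indices.size)
    hemi = np.array(atlas.hemispheres)
    left = hemi == "L"
    mask = left[:, None] & left[None, :]
    dist = np.abs(label_idx[:, None] - label_idx[None, :])
    return mask & (dist >= _ASYM_MIN_LABEL_DISTANCE)


def _sample_timeseries(
    rng: np.random.Generator,
    cfg: SyntheticCohortConfig,
    dmn_mask: np.ndarray,
    in_tea_group: bool,
) -> np.ndarray:
    t, n = cfg.n_timepoints, cfg.n_regions
    c = cfg.base_correlation
    d = cfg.dmn_effect if in_tea_group else 0.0
    load_dmn = np.where(dmn_mask, np.sqrt(d), 0.0)
    resid_var = 1.0 - c - np.where(dmn_mask, d, 0.0)
    g = rng.standard_normal((t, 1))
    f = rng.standard_normal((t, 1))
    e = rng.standard_normal((t, n))
    x = np.sqrt(c) * g + load_dmn * f + np.sqrt(resid_var) * e
    return x + cfg.noise_sd * rng.standard_normal((t, n))


def _sample_demographics(
    rng: np.random.Generator, subject_ids: list[str], groups: list[str]
) -> pd.DataFrame:
    rows = []
    for sid, grp in zip(subject_ids, groups):
        tea = grp == "T"
        age = float(np.clip(rng.normal(70.27 if tea else 71.71, 5.52 if tea else 3.98), 55, 90))
        edu = float(np.clip(rng.normal(6.00 if tea else 4.81, 3.96 if tea else 3.50), 0, 20))
        sex = "male" if rng.random() < (4 / 15 if tea else 2 / 21) else "female"
        hand = "left" if rng.random() < (0.02 if tea else 1 / 21) else "right"
        if tea:
            while True:
                scales = rng.integers(2, 6, size=6)  # six tea scales in [2, 5]
                if (scales[:3].sum() + scales[3:].sum()) / 2 >= 8:
                    break
        else:
            scales = np.ones(6, dtype=int)
        coffee = rng.integers(1, 7, size=2)
        scores = {name: float(rng.normal(50, 10)) for name in NEUROPSYCH_COLUMNS}
        rows.append({
            "subject_id": sid, "age": round(age, 1), "education_years": round(edu, 1),
            "sex": sex, "handedness": hand,
            "green_45": int(scales[0]), "oolong_45": int(scales[1]), "black_45": int(scales[2]),
            "green_now": int(scales[3]), "oolong_now": int(scales[4]), "black_now": int(scales[5]),
            "coffee_45": int(coffee[0]), "coffee_now": int(coffee[1]),
            **scores,
        })
    return pd.DataFrame(rows)


def generate_cohort(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Generate a complete cohort with the configured planted effects.

    All randomness derives from ``config.seed``; identical configs yield
    byte-identical outputs.
    """
    atlas = aal90(config.n_regions)
    n_total = config.n_tea + config.n_nontea
    subject_ids = [f"S{i + 1:03d}" for i in range(n_total)]
    groups = ["T"] * config.n_tea + ["NT"] * config.n_nontea
    dmn_mask = np.array(atlas.dmn, dtype=bool)

    rng_demo = _stage_rng(config.seed, "demographics")
    table = _sample_demographics(rng_demo, subject_ids, groups)

    rng_ts = _stage_rng(config.seed, "timeseries")
    timeseries = tuple(
        ROITimeSeries(
            subject_id=sid,
            data=_sample_timeseries(rng_ts, config, dmn_mask, grp == "T"),
            labels=tuple(atlas.labels),
        )
        for sid, grp in zip(subject_ids, groups)
    )

    template = _structural_template(atlas)
    asym_mask = _left_longrange_mask(atlas)
    rng_sc = _stage_rng(config.seed, "structural")
    streamlines = []
    for sid, grp in zip(subject_ids, groups):
        mu = template.copy()
        if grp == "T":
            mu *= 1.0 + config.sc_global_effect
        else:
            mu[asym_mask] *= 1.0 + config.asym_effect
        n = mu.shape[0]
        iu = np.triu_indices(n, k=1)
        counts = np.zeros((n, n), dtype=np.int64)
        counts[iu] = rng_sc.poisson(np.maximum(mu[iu], 0.0))
        streamlines.append(
            StreamlineCounts(subject_id=sid, counts=counts + counts.T, labels=tuple(atlas.labels))
        )

    atten = 1.0 / (1.0 + config.noise_sd**2)
    dmn_labels = tuple(atlas.labels[i] for i in atlas.dmn_indices)
    dmn_edges = tuple(
        (dmn_labels[i], dmn_labels[j])
        for i in range(len(dmn_labels)) for j in range(i + 1, len(dmn_labels))
    )
    li = np.array(atlas.labels)
    boosted = tuple(
        (str(li[i]), str(li[j]))
        for i, j in zip(*np.where(np.triu(asym_mask, k=1)))
    )
    truth = GroundTruth(
        dmn_regions=dmn_labels,
        dmn_edges=dmn_edges,
        implied_base_correlation=config.base_correlation * atten,
        implied_dmn_correlation_delta=config.dmn_effect * atten,
        sc_global_effect=config.sc_global_effect,
        sc_effect_group="T",
        asym_effect=config.asym_effect,
        asym_target_group="NT",
        asym_boosted_pairs=boosted,
    )
    return SyntheticCohort(
        config=config,
        atlas=atlas,
        cohort_table=table,
        timeseries=timeseries,
        streamlines=tuple(streamlines),
        ground_truth=truth,
    )


def generate_null_cohort(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Cohort with every planted effect forced to zero (calibration runs)."""
    return generate_cohort(
        replace(config, dmn_effect=0.0, sc_global_effect=0.0, asym_effect=0.0)
    )


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> dict:
    """Write all cohort files in pipeline-consumable plain-text formats.

    Layout: ``atlas.csv``, ``cohort.csv``, ``timeseries/<id>.tsv``,
    ``streamlines/<id>.tsv``, and ``manifest.json`` recording the config,
    ground truth, and file list. Returns the manifest dict.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "timeseries").mkdir(exist_ok=True)
    (directory / "streamlines").mkdir(exist_ok=True)

    cohort.atlas.to_csv(directory / "atlas.csv")
    cohort.cohort_table.to_csv(directory / "cohort.csv", index=False)
    files = ["atlas.csv", "cohort.csv"]
    for ts in cohort.timeseries:
        rel = f"timeseries/{ts.subject_id}.tsv"
        pd.DataFrame(ts.data, columns=list(ts.labels)).to_csv(
            directory / rel, sep="\t", index=False
        )
        files.append(rel)
    for sc in cohort.streamlines:
        rel = f"streamlines/{sc.subject_id}.tsv"
        pd.DataFrame(sc.counts, index=list(sc.labels), columns=list(sc.labels)).to_csv(
            directory / rel, sep="\t"
        )
        files.append(rel)

    truth = asdict(cohort.ground_truth)
    truth["dmn_edges"] = [list(e) for e in truth["dmn_edges"]]
    truth["asym_boosted_pairs"] = [list(e) for e in truth["asym_boosted_pairs"]]
    truth["dmn_regions"] = list(truth["dmn_regions"])
    manifest = {
        "config": asdict(cohort.config),
        "ground_truth": truth,
        "files": files,
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
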