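"""End-to-end orchestration: screening, network construction, metric sweeps,
asymmetry, and group comparisons, driven by a single config.

All computation happens before any report file is written, so a failed run
leaves no partial report bundle. A single master seed drives every
stochastic stage through named substreams.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .asymmetry import metric_asymmetries
from .atlas import RegionAtlas
from .cohort import (
    NEUROPSYCH_COLUMNS,
    chi_square_2x2,
    read_cohort_table,
    screen_cohort,
    two_sample_t_summary,
)
from .metrics import GLOBAL_METRIC_NAMES, compute_global_metrics, sweep_and_integrate
from .networks import (
    build_functional_network,
    build_structural_network,
    read_streamlines,
    read_timeseries,
)
from .stats import (
    compare_asymmetry,
    compare_dmn_edges,
    compare_global_metrics,
    compare_nodal_efficiency,
    permutation_test_family,
    results_to_frame,
)

__all__ = ["RunConfig", "run_pipeline", "validate_inputs"]


@dataclass(frozen=True)
class RunConfig:
    cohort_table: str
    timeseries_dir: str
    streamlines_dir: str
    atlas: str
    output_dir: str
    s_min: float = 0.1
    s_max: float = 0.4
    step: float = 0.01
    negative_policy: str = "zero"
    threshold_structural: bool = False
    clustering: str = "onnela"
    n_perm: int = 10_000
    seed: int = 0
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _stage_seed(seed: int, stage: str) -> int:
    return int(np.random.SeedSequence([seed, zlib.crc32(stage.encode())]).generate_state(1)[0])


def validate_inputs(config: RunConfig) -> list[str]:
    """Non-destructive input check; returns a list of problem descriptions."""
    problems: list[str] = []
    for name in ("cohort_table", "atlas"):
        if not Path(getattr(config, name)).is_file():
            problems.append(f"{name} file not found: {getattr(config, name)}")
    for name in ("timeseries_dir", "streamlines_dir"):
        if not Path(getattr(config, name)).is_dir():
            problems.append(f"{name} not found: {getattr(config, name)}")
    if problems:
        return problems
    try:
        atlas = RegionAtlas.from_csv(config.atlas)
    except Exception as exc:  # noqa: BLE001 - collect, don't raise
        return problems + [f"atlas unreadable: {exc}"]
    try:
        table = read_cohort_table(config.cohort_table)
    except Exception as exc:  # noqa: BLE001
        return problems + [f"cohort table unreadable: {exc}"]
    for sid in table["subject_id"].astype(str):
        ts_path = Path(config.timeseries_dir) / f"{sid}.tsv"
        sc_path = Path(config.streamlines_dir) / f"{sid}.tsv"
        if not ts_path.is_file():
            problems.append(f"missing time series for subject {sid}")
            continue
        if not sc_path.is_file():
            problems.append(f"missing streamline matrix for subject {sid}")
            continue
        try:
            read_timeseries(ts_path, atlas, subject_id=sid)
        except Exception as exc:  # noqa: BLE001
            problems.append(f"subject {sid} time series invalid: {exc}")
        try:
            read_streamlines(sc_path, atlas, subject_id=sid)
        except Exception as exc:  # noqa: BLE001
            problems.append(f"subject {sid} streamline matrix invalid: {exc}")
    return problems


def _demographics_report(screened: pd.DataFrame) -> pd.DataFrame:
    t_rows = []
    tea = screened[screened["group"] == "T"]
    non = screened[screened["group"] == "NT"]
    for col in ("age", "education_years"):
        res = two_sample_t_summary(
            tea[col].mean(), tea[col].std(ddof=1), len(tea),
            non[col].mean(), non[col].std(ddof=1), len(non),
        )
        t_rows.append({"variable": col, "test": "t", "statistic": res.t, "df": res.df})
    coffee = (screened["coffee_45"] + screened["coffee_now"]) / 2.0
    res = two_sample_t_summary(
        coffee[screened["group"] == "T"].mean(), coffee[screened["group"] == "T"].std(ddof=1), len(tea),
        coffee[screened["group"] == "NT"].mean(), coffee[screened["group"] == "NT"].std(ddof=1), len(non),
    )
    t_rows.append({"variable": "coffee", "test": "t", "statistic": res.t, "df": res.df})
    for col, positive in (("sex", "male"), ("handedness", "left")):
        a = int((tea[col] == positive).sum())
        b = len(tea) - a
        c = int((non[col] == positive).sum())
        d = len(non) - c
        try:
            chi = chi_square_2x2(a, b, c, d)
            t_rows.append({"variable": col, "test": "chi2", "statistic": chi.chi2, "df": chi.df})
        except ValueError:
            t_rows.append({"variable": col, "test": "chi2", "statistic": np.nan, "df": 1})
    return pd.DataFrame(t_rows)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full analysis; returns a map of report name -> written path."""
    atlas = RegionAtlas.from_csv(config.atlas)
    table = read_cohort_table(config.cohort_table)
    screened = screen_cohort(table)
    analysed = screened[screened["group"].isin(["T", "NT"])].reset_index(drop=True)
    for grp in ("T", "NT"):
        if (analysed["group"] == grp).sum() < 2:
            raise ValueError(f"group {grp} has fewer than 2 subjects after screening")
    groups = analysed["group"].tolist()
    subject_ids = analysed["subject_id"].astype(str).tolist()

    missing = [
        sid for sid in subject_ids
        if not (Path(config.timeseries_dir) / f"{sid}.tsv").is_file()
        or not (Path(config.streamlines_dir) / f"{sid}.tsv").is_file()
    ]
    if missing:
        raise FileNotFoundError(f"missing input files for subjects: {missing}")

    # --- networks ---------------------------------------------------------
    fc_nets = []
    sc_nets = []
    for sid in subject_ids:
        ts = read_timeseries(Path(config.timeseries_dir) / f"{sid}.tsv", atlas, subject_id=sid)
        fc_nets.append(build_functional_network(ts, negative_policy=config.negative_policy))
        counts = read_streamlines(Path(config.streamlines_dir) / f"{sid}.tsv", atlas, subject_id=sid)
        sc_nets.append(build_structural_network(counts, atlas))

    # --- metrics ----------------------------------------------------------
    sweep_kw = dict(s_min=config.s_min, s_max=config.s_max, step=config.step,
                    clustering=config.clustering)
    metric_rows = []
    fc_global = {name: [] for name in GLOBAL_METRIC_NAMES}
    fc_nodal = []
    for net in fc_nets:
        sw = sweep_and_integrate(net, **sweep_kw)
        for name in GLOBAL_METRIC_NAMES:
            fc_global[name].append(sw.integrated[name])
            metric_rows.append({
                "subject": net.subject_id, "modality": "functional",
                "metric": name, "sparsity": "integrated", "value": sw.integrated[name],
            })
        fc_nodal.append(sw.nodal_integrated)

    sc_global = {name: [] for name in GLOBAL_METRIC_NAMES}
    sc_nodal = []
    for net in sc_nets:
        if config.threshold_structural:
            sw = sweep_and_integrate(net, **sweep_kw)
            vals = sw.integrated
            nodal = sw.nodal_integrated
        else:
            m = compute_global_metrics(net, clustering=config.clustering)
            vals = m.as_dict()
            nodal = m.nodal
        for name in GLOBAL_METRIC_NAMES:
            sc_global[name].append(vals[name])
            metric_rows.append({
                "subject": net.subject_id, "modality": "structural",
                "metric": name,
                "sparsity": "integrated" if config.threshold_structural else "unthresholded",
                "value": vals[name],
            })
        sc_nodal.append(nodal)

    # --- asymmetry --------------------------------------------------------
    asym_rows = []
    asym_values = {"functional": {n: [] for n in GLOBAL_METRIC_NAMES},
                   "structural": {n: [] for n in GLOBAL_METRIC_NAMES}}
    for modality, nets, sweep in (
        ("functional", fc_nets, True),
        ("structural", sc_nets, config.threshold_structural),
    ):
        for net in nets:
            idxs = metric_asymmetries(
                net, atlas, sweep=sweep,
                s_min=config.s_min, s_max=config.s_max, step=config.step,
                clustering=config.clustering,
            )
            for name, ai in idxs.items():
                asym_values[modality][name].append(ai.index)
                asym_rows.append({
                    "subject": net.subject_id, "modality": modality, "metric": name,
                    "x_left": ai.x_left, "x_right": ai.x_right, "index": ai.index,
                })

    # --- group statistics -------------------------------------------------
    reports: dict[str, pd.DataFrame] = {}
    reports["demographics"] = _demographics_report(analysed)

    neuro = analysed[list(NEUROPSYCH_COLUMNS)].to_numpy(dtype=float).T
    neuro_res = permutation_test_family(
        neuro, names=list(NEUROPSYCH_COLUMNS),
        group_a_mask=np.array(groups) == "T",
        n_perm=config.n_perm, seed=_stage_seed(config.seed, "neuropsych"), fdr=True,
    )
    reports["neuropsych"] = results_to_frame(neuro_res)

    for modality, glob_vals, nodal_vals in (
        ("functional", fc_global, fc_nodal),
        ("structural", sc_global, sc_nodal),
    ):
        df = pd.DataFrame(glob_vals)
        res = compare_global_metrics(
            df, groups, n_perm=config.n_perm,
            seed=_stage_seed(config.seed, f"global_{modality}"),
        )
        reports[f"compare_global_{modality}"] = results_to_frame(res)

        res = compare_nodal_efficiency(
            np.vstack(nodal_vals), atlas.labels, groups,
            n_perm=config.n_perm, seed=_stage_seed(config.seed, f"nodal_{modality}"),
        )
        reports[f"compare_nodal_{modality}"] = results_to_frame(res)

        adf = pd.DataFrame(asym_values[modality])
        res = compare_asymmetry(
            adf, groups, n_perm=config.n_perm,
            seed=_stage_seed(config.seed, f"asym_{modality}"),
        )
        reports[f"compare_asymmetry_{modality}"] = results_to_frame(res)

        nets = fc_nets if modality == "functional" else sc_nets
        edges = compare_dmn_edges(
            nets, groups, atlas, n_perm=config.n_perm,
            seed=_stage_seed(config.seed, f"dmn_{modality}"), alpha=config.alpha,
        )
        reports[f"dmn_edges_{modality}"] = pd.DataFrame({
            "region_a": [e.region_a for e in edges],
            "region_b": [e.region_b for e in edges],
            "observed_diff": [e.observed_diff for e in edges],
            "p": [e.p for e in edges],
            "significant": [e.significant for e in edges],
        })

    reports["metrics"] = pd.DataFrame(metric_rows)
    reports["asymmetry"] = pd.DataFrame(asym_rows)
    reports["screening"] = analysed[["subject_id", "composite_score", "group"]]

    # --- write everything only after all computation succeeded ------------
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, df in reports.items():
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        written[name] = path
    log = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "version": __version__,
        "n_subjects": len(subject_ids),
        "groups": {g: groups.count(g) for g in ("T", "NT")},
    }
    log_path = out / "run_log.json"
    with open(log_path, "w") as fh:
        json.dump(log, fh, indent=2)
    written["run_log"] = log_path
    return written
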