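"""Permutation-based group inference with Benjamini-Hochberg FDR control.

The test statistic is the difference of group means (a pooled t is
available as an alternative). Two-sided p-values follow the exact-test
convention p = (1 + #{|stat*| >= |stat|}) / (1 + n_perm) when sampling;
when the number of distinct label assignments is at most n_perm the full
assignment space is enumerated instead.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .atlas import RegionAtlas
from .networks import ConnectivityMatrix

__all__ = [
    "PermutationResult",
    "EdgeComparison",
    "permutation_test",
    "permutation_test_family",
    "bh_fdr",
    "compare_global_metrics",
    "compare_nodal_efficiency",
    "compare_asymmetry",
    "compare_dmn_edges",
    "results_to_frame",
]

_TIE_EPS = 1e-12


@dataclass(frozen=True)
class PermutationResult:
    name: str
    observed_diff: float  # group A minus group B (tea minus non-tea)
    p: float
    n_perm: int
    seed: int
    q: float | None = None       # BH-adjusted, set for corrected families
    exhaustive: bool = False
    exploratory: bool = False
    n_used: int | None = None    # subjects actually used (after drops)


@dataclass(frozen=True)
class EdgeComparison:
    region_a: str
    region_b: str
    observed_diff: float
    p: float
    significant: bool


def _null_mean_diffs(
    pooled: np.ndarray, n_a: int, n_perm: int, seed: int, force_sampling: bool
) -> tuple[np.ndarray, bool]:
    """Null mean-difference distribution; returns (diffs, exhaustive)."""
    n = pooled.shape[-1]
    total = math.comb(n, n_a)
    if total <= n_perm and not force_sampling:
        idx = np.array(list(combinations(range(n), n_a)))
        a_mean = pooled[..., idx].mean(axis=-1)  # (..., total)
        exhaustive = True
    else:
        rng = np.random.default_rng(seed)
        perm = np.tile(np.arange(n), (n_perm, 1))
        perm = rng.permuted(perm, axis=1)
        a_mean = pooled[..., perm[:, :n_a]].mean(axis=-1)
        exhaustive = False
    tot_sum = pooled.sum(axis=-1)
    n_b = n - n_a
    b_mean = (tot_sum[..., None] - a_mean * n_a) / n_b
    return a_mean - b_mean, exhaustive


def _p_from_null(observed: np.ndarray, null: np.ndarray, exhaustive: bool) -> np.ndarray:
    hits = (np.abs(null) >= np.abs(observed)[..., None] - _TIE_EPS).sum(axis=-1)
    if exhaustive:
        return hits / null.shape[-1]  # includes the observed assignment
    return (1 + hits) / (1 + null.shape[-1])


def permutation_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    n_perm: int = 10_000,
    seed: int = 0,
    statistic: Literal["mean_diff", "t"] = "mean_diff",
    force_sampling: bool = False,
    name: str = "",
) -> PermutationResult:
    """Two-sided label-permutation test on two groups of scalars."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 subjects")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite values in input")
    pooled = np.concatenate([a, b])
    n_a, n_b = a.size, b.size
    if statistic == "mean_diff":
        observed = a.mean() - b.mean()
        null, exhaustive = _null_mean_diffs(pooled, n_a, n_perm, seed, force_sampling)
    elif statistic == "t":
        observed = _pooled_t(a, b)
        null, exhaustive = _null_t(pooled, n_a, n_perm, seed, force_sampling)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    p = float(_p_from_null(np.asarray(observed), null, exhaustive))
    n_used = null.shape[-1] if exhaustive else n_perm
    return PermutationResult(
        name=name,
        observed_diff=float(a.mean() - b.mean()),
        p=p,
        n_perm=n_used,
        seed=seed,
        exhaustive=exhaustive,
        n_used=n_a + n_b,
    )


def _pooled_t(a: np.ndarray, b: np.ndarray) -> float:
    n_a, n_b = a.size, b.size
    sp2 = ((n_a - 1) * a.var(ddof=1) + (n_b - 1) * b.var(ddof=1)) / (n_a + n_b - 2)
    se = math.sqrt(sp2 * (1 / n_a + 1 / n_b))
    return (a.mean() - b.mean()) / se if se > 0 else 0.0


def _null_t(
    pooled: np.ndarray, n_a: int, n_perm: int, seed: int, force_sampling: bool
) -> tuple[np.ndarray, bool]:
    n = pooled.size
    total = math.comb(n, n_a)
    if total <= n_perm and not force_sampling:
        idx_iter = np.array(list(combinations(range(n), n_a)))
        exhaustive = True
    else:
        rng = np.random.default_rng(seed)
        perm = np.tile(np.arange(n), (n_perm, 1))
        idx_iter = rng.permuted(perm, axis=1)[:, :n_a]
        exhaustive = False
    mask = np.zeros((idx_iter.shape[0], n), dtype=bool)
    np.put_along_axis(mask, idx_iter, True, axis=1)
    out = np.empty(idx_iter.shape[0])
    for i, m in enumerate(mask):
        out[i] = _pooled_t(pooled[m], pooled[~m])
    return out, exhaustive


def permutation_test_family(
    values: np.ndarray,
    names: Sequence[str],
    group_a_mask: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
    fdr: bool = True,
    exploratory: bool = False,
    force_sampling: bool = False,
) -> list[PermutationResult]:
    """Permutation tests for a family of variables sharing one label shuffle.

    ``values`` is (n_variables, n_subjects); ``group_a_mask`` marks group A
    subjects. All variables are tested against the same permutation stream,
    which keeps the family reproducible from a single seed. When ``fdr`` is
    true the BH q-values across the family are attached.
    """
    values = np.asarray(values, dtype=float)
    mask = np.asarray(group_a_mask, dtype=bool)
    if values.ndim != 2 or values.shape[1] != mask.size:
        raise ValueError("values must be (n_variables, n_subjects)")
    if len(names) != values.shape[0]:
        raise ValueError("names length disagrees with values")
    n_a = int(mask.sum())
    n_b = int((~mask).sum())
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs at least 2 subjects")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite values in input")
    # reorder: group A first, so pooled[..., :n_a] is group A
    order = np.concatenate([np.flatnonzero(mask), np.flatnonzero(~mask)])
    pooled = values[:, order]
    observed = pooled[:, :n_a].mean(axis=1) - pooled[:, n_a:].mean(axis=1)
    null, exhaustive = _null_mean_diffs(pooled, n_a, n_perm, seed, force_sampling)
    p = _p_from_null(observed, null, exhaustive)
    q = bh_fdr(p) if fdr else None
    n_eff = null.shape[-1] if exhaustive else n_perm
    return [
        PermutationResult(
            name=str(names[i]),
            observed_diff=float(observed[i]),
            p=float(p[i]),
            n_perm=n_eff,
            seed=seed,
            q=(float(q[i]) if q is not None else None),
            exhaustive=exhaustive,
            exploratory=exploratory,
            n_used=n_a + n_b,
        )
        for i in range(values.shape[0])
    ]


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j on the ascending sort, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# Cohort-level comparison fronts


def _group_mask(groups: Sequence[str]) -> np.ndarray:
    arr = np.asarray(groups)
    bad = sorted(set(arr) - {"T", "NT"})
    if bad:
        raise ValueError(f"unexpected group labels: {bad}")
    return arr == "T"


def compare_global_metrics(
    metric_values: pd.DataFrame,
    groups: Sequence[str],
    n_perm: int = 10_000,
    seed: int = 0,
) -> list[PermutationResult]:
    """One corrected test per global metric (BH family = the columns given).

    ``metric_values``: subjects x metrics (typically the four integrated
    global metrics of one modality).
    """
    mask = _group_mask(groups)
    if metric_values.isna().any().any():
        raise ValueError("missing metric values; compute metrics for every subject")
    return permutation_test_family(
        metric_values.to_numpy(dtype=float).T,
        names=list(metric_values.columns),
        group_a_mask=mask,
        n_perm=n_perm,
        seed=seed,
        fdr=True,
    )


def compare_nodal_efficiency(
    nodal_values: np.ndarray,
    region_labels: Sequence[str],
    groups: Sequence[str],
    n_perm: int = 10_000,
    seed: int = 0,
) -> list[PermutationResult]:
    """Uncorrected exploratory test per region.

    ``nodal_values``: subjects x regions. No FDR is applied; results carry
    an exploratory flag and are conventionally reported at p < 0.01.
    """
    mask = _group_mask(groups)
    vals = np.asarray(nodal_values, dtype=float)
    if vals.shape != (mask.size, len(region_labels)):
        raise ValueError("nodal_values must be (n_subjects, n_regions)")
    return permutation_test_family(
        vals.T, names=list(region_labels), group_a_mask=mask,
        n_perm=n_perm, seed=seed, fdr=False, exploratory=True,
    )


def compare_asymmetry(
    index_values: pd.DataFrame,
    groups: Sequence[str],
    n_perm: int = 10_000,
    seed: int = 0,
) -> list[PermutationResult]:
    """One corrected test per metric's asymmetry index (BH family = columns).

    Subjects with an undefined (NaN) index are dropped from that metric
    with a warning; p-values for different metrics may therefore use
    different subject counts.
    """
    mask = _group_mask(groups)
    results: list[PermutationResult] = []
    per_metric: list[PermutationResult] = []
    for col in index_values.columns:
        v = index_values[col].to_numpy(dtype=float)
        keep = np.isfinite(v)
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} subject(s) with undefined "
                f"asymmetry for metric {col}",
                stacklevel=2,
            )
        res = permutation_test_family(
            v[keep][None, :], names=[col], group_a_mask=mask[keep],
            n_perm=n_perm, seed=seed, fdr=False,
        )[0]
        per_metric.append(res)
    qs = bh_fdr([r.p for r in per_metric])
    for r, qv in zip(per_metric, qs):
        results.append(PermutationResult(
            name=r.name, observed_diff=r.observed_diff, p=r.p,
            n_perm=r.n_perm, seed=r.seed, q=float(qv),
            exhaustive=r.exhaustive, n_used=r.n_used,
        ))
    return results


def compare_dmn_edges(
    networks: Sequence[ConnectivityMatrix],
    groups: Sequence[str],
    atlas: RegionAtlas,
    n_perm: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> list[EdgeComparison]:
    """Edge-wise comparison of raw (unthresholded) DMN connectivity strength.

    Tests every unordered pair of DMN regions (91 for the 14-region set) at
    uncorrected ``alpha``; exploratory by design.
    """
    dmn_idx = atlas.dmn_indices
    if dmn_idx.size < 2:
        raise ValueError("atlas flags fewer than 2 DMN regions")
    mask = _group_mask(groups)
    if len(networks) != mask.size:
        raise ValueError("one network per subject required")
    pairs = [(i, j) for k, i in enumerate(dmn_idx) for j in dmn_idx[k + 1:]]
    values = np.array([
        [net.weights[i, j] for (i, j) in pairs] for net in networks
    ])  # subjects x edges
    names = [f"{atlas.labels[i]}--{atlas.labels[j]}" for (i, j) in pairs]
    results = permutation_test_family(
        values.T, names=names, group_a_mask=mask,
        n_perm=n_perm, seed=seed, fdr=False, exploratory=True,
    )
    return [
        EdgeComparison(
            region_a=atlas.labels[i],
            region_b=atlas.labels[j],
            observed_diff=r.observed_diff,
            p=r.p,
            significant=r.p < alpha,
        )
        for (i, j), r in zip(pairs, results)
    ]


def results_to_frame(results: Sequence[PermutationResult]) -> pd.DataFrame:
    """Tidy results table: variable, observed_diff, p, q, n_perm, seed."""
    return pd.DataFrame({
        "variable": [r.name for r in results],
        "observed_diff": [r.observed_diff for r in results],
        "p": [r.p for r in results],
        "q": [r.q if r.q is not None else np.nan for r in results],
        "n_perm": [r.n_perm for r in results],
        "seed": [r.seed for r in results],
        "exploratory": [r.exploratory for r in results],
    })
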