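"""Cohort screening: tea-frequency composite score, group assignment, and
classical demographic comparison statistics.

The composite score sums the three tea-frequency scales (1-6 each) at two
recall ages and averages the two sums. Coffee frequency is recorded but
never enters the score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import pandas as pd

__all__ = [
    "FrequencyRecord",
    "composite_tea_score",
    "assign_group",
    "two_sample_t_summary",
    "chi_square_2x2",
    "read_cohort_table",
    "screen_cohort",
    "NEUROPSYCH_COLUMNS",
]

TEA_FIELDS_45 = ("green_45", "oolong_45", "black_45")
TEA_FIELDS_NOW = ("green_now", "oolong_now", "black_now")
SCALE_FIELDS = TEA_FIELDS_45 + TEA_FIELDS_NOW + ("coffee_45", "coffee_now")

#: Names of the neuropsychological score columns carried through screening.
NEUROPSYCH_COLUMNS = (
    "RAVLT_ir", "RAVLT_dr", "DigitSpan_fwd", "DigitSpan_bwd",
    "SDMT_written", "SDMT_oral", "BostonNaming", "BlockDesign",
    "CTT1", "CTT2", "MMSE", "MoCA",
)


@dataclass(frozen=True)
class FrequencyRecord:
    """Per-subject drinking-frequency questionnaire (categorical 1-6 scales)."""

    subject_id: str
    green_45: int
    oolong_45: int
    black_45: int
    green_now: int
    oolong_now: int
    black_now: int
    coffee_45: int
    coffee_now: int

    def __post_init__(self) -> None:
        for name in SCALE_FIELDS:
            value = getattr(self, name)
            if value is None or (isinstance(value, float) and math.isnan(value)):
                raise ValueError(f"frequency scale {name!r} is missing")
            if not float(value).is_integer() or not 1 <= int(value) <= 6:
                raise ValueError(
                    f"frequency scale {name!r} must be an integer in [1, 6], got {value!r}"
                )
            object.__setattr__(self, name, int(value))


def composite_tea_score(record: FrequencyRecord) -> float:
    """Sum the three tea scales per recall age, then average the two sums.

    Range is [3, 18]; coffee scales do not contribute.
    """
    sum_45 = sum(getattr(record, f) for f in TEA_FIELDS_45)
    sum_now = sum(getattr(record, f) for f in TEA_FIELDS_NOW)
    return (sum_45 + sum_now) / 2.0


def assign_group(score: float) -> str:
    """Map a composite score to ``"T"``, ``"NT"``, or ``"excluded"``.

    ``"T"`` at score >= 8, ``"NT"`` only at the scale minimum of exactly 3,
    everything in between is excluded from analysis.
    """
    if score < 3:
        raise ValueError(f"composite score {score} below the attainable minimum of 3")
    if score >= 8:
        return "T"
    if score == 3:
        return "NT"
    return "excluded"


class TTestSummary(NamedTuple):
    t: float
    df: int


def two_sample_t_summary(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
) -> TTestSummary:
    """Pooled-variance Student t from per-group summary statistics.

    Sign convention is (a - b). ``df = n_a + n_b - 2``.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2 for a two-sample t-test")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be nonnegative")
    df = n_a + n_b - 2
    pooled_var = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / df
    se = math.sqrt(pooled_var * (1.0 / n_a + 1.0 / n_b))
    if se == 0:
        if mean_a == mean_b:
            return TTestSummary(0.0, df)
        raise ValueError("zero pooled variance with unequal means: t undefined")
    return TTestSummary((mean_a - mean_b) / se, df)


class ChiSquareResult(NamedTuple):
    chi2: float
    df: int


def chi_square_2x2(a: int, b: int, c: int, d: int) -> ChiSquareResult:
    """Pearson chi-square for a 2x2 table, WITHOUT continuity correction.

    Table layout: rows are groups, columns are categories::

        a  b
        c  d

    chi2 = n (ad - bc)^2 / [(a+b)(c+d)(a+c)(b+d)], df = 1.
    """
    counts = (a, b, c, d)
    if any(x < 0 for x in counts):
        raise ValueError("cell counts must be nonnegative")
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        raise ValueError("chi-square undefined: a marginal total is zero")
    return ChiSquareResult(n * (a * d - b * c) ** 2 / denom, 1)


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read the per-subject cohort CSV and validate required columns."""
    df = pd.read_csv(path)
    required = {"subject_id", "age", "education_years", "sex", "handedness", *SCALE_FIELDS}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    if df[sorted(required)].isna().any().any():
        bad = [c for c in sorted(required) if df[c].isna().any()]
        raise ValueError(f"missing values in required cohort columns: {bad}")
    return df


def screen_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Compute composite scores and group labels for every subject.

    Returns a copy of the table with ``composite_score`` and ``group``
    columns; subjects whose score falls strictly between 3 and 8 receive
    the label ``"excluded"``.
    """
    out = table.copy()
    scores = []
    groups = []
    for _, row in table.iterrows():
        rec = FrequencyRecord(
            subject_id=str(row["subject_id"]),
            **{f: row[f] for f in SCALE_FIELDS},
        )
        s = composite_tea_score(rec)
        scores.append(s)
        groups.append(assign_group(s))
    out["composite_score"] = scores
    out["group"] = groups
    return out
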