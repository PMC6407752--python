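"""Supporting group-comparison statistics.

One-way ANOVA across the four severity groups for continuous variables,
Pearson chi-square (no continuity correction) for sex, and the two-way
random-effects absolute-agreement intraclass correlation ICC(2,1) for
two-rater reliability of a questionnaire.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import Cohort, DiagnosticClass, Instrument

__all__ = [
    "RatingsPair",
    "one_way_anova",
    "chi_square_independence",
    "icc_two_rater",
    "group_summary_table",
]


@dataclass
class RatingsPair:
    """The same subjects rated independently by two raters."""

    rater1: np.ndarray
    rater2: np.ndarray

    def __post_init__(self) -> None:
        self.rater1 = np.asarray(self.rater1, dtype=float)
        self.rater2 = np.asarray(self.rater2, dtype=float)
        if self.rater1.shape != self.rater2.shape or self.rater1.ndim != 1:
            raise ValueError("ratings must be two equal-length vectors")
        if self.rater1.size < 3:
            raise ValueError("need at least 3 rated subjects")
        if np.isnan(self.rater1).any() or np.isnan(self.rater2).any():
            raise ValueError("ratings contain missing values")


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA F test across groups.

    Returns (F, p) with F on (k-1, N-k) degrees of freedom.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    for g in arrays:
        if g.size < 2:
            raise ValueError("every group needs at least 2 observations")
    if all(np.ptp(g) == 0 for g in arrays):
        raise ValueError("degenerate groups: no within-group variance anywhere")
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


def chi_square_independence(table) -> tuple[float, float]:
    """Pearson chi-square test of independence on a 2-way count table.

    No continuity correction is applied. Degrees of freedom are
    (r - 1)(c - 1).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or (table < 0).any():
        raise ValueError("table must be a 2-D array of nonnegative counts")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("table has a zero margin")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def icc_two_rater(ratings: RatingsPair, form: str = "two_way_random_absolute") -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rating.

    Computed from the two-way mean squares: with n subjects and k = 2
    raters,

        ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    where MSR, MSC, MSE are the subject, rater and residual mean squares.
    """
    if form != "two_way_random_absolute":
        raise ValueError(f"unsupported ICC form {form!r}")
    x = np.column_stack([ratings.rater1, ratings.rater2])
    n, k = x.shape
    grand = x.mean()
    if np.allclose(x, grand):
        raise ValueError("zero total variance: ICC undefined")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((x - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n))


def group_summary_table(
    cohort: Cohort, instrument: Instrument | None = None
) -> pd.DataFrame:
    """Per-class means/SDs with an F (or chi-square) test per variable.

    Covers age, education, every comparator present on all subjects, the
    instrument sum score when an instrument is given, and sex (as a
    chi-square of the sex-by-class count table). Mirrors the layout of a
    demographics comparison table: one row per variable, one column pair
    per class, then the statistic and p value.
    """
    from .instrument_pipeline import score_cohort  # local: avoid cycle

    classes = [c for c in DiagnosticClass if any(s.dx == c for s in cohort.subjects)]
    rows = []

    def continuous_row(label: str, values_by_class: dict) -> None:
        groups = [values_by_class[c] for c in classes]
        f, p = one_way_anova(groups)
        row: dict[str, object] = {"variable": label, "test": "ANOVA F"}
        for c in classes:
            v = np.asarray(values_by_class[c], dtype=float)
            row[f"{c.name}_mean"] = float(v.mean())
            row[f"{c.name}_sd"] = float(v.std(ddof=1))
        row["statistic"] = f
        row["p"] = p
        rows.append(row)

    def by_class(getter) -> dict:
        return {
            c: [getter(s) for s in cohort.subjects if s.dx == c] for c in classes
        }

    if all(s.age is not None for s in cohort.subjects):
        continuous_row("age", by_class(lambda s: s.age))
    if all(s.education is not None for s in cohort.subjects):
        continuous_row("education", by_class(lambda s: s.education))
    if instrument is not None:
        scores = score_cohort(instrument, cohort)
        values = {
            c: scores[[i for i, s in enumerate(cohort.subjects) if s.dx == c]]
            for c in classes
        }
        continuous_row(instrument.name, values)
    comparators = set.intersection(
        *(set(s.comparators) for s in cohort.subjects)
    ) if cohort.subjects else set()
    for name in sorted(comparators):
        continuous_row(name, by_class(lambda s, name=name: s.comparators[name]))

    if all(s.sex is not None for s in cohort.subjects):
        counts = np.array(
            [
                [
                    sum(1 for s in cohort.subjects if s.dx == c and s.sex == sex)
                    for sex in ("female", "male")
                ]
                for c in classes
            ]
        )
        stat, p = chi_square_independence(counts)
        row = {"variable": "sex", "test": "chi-square"}
        for i, c in enumerate(classes):
            n_c = counts[i].sum()
            row[f"{c.name}_mean"] = counts[i, 0] / n_c  # proportion female
            row[f"{c.name}_sd"] = np.nan
        row["statistic"] = stat
        row["p"] = p
        rows.append(row)

    return pd.DataFrame(rows)
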