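"""Subjects, cohorts and screening instruments, with CSV/JSON persistence.

The central objects of the package live here:

* :class:`DiagnosticClass` — the four CDR-anchored severity stages
  (normal cognition, MCI, very mild dementia, dementia), totally ordered
  by severity.
* :class:`Subject` — one participant: a diagnostic class, the informant's
  45 binary item responses (impairment endorsed / not endorsed, with
  per-item missingness allowed at the I/O level), and optional
  demographics and comparator-instrument scores.
* :class:`Cohort` — an ordered collection of subjects with provenance.
* :class:`Instrument` — an ordered subset of the 45-item panel together
  with per-comparison integer cutoffs; its score is the number of
  endorsed items.

File formats are deliberately plain: cohorts are CSV with a fixed column
order, instruments are small JSON documents. Both carry a
``format_version`` field and round-trip losslessly, including
missingness.
"""

from __future__ import annotations

import enum
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "N_ITEMS",
    "FORMAT_VERSION",
    "COMPARATOR_RANGES",
    "COMPARATOR_HIGHER_IS_IMPAIRED",
    "STAGING_COMPARISONS",
    "DiagnosticClass",
    "Subject",
    "Cohort",
    "Instrument",
    "SchemaError",
    "MonotoneStagingWarning",
    "read_cohort",
    "write_cohort",
    "read_instrument",
    "write_instrument",
]

#: Size of the full informant questionnaire panel.
N_ITEMS = 45

#: Version stamp written by every serializer in this package.
FORMAT_VERSION = 1

#: Valid score ranges of the comparator instruments (inclusive bounds;
#: the NPI sum has no meaningful upper bound in practice).
COMPARATOR_RANGES: dict[str, tuple[float, float]] = {
    "AD8": (0, 8),
    "MMSE": (0, 30),
    "MoCA": (0, 30),
    "CASI": (0, 100),
    "IADL": (0, 8),
    "NPI": (0, math.inf),
}

#: Score direction semantics: True means a higher score indicates more
#: impairment (AD8 symptom count, NPI burden); False means a higher score
#: indicates better function (cognitive tests, IADL ability).
COMPARATOR_HIGHER_IS_IMPAIRED: dict[str, bool] = {
    "AD8": True,
    "NPI": True,
    "MMSE": False,
    "MoCA": False,
    "CASI": False,
    "IADL": False,
}

#: The severity-ordered adjacent/near-adjacent comparisons whose cutoffs,
#: when all present on an instrument, must be nondecreasing for staged use.
STAGING_COMPARISONS = ("NC_vs_MCI", "MCI_vs_VMD", "MCI_vs_DEM", "VMD_vs_DEM")


class SchemaError(ValueError):
    """A file is structurally incompatible with the expected schema."""


class MonotoneStagingWarning(UserWarning):
    """Pairwise-derived cutoffs cross the severity order.

    This can legitimately happen when cutoffs are estimated independently
    on small samples, so it is a warning rather than an error; staged
    classification (as opposed to pairwise use) will refuse such cutoffs.
    """


class DiagnosticClass(enum.IntEnum):
    """CDR-anchored cognitive severity stage.

    The integer values encode the total severity order
    ``NC < MCI < VMD < DEM``. MCI and VMD share a global CDR of 0.5 and
    are distinguished by whether all-cause dementia criteria are met.
    """

    NC = 0
    MCI = 1
    VMD = 2
    DEM = 3

    @property
    def cdr_band(self) -> str:
        """The CDR band the class occupies."""
        return _CDR_BANDS[self]

    @classmethod
    def from_string(cls, text: str) -> "DiagnosticClass":
        try:
            return cls[text.strip()]
        except KeyError:
            raise ValueError(
                f"unknown diagnostic class {text!r}; expected one of "
                f"{[c.name for c in cls]}"
            ) from None


_CDR_BANDS = {
    DiagnosticClass.NC: "0",
    DiagnosticClass.MCI: "0.5 non-demented",
    DiagnosticClass.VMD: "0.5 demented",
    DiagnosticClass.DEM: "≥1",
}


def _as_item_vector(items: Sequence[float] | np.ndarray) -> np.ndarray:
    arr = np.asarray(items, dtype=float)
    if arr.shape != (N_ITEMS,):
        raise ValueError(
            f"items must have exactly {N_ITEMS} positions, got shape {arr.shape}"
        )
    valid = np.isnan(arr) | (arr == 0.0) | (arr == 1.0)
    if not valid.all():
        bad = np.unique(arr[~valid])
        raise ValueError(f"item responses must be 0, 1 or missing; found {bad}")
    return arr


@dataclass
class Subject:
    """One participant as described by their informant.

    ``items`` is a length-45 float vector with values 0 (not endorsed),
    1 (impairment endorsed) or NaN (missing). Item *j* of the
    questionnaire (1-based) lives at index ``j - 1``.
    """

    subject_id: str
    dx: DiagnosticClass
    items: np.ndarray
    age: float | None = None
    sex: str | None = None
    education: float | None = None
    comparators: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dx = DiagnosticClass(self.dx)
        self.items = _as_item_vector(self.items)
        if self.sex is not None and self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        for name, score in self.comparators.items():
            if name not in COMPARATOR_RANGES:
                raise ValueError(f"unknown comparator instrument {name!r}")
            lo, hi = COMPARATOR_RANGES[name]
            if not (lo <= score <= hi):
                raise ValueError(
                    f"{name} score {score} outside instrument range [{lo}, {hi}]"
                )

    def equals(self, other: "Subject") -> bool:
        return (
            self.subject_id == other.subject_id
            and self.dx == other.dx
            and np.array_equal(self.items, other.items, equal_nan=True)
            and _num_eq(self.age, other.age)
            and self.sex == other.sex
            and _num_eq(self.education, other.education)
            and self.comparators.keys() == other.comparators.keys()
            and all(
                _num_eq(self.comparators[k], other.comparators[k])
                for k in self.comparators
            )
        )


def _num_eq(a: float | None, b: float | None) -> bool:
    if a is None or b is None:
        return a is None and b is None
    return math.isclose(a, b, rel_tol=0, abs_tol=1e-9)


@dataclass
class Cohort:
    """An ordered collection of subjects with a provenance note."""

    subjects: list[Subject]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate subject_ids: {dupes}")

    def size(self) -> int:
        return len(self.subjects)

    def class_counts(self) -> dict[DiagnosticClass, int]:
        counts = {c: 0 for c in DiagnosticClass}
        for s in self.subjects:
            counts[s.dx] += 1
        return counts

    def labels(self) -> np.ndarray:
        """Diagnostic classes as an integer array (severity codes)."""
        return np.array([int(s.dx) for s in self.subjects], dtype=int)

    def item_matrix(self) -> np.ndarray:
        """(n_subjects, 45) float matrix of responses; NaN marks missing."""
        if not self.subjects:
            return np.empty((0, N_ITEMS))
        return np.vstack([s.items for s in self.subjects])

    def subset(self, classes: Iterable[DiagnosticClass]) -> "Cohort":
        keep = set(DiagnosticClass(c) for c in classes)
        return Cohort(
            [s for s in self.subjects if s.dx in keep],
            provenance=self.provenance,
        )

    def equals(self, other: "Cohort") -> bool:
        return self.size() == other.size() and all(
            a.equals(b) for a, b in zip(self.subjects, other.subjects)
        )


@dataclass
class Instrument:
    """An ordered item subset of the 45-item panel plus staging cutoffs.

    ``item_ids`` are 1-based questionnaire item numbers. ``cutoffs`` maps a
    comparison name (e.g. ``"NC_vs_MCI"``) to the smallest sum score
    assigned to the more-impaired side of that comparison.
    """

    name: str
    item_ids: list[int]
    cutoffs: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = list(self.item_ids)
        if len(set(ids)) != len(ids):
            raise ValueError(f"instrument {self.name!r} has duplicate item ids")
        for i in ids:
            if not (1 <= int(i) <= N_ITEMS):
                raise ValueError(f"item id {i} outside 1..{N_ITEMS}")
        self.item_ids = [int(i) for i in ids]
        k = len(self.item_ids)
        for comp, cut in self.cutoffs.items():
            if not (0 <= int(cut) <= k + 1):
                raise ValueError(
                    f"cutoff {cut} for {comp} outside 0..{k + 1} "
                    f"(instrument has {k} items)"
                )
        self.cutoffs = {c: int(v) for c, v in self.cutoffs.items()}
        if all(c in self.cutoffs for c in STAGING_COMPARISONS):
            seq = [self.cutoffs[c] for c in STAGING_COMPARISONS]
            if any(b < a for a, b in zip(seq, seq[1:])):
                warnings.warn(
                    f"instrument {self.name!r} cutoffs {dict(zip(STAGING_COMPARISONS, seq))} "
                    "are not nondecreasing in severity order; staged "
                    "classification will be unavailable",
                    MonotoneStagingWarning,
                    stacklevel=2,
                )

    @property
    def k(self) -> int:
        """Number of items; the sum score ranges over 0..k."""
        return len(self.item_ids)

    def column_indices(self) -> np.ndarray:
        """0-based columns of this instrument's items in an item matrix."""
        return np.array(self.item_ids, dtype=int) - 1


# ---------------------------------------------------------------------------
# Cohort CSV I/O
# ---------------------------------------------------------------------------

_ITEM_COLUMNS = [f"item_{j:02d}" for j in range(1, N_ITEMS + 1)]
_OPTIONAL_COLUMNS = ["age", "sex", "education"] + list(COMPARATOR_RANGES)

DEFAULT_SCHEMA: dict[str, str] = {
    "subject_id": "subject_id",
    "dx": "dx",
    **{c: c for c in _ITEM_COLUMNS},
}


def read_cohort(path: str | Path, schema: Mapping[str, str] | None = None) -> Cohort:
    """Read a cohort CSV.

    Parameters
    ----------
    path:
        CSV file with a header row.
    schema:
        Optional map from logical column names (``subject_id``, ``dx``,
        ``item_01`` .. ``item_45``) to the column names used in the file.
        Unmapped logical names fall back to themselves.

    Raises
    ------
    SchemaError
        If a mandatory column is absent.
    ValueError
        If a ``dx`` value is not one of the four class codes, or an item
        value is not 0, 1 or empty (the offending row is named).
    """
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    for logical in ["subject_id", "dx"] + _ITEM_COLUMNS:
        if colmap[logical] not in frame.columns:
            raise SchemaError(f"mandatory column {colmap[logical]!r} is missing")

    subjects: list[Subject] = []
    for pos, (_, row) in enumerate(frame.iterrows()):
        rowno = pos + 2  # header is line 1
        dx_text = row[colmap["dx"]]
        try:
            dx = DiagnosticClass.from_string(dx_text)
        except ValueError as exc:
            raise ValueError(f"row {rowno}: {exc}") from None
        items = np.full(N_ITEMS, np.nan)
        for j, col in enumerate(_ITEM_COLUMNS):
            raw = row[colmap[col]].strip()
            if raw == "":
                continue
            if raw not in ("0", "1"):
                raise ValueError(
                    f"row {rowno}: item value {raw!r} in column "
                    f"{colmap[col]!r} is not 0, 1 or empty"
                )
            items[j] = float(raw)
        kwargs: dict = {}
        for name in ("age", "education"):
            if name in frame.columns and row[name].strip() != "":
                kwargs[name] = float(row[name])
        if "sex" in frame.columns and row["sex"].strip() != "":
            kwargs["sex"] = row["sex"].strip()
        comparators = {
            name: float(row[name])
            for name in COMPARATOR_RANGES
            if name in frame.columns and row[name].strip() != ""
        }
        subjects.append(
            Subject(
                subject_id=row[colmap["subject_id"]],
                dx=dx,
                items=items,
                comparators=comparators,
                **kwargs,
            )
        )
    return Cohort(subjects, provenance=str(path))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as CSV with the fixed column order.

    Columns: ``subject_id, dx, item_01..item_45`` followed by whichever
    optional columns (age, sex, education, comparators) are present for
    at least one subject. Missing values are written as empty fields.
    """
    if cohort.size() == 0:
        raise ValueError("refusing to write an empty cohort")
    records = []
    for s in cohort.subjects:
        rec: dict[str, object] = {"subject_id": s.subject_id, "dx": s.dx.name}
        for j, col in enumerate(_ITEM_COLUMNS):
            v = s.items[j]
            rec[col] = "" if np.isnan(v) else str(int(v))
        rec["age"] = "" if s.age is None else _fmt_num(s.age)
        rec["sex"] = "" if s.sex is None else s.sex
        rec["education"] = "" if s.education is None else _fmt_num(s.education)
        for name in COMPARATOR_RANGES:
            rec[name] = (
                _fmt_num(s.comparators[name]) if name in s.comparators else ""
            )
        records.append(rec)
    frame = pd.DataFrame.from_records(records)
    for col in _OPTIONAL_COLUMNS:
        if (frame[col] == "").all():
            frame = frame.drop(columns=[col])
    frame.to_csv(path, index=False)


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


# ---------------------------------------------------------------------------
# Instrument JSON I/O
# ---------------------------------------------------------------------------

def write_instrument(instrument: Instrument, path: str | Path) -> None:
    doc = {
        "format_version": FORMAT_VERSION,
        "name": instrument.name,
        "item_ids": instrument.item_ids,
        "cutoffs": instrument.cutoffs,
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_instrument(path: str | Path) -> Instrument:
    doc = json.loads(Path(path).read_text())
    for key in ("name", "item_ids", "cutoffs"):
        if key not in doc:
            raise SchemaError(f"instrument JSON is missing key {key!r}")
    return Instrument(
        name=doc["name"],
        item_ids=list(doc["item_ids"]),
        cutoffs=dict(doc["cutoffs"]),
    )
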