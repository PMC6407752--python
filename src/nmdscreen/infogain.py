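"""Entropy-based item ranking (information gain) and top-k selection.

For a labelled dataset D with classes C_1..C_m in proportions p_i, the
class entropy is E(D) = -sum_i p_i log2 p_i. Partitioning D by the v
distinct values of a feature F into subsets D_1..D_v gives the
conditional entropy E_F(D) = sum_j (|D_j|/|D|) E(D_j), and the
information gain of F is IG(F) = E(D) - E_F(D), measured in bits. Items
are ranked by IG, descending, to assemble candidate instruments.

On finite samples the empirical IG of even a class-independent feature
is almost surely strictly positive, so a literal "IG > 0" informative
filter is vacuous. The default filter instead compares each item's IG
with a permutation null: labels are shuffled ``n_perm`` times, the
per-feature IG values under shuffling are pooled, and the (1 - alpha)
quantile of that pool is the informativeness threshold. A strict
epsilon mode (``ig > 1e-12``) is retained for emulation of toolkits
that report rounded zeros.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .cohort_io import Cohort, DiagnosticClass, Instrument, N_ITEMS

__all__ = [
    "LabelledDataset",
    "RankEntry",
    "FeatureRanking",
    "entropy",
    "conditional_entropy",
    "information_gain",
    "rank_features",
    "permutation_null_threshold",
    "select_top_k",
]


def _class_entropy_from_counts(counts: np.ndarray) -> float:
    total = counts.sum()
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def entropy(labels: Sequence) -> float:
    """Shannon entropy of a class-label vector, in bits (0 log 0 = 0)."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("entropy of an empty label vector is undefined")
    _, counts = np.unique(labels, return_counts=True)
    return _class_entropy_from_counts(counts)


def conditional_entropy(feature: Sequence, labels: Sequence) -> float:
    """Expected class entropy after partitioning by a discrete feature."""
    feature = np.asarray(feature)
    labels = np.asarray(labels)
    if feature.shape != labels.shape:
        raise ValueError(
            f"feature and labels have different lengths "
            f"({feature.size} vs {labels.size})"
        )
    if feature.dtype.kind == "f" and np.isnan(feature.astype(float)).any():
        raise ValueError("feature contains missing values")
    n = feature.size
    out = 0.0
    for value in np.unique(feature):
        mask = feature == value
        out += (mask.sum() / n) * entropy(labels[mask])
    return out


def information_gain(feature: Sequence, labels: Sequence) -> float:
    """IG(F) = E(D) - E_F(D), clipped at 0 against floating-point error."""
    return max(0.0, entropy(labels) - conditional_entropy(feature, labels))


@dataclass
class LabelledDataset:
    """A complete-case feature matrix with class labels.

    ``features`` is (n_subjects, n_items) of small discrete values,
    ``labels`` a length-n vector of class codes, ``item_ids`` the 1-based
    questionnaire ids of the columns.
    """

    features: np.ndarray
    labels: np.ndarray
    item_ids: list[int]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("features and labels disagree on subject count")
        if self.features.shape[1] != len(self.item_ids):
            raise ValueError("item_ids must name every feature column")
        if self.features.dtype.kind == "f":
            nan_cols = np.isnan(self.features).any(axis=0)
            if nan_cols.any():
                bad = [self.item_ids[j] for j in np.flatnonzero(nan_cols)]
                raise ValueError(
                    f"missing values in item column(s) {bad}; analysis "
                    "operations require complete cases"
                )
            self.features = self.features.astype(int)

    @classmethod
    def from_cohort(
        cls, cohort: Cohort, label_mode: str = "3class"
    ) -> "LabelledDataset":
        """Build the ranking dataset from a cohort.

        ``label_mode="3class"`` (default) folds very mild dementia into
        the dementia class, ranking items for the NC/MCI/dementia
        discrimination; ``"4class"`` keeps all four stages distinct.
        """
        if label_mode not in ("3class", "4class"):
            raise ValueError("label_mode must be '3class' or '4class'")
        labels = cohort.labels()
        if label_mode == "3class":
            labels = np.where(
                labels == int(DiagnosticClass.VMD), int(DiagnosticClass.DEM), labels
            )
        return cls(
            features=cohort.item_matrix(),
            labels=labels,
            item_ids=list(range(1, N_ITEMS + 1)),
        )

    @property
    def n_classes(self) -> int:
        return int(np.unique(self.labels).size)


@dataclass(frozen=True)
class RankEntry:
    item_id: int
    ig: float
    rank: int
    informative: bool


@dataclass
class FeatureRanking:
    """Per-item information gain in rank order."""

    entries: list[RankEntry]
    null_quantile: float

    def ig_of(self, item_id: int) -> float:
        for e in self.entries:
            if e.item_id == item_id:
                return e.ig
        raise KeyError(item_id)

    def informative_ids(self) -> list[int]:
        return [e.item_id for e in self.entries if e.informative]

    def top_ids(self, k: int) -> list[int]:
        return [e.item_id for e in self.entries[:k]]

    def to_tsv(self, path: str | Path) -> None:
        lines = ["item_id\tig_bits\trank\tinformative"]
        for e in self.entries:
            lines.append(f"{e.item_id}\t{e.ig:.10g}\t{e.rank}\t{int(e.informative)}")
        Path(path).write_text("\n".join(lines) + "\n")

    def to_json(self, path: str | Path) -> None:
        doc = {
            "format_version": 1,
            "null_quantile_bits": self.null_quantile,
            "entries": [
                {
                    "item_id": e.item_id,
                    "ig_bits": e.ig,
                    "rank": e.rank,
                    "informative": e.informative,
                }
                for e in self.entries
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def _ig_all_features(features: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Vectorised per-column IG for a matrix of small discrete features.

    One-hot encodes the labels once, then accumulates class counts per
    feature value with a single matrix product per distinct value.
    """
    n = labels.shape[0]
    classes, label_idx = np.unique(labels, return_inverse=True)
    onehot = np.zeros((n, classes.size))
    onehot[np.arange(n), label_idx] = 1.0
    base = _class_entropy_from_counts(onehot.sum(axis=0))

    cond = np.zeros(features.shape[1])
    for value in np.unique(features):
        mask = (features == value).astype(float)  # n x f
        counts = mask.T @ onehot  # f x m class counts within this value
        sizes = counts.sum(axis=1)  # f
        with np.errstate(divide="ignore", invalid="ignore"):
            p = counts / sizes[:, None]
            plogp = np.where(counts > 0, p * np.log2(p), 0.0)
        ent = -plogp.sum(axis=1)
        cond += np.where(sizes > 0, sizes / n, 0.0) * ent
    return np.maximum(0.0, base - cond)


def permutation_null_threshold(
    data: LabelledDataset,
    n_perm: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """(1 - alpha) quantile of per-feature IG under label permutation.

    The null pools the per-feature IG values across all permutations
    (no max statistic), so under no signal the expected number of items
    exceeding the threshold is about ``alpha * n_items``.
    """
    if n_perm < 50:
        raise ValueError("n_perm must be at least 50 for a stable quantile")
    rng = np.random.default_rng(seed)
    pool = np.empty((n_perm, data.features.shape[1]))
    for b in range(n_perm):
        shuffled = rng.permutation(data.labels)
        pool[b] = _ig_all_features(data.features, shuffled)
    return float(np.quantile(pool.ravel(), 1.0 - alpha))


def rank_features(
    data: LabelledDataset,
    informative_filter: str = "permutation",
    n_perm: int = 200,
    alpha: float = 0.05,
    epsilon: float = 1e-12,
    seed: int = 0,
) -> FeatureRanking:
    """Rank every item by information gain, descending.

    Ties are broken by ascending item id. The ``informative`` flag uses
    the permutation-null threshold by default, or a strict
    ``ig > epsilon`` test when ``informative_filter="epsilon"``.
    """
    if informative_filter not in ("permutation", "epsilon"):
        raise ValueError("informative_filter must be 'permutation' or 'epsilon'")
    igs = _ig_all_features(data.features, data.labels)
    if informative_filter == "permutation":
        threshold = permutation_null_threshold(data, n_perm=n_perm, alpha=alpha, seed=seed)
    else:
        threshold = epsilon
    order = sorted(
        range(len(data.item_ids)), key=lambda j: (-igs[j], data.item_ids[j])
    )
    entries = [
        RankEntry(
            item_id=data.item_ids[j],
            ig=float(igs[j]),
            rank=r + 1,
            informative=bool(igs[j] > threshold),
        )
        for r, j in enumerate(order)
    ]
    return FeatureRanking(entries=entries, null_quantile=float(threshold))


def select_top_k(ranking: FeatureRanking, k: int, name: str | None = None) -> Instrument:
    """Assemble an instrument from the first k ranked items.

    Warns when k exceeds the number of items flagged informative (the
    instrument is still built from the global ranking).
    """
    if not (1 <= k <= len(ranking.entries)):
        raise ValueError(
            f"k must lie in 1..{len(ranking.entries)}, got {k}"
        )
    n_inf = len(ranking.informative_ids())
    if k > n_inf:
        warnings.warn(
            f"k={k} exceeds the {n_inf} items flagged informative; "
            "instrument includes items indistinguishable from noise",
            UserWarning,
            stacklevel=2,
        )
    return Instrument(name=name or f"{k}Q", item_ids=ranking.top_ids(k))
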