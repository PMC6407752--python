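"""ROC curves on discrete screening scores, AUC with ties, and cutoffs.

Conventions
-----------
The positive class is always the more-impaired group. A score is called
positive when it lies at or above a threshold t (``higher_is_positive``);
for instruments where impairment lowers the score (MMSE, MoCA, CASI,
IADL) scores are negated internally so a single code path serves both
directions. Sensitivity at t is P(score >= t | positive) and specificity
is P(score < t | negative); the threshold grid is the sorted unique
scores plus one sentinel above the maximum, so the curve always spans
(sens, spec) = (1, 0) .. (0, 1).

The AUC is the trapezoidal area of the (1 - spec, sens) polyline, which
on this grid coincides exactly with the tie-corrected rank statistic
P(pos > neg) + P(pos = neg)/2.

The operating point is chosen by the minimum-distance rule: the
threshold minimising the Euclidean distance from (sensitivity,
specificity) = (1, 1), i.e. from the upper-left corner of the ROC unit
square, with ties resolved toward higher sensitivity. Integer-score
cutoffs are rendered as a boundary label "a/b": a is the largest score
called negative and b the smallest called positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps

__all__ = [
    "ROCResult",
    "roc_curve",
    "auc",
    "rank_auc",
    "auc_confidence_interval",
    "min_distance_cutoff",
    "sens_spec_at",
]


@dataclass
class ROCResult:
    """A full ROC grid for one binary discrimination.

    ``thresholds``, ``pos_scores`` and ``neg_scores`` live in internal
    score space (negated when ``direction="lower_is_positive"``);
    ``cutoff_label`` is always rendered in the original units.
    """

    thresholds: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    direction: str
    pos_scores: np.ndarray = field(repr=False, default=None)
    neg_scores: np.ndarray = field(repr=False, default=None)
    auc_ci: tuple[float, float] | None = None
    cutoff: float | None = None
    cutoff_label: str | None = None

    def threshold_label(self, t: float) -> str:
        """Render threshold t as the paper-style boundary label "a/b"."""
        if self.direction == "higher_is_positive":
            neg_side, pos_side = t - 1, t
        else:
            pos_side = -t
            neg_side = -t + 1
        return f"{_fmt(neg_side)}/{_fmt(pos_side)}"


def _fmt(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else f"{x:g}"


def roc_curve(
    scores,
    labels,
    direction: str = "higher_is_positive",
) -> ROCResult:
    """Build the ROC grid of a score against binary impairment labels.

    ``labels`` is 1/True for the positive (more-impaired) group. Raises
    for single-class label vectors ("degenerate ROC") and for missing
    scores.
    """
    if direction not in ("higher_is_positive", "lower_is_positive"):
        raise ValueError(f"unknown direction {direction!r}")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if np.isnan(scores).any():
        raise ValueError("scores contain missing values")
    if labels.all() or (~labels).all():
        raise ValueError("degenerate ROC: both classes must be present")

    s = scores if direction == "higher_is_positive" else -scores
    pos = np.sort(s[labels])
    neg = np.sort(s[~labels])
    uniq = np.unique(s)
    thresholds = np.concatenate([uniq, [uniq[-1] + 1.0]])

    # P(pos >= t) and P(neg < t) via binary search on the sorted groups.
    sens = 1.0 - np.searchsorted(pos, thresholds, side="left") / pos.size
    spec = np.searchsorted(neg, thresholds, side="left") / neg.size

    x = 1.0 - spec  # false positive rate, nonincreasing along thresholds
    area = float(np.trapezoid(sens[::-1], x[::-1]))
    return ROCResult(
        thresholds=thresholds,
        sens=sens,
        spec=spec,
        auc=area,
        n_pos=int(pos.size),
        n_neg=int(neg.size),
        direction=direction,
        pos_scores=pos,
        neg_scores=neg,
    )


def auc(roc: ROCResult) -> float:
    """Trapezoidal area under the (1 - spec, sens) polyline."""
    x = 1.0 - roc.spec
    return float(np.trapezoid(roc.sens[::-1], x[::-1]))


def rank_auc(scores, labels, direction: str = "higher_is_positive") -> float:
    """Tie-corrected rank AUC: P(pos > neg) + P(pos = neg) / 2.

    Computed from the Mann-Whitney U statistic via midranks;
    independent of the trapezoid route and used to cross-check it.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    s = scores if direction == "higher_is_positive" else -scores
    pos, neg = s[labels], s[~labels]
    ranks = _sps.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def auc_confidence_interval(
    roc: ROCResult,
    level: float = 0.95,
    method: str = "hanley-mcneil",
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Confidence interval for the AUC, clipped to [0, 1].

    ``"hanley-mcneil"`` (default) uses the Hanley–McNeil standard error
    with a normal interval; ``"bootstrap"`` resamples positives and
    negatives separately and takes percentile bounds.
    """
    if roc.n_pos < 2 or roc.n_neg < 2:
        raise ValueError("need at least 2 positives and 2 negatives for a CI")
    if method == "hanley-mcneil":
        a = roc.auc
        q1 = a / (2.0 - a)
        q2 = 2.0 * a * a / (1.0 + a)
        var = (
            a * (1 - a)
            + (roc.n_pos - 1) * (q1 - a * a)
            + (roc.n_neg - 1) * (q2 - a * a)
        ) / (roc.n_pos * roc.n_neg)
        se = np.sqrt(max(var, 0.0))
        z = _sps.norm.ppf(0.5 + level / 2.0)
        lo, hi = a - z * se, a + z * se
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        pos, neg = roc.pos_scores, roc.neg_scores
        areas = np.empty(n_boot)
        scores = np.concatenate([pos, neg])
        labels = np.concatenate([np.ones(pos.size, bool), np.zeros(neg.size, bool)])
        for b in range(n_boot):
            ip = rng.integers(0, pos.size, pos.size)
            ineg = rng.integers(0, neg.size, neg.size)
            bs = np.concatenate([pos[ip], neg[ineg]])
            areas[b] = rank_auc(bs, labels)
        lo, hi = np.quantile(areas, [(1 - level) / 2, 0.5 + level / 2])
    else:
        raise ValueError(f"unknown CI method {method!r}")
    lo = float(np.clip(lo, 0.0, 1.0))
    hi = float(np.clip(hi, 0.0, 1.0))
    roc.auc_ci = (lo, hi)
    return lo, hi


def min_distance_cutoff(roc: ROCResult) -> float:
    """Threshold closest to the ideal corner (sens, spec) = (1, 1).

    Minimises sqrt((1 - sens)^2 + (1 - spec)^2) over the threshold grid;
    exact ties go to the lower threshold, i.e. the higher-sensitivity
    operating point. Stores and returns the chosen threshold and sets
    ``cutoff_label``.
    """
    d = np.hypot(1.0 - roc.sens, 1.0 - roc.spec)
    idx = int(np.argmin(d))  # first minimum = lowest threshold = max sens
    t = float(roc.thresholds[idx])
    roc.cutoff = t
    roc.cutoff_label = roc.threshold_label(t)
    return t


def sens_spec_at(roc: ROCResult, threshold: float) -> tuple[float, float]:
    """The stored (sensitivity, specificity) pair at a grid threshold."""
    matches = np.flatnonzero(roc.thresholds == threshold)
    if matches.size == 0:
        raise ValueError(
            f"threshold {threshold} is not on the ROC grid "
            f"{roc.thresholds.tolist()}"
        )
    i = int(matches[0])
    return float(roc.sens[i]), float(roc.spec[i])
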