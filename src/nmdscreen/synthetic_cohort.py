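"""Calibrated synthetic cohorts of informant questionnaire responses.

No patient-level data are distributed with the published screening study
this package operationalises; only per-class summary moments of the
12-item sum score (and of the comparator instruments and demographics)
are in print. This module turns those moments into a generative model so
that every downstream stage — item ranking, instrument assembly, ROC
cutoff estimation, staged classification — can be exercised and tested
end to end.

Model
-----
Each subject of diagnostic class *c* carries a latent severity
``p ~ Beta(a_c, b_c)`` with mean ``pi_c`` and concentration
``a_c + b_c = (1 - rho_c) / rho_c`` (``rho_c = 0`` degenerates to
``p = pi_c``). Given *p*, item *j* is endorsed independently with
probability ``lambda_j * p + (1 - lambda_j) * b_j`` where ``lambda_j``
is the item's loading on severity and ``b_j`` its severity-free base
rate. Items split into three roles:

* **core** (``lambda = 1``): the signal items an instrument should find;
  their sum over *k* core items is exactly beta-binomial, with mean
  ``k * pi`` and variance ``k * pi * (1 - pi) * (1 + (k - 1) * rho)``.
* **weak** (``0 < lambda < 1``): attenuated signal.
* **distractor** (``lambda = 0``): class-independent noise.

A plain independent-Bernoulli model cannot reproduce the printed
dementia-group standard deviation (1.3 at mean 11.2 exceeds the binomial
maximum of about 0.86); the shared latent severity supplies the required
positive item correlation, which is why the beta-binomial form is used.

:func:`calibrate_class_params` inverts the two moment identities
(method of moments) so the printed per-class mean/SD pairs become
``(pi, rho)`` parameters; :func:`default_paper_spec` assembles the full
study configuration (class sizes 53/91/108/386 in the test group, 12
core + 12 weak + 21 distractor items, comparator and demographic
moments).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .cohort_io import (
    COMPARATOR_RANGES,
    FORMAT_VERSION,
    N_ITEMS,
    Cohort,
    DiagnosticClass,
    Subject,
)

__all__ = [
    "RHO_MAX",
    "ClassSeverityParams",
    "ItemSpec",
    "GeneratorSpec",
    "calibrate_class_params",
    "generate_cohort",
    "default_paper_spec",
    "write_generator_spec",
    "read_generator_spec",
    "TEST_GROUP_SIZES",
    "SCORE_MOMENTS",
    "COMPARATOR_MOMENTS",
    "DEMOGRAPHICS_MOMENTS",
]

#: Upper clamp for the intra-subject correlation; beyond this the implied
#: beta distribution is implausibly U-shaped for questionnaire data.
RHO_MAX = 0.35

#: Published test-group composition (normal cognition through dementia).
TEST_GROUP_SIZES: dict[DiagnosticClass, int] = {
    DiagnosticClass.NC: 53,
    DiagnosticClass.MCI: 91,
    DiagnosticClass.VMD: 108,
    DiagnosticClass.DEM: 386,
}

#: Published per-class 12-item sum-score (mean, sd).
SCORE_MOMENTS: dict[DiagnosticClass, tuple[float, float]] = {
    DiagnosticClass.NC: (0.6, 0.7),
    DiagnosticClass.MCI: (3.1, 1.7),
    DiagnosticClass.VMD: (6.4, 2.1),
    DiagnosticClass.DEM: (11.2, 1.3),
}

#: Published per-class comparator-instrument (mean, sd), per instrument.
COMPARATOR_MOMENTS: dict[str, dict[DiagnosticClass, tuple[float, float]]] = {
    "AD8": {
        DiagnosticClass.NC: (0.6, 0.7),
        DiagnosticClass.MCI: (2.5, 1.1),
        DiagnosticClass.VMD: (4.1, 1.4),
        DiagnosticClass.DEM: (6.6, 0.9),
    },
    "MMSE": {
        DiagnosticClass.NC: (26.0, 4.1),
        DiagnosticClass.MCI: (24.1, 4.0),
        DiagnosticClass.VMD: (19.7, 4.7),
        DiagnosticClass.DEM: (11.7, 6.4),
    },
    "MoCA": {
        DiagnosticClass.NC: (21.3, 7.0),
        DiagnosticClass.MCI: (17.6, 5.9),
        DiagnosticClass.VMD: (12.4, 6.0),
        DiagnosticClass.DEM: (5.7, 4.7),
    },
    "CASI": {
        DiagnosticClass.NC: (85.7, 4.1),
        DiagnosticClass.MCI: (77.6, 10.8),
        DiagnosticClass.VMD: (65.7, 14.8),
        DiagnosticClass.DEM: (38.2, 22.7),
    },
    "IADL": {
        DiagnosticClass.NC: (8.0, 0.1),
        DiagnosticClass.MCI: (7.5, 1.2),
        DiagnosticClass.VMD: (6.3, 1.3),
        DiagnosticClass.DEM: (2.1, 2.1),
    },
    "NPI": {
        DiagnosticClass.NC: (3.0, 4.1),
        DiagnosticClass.MCI: (5.8, 6.9),
        DiagnosticClass.VMD: (5.1, 6.4),
        DiagnosticClass.DEM: (10.4, 10.4),
    },
}

#: Published per-class demographics: age (mean, sd), education (mean, sd),
#: and the proportion female.
DEMOGRAPHICS_MOMENTS: dict[DiagnosticClass, dict[str, object]] = {
    DiagnosticClass.NC: {"age": (67.8, 10.7), "education": (6.9, 5.1), "pct_female": 0.472},
    DiagnosticClass.MCI: {"age": (71.4, 9.3), "education": (6.0, 4.3), "pct_female": 0.505},
    DiagnosticClass.VMD: {"age": (76.1, 8.8), "education": (4.7, 4.2), "pct_female": 0.602},
    DiagnosticClass.DEM: {"age": (79.5, 8.6), "education": (4.1, 4.5), "pct_female": 0.585},
}

_AGE_RANGE = (40.0, 100.0)
_EDU_RANGE = (0.0, 24.0)


@dataclass(frozen=True)
class ClassSeverityParams:
    """Latent severity distribution of one diagnostic class.

    ``pi`` is the mean per-item endorsement probability of core items,
    ``rho`` the pairwise intra-subject correlation (overdispersion).
    """

    dx: DiagnosticClass
    pi: float
    rho: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.pi <= 1.0):
            raise ValueError(f"pi must lie in [0, 1], got {self.pi}")
        if not (0.0 <= self.rho <= RHO_MAX):
            raise ValueError(f"rho must lie in [0, {RHO_MAX}], got {self.rho}")

    def implied_mean(self, k: int) -> float:
        return k * self.pi

    def implied_sd(self, k: int) -> float:
        var = k * self.pi * (1 - self.pi) * (1 + (k - 1) * self.rho)
        return math.sqrt(var)

    def beta_shape(self) -> tuple[float, float] | None:
        """Beta(a, b) of the latent severity; None if degenerate (rho=0)."""
        if self.rho == 0.0:
            return None
        conc = (1 - self.rho) / self.rho
        return self.pi * conc, (1 - self.pi) * conc


@dataclass(frozen=True)
class ItemSpec:
    """Role and parameters of one questionnaire item."""

    item_id: int
    role: str  # core | weak | distractor
    loading: float
    base_rate: float

    def __post_init__(self) -> None:
        if not (1 <= self.item_id <= N_ITEMS):
            raise ValueError(f"item_id {self.item_id} outside 1..{N_ITEMS}")
        if self.role not in ("core", "weak", "distractor"):
            raise ValueError(f"unknown item role {self.role!r}")
        if not (0.0 <= self.loading <= 1.0 and 0.0 <= self.base_rate <= 1.0):
            raise ValueError("loading and base_rate must lie in [0, 1]")
        expected = {"core": self.loading == 1.0, "weak": 0.0 < self.loading < 1.0,
                    "distractor": self.loading == 0.0}[self.role]
        if not expected:
            raise ValueError(
                f"loading {self.loading} inconsistent with role {self.role!r}"
            )


@dataclass
class GeneratorSpec:
    """Everything needed to reproduce one synthetic cohort."""

    class_sizes: dict[DiagnosticClass, int]
    severity: dict[DiagnosticClass, ClassSeverityParams]
    items: list[ItemSpec]
    seed: int
    comparator_moments: dict[str, dict[DiagnosticClass, tuple[float, float]]] | None = None
    demographics_moments: dict[DiagnosticClass, dict[str, object]] | None = None

    def __post_init__(self) -> None:
        if sorted(s.item_id for s in self.items) != list(range(1, N_ITEMS + 1)):
            raise ValueError(f"items must cover ids 1..{N_ITEMS} exactly once")
        for dx, n in self.class_sizes.items():
            if n < 0:
                raise ValueError(f"negative class size for {DiagnosticClass(dx).name}")

    @property
    def core_item_ids(self) -> list[int]:
        """Designated signal items, in ascending id order."""
        return sorted(s.item_id for s in self.items if s.role == "core")

    def total_size(self) -> int:
        return int(sum(self.class_sizes.values()))

    def to_json_dict(self) -> dict:
        return {
            "format_version": FORMAT_VERSION,
            "class_sizes": {dx.name: int(n) for dx, n in self.class_sizes.items()},
            "severity": {
                p.dx.name: {"pi": p.pi, "rho": p.rho}
                for p in self.severity.values()
            },
            "items": [
                {
                    "item_id": s.item_id,
                    "role": s.role,
                    "loading": s.loading,
                    "base_rate": s.base_rate,
                }
                for s in self.items
            ],
            "seed": int(self.seed),
            "comparator_moments": None
            if self.comparator_moments is None
            else {
                name: {dx.name: list(ms) for dx, ms in per_class.items()}
                for name, per_class in self.comparator_moments.items()
            },
            "demographics_moments": None
            if self.demographics_moments is None
            else {
                dx.name: {
                    "age": list(m["age"]),
                    "education": list(m["education"]),
                    "pct_female": m["pct_female"],
                }
                for dx, m in self.demographics_moments.items()
            },
        }

    @classmethod
    def from_json_dict(cls, doc: dict) -> "GeneratorSpec":
        severity = {
            DiagnosticClass[name]: ClassSeverityParams(
                DiagnosticClass[name], d["pi"], d["rho"]
            )
            for name, d in doc["severity"].items()
        }
        comp = doc.get("comparator_moments")
        demo = doc.get("demographics_moments")
        return cls(
            class_sizes={
                DiagnosticClass[name]: int(n)
                for name, n in doc["class_sizes"].items()
            },
            severity=severity,
            items=[ItemSpec(**d) for d in doc["items"]],
            seed=int(doc["seed"]),
            comparator_moments=None
            if comp is None
            else {
                name: {
                    DiagnosticClass[dxn]: tuple(ms) for dxn, ms in per_class.items()
                }
                for name, per_class in comp.items()
            },
            demographics_moments=None
            if demo is None
            else {
                DiagnosticClass[dxn]: {
                    "age": tuple(m["age"]),
                    "education": tuple(m["education"]),
                    "pct_female": float(m["pct_female"]),
                }
                for dxn, m in demo.items()
            },
        )

    def digest(self) -> str:
        """Stable short hash identifying this spec (used as provenance)."""
        payload = json.dumps(self.to_json_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_generator_spec(spec: GeneratorSpec, path: str | Path) -> None:
    Path(path).write_text(json.dumps(spec.to_json_dict(), indent=2) + "\n")


def read_generator_spec(path: str | Path) -> GeneratorSpec:
    return GeneratorSpec.from_json_dict(json.loads(Path(path).read_text()))


def calibrate_class_params(
    mean: float, sd: float, k: int, dx: DiagnosticClass = DiagnosticClass.NC
) -> ClassSeverityParams:
    """Method-of-moments inversion of the beta-binomial moment identities.

    Solves ``mean = k * pi`` and
    ``sd^2 = k * pi * (1 - pi) * (1 + (k - 1) * rho)`` for ``(pi, rho)``,
    clamping ``rho`` into ``[0, RHO_MAX]``: a slightly negative raw value
    (underdispersion, which the beta-binomial cannot represent) becomes 0.
    """
    if not (0.0 < mean < k):
        raise ValueError(f"mean must lie strictly inside (0, {k}), got {mean}")
    if sd <= 0:
        raise ValueError(f"sd must be positive, got {sd}")
    pi = mean / k
    binom_var = k * pi * (1 - pi)
    rho_raw = (sd * sd / binom_var - 1.0) / (k - 1)
    rho = min(max(rho_raw, 0.0), RHO_MAX)
    return ClassSeverityParams(dx=dx, pi=pi, rho=rho)


def _apportion(total: int, weights: list[int]) -> list[int]:
    """Largest-remainder apportionment of `total` across `weights`."""
    quotas = [total * w / sum(weights) for w in weights]
    floors = [int(math.floor(q)) for q in quotas]
    short = total - sum(floors)
    order = sorted(
        range(len(weights)), key=lambda i: quotas[i] - floors[i], reverse=True
    )
    for i in order[:short]:
        floors[i] += 1
    return floors


def default_paper_spec(group: str, seed: int) -> GeneratorSpec:
    """The study configuration: published class sizes and score moments.

    ``group="test"`` uses the printed test-group composition
    (53/91/108/386, total 638); ``group="train"`` sizes a 716-subject
    cohort at the same class proportions (the published account does not
    break the training group down by class). Severity parameters come
    from :func:`calibrate_class_params` applied to the per-class 12-item
    score moments; the item panel has 12 core items, 12 weak items with
    loadings drawn uniformly in [0.25, 0.6], and 21 distractors with
    base rates in [0.02, 0.15]. Item roles are assigned to shuffled item
    ids, and all draws are fixed by ``seed``.
    """
    if group not in ("test", "train"):
        raise ValueError("group must be 'test' or 'train'")
    classes = list(DiagnosticClass)
    if group == "test":
        sizes = dict(TEST_GROUP_SIZES)
    else:
        counts = _apportion(716, [TEST_GROUP_SIZES[c] for c in classes])
        sizes = dict(zip(classes, counts))

    severity = {
        dx: calibrate_class_params(m, s, k=12, dx=dx)
        for dx, (m, s) in SCORE_MOMENTS.items()
    }

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x17E35]))
    ids = rng.permutation(np.arange(1, N_ITEMS + 1))
    core_ids, weak_ids, distractor_ids = ids[:12], ids[12:24], ids[24:]
    items: list[ItemSpec] = []
    for i in core_ids:
        items.append(ItemSpec(int(i), "core", 1.0, 0.0))
    for i in weak_ids:
        items.append(
            ItemSpec(
                int(i),
                "weak",
                float(rng.uniform(0.25, 0.6)),
                float(rng.uniform(0.02, 0.15)),
            )
        )
    for i in distractor_ids:
        items.append(ItemSpec(int(i), "distractor", 0.0, float(rng.uniform(0.02, 0.15))))
    items.sort(key=lambda s: s.item_id)

    return GeneratorSpec(
        class_sizes=sizes,
        severity=severity,
        items=items,
        seed=int(seed),
        comparator_moments={k: dict(v) for k, v in COMPARATOR_MOMENTS.items()},
        demographics_moments={k: dict(v) for k, v in DEMOGRAPHICS_MOMENTS.items()},
    )


def _truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    lo: float,
    hi: float,
    size: int,
) -> np.ndarray:
    a = (lo - mean) / sd
    b = math.inf if math.isinf(hi) else (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(spec: GeneratorSpec) -> Cohort:
    """Draw one cohort from the generator model.

    Deterministic for a fixed spec (including seed). Each diagnostic
    class is generated from its own child random stream so that changing
    one class's size leaves the other classes' subjects unchanged.
    """
    order = sorted(spec.items, key=lambda s: s.item_id)
    loadings = np.array([s.loading for s in order])
    base_rates = np.array([s.base_rate for s in order])

    root = np.random.SeedSequence(int(spec.seed))
    children = root.spawn(len(DiagnosticClass))
    subjects: list[Subject] = []
    for dx, child in zip(DiagnosticClass, children):
        n = int(spec.class_sizes.get(dx, 0))
        if n == 0:
            continue
        rng = np.random.default_rng(child)
        params = spec.severity[dx]
        shape = params.beta_shape()
        if shape is None:
            p = np.full(n, params.pi)
        else:
            p = rng.beta(*shape, size=n)
        probs = p[:, None] * loadings[None, :] + (1 - loadings)[None, :] * base_rates[None, :]
        items = (rng.random((n, N_ITEMS)) < probs).astype(float)

        comparators_by_name: dict[str, np.ndarray] = {}
        if spec.comparator_moments:
            for name, per_class in spec.comparator_moments.items():
                if dx not in per_class:
                    continue
                mean, sd = per_class[dx]
                lo, hi = COMPARATOR_RANGES[name]
                draws = _truncated_normal(rng, mean, sd, lo, hi, n)
                hi_clip = hi if not math.isinf(hi) else np.inf
                comparators_by_name[name] = np.clip(np.round(draws), lo, hi_clip)

        ages = edus = sexes = None
        if spec.demographics_moments and dx in spec.demographics_moments:
            demo = spec.demographics_moments[dx]
            ages = np.round(
                _truncated_normal(rng, *demo["age"], *_AGE_RANGE, n)
            )
            edus = np.round(
                _truncated_normal(rng, *demo["education"], *_EDU_RANGE, n)
            )
            sexes = rng.random(n) < float(demo["pct_female"])

        for i in range(n):
            subjects.append(
                Subject(
                    subject_id=f"{dx.name}-{i + 1:05d}",
                    dx=dx,
                    items=items[i],
                    age=None if ages is None else float(ages[i]),
                    sex=None if sexes is None else ("female" if sexes[i] else "male"),
                    education=None if edus is None else float(edus[i]),
                    comparators={
                        name: float(vals[i])
                        for name, vals in comparators_by_name.items()
                    },
                )
            )
    return Cohort(subjects, provenance=f"generator:{spec.digest()}:seed={spec.seed}")
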