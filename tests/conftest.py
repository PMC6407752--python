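import numpy as np
import pytest

from nmdscreen import synthetic_cohort as sc
from nmdscreen.cohort_io import Cohort, DiagnosticClass, N_ITEMS, Subject


def make_subject(subject_id, dx, endorsed=(), missing=(), **kwargs):
    """Subject whose listed item ids are endorsed; the rest are 0."""
    items = np.zeros(N_ITEMS)
    for j in endorsed:
        items[j - 1] = 1.0
    for j in missing:
        items[j - 1] = np.nan
    return Subject(subject_id=subject_id, dx=dx, items=items, **kwargs)


@pytest.fixture
def tiny_cohort():
    """Eight handmade subjects, two per class, with optional fields."""
    subjects = [
        make_subject("nc1", DiagnosticClass.NC, endorsed=[], age=68, sex="female",
                     education=6, comparators={"MMSE": 28, "AD8": 0}),
        make_subject("nc2", DiagnosticClass.NC, endorsed=[3]),
        make_subject("mci1", DiagnosticClass.MCI, endorsed=[1, 2, 3],
                     comparators={"MMSE": 24, "AD8": 2}),
        make_subject("mci2", DiagnosticClass.MCI, endorsed=[1, 5, 7, 9]),
        make_subject("vmd1", DiagnosticClass.VMD, endorsed=list(range(1, 7))),
        make_subject("vmd2", DiagnosticClass.VMD, endorsed=list(range(1, 8)),
                     sex="male"),
        make_subject("dem1", DiagnosticClass.DEM, endorsed=list(range(1, 12))),
        make_subject("dem2", DiagnosticClass.DEM, endorsed=list(range(1, 13)),
                     age=81.5, sex="female", education=0,
                     comparators={"MMSE": 10, "AD8": 7, "NPI": 22}),
    ]
    return Cohort(subjects, provenance="tiny-fixture")


@pytest.fixture(scope="session")
def test_spec():
    """Study-condition generator spec for the 638-subject test group."""
    return sc.default_paper_spec("test", seed=1)


@pytest.fixture(scope="session")
def test_cohort(test_spec):
    return sc.generate_cohort(test_spec)


@pytest.fixture(scope="session")
def big_cohort():
    """5000 subjects per class, for moment-recovery checks."""
    spec = sc.default_paper_spec("test", seed=7)
    spec.class_sizes = {c: 5000 for c in DiagnosticClass}
    spec.comparator_moments = None
    spec.demographics_moments = None
    return spec, sc.generate_cohort(spec)
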