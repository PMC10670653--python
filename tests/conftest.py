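import numpy as np
import pytest

from setuperr import Cohort, GeneratorConfig, ScanRecord, SetupError6D, Timepoint
from setuperr.records import Anesthesia
from setuperr.synthetic import generate


def make_record(
    pid="P1",
    timepoint=Timepoint.PRECORRECTION,
    fraction=1,
    week=1,
    anesthesia=Anesthesia.AWAKE,
    dof=(0, 0, 0, 0, 0, 0),
    special=None,
):
    return ScanRecord(
        patient_id=pid,
        timepoint=timepoint,
        fraction=fraction,
        week=week,
        anesthesia=anesthesia,
        error=SetupError6D(*dof),
        special_condition=special,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Synthetic cohort of 20 patients, fixed seed."""
    cohort, truth = generate(GeneratorConfig(n_patients=20, seed=11))
    return cohort, truth


@pytest.fixture
def zero_cohort():
    """Two patients whose every error is identically zero."""
    records = [
        make_record(pid=p, fraction=f, week=1)
        for p in ("A", "B")
        for f in (1, 2, 3)
    ]
    return Cohort(records=records).validate()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
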