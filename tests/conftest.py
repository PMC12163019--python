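import numpy as np
import pytest

from zabedopk.structural_model import default_params
from zabedopk.synthetic_data import PopulationParams
from zabedopk.trial_data import (ConcentrationRecord, DoseEvent, Subject,
                                 TrialDataset)


@pytest.fixture(scope="session")
def params():
    """Calibrated typical-subject structural parameters."""
    return default_params()


@pytest.fixture(scope="session")
def quiet_population(params):
    """Population with no inter-individual or residual variability."""
    return PopulationParams(
        typical=params,
        omega={"cl_u": 0.0, "v": 0.0, "ka": 0.0, "f": 0.0},
        sigma_prop=0.0,
    )


@pytest.fixture()
def two_subject_dataset():
    """A tiny hand-built dataset with clean invariants."""
    ds = TrialDataset(study_tag="SAD", washout_days=14.0)
    for i, sid in enumerate(("S1", "S2")):
        ds.subjects.append(Subject(sid, agp_concentration=0.6))
        ds.doses[(sid, 1)] = [DoseEvent(0.0, 120.0, "oral", "tablet",
                                        "fasted", "120 mg SD")]
        ds.observations[(sid, 1)] = [
            ConcentrationRecord(0.0, None, "total", 0.001, blq_flag=True),
            ConcentrationRecord(1.0, 1.5 + 0.1 * i, "total", 0.001),
            ConcentrationRecord(4.0, 3.0 + 0.1 * i, "total", 0.001),
            ConcentrationRecord(24.0, 1.0, "total", 0.001),
            ConcentrationRecord(48.0, 0.5, "total", 0.001),
            ConcentrationRecord(96.0, None, "total", 0.001, blq_flag=True),
        ]
    return ds


def geomean(x):
    return float(np.exp(np.mean(np.log(np.asarray(x, dtype=float)))))
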