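import numpy as np
import pytest

from glytwin.series import GlucoseSeries
from glytwin.patient_sim import PatientProfile, VirtualPatientParams


def make_series(bgl, insulin=None, cho=None, mask=None, dt=15.0):
    bgl = np.asarray(bgl, dtype=float)
    n = len(bgl)
    return GlucoseSeries(
        np.arange(n) * dt, bgl,
        np.zeros(n) if insulin is None else np.asarray(insulin, float),
        np.zeros(n) if cho is None else np.asarray(cho, float),
        np.ones(n, dtype=bool) if mask is None else np.asarray(mask, bool))


@pytest.fixture
def series_factory():
    return make_series


@pytest.fixture
def quiet_patient():
    """Noiseless linear patient with passthrough meal absorption."""
    profile = PatientProfile(id="T1", age=68, sex="F", bmi=27,
                             target_band=(80.0, 160.0),
                             avg_cho_per_day=240.0, lifestyle="sedentary")
    params = VirtualPatientParams(true_w=(0.9, -1.5, 0.1),
                                  basal_glucose=130.0,
                                  process_noise_sd=0.0,
                                  measurement_noise_sd=0.0,
                                  cho_absorption_tau=0.0)
    return profile, params
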