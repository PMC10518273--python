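import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

from cartispec.records import SpectrumRecord
from cartispec.synthdata import CohortConfig, generate_cohort

#: Reported group means of human knee cartilage mechanics used as
#: generator ground truth throughout the suite.
GROUP_MEANS = {
    "normal": dict(E_eq_MPa=1.29, E_inst_MPa=19.12, E_dyn_MPa=9.42,
                   phase_deg=5.37, thickness_mm=2.37),
    "early_oa": dict(E_eq_MPa=0.74, E_inst_MPa=11.57, E_dyn_MPa=5.46,
                     phase_deg=6.12, thickness_mm=2.57),
    "advanced_oa": dict(E_eq_MPa=0.164, E_inst_MPa=1.67, E_dyn_MPa=1.517,
                        phase_deg=2.88, thickness_mm=2.27),
}


@pytest.fixture(scope="session")
def group_means():
    return GROUP_MEANS


def make_record(wavelengths, intensities, **overrides) -> SpectrumRecord:
    kwargs = dict(donor_id="D01", site="PT", sample_id="D01-PT-S1",
                  replicate=1, oarsi_grade=0)
    kwargs.update(overrides)
    return SpectrumRecord(np.asarray(wavelengths, float),
                          np.asarray(intensities, float), **kwargs)


@pytest.fixture(scope="session")
def small_cohort():
    """Two-site, six-donor cohort shared by classification tests."""
    cfg = CohortConfig(n_donors=6, sites=("PT", "TR"),
                       samples_per_site_per_donor=2, seed=3)
    return generate_cohort(cfg)
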