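import warnings

import numpy as np
import pytest

from dwcmr import PhantomConfig, StudyConfig, fit_adc, generate_phantom, run_study, trace_adc

warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def noise_free_study():
    return generate_phantom(PhantomConfig(snr=None, seed=11))


@pytest.fixture(scope="session")
def noisy_study():
    return generate_phantom(PhantomConfig(seed=7))


@pytest.fixture(scope="session")
def noise_free_trace(noise_free_study):
    st = noise_free_study
    maps = [fit_adc(st.b0, d, st.config.b_value) for d in st.dwi]
    return trace_adc(*maps)


@pytest.fixture(scope="session")
def noisy_trace(noisy_study):
    st = noisy_study
    maps = [fit_adc(st.b0, d, st.config.b_value) for d in st.dwi]
    return trace_adc(*maps)


@pytest.fixture(scope="session")
def study_report():
    """Full 11-subject study at the default conditions and SNR."""
    return run_study(StudyConfig(master_seed=0))


@pytest.fixture(scope="session")
def noise_free_report():
    """Full cohort in the perfect-data limit."""
    return run_study(StudyConfig(master_seed=0, phantom_template=PhantomConfig(snr=None)))


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    return 2.0 * (a & b).sum() / (a.sum() + b.sum())
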