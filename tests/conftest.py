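import numpy as np
import pytest

from t2compart import AcquisitionParams, FitConfig, PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def acq() -> AcquisitionParams:
    return AcquisitionParams()


@pytest.fixture(scope="session")
def fit_cfg() -> FitConfig:
    return FitConfig()


@pytest.fixture(scope="session")
def default_grid(fit_cfg):
    return fit_cfg.grid


@pytest.fixture(scope="session")
def small_phantom():
    """A small noisy phantom shared across tests (fit-free uses only)."""
    spec = PhantomSpec(
        shape=(14, 14, 8),
        lesion_center=(4.0, 7.0, 4.0),
        lesion_radius=2.5,
        flair_radius=1.5,
        ctv_margin=2.5,
        contralateral_radius=2.0,
        snr=200.0,
        seed=11,
    )
    return make_phantom(spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
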