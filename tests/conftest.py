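import numpy as np
import pytest

from kexlitmus import MechanismParams, TitrationDesign
from kexlitmus.simulate import DEFAULT_NU_GRID, snap_nu

# rates consistent with the ubiquitin-side conformational-selection analysis:
# k12 = 1280 s^-1, k21 pinned by k12+k21 = 20000 s^-1, k_minus = 2420 s^-1,
# K_d = 370 uM (k_plus derived)
K12_TRUE = 1280.0
K21_TRUE = 18720.0
KMINUS_TRUE = 2420.0
KD_TRUE = 3.7e-4
KPLUS_TRUE = KMINUS_TRUE * (K12_TRUE + K21_TRUE) / (KD_TRUE * K12_TRUE)

KOFF_TS_TRUE = 1430.0  # partner-side two-state unbinding rate


@pytest.fixture(scope="session")
def cs_params() -> MechanismParams:
    return MechanismParams.conf_selection(K12_TRUE, K21_TRUE, KPLUS_TRUE, KMINUS_TRUE)


@pytest.fixture(scope="session")
def ts_params() -> MechanismParams:
    return MechanismParams.two_state(KOFF_TS_TRUE / KD_TRUE, KOFF_TS_TRUE)


@pytest.fixture(scope="session")
def titration() -> TitrationDesign:
    """1 mM observed protein; partner titrated 0 to 1 mM."""
    return TitrationDesign(P0=1e-3, L0_series=(0.0, 2e-5, 5e-5, 1e-4, 2.5e-4, 5e-4, 1e-3))


@pytest.fixture(scope="session")
def snapped_nu_grid() -> tuple[float, ...]:
    return tuple(snap_nu(v, 0.06) for v in DEFAULT_NU_GRID)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)
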