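import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cypddi.params import (
    DAPACONAZOLE_DOG,
    DAPACONAZOLE_HUMAN,
    DOG_PHYSIOLOGY,
    HUMAN_PHYSIOLOGY,
    KIN_PER_H,
    KOUT_PER_H,
    VSAC_L_KG,
    VSS_L_KG,
)
from cypddi.pbpk import DoseRegimen, PBPKModelSpec

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def dog_spec() -> PBPKModelSpec:
    """Qualified dog model at the 2 mg/kg clearance."""
    return PBPKModelSpec(
        vss=VSS_L_KG,
        vsac=VSAC_L_KG,
        kin=KIN_PER_H,
        kout=KOUT_PER_H,
        compound=DAPACONAZOLE_DOG,
        physiology=DOG_PHYSIOLOGY,
        cl_iv=543.5 * 0.06,
    )


@pytest.fixture(scope="session")
def human_spec() -> PBPKModelSpec:
    """Human model from allometric scaling of the dog parameters."""
    return PBPKModelSpec(
        vss=VSS_L_KG,
        vsac=VSAC_L_KG,
        kin=KIN_PER_H,
        kout=KOUT_PER_H,
        compound=DAPACONAZOLE_HUMAN,
        physiology=HUMAN_PHYSIOLOGY,
        cl_iv=35.5,
    )


@pytest.fixture(scope="session")
def q8h_regimen() -> DoseRegimen:
    """500 mg IV every 8 h over the 60-h DDI protocol."""
    return DoseRegimen(amount=500.0, n_doses=8, interval=8.0)


@pytest.fixture(scope="session")
def dense_dog_grid() -> np.ndarray:
    return np.unique(
        np.concatenate([np.linspace(0.0, 12.0, 241), np.linspace(12.0, 120.0, 217)])
    )
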