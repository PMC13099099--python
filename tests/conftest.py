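import numpy as np
import pytest

from trixrd import (
    CalibrationFit,
    CompositionVector,
    GenerativeParams,
    RIRSet,
    forward_expected_intensities,
)

# Published-instrument parameter values used in worked examples:
# k2 = 3.51, k3 = 1.49, kappa = 43.1, var_k2 = 0.094, var_k3 = 0.023,
# cov_k2k3 = 0.024.
PUB_K2, PUB_K3, PUB_KAPPA = 3.51, 1.49, 43.1
PUB_VAR_K2, PUB_VAR_K3, PUB_COV = 0.094, 0.023, 0.024


@pytest.fixture
def pub_rirs() -> RIRSet:
    return RIRSet.from_values(PUB_K2, PUB_K3)


@pytest.fixture
def pub_fit() -> CalibrationFit:
    return CalibrationFit.from_values(
        PUB_K2, PUB_K3, PUB_KAPPA, PUB_VAR_K2, PUB_VAR_K3, PUB_COV
    )


@pytest.fixture
def mix_50_25_25() -> CompositionVector:
    return CompositionVector(np.array([0.5, 0.25, 0.25]))


@pytest.fixture
def worked_heights(mix_50_25_25, pub_rirs) -> np.ndarray:
    """Noise-free forward intensities of the 50/25/25 mixture at Lambda=3000."""
    return forward_expected_intensities(
        mix_50_25_25, GenerativeParams(pub_rirs, PUB_KAPPA, 3000.0)
    )
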