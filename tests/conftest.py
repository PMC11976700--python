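import numpy as np
import pytest

from halocat.indicator_assay import AssayScenario, BufferSpec, IndicatorCalibration


@pytest.fixture
def calibration() -> IndicatorCalibration:
    return IndicatorCalibration(pka_apparent=7.10, ratio_acid=0.10, ratio_base=2.00)


@pytest.fixture
def scenario(calibration) -> AssayScenario:
    """Default read-mixture scenario: 2 mM sample buffer quenched 1:1."""
    return AssayScenario(
        buffer=BufferSpec(total_conc=1.0, pka_apparent=7.20, initial_ph=7.00),
        calibration=calibration,
        substrate0=10.0,
        dilution_factor=2.0,
    )


@pytest.fixture
def sampling_times() -> np.ndarray:
    """The discontinuous sampling schedule used for initial rates."""
    return np.array([30.0, 60.0, 180.0, 270.0, 360.0])
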