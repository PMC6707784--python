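import pytest

from plmox.calibration import CalibrationSet
from plmox.decay import GateConfig
from plmox.synthetic import SensorModel, SyntheticGroundTruth


@pytest.fixture(scope="session")
def sensor() -> SensorModel:
    return SensorModel()


@pytest.fixture(scope="session")
def cal_set(sensor) -> CalibrationSet:
    """Exact (noise-free) calibration curves at the four standard temperatures."""
    return sensor.calibration_set()


@pytest.fixture(scope="session")
def gate() -> GateConfig:
    return GateConfig()


@pytest.fixture()
def flat_truth(sensor) -> SyntheticGroundTruth:
    """Constant-Po2 capillary (no RBC traffic): Po2 pinned at 42 mmHg, 37 degC."""
    return SyntheticGroundTruth(
        po2_inter_mmHg=42.0,
        eat_peak_mmHg=42.0,
        temperature_c=37.0,
        flux_per_s=0.0,
        velocity_mm_s=0.0,
        sensor=sensor,
    )
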