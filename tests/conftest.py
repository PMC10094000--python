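import numpy as np
import pytest

from enoseml.data import LIQUOR_CLASSES, LIQUOR_LABELS, Measurement, MeasurementSet
from enoseml.synthetic import SyntheticConfig, simulate_protocol


@pytest.fixture(scope="session")
def protocol_set() -> MeasurementSet:
    """One full synthetic acquisition protocol (2025 measurements)."""
    return simulate_protocol(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def small_protocol_set() -> MeasurementSet:
    """A reduced protocol (5 days x 9 classes x 2 replicates = 90)."""
    return simulate_protocol(SyntheticConfig(seed=2, days=5, replicates_per_day=2))


def make_measurement(
    values: np.ndarray | float = 2.0,
    label: str = "BL13",
    day: int = 1,
    replicate: int = 1,
    mid: str = "m1",
) -> Measurement:
    if np.isscalar(values):
        values = np.full((100, 10), float(values))
    return Measurement(
        responses=values,
        liquor=LIQUOR_CLASSES[label],
        day=day,
        replicate=replicate,
        id=mid,
    )


@pytest.fixture
def tiny_set() -> MeasurementSet:
    rng = np.random.default_rng(0)
    mset = MeasurementSet()
    for i, label in enumerate(LIQUOR_LABELS[:2]):
        mset.add(
            make_measurement(
                rng.uniform(0.5, 3.0, size=(100, 10)), label=label, mid=f"m{i}"
            )
        )
    return mset
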