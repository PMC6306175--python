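import numpy as np
import pandas as pd
import pytest

from fibersims.io import IonCube, SpotTable


@pytest.fixture
def small_cube() -> IonCube:
    """Deterministic 5x5x2 cube with intensities in 0..20."""
    rng = np.random.default_rng(7)
    return IonCube(
        intensities=rng.integers(0, 21, size=(5, 5, 2)),
        pixel_size_um=0.2,
        level_depths_um=np.array([0.0, 0.15]),
    )


def make_random_cube(seed: int, shape=(8, 8, 4), high=30) -> IonCube:
    rng = np.random.default_rng(seed)
    return IonCube(
        intensities=rng.integers(0, high, size=shape),
        pixel_size_um=0.2,
        level_depths_um=np.arange(shape[2]) * 0.15,
    )


@pytest.fixture
def four_sample_table() -> SpotTable:
    """4 samples x 4 conditions x 20 locations with known condition means."""
    means = {"initial": 5.0, "washed": 1.0, "incubated_4d": 3.5, "incubated_10d": 3.7}
    rows = []
    rng = np.random.default_rng(11)
    for sample in "ABCD":
        for condition, mean in means.items():
            for loc in range(1, 21):
                ref = 100.0 * (1 + 0.05 * rng.standard_normal())
                rows.append(
                    {
                        "sample_id": sample,
                        "condition": condition,
                        "location_id": loc,
                        "analyte_intensity": mean * ref,
                        "reference_intensity": ref,
                    }
                )
    return SpotTable(pd.DataFrame(rows))
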