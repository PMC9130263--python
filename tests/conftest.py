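import pandas as pd
import pytest

from budqs import SimulationConfig
from budqs.patterns import PatternTally


@pytest.fixture
def zero_noise_config() -> SimulationConfig:
    """Small deterministic study with all noise sources off."""
    return SimulationConfig(
        seed=11,
        cells_per_window=100,
        angle_noise_sd_deg=0.0,
        count_noise_cv=0.0,
        area_noise_cv=0.0,
    )


@pytest.fixture
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=42)


def make_tally(
    counts: dict,
    condition: str = "low_nitrogen",
    window: int = 0,
    n_sites: int = 2,
) -> PatternTally:
    full = {"axial": 0, "bipolar": 0, "unipolar": 0} | counts
    return PatternTally(
        condition=condition, window=window, n_sites=n_sites, counts=full
    )


@pytest.fixture
def growth_table() -> pd.DataFrame:
    rows = []
    for t, cds in [(0, (1e3, 1e3, 1e3)), (10, (1.8e4, 1.9e4, 1.85e4)),
                   (20, (2.0e5, 2.1e5, 2.02e5)), (30, (1.8e5, 1.9e5, 1.85e5))]:
        for rep, cd in zip("ABC", cds):
            rows.append({"time_h": float(t), "replicate": rep, "measured_cd": cd})
    return pd.DataFrame(rows)
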