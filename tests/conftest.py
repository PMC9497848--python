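from __future__ import annotations

import numpy as np
import pytest

from movesync.datatypes import CouplingInterval, DyadTimeSeries
from movesync.synthetic import DyadConfig, generate_coupled_dyad


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240)


@pytest.fixture
def noise_dyad(rng) -> DyadTimeSeries:
    """Independent white-noise members, 900 frames."""
    return DyadTimeSeries(a=rng.uniform(0, 30, 900), b=rng.uniform(0, 30, 900),
                          dyad_id="noise")


@pytest.fixture
def coupled_dyad() -> DyadTimeSeries:
    """Burst dyad with one strong coupling interval at lag 20."""
    cfg = DyadConfig(length_frames=3000, noise_sd=0.5)
    schedule = [CouplingInterval(800, 1700, 20, 1.0, 1)]
    return generate_coupled_dyad(cfg, schedule, seed=11, dyad_id="coupled")
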