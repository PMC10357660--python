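import numpy as np
import pytest
from dataclasses import replace

from evocpm.environment import GradientField, peak_coordinate
from evocpm.io_config import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def small_config(**overrides) -> SimulationConfig:
    """A desk-scale configuration; physics parameters keep their
    canonical values unless overridden."""
    base = dict(L=60, tau_s=4000, init_population=4, d_scale=10.0,
                seasons=3)
    base.update(overrides)
    return replace(SimulationConfig(), **base)


def uniform_field(L: int, value: int = 3) -> GradientField:
    """A flat field: no chemotactic information anywhere."""
    return GradientField(values=np.full((L, L), value, dtype=np.int32),
                         peak_side="up", peak=peak_coordinate(L, "up"),
                         k_chi=5.0, d_max=float(np.hypot(L - 1, L // 2)))
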