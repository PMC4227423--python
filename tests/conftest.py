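import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from crosspath import SimulationConfig


@pytest.fixture
def small_config() -> SimulationConfig:
    """Desk-scale simulation used by most module tests."""
    return SimulationConfig(
        n_genes=300,
        n_samples_per_group_per_platform=8,
        de_fraction=0.1,
        effect_size=2.0,
        ppi_edge_count=500,
        seed=11,
    )
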