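import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/oracles.py

from panplast.simulate import SimulationSpec, simulate_pangenome


@pytest.fixture(scope="session")
def planted_pangenome():
    """The default planted pangenome: 30 genomes, 300/300/400 families."""
    return simulate_pangenome(SimulationSpec(seed=11))


@pytest.fixture(scope="session")
def island_pangenome():
    """Persistent backbone with planted cloud islands (one below the 3 kb rule)."""
    spec = SimulationSpec(
        n_genomes=8,
        n_persistent=150,
        n_shell=0,
        n_cloud=0,
        rgp_islands=((5, 5200), (6, 7000), (4, 2100)),
        p_island=0.5,
        seed=5,
    )
    return simulate_pangenome(spec)
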