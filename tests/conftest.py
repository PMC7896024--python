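import numpy as np
import pytest

from fibertopo.energy import EnergyParams
from fibertopo.fixtures import canonical_fiber
from fibertopo.geometry import CoreTemplate


@pytest.fixture(scope="session")
def template():
    return CoreTemplate()


@pytest.fixture(scope="session")
def energy_params():
    return EnergyParams()


@pytest.fixture(scope="session")
def t2_fiber():
    """Canonical face-stacked two-start fiber (L = 20 bp, 8-mer)."""
    return canonical_fiber("T2", n_nucleosomes=8)


@pytest.fixture(scope="session")
def t1_fiber():
    """Canonical open two-start zigzag (L = 25 bp, 8-mer)."""
    return canonical_fiber("T1", n_nucleosomes=8)


@pytest.fixture(scope="session")
def nrl187_t2_12mer():
    """Energetically optimal two-start fiber at NRL 187 (L = 40 bp),
    rebuilt as a 12-mer."""
    from fibertopo.geometry import FiberSpec, regular_fiber
    from fibertopo.search import optimize_regular_fiber

    best = optimize_regular_fiber(FiberSpec(L=40, n_nucleosomes=8),
                                  starts=8, seed=3)[0]
    return regular_fiber(FiberSpec(L=40, n_nucleosomes=12),
                         best.linker_step,
                         template=best.conformation.template)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
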