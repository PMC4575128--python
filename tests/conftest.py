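import numpy as np
import pytest

import ssrdiv as sd


@pytest.fixture
def tiny_matrix() -> sd.AlleleMatrix:
    """2 individuals x 2 loci: one heterozygote, one missing call."""
    calls = np.array(
        [
            [[150, 150], [98, 98]],
            [[150, 156], [-1, -1]],
        ]
    )
    return sd.AlleleMatrix(["ind1", "ind2"], ["L1", "L2"], calls)


@pytest.fixture
def two_pop_matrix() -> tuple[sd.AlleleMatrix, sd.PopulationMap]:
    """Perfectly structured toy data: pop1 fixed A/A, pop2 fixed B/B."""
    calls = np.array(
        [
            [[100, 100]],
            [[100, 100]],
            [[200, 200]],
            [[200, 200]],
        ]
    )
    m = sd.AlleleMatrix(["a1", "a2", "b1", "b2"], ["L1"], calls)
    pm = sd.PopulationMap({"a1": "p1", "a2": "p1", "b1": "p2", "b2": "p2"})
    return m, pm


@pytest.fixture(scope="session")
def default_panel():
    """Default synthetic panel (86 individuals, 43 loci, 6 populations)."""
    return sd.simulate(sd.SimConfig(seed=42))


@pytest.fixture(scope="session")
def small_panel():
    """Small 3-population panel for faster integration checks."""
    cfg = sd.SimConfig(
        pop_sizes=(12, 12, 12), n_loci=20, divergence_f=0.3, seed=7
    )
    return sd.simulate(cfg)
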