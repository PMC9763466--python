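import numpy as np
import pytest

from ctdna.simulate import (
    SimulationConfig,
    build_ancestral_ctdna,
    simulate_population,
)


@pytest.fixture(scope="session")
def ancestor():
    """Ancestral reference: repeats identical, genes intact."""
    return build_ancestral_ctdna(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_population():
    """One evolved population shared by read-free tests (seed fixed)."""
    cfg = SimulationConfig(seed=3, n_accessions=10, n_homoplasy=1)
    ref, pop = simulate_population(cfg)
    return cfg, ref, pop


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def mutate_window(refmap, edits):
    """Reference window with point edits {1-based position: base}."""
    seq = list(refmap.sequence)
    for pos, base in edits.items():
        seq[pos - 1] = base
    return "".join(seq)
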