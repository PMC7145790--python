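import numpy as np
import pytest

import enwas


@pytest.fixture(scope="session")
def path3():
    """Three areas in a line: a - b - c."""
    return enwas.AreaGraph.from_edges(["a", "b", "c"], [("a", "b"), ("b", "c")])


@pytest.fixture(scope="session")
def lattice16():
    return enwas.simulate_graph(16, "lattice", seed=0)


@pytest.fixture(scope="session")
def planar60():
    return enwas.simulate_graph(60, "random-planar", seed=42)


@pytest.fixture(scope="session")
def small_region():
    """A small but complete synthetic region reused across read-only tests."""
    return enwas.synthesize_region(n_areas=60, n_vars=8, n_causal=2, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
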