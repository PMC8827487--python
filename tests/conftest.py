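import numpy as np
import pytest

from ccd2pi.fixtures import FixtureSpec, make_benchmark_set, make_toy_surface
from ccd2pi.pipeline import run_benchmark


@pytest.fixture(scope="session")
def benchmark_result():
    """Idealized synthetic benchmark run end-to-end (cross-docking included).

    Session-scoped: the 8-protein cross-docking dominates suite runtime and is
    reused by the end-to-end, NIP and pipeline tests.
    """
    return run_benchmark(spec=FixtureSpec(seed=1), seed=1)


@pytest.fixture(scope="session")
def benchmark():
    return make_benchmark_set(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def toy_surface():
    """Spherical toy surface with a designed 20-residue cap interface."""
    return make_toy_surface(n_residues=120, interface_size=20)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
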