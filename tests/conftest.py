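import numpy as np
import pytest

import coccotopo as ct


@pytest.fixture(scope="session")
def default_params():
    return ct.PopulationParams()


@pytest.fixture(scope="session")
def large_coccolith_table(default_params):
    """10^5 synthetic coccoliths for law-of-large-numbers checks."""
    return ct.generate_coccoliths(default_params, 100_000, seed=2024)


@pytest.fixture(scope="session")
def coccosphere_table(default_params):
    """10^4 synthetic coccospheres with coverage-consistent counts."""
    return ct.generate_coccospheres(default_params, 10_000, seed=2024)


@pytest.fixture(scope="session")
def table1_outline_population():
    """300 coccolith outlines drawn at the observed population ratios."""
    rng = np.random.default_rng(7)
    n = 300
    dsl = np.clip(rng.normal(3.04, 0.40, n), 2.05, 4.38)
    rd = np.clip(rng.normal(0.81, 0.07, n), 0.62, 0.99)
    ro = np.clip(rng.normal(0.19, 0.02, n), 0.15, 0.25)
    return [ct.CoccolithOutline(d, d * r1, d * r2) for d, r1, r2 in zip(dsl, rd, ro)]


@pytest.fixture(scope="session")
def polyhedra_by_faces():
    """Exhaustive cubic planar graph lists per face count, memoised per session."""

    def get(f: int):
        return ct.cubic_planar_graphs(f)

    return get
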