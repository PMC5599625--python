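import numpy as np
import pytest

from synaptonet import (
    BaselineDensities,
    NetworkComposition,
    build_baseline,
)


@pytest.fixture(scope="session")
def culture_composition():
    """The full-size culture model: 1200 cells, 35% interneurons."""
    return NetworkComposition(n_total=1200, inhibitory_fraction=0.35)


@pytest.fixture(scope="session")
def toy_composition():
    """20 neurons (13 exc / 7 inh) for brute-force Monte-Carlo checks."""
    return NetworkComposition(n_total=20, inhibitory_fraction=0.35)


@pytest.fixture(scope="session")
def toy_densities():
    return BaselineDensities(
        in_degree={"EE": 8.0, "EI": 8.0, "IE": 4.0, "II": 4.0},
        mean_multiplicity={t: 2.0 for t in ("EE", "EI", "IE", "II")},
    )


@pytest.fixture(scope="session")
def toy_matrix(toy_composition, toy_densities):
    return build_baseline(toy_composition, toy_densities, seed=11)


@pytest.fixture(scope="session")
def baseline_matrix(culture_composition):
    """One full-size baseline network (shared across read-only tests)."""
    return build_baseline(culture_composition, BaselineDensities(), seed=42)
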