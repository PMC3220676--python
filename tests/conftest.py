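import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import dendristab as ds


@pytest.fixture
def single_sphere_system():
    """One 2 Å dendrimer sphere alone in a 50 Å box."""
    cfg = ds.ParticleConfiguration(np.array([[25.0, 25.0, 25.0]]), (50, 50, 50))
    topo = ds.TopologyMap(np.array([0]), {0: "dendrimer"}, radius_of={0: 2.0})
    return cfg, topo


@pytest.fixture
def small_mixture():
    spec = ds.SolutionSpec(
        box=(40, 40, 40), n_dendrimer=3, n_anion=6, n_water=10, seed=7
    )
    return ds.gen_mixture(spec)


@pytest.fixture
def protein_mixture():
    spec = ds.SolutionSpec(
        box=(50, 50, 50), n_dendrimer=5, n_anion=10, n_water=60,
        protein=12.0, seed=11,
    )
    return ds.gen_mixture(spec)


def make_point_topology(species_list, **kwargs):
    """Topology of single-site molecules, one per entry of species_list."""
    n = len(species_list)
    return ds.TopologyMap(
        np.arange(n),
        {i: sp for i, sp in enumerate(species_list)},
        radius_of=kwargs.pop("radius_of", {i: 1.0 for i in range(n)}),
        **kwargs,
    )
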