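"""Hydrogen-bond detection, motif taxonomy and cluster extraction."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dendristab as ds
from dendristab.errors import DendristabError

from _oracles import brute_hbonds, dfs_components, enumerate_bridge_triplets
from conftest import make_point_topology


def _pair_system(separation, with_hydrogen=False, deviation_deg=0.0):
    """One donor(+optional H) molecule and one acceptor molecule.

    With a hydrogen, the acceptor is placed so the D-H⋯A arrangement
    deviates from linearity by exactly ``deviation_deg`` at the hydrogen.
    """
    box = (30.0, 30.0, 30.0)
    donor = np.array([10.0, 10.0, 10.0])
    if with_hydrogen:
        hyd = donor + np.array([1.0, 0.0, 0.0])
        ang = np.deg2rad(deviation_deg)
        acceptor = hyd + 1.9 * np.array([np.cos(ang), np.sin(ang), 0.0])
        coords = [donor, hyd, acceptor]
        topo = ds.TopologyMap(
            np.array([0, 0, 1]),
            {0: "dendrimer", 1: "anion"},
            donors=[(0, 1)],
            acceptors={2},
            radius_of={i: 1.0 for i in range(3)},
        )
    else:
        acceptor = donor + np.array([separation, 0.0, 0.0])
        coords = [donor, acceptor]
        topo = ds.TopologyMap(
            np.array([0, 1]),
            {0: "dendrimer", 1: "anion"},
            donors=[(0, None)],
            acceptors={1},
            radius_of={0: 1.0, 1: 1.0},
        )
    return ds.ParticleConfiguration(np.array(coords), box), topo


def test_bond_inside_cutoffs_detected():
    cfg, topo = _pair_system(2.9, with_hydrogen=True, deviation_deg=5.0)
    bonds = ds.detect_hbonds(cfg, topo)
    assert len(bonds) == 1
    assert bonds[0].distance == pytest.approx(
        np.sqrt((1 + 1.9 * np.cos(np.deg2rad(5))) ** 2
                + (1.9 * np.sin(np.deg2rad(5))) ** 2)
    )
    assert bonds[0].angle == pytest.approx(5.0, abs=1e-6)


def test_pair_beyond_distance_cutoff_rejected():
    cfg, topo = _pair_system(4.0)
    assert ds.detect_hbonds(cfg, topo) == []


def test_pair_beyond_angle_cutoff_rejected():
    cfg, topo = _pair_system(2.9, with_hydrogen=True, deviation_deg=45.0)
    assert ds.detect_hbonds(cfg, topo) == []


def test_no_donors_warns_and_returns_empty():
    cfg = ds.ParticleConfiguration(np.zeros((1, 3)), (10, 10, 10))
    topo = make_point_topology(["water"])
    with pytest.warns(UserWarning):
        assert ds.detect_hbonds(cfg, topo) == []


def test_detection_equals_all_triples_oracle_over_seeds():
    """Vectorized detection equals the brute-force all-triples filter, exactly."""
    for s in range(25):
        spec = ds.SolutionSpec(
            box=(30, 30, 30), n_dendrimer=4, n_anion=10, n_water=5,
            bridge_propensity=0.7, seed=2000 + s,
        )
        cfg, topo = ds.gen_bridged_solution(spec)
        got = {(b.donor_atom, b.acceptor_atom) for b in ds.detect_hbonds(cfg, topo)}
        assert got == brute_hbonds(cfg, topo)


def test_minimum_image_detection_across_boundary():
    box = (20.0, 20.0, 20.0)
    cfg = ds.ParticleConfiguration(np.array([[0.5, 10, 10], [19.0, 10, 10]]), box)
    topo = ds.TopologyMap(
        np.array([0, 1]), {0: "dendrimer", 1: "anion"},
        donors=[(0, None)], acceptors={1}, radius_of={0: 1.0, 1: 1.0},
    )
    bonds = ds.detect_hbonds(cfg, topo)
    assert len(bonds) == 1 and bonds[0].distance == pytest.approx(1.5)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def _bond(u, v):
    """Bare molecule-level bond for classification tests."""
    return ds.HBond(
        donor_atom=u, hydrogen=None, acceptor_atom=v,
        donor_molecule=u, acceptor_molecule=v, distance=3.0, angle=None,
    )


def test_anion_bonded_to_two_dendrimers_is_one_dad():
    topo = make_point_topology(["dendrimer", "dendrimer", "anion"])
    mc = ds.classify_and_count([_bond(0, 2), _bond(1, 2)], topo)
    assert mc.DA == 2 and mc.DAD == 1
    assert mc.dad_triplets == [(0, 2, 1)]


def test_anion_bridging_protein_and_dendrimer_is_one_pad():
    topo = make_point_topology(["protein", "dendrimer", "anion"])
    mc = ds.classify_and_count([_bond(0, 2), _bond(1, 2)], topo)
    assert mc.PA == 1 and mc.DA == 1 and mc.PAD == 1
    assert mc.pad_triplets == [(0, 2, 1)]


def test_pair_category_sum_equals_bond_count():
    topo = make_point_topology(
        ["protein", "dendrimer", "dendrimer", "anion", "anion", "water"]
    )
    bonds = [_bond(0, 3), _bond(1, 3), _bond(1, 2), _bond(2, 4), _bond(0, 1),
             _bond(1, 5)]
    mc = ds.classify_and_count(bonds, topo)
    assert mc.DD + mc.DA + mc.PD + mc.PA + mc.other == len(bonds)


def test_unknown_molecule_in_bond_raises():
    topo = make_point_topology(["dendrimer", "anion"])
    with pytest.raises(DendristabError, match="unknown molecule"):
        ds.classify_and_count([_bond(0, 7)], topo)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.data())
def test_triplet_counts_equal_exhaustive_enumeration(data):
    """Random bipartite-ish bond graphs (≤12 molecules) vs. exhaustive oracle."""
    n = data.draw(st.integers(3, 12))
    species_pool = ["dendrimer", "anion", "protein", "water"]
    species = [data.draw(st.sampled_from(species_pool)) for _ in range(n)]
    topo = make_point_topology(species)
    pairs = data.draw(
        st.lists(
            st.tuples(st.integers(0, n - 1), st.integers(0, n - 1)).filter(
                lambda p: p[0] != p[1]
            ),
            max_size=20,
        )
    )
    bonds = [_bond(u, v) for u, v in pairs]
    mc = ds.classify_and_count(bonds, topo, include_clusters=False)
    dad, pad = enumerate_bridge_triplets(pairs, dict(enumerate(species)))
    assert mc.DAD == len(dad) and mc.PAD == len(pad)
    # every bridge triplet's two pair bonds exist in the bond list
    mol_pairs = {frozenset(p) for p in pairs}
    for d1, a, d2 in mc.dad_triplets:
        assert frozenset((d1, a)) in mol_pairs and frozenset((d2, a)) in mol_pairs


def test_removing_bridge_anion_bonds_decreases_dad():
    topo = make_point_topology(["dendrimer", "dendrimer", "anion", "anion"])
    bonds = [_bond(0, 2), _bond(1, 2), _bond(0, 3), _bond(1, 3)]
    full = ds.classify_and_count(bonds, topo, include_clusters=False)
    pruned = ds.classify_and_count(
        [b for b in bonds if b.acceptor_molecule != 2], topo, include_clusters=False
    )
    assert full.DAD == 2 and pruned.DAD == 1


# ---------------------------------------------------------------------------
# clusters
# ---------------------------------------------------------------------------


def test_no_bonds_gives_all_singletons():
    topo = make_point_topology(["dendrimer"] * 4 + ["anion"] * 3)
    part = ds.cluster_components([], topo)
    assert part.sizes == [1] * 7


def test_chain_is_a_single_component():
    topo = make_point_topology(["dendrimer", "anion", "dendrimer", "anion",
                                "dendrimer"])
    part = ds.cluster_components([(0, 1), (1, 2), (2, 3), (3, 4)], topo)
    assert part.sizes[0] == 5


def test_species_restriction_drops_edges_through_excluded_nodes():
    topo = make_point_topology(["dendrimer", "water", "dendrimer"])
    part = ds.cluster_components(
        [(0, 1), (1, 2)], topo, include_species={"dendrimer"}
    )
    assert part.sizes == [1, 1]


@settings(max_examples=75, deadline=None, derandomize=True)
@given(st.data())
def test_partition_equals_dfs_oracle(data):
    n = data.draw(st.integers(1, 50))
    topo = make_point_topology(["dendrimer"] * n)
    edges = data.draw(
        st.lists(
            st.tuples(st.integers(0, n - 1), st.integers(0, n - 1)).filter(
                lambda p: p[0] != p[1]
            ),
            max_size=60,
        )
    )
    part = ds.cluster_components(edges, topo)
    assert set(part.components) == dfs_components(range(n), edges)
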