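"""Γ23 estimator: closed forms, oracle equivalence, burn-in, salt weighting,
and the exclusion-only reference model."""
import numpy as np
import pytest
from scipy import constants

import dendristab as ds
from dendristab.errors import DendristabError
from dendristab.preferential import _block_stderr, molecule_surface_distances

from _oracles import brute_gamma, grid_shell_volume
from conftest import make_point_topology


def _hand_built_frame():
    """Protein sphere R=2 at center; 2 cosolutes local, 10 waters bulk."""
    box = (60.0, 60.0, 60.0)
    coords = [[30.0, 30.0, 30.0]]  # protein
    coords += [[33.0, 30.0, 30.0], [30.0, 33.5, 30.0]]  # anions, surface dist 1, 1.5
    for k in range(10):  # waters far away
        coords.append([5.0 + 4.0 * k, 5.0, 5.0])
    cfg = ds.ParticleConfiguration(np.array(coords), box)
    topo = make_point_topology(
        ["protein"] + ["anion"] * 2 + ["water"] * 10,
        radius_of={0: 2.0, **{i: 0.5 for i in range(1, 13)}},
    )
    return cfg, topo


def test_closed_form_counts():
    cfg, topo = _hand_built_frame()
    g = ds.instantaneous_gamma(cfg, topo, ds.DomainPartition(8.0), "anion")
    # 2 local cosolutes, all 10 waters bulk, 0 local waters
    assert g == 2.0


def test_no_cosolute_gives_zero():
    cfg, topo = _hand_built_frame()
    g = ds.instantaneous_gamma(cfg, topo, ds.DomainPartition(8.0), "dendrimer")
    assert g == 0.0


def test_no_water_returns_local_count():
    box = (40.0, 40.0, 40.0)
    cfg = ds.ParticleConfiguration(
        np.array([[20.0, 20, 20], [23.0, 20, 20], [5.0, 5, 5]]), box
    )
    topo = make_point_topology(
        ["protein", "anion", "anion"], radius_of={0: 2.0, 1: 0.5, 2: 0.5}
    )
    g = ds.instantaneous_gamma(cfg, topo, ds.DomainPartition(8.0), "anion")
    assert g == 1.0


def test_local_water_without_bulk_water_is_an_error():
    box = (40.0, 40.0, 40.0)
    cfg = ds.ParticleConfiguration(np.array([[20.0, 20, 20], [23.0, 20, 20]]), box)
    topo = make_point_topology(["protein", "water"], radius_of={0: 2.0, 1: 0.5})
    with pytest.raises(DendristabError, match="bulk"):
        ds.instantaneous_gamma(cfg, topo, ds.DomainPartition(8.0), "anion")


def test_missing_protein_is_an_error(small_mixture):
    cfg, topo = small_mixture
    with pytest.raises(DendristabError, match="protein"):
        ds.instantaneous_gamma(cfg, topo, ds.DomainPartition(8.0), "anion")


def test_matches_brute_force_classifier_exactly():
    """Vectorized estimator equals the explicit double-loop oracle, exactly."""
    part = ds.DomainPartition(8.0)
    for s in range(12):
        spec = ds.SolutionSpec(
            box=(50, 50, 50), n_dendrimer=4, n_anion=8, n_water=40,
            protein=10.0, seed=900 + s,
        )
        cfg, topo = ds.gen_mixture(spec)
        for sp in ("anion", "dendrimer"):
            got = ds.instantaneous_gamma(cfg, topo, part, sp)
            assert got == brute_gamma(cfg, topo, part.cutoff, sp)


def test_partition_completeness(protein_mixture):
    cfg, topo = protein_mixture
    part = ds.DomainPartition(8.0)
    _, dmin, species = molecule_surface_distances(cfg, topo, part)
    for sp in ("anion", "water", "dendrimer"):
        n_total = len(topo.molecules_of_species(sp))
        sel = species == sp
        assert int((dmin[sel] <= 8.0).sum() + (dmin[sel] > 8.0).sum()) == n_total


class TestTimeSeries:
    def test_constant_series_has_zero_stderr(self):
        x = np.full(20, 3.7)
        assert _block_stderr(x, 5) == 0.0

    def test_burn_in_arithmetic(self):
        """burn_in 0.5 on per-frame values [9, 9, 1, 1] -> estimate 1."""
        frames = []
        box = (60.0, 60.0, 60.0)
        # 9 local anions in early frames, 1 in late frames; waters all bulk
        for i, n_local in enumerate([9, 9, 1, 1]):
            coords = [[30.0, 30.0, 30.0]]
            for k in range(9):
                near = k < n_local
                coords.append(
                    [33.0 + 0.1 * k, 30.0, 30.0] if near else [5.0 + 4 * k, 5.0, 5.0]
                )
            for k in range(5):
                coords.append([5.0 + 4 * k, 50.0, 5.0])
            frames.append(
                ds.ParticleConfiguration(np.array(coords), box, frame_index=i)
            )
        topo = make_point_topology(
            ["protein"] + ["anion"] * 9 + ["water"] * 5,
            radius_of={0: 2.0, **{i: 0.5 for i in range(1, 15)}},
        )
        series = ds.gamma_timeseries(
            frames, topo, ds.DomainPartition(8.0), "anion",
            burn_in_fraction=0.5, block_count=2,
        )
        assert series.estimate == 1.0
        assert np.allclose(series.per_frame, [9, 9, 1, 1])

    def test_all_frames_burned_is_an_error(self):
        cfg, topo = _hand_built_frame()
        with pytest.raises(DendristabError):
            ds.gamma_timeseries(
                [cfg, cfg], topo, ds.DomainPartition(8.0), "anion",
                burn_in_fraction=0.9, block_count=1,
            )

    def test_components_share_partitions(self, protein_mixture):
        cfg, topo = protein_mixture
        series = ds.gamma_timeseries(
            [cfg] * 4, topo, ds.DomainPartition(8.0), "anion",
            burn_in_fraction=0.0, block_count=2, components=("dendrimer",),
        )
        assert "dendrimer" in series.components
        direct = ds.instantaneous_gamma(
            cfg, topo, ds.DomainPartition(8.0), "dendrimer"
        )
        assert series.components["dendrimer"].estimate == direct


class TestSaltWeighting:
    def test_equal_weights(self):
        g = ds.salt_weighted_gamma(
            {"dendrimer": 1.0, "anion": -7.0}, {"dendrimer": 1, "anion": 1}
        )
        assert g == -3.0

    def test_single_species_identity(self):
        assert ds.salt_weighted_gamma({"anion": -7.0}, {"anion": 2.0}) == -7.0

    def test_presets_on_per_ion_values(self):
        """Per-ion Γ {dend: 1, anion: -7}: group weighting gives -0.6,
        formula-unit weighting -5.4; the experimental salt value is -0.2 ± 1,
        so the group weighting lies within its stated uncertainty."""
        comps = {"dendrimer": 1.0, "anion": -7.0}
        g_group = ds.salt_weighted_gamma(comps, ds.group_weights(4))
        g_stoich = ds.salt_weighted_gamma(comps, ds.stoichiometric_weights(4))
        assert np.isclose(g_group, (4 * 1 + 1 * (-7)) / 5)  # -0.6
        assert np.isclose(g_stoich, (1 * 1 + 4 * (-7)) / 5)  # -5.4
        assert abs(g_group - (-0.2)) < 1.0

    def test_missing_species_raises(self):
        with pytest.raises(DendristabError):
            ds.salt_weighted_gamma({"anion": -7.0}, {"dendrimer": 1.0})


class TestExclusionOnly:
    def test_vanishing_shell(self):
        assert ds.exclusion_only_gamma(0.0, 20.0, 0.18) == 0.0

    def test_sphere_closed_form(self):
        v_shell = 4 / 3 * np.pi * (25.0**3 - 20.0**3) * 1e-27  # L
        expected = -0.18 * constants.N_A * v_shell
        assert np.isclose(ds.exclusion_only_gamma(5.0, 20.0, 0.18), expected)

    def test_monotone_in_radius_linear_in_concentration(self):
        radii = [1.0, 2.0, 4.0, 8.0]
        vals = [ds.exclusion_only_gamma(r, 15.0, 0.1) for r in radii]
        assert all(a > b for a, b in zip(vals, vals[1:]))  # more negative
        g1 = ds.exclusion_only_gamma(3.0, 15.0, 0.1)
        g2 = ds.exclusion_only_gamma(3.0, 15.0, 0.2)
        assert np.isclose(g2, 2 * g1)

    def test_atom_set_monte_carlo_matches_grid_oracle(self):
        protein = {
            "coords": np.array([[0.0, 0, 0], [3.0, 0, 0], [1.5, 2.5, 0]]),
            "radii": np.array([2.0, 2.0, 2.0]),
        }
        got = ds.exclusion_only_gamma(
            2.0, protein, 0.18, n_samples=400_000, seed=1
        )
        v = grid_shell_volume(protein["coords"], protein["radii"], 2.0, spacing=0.1)
        expected = -0.18 * constants.N_A * v * 1e-27
        assert abs(got - expected) / abs(expected) < 0.02
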