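"""SASA sampling accuracy and the additive loss decomposition."""
import numpy as np
import pytest

import dendristab as ds
from dendristab.errors import DendristabError, TopologyValidationError
from dendristab.geometry import random_rotation_matrix

from _oracles import sampled_sphere_area
from conftest import make_point_topology


def test_isolated_sphere_matches_analytic_area(single_sphere_system):
    cfg, topo = single_sphere_system
    res = ds.sasa(cfg, topo, probe=1.4, n_points=960)
    exact = 4 * np.pi * 3.4**2
    assert abs(res.total - exact) / exact < 0.01


def test_separated_spheres_keep_isolated_areas():
    box = (80.0, 80.0, 80.0)
    cfg = ds.ParticleConfiguration(np.array([[20.0, 40, 40], [60.0, 40, 40]]), box)
    topo = make_point_topology(
        ["dendrimer", "dendrimer"], radius_of={0: 2.0, 1: 3.0}
    )
    res = ds.sasa(cfg, topo, probe=1.4, n_points=960)
    assert res.per_molecule[0] == pytest.approx(4 * np.pi * 3.4**2, rel=0.01)
    assert res.per_molecule[1] == pytest.approx(4 * np.pi * 4.4**2, rel=0.01)


def test_two_overlapping_spheres_match_dense_sampling_oracle():
    box = (60.0, 60.0, 60.0)
    sep = 4.0  # expanded radii 3.4 each -> strong overlap
    a = np.array([28.0, 30.0, 30.0])
    b = a + [sep, 0, 0]
    cfg = ds.ParticleConfiguration(np.array([a, b]), box)
    topo = make_point_topology(["dendrimer", "dendrimer"],
                               radius_of={0: 2.0, 1: 2.0})
    res = ds.sasa(cfg, topo, probe=1.4, n_points=960)
    oracle = sampled_sphere_area(a, 3.4, b, 3.4, n_samples=1_000_000, seed=3)
    assert abs(res.per_molecule[0] - oracle) / oracle < 0.005


def test_per_molecule_sums_to_total(small_mixture):
    cfg, topo = small_mixture
    res = ds.sasa(cfg, topo, n_points=240)
    assert res.total == pytest.approx(sum(res.per_molecule.values()))


def test_missing_radius_names_atom():
    cfg = ds.ParticleConfiguration(np.zeros((1, 3)) + 10, (20, 20, 20))
    topo = ds.TopologyMap(np.array([0]), {0: "dendrimer"}, radius_of={})
    with pytest.raises(TopologyValidationError, match="atom 0"):
        ds.sasa(cfg, topo, n_points=96)


def test_point_count_floor_enforced(single_sphere_system):
    cfg, topo = single_sphere_system
    with pytest.raises(ValueError):
        ds.sasa(cfg, topo, n_points=50)


def test_rigid_motion_invariance(small_mixture):
    """Global translation+rotation changes SASA by < 0.5 % per molecule."""
    cfg, topo = small_mixture
    R = random_rotation_matrix(np.random.default_rng(4))
    center = cfg.box / 2
    moved = (cfg.coords - center) @ R.T + center + 1.7
    big_box = cfg.box * 4  # remove periodic wrapping effects from the contrast
    cfg_a = ds.ParticleConfiguration(cfg.coords, big_box)
    cfg_b = ds.ParticleConfiguration(moved, big_box)
    ra = ds.sasa(cfg_a, topo, n_points=960)
    rb = ds.sasa(cfg_b, topo, n_points=960)
    assert rb.total == pytest.approx(ra.total, rel=0.005)
    # per-molecule errors on single-site molecules are individually noisier
    for m in ra.per_molecule:
        assert rb.per_molecule[m] == pytest.approx(ra.per_molecule[m], rel=0.02)


def test_more_points_reduce_analytic_error(single_sphere_system):
    cfg, topo = single_sphere_system
    exact = 4 * np.pi * 3.4**2
    errs = [
        abs(ds.sasa(cfg, topo, n_points=n).total - exact)
        for n in (96, 480, 1920)
    ]
    assert errs[0] >= errs[1] >= errs[2]


class TestDecomposition:
    def test_isolated_dendrimer_loses_nothing(self):
        spec = ds.SolutionSpec(box=(60, 60, 60), n_dendrimer=1, n_anion=0,
                               n_water=0, seed=0)
        cfg, topo = ds.gen_mixture(spec)
        df = ds.saa_loss_decomposition(cfg, topo, n_points=240)
        assert np.allclose(df.dsaa_total, 0.0)

    def test_additivity_is_exact_for_every_input(self):
        for s in range(5):
            spec = ds.SolutionSpec(
                box=(45, 45, 45), n_dendrimer=5, n_anion=10, n_water=0,
                bridge_propensity=0.8, seed=40 + s,
            )
            cfg, topo = ds.gen_bridged_solution(spec)
            df = ds.saa_loss_decomposition(cfg, topo, n_points=240)
            assert np.array_equal(
                df.dsaa_total.to_numpy(), (df.dsaa_dend + df.dsaa_ion).to_numpy()
            )
            # occluders only remove area
            assert np.all(df.saa_iso + 1e-9 >= df.saa_dend_only)
            assert np.all(df.saa_dend_only + 1e-9 >= df.saa_full)

    def test_printed_reference_rows_satisfy_the_bookkeeping(self):
        """The decomposition identities hold on the published per-salt areas
        (isolated-dendrimer area 1260 Å²)."""
        rows = {  # remaining SAA, Δdend, Δion
            "chloride-like": (993.0, 107.0, 160.0),
            "sulfate-like": (760.0, 342.0, 158.0),
            "phosphate-like": (533.0, 435.0, 292.0),
        }
        iso = 1260.0
        for full, d_dend, d_ion in rows.values():
            dend_only = iso - d_dend
            total, got_dend, got_ion = ds.saa_decompose(iso, dend_only, full)
            assert total == pytest.approx(iso - full)
            assert got_dend == pytest.approx(d_dend)
            assert got_ion == pytest.approx(d_ion)
            assert total == pytest.approx(d_dend + d_ion)

    def test_bridged_systems_bury_more_dendrimer_area(self):
        diffs = []
        for s in range(10):
            kw = dict(box=(55, 55, 55), n_dendrimer=6, n_anion=12, n_water=0,
                      seed=700 + s)
            mcfg, mtopo = ds.gen_mixture(ds.SolutionSpec(**kw))
            bcfg, btopo = ds.gen_bridged_solution(
                ds.SolutionSpec(bridge_propensity=0.9, **kw)
            )
            dm = ds.saa_loss_decomposition(mcfg, mtopo, n_points=240)
            db = ds.saa_loss_decomposition(bcfg, btopo, n_points=240)
            diffs.append(db.dsaa_dend.mean() - dm.dsaa_dend.mean())
        assert np.mean(diffs) > 0
        assert sum(d > 0 for d in diffs) >= 9

    def test_no_dendrimers_is_an_error(self):
        cfg = ds.ParticleConfiguration(np.zeros((1, 3)) + 5, (20, 20, 20))
        topo = make_point_topology(["water"])
        with pytest.raises(DendristabError):
            ds.saa_loss_decomposition(cfg, topo)
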