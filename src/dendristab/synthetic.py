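"""Synthetic solution and decay-curve generators.

These samplers emulate the statistical structure the analysis layer assumes:

* well-mixed solutions — every molecule placed uniformly at random with
  hard-core rejection (chloride-like behavior: no ion pairing);
* anion-bridged solutions — a tunable fraction of anions is placed at
  hydrogen-bond geometry between arm sites of one or two dendrimers,
  producing D-A-D bridges and growing hydrogen-bonded clusters
  (sulfate / dihydrogen-phosphate-like behavior);
* second-order monomer-loss curves with additive Gaussian noise.

The dendrimer is reduced to a rigid 5-site star: a core plus 4 guanidinium-
like arm sites (donors) 4 Å from the core, tetrahedral in the free pose.
Anions are single acceptor sites; water sites are featureless counters.
A protein is either a single sphere at the box center or a user-supplied
atom set.  When a protein is present the generators also emulate the two
binding modes the analyses discriminate: in well-mixed solutions a fraction
of dendrimers adopts a cooperative multi-arm surface pose, while in bridged
solutions dendrimers attach through a single anion-mediated arm with the
remaining arms facing the bulk.

Generators are single-shot samplers (no energy function, no propagation)
and are pure functions of their spec, including the seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import PlacementError
from .geometry import (
    minimum_image,
    pair_distances,
    random_rotation_matrix,
    random_unit_vector,
    rotation_aligning,
    wrap,
)
from .model_io import KineticsTable, ParticleConfiguration, TopologyMap

# site geometry / radii (Å) of the reduced model
ARM_LENGTH = 4.0
CORE_RADIUS = 2.0
ARM_RADIUS = 1.6
ANION_RADIUS = 1.3
WATER_RADIUS = 1.4
PROTEIN_RADIUS_DEFAULT = 20.0
#: donor-heavy-atom to acceptor distance used when placing hydrogen-bonded
#: anions; below the 3.5 Å detection cutoff and above the hard-core contact.
HBOND_PLACEMENT_DIST = 2.95

_TETRAHEDRON = np.array(
    [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float
) / np.sqrt(3.0)


@dataclass
class SolutionSpec:
    """Composition and behavior of one synthetic solution frame."""

    box: tuple = (50.0, 50.0, 50.0)
    n_dendrimer: int = 0
    n_anion: Optional[int] = None  # default: anions_per_dendrimer * n_dendrimer
    n_water: int = 0
    anions_per_dendrimer: int = 4  # 4 chloride-like, 2 sulfate-like
    bridge_propensity: float = 0.0
    protein: Optional[object] = None  # sphere radius (float) or (k,3)+radii dict
    protein_radius: float = PROTEIN_RADIUS_DEFAULT
    bound_fraction: float = 0.5  # mixture: fraction of dendrimers surface-bound
    pad_fraction: float = 0.5  # bridged+protein: bridges anchored to the protein
    point_solutes: bool = False  # anions/waters as interaction-free point sites
    seed: int = 0

    def __post_init__(self):
        if self.n_dendrimer < 0 or self.n_water < 0:
            raise ValueError("counts must be nonnegative")
        if self.n_anion is None:
            self.n_anion = self.n_dendrimer * self.anions_per_dendrimer
        if self.n_anion < 0:
            raise ValueError("counts must be nonnegative")
        if not 0.0 <= self.bridge_propensity <= 1.0:
            raise ValueError("bridge_propensity must lie in [0, 1]")
        self._check_density()

    def _check_density(self):
        box = np.asarray(self.box, float)
        vol = float(np.prod(box))
        v = (
            self.n_dendrimer
            * (CORE_RADIUS**3 + 4 * ARM_RADIUS**3)
            + self.n_anion * ANION_RADIUS**3
            + self.n_water * WATER_RADIUS**3
        ) * 4.0 / 3.0 * np.pi
        if self.protein is not None and np.isscalar(self.protein):
            v += 4.0 / 3.0 * np.pi * float(self.protein) ** 3
        if v / vol > 0.45:
            raise ValueError(
                f"packing fraction {v / vol:.2f} too close to hard-sphere packing; "
                "use a larger box or fewer molecules"
            )


# ---------------------------------------------------------------------------
# internal placement machinery
# ---------------------------------------------------------------------------


class _Builder:
    """Accumulates placed sites and enforces the inter-molecular hard core."""

    def __init__(self, box, rng, max_tries=2000):
        self.box = np.asarray(box, float)
        self.periodic = np.array([True, True, True])
        self.rng = rng
        self.max_tries = max_tries
        self.coords: list = []
        self.radii: list = []
        self.mol_of: list = []
        self.species: dict = {}
        self.donors: list = []
        self.acceptors: set = set()
        self.arms: dict = {}
        self.com: dict = {}
        self.next_mol = 0

    def _clashes(self, pts, radii):
        if not self.coords:
            return False
        placed = np.asarray(self.coords)
        placed_r = np.asarray(self.radii)
        d = pair_distances(np.atleast_2d(pts), placed, self.box, self.periodic)
        need = np.add.outer(np.atleast_1d(radii), placed_r)
        return bool(np.any(d < need - 1e-9))

    def _commit(self, pts, radii, species, donor_sites=(), acceptor_sites=(),
                arm_groups=None, com_group=None):
        mol = self.next_mol
        self.next_mol += 1
        start = len(self.coords)
        pts = np.atleast_2d(pts)
        for p, r in zip(pts, np.atleast_1d(radii)):
            self.coords.append(np.asarray(p, float))
            self.radii.append(float(r))
            self.mol_of.append(mol)
        self.species[mol] = species
        for k in donor_sites:
            self.donors.append((start + k, None))
        for k in acceptor_sites:
            self.acceptors.add(start + k)
        if arm_groups is not None:
            self.arms[mol] = [[start + k for k in grp] for grp in arm_groups]
        if com_group is not None:
            self.com[mol] = [start + k for k in com_group]
        return mol, start

    def place_uniform_site(self, radius, species, donor=False, acceptor=False):
        for _ in range(self.max_tries):
            p = self.rng.uniform(0.0, self.box)
            if not self._clashes(p, radius):
                return self._commit(
                    p, radius, species,
                    donor_sites=(0,) if donor else (),
                    acceptor_sites=(0,) if acceptor else (),
                )
        raise PlacementError(
            f"could not place a {species} site after {self.max_tries} tries; "
            "the box is too dense — use a larger box"
        )

    def _star_sites(self, core, arm_dirs):
        return np.vstack([core, core + ARM_LENGTH * arm_dirs])

    def try_place_star(self, core, arm_dirs):
        pts = self._star_sites(core, arm_dirs)
        radii = np.array([CORE_RADIUS] + [ARM_RADIUS] * 4)
        if self._clashes(pts, radii):
            return None
        mol, start = self._commit(
            pts, radii, "dendrimer",
            donor_sites=(1, 2, 3, 4),
            arm_groups=[[1], [2], [3], [4]],
            com_group=[0],
        )
        return mol, pts

    def place_star_uniform(self):
        for _ in range(self.max_tries):
            core = self.rng.uniform(0.0, self.box)
            R = random_rotation_matrix(self.rng)
            out = self.try_place_star(core, _TETRAHEDRON @ R.T)
            if out is not None:
                return out
        raise PlacementError(
            f"could not place a dendrimer after {self.max_tries} tries; "
            "the box is too dense — use a larger box"
        )

    def finish(self, frame_index=0, frame_interval=None):
        coords = wrap(np.asarray(self.coords), self.box, self.periodic)
        config = ParticleConfiguration(
            coords, self.box, self.periodic, frame_index=frame_index
        )
        radius_of = {i: r for i, r in enumerate(self.radii)}
        topo = TopologyMap(
            molecule_of=np.asarray(self.mol_of, int),
            species_of=dict(self.species),
            donors=list(self.donors),
            acceptors=set(self.acceptors),
            radius_of=radius_of,
            arms=dict(self.arms),
            com_group_of=dict(self.com),
            frame_interval=frame_interval,
        )
        return config, topo


def _add_protein(builder: _Builder, spec: SolutionSpec):
    """Place the protein at the box center; sphere or explicit atom set."""
    if spec.protein is None:
        return None
    center = builder.box / 2.0
    if np.isscalar(spec.protein):
        R = float(spec.protein)
        builder._commit(center, R, "protein", donor_sites=(0,), acceptor_sites=(0,))
        return ("sphere", center, R)
    atoms = np.asarray(spec.protein["coords"], float)
    radii = np.asarray(spec.protein["radii"], float)
    pts = atoms - atoms.mean(axis=0) + center
    n = len(pts)
    builder._commit(
        pts, radii, "protein",
        donor_sites=tuple(range(n)), acceptor_sites=tuple(range(n)),
    )
    return ("atoms", pts, radii)


def _surface_point(protein_info, direction, offset):
    """Point at `offset` beyond the protein surface along `direction`."""
    kind, a, b = protein_info
    if kind == "sphere":
        return a + (b + offset) * direction
    # atom set: walk out from the centroid past the farthest-reaching atom
    center = a.mean(axis=0)
    proj = (a - center) @ direction + b  # signed reach of each expanded sphere
    return center + (proj.max() + offset) * direction


def _bound_star_pose(builder, protein_info, rng):
    """Cooperative pose: core just off the surface, all 4 arms tilted toward it."""
    u = random_unit_vector(rng)  # outward surface normal at the contact point
    core = _surface_point(protein_info, u, CORE_RADIUS + 3.0)
    dirs = []
    base = rotation_aligning(np.array([0.0, 0.0, 1.0]), -u)
    spin0 = rng.uniform(0, 2 * np.pi)
    for k in range(4):
        theta = np.deg2rad(rng.uniform(35.0, 55.0))  # tilt from the inward normal
        phi = spin0 + k * np.pi / 2 + rng.uniform(-0.2, 0.2)
        v = np.array(
            [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
        )
        dirs.append(base @ v)
    return core, np.array(dirs)


def _anchored_star_pose(builder, protein_info, rng):
    """Bridged pose: anion at the surface, one arm bonded to it, arms outward.

    Returns (anion_pos, core, arm_dirs) with arm 0 ending HBOND_PLACEMENT_DIST
    from the anion.
    """
    u = random_unit_vector(rng)
    anion = _surface_point(protein_info, u, ANION_RADIUS + 0.4)
    tip = anion + HBOND_PLACEMENT_DIST * u
    core = tip + ARM_LENGTH * u  # arm 0 points back toward the anion/protein
    base = rotation_aligning(np.array([0.0, 0.0, 1.0]), u)
    dirs = [-u]
    spin0 = rng.uniform(0, 2 * np.pi)
    for k in range(3):
        theta = np.deg2rad(rng.uniform(20.0, 60.0))  # tilt from the outward normal
        phi = spin0 + k * 2 * np.pi / 3 + rng.uniform(-0.2, 0.2)
        v = np.array(
            [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
        )
        dirs.append(base @ v)
    return anion, core, np.array(dirs)


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------


def gen_mixture(spec: SolutionSpec):
    """Well-mixed (chloride-like) solution: uniform placement, hard-core rejection.

    With a protein present, ``round(bound_fraction * n_dendrimer)`` dendrimers
    adopt the cooperative multi-arm surface pose; the rest are uniform.
    """
    rng = np.random.default_rng(spec.seed)
    builder = _Builder(spec.box, rng)
    protein_info = _add_protein(builder, spec)

    n_bound = (
        int(round(spec.bound_fraction * spec.n_dendrimer))
        if protein_info is not None
        else 0
    )
    for i in range(spec.n_dendrimer):
        if i < n_bound:
            placed = None
            for _ in range(builder.max_tries):
                core, dirs = _bound_star_pose(builder, protein_info, rng)
                placed = builder.try_place_star(core, dirs)
                if placed is not None:
                    break
            if placed is None:
                raise PlacementError(
                    "could not place a surface-bound dendrimer; use a larger box"
                )
        else:
            builder.place_star_uniform()
    if spec.point_solutes:
        # ideal-mixture mode: interaction-free point sites, both cosolute and
        # water sampled identically (the null condition for Γ calibration)
        for pos in rng.uniform(0.0, builder.box, size=(spec.n_anion, 3)):
            builder._commit(pos, 0.05, "anion", acceptor_sites=(0,))
        for pos in rng.uniform(0.0, builder.box, size=(spec.n_water, 3)):
            builder._commit(pos, 0.05, "water")
    else:
        for _ in range(spec.n_anion):
            builder.place_uniform_site(ANION_RADIUS, "anion", acceptor=True)
        for _ in range(spec.n_water):
            builder.place_uniform_site(WATER_RADIUS, "water")
    return builder.finish()


def gen_bridged_solution(spec: SolutionSpec):
    """Anion-bridged (sulfate-like) solution.

    Each anion independently becomes a bridge with probability
    ``bridge_propensity``.  A bridging anion sits at hydrogen-bond distance
    from arm sites of one or two distinct dendrimers; the two-dendrimer
    placement creates a D-A-D motif, and chains of bridges grow clusters.
    With a protein present, a ``pad_fraction`` share of bridges instead
    anchors a dendrimer to the protein surface through the anion (single-arm
    attachment, remaining arms facing the bulk).
    """
    if spec.bridge_propensity == 0.0:
        # degenerate case: identical to the well-mixed sampler
        return gen_mixture(spec)
    rng = np.random.default_rng(spec.seed)
    builder = _Builder(spec.box, rng)
    protein_info = _add_protein(builder, spec)

    is_bridge = rng.random(spec.n_anion) < spec.bridge_propensity
    unplaced = list(range(spec.n_dendrimer))
    placed_tips: dict = {}  # dendrimer mol -> (4,3) arm tip coords

    def _place_uniform_dend():
        mol, pts = builder.place_star_uniform()
        placed_tips[mol] = pts[1:]
        return mol

    def _place_partner_near(anion_pos, first_dir):
        """Place a new dendrimer with one tip hydrogen-bonded to anion_pos."""
        for _ in range(builder.max_tries):
            # bent bridge: 70-140 degrees between the two tip->anion vectors
            bend = np.deg2rad(rng.uniform(70.0, 140.0))
            axis = random_unit_vector(rng)
            perp = np.cross(first_dir, axis)
            nrm = np.linalg.norm(perp)
            if nrm < 1e-8:
                continue
            perp /= nrm
            v = np.cos(bend) * (-first_dir) + np.sin(bend) * perp
            tip = anion_pos + HBOND_PLACEMENT_DIST * v
            w = random_unit_vector(rng)
            if np.dot(w, v) < 0:
                w = -w  # arm points from core toward the anion side
            core = tip - ARM_LENGTH * w
            spin = rotation_aligning(_TETRAHEDRON[0], w)
            dirs = _TETRAHEDRON @ spin.T
            dirs[0] = w
            out = builder.try_place_star(core, dirs)
            if out is not None:
                mol, pts = out
                placed_tips[mol] = pts[1:]
                return mol
        return None

    def _place_anion_near_tip(tip):
        for _ in range(builder.max_tries):
            v = random_unit_vector(rng)
            pos = tip + HBOND_PLACEMENT_DIST * v
            if not builder._clashes(pos, ANION_RADIUS):
                mol, start = builder._commit(
                    pos, ANION_RADIUS, "anion", acceptor_sites=(0,)
                )
                return mol, pos, v
        return None

    for bridge in is_bridge:
        if not bridge or spec.n_dendrimer == 0:
            continue
        if (
            protein_info is not None
            and rng.random() < spec.pad_fraction
        ):
            # protein-anchored bridge: anion at the surface, dendrimer on one arm
            if not unplaced:
                continue  # bookkeeping below places this anion uniformly
            mol_id = unplaced.pop(rng.integers(len(unplaced)))
            done = False
            for _ in range(builder.max_tries):
                anion_pos, core, dirs = _anchored_star_pose(
                    builder, protein_info, rng
                )
                if builder._clashes(anion_pos, ANION_RADIUS):
                    continue
                out = builder.try_place_star(core, dirs)
                if out is not None:
                    mol, pts = out
                    placed_tips[mol] = pts[1:]
                    builder._commit(
                        anion_pos, ANION_RADIUS, "anion", acceptor_sites=(0,)
                    )
                    done = True
                    break
            if not done:
                raise PlacementError(
                    "could not place a protein-anchored bridge; use a larger box"
                )
            continue
        # dendrimer-dendrimer bridge
        if unplaced:
            first = unplaced.pop(rng.integers(len(unplaced)))
            _ = first
            mol, pts = builder.place_star_uniform()
            placed_tips[mol] = pts[1:]
            host = mol
        elif placed_tips:
            host = list(placed_tips)[rng.integers(len(placed_tips))]
        else:
            host = _place_uniform_dend()
        tips = placed_tips[host]
        tip = tips[rng.integers(4)]
        placed = _place_anion_near_tip(tip)
        if placed is None:
            raise PlacementError(
                "could not place a bridging anion; use a larger box"
            )
        _, anion_pos, v = placed
        if spec.n_dendrimer >= 2:
            if unplaced:
                partner_id = unplaced.pop(rng.integers(len(unplaced)))
                _ = partner_id
                if _place_partner_near(anion_pos, v) is None:
                    raise PlacementError(
                        "could not place a bridge partner dendrimer; use a larger box"
                    )
            # else: the anion decorates an existing dendrimer (chain growth)

    # account for dendrimers consumed vs. actually placed: the bookkeeping
    # above pops ids only when a star is committed, so remaining ids are free
    n_placed = len(placed_tips) + (
        len([m for m, s in builder.species.items() if s == "dendrimer"])
        - len(placed_tips)
    )
    for _ in range(spec.n_dendrimer - n_placed):
        _place_uniform_dend()

    n_anions_placed = sum(1 for s in builder.species.values() if s == "anion")
    for _ in range(spec.n_anion - n_anions_placed):
        builder.place_uniform_site(ANION_RADIUS, "anion", acceptor=True)
    for _ in range(spec.n_water):
        builder.place_uniform_site(WATER_RADIUS, "water")
    return builder.finish()


def gen_mixture_frames(spec: SolutionSpec, n_frames: int):
    """Independent well-mixed frames; frame f uses seed ``spec.seed + f``."""
    frames = []
    topo = None
    for f in range(n_frames):
        cfg, t = gen_mixture(replace(spec, seed=spec.seed + f))
        cfg.frame_index = f
        frames.append(cfg)
        topo = t
    return frames, topo


def gen_decay(
    k: float,
    m0: float,
    times,
    noise_sd: float = 0.0,
    seed: int = 0,
    label: str = "",
    time_unit: str = "min",
) -> KineticsTable:
    """Second-order monomer-loss curve M(t) = M0 / (1 + k·M0·t) plus noise.

    Gaussian noise of standard deviation ``noise_sd`` (mg/mL) is added
    independently per point and truncated at zero from below (re-drawn while
    nonpositive, so readings stay positive).
    """
    if k < 0:
        raise ValueError("rate constant k must be nonnegative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    times = np.asarray(times, float)
    if np.any(times < 0):
        raise ValueError("times must be nonnegative")
    rng = np.random.default_rng(seed)
    m = m0 / (1.0 + k * m0 * times)
    if noise_sd > 0:
        noisy = m + rng.normal(scale=noise_sd, size=m.shape)
        tiny = 1e-9 * m0
        for _ in range(100):
            bad = noisy <= 0
            if not np.any(bad):
                break
            noisy[bad] = m[bad] + rng.normal(scale=noise_sd, size=int(bad.sum()))
        noisy = np.maximum(noisy, tiny)
        m = noisy
    return KineticsTable(
        times=times, monomer=m, m0=m0, label=label, time_unit=time_unit
    )
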