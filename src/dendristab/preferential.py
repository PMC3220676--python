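"""Preferential interaction coefficients (Γ23) from particle configurations.

The estimator follows the local/bulk two-domain construction: the solution
around the single protein is split at a surface-distance cutoff, and the
instantaneous coefficient compares cosolute (species 3) counts against the
water (species 1) composition of the bulk::

    Γ_inst = n3_local − (n3_bulk / n1_bulk) · n1_local

Molecules — not atoms — are assigned to the local or bulk domain, by the
minimum distance from any of the molecule's atoms to the protein surface.
Negative Γ means preferential exclusion, positive preferential binding.

Time averaging discards an initial burn-in fraction of frames (the early,
unequilibrated part of a trajectory) and reports a block-averaged standard
error, the standard treatment for correlated series.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import constants

from .errors import DendristabError
from .geometry import pair_distances
from .model_io import ParticleConfiguration, TopologyMap


@dataclass
class DomainPartition:
    """Boundary between local and bulk domains around the protein.

    ``cutoff`` is measured from the protein *surface* (Å).  ``distance_mode``
    selects how that surface is defined: ``"surface"`` subtracts each protein
    atom's radius from the center distance (a sphere-mode protein is simply a
    one-atom protein with a large radius); ``"atom"`` uses bare center
    distances.
    """

    cutoff: float = 8.0
    distance_mode: str = "surface"  # "surface" | "atom"

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.distance_mode not in ("surface", "atom"):
            raise ValueError("distance_mode must be 'surface' or 'atom'")


@dataclass
class GammaSeries:
    """Per-frame Γ values with burn-in, cumulative average and block stderr."""

    per_frame: np.ndarray
    burn_in_frames: int
    cumulative: np.ndarray  # running mean over post-burn-in frames
    estimate: float
    stderr: float
    species: str = ""
    block_count: int = 5
    components: dict = field(default_factory=dict)  # species -> GammaSeries


def molecule_surface_distances(
    config: ParticleConfiguration, topo: TopologyMap, part: DomainPartition
):
    """Per-molecule minimum distance to the protein surface.

    Returns (mol_ids, distances, species) arrays over all non-protein
    molecules, using the minimum over each molecule's atoms.
    """
    prot_mols = topo.protein_molecules()
    if len(prot_mols) != 1:
        raise DendristabError(
            f"configuration must contain exactly one protein (found {len(prot_mols)})"
        )
    prot_atoms = topo.atoms_of(prot_mols[0])
    prot_xyz = config.coords[prot_atoms]
    is_prot = np.isin(topo.molecule_of, prot_mols)
    other = np.flatnonzero(~is_prot)
    d = pair_distances(config.coords[other], prot_xyz, config.box, config.periodic)
    if part.distance_mode == "surface":
        d = d - topo.radii(prot_atoms)[None, :]
    atom_min = d.min(axis=1)
    # group the per-atom minima by molecule
    mols = topo.molecule_of[other]
    order = np.argsort(mols, kind="stable")
    sorted_mols = mols[order]
    starts = np.flatnonzero(np.r_[True, np.diff(sorted_mols) != 0])
    mol_ids = sorted_mols[starts]
    dmin = np.minimum.reduceat(atom_min[order], starts)
    species = np.array([topo.species_of[int(m)] for m in mol_ids])
    return mol_ids, dmin, species


def _domain_counts(config, topo, part):
    _, dmin, species = molecule_surface_distances(config, topo, part)
    local = dmin <= part.cutoff
    counts = {}
    for sp in set(species):
        sel = species == sp
        counts[sp] = (int(np.sum(sel & local)), int(np.sum(sel & ~local)))
    return counts


def _gamma_from_counts(counts: dict, species3: str) -> float:
    n3_local, n3_bulk = counts.get(species3, (0, 0))
    n1_local, n1_bulk = counts.get("water", (0, 0))
    if n1_bulk == 0:
        if n1_local == 0:
            return float(n3_local)
        raise DendristabError(
            "no bulk water but local water present: bulk composition ratio undefined "
            "(enlarge the box or the bulk domain)"
        )
    return float(n3_local - (n3_bulk / n1_bulk) * n1_local)


def instantaneous_gamma(
    config: ParticleConfiguration,
    topo: TopologyMap,
    part: DomainPartition,
    species3: str,
) -> float:
    """Instantaneous Γ23 of one frame for cosolute species ``species3``."""
    return _gamma_from_counts(_domain_counts(config, topo, part), species3)


def gamma_timeseries(
    frames,
    topo: TopologyMap,
    part: DomainPartition,
    species3: str,
    burn_in_fraction: float = 0.2,
    block_count: int = 5,
    components: tuple = (),
) -> GammaSeries:
    """Γ23 over a trajectory with burn-in, cumulative mean and block stderr.

    ``components`` optionally names further cosolute species whose series are
    computed on the identical local/bulk partitions and attached to the
    result (e.g. ``("dendrimer", "anion")`` for a salt).
    """
    frames = list(frames)
    if not 0.0 <= burn_in_fraction < 1.0:
        raise ValueError("burn_in_fraction must lie in [0, 1)")
    if block_count < 1:
        raise ValueError("block_count must be >= 1")
    all_species = (species3,) + tuple(s for s in components if s != species3)
    per = {sp: np.empty(len(frames)) for sp in all_species}
    for i, fr in enumerate(frames):
        counts = _domain_counts(fr, topo, part)
        for sp in all_species:
            per[sp][i] = _gamma_from_counts(counts, sp)
    burn = int(np.floor(burn_in_fraction * len(frames)))
    if len(frames) - burn < 2:
        raise DendristabError(
            f"burn-in leaves {len(frames) - burn} frames; need at least 2"
        )

    def _series(sp):
        x = per[sp][burn:]
        cumulative = np.cumsum(x) / np.arange(1, len(x) + 1)
        estimate = float(np.mean(x))
        stderr = _block_stderr(x, block_count)
        return GammaSeries(
            per_frame=per[sp],
            burn_in_frames=burn,
            cumulative=cumulative,
            estimate=estimate,
            stderr=stderr,
            species=sp,
            block_count=block_count,
        )

    main = _series(species3)
    for sp in all_species[1:]:
        main.components[sp] = _series(sp)
    return main


def _block_stderr(x: np.ndarray, block_count: int) -> float:
    """Standard error from non-overlapping block means."""
    if block_count > len(x):
        raise DendristabError(
            f"cannot form {block_count} blocks from {len(x)} frames"
        )
    blocks = np.array_split(x, block_count)
    means = np.array([b.mean() for b in blocks])
    if block_count == 1:
        return 0.0
    return float(means.std(ddof=1) / np.sqrt(block_count))


# ---------------------------------------------------------------------------
# salt-level combination and the exclusion-only reference
# ---------------------------------------------------------------------------

#: preset weightings for combining per-ion Γ values into a salt-level value.
#: "formula_unit": ion counts per formula unit of the salt (1 dendrimer
#: polycation : n anions).  "per_group": weight the dendrimer by its number
#: of charged surface groups (4 for a generation-0 star) against 1 anion.
def stoichiometric_weights(n_anions_per_dendrimer: int = 4) -> dict:
    return {"dendrimer": 1.0, "anion": float(n_anions_per_dendrimer)}


def group_weights(n_surface_groups: int = 4) -> dict:
    return {"dendrimer": float(n_surface_groups), "anion": 1.0}


def salt_weighted_gamma(component_gammas: dict, weights: dict) -> float:
    """Weighted average of per-ion Γ values: Σ w_s Γ_s / Σ w_s.

    Weights are caller-supplied; ``stoichiometric_weights`` and
    ``group_weights`` provide the two natural presets.
    """
    missing = [s for s in component_gammas if s not in weights]
    if missing:
        raise DendristabError(f"weights missing for species: {missing}")
    w = np.array([weights[s] for s in component_gammas], float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if w.sum() == 0:
        raise ValueError("weights must not all be zero")
    g = np.array([component_gammas[s] for s in component_gammas], float)
    return float(np.dot(w, g) / w.sum())


def exclusion_only_gamma(
    solute_radius: float,
    protein,
    c3: float,
    n_samples: int = 200_000,
    seed: int = 0,
) -> float:
    """Γ of an inert, purely excluded solute: Γ_excl = −c3·N_A·V_shell.

    ``V_shell`` is the volume of the region around the protein that the
    solute *center* cannot enter, excluding the protein interior itself: a
    shell of thickness ``solute_radius`` over the protein surface.  For a
    sphere protein (``protein`` a radius in Å) the shell volume is analytic;
    for an atom-set protein (dict with ``coords`` (k,3) and ``radii`` (k,))
    it is estimated by Monte-Carlo integration over a bounding box.

    ``c3`` is the bulk solute concentration in mol/L; the result is mol/mol.
    """
    if solute_radius < 0:
        raise ValueError("solute_radius must be nonnegative")
    if c3 < 0:
        raise ValueError("c3 must be nonnegative")
    if np.isscalar(protein):
        R = float(protein)
        if R <= 0:
            raise ValueError("protein radius must be positive")
        v_shell_A3 = 4.0 / 3.0 * np.pi * ((R + solute_radius) ** 3 - R**3)
    else:
        coords = np.asarray(protein["coords"], float)
        radii = np.asarray(protein["radii"], float)
        if np.any(radii <= 0):
            raise ValueError("protein atom radii must be positive")
        rng = np.random.default_rng(seed)
        expanded = radii + solute_radius
        lo = (coords - expanded[:, None]).min(axis=0)
        hi = (coords + expanded[:, None]).max(axis=0)
        pts = rng.uniform(lo, hi, size=(n_samples, 3))
        d = np.sqrt(
            ((pts[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
        )
        in_expanded = np.any(d < expanded[None, :], axis=1)
        in_bare = np.any(d < radii[None, :], axis=1)
        frac = np.mean(in_expanded & ~in_bare)
        v_shell_A3 = float(frac * np.prod(hi - lo))
    v_shell_L = v_shell_A3 * 1e-27
    return float(-c3 * constants.N_A * v_shell_L)
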