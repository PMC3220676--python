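"""Geometric hydrogen-bond detection, motif taxonomy and cluster extraction.

A hydrogen bond is detected when a donor heavy atom and an acceptor atom are
within a distance cutoff (default 3.5 Å) and, when an explicit hydrogen is
present, the D-H⋯A angle deviates from linearity by at most an angle cutoff
(default 30°) — the de-facto geometric criteria in simulation analysis.
Reduced models without explicit hydrogens use distance-only detection.

Bonds are classified by the species pair of their molecules into the
categories D-D, D-A, P-D, P-A (D dendrimer, A anion, P protein), and
anion-bridged motifs are counted as distinct unordered triplets:

* D-A-D — an anion hydrogen-bonded to two distinct dendrimers, joining them;
* P-A-D — an anion bonded to both the protein and a dendrimer, an indirect
  protein-dendrimer contact.

Clusters are connected components of the molecule graph induced by the bond
list (optionally restricted by species), the solution-structure signature of
bridging counterions.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np

from .errors import DendristabError
from .geometry import minimum_image, pair_distances
from .model_io import ParticleConfiguration, TopologyMap

DEFAULT_DIST_CUTOFF = 3.5  # Å, donor heavy atom to acceptor
DEFAULT_ANGLE_CUTOFF = 30.0  # degrees deviation from linear D-H...A


@dataclass(frozen=True)
class HBond:
    donor_atom: int
    hydrogen: int | None
    acceptor_atom: int
    donor_molecule: int
    acceptor_molecule: int
    distance: float  # Å, heavy-atom
    angle: float | None  # degrees deviation from linearity (None: no hydrogen)


@dataclass
class MotifCounts:
    """Hydrogen-bond counts in the six pairwise/bridged categories."""

    DD: int = 0
    DA: int = 0
    DAD: int = 0
    PD: int = 0
    PA: int = 0
    PAD: int = 0
    other: int = 0
    dad_triplets: list = field(default_factory=list)  # (dend, anion, dend')
    pad_triplets: list = field(default_factory=list)  # (protein, anion, dend)
    clusters: "ClusterPartition | None" = None

    def as_dict(self) -> dict:
        return {
            "D-D": self.DD,
            "D-A": self.DA,
            "D-A-D": self.DAD,
            "P-D": self.PD,
            "P-A": self.PA,
            "P-A-D": self.PAD,
            "other": self.other,
        }


@dataclass
class ClusterPartition:
    """Molecule partition into connected components, sizes sorted descending."""

    components: list  # list of frozensets of molecule ids
    sizes: list

    @property
    def mean_size(self) -> float:
        return float(np.mean(self.sizes)) if self.sizes else 0.0

    @property
    def largest(self) -> int:
        return self.sizes[0] if self.sizes else 0


def detect_hbonds(
    config: ParticleConfiguration,
    topo: TopologyMap,
    dist_cutoff: float = DEFAULT_DIST_CUTOFF,
    angle_cutoff: float = DEFAULT_ANGLE_CUTOFF,
    include_intramolecular: bool = False,
) -> list:
    """All donor→acceptor hydrogen bonds of one frame under minimum image."""
    if not topo.donors or not topo.acceptors:
        warnings.warn("no donors or no acceptors flagged; no bonds detected",
                      stacklevel=2)
        return []
    heavy = np.array([d for d, _ in topo.donors], int)
    hyd = [h for _, h in topo.donors]
    acc = np.array(sorted(topo.acceptors), int)
    d = pair_distances(
        config.coords[heavy], config.coords[acc], config.box, config.periodic
    )
    bonds = []
    don_mol = topo.molecule_of[heavy]
    acc_mol = topo.molecule_of[acc]
    within = d <= dist_cutoff
    if not include_intramolecular:
        within &= don_mol[:, None] != acc_mol[None, :]
    within &= heavy[:, None] != acc[None, :]
    for i, j in zip(*np.nonzero(within)):
        angle = None
        if hyd[i] is not None:
            angle = _linearity_deviation(
                config, heavy[i], hyd[i], acc[j]
            )
            if angle > angle_cutoff:
                continue
        bonds.append(
            HBond(
                donor_atom=int(heavy[i]),
                hydrogen=hyd[i],
                acceptor_atom=int(acc[j]),
                donor_molecule=int(don_mol[i]),
                acceptor_molecule=int(acc_mol[j]),
                distance=float(d[i, j]),
                angle=angle,
            )
        )
    return bonds


def _linearity_deviation(config, donor, hydrogen, acceptor) -> float:
    """Deviation (degrees) of the D-H⋯A arrangement from linear."""
    hd = minimum_image(
        config.coords[donor] - config.coords[hydrogen], config.box, config.periodic
    )
    ha = minimum_image(
        config.coords[acceptor] - config.coords[hydrogen], config.box, config.periodic
    )
    cosang = np.dot(hd, ha) / (np.linalg.norm(hd) * np.linalg.norm(ha))
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return float(180.0 - angle)


def classify_and_count(
    bonds, topo: TopologyMap, include_clusters: bool = True
) -> MotifCounts:
    """Classify bonds into pair categories and count bridged triplets."""
    mc = MotifCounts()
    #: anion molecule -> set of partner molecules per species
    anion_partners: dict = {}
    for b in bonds:
        try:
            sp_d = topo.species_of[b.donor_molecule]
            sp_a = topo.species_of[b.acceptor_molecule]
        except KeyError as exc:
            raise DendristabError(
                f"bond references unknown molecule {exc.args[0]}"
            ) from None
        pair = frozenset((sp_d, sp_a)) if sp_d != sp_a else frozenset((sp_d,))
        if pair == frozenset(("dendrimer",)):
            mc.DD += 1
        elif pair == frozenset(("dendrimer", "anion")):
            mc.DA += 1
        elif pair == frozenset(("protein", "dendrimer")):
            mc.PD += 1
        elif pair == frozenset(("protein", "anion")):
            mc.PA += 1
        else:
            mc.other += 1
        for mol, sp, partner in (
            (b.donor_molecule, sp_d, b.acceptor_molecule),
            (b.acceptor_molecule, sp_a, b.donor_molecule),
        ):
            if sp == "anion":
                psp = topo.species_of[partner]
                anion_partners.setdefault(mol, {}).setdefault(psp, set()).add(partner)

    for anion, partners in sorted(anion_partners.items()):
        dends = sorted(partners.get("dendrimer", ()))
        prots = sorted(partners.get("protein", ()))
        for d1, d2 in combinations(dends, 2):
            mc.dad_triplets.append((d1, anion, d2))
        for p in prots:
            for dd in dends:
                mc.pad_triplets.append((p, anion, dd))
    mc.DAD = len(mc.dad_triplets)
    mc.PAD = len(mc.pad_triplets)
    if include_clusters:
        mc.clusters = cluster_components(bonds, topo)
    return mc


def cluster_components(
    bonds, topo: TopologyMap, include_species: set | None = None
) -> ClusterPartition:
    """Connected components of the molecule graph induced by bonds/contacts.

    ``bonds`` may be HBond objects or bare (molecule, molecule) pairs.
    Singleton molecules of the included species appear as size-1 components.
    """
    if include_species is None:
        include_species = set(topo.species_of.values())
    g = nx.Graph()
    for mol, sp in topo.species_of.items():
        if sp in include_species:
            g.add_node(mol)
    for b in bonds:
        if isinstance(b, HBond):
            u, v = b.donor_molecule, b.acceptor_molecule
        else:
            u, v = b
        if g.has_node(u) and g.has_node(v):
            g.add_edge(u, v)
    comps = [frozenset(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return ClusterPartition(components=comps, sizes=[len(c) for c in comps])


def motif_counts_over_frames(frames, topo, **kwargs) -> list:
    """Per-frame MotifCounts for a trajectory."""
    return [
        classify_and_count(detect_hbonds(fr, topo, **kwargs), topo) for fr in frames
    ]
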