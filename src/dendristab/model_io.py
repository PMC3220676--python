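"""Domain types and file I/O.

Coordinates are Å throughout. Atom indices are 0-based in memory and in the
topology sidecar; PDB serials are written 1-based per that format's convention.
Boxes are orthorhombic; anything else is rejected.

The topology sidecar is a keyed plain-text format defined by this package
(neither XYZ nor PDB can carry species roles, donor/acceptor flags, radii or
arm groupings).  Grammar, one directive per line, ``#`` comments allowed::

    natoms <N>
    frame_interval <float>              # optional; only used for axis labels
    molecule <mol-id> <species> <atom> [<atom> ...]
    donor <atom> [<hydrogen-atom>|-]    # '-' or omitted: no explicit hydrogen
    acceptor <atom>
    radius <atom> <r>                   # Å
    arm <mol-id> <arm-index 1..4> <atom> [<atom> ...]
    com <mol-id> <atom> [<atom> ...]    # optional center-of-mass group

Species are ``protein``, ``dendrimer``, ``anion``, ``water`` or ``other``.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    KineticsDataError,
    StructureError,
    TopologyValidationError,
    TrajectoryParseError,
)
from .geometry import wrap

SPECIES = frozenset({"protein", "dendrimer", "anion", "water", "other"})

#: element-style labels used when writing XYZ/PDB, chosen per species for
#: readability in viewers; they carry no chemistry.
_SPECIES_LABEL = {
    "protein": "P",
    "dendrimer": "D",
    "anion": "A",
    "water": "W",
    "other": "X",
}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ParticleConfiguration:
    """One frame of particle coordinates in an orthorhombic periodic box."""

    coords: np.ndarray  # (N, 3) Å
    box: np.ndarray  # (3,) Å
    periodic: np.ndarray = field(default_factory=lambda: np.array([True] * 3))
    atom_ids: Optional[np.ndarray] = None  # (N,) 0-based
    frame_index: int = 0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        self.periodic = np.asarray(self.periodic, dtype=bool).reshape(3)
        if self.atom_ids is None:
            self.atom_ids = np.arange(self.n_atoms)
        else:
            self.atom_ids = np.asarray(self.atom_ids, dtype=int).reshape(-1)
        if not np.all(np.isfinite(self.coords)):
            raise StructureError(
                f"frame {self.frame_index}: non-finite coordinates"
            )
        if np.any(self.box <= 0):
            raise StructureError(
                f"frame {self.frame_index}: box lengths must be strictly positive"
            )
        if len(self.atom_ids) != self.n_atoms:
            raise StructureError(
                f"frame {self.frame_index}: atom_ids length != coordinate count"
            )

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def wrapped(self) -> "ParticleConfiguration":
        """Copy with coordinates wrapped into [0, box) on periodic axes."""
        return ParticleConfiguration(
            wrap(self.coords, self.box, self.periodic),
            self.box.copy(),
            self.periodic.copy(),
            self.atom_ids.copy(),
            self.frame_index,
        )


@dataclass
class TopologyMap:
    """Semantic overlay on a trajectory: molecules, species, H-bond roles, radii, arms.

    ``molecule_of`` maps each atom (by index) to a molecule id; every molecule
    has a species.  ``donors`` is a list of (heavy-atom, hydrogen-or-None)
    pairs — reduced models without explicit hydrogens use None, which switches
    hydrogen-bond detection to distance-only mode.  ``arms`` groups a
    dendrimer's surface sites into its 4 labelled arms.
    """

    molecule_of: np.ndarray  # (n_atoms,) int
    species_of: dict  # molecule id -> species
    donors: list = field(default_factory=list)  # [(heavy, hydrogen|None), ...]
    acceptors: set = field(default_factory=set)
    radius_of: dict = field(default_factory=dict)  # atom -> Å
    arms: dict = field(default_factory=dict)  # dendrimer mol -> [4 atom lists]
    com_group_of: dict = field(default_factory=dict)  # mol -> atom list
    frame_interval: Optional[float] = None

    def __post_init__(self):
        self.molecule_of = np.asarray(self.molecule_of, dtype=int).reshape(-1)
        self._atoms_cache: dict | None = None

    # -- basic queries ------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.molecule_of)

    def molecules(self) -> list:
        return sorted(self.species_of)

    def atoms_of(self, mol: int) -> np.ndarray:
        if self._atoms_cache is None:
            cache: dict = {}
            order = np.argsort(self.molecule_of, kind="stable")
            mols = self.molecule_of[order]
            bounds = np.flatnonzero(np.diff(mols)) + 1
            for m, grp in zip(
                np.concatenate([[mols[0]], mols[bounds]]) if len(mols) else [],
                np.split(order, bounds),
            ):
                cache[int(m)] = grp
            self._atoms_cache = cache
        return self._atoms_cache[mol]

    def molecules_of_species(self, species: str) -> list:
        return [m for m in self.molecules() if self.species_of[m] == species]

    def species_of_atom(self, atom: int) -> str:
        return self.species_of[int(self.molecule_of[atom])]

    def protein_molecules(self) -> list:
        return self.molecules_of_species("protein")

    def radii(self, atoms: Sequence[int]) -> np.ndarray:
        try:
            return np.array([self.radius_of[int(a)] for a in atoms], float)
        except KeyError as exc:
            raise TopologyValidationError(
                f"atom {exc.args[0]} has no radius in the topology"
            ) from None

    # -- validation ---------------------------------------------------------

    def validate(self, n_atoms: Optional[int] = None) -> None:
        if n_atoms is not None and self.n_atoms != n_atoms:
            raise TopologyValidationError(
                f"topology describes {self.n_atoms} atoms but trajectory has {n_atoms}"
            )
        seen = np.zeros(self.n_atoms, dtype=int)
        for m in self.molecules():
            sp = self.species_of[m]
            if sp not in SPECIES:
                raise TopologyValidationError(f"unknown species label {sp!r}")
            seen[self.atoms_of(m)] += 1
        if np.any(seen != 1):
            bad = int(np.flatnonzero(seen != 1)[0])
            raise TopologyValidationError(
                f"atom {bad} belongs to {seen[bad]} molecules (must be exactly 1)"
            )
        for m, groups in self.arms.items():
            if self.species_of.get(m) != "dendrimer":
                raise TopologyValidationError(f"arm groups on non-dendrimer molecule {m}")
            if len(groups) != 4:
                raise TopologyValidationError(
                    f"dendrimer molecule {m} has {len(groups)} arm groups (expected 4)"
                )
            flat = [a for g in groups for a in g]
            if len(set(flat)) != len(flat):
                raise TopologyValidationError(f"arm groups of molecule {m} overlap")
        for r in self.radius_of.values():
            if r <= 0:
                raise TopologyValidationError("atomic radii must be strictly positive")

    def species_counts(self) -> dict:
        out: dict = {}
        for m, sp in self.species_of.items():
            out[sp] = out.get(sp, 0) + 1
        return out


@dataclass
class KineticsTable:
    """Time series of monomeric protein concentration during aggregation."""

    times: np.ndarray  # declared unit (min or h)
    monomer: np.ndarray  # mg/mL
    m0: float  # mg/mL
    label: str = ""
    time_unit: str = "min"
    excess_tolerance: float = 0.05

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float).reshape(-1)
        self.monomer = np.asarray(self.monomer, dtype=float).reshape(-1)
        if len(self.times) != len(self.monomer):
            raise KineticsDataError("time and monomer columns differ in length")
        if len(self.times) < 2:
            raise KineticsDataError(
                "kinetics table needs at least 2 rows (and fits need at least 3 points)"
            )
        if np.any(self.times < 0):
            raise KineticsDataError("times must be nonnegative")
        if np.any(np.diff(self.times) <= 0):
            raise KineticsDataError("times must be strictly increasing")
        if self.m0 <= 0:
            raise KineticsDataError("M0 must be positive")
        if np.any(self.monomer <= 0):
            raise KineticsDataError("monomer concentrations must be positive")

    @property
    def relative(self) -> np.ndarray:
        """M/M0."""
        return self.monomer / self.m0

    def rows_exceeding_m0(self) -> np.ndarray:
        """Row indices where monomer exceeds M0 beyond the tolerance."""
        return np.flatnonzero(self.monomer > self.m0 * (1 + self.excess_tolerance))


# ---------------------------------------------------------------------------
# Topology sidecar I/O
# ---------------------------------------------------------------------------


def read_topology(path) -> TopologyMap:
    """Parse a topology sidecar file (grammar in the module docstring)."""
    text = Path(path).read_text()
    return parse_topology(text)


def parse_topology(text: str) -> TopologyMap:
    natoms = None
    frame_interval = None
    mol_atoms: dict = {}
    species: dict = {}
    donors: list = []
    acceptors: set = set()
    radii: dict = {}
    arms: dict = {}
    com: dict = {}

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tok = line.split()
        key = tok[0].lower()
        try:
            if key == "natoms":
                natoms = int(tok[1])
            elif key == "frame_interval":
                frame_interval = float(tok[1])
            elif key == "molecule":
                mol = int(tok[1])
                sp = tok[2].lower()
                if sp not in SPECIES:
                    raise TopologyValidationError(
                        f"line {lineno}: unknown species label {sp!r}"
                    )
                atoms = [int(a) for a in tok[3:]]
                if not atoms:
                    raise TopologyValidationError(
                        f"line {lineno}: molecule {mol} lists no atoms"
                    )
                if mol in mol_atoms:
                    raise TopologyValidationError(
                        f"line {lineno}: molecule {mol} defined twice"
                    )
                mol_atoms[mol] = atoms
                species[mol] = sp
            elif key == "donor":
                heavy = int(tok[1])
                hyd = None
                if len(tok) > 2 and tok[2] != "-":
                    hyd = int(tok[2])
                donors.append((heavy, hyd))
            elif key == "acceptor":
                acceptors.add(int(tok[1]))
            elif key == "radius":
                radii[int(tok[1])] = float(tok[2])
            elif key == "arm":
                mol = int(tok[1])
                idx = int(tok[2])
                if not 1 <= idx <= 4:
                    raise TopologyValidationError(
                        f"line {lineno}: arm index {idx} outside 1..4"
                    )
                arms.setdefault(mol, {})[idx] = [int(a) for a in tok[3:]]
            elif key == "com":
                com[int(tok[1])] = [int(a) for a in tok[2:]]
            else:
                raise TopologyValidationError(f"line {lineno}: unknown directive {key!r}")
        except (ValueError, IndexError):
            raise TopologyValidationError(
                f"line {lineno}: malformed {key!r} directive: {raw.strip()!r}"
            ) from None

    if natoms is None:
        natoms = 1 + max((a for atoms in mol_atoms.values() for a in atoms), default=-1)
    molecule_of = np.full(natoms, -1, dtype=int)
    for mol, atoms in mol_atoms.items():
        for a in atoms:
            if not 0 <= a < natoms:
                raise TopologyValidationError(
                    f"molecule {mol} references atom {a} outside 0..{natoms - 1}"
                )
            if molecule_of[a] != -1:
                raise TopologyValidationError(
                    f"atom {a} assigned to molecules {molecule_of[a]} and {mol}"
                )
            molecule_of[a] = mol
    if np.any(molecule_of == -1):
        missing = int(np.flatnonzero(molecule_of == -1)[0])
        raise TopologyValidationError(f"atom {missing} belongs to no molecule")

    for heavy, hyd in donors:
        for a in (heavy,) if hyd is None else (heavy, hyd):
            if not 0 <= a < natoms:
                raise TopologyValidationError(f"donor references unknown atom {a}")
    for a in acceptors:
        if not 0 <= a < natoms:
            raise TopologyValidationError(f"acceptor references unknown atom {a}")

    arm_lists = {}
    for mol, groups in arms.items():
        if sorted(groups) != [1, 2, 3, 4]:
            raise TopologyValidationError(
                f"dendrimer molecule {mol} must define arms 1..4 exactly once each"
            )
        arm_lists[mol] = [groups[i] for i in (1, 2, 3, 4)]

    topo = TopologyMap(
        molecule_of=molecule_of,
        species_of=species,
        donors=donors,
        acceptors=acceptors,
        radius_of=radii,
        arms=arm_lists,
        com_group_of=com,
        frame_interval=frame_interval,
    )
    topo.validate()
    return topo


def write_topology(topo: TopologyMap, path) -> None:
    buf = io.StringIO()
    buf.write(f"natoms {topo.n_atoms}\n")
    if topo.frame_interval is not None:
        buf.write(f"frame_interval {topo.frame_interval}\n")
    for mol in topo.molecules():
        atoms = " ".join(str(int(a)) for a in sorted(topo.atoms_of(mol)))
        buf.write(f"molecule {mol} {topo.species_of[mol]} {atoms}\n")
    for heavy, hyd in topo.donors:
        buf.write(f"donor {heavy} {'-' if hyd is None else hyd}\n")
    for a in sorted(topo.acceptors):
        buf.write(f"acceptor {a}\n")
    for a in sorted(topo.radius_of):
        buf.write(f"radius {a} {topo.radius_of[a]:.6g}\n")
    for mol, groups in sorted(topo.arms.items()):
        for i, grp in enumerate(groups, start=1):
            buf.write(f"arm {mol} {i} " + " ".join(map(str, grp)) + "\n")
    for mol, grp in sorted(topo.com_group_of.items()):
        buf.write(f"com {mol} " + " ".join(map(str, grp)) + "\n")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# Trajectory I/O
# ---------------------------------------------------------------------------


def load_trajectory(path, topology):
    """Load a multi-frame XYZ or multi-model PDB with its topology sidecar.

    Returns (frames, TopologyMap).  Frames come back in file order; every
    frame is validated against the sidecar's atom count.
    """
    path = Path(path)
    topo = read_topology(topology)
    if path.suffix.lower() == ".pdb":
        frames = read_pdb_frames(path)
    else:
        frames = read_xyz_frames(path)
    n0 = frames[0].n_atoms
    for fr in frames:
        if fr.n_atoms != n0:
            raise StructureError(
                f"frame {fr.frame_index} has {fr.n_atoms} atoms; frame 0 has {n0}"
            )
    topo.validate(n_atoms=n0)
    return frames, topo


def read_xyz_frames(path) -> list:
    """Read a multi-frame XYZ file.

    The comment line of each frame must carry the box, e.g.::

        box 50.0 50.0 50.0 periodic 1 1 1

    (``periodic`` optional, default fully periodic).
    """
    lines = Path(path).read_text().splitlines()
    frames = []
    i = 0
    frame_index = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError:
            raise TrajectoryParseError(
                f"expected an atom count, got {lines[i]!r}", line=i + 1
            ) from None
        if i + 1 >= len(lines):
            raise TrajectoryParseError("missing comment line", line=i + 2)
        box, periodic = _parse_xyz_comment(lines[i + 1], i + 2)
        coords = np.empty((natoms, 3))
        for k in range(natoms):
            lineno = i + 2 + k
            if lineno >= len(lines):
                raise StructureError(
                    f"frame {frame_index}: file ends after {k} of {natoms} atoms"
                )
            parts = lines[lineno].split()
            if len(parts) < 4:
                raise TrajectoryParseError(
                    f"expected 'label x y z', got {lines[lineno]!r}", line=lineno + 1
                )
            try:
                coords[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError:
                raise TrajectoryParseError(
                    f"unreadable coordinates {lines[lineno]!r}", line=lineno + 1
                ) from None
        frames.append(
            ParticleConfiguration(coords, box, periodic, frame_index=frame_index)
        )
        i += 2 + natoms
        frame_index += 1
    if not frames:
        raise TrajectoryParseError("no frames found", line=1)
    return frames


def _parse_xyz_comment(comment: str, lineno: int):
    tok = comment.split()
    box = None
    periodic = np.array([True, True, True])
    j = 0
    while j < len(tok):
        if tok[j].lower() == "box":
            try:
                box = np.array([float(tok[j + 1]), float(tok[j + 2]), float(tok[j + 3])])
            except (ValueError, IndexError):
                raise TrajectoryParseError("malformed box entry", line=lineno) from None
            j += 4
        elif tok[j].lower() == "periodic":
            try:
                periodic = np.array([bool(int(tok[j + k])) for k in (1, 2, 3)])
            except (ValueError, IndexError):
                raise TrajectoryParseError(
                    "malformed periodic entry", line=lineno
                ) from None
            j += 4
        else:
            j += 1
    if box is None:
        raise TrajectoryParseError(
            "comment line must carry 'box Lx Ly Lz'", line=lineno
        )
    return box, periodic


def write_xyz(frames, topo: Optional[TopologyMap], path, precision: int = 6) -> None:
    """Write frames as multi-frame XYZ with the box on the comment line."""
    frames = [frames] if isinstance(frames, ParticleConfiguration) else list(frames)
    with open(path, "w") as fh:
        for fr in frames:
            fh.write(f"{fr.n_atoms}\n")
            per = " ".join(str(int(p)) for p in fr.periodic)
            fh.write(
                f"box {fr.box[0]:.{precision}f} {fr.box[1]:.{precision}f} "
                f"{fr.box[2]:.{precision}f} periodic {per} frame {fr.frame_index}\n"
            )
            for a in range(fr.n_atoms):
                label = (
                    _SPECIES_LABEL.get(topo.species_of_atom(a), "X")
                    if topo is not None
                    else "X"
                )
                x, y, z = fr.coords[a]
                fh.write(
                    f"{label} {x:.{precision}f} {y:.{precision}f} {z:.{precision}f}\n"
                )


def read_pdb_frames(path) -> list:
    """Read a multi-model PDB into a list of frames (box from CRYST1)."""
    import biotite.structure.io.pdb as pdb

    pf = pdb.PDBFile.read(str(path))
    stack = pf.get_structure(model=None)
    box_mat = stack.box[0] if stack.box is not None else None
    if box_mat is None:
        raise TrajectoryParseError("PDB file carries no CRYST1 box", line=1)
    off_diag = box_mat - np.diag(np.diag(box_mat))
    if np.any(np.abs(off_diag) > 1e-6):
        raise StructureError("triclinic boxes are not supported (orthorhombic only)")
    box = np.diag(box_mat)
    return [
        ParticleConfiguration(stack.coord[i], box, frame_index=i)
        for i in range(stack.stack_depth())
    ]


def write_pdb(frames, topo: Optional[TopologyMap], path) -> None:
    """Write frames as a multi-model PDB (1-based serials, CRYST1 box)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    frames = [frames] if isinstance(frames, ParticleConfiguration) else list(frames)
    n = frames[0].n_atoms
    coord = np.stack([fr.coords for fr in frames]).astype(np.float32)
    stack = struc.AtomArrayStack(len(frames), n)
    stack.coord = coord
    stack.chain_id = np.full(n, "A")
    stack.res_name = np.full(n, "MOL")
    stack.hetero = np.full(n, True)
    if topo is not None:
        stack.res_id = topo.molecule_of + 1
        labels = [_SPECIES_LABEL.get(topo.species_of_atom(a), "X") for a in range(n)]
    else:
        stack.res_id = np.ones(n, int)
        labels = ["X"] * n
    stack.atom_name = np.array(labels)
    stack.element = np.array(labels)
    box = frames[0].box
    stack.box = np.repeat(np.diag(box)[None, :, :], len(frames), axis=0)
    pf = pdb.PDBFile()
    pf.set_structure(stack)
    pf.write(str(path))


# ---------------------------------------------------------------------------
# Kinetics tables
# ---------------------------------------------------------------------------


def load_kinetics_table(
    path, m0: float, label: str = "", time_unit: str = "min"
) -> KineticsTable:
    """Load a two-column delimited (time, monomer) table.

    The delimiter is sniffed by pandas; a header row is optional.  Rows must
    be in strictly increasing time order.  Monomer readings above
    M0·(1+tolerance) produce a warning listing the offending rows.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if df.shape[1] < 2:
        raise KineticsDataError("kinetics table needs two columns (time, monomer)")
    # tolerate a file without a header: first row may actually be data
    try:
        float(df.columns[0])
        df = pd.read_csv(path, sep=None, engine="python", comment="#", header=None)
    except (TypeError, ValueError):
        pass
    times = pd.to_numeric(df.iloc[:, 0], errors="raise").to_numpy(float)
    monomer = pd.to_numeric(df.iloc[:, 1], errors="raise").to_numpy(float)
    table = KineticsTable(
        times=times, monomer=monomer, m0=m0, label=label or Path(path).stem,
        time_unit=time_unit,
    )
    bad = table.rows_exceeding_m0()
    if len(bad):
        import warnings

        warnings.warn(
            f"monomer exceeds M0 beyond tolerance in rows {bad.tolist()}",
            stacklevel=2,
        )
    return table


def write_kinetics_table(table: KineticsTable, path) -> None:
    pd.DataFrame(
        {f"time_{table.time_unit}": table.times, "monomer_mg_per_mL": table.monomer}
    ).to_csv(path, index=False)
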