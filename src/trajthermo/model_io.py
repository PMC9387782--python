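"""Structures, trajectories, parameter sidecars, selections, and tabular I/O.

The in-memory model is deliberately small: a :class:`Topology` (ordered
atoms grouped into residues), a :class:`Frame` (N x 3 Cartesian coordinates
in Å with an optional orthorhombic box), and a :class:`TrajectoryEnsemble`
tying the two together.  Structures are read from the ATOM/HETATM subset of
the PDB format (via Biopython); trajectories from multi-model PDB or plain
XYZ frame series.  Force-field style per-atom parameters (mass, partial
charge, Lennard-Jones sigma/epsilon, PB radius) come from a transparent TSV
sidecar keyed on (residue_name, atom_name) rather than from a force-field
assignment pipeline.

Units: Å, amu, elementary charge, kcal/mol, ps.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AtomRecord",
    "Residue",
    "Topology",
    "Frame",
    "TrajectoryEnsemble",
    "Selection",
    "ValidationError",
    "SelectionError",
    "read_structure",
    "read_trajectory",
    "write_trajectory",
    "read_params",
    "select",
    "write_table",
    "read_table",
]


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


class SelectionError(ValidationError):
    """Raised for empty or malformed atom selections."""


# three-letter codes of the twenty standard amino acids
STANDARD_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    # common protonation-variant names
    "HID", "HIE", "HIP", "CYX", "ASH", "GLH", "LYN",
}

SOLVENT_RESIDUES = {"HOH", "WAT", "TIP3", "SOL"}

# masses (amu) and rough van der Waals radii (Å) for elements that occur in
# desk-scale fixtures; used only as fallbacks when no sidecar row matches
ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "NA": 22.990, "MG": 24.305, "P": 30.974, "S": 32.06, "CL": 35.45,
    "K": 39.098, "CA": 40.078, "FE": 55.845, "ZN": 65.38, "BR": 79.904,
    "I": 126.904, "AR": 39.948, "HE": 4.0026, "NE": 20.180,
}

ELEMENT_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47, "NA": 2.27,
    "MG": 1.73, "P": 1.80, "S": 1.80, "CL": 1.75, "K": 2.75, "CA": 2.31,
    "FE": 2.00, "ZN": 1.39, "BR": 1.85, "I": 1.98, "AR": 1.88, "HE": 1.40,
    "NE": 1.54,
}


@dataclass(frozen=True)
class AtomRecord:
    """One atom with identity and per-atom force-field style parameters."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str
    mass: float
    partial_charge: float = 0.0
    lj_sigma: float = 0.0
    lj_epsilon: float = 0.0
    pb_radius: float = 0.0
    molecule_role: str = "protein"

    def __post_init__(self):
        if self.serial <= 0:
            raise ValidationError(f"atom serial must be positive, got {self.serial}")
        if self.mass <= 0:
            raise ValidationError(f"atom {self.serial} ({self.name}): mass must be > 0")
        if self.lj_epsilon < 0:
            raise ValidationError(f"atom {self.serial} ({self.name}): lj_epsilon must be >= 0")
        if self.pb_radius < 0:
            raise ValidationError(f"atom {self.serial} ({self.name}): pb_radius must be >= 0")
        if self.molecule_role not in ("protein", "ligand", "ion", "solvent"):
            raise ValidationError(f"unknown molecule_role {self.molecule_role!r}")


@dataclass(frozen=True)
class Residue:
    chain_id: str
    residue_seq: int
    residue_name: str
    atom_indices: tuple  # contiguous 0-based indices into Topology.atoms

    @property
    def key(self):
        return (self.chain_id, self.residue_seq, self.residue_name)


class Topology:
    """Ordered atom list with contiguous residue grouping."""

    def __init__(self, atoms: Sequence[AtomRecord]):
        atoms = list(atoms)
        if not atoms:
            raise ValidationError("topology must contain at least one atom")
        serials = [a.serial for a in atoms]
        if len(set(serials)) != len(serials):
            dup = sorted({s for s in serials if serials.count(s) > 1})
            raise ValidationError(f"duplicate atom serials: {dup}")
        self.atoms = atoms
        self.residues = self._group_residues(atoms)

    @staticmethod
    def _group_residues(atoms):
        residues = []
        current_key, start = None, 0
        for i, a in enumerate(atoms):
            key = (a.chain_id, a.residue_seq, a.residue_name)
            if key != current_key:
                if current_key is not None:
                    residues.append(Residue(*current_key, tuple(range(start, i))))
                current_key, start = key, i
        residues.append(Residue(*current_key, tuple(range(start, len(atoms)))))
        seen = set()
        for r in residues:
            if r.key in seen:
                raise ValidationError(
                    f"residue {r.key} appears in non-contiguous atom blocks"
                )
            seen.add(r.key)
        return residues

    def __len__(self):
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms])

    @property
    def pb_radii(self) -> np.ndarray:
        return np.array([a.pb_radius for a in self.atoms])

    @property
    def lj_sigmas(self) -> np.ndarray:
        return np.array([a.lj_sigma for a in self.atoms])

    @property
    def lj_epsilons(self) -> np.ndarray:
        return np.array([a.lj_epsilon for a in self.atoms])

    def residue_of_atom(self, index: int) -> Residue:
        for r in self.residues:
            if r.atom_indices[0] <= index <= r.atom_indices[-1]:
                return r
        raise IndexError(index)

    def subset(self, indices: Sequence[int]) -> "Topology":
        """New topology containing only the given atoms (order preserved)."""
        return Topology([self.atoms[i] for i in indices])


@dataclass
class Frame:
    """One snapshot: N x 3 coordinates in Å, optional orthorhombic box."""

    coords: np.ndarray
    box: np.ndarray | None = None
    time: float = 0.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValidationError(f"coords must be N x 3, got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("coords contain NaN or Inf")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or np.any(self.box <= 0):
                raise ValidationError("box must be three positive lengths")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def copy(self) -> "Frame":
        return Frame(self.coords.copy(),
                     None if self.box is None else self.box.copy(),
                     self.time)


class TrajectoryEnsemble:
    """A topology plus an ordered list of frames."""

    def __init__(self, topology: Topology, frames: Sequence[Frame]):
        frames = list(frames)
        if not frames:
            raise ValidationError("ensemble must contain at least one frame")
        n = topology.n_atoms
        for i, f in enumerate(frames):
            if f.n_atoms != n:
                raise ValidationError(
                    f"frame {i}: expected {n} atoms, got {f.n_atoms}"
                )
        times = [f.time for f in frames]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValidationError("frame times must be non-decreasing")
        self.topology = topology
        self.frames = frames

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms

    def coordinate_array(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) stacked coordinates."""
        return np.stack([f.coords for f in self.frames])

    def window(self, start: int, stop: int | None = None) -> "TrajectoryEnsemble":
        frames = self.frames[start:stop]
        if not frames:
            raise ValidationError(f"empty frame window [{start}:{stop}]")
        return TrajectoryEnsemble(self.topology, frames)

    def subset(self, sel: "Selection") -> "TrajectoryEnsemble":
        idx = list(sel.indices)
        topo = self.topology.subset(idx)
        frames = [Frame(f.coords[idx], f.box, f.time) for f in self.frames]
        return TrajectoryEnsemble(topo, frames)


@dataclass(frozen=True)
class Selection:
    """Strictly increasing 0-based atom indices with a label."""

    indices: tuple
    label: str = ""

    def __post_init__(self):
        idx = tuple(int(i) for i in self.indices)
        if not idx:
            raise SelectionError(f"selection {self.label!r} is empty")
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValidationError("selection indices must be strictly increasing")
        if idx[0] < 0:
            raise ValidationError("selection indices must be non-negative")
        object.__setattr__(self, "indices", idx)

    def __len__(self):
        return len(self.indices)

    def array(self) -> np.ndarray:
        return np.array(self.indices, dtype=int)


# ---------------------------------------------------------------------------
# role inference and parameter sidecar

def _infer_role(residue_name: str, element: str, is_hetatm: bool,
                residue_size: int) -> str:
    rn = residue_name.upper()
    if rn in STANDARD_AMINO_ACIDS:
        return "protein"
    if rn in SOLVENT_RESIDUES:
        return "solvent"
    metal_like = element.upper() in {
        "ZN", "MG", "CA", "NA", "K", "FE", "MN", "CU", "CL", "BR", "I",
    }
    if residue_size == 1 and metal_like:
        return "ion"
    return "ligand"


def read_params(path) -> pd.DataFrame:
    """Read the per-atom parameter sidecar TSV.

    Columns: residue_name, atom_name, mass, charge, sigma, epsilon,
    pb_radius.  Rows key on (residue_name, atom_name).
    """
    df = pd.read_csv(path, sep="\t", dtype={"residue_name": str, "atom_name": str})
    required = {"residue_name", "atom_name", "mass", "charge", "sigma",
                "epsilon", "pb_radius"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"parameter sidecar missing columns: {sorted(missing)}")
    return df


def write_params(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _apply_params(atoms: list[AtomRecord], params: pd.DataFrame | None):
    lookup = {}
    if params is not None:
        for row in params.itertuples(index=False):
            lookup[(row.residue_name.upper(), row.atom_name.upper())] = row
    out = []
    for a in atoms:
        row = lookup.get((a.residue_name.upper(), a.name.upper()))
        if row is not None:
            a = replace(a, mass=float(row.mass), partial_charge=float(row.charge),
                        lj_sigma=float(row.sigma), lj_epsilon=float(row.epsilon),
                        pb_radius=float(row.pb_radius))
        out.append(a)
    return out


# ---------------------------------------------------------------------------
# PDB reading/writing (ATOM/HETATM/MODEL/ENDMDL/TER subset, wwPDB columns)

def _parse_pdb_models(path):
    """Parse the ATOM/HETATM subset of a PDB file via Biopython.

    Returns (atom_meta, list-of-coordinate-arrays); atom_meta is taken from
    the first model.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("s", str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # Biopython raises various exception types
        raise ValidationError(f"cannot parse PDB file {path}: {exc}") from exc

    models = list(structure)
    if not models:
        raise ValidationError(f"{path}: no models found")

    meta = []
    coord_sets = []
    for mi, model in enumerate(models):
        coords = []
        count = 0
        for chain in model:
            for residue in chain:
                hetflag, resseq, _ = residue.id
                is_het = hetflag.strip() != ""
                for atom in residue:
                    count += 1
                    coords.append(atom.coord.astype(float))
                    if mi == 0:
                        element = (atom.element or "").strip().upper()
                        if not element:
                            element = atom.get_name().strip()[0].upper()
                        meta.append(dict(
                            serial=atom.serial_number,
                            name=atom.get_name().strip(),
                            element=element,
                            residue_name=residue.get_resname().strip(),
                            residue_seq=int(resseq),
                            chain_id=(chain.id.strip() or "A"),
                            is_hetatm=is_het,
                        ))
        coord_sets.append(np.array(coords))
    return meta, coord_sets


def read_structure(path, params_path=None) -> TrajectoryEnsemble:
    """Read a PDB structure into a single-frame ensemble.

    Atoms lacking a sidecar parameter row fall back to an element mass
    lookup, zero partial charge, zero LJ epsilon, and an element van der
    Waals radius for the PB radius.  Molecule roles are inferred from
    residue names (standard amino acids -> protein, HOH -> solvent,
    single-atom metal records -> ion, anything else -> ligand).
    """
    meta, coord_sets = _parse_pdb_models(path)
    if not meta:
        raise ValidationError(f"{path}: no ATOM/HETATM records")
    serials = [m["serial"] for m in meta]
    if len(set(serials)) != len(serials):
        dup = sorted({s for s in serials if serials.count(s) > 1})
        raise ValidationError(f"{path}: duplicate atom serials {dup}")

    # residue sizes for ion inference
    res_sizes: dict = {}
    for m in meta:
        key = (m["chain_id"], m["residue_seq"], m["residue_name"])
        res_sizes[key] = res_sizes.get(key, 0) + 1

    atoms = []
    for m in meta:
        el = m["element"]
        if el not in ELEMENT_MASSES:
            raise ValidationError(
                f"unknown element {el!r} in record serial {m['serial']} "
                f"({m['residue_name']} {m['name']})"
            )
        key = (m["chain_id"], m["residue_seq"], m["residue_name"])
        role = _infer_role(m["residue_name"], el, m["is_hetatm"], res_sizes[key])
        atoms.append(AtomRecord(
            serial=m["serial"], name=m["name"], element=el,
            residue_name=m["residue_name"], residue_seq=m["residue_seq"],
            chain_id=m["chain_id"], mass=ELEMENT_MASSES[el],
            partial_charge=0.0, lj_sigma=0.0, lj_epsilon=0.0,
            pb_radius=ELEMENT_RADII[el], molecule_role=role,
        ))

    if params_path is not None:
        atoms = _apply_params(atoms, read_params(params_path))

    topo = Topology(atoms)
    frame = Frame(coord_sets[0], box=None, time=0.0)
    return TrajectoryEnsemble(topo, [frame])


def read_trajectory(path, topology: Topology) -> TrajectoryEnsemble:
    """Read a multi-model PDB or XYZ frame series against a known topology."""
    path = Path(path)
    text_head = path.open().readline()
    if _looks_like_xyz(text_head):
        frames = _read_xyz_frames(path, topology)
    else:
        _, coord_sets = _parse_pdb_models(path)
        frames = []
        for i, coords in enumerate(coord_sets):
            if coords.shape[0] != topology.n_atoms:
                raise ValidationError(
                    f"frame {i}: expected {topology.n_atoms} atoms, "
                    f"got {coords.shape[0]}"
                )
            frames.append(Frame(coords, time=float(i)))
    return TrajectoryEnsemble(topology, frames)


def _looks_like_xyz(first_line: str) -> bool:
    try:
        int(first_line.split()[0])
        return len(first_line.split()) == 1
    except (ValueError, IndexError):
        return False


def _read_xyz_frames(path, topology):
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos, fi = 0, 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        n = int(lines[pos].split()[0])
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        time = 0.0
        if "t=" in comment:
            try:
                time = float(comment.split("t=")[1].split()[0])
            except (ValueError, IndexError):
                pass
        body = lines[pos + 2: pos + 2 + n]
        if len(body) < n or any(len(l.split()) < 4 for l in body):
            got = sum(1 for l in body if len(l.split()) >= 4)
            raise ValidationError(f"frame {fi}: expected {n} atoms, got {got}")
        if n != topology.n_atoms:
            raise ValidationError(
                f"frame {fi}: expected {topology.n_atoms} atoms, got {n}"
            )
        coords = np.array([[float(x) for x in l.split()[1:4]] for l in body])
        frames.append(Frame(coords, time=time))
        pos += 2 + n
        fi += 1
    if not frames:
        raise ValidationError(f"{path}: no frames found")
    return frames


_PDB_ATOM_FMT = (
    "{record:<6s}{serial:>5d} {name:<4s}{altloc:1s}{resname:<3s} {chain:1s}"
    "{resseq:>4d}{icode:1s}   {x:>8.3f}{y:>8.3f}{z:>8.3f}{occ:>6.2f}{b:>6.2f}"
    "          {element:>2s}\n"
)


def _format_atom_name(name: str, element: str) -> str:
    # wwPDB: element symbols of one letter start in column 14
    if len(element) == 1 and len(name) < 4:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_trajectory(ensemble: TrajectoryEnsemble, path, fmt: str | None = None):
    """Write frames as multi-model PDB or XYZ (chosen by extension or fmt)."""
    path = Path(path)
    if fmt is None:
        fmt = "xyz" if path.suffix.lower() == ".xyz" else "pdb"
    if fmt == "xyz":
        with open(path, "w") as fh:
            for f in ensemble.frames:
                fh.write(f"{ensemble.n_atoms}\n")
                fh.write(f"t={f.time:.4f}\n")
                for a, xyz in zip(ensemble.topology.atoms, f.coords):
                    fh.write(f"{a.element:<2s} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}\n")
        return
    with open(path, "w") as fh:
        multi = ensemble.n_frames > 1
        for mi, f in enumerate(ensemble.frames, start=1):
            if multi:
                fh.write(f"MODEL     {mi:>4d}\n")
            for a, xyz in zip(ensemble.topology.atoms, f.coords):
                record = "ATOM" if a.molecule_role == "protein" else "HETATM"
                fh.write(_PDB_ATOM_FMT.format(
                    record=record, serial=a.serial,
                    name=_format_atom_name(a.name, a.element), altloc=" ",
                    resname=a.residue_name[:3], chain=a.chain_id[:1],
                    resseq=a.residue_seq, icode=" ",
                    x=xyz[0], y=xyz[1], z=xyz[2], occ=1.0, b=0.0,
                    element=a.element[:2],
                ))
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# selection mini-grammar

def select(topology: Topology, expr: str) -> Selection:
    """Evaluate a selection expression against a topology.

    Grammar: clauses joined by ``and``; each clause is a role keyword
    (``protein`` | ``ligand`` | ``ion`` | ``solvent``), an atom-name match
    (``name CA CB``), or a residue range (``resid 10-20`` / ``resid 5``).
    Multiple values inside one clause are OR-ed.
    """
    tokens = expr.split()
    if not tokens:
        raise SelectionError("empty selection expression")
    clauses: list[list[str]] = [[]]
    for t in tokens:
        if t.lower() == "and":
            if not clauses[-1]:
                raise SelectionError(f"malformed expression {expr!r}")
            clauses.append([])
        else:
            clauses[-1].append(t)
    if not clauses[-1]:
        raise SelectionError(f"malformed expression {expr!r}")

    mask = np.ones(topology.n_atoms, dtype=bool)
    for clause in clauses:
        mask &= _eval_clause(topology, clause, expr)
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        raise SelectionError(f"selection {expr!r} matched no atoms")
    return Selection(tuple(int(i) for i in idx), label=expr)


def _eval_clause(topology, clause, expr):
    head = clause[0].lower()
    atoms = topology.atoms
    if head in ("protein", "ligand", "ion", "solvent"):
        if len(clause) != 1:
            raise SelectionError(f"malformed clause {' '.join(clause)!r} in {expr!r}")
        return np.array([a.molecule_role == head for a in atoms])
    if head == "name":
        if len(clause) < 2:
            raise SelectionError(f"'name' needs at least one atom name in {expr!r}")
        names = {n.upper() for n in clause[1:]}
        return np.array([a.name.upper() in names for a in atoms])
    if head == "resid":
        if len(clause) < 2:
            raise SelectionError(f"'resid' needs a value or range in {expr!r}")
        wanted = set()
        for spec in clause[1:]:
            if "-" in spec[1:]:
                lo, hi = spec.split("-", 1) if not spec.startswith("-") else (None, None)
                try:
                    lo, hi = int(lo), int(hi)
                except (TypeError, ValueError):
                    raise SelectionError(f"bad resid range {spec!r} in {expr!r}")
                wanted.update(range(lo, hi + 1))
            else:
                try:
                    wanted.add(int(spec))
                except ValueError:
                    raise SelectionError(f"bad resid {spec!r} in {expr!r}")
        return np.array([a.residue_seq in wanted for a in atoms])
    raise SelectionError(f"unknown selection keyword {clause[0]!r} in {expr!r}")


# ---------------------------------------------------------------------------
# tabular reports

def write_table(rows: Iterable[dict], path, float_fmt: str = "%.2f",
                columns: Sequence[str] | None = None) -> None:
    """Write keyed numeric records as a TSV with fixed column order.

    Column order follows the first row (or ``columns`` when given); all rows
    must share the same keys.  Energies (floats) are printed with two
    decimals by default.  Empty ``rows`` with ``columns`` yields a
    header-only file.
    """
    rows = list(rows)
    if not rows:
        Path(path).write_text("\t".join(columns) + "\n" if columns else "")
        return
    keys = list(columns) if columns is not None else list(rows[0].keys())
    for i, r in enumerate(rows):
        if list(r.keys()) != keys:
            raise ValidationError(
                f"row {i} keys {list(r.keys())} differ from header {keys}"
            )
    df = pd.DataFrame(rows, columns=keys)
    df.to_csv(path, sep="\t", index=False, float_format=float_fmt)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
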