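"""Structure, trajectory, and volumetric-grid I/O plus a minimal atom-selection grammar.

Formats handled (deliberately small dialects, documented below):

* PDB — ATOM/HETATM records, multi-model trajectories via MODEL/ENDMDL.
  Element taken from columns 77-78 when non-blank, otherwise inferred from the
  atom-name field (leading alphabetic characters, digits stripped).
* XYZ — single and multi-frame.
* Cube — volumetric scalar fields with atom records, z-fastest value ordering,
  coordinates written in Bohr (the format's convention); all in-memory
  geometry stays in Angstrom.
* Delimited tables (comma or tab, header row) for orbital energies.

The selection grammar is a conjunction of simple predicates::

    resname FMN and name N5
    resname TNT and not element H

Supported predicates: ``resname X``, ``resid N``, ``name X``, ``element X``,
and the negation ``not element X``.  No ranges, no wildcards.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .reactivity import OrbitalEnergies

BOHR_PER_ANGSTROM = 1.8897259886
ANGSTROM_PER_BOHR = 1.0 / BOHR_PER_ANGSTROM

#: Elements the toolkit recognizes (atomic numbers for cube atom records).
ATOMIC_NUMBERS = {
    "H": 1, "C": 6, "N": 7, "O": 8, "F": 9, "P": 15, "S": 16, "CL": 17,
    "BR": 35, "I": 53, "FE": 26, "MG": 12, "ZN": 30, "NA": 11, "K": 19,
}
_NUM_TO_ELEMENT = {z: el.capitalize() for el, z in ATOMIC_NUMBERS.items()}

_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


class ParseError(ValueError):
    """A file did not parse under the expected format."""


class SelectionError(ValueError):
    """A selection expression was syntactically invalid."""


@dataclass(frozen=True)
class Atom:
    element: str
    name: str
    residue_name: str
    residue_id: int
    chain: str
    position: np.ndarray  # 3-vector, Angstrom

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        object.__setattr__(self, "position", pos)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if self.element.upper() not in ATOMIC_NUMBERS:
            raise ValueError(
                f"unknown element {self.element!r} for atom {self.name} "
                f"({self.residue_name} {self.residue_id})"
            )


@dataclass
class Structure:
    atoms: list[Atom]
    title: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("a Structure needs at least one atom")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError("coordinate array shape does not match atom count")
        atoms = [
            Atom(a.element, a.name, a.residue_name, a.residue_id, a.chain, xyz)
            for a, xyz in zip(self.atoms, coords)
        ]
        return Structure(atoms, self.title)


@dataclass
class Trajectory:
    topology: Structure
    frames: np.ndarray  # (n_frames, n_atoms, 3), Angstrom
    frame_times: np.ndarray | None = None  # ns

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (self.topology.n_atoms, 3):
            raise ValueError(
                f"frames must be (n_frames, {self.topology.n_atoms}, 3); "
                f"got {self.frames.shape}"
            )
        if self.frame_times is not None:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if self.frame_times.shape != (self.n_frames,):
                raise ValueError("frame_times length must equal frame count")
            if self.n_frames > 1 and not np.all(np.diff(self.frame_times) > 0):
                raise ValueError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_structure(self, i: int) -> Structure:
        return self.topology.with_coords(self.frames[i])


@dataclass(frozen=True)
class AtomSelection:
    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("selection indices must be unique")
        if any(i < 0 for i in self.indices):
            raise ValueError("selection indices must be nonnegative")

    def __len__(self) -> int:
        return len(self.indices)

    def validate(self, structure: Structure) -> None:
        if any(i >= structure.n_atoms for i in self.indices):
            raise ValueError("selection index out of bounds for structure")


@dataclass
class VolumetricGrid:
    """A scalar field on a regular (possibly skewed) 3-D grid, Angstrom geometry."""

    origin: np.ndarray  # (3,), Angstrom
    axes: np.ndarray  # (3, 3) step vectors (rows), Angstrom
    shape: tuple[int, int, int]
    values: np.ndarray  # flat, z-fastest ordering, length prod(shape)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        self.shape = tuple(int(n) for n in self.shape)
        self.values = np.asarray(self.values, dtype=float).ravel()
        if any(n < 1 for n in self.shape):
            raise ValueError("grid shape entries must be positive")
        if abs(np.linalg.det(self.axes)) < 1e-12:
            raise ValueError("grid axes must be linearly independent")
        if self.values.size != int(np.prod(self.shape)):
            raise ValueError(
                f"value count {self.values.size} does not match shape "
                f"{self.shape} (expected {int(np.prod(self.shape))})"
            )

    def points(self) -> np.ndarray:
        """Grid node coordinates, (N, 3) Angstrom, z-fastest ordering."""
        nx, ny, nz = self.shape
        ii, jj, kk = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1).astype(float)
        return self.origin[None, :] + idx @ self.axes


# ---------------------------------------------------------------------------
# element inference

def _infer_element(atom_name: str, element_field: str = "") -> str:
    el = element_field.strip()
    if el:
        cand = el.upper()
    else:
        stripped = re.sub(r"\d", "", atom_name).strip()
        m = re.match(r"[A-Za-z]+", stripped)
        if not m:
            raise ParseError(f"cannot infer element from atom name {atom_name!r}")
        token = m.group(0).upper()
        # Two-letter symbols only when the full token matches one (CL, FE, ...);
        # otherwise the leading letter (CA is an alpha carbon, not calcium, in
        # protein PDB naming).
        cand = token if token in ATOMIC_NUMBERS and len(token) > 1 else token[0]
    if cand not in ATOMIC_NUMBERS:
        raise ParseError(f"unknown element {cand!r} for atom {atom_name!r}")
    return cand.capitalize() if len(cand) > 1 else cand


# ---------------------------------------------------------------------------
# PDB

def _parse_pdb_atom(line: str, lineno: int) -> Atom:
    try:
        name = line[12:16].strip()
        resname = line[17:20].strip()
        chain = line[21:22].strip() or "A"
        resid = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"line {lineno}: malformed PDB atom record: {exc}") from exc
    element = _infer_element(name, line[76:78] if len(line) >= 78 else "")
    return Atom(element, name, resname, resid, chain, np.array([x, y, z]))


def _read_pdb_models(path: Path) -> tuple[list[list[Atom]], str]:
    models: list[list[Atom]] = []
    current: list[Atom] = []
    title = ""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "TITLE":
                title = (title + " " + line[10:].strip()).strip()
            elif rec == "MODEL":
                if current:
                    models.append(current)
                current = []
            elif rec == "ENDMDL":
                models.append(current)
                current = []
            elif rec in ("ATOM", "HETATM"):
                current.append(_parse_pdb_atom(line, lineno))
    if current:
        models.append(current)  # trailing atoms / file without MODEL records
    if not models:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    return models, title


def _format_pdb_atom(atom: Atom, serial: int) -> str:
    record = "ATOM" if atom.residue_name.upper() in _AMINO_ACIDS else "HETATM"
    name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3}"
    x, y, z = atom.position
    return (
        f"{record:<6}{serial:>5} {name:<4} {atom.residue_name:>3} "
        f"{atom.chain:1}{atom.residue_id:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
        f"{atom.element.upper():>2}"
    )


# ---------------------------------------------------------------------------
# XYZ

def _read_xyz_frames(path: Path) -> tuple[list[tuple[str, list[tuple[str, np.ndarray]]]], None]:
    frames = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError as exc:
            raise ParseError(f"line {i + 1}: expected atom count, got "
                             f"{lines[i].strip()!r}") from exc
        comment = lines[i + 1].rstrip("\n") if i + 1 < len(lines) else ""
        atoms = []
        for k in range(natoms):
            lineno = i + 2 + k
            if lineno >= len(lines):
                raise ParseError(f"line {lineno + 1}: truncated XYZ frame")
            parts = lines[lineno].split()
            if len(parts) < 4:
                raise ParseError(f"line {lineno + 1}: malformed XYZ atom line")
            try:
                xyz = np.array([float(p) for p in parts[1:4]])
            except ValueError as exc:
                raise ParseError(
                    f"line {lineno + 1}: malformed XYZ coordinates"
                ) from exc
            atoms.append((parts[0], xyz))
        frames.append((comment, atoms))
        i += 2 + natoms
    if not frames:
        raise ParseError(f"{path}: empty XYZ file")
    return frames, None


def _xyz_atoms_to_structure(atoms: list[tuple[str, np.ndarray]], title: str) -> Structure:
    return Structure(
        [
            Atom(_infer_element(sym), sym, "MOL", 1, "A", xyz)
            for sym, xyz in atoms
        ],
        title=title,
    )


# ---------------------------------------------------------------------------
# public structure / trajectory API

def _guess_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("pdb", "ent"):
        return "pdb"
    if suffix == "xyz":
        return "xyz"
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


def read_structure(path, format: str | None = None) -> Structure:
    """Read a single-frame structure from a PDB or XYZ file."""
    path = Path(path)
    fmt = _guess_format(path, format)
    if fmt == "pdb":
        models, title = _read_pdb_models(path)
        return Structure(models[0], title=title)
    if fmt == "xyz":
        frames, _ = _read_xyz_frames(path)
        comment, atoms = frames[0]
        return _xyz_atoms_to_structure(atoms, comment)
    raise ValueError(f"unsupported structure format {fmt!r}")


def write_structure(structure: Structure, path, format: str | None = None) -> None:
    path = Path(path)
    fmt = _guess_format(path, format)
    if fmt == "pdb":
        lines = []
        if structure.title:
            lines.append(f"TITLE     {structure.title}")
        lines += [_format_pdb_atom(a, i + 1) for i, a in enumerate(structure.atoms)]
        lines.append("END")
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "xyz":
        lines = [str(structure.n_atoms), structure.title]
        for a in structure.atoms:
            x, y, z = a.position
            lines.append(f"{a.element:<2} {x:18.10f} {y:18.10f} {z:18.10f}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unsupported structure format {fmt!r}")


def read_trajectory(path, format: str | None = None) -> Trajectory:
    """Read a multi-model PDB or multi-frame XYZ file as a Trajectory.

    The topology is taken from the first frame; every later frame must carry
    the same atom count (and, for PDB, the same atom ordering is assumed).
    """
    path = Path(path)
    fmt = _guess_format(path, format)
    if fmt == "pdb":
        models, title = _read_pdb_models(path)
        topo = Structure(models[0], title=title)
        frames = np.empty((len(models), topo.n_atoms, 3))
        for i, model in enumerate(models):
            if len(model) != topo.n_atoms:
                raise ParseError(
                    f"frame {i + 1}: atom count {len(model)} differs from "
                    f"frame 1 ({topo.n_atoms})"
                )
            frames[i] = [a.position for a in model]
        return Trajectory(topo, frames)
    if fmt == "xyz":
        raw, _ = _read_xyz_frames(path)
        comment, atoms0 = raw[0]
        topo = _xyz_atoms_to_structure(atoms0, comment)
        frames = np.empty((len(raw), topo.n_atoms, 3))
        for i, (_, atoms) in enumerate(raw):
            if len(atoms) != topo.n_atoms:
                raise ParseError(
                    f"frame {i + 1}: atom count {len(atoms)} differs from "
                    f"frame 1 ({topo.n_atoms})"
                )
            frames[i] = [xyz for _, xyz in atoms]
        return Trajectory(topo, frames)
    raise ValueError(f"unsupported trajectory format {fmt!r}")


def write_trajectory(traj: Trajectory, path, format: str | None = None) -> None:
    path = Path(path)
    fmt = _guess_format(path, format)
    if fmt == "pdb":
        lines = []
        if traj.topology.title:
            lines.append(f"TITLE     {traj.topology.title}")
        for i in range(traj.n_frames):
            lines.append(f"MODEL     {i + 1:>4}")
            frame = traj.topology.with_coords(traj.frames[i])
            lines += [_format_pdb_atom(a, j + 1) for j, a in enumerate(frame.atoms)]
            lines.append("ENDMDL")
        lines.append("END")
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "xyz":
        chunks = []
        for i in range(traj.n_frames):
            frame = traj.topology.with_coords(traj.frames[i])
            lines = [str(frame.n_atoms), f"frame {i + 1}"]
            for a in frame.atoms:
                x, y, z = a.position
                lines.append(f"{a.element:<2} {x:18.10f} {y:18.10f} {z:18.10f}")
            chunks.append("\n".join(lines))
        path.write_text("\n".join(chunks) + "\n")
    else:
        raise ValueError(f"unsupported trajectory format {fmt!r}")


# ---------------------------------------------------------------------------
# selections

_PREDICATE_RE = re.compile(
    r"^(?P<neg>not\s+)?(?P<key>resname|resid|name|element)\s+(?P<value>\S+)$"
)


def select_atoms(structure: Structure, expression: str) -> AtomSelection:
    """Evaluate a conjunction of simple predicates against a structure.

    Grammar: ``predicate ('and' predicate)*`` with predicates ``resname X``,
    ``resid N``, ``name X``, ``element X``, ``not element X``.  Matching is
    case-insensitive.  An empty match is a valid (empty) selection.
    """
    clauses = [c.strip() for c in re.split(r"\band\b", expression)]
    if not clauses or any(not c for c in clauses):
        raise SelectionError(f"invalid selection expression: {expression!r}")
    tests = []
    for clause in clauses:
        m = _PREDICATE_RE.match(clause)
        if m is None:
            raise SelectionError(
                f"invalid selection expression: {expression!r} "
                f"(cannot parse clause {clause!r})"
            )
        key, value, neg = m["key"], m["value"], bool(m["neg"])
        if neg and key != "element":
            raise SelectionError(
                f"invalid selection expression: {expression!r} "
                f"(negation is only supported for 'element')"
            )
        if key == "resid":
            try:
                want_id = int(value)
            except ValueError as exc:
                raise SelectionError(
                    f"invalid selection expression: {expression!r} "
                    f"(resid needs an integer, got {value!r})"
                ) from exc
            tests.append(lambda a, want=want_id: a.residue_id == want)
        else:
            attr = {"resname": "residue_name", "name": "name", "element": "element"}[key]
            want = value.upper()
            if neg:
                tests.append(lambda a, attr=attr, want=want: getattr(a, attr).upper() != want)
            else:
                tests.append(lambda a, attr=attr, want=want: getattr(a, attr).upper() == want)
    indices = tuple(
        i for i, a in enumerate(structure.atoms) if all(t(a) for t in tests)
    )
    return AtomSelection(indices)


def select_single_atom(structure: Structure, expression: str) -> int:
    """Resolve a selection that must match exactly one atom; return its index."""
    sel = select_atoms(structure, expression)
    if len(sel) != 1:
        matches = [
            f"{structure.atoms[i].residue_name}{structure.atoms[i].residue_id}:"
            f"{structure.atoms[i].name}"
            for i in sel.indices
        ]
        raise ValueError(
            f"selection {expression!r} must match exactly one atom; "
            f"matched {len(sel)}: {matches}"
        )
    return sel.indices[0]


# ---------------------------------------------------------------------------
# cube files

def write_grid(grid: VolumetricGrid, structure: Structure, path) -> None:
    """Write a volumetric grid plus atom records as a cube-format file.

    Geometry is converted to Bohr (positive atom counts mark Bohr units in the
    format); values are emitted z-fastest, six per line.
    """
    path = Path(path)
    lines = [
        "xenbkit volumetric field",
        "cube format: z-fastest value ordering, Bohr geometry",
    ]
    origin_b = grid.origin * BOHR_PER_ANGSTROM
    lines.append(
        f"{structure.n_atoms:5d}{origin_b[0]:12.6f}{origin_b[1]:12.6f}{origin_b[2]:12.6f}"
    )
    for n, axis in zip(grid.shape, grid.axes):
        ab = axis * BOHR_PER_ANGSTROM
        lines.append(f"{n:5d}{ab[0]:12.6f}{ab[1]:12.6f}{ab[2]:12.6f}")
    for atom in structure.atoms:
        z = ATOMIC_NUMBERS[atom.element.upper()]
        pb = atom.position * BOHR_PER_ANGSTROM
        lines.append(f"{z:5d}{float(z):12.6f}{pb[0]:12.6f}{pb[1]:12.6f}{pb[2]:12.6f}")
    vals = grid.values
    for start in range(0, vals.size, 6):
        lines.append("".join(f"{v:14.6E}" for v in vals[start:start + 6]))
    path.write_text("\n".join(lines) + "\n")


def read_grid(path) -> tuple[VolumetricGrid, Structure]:
    """Read a cube-format file back into a grid (Angstrom) and its atoms."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.readlines()
    if len(lines) < 7:
        raise ParseError(f"{path}: truncated cube file")
    try:
        head = lines[2].split()
        natoms = int(head[0])
        origin = np.array([float(x) for x in head[1:4]]) * ANGSTROM_PER_BOHR
        shape = []
        axes = []
        for i in range(3):
            parts = lines[3 + i].split()
            shape.append(abs(int(parts[0])))
            axes.append([float(x) * ANGSTROM_PER_BOHR for x in parts[1:4]])
        atoms = []
        for i in range(natoms):
            parts = lines[6 + i].split()
            z = int(parts[0])
            pos = np.array([float(x) for x in parts[2:5]]) * ANGSTROM_PER_BOHR
            el = _NUM_TO_ELEMENT.get(z)
            if el is None:
                raise ParseError(f"{path}: unsupported atomic number {z}")
            atoms.append(Atom(el, el, "MOL", 1, "A", pos))
        values = []
        for line in lines[6 + natoms:]:
            values.extend(float(v) for v in line.split())
    except (ValueError, IndexError) as exc:
        raise ParseError(f"{path}: malformed cube file: {exc}") from exc
    grid = VolumetricGrid(origin, np.array(axes), tuple(shape), np.array(values))
    return grid, Structure(atoms, title="cube atoms")


# ---------------------------------------------------------------------------
# orbital-energy tables

_ORBITAL_COLUMN_ALIASES = {
    "compound": "compound", "id": "compound", "name": "compound",
    "eps_homo": "eps_homo", "homo": "eps_homo", "e_homo": "eps_homo",
    "eps_homo_ev": "eps_homo",
    "eps_lumo": "eps_lumo", "lumo": "eps_lumo", "e_lumo": "eps_lumo",
    "eps_lumo_ev": "eps_lumo",
}


def read_orbital_table(path) -> list[OrbitalEnergies]:
    """Read a delimited table of per-compound frontier orbital energies (eV).

    Requires a header row naming a compound column and HOMO/LUMO energy
    columns (``eps_homo``/``eps_lumo`` or common aliases); comma or tab
    delimited.  Rows with eps_lumo < eps_homo are rejected.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    rename = {}
    for col in df.columns:
        alias = _ORBITAL_COLUMN_ALIASES.get(col.strip().lower())
        if alias is not None and alias not in rename.values():
            rename[col] = alias
    df = df.rename(columns=rename)
    missing = {"compound", "eps_homo", "eps_lumo"} - set(df.columns)
    if missing:
        raise ParseError(
            f"{path}: missing required column(s): {', '.join(sorted(missing))}"
        )
    records = []
    for _, row in df.iterrows():
        if float(row["eps_lumo"]) < float(row["eps_homo"]):
            raise ValueError(
                f"{row['compound']}: eps_lumo ({row['eps_lumo']}) below eps_homo "
                f"({row['eps_homo']}); an occupied level above the unoccupied "
                "one is unphysical here"
            )
        records.append(
            OrbitalEnergies(str(row["compound"]), float(row["eps_homo"]),
                            float(row["eps_lumo"]))
        )
    return records
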