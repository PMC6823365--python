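"""Structure and trajectory I/O, atom selection, superposition and RMSD.

Fixed-width PDB and whitespace-delimited PQR records are parsed directly so
that altloc policy, identifier round-trips and PQR charge/radius columns are
under explicit control.  Coordinates are in Å throughout; the membrane normal
is +z by convention.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "Structure",
    "TrajectoryFrame",
    "AtomSelection",
    "PDBParseError",
    "SelectionError",
    "VDW_RADII",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "select",
    "superpose",
    "region_rmsd",
]

#: Bondi-style van der Waals radii by element symbol (Å).  Overridable via
#: the ``vdw_overrides`` argument of :func:`read_structure`.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "K": 2.75,
    "NA": 2.27,
    "MG": 1.73,
    "CA": 2.31,
    "ZN": 1.39,
    "FE": 1.95,
    "BR": 1.85,
    "I": 1.98,
}

_FALLBACK_RADIUS = 1.70

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})

_WATER_NAMES = frozenset({"HOH", "TIP3", "WAT", "SOL", "TIP", "SPC"})


class PDBParseError(ValueError):
    """Raised when an ATOM/HETATM record cannot be parsed."""


class SelectionError(ValueError):
    """Raised when a selection is empty or refers to missing residues."""


@dataclass(frozen=True)
class AtomRecord:
    """A single atom with identifiers, coordinates and assigned radius."""

    serial: int
    atom_name: str
    residue_name: str
    chain_id: str
    residue_number: int
    coords: np.ndarray  # shape (3,), Å
    element: str
    vdw_radius: float = _FALLBACK_RADIUS
    partial_charge: float | None = None
    altloc: str = ""
    occupancy: float = 1.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "coords", np.asarray(self.coords, dtype=float).reshape(3)
        )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.serial}")
        if self.vdw_radius <= 0:
            raise ValueError(f"vdw_radius must be > 0 (atom {self.serial})")

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"

    @property
    def is_water(self) -> bool:
        return self.residue_name in _WATER_NAMES


@dataclass
class Structure:
    """An ordered collection of atoms with stable identifiers."""

    atoms: list[AtomRecord]
    title: str = ""

    def __post_init__(self) -> None:
        self._index = None  # lazily built residue lookup

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coordinate array shape {coords.shape} does not match atom "
                f"count {len(self.atoms)}"
            )
        atoms = [replace(a, coords=c) for a, c in zip(self.atoms, coords)]
        return Structure(atoms, title=self.title)

    def _residue_index(self) -> dict[tuple[str, int], list[int]]:
        if self._index is None:
            idx: dict[tuple[str, int], list[int]] = {}
            for i, a in enumerate(self.atoms):
                idx.setdefault((a.chain_id, a.residue_number), []).append(i)
            self._index = idx
        return self._index

    def residue_atoms(self, chain: str, number: int) -> list[int]:
        """Indices of atoms belonging to residue ``(chain, number)``."""
        return self._residue_index().get((chain, number), [])

    def has_residue(self, chain: str, number: int) -> bool:
        return bool(self.residue_atoms(chain, number))


@dataclass(frozen=True)
class TrajectoryFrame:
    """One coordinate frame aligned to a reference :class:`Structure`."""

    frame_index: int
    coords: np.ndarray  # (N, 3) Å
    time: float | None = None  # ns

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "coords", np.asarray(self.coords, dtype=float).reshape(-1, 3)
        )


@dataclass(frozen=True)
class AtomSelection:
    """Ordered, unique indices into ``Structure.atoms``."""

    indices: tuple[int, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("selection indices must be unique")

    def __len__(self) -> int:
        return len(self.indices)


# ---------------------------------------------------------------------------
# Parsing


def _parse_pdb_atom_line(line: str, lineno: int) -> AtomRecord:
    try:
        serial = int(line[6:11])
        atom_name = line[12:16].strip()
        altloc = line[16].strip()
        residue_name = line[17:20].strip()
        chain_id = line[21].strip() or "A"
        residue_number = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        element = line[76:78].strip().upper()
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"malformed {line[:6].strip()} record at line {lineno}: {exc}") from exc
    if not element:
        element = _guess_element(atom_name)
    return AtomRecord(
        serial=serial,
        atom_name=atom_name,
        residue_name=residue_name,
        chain_id=chain_id,
        residue_number=residue_number,
        coords=np.array([x, y, z]),
        element=element,
        vdw_radius=_radius_for(element),
        altloc=altloc,
        occupancy=occupancy,
        is_hetero=line.startswith("HETATM"),
    )


def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    if not name:
        return "C"
    # two-letter elements common in biomolecules
    head = name.lstrip("0123456789")
    if head[:2].upper() in ("CL", "BR", "NA", "MG", "ZN", "FE"):
        return head[:2].upper()
    return head[0].upper()


def _radius_for(element: str, overrides: dict[str, float] | None = None) -> float:
    table = VDW_RADII if overrides is None else {**VDW_RADII, **overrides}
    if element in table:
        return table[element]
    warnings.warn(
        f"unknown element {element!r}: falling back to vdW radius "
        f"{_FALLBACK_RADIUS} Å",
        stacklevel=2,
    )
    return _FALLBACK_RADIUS


def _parse_pqr_atom_line(line: str, lineno: int) -> AtomRecord:
    fields = line.split()
    # PDB-like whitespace PQR: name serial atom res [chain] resnum x y z q r
    try:
        if len(fields) == 11:
            (_, serial, atom_name, residue_name, chain_id, residue_number,
             x, y, z, q, r) = fields
        elif len(fields) == 10:
            (_, serial, atom_name, residue_name, residue_number,
             x, y, z, q, r) = fields
            chain_id = "A"
        else:
            raise ValueError(f"expected 10 or 11 fields, got {len(fields)}")
        return AtomRecord(
            serial=int(serial),
            atom_name=atom_name,
            residue_name=residue_name,
            chain_id=chain_id,
            residue_number=int(residue_number),
            coords=np.array([float(x), float(y), float(z)]),
            element=_guess_element(atom_name),
            vdw_radius=max(float(r), 1e-6),
            partial_charge=float(q),
            is_hetero=line.startswith("HETATM"),
        )
    except ValueError as exc:
        raise PDBParseError(f"malformed PQR record at line {lineno}: {exc}") from exc


def _resolve_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep a single conformer per atom: highest occupancy, ties -> 'A'."""
    best: dict[tuple[str, int, str], AtomRecord] = {}
    order: list[tuple[str, int, str]] = []
    any_alt = any(a.altloc for a in atoms)
    if not any_alt:
        return atoms
    for a in atoms:
        key = (a.chain_id, a.residue_number, a.atom_name)
        cur = best.get(key)
        if cur is None:
            best[key] = a
            order.append(key)
        else:
            if (a.occupancy, -ord(a.altloc or "Z")) > (
                cur.occupancy, -ord(cur.altloc or "Z")
            ):
                best[key] = a
    return [replace(best[k], altloc="") for k in order]


def read_structure(
    path: str | Path,
    format: str | None = None,
    *,
    model: int = 1,
    vdw_overrides: dict[str, float] | None = None,
) -> Structure:
    """Read a PDB or PQR file into a :class:`Structure`.

    Parameters
    ----------
    path:
        Input file.  Format is inferred from the suffix when not given.
    format:
        ``"pdb"`` or ``"pqr"``.
    model:
        1-based MODEL number to read from multi-model PDB files.
    vdw_overrides:
        Element -> radius overrides applied on top of the built-in table
        (PDB input only; PQR radii come from the file).
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower() or "pdb"
    if format not in ("pdb", "pqr"):
        raise ValueError(f"unsupported format {format!r}")

    atoms: list[AtomRecord] = []
    title = ""
    current_model = 0
    in_target_model = model == 1  # files without MODEL records
    saw_model_records = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "TITLE ":
                title = (title + " " + line[10:].strip()).strip()
            elif rec.startswith("MODEL"):
                saw_model_records = True
                current_model += 1
                in_target_model = current_model == model
            elif rec.startswith("ENDMDL"):
                in_target_model = False
            elif rec in ("ATOM  ", "HETATM") and in_target_model:
                if format == "pqr":
                    atoms.append(_parse_pqr_atom_line(line, lineno))
                else:
                    atom = _parse_pdb_atom_line(line, lineno)
                    if vdw_overrides is not None:
                        atom = replace(
                            atom,
                            vdw_radius=_radius_for(atom.element, vdw_overrides),
                        )
                    atoms.append(atom)
    if saw_model_records and current_model < model:
        raise PDBParseError(f"model {model} not present in {path}")
    if not atoms:
        raise PDBParseError(f"no ATOM/HETATM records read from {path}")
    atoms = _resolve_altlocs(atoms)
    return Structure(atoms, title=title or path.stem)


def read_trajectory(
    path: str | Path, reference: Structure | None = None
) -> tuple[Structure, list[TrajectoryFrame]]:
    """Read a multi-model PDB or a ``frame,atom_index,x,y,z`` CSV trajectory.

    Returns the reference structure (first model for PDB input; the given
    ``reference`` for CSV input, required) and the list of frames.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        if reference is None:
            raise ValueError("CSV trajectories require a reference Structure")
        return reference, _read_csv_frames(path, len(reference))
    frames: list[TrajectoryFrame] = []
    i = 0
    while True:
        try:
            model = read_structure(path, "pdb", model=i + 1)
        except PDBParseError:
            break
        frames.append(TrajectoryFrame(frame_index=i, coords=model.coords))
        i += 1
        # single-model file: stop after the first
        with open(path) as fh:
            if not any(l.startswith("MODEL") for l in fh):
                break
    ref = reference if reference is not None else read_structure(path, "pdb")
    for f in frames:
        if f.coords.shape[0] != len(ref):
            raise ValueError(
                f"frame {f.frame_index} has {f.coords.shape[0]} atoms, "
                f"reference has {len(ref)}"
            )
    return ref, frames


def _read_csv_frames(path: Path, n_atoms: int) -> list[TrajectoryFrame]:
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    required = {"frame", "atom_index", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"trajectory CSV must have columns {sorted(required)}")
    frames = []
    for fi, grp in df.groupby("frame", sort=True):
        grp = grp.sort_values("atom_index")
        if len(grp) != n_atoms:
            raise ValueError(f"frame {fi} has {len(grp)} atoms, expected {n_atoms}")
        frames.append(
            TrajectoryFrame(
                frame_index=int(fi), coords=grp[["x", "y", "z"]].to_numpy()
            )
        )
    return frames


# ---------------------------------------------------------------------------
# Writing


def _format_pdb_atom(a: AtomRecord) -> str:
    rec = "HETATM" if a.is_hetero else "ATOM  "
    name = a.atom_name
    # element-aligned atom-name field per PDB convention
    if len(name) < 4 and len(a.element) == 1:
        name = " " + name
    x, y, z = a.coords
    return (
        f"{rec}{a.serial:5d} {name:<4s}{a.altloc or ' '}{a.residue_name:<3s} "
        f"{a.chain_id:1s}{a.residue_number:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}          "
        f"{a.element:>2s}\n"
    )


def _format_pqr_atom(a: AtomRecord) -> str:
    rec = "HETATM" if a.is_hetero else "ATOM"
    q = a.partial_charge if a.partial_charge is not None else 0.0
    x, y, z = a.coords
    return (
        f"{rec:<6s}{a.serial:5d} {a.atom_name:<4s} {a.residue_name:<4s} "
        f"{a.chain_id:1s} {a.residue_number:4d} "
        f"{x:10.4f} {y:10.4f} {z:10.4f} {q:8.4f} {a.vdw_radius:7.4f}\n"
    )


def write_structure(structure: Structure, path: str | Path, format: str | None = None) -> None:
    """Write a structure as PDB or PQR."""
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower() or "pdb"
    fmt = _format_pqr_atom if format == "pqr" else _format_pdb_atom
    with open(path, "w") as fh:
        if structure.title:
            fh.write(f"TITLE     {structure.title}\n")
        for a in structure.atoms:
            fh.write(fmt(a))
        fh.write("END\n")


def write_trajectory(
    structure: Structure, frames: Sequence[TrajectoryFrame], path: str | Path
) -> None:
    """Write frames as a multi-model PDB aligned to ``structure``."""
    with open(path, "w") as fh:
        for f in frames:
            fh.write(f"MODEL     {f.frame_index + 1:4d}\n")
            for a, c in zip(structure.atoms, f.coords):
                fh.write(_format_pdb_atom(replace(a, coords=c)))
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Selection

_ATOM_CLASSES = ("all", "heavy", "backbone", "sidechain_heavy", "CA")


def _atom_in_class(a: AtomRecord, atom_class: str) -> bool:
    if atom_class == "all":
        return True
    if atom_class == "heavy":
        return not a.is_hydrogen
    if atom_class == "CA":
        return a.atom_name == "CA" and a.element != "CA"  # exclude calcium ions
    if atom_class == "backbone":
        return a.atom_name in BACKBONE_ATOMS and not a.is_hydrogen
    if atom_class == "sidechain_heavy":
        if a.is_hydrogen or a.atom_name in BACKBONE_ATOMS:
            return False
        return True
    raise ValueError(f"unknown atom_class {atom_class!r}; choose from {_ATOM_CLASSES}")


def select(
    structure: Structure,
    chain: str,
    residues: Iterable[int],
    atom_class: str = "heavy",
) -> AtomSelection:
    """Select atoms of the given residues in one chain by atom class.

    Glycine convention: for ``sidechain_heavy`` selections a GLY residue
    contributes its CA atom (logged), so selections over residue lists that
    include glycines never silently shrink.
    """
    residues = list(residues)
    missing = [r for r in residues if not structure.has_residue(chain, r)]
    if missing:
        raise SelectionError(
            f"residues {missing} not present in chain {chain!r}"
        )
    indices: list[int] = []
    for r in residues:
        atom_idx = structure.residue_atoms(chain, r)
        picked = [i for i in atom_idx if _atom_in_class(structure.atoms[i], atom_class)]
        if not picked and atom_class == "sidechain_heavy":
            resname = structure.atoms[atom_idx[0]].residue_name
            if resname == "GLY":
                picked = [
                    i for i in atom_idx if structure.atoms[i].atom_name == "CA"
                ]
                logger.info(
                    "GLY %s/%d: using CA as sidechain terminus", chain, r
                )
        if not picked:
            raise SelectionError(
                f"empty selection: residue {chain}/{r} has no {atom_class} atoms"
            )
        indices.extend(picked)
    return AtomSelection(
        indices=tuple(indices),
        description=f"{atom_class} atoms of chain {chain} residues {residues}",
    )


# ---------------------------------------------------------------------------
# Superposition and RMSD


def superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition (Kabsch, SVD form).

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` optimally matches ``reference``;
    the rotation is proper (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both be (N, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition requires at least 3 points")
    mu_m = mobile.mean(axis=0)
    mu_r = reference.mean(axis=0)
    P = mobile - mu_m
    Q = reference - mu_r
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    if S[1] <= 1e-12 * max(S[0], 1.0):
        raise ValueError("degenerate (rank-deficient) point configuration")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_r - R @ mu_m
    moved = P @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return R, t, rmsd


def region_rmsd(
    a: Structure,
    b: Structure,
    residue_ranges: Sequence[tuple[str, int, int]],
    atom_class: str = "backbone",
) -> float:
    """RMSD over named residue ranges after optimal superposition.

    Atoms are matched by ``(chain, residue_number, atom_name)``; every named
    residue must be present in both structures with at least one atom of the
    requested class, otherwise an error lists the missing residues.
    """
    keys_a = _region_atom_keys(a, residue_ranges, atom_class, "first")
    keys_b = _region_atom_keys(b, residue_ranges, atom_class, "second")
    common = [k for k in keys_a if k in keys_b]
    if len(common) < 3:
        raise SelectionError(
            f"only {len(common)} matched atoms in the named region"
        )
    ca = np.array([a.atoms[keys_a[k]].coords for k in common])
    cb = np.array([b.atoms[keys_b[k]].coords for k in common])
    _, _, rmsd = superpose(ca, cb)
    return rmsd


def _region_atom_keys(
    s: Structure,
    residue_ranges: Sequence[tuple[str, int, int]],
    atom_class: str,
    which: str,
) -> dict[tuple[str, int, str], int]:
    keys: dict[tuple[str, int, str], int] = {}
    missing: list[tuple[str, int]] = []
    for chain, start, end in residue_ranges:
        for r in range(start, end + 1):
            atom_idx = s.residue_atoms(chain, r)
            if not atom_idx:
                missing.append((chain, r))
                continue
            for i in atom_idx:
                atom = s.atoms[i]
                if _atom_in_class(atom, atom_class):
                    keys[(chain, r, atom.atom_name)] = i
    if missing:
        raise SelectionError(
            f"residues missing from the {which} structure: {missing}"
        )
    return keys
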