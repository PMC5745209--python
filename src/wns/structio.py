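"""Structure and trajectory I/O plus the atom-type parameter table.

The interchange formats are deliberately plain text: PDB for structures and
multi-model PDB for trajectories, with AutoDock-style partial-charge and
atom-type columns (the PDBQT dialect) so that excluded atoms — atom type
``"X"``, zero charge — survive a round trip.  Ligand copies in a wrapped
complex are stored on chain ``L`` with one residue number per copy and a
``REMARK 300`` provenance line recording the wrapping cycle that produced it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    ParameterLookupError,
    StructureParseError,
    TrajectoryFormatError,
)

log = logging.getLogger(__name__)

#: Atom types treated as hydrogen (not "heavy") throughout the package.
HYDROGEN_TYPES = frozenset({"H", "HD", "HS"})

#: Reserved code for the excluded atom type.
EXCLUDED_TYPE = "X"


# ---------------------------------------------------------------------------
# Parameter table
# ---------------------------------------------------------------------------

class ParameterTable:
    """Per-atom-type Lennard-Jones parameters (Rii in Å, epsii in kcal/mol).

    The shipped table carries published AutoDock 4 values for the common
    organic atom types plus the reserved excluded type ``"X"`` whose entry
    holds the calibrated monolayer parameters (well depth 1e-4 kcal/mol;
    the pair-distance default is the 3.6 Å field value, overridable with
    :meth:`with_x_radius` or by loading a custom table).
    """

    def __init__(self, entries: dict[str, tuple[float, float]]):
        for t, (r, e) in entries.items():
            if r <= 0 or e < 0:
                raise ValueError(f"invalid LJ parameters for type {t!r}: Rii={r}, epsii={e}")
        for required in ("O", "C", "H", EXCLUDED_TYPE):
            if required not in entries:
                raise ValueError(f"parameter table must define type {required!r}")
        self._entries = dict(entries)

    @classmethod
    def from_file(cls, path: str | Path) -> "ParameterTable":
        entries: dict[str, tuple[float, float]] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 3:
                raise ValueError(f"malformed parameter line: {line!r}")
            entries[fields[0]] = (float(fields[1]), float(fields[2]))
        return cls(entries)

    _default: "ParameterTable | None" = None

    @classmethod
    def default(cls) -> "ParameterTable":
        """The table shipped with the package (cached; treat as read-only)."""
        if cls._default is None:
            ref = resources.files("wns.data").joinpath("atom_types.tsv")
            with resources.as_file(ref) as p:
                cls._default = cls.from_file(p)
        return cls._default

    def with_x_radius(self, r_x: float, eps_x: float | None = None) -> "ParameterTable":
        """A copy of this table with the excluded-type entry replaced."""
        entries = dict(self._entries)
        eps = entries[EXCLUDED_TYPE][1] if eps_x is None else eps_x
        entries[EXCLUDED_TYPE] = (float(r_x), float(eps))
        return ParameterTable(entries)

    def __contains__(self, atom_type: str) -> bool:
        return atom_type in self._entries

    def lookup(self, atom_type: str) -> tuple[float, float]:
        """Return ``(Rii, epsii)`` for *atom_type*."""
        try:
            return self._entries[atom_type]
        except KeyError:
            raise ParameterLookupError(
                f"atom type {atom_type!r} not in parameter table"
            ) from None

    def types(self) -> list[str]:
        return sorted(self._entries)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class AtomRecord:
    """One atom: coordinates, AutoDock-style typing, charge, LJ parameters.

    ``base_type``/``base_charge`` preserve the original (pre-exclusion)
    typing so downstream energy metrics can score with standard parameters
    even after the atom was re-typed to ``"X"`` during wrapping.
    """

    serial: int
    name: str
    coords: np.ndarray
    atom_type: str
    charge: float
    lj_R: float
    lj_eps: float
    is_excluded: bool = False
    resname: str = "UNK"
    resid: int = 1
    chain: str = "A"
    base_type: str = ""
    base_charge: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(3)
        if not self.base_type:
            self.base_type = self.atom_type
            self.base_charge = self.charge
        if self.lj_R <= 0:
            raise ValueError(f"atom {self.serial}: lj_R must be positive")
        if self.lj_eps < 0:
            raise ValueError(f"atom {self.serial}: lj_eps must be non-negative")
        if self.is_excluded and (self.charge != 0.0 or self.atom_type != EXCLUDED_TYPE):
            raise ValueError(
                f"atom {self.serial}: excluded atoms must have type 'X' and zero charge"
            )

    @property
    def is_heavy(self) -> bool:
        return self.base_type not in HYDROGEN_TYPES

    def copy(self) -> "AtomRecord":
        return replace(self, coords=self.coords.copy())


@dataclass
class Structure:
    """An ordered atom collection with a label and optional metadata.

    ``meta`` carries free-form annotations such as the molecular weight of a
    toy ligand (``meta["mw"]``) that the annealing scheduler consumes.
    """

    atoms: list[AtomRecord]
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            dupes = sorted({s for s in serials if serials.count(s) > 1})
            raise StructureParseError(f"duplicate atom serials: {dupes}")
        if self.atoms and not any(a.is_heavy for a in self.atoms):
            raise StructureParseError("structure contains no heavy atom")

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        """All coordinates as an (N, 3) float array (a copy)."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        for a, c in zip(self.atoms, xyz):
            a.coords = c.copy()

    def heavy_mask(self) -> np.ndarray:
        return np.array([a.is_heavy for a in self.atoms], dtype=bool)

    def heavy_coords(self) -> np.ndarray:
        return self.coords()[self.heavy_mask()]

    def copy(self) -> "Structure":
        return Structure(
            [a.copy() for a in self.atoms], label=self.label, meta=dict(self.meta)
        )


@dataclass
class TrajectorySeries:
    """Per-frame coordinates of the mobile atoms of a complex.

    ``copy_atoms`` maps each ligand-copy id to the indices (into the atom
    axis) of its atoms; ``atoms`` is the per-atom metadata template shared by
    every frame.
    """

    coords: np.ndarray                      # (n_frames, n_atoms, 3)
    atoms: list[AtomRecord]
    copy_atoms: dict[int, np.ndarray]
    remarks: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TrajectoryFormatError("trajectory coordinates must be (frames, atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise TrajectoryFormatError("atom metadata does not match coordinate width")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _parse_atom_line(
    line: str,
    lineno: int,
    fmt: str,
    table: ParameterTable,
    warned: dict,
) -> AtomRecord:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        resname = line[17:20].strip() or "UNK"
        chain = line[21:22].strip() or "A"
        resid = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise StructureParseError(f"line {lineno}: malformed atom record: {exc}") from None

    charge = 0.0
    atom_type = ""
    if fmt == "pdbqt":
        try:
            charge = float(line[66:76])
        except ValueError:
            raise StructureParseError(f"line {lineno}: malformed charge field") from None
        atom_type = line[77:79].strip()
    else:
        atom_type = line[76:78].strip()
        if not warned.get("charges"):
            warned["charges"] = True
            warnings.warn(
                "PDB input carries no partial charges; all charges set to 0",
                stacklevel=3,
            )
    if not atom_type:
        atom_type = next((c for c in name if c.isalpha()), "")
    if atom_type not in table:
        fallback = atom_type[:1].upper()
        if fallback in table:
            if atom_type not in warned:
                warned[atom_type] = True
                warnings.warn(
                    f"unknown atom type {atom_type!r}; falling back to element {fallback!r}",
                    stacklevel=3,
                )
            atom_type = fallback
        else:
            raise StructureParseError(
                f"line {lineno}: unknown atom type {atom_type!r} with no element fallback"
            )
    lj_R, lj_eps = table.lookup(atom_type)
    excluded = atom_type == EXCLUDED_TYPE
    if excluded and charge != 0.0:
        raise StructureParseError(
            f"line {lineno}: excluded atom (type X) carries non-zero charge {charge}"
        )
    return AtomRecord(
        serial=serial, name=name, coords=np.array([x, y, z]),
        atom_type=atom_type, charge=charge, lj_R=lj_R, lj_eps=lj_eps,
        is_excluded=excluded, resname=resname, resid=resid, chain=chain,
    )


def _looks_like_pdbqt(lines: list[str]) -> bool:
    for line in lines:
        if line[:6] in ("ATOM  ", "HETATM"):
            try:
                float(line[66:76])
            except (ValueError, IndexError):
                return False
            return bool(line[77:79].strip())
    return False


def _infer_format(path: Path, fmt: str | None, lines: list[str]) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in ("pdb", "pdbqt"):
            raise ValueError(f"unsupported format {fmt!r} (expected 'pdb' or 'pdbqt')")
        return fmt
    if path.suffix.lower() == ".pdbqt" or _looks_like_pdbqt(lines):
        return "pdbqt"
    return "pdb"


def read_structure(
    path: str | Path,
    format: str | None = None,
    table: ParameterTable | None = None,
) -> Structure:
    """Read a single-model PDB or PDBQT file into a :class:`Structure`.

    PDBQT partial charges and AutoDock atom types are captured (files with
    charge/type columns are recognised regardless of suffix); plain PDB
    input gets zero charges (with a warning) and element-derived typing.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    fmt = _infer_format(path, format, lines)
    table = table or ParameterTable.default()
    atoms: list[AtomRecord] = []
    warned: dict = {}
    meta: dict = {}
    for lineno, line in enumerate(lines, start=1):
        rec = line[:6]
        if rec in ("ATOM  ", "HETATM"):
            atoms.append(_parse_atom_line(line, lineno, fmt, table, warned))
        elif line.startswith("REMARK 300 MW "):
            meta["mw"] = float(line.split()[3])
    return Structure(atoms, label=path.stem, meta=meta)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _format_atom_line(a: AtomRecord, serial: int, hetatm: bool = False) -> str:
    rec = "HETATM" if hetatm else "ATOM  "
    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
    return (
        f"{rec}{serial:>5d} {name:<4.4s} {a.resname:<3.3s} {a.chain:1.1s}"
        f"{a.resid:>4d}    {a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
        f"{1.0:6.2f}{0.0:6.2f}    {a.charge:6.3f} {a.atom_type:<2.2s}"
    )


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a structure as a single-model PDB with charge/type columns."""
    lines = []
    if "mw" in structure.meta:
        lines.append(f"REMARK 300 MW {structure.meta['mw']:.3f}")
    lines += [_format_atom_line(a, a.serial) for a in structure.atoms]
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_complex(
    target: Structure,
    copies: Sequence,            # Sequence[LigandPose]; duck-typed to avoid a cycle
    path: str | Path,
) -> None:
    """Write a wrapped complex: target first, each ligand copy on chain L.

    Each copy becomes one residue (resid = copy ordinal, 1-based) and a
    ``REMARK 300 COPY <i> CYCLE <c>`` line records its wrapping-cycle
    provenance.  Charges and AutoDock atom types are written in PDBQT-style
    columns so exclusions round-trip.
    """
    lines = ["REMARK 300 WRAPPED COMPLEX", f"REMARK 300 NCOPIES {len(copies)}"]
    for i, pose in enumerate(copies, start=1):
        lines.append(f"REMARK 300 COPY {i} CYCLE {pose.cycle}")
    serial = 0
    for a in target.atoms:
        serial += 1
        lines.append(_format_atom_line(a, serial))
    for i, pose in enumerate(copies, start=1):
        for a, xyz in zip(pose.template.atoms, pose.coords):
            serial += 1
            rec = replace(
                a, coords=np.asarray(xyz, dtype=float),
                chain="L", resid=i, resname="LIG",
            )
            lines.append(_format_atom_line(rec, serial, hetatm=True))
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_complex(
    path: str | Path,
    table: ParameterTable | None = None,
) -> tuple[Structure, list[tuple[Structure, int]]]:
    """Read a wrapped complex back into a target and per-copy structures.

    Returns ``(target, [(copy_structure, cycle), ...])``; copy ordering
    follows the chain-L residue numbering written by :func:`write_complex`.
    """
    path = Path(path)
    table = table or ParameterTable.default()
    atoms: list[AtomRecord] = []
    cycles: dict[int, int] = {}
    warned: dict = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith("REMARK 300 COPY"):
            fields = line.split()
            cycles[int(fields[3])] = int(fields[5])
        elif line[:6] in ("ATOM  ", "HETATM"):
            atoms.append(_parse_atom_line(line, lineno, "pdbqt", table, warned))
    target_atoms = [a for a in atoms if a.chain != "L"]
    copy_atoms: dict[int, list[AtomRecord]] = {}
    for a in atoms:
        if a.chain == "L":
            copy_atoms.setdefault(a.resid, []).append(a)
    target = Structure(target_atoms, label=path.stem)
    copies = [
        (Structure(copy_atoms[i], label=f"copy{i}"), cycles.get(i, 1))
        for i in sorted(copy_atoms)
    ]
    return target, copies


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def write_trajectory(traj: TrajectorySeries, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB (one MODEL per frame)."""
    lines = [f"REMARK 250 {r}" for r in traj.remarks]
    for f in range(traj.n_frames):
        lines.append(f"MODEL {f + 1:>8d}")
        for i, a in enumerate(traj.atoms):
            rec = replace(a, coords=traj.coords[f, i])
            lines.append(_format_atom_line(rec, i + 1, hetatm=True))
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_trajectory(
    path: str | Path,
    table: ParameterTable | None = None,
) -> TrajectorySeries:
    """Read a multi-model PDB trajectory.

    Frames are ordered by MODEL index; every model must contain the same
    number of atoms.  Ligand copies are identified by grouping atoms on
    ``(chain, resid)`` in first-model order (chain-L residue ids, as written
    by this package, become the copy ids).
    """
    path = Path(path)
    table = table or ParameterTable.default()
    frames: list[list[AtomRecord]] = []
    current: list[AtomRecord] | None = None
    remarks: list[str] = []
    warned: dict = {}
    saw_model = False
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith("MODEL"):
            saw_model = True
            current = []
        elif line.startswith("ENDMDL"):
            if current is None:
                raise TrajectoryFormatError(f"line {lineno}: ENDMDL without MODEL")
            frames.append(current)
            current = None
        elif line.startswith("REMARK 250"):
            remarks.append(line[11:].strip())
        elif line[:6] in ("ATOM  ", "HETATM"):
            rec = _parse_atom_line(line, lineno, "pdbqt", table, warned)
            if current is None:
                if saw_model:
                    raise TrajectoryFormatError(f"line {lineno}: atom outside MODEL block")
                current = []
                saw_model = True  # headerless single-model file
                frames.append(current)
            current.append(rec)
    if current is not None and current not in frames:
        frames.append(current)
    if not frames:
        raise TrajectoryFormatError("no frames found")
    n_atoms = len(frames[0])
    for i, fr in enumerate(frames, start=1):
        if len(fr) != n_atoms:
            raise TrajectoryFormatError(
                f"model {i} has {len(fr)} atoms, expected {n_atoms}"
            )
    coords = np.array([[a.coords for a in fr] for fr in frames], dtype=float)
    atoms = frames[0]
    copy_atoms: dict[int, list[int]] = {}
    keys: dict[tuple, int] = {}
    for idx, a in enumerate(atoms):
        key = (a.chain, a.resid)
        if key not in keys:
            keys[key] = a.resid if a.chain == "L" else len(keys) + 1
        copy_atoms.setdefault(keys[key], []).append(idx)
    return TrajectorySeries(
        coords=coords,
        atoms=atoms,
        copy_atoms={k: np.array(v, dtype=int) for k, v in copy_atoms.items()},
        remarks=remarks,
    )
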