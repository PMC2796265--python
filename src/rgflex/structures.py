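"""Protein structures, ensembles and atom selections.

Structures are heavy-atom representations read from PDB files (gemmi does the
parsing); conformational ensembles share one atom topology and are stored as a
list of coordinate frames, serialized as multi-model PDB.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "FrameInfo",
    "Ensemble",
    "StructureError",
    "read_structure",
    "read_ensemble",
    "write_structure",
    "write_ensemble",
    "select_atoms",
]

#: residue names treated as crystallographic water
WATER_NAMES = frozenset({"HOH", "WAT"})

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})


class StructureError(ValueError):
    """Raised for unreadable, empty or inconsistent structures."""


@dataclasses.dataclass(frozen=True)
class Atom:
    """One heavy atom.

    ``residue_id`` is ``(chain id, residue number, insertion code)`` exactly as
    in the PDB file; coordinates are Angstrom.
    """

    serial: int
    name: str
    element: str
    mass: float
    residue_name: str
    residue_id: tuple[str, int, str]
    is_hetero: bool = False

    def __post_init__(self) -> None:
        if not self.mass > 0:
            raise StructureError(
                f"atom {self.name} ({self.element}): non-positive mass {self.mass}"
            )


class Structure:
    """An ordered collection of heavy atoms plus one coordinate set."""

    def __init__(self, atoms: Sequence[Atom], coords: np.ndarray, model_id: int = 1):
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(atoms), 3):
            raise StructureError(
                f"coords shape {coords.shape} does not match {len(atoms)} atoms"
            )
        if not np.all(np.isfinite(coords)):
            raise StructureError("non-finite coordinates")
        self.atoms: list[Atom] = list(atoms)
        self.coords: np.ndarray = coords
        self.model_id = model_id

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.atoms]

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def residue_ids(self) -> list[tuple[str, int, str]]:
        """Residue id of every atom (length n_atoms, with repeats)."""
        return [a.residue_id for a in self.atoms]

    def residues(self) -> list[tuple[tuple[str, int, str], str, list[int]]]:
        """Unique residues in atom order: (residue_id, residue_name, atom indices)."""
        out: list[tuple[tuple[str, int, str], str, list[int]]] = []
        index: dict[tuple[str, int, str], int] = {}
        for i, a in enumerate(self.atoms):
            k = a.residue_id
            if k not in index:
                index[k] = len(out)
                out.append((k, a.residue_name, []))
            out[index[k]][2].append(i)
        return out

    def with_coords(self, coords: np.ndarray, model_id: int | None = None) -> "Structure":
        """New Structure sharing this topology with replaced coordinates."""
        return Structure(self.atoms, np.array(coords, dtype=float),
                         self.model_id if model_id is None else model_id)

    def subset(self, indices: Sequence[int]) -> "Structure":
        idx = list(indices)
        return Structure([self.atoms[i] for i in idx], self.coords[idx], self.model_id)


@dataclasses.dataclass(frozen=True)
class FrameInfo:
    """Provenance of one ensemble frame."""

    seed: int
    sweeps: int
    rg: float


class Ensemble:
    """Conformations sharing one atom topology."""

    def __init__(self, topology: Structure, frames: Iterable[np.ndarray],
                 provenance: Sequence[FrameInfo] | None = None):
        self.topology = topology
        self.frames: list[np.ndarray] = []
        for f in frames:
            f = np.asarray(f, dtype=float)
            if f.shape != (topology.n_atoms, 3):
                raise StructureError(
                    f"frame shape {f.shape} does not match topology "
                    f"({topology.n_atoms} atoms)"
                )
            self.frames.append(f)
        self.provenance: list[FrameInfo] = list(provenance) if provenance else []
        if self.provenance and len(self.provenance) != len(self.frames):
            raise StructureError("provenance length does not match frame count")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def structure(self, i: int) -> Structure:
        return self.topology.with_coords(self.frames[i], model_id=i + 1)

    def subset(self, frame_indices: Sequence[int]) -> "Ensemble":
        prov = [self.provenance[i] for i in frame_indices] if self.provenance else None
        return Ensemble(self.topology, [self.frames[i] for i in frame_indices], prov)


# ---------------------------------------------------------------------------
# reading


def _element_and_mass(atom: gemmi.Atom) -> tuple[str, float]:
    el = atom.element
    if el is None or el.name in ("X", ""):
        raise StructureError(f"cannot resolve element for atom {atom.name!r}")
    w = float(el.weight)
    if not w > 0:
        raise StructureError(f"element {el.name} has no standard atomic weight")
    return el.name, w


def _iter_model_atoms(model: gemmi.Model, strip_waters: bool, keep_hetero: bool):
    """Yield (chain, residue, atom) for retained heavy atoms, resolving altlocs.

    Altloc policy: per (residue, atom name) keep the highest occupancy;
    ties go to the alphabetically first altloc letter.
    """
    for chain in model:
        for res in chain:
            if strip_waters and res.name.upper() in WATER_NAMES:
                continue
            het = res.het_flag == "H"
            if het and not keep_hetero:
                continue
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                prev = best.get(atom.name)
                if prev is None:
                    best[atom.name] = atom
                else:
                    def _alt(a: gemmi.Atom) -> str:
                        c = a.altloc
                        return c if c and c != "\x00" else "~"
                    if (atom.occ, -ord(_alt(atom))) > (prev.occ, -ord(_alt(prev))):
                        best[atom.name] = atom
            for atom in best.values():
                yield chain, res, atom, het


def _model_to_structure(model: gemmi.Model, strip_waters: bool,
                        keep_hetero: bool, model_id: int) -> Structure:
    atoms: list[Atom] = []
    xyz: list[tuple[float, float, float]] = []
    for chain, res, atom, het in _iter_model_atoms(model, strip_waters, keep_hetero):
        element, mass = _element_and_mass(atom)
        atoms.append(
            Atom(
                serial=atom.serial,
                name=atom.name,
                element=element,
                mass=mass,
                residue_name=res.name,
                residue_id=(chain.name, res.seqid.num, res.seqid.icode.strip()),
                is_hetero=het,
            )
        )
        xyz.append((atom.pos.x, atom.pos.y, atom.pos.z))
    if not atoms:
        raise StructureError("no atoms left after filtering")
    return Structure(atoms, np.array(xyz, dtype=float), model_id=model_id)


def _read_gemmi(path: str | Path) -> gemmi.Structure:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:  # gemmi reports the offending line
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path}: no models found")
    return st


def read_structure(path: str | Path, strip_waters: bool = True,
                   keep_hetero: bool = False) -> Structure:
    """Read a PDB file into a heavy-atom :class:`Structure`.

    Hydrogens are always dropped; waters (HOH/WAT) are removed when
    ``strip_waters``; HETATM records are kept only when ``keep_hetero``.
    Only the first model of a multi-model file is used.
    """
    st = _read_gemmi(path)
    return _model_to_structure(st[0], strip_waters, keep_hetero, model_id=1)


def read_ensemble(path: str | Path, strip_waters: bool = True,
                  keep_hetero: bool = False) -> Ensemble:
    """Read a (multi-model) PDB file as an :class:`Ensemble`."""
    st = _read_gemmi(path)
    structures = [
        _model_to_structure(m, strip_waters, keep_hetero, i + 1)
        for i, m in enumerate(st)
    ]
    top = structures[0]
    for s in structures[1:]:
        if s.n_atoms != top.n_atoms:
            raise StructureError("models differ in atom count; not an ensemble")
    return Ensemble(top, [s.coords for s in structures])


# ---------------------------------------------------------------------------
# writing (own fixed-width formatter: byte-for-byte deterministic output)


def _format_atom_name(name: str, element: str) -> str:
    # PDB columns 13-16: element right-justified in 13-14 for 1/2-letter names
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return name.ljust(4)
    return " " + name.ljust(3)


def _atom_record(i: int, atom: Atom, pos: np.ndarray) -> str:
    rec = "HETATM" if atom.is_hetero else "ATOM  "
    chain = (atom.residue_id[0] or "A")[:1]
    icode = atom.residue_id[2][:1] if atom.residue_id[2] else " "
    return (
        f"{rec}{i % 100000:5d} {_format_atom_name(atom.name, atom.element)}"
        f" {atom.residue_name:>3s} {chain}{atom.residue_id[1]:4d}{icode}   "
        f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {atom.element:>2s}"
    )


def _structure_lines(structure: Structure, coords: np.ndarray) -> list[str]:
    lines = []
    serial = 0
    prev_chain = None
    for atom, pos in zip(structure.atoms, coords):
        chain = atom.residue_id[0]
        if prev_chain is not None and chain != prev_chain:
            lines.append("TER")
        prev_chain = chain
        serial += 1
        lines.append(_atom_record(serial, atom, pos))
    lines.append("TER")
    return lines


def write_structure(structure: Structure, path: str | Path) -> Path:
    """Write a single-conformation PDB file."""
    path = Path(path)
    lines = _structure_lines(structure, structure.coords)
    path.write_text("\n".join(lines + ["END"]) + "\n")
    return path


def write_ensemble(ensemble: Ensemble, path: str | Path) -> Path:
    """Write an ensemble as a multi-model PDB (MODEL/ENDMDL per frame)."""
    if ensemble.n_frames == 0:
        raise StructureError("refusing to write an empty ensemble")
    path = Path(path)
    lines: list[str] = []
    for k, frame in enumerate(ensemble.frames):
        lines.append(f"MODEL     {k + 1:4d}")
        lines.extend(_structure_lines(ensemble.topology, frame))
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# selections


def select_atoms(structure: Structure, selector) -> list[int]:
    """Indices of atoms matching a selector, in structure order.

    ``selector`` is ``"backbone"`` (N, CA, C, O of non-hetero residues),
    ``"ca"`` (CA of non-hetero residues), ``"all"``, or a residue-id
    collection.  Residue ids may be given as ``(chain, resnum, icode)``,
    ``(chain, resnum)`` or bare residue numbers.
    """
    if isinstance(selector, str):
        key = selector.lower()
        if key == "all":
            return list(range(structure.n_atoms))
        if key == "backbone":
            return [
                i for i, a in enumerate(structure.atoms)
                if not a.is_hetero and a.name in BACKBONE_NAMES
            ]
        if key in ("ca", "ca-only"):
            return [
                i for i, a in enumerate(structure.atoms)
                if not a.is_hetero and a.name == "CA"
            ]
        raise ValueError(f"unknown selector {selector!r}")
    try:
        wanted = set(selector)
    except TypeError:
        raise ValueError(f"unsupported selector {selector!r}") from None
    out = []
    for i, a in enumerate(structure.atoms):
        chain, num, icode = a.residue_id
        if (
            a.residue_id in wanted
            or (chain, num) in wanted
            or num in wanted
        ):
            out.append(i)
    return out
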