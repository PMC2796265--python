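"""Core structural measures.

Radius of gyration (mass-weighted, about the centre of mass), least-squares
rigid-body superposition (Kabsch, reflection-corrected), RMSD, and the
distance-based binding-site definition (every receptor residue with at least
one heavy atom within a cutoff of any ligand atom).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structures import Structure, StructureError

__all__ = [
    "RgValue",
    "SuperpositionResult",
    "radius_of_gyration",
    "rg_of_structure",
    "superpose",
    "rmsd",
    "binding_site",
    "pair_common_atoms",
]

log = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class RgValue:
    """Radius of gyration in Angstrom over a stated atom selection."""

    value: float
    selection: tuple[int, ...] | None = None
    mass_weighted: bool = True

    def __float__(self) -> float:
        return self.value


@dataclasses.dataclass(frozen=True)
class SuperpositionResult:
    """Optimal proper rotation + translation mapping mobile onto reference.

    ``rotation @ x + translation`` maps a mobile point x onto the reference
    frame; ``fitted_rmsd`` is the (weighted) RMSD after the fit.
    """

    rotation: np.ndarray
    translation: np.ndarray
    fitted_rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray,
                       selection: Sequence[int] | None = None) -> RgValue:
    """Mass-weighted radius of gyration.

    R_g = sqrt( sum_i m_i |r_i - r_com|^2 / sum_i m_i ) with r_com the
    mass-weighted centre; invariant under rigid-body motion.
    """
    coords = np.asarray(coords, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if selection is not None:
        sel = np.asarray(list(selection), dtype=int)
        coords = coords[sel]
        masses = masses[sel]
    if coords.ndim != 2 or coords.shape[0] == 0:
        raise ValueError("radius of gyration of an empty selection")
    if np.any(masses <= 0):
        raise ValueError("all masses must be positive")
    total = masses.sum()
    com = (masses[:, None] * coords).sum(axis=0) / total
    d2 = ((coords - com) ** 2).sum(axis=1)
    value = float(np.sqrt((masses * d2).sum() / total))
    return RgValue(value, tuple(selection) if selection is not None else None)


def rg_of_structure(structure: Structure,
                    selection: Sequence[int] | None = None) -> float:
    return radius_of_gyration(structure.coords, structure.masses, selection).value


def superpose(mobile: np.ndarray, reference: np.ndarray,
              weights: np.ndarray | None = None) -> SuperpositionResult:
    """Kabsch superposition of ``mobile`` onto ``reference``.

    Returns the proper rotation (det = +1; a reflection is never returned,
    even when it would fit better) and translation minimizing the weighted
    RMSD.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(f"point count mismatch: {mobile.shape} vs {reference.shape}")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
    wsum = w.sum()
    cm = (w[:, None] * mobile).sum(axis=0) / wsum
    cr = (w[:, None] * reference).sum(axis=0) / wsum
    x = mobile - cm
    y = reference - cr
    h = (w[:, None] * x).T @ y
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    translation = cr - rot @ cm
    fitted = x @ rot.T
    fitted_rmsd = float(np.sqrt((w * ((fitted - y) ** 2).sum(axis=1)).sum() / wsum))
    return SuperpositionResult(rot, translation, fitted_rmsd)


def rmsd(a: np.ndarray, b: np.ndarray, fit: bool = True,
         weights: np.ndarray | None = None) -> float:
    """RMSD between two conformations of the same atoms.

    With ``fit`` the optimal rigid-body superposition is applied first
    (fitted RMSD <= raw RMSD always); without it the coordinates are compared
    as given.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"point count mismatch: {a.shape} vs {b.shape}")
    if fit:
        if a.shape[0] == 2:
            # degenerate two-point case: align along the common axis
            d1 = float(np.linalg.norm(a[1] - a[0]))
            d2 = float(np.linalg.norm(b[1] - b[0]))
            return abs(d1 - d2) / 2
        return superpose(a, b, weights).fitted_rmsd
    if weights is None:
        return float(np.sqrt(((a - b) ** 2).sum(axis=1).mean()))
    w = np.asarray(weights, dtype=float)
    return float(np.sqrt((w * ((a - b) ** 2).sum(axis=1)).sum() / w.sum()))


def binding_site(receptor: Structure, ligand: Structure,
                 cutoff: float = 6.0) -> set[tuple[str, int, str]]:
    """Receptor residues with >=1 heavy atom within ``cutoff`` of any ligand atom.

    The comparison is inclusive (distance <= cutoff). Returns residue ids
    ``(chain, resnum, icode)``.
    """
    if receptor.n_atoms == 0 or ligand.n_atoms == 0:
        raise StructureError("binding_site needs non-empty receptor and ligand")
    tree = cKDTree(ligand.coords)
    dmin, _ = tree.query(receptor.coords, k=1)
    out: set[tuple[str, int, str]] = set()
    for i in np.nonzero(dmin <= cutoff)[0]:
        out.add(receptor.atoms[int(i)].residue_id)
    return out


def pair_common_atoms(a: Structure, b: Structure) -> tuple[list[int], list[int]]:
    """Match atoms of two structures by (chain, residue number, icode, atom name).

    Returns paired index lists in ``a``'s order; unmatched atoms are dropped
    with a logged count (crystal structures often differ in resolved
    residues).
    """
    key_b = {(at.residue_id, at.name): i for i, at in enumerate(b.atoms)}
    ia: list[int] = []
    ib: list[int] = []
    for i, at in enumerate(a.atoms):
        j = key_b.get((at.residue_id, at.name))
        if j is not None:
            ia.append(i)
            ib.append(j)
    dropped = (a.n_atoms - len(ia)) + (b.n_atoms - len(ib))
    if dropped:
        log.info("common-atom pairing dropped %d unmatched atoms", dropped)
    if not ia:
        raise StructureError("no common atoms between the two structures")
    return ia, ib
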