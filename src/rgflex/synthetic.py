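"""Synthetic test structures with known ground truth.

Builds idealized heavy-atom peptides (standard bond lengths/angles, canonical
phi/psi, most-common rotamers) and a two-domain hinge protein whose open and
closed conformations differ by a rigid rotation of the second domain about a
hinge axis -- a desk-scale stand-in for the domain-closure motions of
periplasmic-binding-protein-like receptors.  All stored ground-truth numbers
(Rg of both states, open/closed backbone RMSD) are recomputable from the
emitted coordinates.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .structures import Atom, Structure, select_atoms
from .geometry import rg_of_structure, rmsd, superpose

__all__ = ["HingePair", "make_hinge_protein", "make_toy_peptide"]

# one-letter -> three-letter codes
AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

_MASS = {"C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}

# canonical backbone torsions, degrees
_PHI_PSI = {"helix": (-57.0, -47.0), "extended": (-139.0, 135.0)}

# Engh-Huber-like backbone geometry
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF: position of atom d bonded to c with given internal coordinates
    (angle b-c-d, torsion a-b-c-d, degrees)."""
    ang = np.radians(angle)
    tor = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-10:  # collinear reference: pick any perpendicular
        helper = np.array([1.0, 0.0, 0.0])
        if abs(bc @ helper) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(bc, helper)
        norm = np.linalg.norm(n)
    n /= norm
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# Side-chain recipes: (atom, (ref1, ref2, ref3), bond, angle, torsion).
# The atom is bonded to ref3; references are backbone or earlier side-chain
# atoms of the same residue.  Torsions encode the most common rotamer.
_CB = ("CB", ("N", "C", "CA"), 1.530, 110.1, -122.6)
_SIDE_RECIPES: dict[str, list[tuple]] = {
    "GLY": [],
    "ALA": [_CB],
    "SER": [_CB, ("OG", ("N", "CA", "CB"), 1.417, 110.8, -65.0)],
    "CYS": [_CB, ("SG", ("N", "CA", "CB"), 1.808, 113.8, -65.0)],
    "THR": [_CB, ("OG1", ("N", "CA", "CB"), 1.433, 109.6, -60.0),
            ("CG2", ("N", "CA", "CB"), 1.521, 110.5, 60.0)],
    "VAL": [_CB, ("CG1", ("N", "CA", "CB"), 1.527, 110.5, 175.0),
            ("CG2", ("N", "CA", "CB"), 1.527, 110.5, -65.0)],
    "LEU": [_CB, ("CG", ("N", "CA", "CB"), 1.530, 116.3, -65.0),
            ("CD1", ("CA", "CB", "CG"), 1.521, 110.7, 175.0),
            ("CD2", ("CA", "CB", "CG"), 1.521, 110.7, -65.0)],
    "ILE": [_CB, ("CG1", ("N", "CA", "CB"), 1.530, 110.4, -60.0),
            ("CG2", ("N", "CA", "CB"), 1.521, 110.5, 60.0),
            ("CD1", ("CA", "CB", "CG1"), 1.513, 113.8, 170.0)],
    "MET": [_CB, ("CG", ("N", "CA", "CB"), 1.520, 114.1, -65.0),
            ("SD", ("CA", "CB", "CG"), 1.803, 112.7, 180.0),
            ("CE", ("CB", "CG", "SD"), 1.791, 100.9, 180.0)],
    "PRO": [_CB, ("CG", ("N", "CA", "CB"), 1.495, 104.5, 30.0),
            ("CD", ("CA", "CB", "CG"), 1.507, 105.5, -35.0)],
    "LYS": [_CB, ("CG", ("N", "CA", "CB"), 1.520, 114.1, -65.0),
            ("CD", ("CA", "CB", "CG"), 1.520, 111.3, 180.0),
            ("CE", ("CB", "CG", "CD"), 1.520, 111.3, 180.0),
            ("NZ", ("CG", "CD", "CE"), 1.489, 111.9, 180.0)],
    "ARG": [_CB, ("CG", ("N", "CA", "CB"), 1.520, 114.1, -65.0),
            ("CD", ("CA", "CB", "CG"), 1.520, 111.3, 180.0),
            ("NE", ("CB", "CG", "CD"), 1.461, 112.0, 180.0),
            ("CZ", ("CG", "CD", "NE"), 1.329, 124.2, 180.0),
            ("NH1", ("CD", "NE", "CZ"), 1.326, 120.0, 0.0),
            ("NH2", ("CD", "NE", "CZ"), 1.326, 120.0, 180.0)],
    "ASP": [_CB, ("CG", ("N", "CA", "CB"), 1.516, 112.6, -70.0),
            ("OD1", ("CA", "CB", "CG"), 1.249, 118.4, 0.0),
            ("OD2", ("CA", "CB", "CG"), 1.249, 118.4, 180.0)],
    "ASN": [_CB, ("CG", ("N", "CA", "CB"), 1.516, 112.6, -70.0),
            ("OD1", ("CA", "CB", "CG"), 1.231, 120.8, 0.0),
            ("ND2", ("CA", "CB", "CG"), 1.328, 116.4, 180.0)],
    "GLU": [_CB, ("CG", ("N", "CA", "CB"), 1.520, 114.1, -65.0),
            ("CD", ("CA", "CB", "CG"), 1.516, 112.6, 180.0),
            ("OE1", ("CB", "CG", "CD"), 1.249, 118.4, 0.0),
            ("OE2", ("CB", "CG", "CD"), 1.249, 118.4, 180.0)],
    "GLN": [_CB, ("CG", ("N", "CA", "CB"), 1.520, 114.1, -65.0),
            ("CD", ("CA", "CB", "CG"), 1.516, 112.6, 180.0),
            ("OE1", ("CB", "CG", "CD"), 1.231, 120.8, 0.0),
            ("NE2", ("CB", "CG", "CD"), 1.328, 116.4, 180.0)],
    "PHE": [_CB, ("CG", ("N", "CA", "CB"), 1.502, 113.8, -65.0),
            ("CD1", ("CA", "CB", "CG"), 1.391, 120.7, 90.0),
            ("CD2", ("CD1", "CB", "CG"), 1.391, 120.7, 180.0),
            ("CE1", ("CB", "CG", "CD1"), 1.391, 120.0, 180.0),
            ("CE2", ("CB", "CG", "CD2"), 1.391, 120.0, 180.0),
            ("CZ", ("CG", "CD1", "CE1"), 1.391, 120.0, 0.0)],
    "TYR": [_CB, ("CG", ("N", "CA", "CB"), 1.502, 113.8, -65.0),
            ("CD1", ("CA", "CB", "CG"), 1.391, 120.7, 90.0),
            ("CD2", ("CD1", "CB", "CG"), 1.391, 120.7, 180.0),
            ("CE1", ("CB", "CG", "CD1"), 1.391, 120.0, 180.0),
            ("CE2", ("CB", "CG", "CD2"), 1.391, 120.0, 180.0),
            ("CZ", ("CG", "CD1", "CE1"), 1.391, 120.0, 0.0),
            ("OH", ("CD1", "CE1", "CZ"), 1.377, 119.9, 180.0)],
    "TRP": [_CB, ("CG", ("N", "CA", "CB"), 1.498, 113.8, -65.0),
            ("CD1", ("CA", "CB", "CG"), 1.365, 127.0, 90.0),
            ("CD2", ("CD1", "CB", "CG"), 1.433, 126.6, 180.0),
            ("NE1", ("CB", "CG", "CD1"), 1.374, 110.1, 180.0),
            ("CE2", ("CD1", "CG", "CD2"), 1.409, 107.3, 0.0),
            ("CE3", ("CD1", "CG", "CD2"), 1.398, 133.9, 180.0),
            ("CZ2", ("CG", "CD2", "CE2"), 1.398, 122.4, 180.0),
            ("CZ3", ("CG", "CD2", "CE3"), 1.392, 118.6, 180.0),
            ("CH2", ("CD2", "CE2", "CZ2"), 1.372, 117.5, 0.0)],
    "HIS": [_CB, ("CG", ("N", "CA", "CB"), 1.492, 113.8, -65.0),
            ("ND1", ("CA", "CB", "CG"), 1.380, 122.7, -75.0),
            ("CD2", ("ND1", "CB", "CG"), 1.354, 131.2, 180.0),
            ("CE1", ("CB", "CG", "ND1"), 1.326, 109.3, 180.0),
            ("NE2", ("CG", "ND1", "CE1"), 1.343, 111.4, 0.0)],
}


def make_toy_peptide(sequence: str, conformation: str = "helix",
                     chain: str = "A", first_resnum: int = 1) -> Structure:
    """Idealized heavy-atom peptide with canonical phi/psi.

    ``conformation`` is ``"helix"`` (alpha, plants i -> i+4 backbone hydrogen
    bond geometry) or ``"extended"`` (beta strand); per-residue torsions may
    also be supplied as a list of (phi, psi) tuples.
    """
    if isinstance(conformation, str):
        if conformation not in _PHI_PSI:
            raise ValueError(f"unknown conformation {conformation!r}")
        torsions = [_PHI_PSI[conformation]] * len(sequence)
    else:
        torsions = list(conformation)
        if len(torsions) != len(sequence):
            raise ValueError("per-residue torsions must match sequence length")
    for letter in sequence:
        if letter not in AA3:
            raise ValueError(f"unknown residue letter {letter!r}")

    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    serial = 0

    def emit(name: str, element: str, resname: str, resnum: int,
             pos: np.ndarray) -> None:
        nonlocal serial
        serial += 1
        atoms.append(Atom(serial, name, element, _MASS[element], resname,
                          (chain, resnum, "")))
        coords.append(np.asarray(pos, dtype=float))

    prev = {}  # backbone atoms of the previous residue
    for ridx, letter in enumerate(sequence):
        resname = AA3[letter]
        phi, psi = torsions[ridx]
        resnum = first_resnum + ridx
        if ridx == 0:
            n = np.zeros(3)
            ca = np.array([_B_N_CA, 0.0, 0.0])
            ang = np.radians(_A_N_CA_C)
            c = ca + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
        else:
            n = _place(prev["N"], prev["CA"], prev["C"],
                       _B_C_N, _A_CA_C_N, prev["psi"])
            ca = _place(prev["CA"], prev["C"], n, _B_N_CA, _A_C_N_CA, 180.0)
            c = _place(prev["C"], n, ca, _B_CA_C, _A_N_CA_C, phi)
        o = _place(n, ca, c, _B_C_O, _A_CA_C_O, psi + 180.0)

        placed = {"N": n, "CA": ca, "C": c, "O": o}
        emit("N", "N", resname, resnum, n)
        emit("CA", "C", resname, resnum, ca)
        emit("C", "C", resname, resnum, c)
        emit("O", "O", resname, resnum, o)
        for name, refs, bond, angle, torsion in _SIDE_RECIPES[resname]:
            pos = _place(placed[refs[0]], placed[refs[1]], placed[refs[2]],
                         bond, angle, torsion)
            placed[name] = pos
            emit(name, name[0] if name[0] in _MASS else "C",
                 resname, resnum, pos)
        prev = {"N": n, "CA": ca, "C": c, "psi": psi}

    return Structure(atoms, np.array(coords))


# ---------------------------------------------------------------------------
# hinge protein


@dataclasses.dataclass(frozen=True)
class HingePair:
    """Open/closed conformations of a two-domain hinge protein plus a
    pseudo-ligand sitting in the closed cleft; ground-truth numbers are
    recomputable from the coordinates."""

    open: Structure
    closed: Structure
    ligand: Structure
    rg_open: float
    rg_closed: float
    bb_rmsd_open_closed: float


def _rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * k + (1 - np.cos(angle_rad)) * (k @ k)


def _domain_angle(coords: np.ndarray, idx1: np.ndarray, idx2: np.ndarray,
                  pivot: np.ndarray) -> float:
    v1 = coords[idx1].mean(axis=0) - pivot
    v2 = coords[idx2].mean(axis=0) - pivot
    cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def make_hinge_protein(n_res_per_domain: int = 8,
                       hinge_angle_open: float = 150.0,
                       hinge_angle_closed: float = 85.0,
                       seed: int = 0) -> HingePair:
    """Two helical domains joined by a 3-residue extended hinge.

    The open and closed states share one topology and differ only by a rigid
    rotation of domain 2 (plus the hinge carbonyl) about an axis through the
    central hinge CA; the requested angles are the inter-domain-centroid
    angles at that pivot.  A 4-atom pseudo-ligand is placed in the closed
    cleft.  Construction is deterministic for a given seed.
    """
    if n_res_per_domain < 5:
        raise ValueError("need at least 5 residues per domain")
    if hinge_angle_open < hinge_angle_closed:
        raise ValueError("open angle must not be smaller than the closed angle")

    # LEU-rich helical domains give each domain a hydrophobic spine; the
    # 3-residue extended hinge carries no planted interactions
    pattern = "LALSLALSLALSLALSLALS"
    dom = (pattern * (n_res_per_domain // len(pattern) + 1))[:n_res_per_domain]
    seq = dom + "ASA" + dom
    n1, nh = n_res_per_domain, 3
    torsions = ([_PHI_PSI["helix"]] * n1 + [_PHI_PSI["extended"]] * nh
                + [_PHI_PSI["helix"]] * n1)
    base = make_toy_peptide(seq, torsions)

    res = base.residues()
    dom1_atoms = np.array([i for r in res[:n1] for i in r[2]])
    dom2_atoms = np.array([i for r in res[n1 + nh:] for i in r[2]])
    hinge_res = res[n1 + 1]  # central hinge residue
    names = {base.atoms[i].name: i for i in hinge_res[2]}
    pivot_idx = names["CA"]
    # the rotating body: everything C-terminal of the pivot CA
    moving = np.array([names["C"], names["O"]]
                      + [i for r in res[n1 + 2:] for i in r[2]])

    coords0 = base.coords
    pivot = coords0[pivot_idx]
    v1 = coords0[dom1_atoms].mean(axis=0) - pivot
    v2 = coords0[dom2_atoms].mean(axis=0) - pivot
    axis = np.cross(v1, v2)
    if np.linalg.norm(axis) < 1e-6:
        axis = np.cross(v1, np.array([0.0, 0.0, 1.0]))
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(v1, np.array([0.0, 1.0, 0.0]))
    axis /= np.linalg.norm(axis)

    def bent(angle_target: float) -> np.ndarray:
        # solve the rotation angle that realizes the requested centroid angle
        c20 = coords0[dom2_atoms].mean(axis=0) - pivot
        c_par = (c20 @ axis) * axis
        c_perp = c20 - c_par
        w = np.cross(axis, c_perp)
        deltas = np.radians(np.linspace(-180.0, 180.0, 36001))
        c = (c_par[None, :] + np.cos(deltas)[:, None] * c_perp
             + np.sin(deltas)[:, None] * w)
        cosang = (c @ v1) / (np.linalg.norm(c, axis=1) * np.linalg.norm(v1))
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        err = np.abs(ang - angle_target)
        # the target angle is reached on two rotation branches; keep every
        # local optimum and pick the branch with the larger inter-domain
        # clearance (ties: smaller |rotation|)
        local = np.nonzero((err <= np.roll(err, 1)) & (err <= np.roll(err, -1))
                           & (err < 1.0))[0]
        if len(local) == 0:
            local = np.array([int(np.argmin(err))])
        best = None
        for k in local:
            rot = _rotation_about_axis(axis, float(deltas[k]))
            cand = coords0.copy()
            cand[moving] = (rot @ (coords0[moving] - pivot).T).T + pivot
            d1c = cand[dom1_atoms]
            d2c = cand[dom2_atoms]
            dmin = np.min(np.linalg.norm(d1c[:, None, :] - d2c[None, :, :],
                                         axis=-1))
            key = (round(dmin, 6), -abs(float(deltas[k])))
            if best is None or key > best[0]:
                best = (key, cand)
        return best[1]

    open_coords = bent(hinge_angle_open)
    closed_coords = bent(hinge_angle_closed)

    # clash check between the two domains of the closed state
    d1 = closed_coords[dom1_atoms]
    d2 = closed_coords[dom2_atoms]
    dmin = np.min(np.linalg.norm(d1[:, None, :] - d2[None, :, :], axis=-1))
    if dmin < 2.4:
        raise ValueError(
            f"closed conformation clashes (min inter-domain distance "
            f"{dmin:.2f} A); choose a larger closed angle"
        )

    open_st = base.with_coords(open_coords)
    closed_st = base.with_coords(closed_coords)

    # pseudo-ligand: small tetrahedron nudged into the closed cleft
    rng = np.random.default_rng(seed)
    center = 0.5 * (closed_coords[dom1_atoms].mean(axis=0)
                    + closed_coords[dom2_atoms].mean(axis=0))
    direction = center - pivot
    direction /= max(np.linalg.norm(direction), 1e-9)
    for step in np.linspace(0.0, 12.0, 121):
        pos = center + step * direction
        dmin_l = np.min(np.linalg.norm(closed_coords - pos, axis=1))
        if dmin_l >= 2.6:
            center = pos
            break
    lig_local = 1.2 * np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1],
                                [-1, -1, 1]], dtype=float) / np.sqrt(3)
    lig_local += 0.05 * rng.standard_normal(lig_local.shape)
    lig_atoms = [
        Atom(i + 1, f"C{i + 1}", "C", _MASS["C"], "LIG", ("L", 1, ""),
             is_hetero=True)
        for i in range(len(lig_local))
    ]
    ligand = Structure(lig_atoms, lig_local + center)

    bb = select_atoms(base, "backbone")
    fit = superpose(open_coords[bb], closed_coords[bb])
    return HingePair(
        open=open_st,
        closed=closed_st,
        ligand=ligand,
        rg_open=rg_of_structure(open_st),
        rg_closed=rg_of_structure(closed_st),
        bb_rmsd_open_closed=float(fit.fitted_rmsd),
    )
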