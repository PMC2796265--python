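"""Translate conserved interactions of a structure into distance constraints.

The sampler never sees a force field: everything it knows about the molecule
is a list of pairwise distance bounds.  Covalent structure (bonds, 1-3 pairs
fixing angles, 1-4 pairs limiting torsions) gives tight bounds; hydrogen bonds
that pass a desolvation-stability test and hydrophobic clusters give looser
bounds that preserve tertiary packing; every remaining atom pair receives an
excluded-volume lower bound.  The input structure satisfies every emitted
constraint by construction.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structures import Structure
from .geometry import rg_of_structure

__all__ = [
    "ConstraintError",
    "ConstraintConfig",
    "DistanceConstraint",
    "ConstraintSet",
    "HBond",
    "derive_topology",
    "detect_hbonds",
    "detect_hydrophobic_clusters",
    "build_constraints",
    "KIND_NAMES",
]


class ConstraintError(ValueError):
    pass


# constraint kind codes (int8 in the arrays; order = bound-tightness priority)
BOND, ANGLE13, PAIR14, HBOND, HYDROPHOBIC, EXCLUDED = range(6)
KIND_NAMES = ("bond", "angle13", "pair14", "hbond", "hydrophobic", "excluded-volume")
KIND_CODES = {n: i for i, n in enumerate(KIND_NAMES)}


@dataclasses.dataclass(frozen=True)
class ConstraintConfig:
    """Tolerances and cutoffs of the constraint generator (all configurable).

    Relative bound tolerances follow a tightness hierarchy
    bond < angle13 < pair14 < hbond < hydrophobic; 1-4 pairs across rigid
    (peptide / sp2-planar) bonds stay tight to keep those groups planar.
    """

    bond_tol: float = 0.005
    angle13_tol: float = 0.015
    pair14_lower_tol: float = 0.03
    pair14_upper_tol: float = 0.05
    pair14_rigid_tol: float = 0.01
    hbond_tol: float = 0.10
    hydrophobic_tol: float = 0.20
    hbond_max_dist: float = 3.5     # heavy-atom donor-acceptor cutoff, A
    hbond_min_angle: float = 90.0   # antecedent-donor-acceptor, degrees
    desolvation_radius: float = 5.0  # around the donor-acceptor midpoint, A
    desolvation_threshold: int = 2   # apolar minus polar neighbour count
    cluster_edge_cutoff: float = 4.5  # apolar atom graph edge, A
    cluster_pair_max: float = 6.0     # within-cluster pairs constrained up to, A
    min_cluster_atoms: int = 3
    excluded_volume_factor: float = 0.8  # x sum of Bondi radii
    disulfide_cutoff: float = 2.5


@dataclasses.dataclass(frozen=True)
class DistanceConstraint:
    i: int
    j: int
    lower: float
    upper: float
    kind: str

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ConstraintError("constraint between an atom and itself")
        if not (0 < self.lower <= self.upper):
            raise ConstraintError(
                f"invalid bounds [{self.lower}, {self.upper}] for pair "
                f"({self.i}, {self.j})"
            )


@dataclasses.dataclass(frozen=True)
class HBond:
    donor: int
    acceptor: int
    distance: float
    angle: float
    stability_score: float
    stable: bool


class ConstraintSet:
    """Array-backed collection of pairwise distance constraints."""

    def __init__(self, i: np.ndarray, j: np.ndarray, lower: np.ndarray,
                 upper: np.ndarray, kind: np.ndarray, n_atoms: int,
                 source_rg: float):
        self.i = np.asarray(i, dtype=np.int64)
        self.j = np.asarray(j, dtype=np.int64)
        self.lower = np.asarray(lower, dtype=float)
        self.upper = np.asarray(upper, dtype=float)
        self.kind = np.asarray(kind, dtype=np.int8)
        self.n_atoms = int(n_atoms)
        self.source_rg = float(source_rg)
        if not (len(self.i) == len(self.j) == len(self.lower)
                == len(self.upper) == len(self.kind)):
            raise ConstraintError("ragged constraint arrays")
        if len(self.i) and (self.i.max() >= n_atoms or self.j.max() >= n_atoms):
            raise ConstraintError("constraint index out of range")

    def __len__(self) -> int:
        return len(self.i)

    def __iter__(self) -> Iterator[DistanceConstraint]:
        for k in range(len(self.i)):
            yield DistanceConstraint(int(self.i[k]), int(self.j[k]),
                                     float(self.lower[k]), float(self.upper[k]),
                                     KIND_NAMES[self.kind[k]])

    def by_kind(self, kind: str) -> "ConstraintSet":
        m = self.kind == KIND_CODES[kind]
        return ConstraintSet(self.i[m], self.j[m], self.lower[m], self.upper[m],
                             self.kind[m], self.n_atoms, self.source_rg)

    def violations(self, coords: np.ndarray) -> np.ndarray:
        """Per-constraint violation in A (0 where satisfied)."""
        d = np.linalg.norm(coords[self.i] - coords[self.j], axis=1)
        return np.maximum(np.maximum(self.lower - d, d - self.upper), 0.0)

    def max_violation(self, coords: np.ndarray) -> float:
        v = self.violations(coords)
        return float(v.max()) if len(v) else 0.0

    def satisfaction_rate(self, coords: np.ndarray, tol: float = 1e-3) -> float:
        if len(self) == 0:
            return 1.0
        return float((self.violations(coords) <= tol).mean())

    # -- plain-text serialization (i, j, lower, upper, kind) ---------------
    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"# n_atoms={self.n_atoms}\tsource_rg={self.source_rg:.6f}\n")
            fh.write("i\tj\tlower\tupper\tkind\n")
            for c in self:
                up = "inf" if np.isinf(c.upper) else f"{c.upper:.6f}"
                fh.write(f"{c.i}\t{c.j}\t{c.lower:.6f}\t{up}\t{c.kind}\n")
        return path

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ConstraintSet":
        path = Path(path)
        lines = path.read_text().splitlines()
        header = lines[0].lstrip("# ").split("\t")
        meta = dict(kv.split("=") for kv in header)
        ii, jj, lo, up, kk = [], [], [], [], []
        for line in lines[2:]:
            if not line.strip():
                continue
            i, j, lower, upper, kind = line.split("\t")
            ii.append(int(i))
            jj.append(int(j))
            lo.append(float(lower))
            up.append(np.inf if upper == "inf" else float(upper))
            kk.append(KIND_CODES[kind])
        return cls(np.array(ii), np.array(jj), np.array(lo), np.array(up),
                   np.array(kk), int(meta["n_atoms"]), float(meta["source_rg"]))


# ---------------------------------------------------------------------------
# residue chemistry tables

#: heavy-atom intra-residue covalent bonds of the 20 standard amino acids
_BB = [("N", "CA"), ("CA", "C"), ("C", "O")]
_SIDECHAINS: dict[str, list[tuple[str, str]]] = {
    "GLY": [],
    "ALA": [("CA", "CB")],
    "SER": [("CA", "CB"), ("CB", "OG")],
    "CYS": [("CA", "CB"), ("CB", "SG")],
    "THR": [("CA", "CB"), ("CB", "OG1"), ("CB", "CG2")],
    "VAL": [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2")],
    "LEU": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")],
    "ILE": [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD1")],
    "MET": [("CA", "CB"), ("CB", "CG"), ("CG", "SD"), ("SD", "CE")],
    "PRO": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "N")],
    "PHE": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ")],
    "TYR": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ"),
            ("CZ", "OH")],
    "TRP": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "NE1"), ("NE1", "CE2"), ("CD2", "CE2"), ("CD2", "CE3"),
            ("CE2", "CZ2"), ("CE3", "CZ3"), ("CZ2", "CH2"), ("CZ3", "CH2")],
    "ASP": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")],
    "ASN": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "ND2")],
    "GLU": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"),
            ("CD", "OE2")],
    "GLN": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"),
            ("CD", "NE2")],
    "LYS": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "CE"),
            ("CE", "NZ")],
    "ARG": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "NE"),
            ("NE", "CZ"), ("CZ", "NH1"), ("CZ", "NH2")],
    "HIS": [("CA", "CB"), ("CB", "CG"), ("CG", "ND1"), ("CG", "CD2"),
            ("ND1", "CE1"), ("CD2", "NE2"), ("CE1", "NE2")],
}
RESIDUE_BONDS = {name: _BB + sc for name, sc in _SIDECHAINS.items()}

#: atoms belonging to rigid sp2-planar groups; 1-4 pairs across bonds inside
#: one of these groups (and across the peptide bond) keep tight bounds
_PLANAR_GROUPS: dict[str, frozenset[str]] = {
    "PHE": frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "TYR": frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"}),
    "TRP": frozenset({"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2",
                      "CZ3", "CH2"}),
    "HIS": frozenset({"CG", "ND1", "CD2", "CE1", "NE2"}),
    "ARG": frozenset({"NE", "CZ", "NH1", "NH2"}),
    "ASP": frozenset({"CB", "CG", "OD1", "OD2"}),
    "GLU": frozenset({"CG", "CD", "OE1", "OE2"}),
    "ASN": frozenset({"CB", "CG", "OD1", "ND2"}),
    "GLN": frozenset({"CG", "CD", "OE1", "NE2"}),
}

#: apolar side chains whose carbons/sulfur seed hydrophobic clusters
HYDROPHOBIC_RESIDUES = frozenset(
    {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO", "CYS"}
)
_BACKBONE_SET = frozenset({"N", "CA", "C", "O", "OXT"})

#: Bondi van der Waals radii, A
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
             "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90}
_DEFAULT_VDW = 1.70


# ---------------------------------------------------------------------------
# covalent graph


def _covalent_bonds(structure: Structure) -> list[tuple[int, int]]:
    """Covalent bonds as index pairs: residue templates + peptide links +
    disulfides; hetero residues fall back to distance-based bonding."""
    bonds: list[tuple[int, int]] = []
    coords = structure.coords
    residues = structure.residues()
    atom_index: dict[tuple[tuple[str, int, str], str], int] = {}
    for rid, rname, idxs in residues:
        for k in idxs:
            atom_index[(rid, structure.atoms[k].name)] = k

    for rid, rname, idxs in residues:
        hetero = structure.atoms[idxs[0]].is_hetero
        if hetero or rname not in RESIDUE_BONDS:
            if not hetero:
                raise ConstraintError(
                    f"no covalent template for residue {rname} {rid}"
                )
            # generic bonding for hetero groups: any pair closer than 1.9 A
            for a in range(len(idxs)):
                for b in range(a + 1, len(idxs)):
                    d = np.linalg.norm(coords[idxs[a]] - coords[idxs[b]])
                    if d < 1.9:
                        bonds.append((idxs[a], idxs[b]))
            continue
        for n1, n2 in RESIDUE_BONDS[rname]:
            i = atom_index.get((rid, n1))
            j = atom_index.get((rid, n2))
            if i is not None and j is not None:
                bonds.append((i, j))
        oxt = atom_index.get((rid, "OXT"))
        c = atom_index.get((rid, "C"))
        if oxt is not None and c is not None:
            bonds.append((c, oxt))

    # peptide links between consecutive residues of the same chain
    for (rid1, rn1, _), (rid2, rn2, _) in zip(residues, residues[1:]):
        if rid1[0] != rid2[0] or rn1 not in RESIDUE_BONDS or rn2 not in RESIDUE_BONDS:
            continue
        c = atom_index.get((rid1, "C"))
        n = atom_index.get((rid2, "N"))
        if c is not None and n is not None:
            if np.linalg.norm(coords[c] - coords[n]) < 1.8:
                bonds.append((c, n))

    # disulfide bridges
    sg = [atom_index[k] for k in atom_index
          if k[1] == "SG" and structure.atoms[atom_index[k]].residue_name == "CYS"]
    for a in range(len(sg)):
        for b in range(a + 1, len(sg)):
            cfg_cut = ConstraintConfig().disulfide_cutoff
            if np.linalg.norm(coords[sg[a]] - coords[sg[b]]) < cfg_cut:
                bonds.append((sg[a], sg[b]))
    return bonds


def _adjacency(n: int, bonds: Sequence[tuple[int, int]]) -> list[list[int]]:
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j in bonds:
        adj[i].append(j)
        adj[j].append(i)
    return adj


def _is_rigid_bond(structure: Structure, b: int, c: int) -> bool:
    ab, ac = structure.atoms[b], structure.atoms[c]
    if ab.residue_id != ac.residue_id:
        # inter-residue heavy-atom bond = peptide (or disulfide) -> planar omega
        return {ab.name, ac.name} == {"C", "N"}
    group = _PLANAR_GROUPS.get(ab.residue_name)
    return group is not None and ab.name in group and ac.name in group


def derive_topology(structure: Structure,
                    config: ConstraintConfig | None = None
                    ) -> list[DistanceConstraint]:
    """Bond, 1-3 (angle) and 1-4 (dihedral) distance constraints.

    Bounds are relative windows around the measured distances; 1-4 pairs get
    an asymmetric window (wider above) so dihedrals can rotate, except across
    peptide bonds and sp2-planar groups which stay near-rigid.
    """
    cfg = config or ConstraintConfig()
    coords = structure.coords
    bonds = _covalent_bonds(structure)
    adj = _adjacency(structure.n_atoms, bonds)
    bonded = {frozenset(b) for b in bonds}

    out: list[DistanceConstraint] = []
    seen: set[frozenset[int]] = set(bonded)
    for i, j in bonds:
        d = float(np.linalg.norm(coords[i] - coords[j]))
        out.append(DistanceConstraint(i, j, d * (1 - cfg.bond_tol),
                                      d * (1 + cfg.bond_tol), "bond"))

    # 1-3 pairs: two atoms bonded to a common centre
    pairs13: set[frozenset[int]] = set()
    for b in range(structure.n_atoms):
        nb = adj[b]
        for x in range(len(nb)):
            for y in range(x + 1, len(nb)):
                key = frozenset((nb[x], nb[y]))
                if key not in seen:
                    pairs13.add(key)
    for key in sorted(pairs13, key=sorted):
        i, j = sorted(key)
        d = float(np.linalg.norm(coords[i] - coords[j]))
        out.append(DistanceConstraint(i, j, d * (1 - cfg.angle13_tol),
                                      d * (1 + cfg.angle13_tol), "angle13"))
    seen |= pairs13

    # 1-4 pairs around every central bond
    pairs14: dict[frozenset[int], bool] = {}
    for b, c in bonds:
        rigid = _is_rigid_bond(structure, b, c)
        for a in adj[b]:
            if a == c:
                continue
            for d_ in adj[c]:
                if d_ == b or d_ == a:
                    continue
                key = frozenset((a, d_))
                if key in seen:
                    continue
                pairs14[key] = pairs14.get(key, False) or rigid
    for key in sorted(pairs14, key=sorted):
        i, j = sorted(key)
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if pairs14[key]:
            lo, up = d * (1 - cfg.pair14_rigid_tol), d * (1 + cfg.pair14_rigid_tol)
        else:
            lo, up = d * (1 - cfg.pair14_lower_tol), d * (1 + cfg.pair14_upper_tol)
        out.append(DistanceConstraint(i, j, lo, up, "pair14"))
    return out


# ---------------------------------------------------------------------------
# hydrogen bonds


def _graph_distance_le(adj: list[list[int]], i: int, j: int, cutoff: int) -> bool:
    """True when i and j are within `cutoff` covalent bonds of each other."""
    frontier = {i}
    seen = {i}
    for _ in range(cutoff):
        nxt = set()
        for a in frontier:
            for b in adj[a]:
                if b == j:
                    return True
                if b not in seen:
                    seen.add(b)
                    nxt.add(b)
        frontier = nxt
    return False


def detect_hbonds(structure: Structure,
                  config: ConstraintConfig | None = None) -> list[HBond]:
    """Geometric hydrogen-bond detection on heavy atoms.

    N/O donor and acceptor within 3.5 A, antecedent-donor-acceptor angle
    >= 90 deg (no explicit hydrogens).  Each bond is scored by a
    desolvation-stability proxy: the excess of apolar (C/S) over polar (N/O)
    heavy atoms within 5 A of the donor-acceptor midpoint, donor and acceptor
    residues excluded; a buried, apolar-shielded hydrogen bond is expected to
    survive conformational change, an exposed one is not.
    """
    cfg = config or ConstraintConfig()
    coords = structure.coords
    bonds = _covalent_bonds(structure)
    adj = _adjacency(structure.n_atoms, bonds)
    polar_idx = np.array(
        [i for i, a in enumerate(structure.atoms)
         if a.element in ("N", "O") and not a.is_hetero],
        dtype=int,
    )
    if len(polar_idx) < 2:
        return []
    elements = structure.elements
    tree = cKDTree(coords[polar_idx])
    cand = tree.query_pairs(cfg.hbond_max_dist, output_type="ndarray")

    all_tree = cKDTree(coords)
    out: list[HBond] = []
    for a_, b_ in cand:
        p, q = int(polar_idx[a_]), int(polar_idx[b_])
        ap, aq = structure.atoms[p], structure.atoms[q]
        if ap.residue_id == aq.residue_id:
            continue
        if _graph_distance_le(adj, p, q, 3):
            continue
        d = float(np.linalg.norm(coords[p] - coords[q]))

        def _best_angle(donor: int, acceptor: int) -> float:
            best = -1.0
            for ante in adj[donor]:
                u = coords[ante] - coords[donor]
                v = coords[acceptor] - coords[donor]
                cosang = float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))
                best = max(best, float(np.degrees(np.arccos(np.clip(cosang, -1, 1)))))
            return best if best >= 0 else 180.0

        choices = []
        for donor, acceptor in ((p, q), (q, p)):
            ang = _best_angle(donor, acceptor)
            if ang >= cfg.hbond_min_angle:
                choices.append((donor, acceptor, ang))
        if not choices:
            continue
        # prefer an N donor (backbone amide) when both directions pass
        choices.sort(key=lambda t: (elements[t[0]] != "N", t[0]))
        donor, acceptor, ang = choices[0]

        mid = 0.5 * (coords[p] + coords[q])
        near = all_tree.query_ball_point(mid, cfg.desolvation_radius)
        score = 0
        excl = {ap.residue_id, aq.residue_id}
        for k in near:
            ak = structure.atoms[k]
            if ak.residue_id in excl:
                continue
            if ak.element in ("C", "S"):
                score += 1
            elif ak.element in ("N", "O"):
                score -= 1
        out.append(HBond(donor, acceptor, d, ang, float(score),
                         score >= cfg.desolvation_threshold))
    out.sort(key=lambda h: (min(h.donor, h.acceptor), max(h.donor, h.acceptor)))
    return out


# ---------------------------------------------------------------------------
# hydrophobic clusters


def detect_hydrophobic_clusters(structure: Structure,
                                config: ConstraintConfig | None = None
                                ) -> list[set[int]]:
    """Connected components of packed apolar side-chain atoms.

    Nodes are side-chain carbons/sulfur of hydrophobic residues; edges join
    atoms within the edge cutoff (4.5 A).  A component only counts as a
    cluster when it has >= 3 atoms spanning >= 2 residues (a lone side chain
    is not a cluster).
    """
    cfg = config or ConstraintConfig()
    nodes = [
        i for i, a in enumerate(structure.atoms)
        if (not a.is_hetero and a.residue_name in HYDROPHOBIC_RESIDUES
            and a.element in ("C", "S") and a.name not in _BACKBONE_SET)
    ]
    if not nodes:
        return []
    tree = cKDTree(structure.coords[nodes])
    pairs = tree.query_pairs(cfg.cluster_edge_cutoff)

    parent = list(range(len(nodes)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    comps: dict[int, set[int]] = {}
    for k in range(len(nodes)):
        comps.setdefault(find(k), set()).add(nodes[k])
    clusters = []
    for comp in comps.values():
        if len(comp) < cfg.min_cluster_atoms:
            continue
        nres = len({structure.atoms[i].residue_id for i in comp})
        if nres < 2:
            continue
        clusters.append(comp)
    clusters.sort(key=min)
    return clusters


# ---------------------------------------------------------------------------
# assembly


def build_constraints(structure: Structure,
                      config: ConstraintConfig | None = None) -> ConstraintSet:
    """Full constraint set: topology + stable H-bonds + hydrophobic clusters
    + excluded-volume lower bounds for every remaining pair.

    At most one non-excluded-volume constraint per pair (the tightest kind
    wins); excluded-volume lower bounds are 0.8 x the Bondi-radius sum,
    capped at the measured distance so the input structure satisfies its own
    constraint set exactly.
    """
    cfg = config or ConstraintConfig()
    coords = structure.coords
    n = structure.n_atoms

    best: dict[tuple[int, int], tuple[int, float, float]] = {}

    def add(i: int, j: int, lo: float, up: float, kind: int) -> None:
        key = (min(i, j), max(i, j))
        prev = best.get(key)
        if prev is None or kind < prev[0]:
            best[key] = (kind, lo, up)

    for c in derive_topology(structure, cfg):
        add(c.i, c.j, c.lower, c.upper, KIND_CODES[c.kind])

    for hb in detect_hbonds(structure, cfg):
        if not hb.stable:
            continue
        add(hb.donor, hb.acceptor, hb.distance * (1 - cfg.hbond_tol),
            hb.distance * (1 + cfg.hbond_tol), HBOND)

    for cluster in detect_hydrophobic_clusters(structure, cfg):
        members = sorted(cluster)
        rid = structure.residue_ids()
        for x in range(len(members)):
            for y in range(x + 1, len(members)):
                i, j = members[x], members[y]
                if rid[i] == rid[j]:
                    continue
                d = float(np.linalg.norm(coords[i] - coords[j]))
                if d > cfg.cluster_pair_max:
                    continue
                add(i, j, d * (1 - cfg.hydrophobic_tol),
                    d * (1 + cfg.hydrophobic_tol), HYDROPHOBIC)

    # excluded volume for every remaining pair (vectorized over i<j)
    iu, ju = np.triu_indices(n, k=1)
    radii = np.array([VDW_RADII.get(a.element.upper(), _DEFAULT_VDW)
                      for a in structure.atoms])
    ev_lower = cfg.excluded_volume_factor * (radii[iu] + radii[ju])
    dist = np.linalg.norm(coords[iu] - coords[ju], axis=1)
    ev_lower = np.minimum(ev_lower, dist)  # never contradict the input packing

    constrained = np.zeros(n * n, dtype=bool)
    for (i, j) in best:
        constrained[i * n + j] = True
    free = ~constrained[iu * n + ju]

    ii = [k[0] for k in best]
    jj = [k[1] for k in best]
    lo = [v[1] for v in best.values()]
    up = [v[2] for v in best.values()]
    kk = [v[0] for v in best.values()]

    i_all = np.concatenate([np.array(ii, dtype=np.int64), iu[free]])
    j_all = np.concatenate([np.array(jj, dtype=np.int64), ju[free]])
    lo_all = np.concatenate([np.array(lo), ev_lower[free]])
    up_all = np.concatenate([np.array(up), np.full(free.sum(), np.inf)])
    k_all = np.concatenate([np.array(kk, dtype=np.int8),
                            np.full(free.sum(), EXCLUDED, dtype=np.int8)])

    order = np.lexsort((j_all, i_all, k_all))
    return ConstraintSet(i_all[order], j_all[order], lo_all[order],
                         up_all[order], k_all[order], n,
                         rg_of_structure(structure))
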