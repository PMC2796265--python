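"""Reduce, rank and filter conformational ensembles.

Greedy leader clustering on fitted backbone RMSD reduces an ensemble to a
pool of distinct conformations; Rg-compliance ranking and the 1%-deviation
filter (with a widening fallback when too few models survive) pick the
models whose compactness matches the target shape; assessment reports
RMSD-to-reference per frame, globally and over the binding site.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .structures import Structure, Ensemble, select_atoms
from .geometry import radius_of_gyration, rmsd, pair_common_atoms, superpose

__all__ = [
    "ClusterResult",
    "RankingReport",
    "cluster_by_rmsd",
    "cluster_to_size",
    "rank_by_rg",
    "rank_by_score",
    "filter_by_rg",
    "assess_against_reference",
]

log = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class ClusterResult:
    """Greedy-leader clustering outcome: representative frames and a
    frame -> cluster assignment at a given RMSD cutoff."""

    representatives: list[int]
    assignment: dict[int, int]
    cutoff: float

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)


@dataclasses.dataclass
class RankingReport:
    """Per-frame records plus a rank order (ascending Rg deviation unless
    stated otherwise); ``table`` is a pandas DataFrame in frame order."""

    table: pd.DataFrame
    order: list[int]

    def top(self, k: int) -> list[int]:
        return self.order[:k]

    def rank_of_first_under(self, column: str, threshold: float) -> int | None:
        """1-based rank of the first frame (in ranking order) whose value in
        ``column`` is below ``threshold``; None when no frame qualifies
        (reported as "-" in tables)."""
        for rank, idx in enumerate(self.order, start=1):
            if self.table.loc[idx, column] < threshold:
                return rank
        return None


def cluster_by_rmsd(ensemble: Ensemble, cutoff: float,
                    selection: Sequence[int] | None = None) -> ClusterResult:
    """Greedy leader clustering on fitted RMSD over ``selection`` atoms.

    The first unassigned frame becomes a representative; every later frame
    within ``cutoff`` of it joins its cluster.  Deterministic in frame order.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if ensemble.n_frames == 0:
        raise ValueError("cannot cluster an empty ensemble")
    if selection is None:
        selection = select_atoms(ensemble.topology, "backbone")
    sel = np.asarray(list(selection), dtype=int)

    reps: list[int] = []
    assignment: dict[int, int] = {}
    for f in range(ensemble.n_frames):
        placed = False
        for c, rep in enumerate(reps):
            if rmsd(ensemble.frames[f][sel], ensemble.frames[rep][sel],
                    fit=True) <= cutoff:
                assignment[f] = c
                placed = True
                break
        if not placed:
            assignment[f] = len(reps)
            reps.append(f)
    return ClusterResult(reps, assignment, float(cutoff))


def cluster_to_size(ensemble: Ensemble, target_size: int,
                    selection: Sequence[int] | None = None,
                    rel_tol: float = 0.10, max_iter: int = 30) -> ClusterResult:
    """Binary-search the RMSD cutoff so the representative count lands within
    ``rel_tol`` of ``target_size`` (used when a pool of roughly N distinct
    conformations is wanted rather than a fixed radius)."""
    if target_size < 1:
        raise ValueError("target_size must be >= 1")
    if ensemble.n_frames <= target_size:
        return cluster_by_rmsd(ensemble, 1e-6, selection)
    lo_cut, hi_cut = 1e-3, 100.0
    best = None
    for _ in range(max_iter):
        mid = np.sqrt(lo_cut * hi_cut)
        res = cluster_by_rmsd(ensemble, mid, selection)
        if best is None or (abs(res.n_clusters - target_size)
                            < abs(best.n_clusters - target_size)):
            best = res
        if abs(res.n_clusters - target_size) <= rel_tol * target_size:
            return res
        if res.n_clusters > target_size:
            lo_cut = mid  # need a larger radius -> fewer clusters
        else:
            hi_cut = mid
    return best


def _frame_rgs(ensemble: Ensemble, masses: np.ndarray | None = None) -> np.ndarray:
    if masses is None:
        masses = ensemble.topology.masses
    return np.array([radius_of_gyration(f, masses).value
                     for f in ensemble.frames])


def rank_by_rg(ensemble: Ensemble, target: float,
               masses: np.ndarray | None = None) -> RankingReport:
    """Rank frames by |Rg - target| ascending; ties go to the lower frame
    index."""
    if ensemble.n_frames == 0:
        raise ValueError("cannot rank an empty ensemble")
    rgs = _frame_rgs(ensemble, masses)
    abs_dev = np.abs(rgs - target)
    table = pd.DataFrame({
        "frame": np.arange(ensemble.n_frames),
        "rg": rgs,
        "rg_abs_dev": abs_dev,
        "rg_rel_dev": abs_dev / target,
    })
    order = sorted(range(ensemble.n_frames), key=lambda k: (abs_dev[k], k))
    return RankingReport(table, order)


def rank_by_score(ensemble: Ensemble,
                  scores: dict[int, float] | Callable[[int], float]
                  ) -> RankingReport:
    """Generic ranking hook for externally computed per-frame scores
    (lower = better), e.g. from an external scoring or refinement engine."""
    get = scores.__getitem__ if isinstance(scores, dict) else scores
    vals = np.array([float(get(k)) for k in range(ensemble.n_frames)])
    table = pd.DataFrame({"frame": np.arange(ensemble.n_frames), "score": vals})
    order = sorted(range(ensemble.n_frames), key=lambda k: (vals[k], k))
    return RankingReport(table, order)


def filter_by_rg(ensemble: Ensemble, target: float,
                 rel_cutoff: float = 0.01, min_keep: int = 1,
                 masses: np.ndarray | None = None,
                 max_rel_cutoff: float = 0.16) -> list[int]:
    """Frames whose Rg deviates from the target by less than ``rel_cutoff``
    (relative).  When fewer than ``min_keep`` survive, the cutoff doubles
    (each widening logged) until enough do or it exceeds ``max_rel_cutoff``.
    """
    if ensemble.n_frames == 0:
        raise ValueError("cannot filter an empty ensemble")
    rel_dev = np.abs(_frame_rgs(ensemble, masses) - target) / target
    cutoff = rel_cutoff
    kept = [int(i) for i in np.nonzero(rel_dev < cutoff)[0]]
    while len(kept) < min_keep and cutoff <= max_rel_cutoff:
        cutoff *= 2
        log.info("Rg filter widened to %.3f relative deviation", cutoff)
        kept = [int(i) for i in np.nonzero(rel_dev < cutoff)[0]]
    return kept


def assess_against_reference(ensemble: Ensemble, reference: Structure,
                             site: set | None = None,
                             local_site_fit: bool = True) -> RankingReport:
    """Fitted backbone RMSD (global) plus binding-site RMSD per frame.

    Atoms are paired with the reference by (chain, residue, name); the site
    RMSD is reported backbone-only and all-heavy-atom, superposed on the site
    atoms themselves (``local_site_fit``) or on the global backbone.
    Ordering follows the global backbone RMSD ascending.
    """
    top = ensemble.topology
    ia, ib = pair_common_atoms(top, reference)
    ia_arr, ib_arr = np.asarray(ia), np.asarray(ib)

    bb_names = {"N", "CA", "C", "O"}
    bb_mask = np.array([top.atoms[i].name in bb_names
                        and not top.atoms[i].is_hetero for i in ia])
    if site is not None:
        site_mask = np.array([top.atoms[i].residue_id in site for i in ia])
    else:
        site_mask = np.zeros(len(ia), dtype=bool)

    ref_paired = reference.coords[ib_arr]
    rows = []
    for f, frame in enumerate(ensemble.frames):
        mob = frame[ia_arr]
        row = {"frame": f, "rmsd_bb": rmsd(mob[bb_mask], ref_paired[bb_mask],
                                           fit=True)}
        if site_mask.any():
            sb = site_mask & bb_mask
            if local_site_fit:
                row["rmsd_site_bb"] = rmsd(mob[sb], ref_paired[sb], fit=True)
                row["rmsd_site_all"] = rmsd(mob[site_mask],
                                            ref_paired[site_mask], fit=True)
            else:
                fit = superpose(mob[bb_mask], ref_paired[bb_mask])
                moved = fit.apply(mob)
                row["rmsd_site_bb"] = rmsd(moved[sb], ref_paired[sb], fit=False)
                row["rmsd_site_all"] = rmsd(moved[site_mask],
                                            ref_paired[site_mask], fit=False)
        rows.append(row)
    table = pd.DataFrame(rows)
    order = sorted(range(len(rows)), key=lambda k: (rows[k]["rmsd_bb"], k))
    return RankingReport(table, order)
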