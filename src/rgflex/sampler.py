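"""Constraint-based conformational sampling with a radius-of-gyration bias.

A new conformation is rebuilt from a randomized start: the input coordinates
are deformed by random long-wavelength modes plus white noise (which
randomizes the soft degrees of freedom -- hinge and loop motions -- while
keeping the covalent topology recoverable), then driven back into the
feasible set of the distance constraints.  Relaxation is hybrid: FIRE
descent on the squared bound violations over an active subset of pairs,
alternated with uniform rescaling about the centre of mass toward the target
radius of gyration and local re-randomization of atoms stuck in infeasible
local geometry, followed by Gauss-Seidel pair-correction sweeps that settle
every bound to within the convergence tolerance.  When a target Rg is given,
a converged frame additionally lies within the Rg tolerance; the compactness
bias steers sampling toward ligand-bound-like (domain-closed) states without
dictating which contacts close.  A mirror check guards against globally
inverted solutions, which pure distance geometry cannot distinguish.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Sequence

import numpy as np
from numba import njit

from .structures import Structure, Ensemble, FrameInfo
from .geometry import radius_of_gyration
from .constraints import (
    ConstraintConfig,
    ConstraintSet,
    build_constraints,
    detect_hbonds,
    detect_hydrophobic_clusters,
    KIND_CODES,
    EXCLUDED,
)

__all__ = [
    "RgConstraint",
    "SamplerConfig",
    "RebuildResult",
    "rebuild_conformation",
    "generate_ensemble",
    "predict_flexible_sidechains",
    "resample_sidechains",
    "SamplerError",
]

log = logging.getLogger(__name__)

_BACKBONE = frozenset({"N", "CA", "C", "O", "OXT"})


class SamplerError(RuntimeError):
    pass


@dataclasses.dataclass(frozen=True)
class RgConstraint:
    """Target radius of gyration (A) with tolerance (default 0.1 A)."""

    target: float
    tolerance: float = 0.1

    def __post_init__(self) -> None:
        if not self.target > 0 or not self.tolerance > 0:
            raise ValueError("Rg target and tolerance must be positive")


@dataclasses.dataclass
class SamplerConfig:
    """Knobs of the rebuild loop (defaults: 1000-member ensembles, 0.1 A
    Rg tolerance, 1e-3 A violation tolerance)."""

    n_conformers: int = 1000
    seed: int = 0
    max_sweeps: int = 500         # final exact-feasibility sweep budget
    max_restarts: int = 10
    n_outer_rounds: int = 12      # rescale / FIRE / repair rounds
    fire_iters: int = 350
    fire_iters_later: int = 250   # per outer round after the first
    violation_tol: float = 1e-3   # A
    interior_frac: float = 0.3    # corrections aim this far into the window
    rg_scale_clip: tuple[float, float] = (0.99, 1.01)  # per-sweep rescale
    perturb_mode_amp: float = 1.0   # A, low-frequency start deformation
    perturb_white: float = 1.0      # A, white-noise start deformation
    n_perturb_modes: int = 3
    active_margin: float = 1.5      # A, excluded-volume active-set margin
    start_box_factor: float = 4.0   # cube side = factor x Rg (no-reference start)
    constraints: ConstraintConfig = dataclasses.field(default_factory=ConstraintConfig)

    def __post_init__(self) -> None:
        if self.n_conformers < 1 or self.max_sweeps < 1:
            raise ValueError("n_conformers and max_sweeps must be >= 1")


@dataclasses.dataclass
class RebuildResult:
    coords: np.ndarray
    converged: bool
    sweeps_used: int
    max_violation: float
    final_rg: float


# ---------------------------------------------------------------------------
# numba kernels


@njit(cache=True)
def _sweep(x, ci, cj, lo, up, w, order, frac):  # pragma: no cover - jitted
    """One Gauss-Seidel sweep: move each violated pair to a point ``frac``
    inside its allowed window (pinned atoms absorb zero displacement)."""
    for t in range(order.shape[0]):
        k = order[t]
        i = ci[k]
        j = cj[k]
        wi = w[i]
        wj = w[j]
        s = wi + wj
        if s <= 0.0:
            continue
        dx = x[j, 0] - x[i, 0]
        dy = x[j, 1] - x[i, 1]
        dz = x[j, 2] - x[i, 2]
        d2 = dx * dx + dy * dy + dz * dz
        if d2 < 1e-12:
            # coincident atoms: separate along a deterministic direction
            dx = 1e-3 * (1.0 + (k % 3))
            dy = 1e-3 * (1.0 + (k % 5))
            dz = 1e-3 * (1.0 + (k % 7))
            d2 = dx * dx + dy * dy + dz * dz
        d = np.sqrt(d2)
        l = lo[k]
        u = up[k]
        if d < l:
            hi = u if u < l * 1.1 else l * 1.1
            tgt = l + frac * (hi - l)
        elif d > u:
            lo2 = l if l > u * 0.9 else u * 0.9
            tgt = u - frac * (u - lo2)
        else:
            continue
        f = (tgt - d) / d
        fi = f * wi / s
        fj = f * wj / s
        x[i, 0] -= dx * fi
        x[i, 1] -= dy * fi
        x[i, 2] -= dz * fi
        x[j, 0] += dx * fj
        x[j, 1] += dy * fj
        x[j, 2] += dz * fj


@njit(cache=True)
def _max_violation(x, ci, cj, lo, up, fin):  # pragma: no cover - jitted
    mv = 0.0
    for k in range(ci.shape[0]):
        i = ci[k]
        j = cj[k]
        dx = x[j, 0] - x[i, 0]
        dy = x[j, 1] - x[i, 1]
        dz = x[j, 2] - x[i, 2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        viol = lo[k] - d
        if fin[k] and d - up[k] > viol:
            viol = d - up[k]
        if viol > mv:
            mv = viol
    return mv


@njit(cache=True)
def _fire_relax(x, ci, cj, lo, up, fin, w, max_iter, tol):  # pragma: no cover
    """FIRE descent on the sum of squared bound violations; atoms with
    weight 0 are pinned.  Returns (iterations used, max violation)."""
    nat = x.shape[0]
    v = np.zeros((nat, 3))
    g = np.zeros((nat, 3))
    dt = 0.05
    dt_max = 0.3
    alpha = 0.1
    n_pos = 0
    mv = 1e30
    for it in range(max_iter):
        g[:] = 0.0
        mv = 0.0
        for k in range(ci.shape[0]):
            i = ci[k]
            j = cj[k]
            dx = x[j, 0] - x[i, 0]
            dy = x[j, 1] - x[i, 1]
            dz = x[j, 2] - x[i, 2]
            d = np.sqrt(dx * dx + dy * dy + dz * dz)
            if d < 1e-8:
                d = 1e-8
            l = lo[k]
            u = up[k]
            viol = 0.0
            if d < l:
                viol = l - d
                coef = 2.0 * viol / d
                g[i, 0] += coef * dx
                g[i, 1] += coef * dy
                g[i, 2] += coef * dz
                g[j, 0] -= coef * dx
                g[j, 1] -= coef * dy
                g[j, 2] -= coef * dz
            elif fin[k] and d > u:
                viol = d - u
                coef = 2.0 * viol / d
                g[i, 0] -= coef * dx
                g[i, 1] -= coef * dy
                g[i, 2] -= coef * dz
                g[j, 0] += coef * dx
                g[j, 1] += coef * dy
                g[j, 2] += coef * dz
            if viol > mv:
                mv = viol
        if mv <= tol:
            return it, mv
        p = 0.0
        for a in range(nat):
            p += -(g[a, 0] * v[a, 0] + g[a, 1] * v[a, 1] + g[a, 2] * v[a, 2])
        if p > 0:
            n_pos += 1
            if n_pos > 5:
                dt = min(dt * 1.1, dt_max)
                alpha *= 0.99
        else:
            n_pos = 0
            dt *= 0.5
            alpha = 0.1
            v[:] = 0.0
        gn = 0.0
        vn = 0.0
        for a in range(nat):
            gn += g[a, 0] ** 2 + g[a, 1] ** 2 + g[a, 2] ** 2
            vn += v[a, 0] ** 2 + v[a, 1] ** 2 + v[a, 2] ** 2
        gn = np.sqrt(gn)
        vn = np.sqrt(vn)
        for a in range(nat):
            for c in range(3):
                vmix = (1 - alpha) * v[a, c]
                if gn > 0:
                    vmix += alpha * vn / gn * (-g[a, c])
                v[a, c] = vmix - dt * g[a, c]
                if w[a] > 0:
                    x[a, c] += dt * v[a, c]
    return max_iter, mv


# ---------------------------------------------------------------------------
# chirality bookkeeping


def chirality_quadruples(structure: Structure) -> np.ndarray:
    """(n_res, 4) indices of (CA, N, C, CB) per residue having all four."""
    quads = []
    for rid, rname, idxs in structure.residues():
        names = {structure.atoms[i].name: i for i in idxs}
        if all(k in names for k in ("CA", "N", "C", "CB")):
            quads.append((names["CA"], names["N"], names["C"], names["CB"]))
    return np.array(quads, dtype=np.int64).reshape(-1, 4)


def mean_signed_volume(coords: np.ndarray, quads: np.ndarray) -> float:
    """Mean signed volume of the (N, C, CB) frame about each CA; its sign is
    the handedness of the backbone."""
    if len(quads) == 0:
        return 0.0
    ca = coords[quads[:, 0]]
    v1 = coords[quads[:, 1]] - ca
    v2 = coords[quads[:, 2]] - ca
    v3 = coords[quads[:, 3]] - ca
    return float(np.mean(np.einsum("ij,ij->i", v1, np.cross(v2, v3))))


# ---------------------------------------------------------------------------
# single-conformation rebuild


def _weighted_com(x: np.ndarray, masses: np.ndarray) -> np.ndarray:
    return (masses[:, None] * x).sum(axis=0) / masses.sum()


def _perturbed_start(reference: np.ndarray, rng: np.random.Generator,
                     cfg: SamplerConfig, free: np.ndarray | None) -> np.ndarray:
    """Randomized start: reference + low-frequency modes + white noise.

    The smooth modes displace whole stretches of the chain coherently, so
    soft collective degrees of freedom (hinges, loops) start in genuinely
    different states from frame to frame."""
    n = reference.shape[0]
    x = reference.copy()
    t = np.linspace(0.0, 1.0, n)
    disp = np.zeros((n, 3))
    for k in range(1, cfg.n_perturb_modes + 1):
        phase = rng.uniform(0, 2 * np.pi)
        vec = rng.standard_normal(3)
        disp += np.outer(np.sin(np.pi * k * t + phase), vec) * (
            cfg.perturb_mode_amp / k)
    disp += cfg.perturb_white * rng.standard_normal((n, 3))
    if free is None:
        x += disp
    else:
        x[free] += disp[free]
    return x


def _bond_partners(cs: ConstraintSet) -> list[list[tuple[int, float]]]:
    partners: list[list[tuple[int, float]]] = [[] for _ in range(cs.n_atoms)]
    bonds = cs.kind == KIND_CODES["bond"]
    for i, j, l in zip(cs.i[bonds], cs.j[bonds], cs.lower[bonds]):
        partners[int(i)].append((int(j), float(l)))
        partners[int(j)].append((int(i), float(l)))
    return partners


def rebuild_conformation(
    cs: ConstraintSet,
    rg: RgConstraint | None,
    masses: np.ndarray,
    seed: int,
    config: SamplerConfig | None = None,
    reference_coords: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    chirality_ref: tuple[np.ndarray, float] | None = None,
) -> RebuildResult:
    """Rebuild one conformation satisfying ``cs`` from a randomized start.

    ``reference_coords`` seeds the randomized start (without it atoms start
    uniformly in a cube scaled to the source Rg -- workable only for very
    small systems); ``weights`` (0 = pinned, 1 = free) supports the
    fixed-backbone resampling mode; ``chirality_ref`` is ``(quads, sign)``
    from the input structure.
    """
    cfg = config or SamplerConfig()
    masses = np.asarray(masses, dtype=float)
    n = cs.n_atoms
    if masses.shape != (n,):
        raise ValueError("masses length does not match constraint set")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    free = None if weights is None else (w > 0)
    m = len(cs)
    fin = np.isfinite(cs.upper)
    up_safe = np.where(fin, cs.upper, 1e9)
    struct_idx = np.nonzero(cs.kind != EXCLUDED)[0]
    ev_idx = np.nonzero(cs.kind == EXCLUDED)[0]
    partners = _bond_partners(cs)
    quads, ref_sign = (np.empty((0, 4), dtype=np.int64), 0.0)
    if chirality_ref is not None:
        quads, ref_sign = chirality_ref

    def rg_value(x: np.ndarray) -> float:
        return radius_of_gyration(x, masses).value

    def full_mv(x: np.ndarray) -> float:
        return float(_max_violation(x, cs.i, cs.j, cs.lower, up_safe, fin))

    def rg_ok(x: np.ndarray) -> bool:
        return rg is None or abs(rg_value(x) - rg.target) <= rg.tolerance

    def chirality_ok(x: np.ndarray) -> bool:
        if len(quads) == 0 or ref_sign == 0.0:
            return True
        return mean_signed_volume(x, quads) * ref_sign > 0

    best: RebuildResult | None = None
    for attempt in range(cfg.max_restarts + 1):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF,
                                   spawn_key=(attempt,))
        )
        if reference_coords is not None:
            x = _perturbed_start(np.asarray(reference_coords, dtype=float),
                                 rng, cfg, free)
        else:
            side = cfg.start_box_factor * max(cs.source_rg, 1.0)
            x = rng.uniform(-side / 2, side / 2, size=(n, 3))

        sweeps = 0
        # phase 1: outer rounds of (rescale to target Rg) -> active-set FIRE
        # -> local repair of stuck atoms
        for rd in range(cfg.n_outer_rounds):
            if rg is not None and weights is None:
                cur = rg_value(x)
                com = _weighted_com(x, masses)
                x = com + (x - com) * (rg.target / max(cur, 1e-9))
            if len(ev_idx):
                d_ev = np.linalg.norm(x[cs.i[ev_idx]] - x[cs.j[ev_idx]],
                                      axis=1)
                act = np.concatenate([
                    struct_idx,
                    ev_idx[d_ev < cs.lower[ev_idx] + cfg.active_margin],
                ])
            else:
                act = struct_idx if len(struct_idx) else np.arange(m)
            iters = cfg.fire_iters if rd == 0 else cfg.fire_iters_later
            it, _ = _fire_relax(x, cs.i[act], cs.j[act], cs.lower[act],
                                up_safe[act], fin[act], w, iters,
                                cfg.violation_tol)
            sweeps += it
            mv_now = full_mv(x)
            if mv_now <= cfg.violation_tol and rg_ok(x) and chirality_ok(x):
                break
            if mv_now > cfg.violation_tol:
                v = cs.violations(x)
                viol_struct = struct_idx[v[struct_idx] > cfg.violation_tol]
                if len(viol_struct) == 0:
                    # only freshly violated excluded-volume pairs: re-select
                    # the active set next round instead of repairing
                    continue
                bad = np.unique(np.concatenate(
                    [cs.i[viol_struct], cs.j[viol_struct]]
                ))
                if len(bad) <= 30:
                    # re-place atoms trapped in infeasible local geometry
                    # next to a bonded partner
                    for a in bad:
                        if w[a] <= 0:
                            continue
                        if partners[a]:
                            b, blen = partners[a][rng.integers(len(partners[a]))]
                            u = rng.standard_normal(3)
                            u /= np.linalg.norm(u)
                            x[a] = x[b] + blen * u
                        else:
                            x[a] = x[a] + rng.normal(0.0, 1.0, 3)

        # phase 2: exact-feasibility sweeps (+ gentle Rg rescale per sweep)
        converged = False
        for sweep in range(cfg.max_sweeps):
            mv = full_mv(x)
            ok = mv <= cfg.violation_tol and rg_ok(x)
            if ok and not chirality_ok(x):
                # mirror through the yz-plane at the mass centre: distances
                # and Rg are invariant, handedness flips; keep sweeping
                com = _weighted_com(x, masses)
                x[:, 0] = 2 * com[0] - x[:, 0]
                ok = True
            if ok and chirality_ok(x):
                converged = True
                break
            sweeps += 1
            order = rng.permutation(m)
            _sweep(x, cs.i, cs.j, cs.lower, cs.upper, w, order,
                   cfg.interior_frac)
            if rg is not None and weights is None and not rg_ok(x):
                cur = rg_value(x)
                fac = float(np.clip(rg.target / max(cur, 1e-9),
                                    *cfg.rg_scale_clip))
                com = _weighted_com(x, masses)
                x = com + (x - com) * fac

        result = RebuildResult(x, converged, sweeps, full_mv(x), rg_value(x))
        if converged:
            return result
        if best is None or result.max_violation < best.max_violation:
            best = result
    return best  # non-converged after all restarts


# ---------------------------------------------------------------------------
# ensemble generation


def generate_ensemble(structure: Structure, config: SamplerConfig,
                      rg: RgConstraint | None = None,
                      cs: ConstraintSet | None = None) -> Ensemble:
    """Generate ``config.n_conformers`` independent rebuilds (seeds seed+k).

    Non-converged attempts are dropped and logged; every kept frame satisfies
    the full constraint set and, when requested, the Rg window.
    """
    if cs is None:
        cs = build_constraints(structure, config.constraints)
    viol = cs.max_violation(structure.coords)
    if viol > config.violation_tol:
        raise SamplerError(
            f"inconsistent constraint set: input structure violates its own "
            f"bounds by {viol:.3f} A"
        )
    masses = structure.masses
    quads = chirality_quadruples(structure)
    ref_sign = mean_signed_volume(structure.coords, quads)
    frames: list[np.ndarray] = []
    prov: list[FrameInfo] = []
    n_failed = 0
    for k in range(config.n_conformers):
        res = rebuild_conformation(
            cs, rg, masses, config.seed + k, config,
            reference_coords=structure.coords,
            chirality_ref=(quads, ref_sign),
        )
        if res.converged:
            frames.append(res.coords)
            prov.append(FrameInfo(seed=config.seed + k, sweeps=res.sweeps_used,
                                  rg=res.final_rg))
        else:
            n_failed += 1
            log.debug("seed %d failed to converge (max violation %.3f A)",
                      config.seed + k, res.max_violation)
    if n_failed == config.n_conformers:
        raise SamplerError(
            "no conformation converged; consider loosening constraint "
            "tolerances or the Rg tolerance"
        )
    if n_failed > config.n_conformers / 2:
        warnings.warn(
            f"{n_failed}/{config.n_conformers} rebuilds failed to converge",
            RuntimeWarning, stacklevel=2,
        )
    return Ensemble(structure, frames, prov)


# ---------------------------------------------------------------------------
# sidechain resampling


def predict_flexible_sidechains(structure: Structure,
                                config: ConstraintConfig | None = None,
                                packing_radius: float = 5.0,
                                max_neighbors: float = 14.0
                                ) -> set[tuple[str, int, str]]:
    """Residues whose side chains are predicted mobile.

    A side chain counts as flexible when it (a) has rotatable atoms beyond
    CB, (b) takes part in no stable hydrogen bond, (c) belongs to no
    hydrophobic cluster and (d) is loosely packed: fewer than
    ``max_neighbors`` non-self heavy atoms within ``packing_radius`` of a
    side-chain atom on average.
    """
    cfg = config or ConstraintConfig()
    from scipy.spatial import cKDTree

    hbond_atoms: set[int] = set()
    for hb in detect_hbonds(structure, cfg):
        if hb.stable:
            hbond_atoms.add(hb.donor)
            hbond_atoms.add(hb.acceptor)
    cluster_atoms: set[int] = set()
    for cl in detect_hydrophobic_clusters(structure, cfg):
        cluster_atoms |= cl

    tree = cKDTree(structure.coords)
    out: set[tuple[str, int, str]] = set()
    for rid, rname, idxs in structure.residues():
        side = [i for i in idxs
                if structure.atoms[i].name not in _BACKBONE
                and structure.atoms[i].name != "CB"]
        if not side:  # GLY/ALA: nothing to rotate
            continue
        side_all = [i for i in idxs if structure.atoms[i].name not in _BACKBONE]
        if any(i in hbond_atoms for i in side_all):
            continue
        if any(i in cluster_atoms for i in side_all):
            continue
        counts = []
        own = set(idxs)
        for i in side_all:
            near = tree.query_ball_point(structure.coords[i], packing_radius)
            counts.append(len([k for k in near if k not in own]))
        if np.mean(counts) < max_neighbors:
            out.add(rid)
    return out


def _widen_sidechain_pair14(cs: ConstraintSet, structure: Structure,
                            free_atoms: set[int]) -> ConstraintSet:
    """Open the torsional windows of 1-4 pairs that involve a free
    side-chain atom, granting rotamer freedom while angles and bonds stay."""
    lo = cs.lower.copy()
    up = cs.upper.copy()
    code = KIND_CODES["pair14"]
    for k in range(len(cs)):
        if cs.kind[k] != code:
            continue
        i, j = int(cs.i[k]), int(cs.j[k])
        if i in free_atoms or j in free_atoms:
            lo[k] = max(2.4, lo[k] * 0.65)   # gauche reach
            up[k] = up[k] * 1.50             # anti reach
            if lo[k] > up[k]:
                lo[k] = up[k] * 0.65
    return ConstraintSet(cs.i, cs.j, lo, up, cs.kind, cs.n_atoms, cs.source_rg)


def resample_sidechains(structure: Structure, n: int, seed: int,
                        config: SamplerConfig | None = None,
                        flexible: Sequence[tuple[str, int, str]] | None = None
                        ) -> Ensemble:
    """Fixed-backbone rotamer resampling.

    Flexible side chains are perturbed and rebuilt by the constraint
    relaxation loop with every other atom pinned; backbone coordinates of
    the output frames equal the input exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = config or SamplerConfig()
    if flexible is None:
        flexible = predict_flexible_sidechains(structure, cfg.constraints)
    flexible = set(flexible)

    free_atoms: set[int] = set()
    for rid, rname, idxs in structure.residues():
        if rid in flexible:
            for i in idxs:
                if structure.atoms[i].name not in _BACKBONE:
                    free_atoms.add(i)

    frames: list[np.ndarray] = []
    prov: list[FrameInfo] = []
    masses = structure.masses
    if not free_atoms:
        for k in range(n):
            frames.append(structure.coords.copy())
            prov.append(FrameInfo(seed=seed + k, sweeps=0,
                                  rg=radius_of_gyration(structure.coords,
                                                        masses).value))
        return Ensemble(structure, frames, prov)

    cs = build_constraints(structure, cfg.constraints)
    cs = _widen_sidechain_pair14(cs, structure, free_atoms)
    w = np.zeros(structure.n_atoms)
    w[list(free_atoms)] = 1.0
    for k in range(n):
        res = rebuild_conformation(
            cs, None, masses, seed + k, cfg,
            reference_coords=structure.coords, weights=w,
        )
        coords = res.coords if res.converged else structure.coords.copy()
        frames.append(coords)
        prov.append(FrameInfo(seed=seed + k, sweeps=res.sweeps_used,
                              rg=radius_of_gyration(coords, masses).value))
    return Ensemble(structure, frames, prov)
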