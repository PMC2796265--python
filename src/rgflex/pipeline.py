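"""End-to-end modelling protocol.

Stages: Rg-biased ensemble generation from the apo structure -> RMSD
clustering to a pool of distinct conformations -> (optional external
score/refine hook) -> top-model selection by Rg compliance -> fixed-backbone
sidechain resampling -> (optional external docking/refinement hooks) -> Rg
filter -> final Rg-compliance ranking.  External engines (minimization,
docking, MD, statistical scoring) are not reimplemented; they plug in as
command templates exchanging multi-model PDB files, and the pipeline runs
end-to-end without them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import subprocess
import time
from pathlib import Path

import numpy as np
import yaml

from .structures import (
    Structure,
    Ensemble,
    read_structure,
    read_ensemble,
    write_ensemble,
    write_structure,
)
from .sampler import (
    SamplerConfig,
    RgConstraint,
    generate_ensemble,
    resample_sidechains,
)
from .ensemble_ops import cluster_to_size, rank_by_rg, filter_by_rg

__all__ = ["ProtocolConfig", "StageRecord", "PipelineError", "run_protocol"]


class PipelineError(RuntimeError):
    pass


@dataclasses.dataclass
class ProtocolConfig:
    """Protocol parameters (defaults: 1000-member initial ensemble, 50 top
    models x 100 sidechain variants each, 1% Rg filter, 0.1 A Rg
    tolerance, two refinement cycles)."""

    input_pdb: str | Path = ""
    rg_target: float = 0.0
    rg_tolerance: float = 0.1
    n_initial: int = 1000
    n_cluster: int = 200
    n_top_models: int = 50
    n_sidechain: int = 100
    rg_filter_rel: float = 0.01
    min_keep: int = 1
    n_cycles: int = 2
    n_refine_models: int = 10
    seed: int = 0
    external_hooks: dict = dataclasses.field(default_factory=dict)
    sampler: SamplerConfig = dataclasses.field(default_factory=SamplerConfig)

    def __post_init__(self) -> None:
        for field in ("n_initial", "n_cluster", "n_top_models", "n_sidechain"):
            if getattr(self, field) < 1:
                raise ValueError(f"{field} must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ProtocolConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        sampler = SamplerConfig(**data.pop("sampler", {}))
        return cls(sampler=sampler, **data)


@dataclasses.dataclass
class StageRecord:
    stage: str
    n_in: int
    n_out: int
    seed: int
    output: str
    sha256: str
    wall_time_s: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _run_hook(command_template: str, pdb_in: Path, pdb_out: Path) -> None:
    cmd = command_template.format(input=pdb_in, output=pdb_out)
    proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
    if proc.returncode != 0 or not pdb_out.exists():
        raise PipelineError(f"external hook failed: {cmd}\n{proc.stderr}")


def run_protocol(config: ProtocolConfig, out_dir: str | Path = "run",
                 structure: Structure | None = None) -> Path:
    """Execute the staged protocol; returns the run directory.

    Every stage writes a multi-model PDB and a stage record; the run is
    byte-for-byte reproducible for a fixed seed when no external hooks are
    configured.  A stage leaving zero survivors aborts with its name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records: list[StageRecord] = []

    def record(stage: str, n_in: int, ens: Ensemble, path: Path,
               t0: float, seed: int) -> None:
        if ens.n_frames == 0:
            raise PipelineError(
                f"stage {stage!r} left zero survivors; widen the Rg window "
                f"or loosen constraint tolerances"
            )
        write_ensemble(ens, path)
        records.append(StageRecord(stage, n_in, ens.n_frames, seed,
                                   path.name, _digest(path),
                                   round(time.perf_counter() - t0, 3)))

    if structure is None:
        p = Path(config.input_pdb)
        if not p.exists():
            raise FileNotFoundError(f"input structure not found: {p}")
        structure = read_structure(p)
    write_structure(structure, out / "input.pdb")
    rg = RgConstraint(config.rg_target, config.rg_tolerance)

    # 1. biased sampling
    t0 = time.perf_counter()
    scfg = dataclasses.replace(config.sampler, n_conformers=config.n_initial,
                               seed=config.seed)
    ens = generate_ensemble(structure, scfg, rg)
    record("biased_sampling", 1, ens, out / "stage1_sampling.pdb", t0,
           config.seed)

    # 2. RMSD clustering to a pool of distinct conformations
    t0 = time.perf_counter()
    n_in = ens.n_frames
    clust = cluster_to_size(ens, min(config.n_cluster, ens.n_frames))
    ens = ens.subset(clust.representatives)
    record("rmsd_clustering", n_in, ens, out / "stage2_clustered.pdb", t0,
           config.seed)

    # 3. optional external score/refine hook on the clustered pool
    hook = config.external_hooks.get("refine")
    if hook:
        t0 = time.perf_counter()
        n_in = ens.n_frames
        hook_out = out / "stage3_refined.pdb"
        _run_hook(hook, out / "stage2_clustered.pdb", hook_out)
        ens = read_ensemble(hook_out)
        record("external_refine", n_in, ens, hook_out, t0, config.seed)
    else:
        records.append(StageRecord("external_refine(skipped)", ens.n_frames,
                                   ens.n_frames, config.seed, "", "", 0.0))

    # 4. top-model selection by Rg compliance
    t0 = time.perf_counter()
    n_in = ens.n_frames
    ranking = rank_by_rg(ens, config.rg_target)
    ens = ens.subset(ranking.top(min(config.n_top_models, ens.n_frames)))
    record("top_model_selection", n_in, ens, out / "stage4_top_models.pdb",
           t0, config.seed)

    def resample_stage(pool: Ensemble, tag: str, seed0: int) -> Ensemble:
        t0 = time.perf_counter()
        n_in = pool.n_frames
        frames, prov = [], []
        for k in range(pool.n_frames):
            sub = resample_sidechains(pool.structure(k), config.n_sidechain,
                                      seed=seed0 + 100_000 * (k + 1),
                                      config=config.sampler)
            frames.extend(sub.frames)
            prov.extend(sub.provenance)
        pool = Ensemble(pool.topology, frames, prov)
        record(f"sidechain_resampling{tag}", n_in, pool,
               out / f"stage5{tag}_resampled.pdb", t0, seed0)
        return pool

    def filter_rank_stage(pool: Ensemble, tag: str) -> Ensemble:
        t0 = time.perf_counter()
        n_in = pool.n_frames
        kept = filter_by_rg(pool, config.rg_target, config.rg_filter_rel,
                            config.min_keep)
        pool = pool.subset(kept)
        record(f"rg_filter{tag}", n_in, pool,
               out / f"stage7{tag}_filtered.pdb", t0, config.seed)
        t0 = time.perf_counter()
        n_in = pool.n_frames
        ranking = rank_by_rg(pool, config.rg_target)
        pool = pool.subset(ranking.order)
        record(f"rg_ranking{tag}", n_in, pool,
               out / f"stage8{tag}_ranked.pdb", t0, config.seed)
        return pool

    # 5. sidechain resampling: n_sidechain variants per top model
    ens = resample_stage(ens, "", config.seed)

    # 6. optional external docking/MD hook
    hook = config.external_hooks.get("dock")
    if hook:
        t0 = time.perf_counter()
        n_in = ens.n_frames
        hook_out = out / "stage6_docked.pdb"
        _run_hook(hook, out / "stage5_resampled.pdb", hook_out)
        ens = read_ensemble(hook_out)
        record("external_dock", n_in, ens, hook_out, t0, config.seed)
    else:
        records.append(StageRecord("external_dock(skipped)", ens.n_frames,
                                   ens.n_frames, config.seed, "", "", 0.0))

    # 7/8. Rg filter with widening fallback, then final ranking
    ens = filter_rank_stage(ens, "")

    # further refinement cycles: the best models are resampled and
    # re-filtered (external docking/MD slots in between when configured)
    for cycle in range(2, config.n_cycles + 1):
        tag = f"_cycle{cycle}"
        pool = ens.subset(list(range(min(config.n_refine_models,
                                         ens.n_frames))))
        pool = resample_stage(pool, tag, config.seed + 10_000_000 * cycle)
        ens = filter_rank_stage(pool, tag)

    write_ensemble(ens, out / "final_ranked.pdb")
    records.append(StageRecord("final", ens.n_frames, ens.n_frames,
                               config.seed, "final_ranked.pdb",
                               _digest(out / "final_ranked.pdb"), 0.0))

    manifest = {
        "config": {
            "input_pdb": str(config.input_pdb),
            "rg_target": config.rg_target,
            "rg_tolerance": config.rg_tolerance,
            "n_initial": config.n_initial,
            "n_cluster": config.n_cluster,
            "n_top_models": config.n_top_models,
            "n_sidechain": config.n_sidechain,
            "rg_filter_rel": config.rg_filter_rel,
            "n_cycles": config.n_cycles,
            "seed": config.seed,
        },
        "stages": [r.to_dict() for r in records],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out
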