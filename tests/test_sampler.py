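import numpy as np
import pytest

import rgflex
from rgflex.constraints import ConstraintSet
from rgflex.sampler import (
    RgConstraint,
    SamplerConfig,
    SamplerError,
    rebuild_conformation,
    chirality_quadruples,
    mean_signed_volume,
)


def tiny_config(**kw):
    return SamplerConfig(n_conformers=kw.pop("n_conformers", 1), **kw)


class TestRebuildConformation:
    def test_single_bond_system(self):
        cs = ConstraintSet(np.array([0]), np.array([1]), np.array([1.4925]),
                           np.array([1.5075]), np.array([0], dtype=np.int8),
                           n_atoms=2, source_rg=0.75)
        res = rebuild_conformation(cs, None, np.array([12.0, 12.0]), seed=3,
                                   config=tiny_config())
        assert res.converged
        d = np.linalg.norm(res.coords[1] - res.coords[0])
        assert 1.4925 - 1e-3 <= d <= 1.5075 + 1e-3

    def test_equilateral_triangle_with_rg_target(self):
        # three equal masses on a 2 A equilateral triangle: Rg = 2/sqrt(3)
        side = 2.0
        i = np.array([0, 0, 1])
        j = np.array([1, 2, 2])
        lo = np.full(3, side * 0.995)
        up = np.full(3, side * 1.005)
        cs = ConstraintSet(i, j, lo, up, np.zeros(3, dtype=np.int8),
                           n_atoms=3, source_rg=side / np.sqrt(3))
        rg = RgConstraint(side / np.sqrt(3), 0.1)
        res = rebuild_conformation(cs, rg, np.ones(3), seed=5,
                                   config=tiny_config())
        assert res.converged
        assert res.max_violation <= 1e-3
        assert abs(res.final_rg - side / np.sqrt(3)) <= 0.1

    def test_seeded_determinism_bitwise(self, hinge, hinge_constraints):
        cfg = tiny_config()
        a = rebuild_conformation(hinge_constraints, None, hinge.open.masses,
                                 seed=9, config=cfg,
                                 reference_coords=hinge.open.coords)
        b = rebuild_conformation(hinge_constraints, None, hinge.open.masses,
                                 seed=9, config=cfg,
                                 reference_coords=hinge.open.coords)
        assert a.converged and b.converged
        assert np.array_equal(a.coords, b.coords)

    def test_different_seeds_differ(self, hinge, hinge_constraints):
        cfg = tiny_config()
        a = rebuild_conformation(hinge_constraints, None, hinge.open.masses,
                                 seed=1, config=cfg,
                                 reference_coords=hinge.open.coords)
        b = rebuild_conformation(hinge_constraints, None, hinge.open.masses,
                                 seed=2, config=cfg,
                                 reference_coords=hinge.open.coords)
        assert not np.array_equal(a.coords, b.coords)


class TestGenerateEnsemble:
    def test_inconsistent_constraints_rejected(self, hinge, hinge_constraints):
        bad = ConstraintSet(hinge_constraints.i, hinge_constraints.j,
                            hinge_constraints.lower * 1.2,
                            hinge_constraints.upper * 1.2,
                            hinge_constraints.kind,
                            hinge_constraints.n_atoms,
                            hinge_constraints.source_rg)
        with pytest.raises(SamplerError, match="inconsistent"):
            rgflex.generate_ensemble(hinge.open, tiny_config(), cs=bad)

    def test_single_conformer_cap(self, hinge):
        ens = rgflex.generate_ensemble(hinge.open, tiny_config(seed=3))
        assert ens.n_frames <= 1

    def test_biased_frames_hit_rg_window(self, hinge, biased_ensemble):
        target = hinge.rg_closed
        for info in biased_ensemble.provenance:
            assert abs(info.rg - target) <= 0.1

    def test_all_frames_satisfy_constraints(self, hinge, hinge_constraints,
                                            biased_ensemble):
        for frame in biased_ensemble.frames:
            assert hinge_constraints.max_violation(frame) <= 1e-3 + 1e-9

    def test_reproducible_byte_for_byte(self, hinge, biased_ensemble):
        cfg = SamplerConfig(n_conformers=30, seed=42)
        again = rgflex.generate_ensemble(
            hinge.open, cfg, RgConstraint(hinge.rg_closed, 0.1))
        assert again.n_frames == biased_ensemble.n_frames
        for a, b in zip(again.frames, biased_ensemble.frames):
            assert a.tobytes() == b.tobytes()

    def test_unbiased_rg_spread_spans_open_state(self, hinge,
                                                 unbiased_ensemble):
        rgs = np.array([p.rg for p in unbiased_ensemble.provenance])
        assert rgs.min() < hinge.rg_open < rgs.max()

    def test_bias_pulls_mean_rg_deviation_down(self, hinge, biased_ensemble,
                                               unbiased_ensemble):
        target = hinge.rg_closed
        dev_b = np.mean([abs(p.rg - target)
                         for p in biased_ensemble.provenance])
        dev_u = np.mean([abs(p.rg - target)
                         for p in unbiased_ensemble.provenance])
        assert dev_b < dev_u

    def test_no_chirality_inversion(self, hinge, biased_ensemble,
                                    unbiased_ensemble):
        quads = chirality_quadruples(hinge.open)
        ref = mean_signed_volume(hinge.open.coords, quads)
        for ens in (biased_ensemble, unbiased_ensemble):
            for frame in ens.frames:
                assert mean_signed_volume(frame, quads) * ref > 0


class TestFlexibleSidechains:
    def test_exposed_lysine_is_flexible(self):
        pep = rgflex.make_toy_peptide("AAKAA", "helix")
        flex = rgflex.predict_flexible_sidechains(pep)
        assert ("A", 3, "") in flex

    def test_core_leucine_is_not_flexible(self, hinge):
        flex = rgflex.predict_flexible_sidechains(hinge.open)
        clustered = set()
        from rgflex.constraints import detect_hydrophobic_clusters
        for cl in detect_hydrophobic_clusters(hinge.open):
            clustered |= {hinge.open.atoms[i].residue_id for i in cl}
        assert not (flex & clustered)

    def test_gly_ala_never_flexible(self):
        pep = rgflex.make_toy_peptide("GAGAG", "extended")
        assert rgflex.predict_flexible_sidechains(pep) == set()


class TestResampleSidechains:
    def test_backbone_pinned_exactly(self, hinge):
        ens = rgflex.resample_sidechains(hinge.open, 5, seed=1)
        assert ens.n_frames == 5
        bb = rgflex.select_atoms(hinge.open, "backbone")
        for frame in ens.frames:
            assert np.array_equal(frame[bb], hinge.open.coords[bb])

    def test_no_flexible_residues_returns_input(self):
        pep = rgflex.make_toy_peptide("GAGAG", "extended")
        ens = rgflex.resample_sidechains(pep, 3, seed=0)
        for frame in ens.frames:
            assert np.array_equal(frame, pep.coords)

    def test_rotamer_diversity(self, hinge):
        ens = rgflex.resample_sidechains(hinge.open, 20, seed=4)
        assert len({f.tobytes() for f in ens.frames}) >= 2

    def test_invalid_count_rejected(self, hinge):
        with pytest.raises(ValueError):
            rgflex.resample_sidechains(hinge.open, 0, seed=0)
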