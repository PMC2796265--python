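import numpy as np
import pytest

import rgflex
from rgflex.ensemble_ops import (
    cluster_by_rmsd,
    cluster_to_size,
    rank_by_rg,
    rank_by_score,
    filter_by_rg,
    assess_against_reference,
)
from rgflex.geometry import rmsd, radius_of_gyration


def ensemble_with_rgs(topology, rgs):
    """Frames that are uniformly scaled copies of a structure, hitting the
    requested radii of gyration exactly."""
    masses = topology.masses
    base_rg = radius_of_gyration(topology.coords, masses).value
    com = (masses[:, None] * topology.coords).sum(0) / masses.sum()
    frames = [com + (topology.coords - com) * (r / base_rg) for r in rgs]
    return rgflex.Ensemble(topology, frames)


class TestClusterByRmsd:
    def test_identical_frames_one_cluster(self, hinge):
        ens = rgflex.Ensemble(hinge.open, [hinge.open.coords] * 6)
        res = cluster_by_rmsd(ens, cutoff=0.5)
        assert res.n_clusters == 1
        assert set(res.assignment.values()) == {0}

    def test_tiny_cutoff_every_frame_its_own_cluster(self, random_ensemble):
        res = cluster_by_rmsd(random_ensemble, cutoff=1e-6)
        assert res.n_clusters == random_ensemble.n_frames

    def test_matches_brute_force_leader_oracle(self, random_ensemble):
        sel = rgflex.select_atoms(random_ensemble.topology, "backbone")
        sub = random_ensemble.subset(list(range(20)))
        cutoff = 1.0
        res = cluster_by_rmsd(sub, cutoff, sel)
        # brute force from the full pairwise matrix
        mat = np.zeros((20, 20))
        for a in range(20):
            for b in range(20):
                mat[a, b] = rmsd(sub.frames[a][sel], sub.frames[b][sel])
        reps, assign = [], {}
        for f in range(20):
            for c, rep in enumerate(reps):
                if mat[f, rep] <= cutoff:
                    assign[f] = c
                    break
            else:
                assign[f] = len(reps)
                reps.append(f)
        assert res.representatives == reps
        assert res.assignment == assign

    def test_representative_count_non_increasing_in_cutoff(self,
                                                           random_ensemble):
        counts = [cluster_by_rmsd(random_ensemble, c).n_clusters
                  for c in (0.2, 0.6, 1.5, 4.0)]
        assert counts == sorted(counts, reverse=True)

    def test_invalid_cutoff(self, random_ensemble):
        with pytest.raises(ValueError):
            cluster_by_rmsd(random_ensemble, 0.0)

    def test_cluster_to_size_hits_window(self, random_ensemble):
        res = cluster_to_size(random_ensemble, 10)
        assert 8 <= res.n_clusters <= 12


class TestRankByRg:
    def test_three_frame_order(self, hinge):
        ens = ensemble_with_rgs(hinge.open, [10.3, 10.05, 11.0])
        rep = rank_by_rg(ens, target=10.0)
        assert rep.order == [1, 0, 2]

    def test_single_frame(self, hinge):
        ens = ensemble_with_rgs(hinge.open, [9.0])
        assert rank_by_rg(ens, 8.0).order == [0]

    def test_matches_independent_sort(self, random_ensemble):
        rep = rank_by_rg(random_ensemble, target=9.0)
        masses = random_ensemble.topology.masses
        devs = [abs(radius_of_gyration(f, masses).value - 9.0)
                for f in random_ensemble.frames]
        expected = sorted(range(len(devs)), key=lambda k: (devs[k], k))
        assert rep.order == expected

    def test_order_stable_under_permutation(self, hinge):
        rgs = [9.1, 8.7, 10.2, 9.6, 8.9]
        ens = ensemble_with_rgs(hinge.open, rgs)
        rep = rank_by_rg(ens, 9.0)
        perm = [3, 0, 4, 1, 2]
        ens2 = ens.subset(perm)
        rep2 = rank_by_rg(ens2, 9.0)
        # ranked Rg sequences agree regardless of frame order
        got = [rep.table.loc[i, "rg"] for i in rep.order]
        got2 = [rep2.table.loc[i, "rg"] for i in rep2.order]
        assert np.allclose(got, got2)

    def test_rank_by_score_hook(self, hinge):
        ens = ensemble_with_rgs(hinge.open, [9.0, 9.5, 8.5])
        rep = rank_by_score(ens, {0: 5.0, 1: -2.0, 2: 1.0})
        assert rep.order == [1, 2, 0]


class TestFilterByRg:
    def test_one_percent_window(self, hinge):
        ens = ensemble_with_rgs(hinge.open, [10.0, 10.05, 11.0])
        kept = filter_by_rg(ens, target=10.0, rel_cutoff=0.01)
        assert kept == [0, 1]

    def test_widening_fallback_logged_and_nonempty(self, hinge, caplog):
        ens = ensemble_with_rgs(hinge.open, [12.0, 13.0])
        import logging
        with caplog.at_level(logging.INFO, logger="rgflex.ensemble_ops"):
            kept = filter_by_rg(ens, target=10.0, rel_cutoff=0.01, min_keep=1)
        assert kept  # widened until something survives
        assert any("widened" in r.message for r in caplog.records)

    def test_matches_threshold_scan_oracle(self, random_ensemble):
        target = 9.0
        kept = filter_by_rg(random_ensemble, target, rel_cutoff=0.03,
                            min_keep=0)
        masses = random_ensemble.topology.masses
        expected = [i for i, f in enumerate(random_ensemble.frames)
                    if abs(radius_of_gyration(f, masses).value - target)
                    / target < 0.03]
        assert kept == expected

    def test_infinite_cutoff_keeps_all_zero_keeps_exact(self, hinge):
        ens = ensemble_with_rgs(hinge.open, [9.0, 9.5])
        assert filter_by_rg(ens, 9.0, rel_cutoff=np.inf) == [0, 1]
        assert filter_by_rg(ens, 9.25, rel_cutoff=1e-12, min_keep=0) == []


class TestAssessAgainstReference:
    def test_reference_frame_ranks_first(self, hinge, random_ensemble):
        frames = list(random_ensemble.frames) + [hinge.closed.coords]
        ens = rgflex.Ensemble(hinge.open, frames)
        rep = assess_against_reference(ens, hinge.closed)
        last = len(frames) - 1
        assert rep.table.loc[last, "rmsd_bb"] == pytest.approx(0.0, abs=1e-9)
        assert rep.order[0] == last
        assert rep.rank_of_first_under("rmsd_bb", 1.5) == 1

    def test_threshold_below_all_reports_none(self, hinge, random_ensemble):
        rep = assess_against_reference(random_ensemble, hinge.closed)
        assert rep.rank_of_first_under("rmsd_bb", 1e-9) is None

    def test_matches_direct_geometry_calls(self, hinge, random_ensemble):
        site = rgflex.binding_site(hinge.closed, hinge.ligand, 6.0)
        rep = assess_against_reference(random_ensemble, hinge.closed, site)
        bb = rgflex.select_atoms(hinge.open, "backbone")
        for f in (0, 17, 42):
            direct = rmsd(random_ensemble.frames[f][bb],
                          hinge.closed.coords[bb])
            assert rep.table.loc[f, "rmsd_bb"] == pytest.approx(direct,
                                                                abs=1e-9)
        assert {"rmsd_site_bb", "rmsd_site_all"} <= set(rep.table.columns)
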