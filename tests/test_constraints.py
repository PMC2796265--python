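import numpy as np
import pytest

import rgflex
from rgflex.constraints import (
    ConstraintConfig,
    ConstraintError,
    ConstraintSet,
    build_constraints,
    derive_topology,
    detect_hbonds,
    detect_hydrophobic_clusters,
    KIND_NAMES,
)


def three_atom_chain():
    """A GLY backbone fragment N-CA-C: a 3-atom covalent chain A-B-C."""
    atoms = [
        rgflex.Atom(1, "N", "N", 14.007, "GLY", ("A", 1, "")),
        rgflex.Atom(2, "CA", "C", 12.011, "GLY", ("A", 1, "")),
        rgflex.Atom(3, "C", "C", 12.011, "GLY", ("A", 1, "")),
    ]
    coords = np.array([[0.0, 0, 0], [1.46, 0, 0], [1.98, 1.43, 0]])
    return rgflex.Structure(atoms, coords)


def adjacency_oracle(structure):
    """Hand-rolled covalent graph from the residue templates (test-local)."""
    from rgflex.constraints import RESIDUE_BONDS

    bonds = set()
    residues = structure.residues()
    index = {}
    for rid, rname, idxs in residues:
        for k in idxs:
            index[(rid, structure.atoms[k].name)] = k
    for rid, rname, idxs in residues:
        for a, b in RESIDUE_BONDS[rname]:
            if (rid, a) in index and (rid, b) in index:
                bonds.add(frozenset((index[(rid, a)], index[(rid, b)])))
    for (r1, n1, _), (r2, n2, _) in zip(residues, residues[1:]):
        if (r1, "C") in index and (r2, "N") in index:
            bonds.add(frozenset((index[(r1, "C")], index[(r2, "N")])))
    return bonds


class TestDeriveTopology:
    def test_three_atom_chain_counts(self):
        cons = derive_topology(three_atom_chain())
        kinds = [c.kind for c in cons]
        assert kinds.count("bond") == 2
        assert kinds.count("angle13") == 1
        assert kinds.count("pair14") == 0

    def test_dipeptide_matches_template_graph_oracle(self):
        pep = rgflex.make_toy_peptide("AA", "extended")
        cons = derive_topology(pep)
        got_bonds = {frozenset((c.i, c.j)) for c in cons if c.kind == "bond"}
        assert got_bonds == adjacency_oracle(pep)
        # independent 1-3 enumeration from that graph
        adj = {}
        for b in got_bonds:
            i, j = tuple(b)
            adj.setdefault(i, set()).add(j)
            adj.setdefault(j, set()).add(i)
        expect13 = set()
        for centre, nbrs in adj.items():
            ns = sorted(nbrs)
            for x in range(len(ns)):
                for y in range(x + 1, len(ns)):
                    key = frozenset((ns[x], ns[y]))
                    if key not in got_bonds:
                        expect13.add(key)
        got13 = {frozenset((c.i, c.j)) for c in cons if c.kind == "angle13"}
        assert got13 == expect13

    def test_glycine_has_no_cb_constraints(self):
        pep = rgflex.make_toy_peptide("G", "extended")
        assert all(a.name != "CB" for a in pep.atoms)
        cons = derive_topology(pep)
        assert cons  # N-CA, CA-C, C-O at least

    def test_measured_distances_inside_bounds(self, hinge):
        cons = derive_topology(hinge.open)
        coords = hinge.open.coords
        for c in cons:
            d = np.linalg.norm(coords[c.i] - coords[c.j])
            assert c.lower <= d <= c.upper

    def test_unknown_residue_rejected(self):
        atoms = [rgflex.Atom(1, "X1", "C", 12.011, "XXX", ("A", 1, ""))]
        st = rgflex.Structure(atoms, np.zeros((1, 3)))
        with pytest.raises(ConstraintError, match="XXX"):
            derive_topology(st)


class TestDetectHbonds:
    def test_helix_plants_i_to_i4_backbone_hbonds(self, helix):
        hb = detect_hbonds(helix)
        pairs = {(helix.atoms[h.donor].residue_id[1],
                  helix.atoms[h.acceptor].residue_id[1]) for h in hb}
        # i -> i+4: donor N of residue i+4, acceptor O of residue i
        planted = {(i + 4, i) for i in range(1, 7)}
        assert planted <= pairs
        assert len(hb) >= 5

    def test_extended_strand_has_none(self):
        ext = rgflex.make_toy_peptide("AAAAA", "extended")
        assert detect_hbonds(ext) == []

    def test_distance_cutoff_respected(self, helix):
        for h in detect_hbonds(helix):
            assert h.distance <= ConstraintConfig().hbond_max_dist
            assert h.angle >= ConstraintConfig().hbond_min_angle


class TestHydrophobicClusters:
    def test_two_packed_leucines_form_one_cluster(self):
        # adjacent LEU side chains in a helix pack within the edge cutoff
        pep = rgflex.make_toy_peptide("LLLL", "helix")
        clusters = detect_hydrophobic_clusters(pep)
        assert len(clusters) >= 1
        residues = {pep.atoms[i].residue_id[1] for i in clusters[0]}
        assert len(residues) >= 2

    def test_single_side_chain_is_not_a_cluster(self):
        # one LEU flanked by serines in an extended strand: its 4 apolar
        # side-chain atoms are mutually close but span a single residue
        pep = rgflex.make_toy_peptide("SLS", "extended")
        assert detect_hydrophobic_clusters(pep) == []

    def test_matches_union_find_oracle(self, hinge):
        from rgflex.constraints import HYDROPHOBIC_RESIDUES, _BACKBONE_SET

        st = hinge.open
        cfg = ConstraintConfig()
        nodes = [i for i, a in enumerate(st.atoms)
                 if a.residue_name in HYDROPHOBIC_RESIDUES
                 and a.element in ("C", "S") and a.name not in _BACKBONE_SET]
        # brute-force O(N^2) connected components
        import networkx as nx
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for x in range(len(nodes)):
            for y in range(x + 1, len(nodes)):
                d = np.linalg.norm(st.coords[nodes[x]] - st.coords[nodes[y]])
                if d <= cfg.cluster_edge_cutoff:
                    g.add_edge(nodes[x], nodes[y])
        expected = []
        for comp in nx.connected_components(g):
            if len(comp) < cfg.min_cluster_atoms:
                continue
            if len({st.atoms[i].residue_id for i in comp}) < 2:
                continue
            expected.append(frozenset(comp))
        got = {frozenset(c) for c in detect_hydrophobic_clusters(st)}
        assert got == set(expected)


class TestBuildConstraints:
    def test_input_satisfies_every_constraint(self, hinge, hinge_constraints):
        assert hinge_constraints.satisfaction_rate(hinge.open.coords) == 1.0
        assert hinge_constraints.max_violation(hinge.open.coords) == \
            pytest.approx(0.0, abs=1e-12)

    def test_deterministic(self, hinge, hinge_constraints):
        again = build_constraints(hinge.open)
        assert np.array_equal(again.i, hinge_constraints.i)
        assert np.array_equal(again.lower, hinge_constraints.lower)
        assert np.array_equal(again.kind, hinge_constraints.kind)

    def test_excluded_volume_covers_exactly_the_free_pairs(self):
        st = three_atom_chain()
        cs = build_constraints(st)
        pairs = {(c.i, c.j): c.kind for c in cs}
        # N-CA, CA-C bonded; N-C is the single 1-3 pair; nothing is free
        assert pairs[(0, 1)] == "bond"
        assert pairs[(1, 2)] == "bond"
        assert pairs[(0, 2)] == "angle13"
        assert len(cs) == 3

    def test_structure_without_stable_hbonds_has_no_hbond_kind(self):
        ext = rgflex.make_toy_peptide("AAA", "extended")
        cs = build_constraints(ext)
        assert len(cs.by_kind("hbond")) == 0

    def test_tightness_ordering_of_mean_relative_widths(self, hinge_constraints):
        widths = {}
        for kind in ("bond", "angle13", "pair14", "hbond", "hydrophobic"):
            sub = hinge_constraints.by_kind(kind)
            if len(sub) == 0:
                continue
            mid = (sub.lower + sub.upper) / 2
            widths[kind] = float(np.mean((sub.upper - sub.lower) / mid))
        order = [widths[k] for k in ("bond", "angle13", "pair14", "hbond",
                                     "hydrophobic") if k in widths]
        assert order == sorted(order)

    def test_tsv_round_trip(self, hinge_constraints, tmp_path):
        p = hinge_constraints.to_tsv(tmp_path / "cs.tsv")
        back = ConstraintSet.from_tsv(p)
        assert len(back) == len(hinge_constraints)
        assert np.array_equal(back.i, hinge_constraints.i)
        assert np.array_equal(back.kind, hinge_constraints.kind)
        assert np.allclose(back.lower, hinge_constraints.lower, atol=1e-6)
        up_f = np.isfinite(hinge_constraints.upper)
        assert np.array_equal(np.isfinite(back.upper), up_f)
        assert np.allclose(back.upper[up_f], hinge_constraints.upper[up_f],
                           atol=1e-6)

    def test_strictest_kind_wins_per_pair(self, hinge_constraints):
        seen = {}
        for c in hinge_constraints:
            key = (min(c.i, c.j), max(c.i, c.j))
            assert key not in seen, "duplicate pair in constraint set"
            seen[key] = c.kind
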