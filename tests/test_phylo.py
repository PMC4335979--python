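import numpy as np
import pytest

from oracles import path_distance_matrix, random_binary_tree
from jenscape.io_formats import read_newick
from jenscape.phylo import (DistanceMatrix, GammaConfig, SaturationError,
                            bionj, bipartitions, bootstrap_support,
                            correct_distance, neighbor_joining,
                            p_distance_matrix, robinson_foulds,
                            root_with_outgroup, unroot)


class TestPDistance:
    def test_identical_rows(self):
        dm = p_distance_matrix([("a", "MKVL"), ("b", "MKVL")])
        assert dm.d[0, 1] == 0.0

    def test_definition(self):
        dm = p_distance_matrix([("a", "AAAA"), ("b", "AAAT")])
        assert dm.d[0, 1] == 0.25

    def test_pairwise_deletion(self):
        dm = p_distance_matrix([("a", "A-AA"), ("b", "AT-A")])
        # comparable columns: 1 and 4, both identical
        assert dm.d[0, 1] == 0.0

    def test_no_comparable_columns_error(self):
        with pytest.raises(SaturationError, match="a"):
            p_distance_matrix([("a", "A--"), ("b", "-TT")])


class TestCorrection:
    def test_zero_at_zero(self):
        assert correct_distance(0.0, "poisson") == 0.0
        assert correct_distance(0.0, "gamma", GammaConfig(0.5)) == 0.0

    def test_poisson_closed_form(self):
        assert correct_distance(0.1, "poisson") == pytest.approx(-np.log(0.9))

    def test_gamma_converges_to_poisson(self):
        g = correct_distance(0.3, "gamma", GammaConfig(1e6))
        assert g == pytest.approx(correct_distance(0.3, "poisson"), abs=1e-6)

    def test_gamma_exceeds_poisson_and_monotone(self):
        ps = np.linspace(0.01, 0.9, 30)
        for alpha in (0.3, 1.0, 5.0):
            vals = [correct_distance(p, "gamma", GammaConfig(alpha)) for p in ps]
            pois = [correct_distance(p, "poisson") for p in ps]
            assert all(x < y for x, y in zip(vals, vals[1:]))
            assert all(g >= po for g, po in zip(vals, pois))

    def test_saturation(self):
        with pytest.raises(SaturationError):
            correct_distance(0.995, "poisson")
        assert correct_distance(0.995, "poisson", cap=10.0) == 10.0


class TestNeighborJoining:
    def test_three_taxa_three_point_formulas(self):
        D = DistanceMatrix(["a", "b", "c"],
                           np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
        t = neighbor_joining(D)
        lengths = {c.name: c.length for c in t.children}
        assert lengths == {"a": 1.0, "b": 1.0, "c": 3.0}

    def test_two_taxa_single_edge(self):
        D = DistanceMatrix(["a", "b"], np.array([[0, 3.0], [3.0, 0]]))
        t = neighbor_joining(D)
        assert t.total_branch_length() == pytest.approx(3.0)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]], float))

    def test_additive_consistency_and_length(self, rng):
        """NJ recovers topology and total length from additive matrices."""
        for _ in range(40):
            n = int(rng.integers(4, 13))
            true = random_binary_tree([f"x{i}" for i in range(n)], rng)
            labels, d = path_distance_matrix(true)
            t = neighbor_joining(DistanceMatrix(labels, d))
            assert robinson_foulds(t, true) == 0
            assert t.total_branch_length() == pytest.approx(
                true.total_branch_length(), abs=1e-9)


class TestBioNJ:
    def test_three_taxa_matches_nj(self):
        D = DistanceMatrix(["a", "b", "c"],
                           np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
        assert robinson_foulds(bionj(D), neighbor_joining(D)) == 0

    def test_additive_matches_nj_topology(self, rng):
        for _ in range(20):
            true = random_binary_tree([f"x{i}" for i in range(8)], rng)
            labels, d = path_distance_matrix(true)
            D = DistanceMatrix(labels, d)
            assert robinson_foulds(bionj(D), true) == 0

    def test_noisy_noninferiority(self, rng):
        """Under multiplicative distance noise BioNJ recovers the topology
        at least as often as NJ on average."""
        wins = 0
        trials = 100
        for k in range(trials):
            true = random_binary_tree([f"x{i}" for i in range(8)], rng)
            labels, d = path_distance_matrix(true)
            noise = np.triu(rng.uniform(0.98, 1.02, size=d.shape), 1)
            factor = noise + noise.T
            d_noisy = d * np.where(factor == 0, 1.0, factor)
            np.fill_diagonal(d_noisy, 0)
            D = DistanceMatrix(labels, d_noisy)
            rf_nj = robinson_foulds(neighbor_joining(D), true)
            rf_bj = robinson_foulds(bionj(D), true)
            if rf_bj <= rf_nj:
                wins += 1
        assert wins >= trials // 2


class TestRobinsonFoulds:
    def test_identical(self):
        t = read_newick("((a,b),(c,d),e);")
        assert robinson_foulds(t, read_newick("((a,b),(c,d),e);")) == 0

    def test_single_nni_is_two(self):
        t1 = read_newick("(((a,b),c),d,e);")
        t2 = read_newick("(((a,c),b),d,e);")
        assert robinson_foulds(t1, t2) == 2

    def test_star_vs_binary(self):
        star = read_newick("(a,b,c,d,e,f);")
        binary = read_newick("(((a,b),(c,d)),e,f);")
        assert robinson_foulds(star, binary) == 6 - 3

    def test_leaf_mismatch_error(self):
        with pytest.raises(ValueError):
            robinson_foulds(read_newick("(a,b,c);"), read_newick("(a,b,d);"))


class TestRooting:
    def test_four_leaf_outgroup(self):
        t = read_newick("((a:1,b:1):1,c:1,d:4);")
        rooted = root_with_outgroup(t, "d")
        sides = [set(c.leaf_names()) for c in rooted.children]
        assert {"d"} in sides and {"a", "b", "c"} in sides
        assert [c.length for c in rooted.children] == [2.0, 2.0]

    def test_root_then_unroot_is_identity(self, rng):
        for _ in range(10):
            true = random_binary_tree([f"x{i}" for i in range(7)], rng)
            labels, d = path_distance_matrix(true)
            t = neighbor_joining(DistanceMatrix(labels, d))
            rooted = root_with_outgroup(t, "x0")
            assert robinson_foulds(unroot(rooted), t) == 0

    def test_outgroup_splitting_cherry_errors(self):
        t = read_newick("((a,b),(c,d),e);")
        with pytest.raises(ValueError, match="monophyletic"):
            root_with_outgroup(t, {"a", "c"})

    def test_supports_carried(self):
        t = read_newick("((a:1,b:1)80:1,(c:1,d:1)60:1,e:1);")
        rooted = root_with_outgroup(t, "e")
        sup = {frozenset(n.leaf_names()): n.support
               for n in rooted.preorder() if not n.is_leaf() and n is not rooted}
        assert sup[frozenset({"a", "b"})] == 80.0
        assert sup[frozenset({"c", "d"})] == 60.0


class TestBootstrap:
    def _alignment(self, rng, n_taxa=6, n_cols=80):
        from jenscape.synthetic_data import (SimulationConfig,
                                             evolve_sequences,
                                             simulate_gene_family,
                                             simulate_species_tree)
        from jenscape.io_formats import SeqRecord
        cfg = SimulationConfig(seq_length=n_cols, n_decoys_per_species=0,
                               dup_rate=0.0, loss_rate=0.0, seed=9)
        st = simulate_species_tree(n_taxa, seed=9)
        truth = simulate_gene_family(st, cfg, seed=9)
        prot = evolve_sequences(truth.gene_tree, cfg, seed=9)
        rows = [(r.id, r.residues) for recs in prot.values() for r in recs]
        return rows

    def test_uniform_signal_gives_full_support(self):
        rows = [("a", "AAAA"), ("b", "AAAA"), ("c", "CCCC"), ("d", "CCCC")]
        res = bootstrap_support(rows, n_replicates=20, seed=1)
        sups = [n.support for n in res.main_tree.preorder()
                if not n.is_leaf() and n is not res.main_tree]
        assert sups and all(s == 100.0 for s in sups)

    def test_deterministic_under_seed(self, rng):
        rows = self._alignment(rng)
        r1 = bootstrap_support(rows, n_replicates=50, seed=5)
        r2 = bootstrap_support(rows, n_replicates=50, seed=5)
        s1 = sorted((frozenset(n.leaf_names()), n.support)
                    for n in r1.main_tree.preorder() if not n.is_leaf())
        s2 = sorted((frozenset(n.leaf_names()), n.support)
                    for n in r2.main_tree.preorder() if not n.is_leaf())
        assert s1 == s2

    def test_supports_in_range_and_relabeling_invariant(self, rng):
        rows = self._alignment(rng)
        res = bootstrap_support(rows, n_replicates=40, seed=7)
        sups = {frozenset(n.leaf_names()): n.support
                for n in res.main_tree.preorder()
                if not n.is_leaf() and n is not res.main_tree}
        assert all(0 <= s <= 100 for s in sups.values())
        # bijective relabeling
        perm = {rid: f"z{k}" for k, (rid, _) in enumerate(rows)}
        rows2 = [(perm[rid], s) for rid, s in rows]
        res2 = bootstrap_support(rows2, n_replicates=40, seed=7)
        sups2 = {frozenset(perm[x] for x in bp): s for bp, s in sups.items()}
        got2 = {frozenset(n.leaf_names()): n.support
                for n in res2.main_tree.preorder()
                if not n.is_leaf() and n is not res2.main_tree}
        # compare on shared bipartitions (canonical side may flip under relabeling)
        all_names = frozenset(perm.values())
        norm = lambda d: {min(bp, all_names - bp, key=sorted): s
                          for bp, s in d.items()}
        assert norm(got2) == norm(sups2)
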