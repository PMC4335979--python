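import numpy as np
import pytest

from jenscape.io_formats import write_newick
from jenscape.reconcile import lca_reconcile
from jenscape.synthetic_data import (ConsumptionTruth, SimulationConfig,
                                     evolve_sequences, is_fully_observable,
                                     simulate_consumption_series,
                                     simulate_gene_family,
                                     simulate_species_tree)


class TestSpeciesTree:
    def test_two_species_cherry(self):
        t = simulate_species_tree(2, seed=0)
        assert len(t.leaves()) == 2 and len(t.children) == 2

    def test_deterministic(self):
        assert write_newick(simulate_species_tree(6, 1)) == \
            write_newick(simulate_species_tree(6, 1))

    def test_node_count_formula(self):
        t = simulate_species_tree(50, seed=7)
        nodes = list(t.preorder())
        assert len(t.leaves()) == 50
        assert len(nodes) == 2 * 50 - 1

    def test_too_few_species(self):
        with pytest.raises(ValueError):
            simulate_species_tree(1, seed=0)

    def test_branch_length_mean(self):
        t = simulate_species_tree(200, seed=3, branch_length_mean=0.1)
        lengths = [n.length for n in t.preorder() if n is not t]
        assert np.mean(lengths) == pytest.approx(0.1, rel=0.15)


class TestGeneFamily:
    def test_no_events_reproduces_species_tree(self):
        st = simulate_species_tree(6, seed=2)
        cfg = SimulationConfig(dup_rate=0.0, loss_rate=0.0)
        truth = simulate_gene_family(st, cfg, seed=5)
        assert truth.events == []
        assert truth.n_duplications == truth.n_losses == 0
        assert sorted(truth.surviving_leaves()) == \
            sorted(f"{s}__1" for s in st.leaf_names())
        r = lca_reconcile(truth.gene_tree, truth.species_tree)
        assert (r.n_duplications, r.n_losses) == (0, 0)

    def test_huge_loss_rate_extinguishes_family(self):
        st = simulate_species_tree(6, seed=2)
        cfg = SimulationConfig(dup_rate=0.0, loss_rate=500.0)
        truth = simulate_gene_family(st, cfg, seed=5)
        assert truth.extinct and truth.gene_tree is None
        assert truth.n_duplications == 0 and truth.n_losses > 0
        assert all(e[0] == "loss" for e in truth.events)

    def test_missing_branch_lengths_error(self):
        from jenscape.io_formats import read_newick
        st = read_newick("((a,b),c);")
        with pytest.raises(ValueError, match="branch length"):
            simulate_gene_family(st, SimulationConfig(), seed=0)

    def test_deterministic(self):
        st = simulate_species_tree(6, seed=2)
        cfg = SimulationConfig()
        t1 = simulate_gene_family(st, cfg, seed=11)
        t2 = simulate_gene_family(st, cfg, seed=11)
        assert t1.events == t2.events
        assert write_newick(t1.gene_tree) == write_newick(t2.gene_tree)

    def test_duplication_count_matches_poisson_expectation(self):
        """Mean duplications across seeds ~ rate x total lineage path length.

        With loss_rate 0 every lineage survives, so the expected number of
        duplications solves E[N] = rate * E[L] where E[L] is the expected
        total gene-lineage branch length; each duplication doubles the
        downstream lineage, so E[L] is computed recursively:
        for a branch of length t carrying expected m copies at its top,
        E[copies at bottom] = m * exp(rate * t) and the expected lineage
        length on the branch is m * (exp(rate * t) - 1) / rate.
        """
        rate = 0.5
        st = simulate_species_tree(6, seed=4)
        cfg = SimulationConfig(dup_rate=rate, loss_rate=0.0)

        def expected_length(node, m):
            total = 0.0
            for c in node.children:
                growth = np.exp(rate * c.length)
                total += m * (growth - 1.0) / rate
                total += expected_length(c, m * growth)
            return total

        expect = rate * expected_length(st, 1.0)
        counts = [simulate_gene_family(st, cfg, seed=s).n_duplications
                  for s in range(2000)]
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expect) < 3 * se

    def test_parsimony_never_exceeds_truth_and_matches_when_observable(self):
        st = simulate_species_tree(6, seed=1)
        cfg = SimulationConfig()
        n_obs = 0
        for seed in range(300):
            truth = simulate_gene_family(st, cfg, seed=seed)
            if truth.extinct or truth.gene_tree.is_leaf():
                continue
            r = lca_reconcile(truth.gene_tree, truth.species_tree)
            assert r.n_duplications <= truth.n_duplications
            assert r.n_duplications + r.n_losses <= \
                truth.n_duplications + truth.n_losses
            if is_fully_observable(truth):
                n_obs += 1
                assert (r.n_duplications, r.n_losses) == \
                    (truth.n_duplications, truth.n_losses)
        assert n_obs > 100  # the filter keeps most replicates


class TestSequenceEvolution:
    def test_zero_rate_keeps_root_sequence(self):
        st = simulate_species_tree(4, seed=3)
        cfg = SimulationConfig(subst_rate=0.0, n_decoys_per_species=0,
                               dup_rate=0, loss_rate=0, seq_length=50)
        truth = simulate_gene_family(st, cfg, seed=3)
        root = "MKV" * 16 + "AA"
        prot = evolve_sequences(truth.gene_tree, cfg, root_seq=root, seed=3)
        for recs in prot.values():
            assert all(r.residues == root for r in recs)

    def test_deterministic(self):
        st = simulate_species_tree(4, seed=3)
        cfg = SimulationConfig(seq_length=80)
        truth = simulate_gene_family(st, cfg, seed=4)
        p1 = evolve_sequences(truth.gene_tree, cfg, seed=5)
        p2 = evolve_sequences(truth.gene_tree, cfg, seed=5)
        assert {k: [(r.id, r.residues) for r in v] for k, v in p1.items()} == \
            {k: [(r.id, r.residues) for r in v] for k, v in p2.items()}

    def test_decoys_added_for_all_requested_species(self):
        st = simulate_species_tree(4, seed=3)
        cfg = SimulationConfig(seq_length=40, n_decoys_per_species=3)
        truth = simulate_gene_family(st, cfg, seed=4)
        prot = evolve_sequences(truth.gene_tree, cfg, seed=5,
                                species=st.leaf_names())
        assert set(prot) == set(st.leaf_names())
        for recs in prot.values():
            decoys = [r for r in recs if r.description == "decoy"]
            assert len(decoys) == 3
            assert all(200 <= len(r) <= 800 for r in decoys)

    def test_saturation_limit_p_distance(self):
        """At huge divergence the expected identity approaches 1/20."""
        from jenscape.io_formats import TreeNode
        gt = TreeNode()
        for name in ("a__1", "b__1"):
            gt.add_child(TreeNode(name=name, length=50.0))
        cfg = SimulationConfig(seq_length=10_000, subst_rate=1.0,
                               n_decoys_per_species=0)
        prot = evolve_sequences(gt, cfg, seed=6)
        s1 = prot["a"][0].residues
        s2 = prot["b"][0].residues
        ident = np.mean([x == y for x, y in zip(s1, s2)])
        se = np.sqrt(0.05 * 0.95 / 10_000)
        assert abs(ident - 0.05) < 4 * se

    def test_jukes_cantor_type_expected_p_distance(self):
        """Observed p-distance matches the 20-state equal-rates closed form
        0.95 (1 - exp(-(20/19) r t)) at large sequence length."""
        from jenscape.io_formats import TreeNode
        t_branch = 0.8
        gt = TreeNode()
        for name in ("a__1", "b__1"):
            gt.add_child(TreeNode(name=name, length=t_branch / 2))
        cfg = SimulationConfig(seq_length=10_000, subst_rate=1.0,
                               n_decoys_per_species=0)
        prot = evolve_sequences(gt, cfg, seed=7)
        s1, s2 = prot["a"][0].residues, prot["b"][0].residues
        p_obs = np.mean([x != y for x, y in zip(s1, s2)])
        # per-branch substitution probability q; two independent branches
        q = 1 - np.exp(-1.0 * t_branch / 2)
        # exact two-branch mismatch probability under uniform replacement
        p_match = (1 - q) ** 2 + 2 * q * (1 - q) * 0 + q * q * (1 / 19)
        expect = 1 - ((1 - q) ** 2 + q * q / 19)
        se = np.sqrt(expect * (1 - expect) / 10_000)
        assert abs(p_obs - expect) < 4 * se
        # and the Markov closed form agrees at these settings to ~1%
        closed = 0.95 * (1 - np.exp(-(20 / 19) * 1.0 * t_branch))
        assert abs(expect - closed) < 0.02


class TestConsumption:
    def test_noiseless_linear_until_depletion(self):
        truth = ConsumptionTruth("fumarate", c0=10.0, true_rate=0.22,
                                 noise_sd=0.0, times=list(range(0, 41, 2)))
        ts = simulate_consumption_series(truth, seed=0)
        c = ts.concentrations
        t = ts.times
        assert np.allclose(c, np.maximum(0, 10 - 0.22 * t))

    def test_zero_rate_constant(self):
        truth = ConsumptionTruth("malate", c0=5.0, true_rate=0.0,
                                 noise_sd=0.0, times=[0, 10, 20])
        ts = simulate_consumption_series(truth, seed=0)
        assert np.allclose(ts.concentrations, 5.0)

    def test_breakpoint_changes_slope(self):
        truth = ConsumptionTruth("fumarate", c0=10.0, true_rate=0.16,
                                 noise_sd=0.0, times=list(range(0, 45, 2)),
                                 breakpoint=22.0, rate_after=0.057)
        ts = simulate_consumption_series(truth, seed=0)
        c = dict(zip(ts.times, ts.concentrations))
        assert c[20] - c[22] != pytest.approx(c[24] - c[26])

    def test_seeded_replay_identical(self):
        truth = ConsumptionTruth("lactate", c0=8.0, true_rate=0.21,
                                 noise_sd=0.05, times=list(range(0, 41, 4)))
        a = simulate_consumption_series(truth, seed=9)
        b = simulate_consumption_series(truth, seed=9)
        assert np.array_equal(a.concentrations, b.concentrations)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            ConsumptionTruth("x", c0=1.0, true_rate=0.1, noise_sd=-0.1,
                             times=[0, 1])
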