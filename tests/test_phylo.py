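"""Likelihood machinery: distances, NJ, pruning, optimization, NNI, RF
and the congruence test's basic contracts."""

import numpy as np
import pytest

from virago.phylo import (
    Tree,
    concat_partitions,
    congruence_test,
    jc_distance,
    ml_tree,
    nj_tree,
    pruning_lnL,
    rf_distance,
)
from virago.phylo.likelihood import (
    encode_alignment,
    make_model,
    nni_search,
    optimize_branch_lengths,
    optimize_model_parameters,
    simulate_alignment,
)
from virago.phylo.tree import random_topology
from ._oracles import all_topologies, enumeration_lnL, rf_dendropy


class TestJCDistance:
    def test_identical_zero(self):
        assert jc_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_formula_value(self):
        # p = 0.25 -> d = -(3/4) ln(2/3)
        d = jc_distance("AAAA", "AAAC")
        assert d == pytest.approx(-0.75 * np.log(1 - 4 * 0.25 / 3))

    def test_saturated_pair_rejected_by_name(self):
        with pytest.raises(ValueError, match="saturated"):
            jc_distance("AAAA", "CCCC", pair=("x", "y"))

    def test_large_near_saturation(self):
        d = jc_distance("A" * 100, "C" * 74 + "A" * 26)
        assert d > 2.0


class TestNJ:
    def test_recovers_topology_from_additive_matrix(self):
        true = Tree.from_newick("((A:0.1,B:0.2):0.05,(C:0.3,D:0.15):0.04,"
                                "(E:0.2,F:0.05):0.06);")
        labels = sorted(true.taxa)
        pl = true.leaf_path_lengths()
        D = np.array([[pl[(a, b)] for b in labels] for a in labels])
        nj = nj_tree(D, labels)
        assert rf_distance(nj, true) == 0

    def test_recovers_branch_lengths_from_additive_matrix(self):
        true = Tree.from_newick("((A:0.1,B:0.2):0.05,C:0.3,D:0.15);")
        labels = sorted(true.taxa)
        pl = true.leaf_path_lengths()
        D = np.array([[pl[(a, b)] for b in labels] for a in labels])
        nj = nj_tree(D, labels)
        out = nj.leaf_path_lengths()
        for k, v in pl.items():
            assert out[k] == pytest.approx(v, abs=1e-9)


class TestPruning:
    def test_two_taxa_identical_site_zero_branch(self):
        t = Tree(["A", "B"], {0: {2: 0.0}, 1: {2: 0.0},
                              2: {0: 0.0, 1: 0.0}})
        assert pruning_lnL(t, {"A": "A", "B": "A"}, "JC") == pytest.approx(
            np.log(0.25)
        )

    def test_two_taxa_infinite_branches_independent(self):
        t = Tree(["A", "B"], {0: {2: 10.0}, 1: {2: 10.0},
                              2: {0: 10.0, 1: 10.0}})
        lnL = pruning_lnL(t, {"A": "A", "B": "C"}, "JC")
        assert lnL == pytest.approx(2 * np.log(0.25), abs=1e-4)

    def test_three_taxa_one_site_equals_state_enumeration(self, rng):
        model = make_model("JC")
        tree = random_topology(["A", "B", "C"], rng)
        for u, v, _ in tree.edges():
            tree.set_length(u, v, rng.uniform(0.05, 0.8))
        aln = {"A": "A", "B": "C", "C": "G"}
        assert pruning_lnL(tree, aln, model) == pytest.approx(
            enumeration_lnL(tree, aln, model)
        )

    def test_invariant_to_taxon_input_order(self, rng):
        tree = random_topology(list("ABCDE"), rng)
        aln = {t: "".join(rng.choice(list("ACGT"), 30)) for t in "ABCDE"}
        shuffled = {t: aln[t] for t in "ECABD"}
        assert pruning_lnL(tree, aln, "JC") == pytest.approx(
            pruning_lnL(tree, shuffled, "JC")
        )

    def test_invariant_to_pruning_root(self, rng):
        """The unrooted likelihood must not depend on where the pruning
        recursion is rooted (checked via the generic path for K80)."""
        from virago.phylo.likelihood import _postorder_partials

        model = make_model("K80", kappa=3.0)
        tree = random_topology(list("ABCD"), rng)
        aln = {t: "".join(rng.choice(list("ACGT"), 20)) for t in "ABCD"}
        data = encode_alignment(aln)
        vals = []
        for root in [n for n in tree.adj if n >= tree.n_leaves]:
            partials, scale, order = _postorder_partials(
                tree, data, model, tree.postorder(root)
            )
            site = partials[root] @ model.freqs
            vals.append(float(np.sum(data.weights * (np.log(site) + scale))))
        assert np.ptp(vals) < 1e-9

    def test_missing_data_marginalized(self, rng):
        model = make_model("JC")
        tree = random_topology(list("ABC"), rng)
        aln = {"A": "AN", "B": "CA", "C": "GA"}
        assert pruning_lnL(tree, aln, model) == pytest.approx(
            enumeration_lnL(tree, aln, model)
        )

    def test_taxon_mismatch_rejected(self, rng):
        tree = random_topology(list("ABC"), rng)
        with pytest.raises(ValueError, match="match"):
            pruning_lnL(tree, {"A": "A", "B": "C", "X": "G"}, "JC")


class TestOptimization:
    def test_lnl_never_decreases_from_true_tree(self, rng):
        true = Tree.from_newick(
            "((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1,(E:0.1,F:0.1):0.1);"
        )
        aln = simulate_alignment(true, "JC", 1000, rng)
        before = pruning_lnL(true, aln, "JC")
        _, after, _ = optimize_branch_lengths(true.copy(), aln, "JC")
        assert after >= before - 1e-9

    def test_branch_recovery_within_three_se(self, rng):
        """Branch lengths re-estimated from 10-kb data lie within 3
        standard errors of the truth (delta-method SE on the JC
        distance)."""
        true = Tree.from_newick("((A:0.1,B:0.1):0.1,C:0.1,D:0.1);")
        n_sites = 10_000
        p = 0.75 * (1 - np.exp(-4 * 0.1 / 3))
        se = np.sqrt(p * (1 - p) / n_sites) / (1 - 4 * p / 3)
        hits = total = 0
        for seed in range(20):
            local = np.random.default_rng(seed)
            aln = simulate_alignment(true, "JC", n_sites, local)
            fit, _, _ = optimize_branch_lengths(true.copy(), aln, "JC")
            for u, v, t in fit.edges():
                total += 1
                if abs(t - 0.1) <= 3 * se:
                    hits += 1
        assert hits / total >= 0.95

    def test_nni_agrees_with_exhaustive_four_taxon_scan(self, rng):
        model = make_model("JC")
        true = Tree.from_newick("((A:0.05,B:0.05):0.15,C:0.05,D:0.05);")
        aln = simulate_alignment(true, model, 2000, rng)
        data = encode_alignment(aln)
        # exhaustive: optimize branch lengths on all three topologies
        best_lnL, best_tree = -np.inf, None
        for cand in all_topologies(list("ABCD")):
            cand, lnL, _ = optimize_branch_lengths(cand, data, model)
            if lnL > best_lnL:
                best_lnL, best_tree = lnL, cand
        tree, lnL = ml_tree(aln, model)
        assert rf_distance(tree, best_tree) == 0
        assert lnL == pytest.approx(best_lnL, abs=1e-3)

    def test_gtr_rate_ratios_recovered(self):
        """GTR exchangeability ratios recovered within 20% from long
        alignments simulated under known rates."""
        true_rates = np.array([1.0, 4.0, 0.7, 1.3, 5.0, 1.0])
        model = make_model("GTR", rates=true_rates)
        tree = Tree.from_newick("((A:0.15,B:0.15):0.1,(C:0.15,D:0.15):0.1,"
                                "E:0.2);")
        errs = []
        for seed in range(5):
            local = np.random.default_rng(seed)
            aln = simulate_alignment(tree, model, 50_000, local)
            fit_tree = tree.copy()
            start = make_model("GTR")
            _, fitted, _ = optimize_model_parameters(fit_tree, aln, start,
                                                     rounds=2)
            ratios = fitted.rates / fitted.rates[5]
            errs.append(np.max(np.abs(ratios - true_rates) / true_rates))
        assert np.median(errs) <= 0.20


class TestRF:
    def test_identical_trees_zero(self, rng):
        t = random_topology(list("ABCDEF"), rng)
        assert rf_distance(t, t.copy()) == 0

    def test_four_taxon_alternative_topologies_distance_two(self):
        t1 = Tree.from_newick("((A:1,B:1):1,C:1,D:1);")
        t2 = Tree.from_newick("((A:1,C:1):1,B:1,D:1);")
        assert rf_distance(t1, t2) == 2

    def test_matches_dendropy_on_random_pairs(self, rng):
        taxa = list("ABCDEFGH")
        for _ in range(20):
            t1 = random_topology(taxa, rng)
            t2 = random_topology(taxa, rng)
            assert rf_distance(t1, t2) == rf_dendropy(
                t1.to_newick(), t2.to_newick()
            )

    def test_taxon_mismatch_rejected(self, rng):
        t1 = random_topology(list("ABCD"), rng)
        t2 = random_topology(list("ABCE"), rng)
        with pytest.raises(ValueError, match="taxon"):
            rf_distance(t1, t2)


class TestConcat:
    def test_column_counts_and_boundaries(self):
        a = {"A": "A" * 100, "B": "C" * 100}
        b = {"A": "G" * 100, "B": "T" * 100}
        cat, bounds = concat_partitions([a, b])
        assert len(cat["A"]) == 200
        assert bounds == [(0, 100), (100, 200)]

    def test_unlinked_lnl_sums_across_partitions(self, rng):
        tree = random_topology(list("ABCD"), rng)
        a = simulate_alignment(tree, "JC", 80, rng)
        b = simulate_alignment(tree, "JC", 120, rng)
        cat, bounds = concat_partitions([a, b])
        sliced = [
            {t: cat[t][i:j] for t in cat} for i, j in bounds
        ]
        total = sum(pruning_lnL(tree, p, "JC") for p in sliced)
        separate = pruning_lnL(tree, a, "JC") + pruning_lnL(tree, b, "JC")
        assert total == pytest.approx(separate)

    def test_taxon_mismatch_rejected(self):
        with pytest.raises(ValueError, match="taxon"):
            concat_partitions([{"A": "AC"}, {"B": "AC"}])


class TestCongruence:
    def test_identical_partitions_give_null_delta(self, rng):
        tree = random_topology(list("ABCDEF"), rng)
        aln = simulate_alignment(tree, "JC", 500, rng)
        res = congruence_test([aln, dict(aln), dict(aln)], model="JC")
        assert res.delta <= 1e-6
        assert res.p_chi2 == pytest.approx(1.0)

    def test_df_heuristic(self, rng):
        tree = random_topology(list("ABCDEF"), rng)
        aln = simulate_alignment(tree, "JC", 200, rng)
        res = congruence_test([aln, dict(aln), dict(aln)], model="JC")
        assert res.df_heuristic == (3 - 1) * (6 - 3)

    def test_delta_nonnegative_and_pvalues_valid(self, rng):
        for _ in range(5):
            t1 = random_topology(list("ABCDE"), rng,
                                 internal_length=0.02, terminal_length=0.05)
            t2 = random_topology(list("ABCDE"), rng,
                                 internal_length=0.02, terminal_length=0.05)
            parts = [simulate_alignment(t1, "JC", 300, rng),
                     simulate_alignment(t2, "JC", 300, rng)]
            res = congruence_test(parts, model="JC")
            assert res.delta >= -1e-6
            assert 0.0 <= res.p_chi2 <= 1.0

    def test_planted_reassortment_detected(self, rng):
        ta = Tree.from_newick("((A:0.1,B:0.1):0.2,(C:0.1,D:0.1):0.2,"
                              "(E:0.1,F:0.1):0.2);")
        tb = Tree.from_newick("((A:0.1,D:0.1):0.2,(B:0.1,E:0.1):0.2,"
                              "(C:0.1,F:0.1):0.2);")
        parts = [simulate_alignment(ta, "JC", 2000, rng),
                 simulate_alignment(tb, "JC", 2000, rng)]
        res = congruence_test(parts, model="JC", n_bootstrap=100, seed=5)
        assert res.delta > 50
        assert res.p_bootstrap < 0.01

    def test_taxon_set_mismatch_rejected(self, rng):
        a = {t: "ACGT" for t in "ABCD"}
        b = {t: "ACGT" for t in "ABCE"}
        with pytest.raises(ValueError, match="taxon"):
            congruence_test([a, b])

    def test_fewer_than_four_taxa_rejected(self):
        a = {t: "ACGT" for t in "ABC"}
        with pytest.raises(ValueError, match="four taxa"):
            congruence_test([a, dict(a)])
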