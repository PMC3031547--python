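import numpy as np
import pytest

from alnsens.io_formats import MultipleAlignment, SequenceRecord, read_newick
from alnsens.phylo import (AA_ORDER, ProteinLikelihood, bionj,
                           bootstrap_support, distance_matrix,
                           fitch_parsimony, lg_model, mean_internal_support,
                           midpoint_root, nni_search, optimize_branch_lengths,
                           protein_distance, tree_loglik, tree_size,
                           leaf_distance_matrix)
from alnsens.treecmp import rf_distance

from conftest import make_study_tree
from oracles import brute_fitch, brute_tree_loglik, simulate_protein_alignment

IDX = {a: i for i, a in enumerate(AA_ORDER)}


def aln_of(rows, ids):
    return MultipleAlignment(tuple(
        SequenceRecord(i, r, "aa", gapped=True) for i, r in zip(ids, rows)))


def rows_to_aln(rows_dict):
    ids = sorted(rows_dict)
    return aln_of(["".join(AA_ORDER[s] for s in rows_dict[i]) for i in ids],
                  ids)


class TestDistances:
    def test_identical_rows_have_zero_distance(self):
        for corr in ("p", "poisson", "gamma"):
            assert protein_distance("MKL", "MKL", corr) == 0.0

    def test_poisson_closed_form_at_half_mismatch(self):
        assert protein_distance("MKLA", "MKCD", "poisson") == \
            pytest.approx(-np.log(0.5))

    def test_gamma_approaches_poisson_for_large_alpha(self):
        p = protein_distance("MKLAMK", "MKCDMK", "poisson")
        g = protein_distance("MKLAMK", "MKCDMK", "gamma", alpha=1e6)
        assert abs(p - g) < 1e-4

    def test_no_shared_columns_is_an_error(self):
        with pytest.raises(ValueError):
            protein_distance("M-", "-M", "p")


class TestBioNJ:
    def test_recovers_additive_four_taxon_tree(self):
        # distances from ((a:1,b:2):1,(c:3,d:4))
        D = np.array([[0, 3, 5, 6],
                      [3, 0, 6, 7],
                      [5, 6, 0, 7],
                      [6, 7, 7, 0]], float)
        t = bionj(D, ["a", "b", "c", "d"])
        ref = read_newick("((a:1,b:2):1,(c:3,d:4));")
        assert rf_distance(t, ref).rf == 0
        lengths = {lf.taxon.label: lf.edge.length for lf in t.leaf_node_iter()}
        assert lengths == pytest.approx({"a": 1, "b": 2, "c": 3, "d": 4})

    def test_three_taxa_closed_form(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        t = bionj(D, ["a", "b", "c"])
        lengths = {lf.taxon.label: lf.edge.length for lf in t.leaf_node_iter()}
        assert lengths == pytest.approx({"a": 1, "b": 2, "c": 3})

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.random((6, 4))
        D = np.abs(X[:, None, :] - X[None, :, :]).sum(-1)
        np.fill_diagonal(D, 0)
        labels = [f"t{i}" for i in range(6)]
        t1 = bionj(D, labels)
        perm = [3, 1, 5, 0, 4, 2]
        t2 = bionj(D[np.ix_(perm, perm)], [labels[i] for i in perm])
        assert rf_distance(t1, t2).rf == 0

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]])
        with pytest.raises(ValueError):
            bionj(D, list("abc"))


class TestLikelihood:
    def test_two_taxon_single_column_closed_form(self):
        model = lg_model(alpha=1.0, p_inv=0.0, n_rate_cats=1)
        t = read_newick("(a:0.3,b:0.4);")
        aln = aln_of(["M", "K"], ["a", "b"])
        A, Ainv, lam = model.eigen()
        P = (A * np.exp(lam * 0.7)) @ Ainv
        pi = model.equilibrium_freqs
        expect = np.log(pi[IDX["M"]] * P[IDX["M"], IDX["K"]])
        assert tree_loglik(t, aln, model) == pytest.approx(expect, abs=1e-10)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_state_summation(self, seed):
        """Pruning equals brute-force summation over internal states,
        including +I and gamma rate mixing, with gaps as missing data."""
        rng = np.random.default_rng(seed)
        model = lg_model(alpha=0.7 + seed / 10, p_inv=0.15, n_rate_cats=2)
        t = read_newick("((a:0.2,b:0.5):0.15,(c:0.3,d:0.6):0.1);")
        rows = {}
        for lab in "abcd":
            chars = [AA_ORDER[i] for i in rng.integers(0, 20, 5)]
            if rng.random() < 0.5:
                chars[rng.integers(5)] = "-"
            rows[lab] = "".join(chars)
        aln = aln_of([rows[l] for l in "abcd"], list("abcd"))
        got = tree_loglik(t, aln, model)
        A, Ainv, lam = model.eigen()

        def trans(t_, r):
            return (A * np.exp(lam * r * t_)) @ Ainv

        expect = brute_tree_loglik(
            t, rows, {a: i for i, a in enumerate(AA_ORDER)},
            model.equilibrium_freqs, trans,
            rates=list(model.rate_categories()), p_inv=model.p_inv)
        assert got == pytest.approx(expect, abs=1e-8)

    def test_rerooting_invariance(self):
        model = lg_model(alpha=1.2, p_inv=0.1)
        t = read_newick("((a:0.2,b:0.5):0.15,(c:0.3,d:0.6):0.1);")
        rng = np.random.default_rng(1)
        aln = aln_of(["".join(AA_ORDER[i] for i in rng.integers(0, 20, 30))
                      for _ in range(4)], list("abcd"))
        l1 = tree_loglik(t, aln, model)
        t2 = read_newick("((a:0.2,b:0.5):0.15,(c:0.3,d:0.6):0.1);")
        t2.reroot_at_node(t2.seed_node.child_nodes()[0])
        t2.suppress_unifurcations()
        assert tree_loglik(t2, aln, model) == pytest.approx(l1, abs=1e-8)

    def test_leaf_row_mismatch_rejected(self):
        model = lg_model()
        t = read_newick("((a:1,b:1):1,(c:1,e:1):1);")
        aln = aln_of(["MK", "MK", "MK", "MK"], list("abcd"))
        with pytest.raises(ValueError):
            tree_loglik(t, aln, model)


class TestBranchOptimization:
    def test_perturbed_lengths_recovered(self):
        """Simulate on a known tree, double all lengths, re-optimize:
        recovered total length within 20% of truth (400 columns)."""
        model = lg_model(alpha=1.0, p_inv=0.0, n_rate_cats=1)
        true = make_study_tree(6, seed=2, total_length=2.0)
        rows = simulate_protein_alignment(true, model, 400, seed=3)
        aln = rows_to_aln(rows)
        start = make_study_tree(6, seed=2, total_length=2.0)
        for e in start.preorder_edge_iter():
            if e.length:
                e.length *= 2.0
        _, lnl = optimize_branch_lengths(start, aln, model)
        assert tree_size(start) == pytest.approx(2.0, rel=0.2)

    def test_reoptimizing_an_optimum_is_stable(self, small_family):
        model = lg_model(alpha=1.0)
        aln = small_family.true_alignment_aa
        D, labels = distance_matrix(aln, "gamma")
        t = bionj(D, labels)
        lik = ProteinLikelihood(t, aln, model)
        _, l1 = lik.optimize_branch_lengths(max_cycles=40)
        _, l2 = lik.optimize_branch_lengths(max_cycles=2)
        assert abs(l2 - l1) < 1e-4

    def test_monotone_improvement(self, small_family):
        model = lg_model(alpha=1.0)
        aln = small_family.true_alignment_aa
        D, labels = distance_matrix(aln, "gamma")
        t = bionj(D, labels)
        lik = ProteinLikelihood(t, aln, model)
        before = lik.loglik()
        prev = before
        for _ in range(3):
            _, cur = lik.optimize_branch_lengths(max_cycles=1)
            assert cur >= prev - 1e-9
            prev = cur


class TestNNI:
    def test_four_taxa_matches_exhaustive_topology_search(self):
        model = lg_model(alpha=1.0, n_rate_cats=1)
        true = read_newick("((a:0.3,b:0.3):0.4,(c:0.3,d:0.3):0.1);")
        rows = simulate_protein_alignment(true, model, 300, seed=9)
        aln = rows_to_aln(rows)
        topos = ["((a:0.3,b:0.3):0.2,(c:0.3,d:0.3):0.2);",
                 "((a:0.3,c:0.3):0.2,(b:0.3,d:0.3):0.2);",
                 "((a:0.3,d:0.3):0.2,(b:0.3,c:0.3):0.2);"]
        best_exh, best_lnl = None, -np.inf
        for s in topos:
            t = read_newick(s)
            optimize_branch_lengths(t, aln, model)
            lnl = tree_loglik(t, aln, model)
            if lnl > best_lnl:
                best_exh, best_lnl = t, lnl
        start = read_newick(topos[1])
        found, lnl = nni_search(start, aln, model, n_starts=2, seed=0)
        assert rf_distance(found, best_exh).rf == 0
        assert lnl == pytest.approx(best_lnl, abs=0.05)

    def test_result_at_least_as_good_as_start(self, small_family):
        model = lg_model(alpha=1.0)
        aln = small_family.true_alignment_aa
        D, labels = distance_matrix(aln, "gamma")
        start = bionj(D, labels)
        start_lnl = tree_loglik(start, aln, model)
        _, lnl = nni_search(start, aln, model, n_starts=1, seed=0,
                            max_rounds=3)
        assert lnl >= start_lnl - 1e-6

    def test_expansion_clade_recovered_by_search(self):
        """ML NNI search recovers the simulated expansion clade as
        monophyletic in >=80% of seeds (desk-scale families)."""
        from alnsens.simulate import FamilySimConfig, simulate_family
        from alnsens.treecmp import nontrivial_bipartitions

        model = lg_model(alpha=1.0)
        hits = 0
        for seed in range(5):
            fam = simulate_family(FamilySimConfig(
                seed=400 + seed, n_conserved=5, n_expansion=5,
                n_codons=100, target_identity=0.3))
            aln = fam.true_alignment_aa
            D, labels = distance_matrix(aln, "gamma")
            best, _ = nni_search(bionj(D, labels), aln, model, n_starts=2,
                                 seed=seed)
            labels_all = frozenset(l.taxon.label
                                   for l in best.leaf_node_iter())
            want = frozenset(fam.expansion_leaves)
            key = want if min(labels_all) not in want else labels_all - want
            hits += key in nontrivial_bipartitions(best)
        assert hits >= 4

    def test_seeded_determinism(self, small_family):
        model = lg_model(alpha=1.0)
        aln = small_family.true_alignment_aa
        D, labels = distance_matrix(aln, "gamma")
        t1, l1 = nni_search(bionj(D, labels), aln, model, n_starts=2, seed=5,
                            max_rounds=2)
        t2, l2 = nni_search(bionj(D, labels), aln, model, n_starts=2, seed=5,
                            max_rounds=2)
        assert l1 == l2 and rf_distance(t1, t2).rf == 0


class TestBootstrap:
    def test_clean_data_gets_high_support(self):
        model = lg_model(alpha=1.0, n_rate_cats=1)
        true = make_study_tree(5, seed=4, total_length=1.2)
        rows = simulate_protein_alignment(true, model, 800, seed=5)
        aln = rows_to_aln(rows)
        D, labels = distance_matrix(aln, "poisson")
        t = bionj(D, labels)
        bootstrap_support(t, aln, model, n_reps=80, seed=6)
        assert mean_internal_support(t) >= 0.9

    def test_support_on_every_internal_edge(self, small_family):
        model = lg_model()
        aln = small_family.true_alignment_aa
        D, labels = distance_matrix(aln, "poisson")
        t = bionj(D, labels)
        bootstrap_support(t, aln, model, n_reps=20, seed=1)
        internal = [nd for nd in t.preorder_node_iter()
                    if nd.parent_node is not None and nd.is_internal()]
        assert all(getattr(nd.edge, "support", None) is not None
                   for nd in internal)

    def test_zero_reps_is_a_noop(self, small_family):
        model = lg_model()
        aln = small_family.true_alignment_aa
        D, labels = distance_matrix(aln, "poisson")
        t = bionj(D, labels)
        before = {id(e): e.length for e in t.preorder_edge_iter()}
        bootstrap_support(t, aln, model, n_reps=0, seed=1)
        assert {id(e): e.length for e in t.preorder_edge_iter()} == before


class TestParsimony:
    def test_constant_column_costs_nothing(self):
        t = read_newick("((a:1,b:1):1,(c:1,d:1):1);")
        assert fitch_parsimony(t, aln_of(["M", "M", "M", "M"], list("abcd"))) == 0

    def test_textbook_two_state_column(self):
        t = read_newick("((a:1,b:1):1,(c:1,d:1):1);")
        assert fitch_parsimony(t, aln_of(["A", "A", "C", "C"], list("abcd"))) == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_labeling(self, seed):
        rng = np.random.default_rng(seed)
        t = make_study_tree(6, seed=seed)
        alphabet = "ACDE"
        rows = {f"t{i:02d}": "".join(rng.choice(list(alphabet + "-"), 4))
                for i in range(6)}
        ids = sorted(rows)
        aln = aln_of([rows[i] for i in ids], ids)
        assert fitch_parsimony(t, aln) == brute_fitch(t, rows, alphabet)


class TestRootingAndSize:
    def test_two_leaf_midpoint_is_halfway(self):
        t = read_newick("(a:1,b:3);")
        midpoint_root(t)
        depths = {lf.taxon.label: sum(
            e.length for e in _path_edges(lf)) for lf in t.leaf_node_iter()}
        assert depths["a"] == pytest.approx(2.0)
        assert depths["b"] == pytest.approx(2.0)

    def test_tree_size_is_branch_length_sum(self):
        assert tree_size(read_newick("((a:1,b:1):1,c:2);")) == pytest.approx(5.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_farthest_leaves_equidistant_from_root(self, seed):
        t = make_study_tree(7, seed=seed, total_length=4.0)
        D, labels = leaf_distance_matrix(t)
        i, j = np.unravel_index(np.argmax(D), D.shape)
        midpoint_root(t)
        depths = {lf.taxon.label: sum(e.length for e in _path_edges(lf))
                  for lf in t.leaf_node_iter()}
        assert depths[labels[i]] == pytest.approx(depths[labels[j]], abs=1e-9)
        assert tree_size(t) == pytest.approx(4.0, abs=1e-9)


def _path_edges(leaf):
    node = leaf
    while node.parent_node is not None:
        yield node.edge
        node = node.parent_node
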