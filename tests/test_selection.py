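import numpy as np
import pytest
from scipy.linalg import expm

from alnsens.io_formats import MultipleAlignment, SequenceRecord, read_newick
from alnsens.selection import (CODONS, CODON_INDEX, CodonLikelihood, N_CODONS,
                               SelectionError, codon_q_matrix,
                               codon_rate_matrix, encode_codon_alignment, f3x4,
                               fit_branch_model, fit_branch_site_A,
                               fit_site_model, lrt, selection_report,
                               site_posteriors, _matrix_rate)
from alnsens.simulate import simulate_codon_alignment

from conftest import make_study_tree
from oracles import brute_tree_loglik


def codon_aln(rows, ids=None):
    ids = ids or [f"s{i}" for i in range(len(rows))]
    return MultipleAlignment(tuple(
        SequenceRecord(i, r, "nt", gapped=True) for i, r in zip(ids, rows)))


class TestF3x4:
    def test_uniform_composition_gives_equal_codon_frequencies(self):
        # all four nucleotides equally frequent at every position
        rows = ["".join(CODONS[i] for i in range(0, 61, 10)) + "ACGGCATTG"]
        aln = codon_aln(["ACGTACGTACGT", "TGCATGCATGCA"])
        pi = f3x4(aln)
        assert pi == pytest.approx(np.full(61, 1 / 61))

    def test_sums_to_one(self, small_family):
        assert f3x4(small_family.true_alignment_nt).sum() == pytest.approx(1.0)

    def test_matches_literal_three_position_tally(self):
        rows = ["ATGAAATTT", "ATGCCCTTT"]
        aln = codon_aln(rows)
        counts = np.zeros((3, 4))
        order = "ACGT"
        for r in rows:
            for pos, ch in enumerate(r):
                counts[pos % 3, order.index(ch)] += 1
        freqs = counts / counts.sum(axis=1, keepdims=True)
        expect = np.array([freqs[0, order.index(c[0])]
                           * freqs[1, order.index(c[1])]
                           * freqs[2, order.index(c[2])] for c in CODONS])
        expect /= expect.sum()
        assert f3x4(aln) == pytest.approx(expect)


class TestQMatrix:
    def setup_method(self):
        self.pi = np.full(61, 1 / 61)

    def test_omega_zero_kills_nonsynonymous_rates(self):
        from alnsens.selection import AA_OF_CODON, _PAIR_I, _PAIR_J, _PAIR_NS
        Q = codon_rate_matrix(2.0, 0.0, self.pi)
        assert np.all(Q[_PAIR_I[_PAIR_NS], _PAIR_J[_PAIR_NS]] == 0)

    def test_detailed_balance(self):
        rng = np.random.default_rng(0)
        pi = rng.dirichlet(np.ones(61))
        Q = codon_rate_matrix(3.1, 0.7, pi)
        assert np.allclose(pi[:, None] * Q, (pi[:, None] * Q).T, atol=1e-14)

    def test_rows_sum_to_zero(self):
        for kappa, omega in [(0.5, 0.1), (2.0, 1.0), (10.0, 5.0)]:
            Q = codon_rate_matrix(kappa, omega, self.pi)
            assert np.abs(Q.sum(axis=1)).max() < 1e-12

    def test_mixture_scaling_gives_unit_mean_rate(self):
        props, omegas = [0.6, 0.4], [0.2, 2.0]
        Qs = codon_q_matrix(2.0, self.pi, props, omegas)
        mean = sum(p * _matrix_rate(Q, self.pi) for p, Q in zip(props, Qs))
        assert mean == pytest.approx(1.0)


class TestEncoding:
    def test_stop_codon_is_an_error(self):
        with pytest.raises(SelectionError, match="stop codon"):
            encode_codon_alignment(codon_aln(["ATGTAA", "ATGAAA"]))

    def test_all_gap_codon_sites_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="all-gap"):
            mat, kept = encode_codon_alignment(
                codon_aln(["---AAA", "---AAG"]))
        assert kept.tolist() == [1]

    def test_partial_gap_codons_are_missing_data(self):
        mat, _ = encode_codon_alignment(codon_aln(["A--AAA", "ATGAAG"]))
        assert mat[0, 0] == -1 and mat[1, 0] == CODON_INDEX["ATG"]


class TestLRT:
    def test_published_likelihood_pair_reproduces_statistic(self):
        res = lrt(-16240.8767, -16219.8, df=2)
        assert f"{res.statistic:.4f}" == "42.1534"

    def test_equal_likelihoods_give_zero_and_p_one(self):
        res = lrt(-100.0, -100.0, df=1)
        assert res.statistic == 0.0 and res.p_chi2_df == 1.0

    def test_chi_square_boundary_p_value(self):
        res = lrt(0.0, 3.8415 / 2, df=1)
        assert res.p_chi2_df == pytest.approx(0.05, abs=1e-4)

    def test_better_null_is_floored_at_zero(self):
        assert lrt(-99.0, -100.0, df=1).statistic == 0.0

    def test_df_below_one_rejected(self):
        with pytest.raises(SelectionError):
            lrt(-1.0, 0.0, df=0)


class TestCodonPruning:
    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_state_summation(self, seed):
        rng = np.random.default_rng(seed)
        t = read_newick("((a:0.2,b:0.4):0.1,(c:0.3,d:0.5):0.2);")
        rows = {lab: "".join(CODONS[i] for i in rng.integers(0, 61, 3))
                for lab in "abcd"}
        aln = codon_aln([rows[l] for l in "abcd"], list("abcd"))
        lik = CodonLikelihood(t, aln)
        kappa, omega = 1.5 + seed, 0.3 + 0.4 * seed
        got = float(lik.weights @ lik.class_site_loglikes(kappa, omega, 1.0))
        Q = codon_rate_matrix(kappa, omega, lik.pi)
        ref = _matrix_rate(codon_rate_matrix(kappa, 1.0, lik.pi), lik.pi)

        def trans(t_, r):
            return expm(Q / ref * t_)

        expect = brute_tree_loglik(t, rows_to_sites(rows), CODON_INDEX,
                                   lik.pi, trans)
        assert got == pytest.approx(expect, abs=1e-8)


def rows_to_sites(rows):
    return {lab: [seq[3 * k: 3 * k + 3] for k in range(len(seq) // 3)]
            for lab, seq in rows.items()}


@pytest.fixture(scope="module")
def fitted_pair():
    """Shared M1a/M2a fits on one simulated dataset."""
    tree = make_study_tree(8, seed=3)
    aln, classes = simulate_codon_alignment(
        tree, [(0.6, 0.1), (0.3, 1.0), (0.1, 4.0)], 2.0, 250, seed=5)
    lik = CodonLikelihood(tree, aln)
    m1a = fit_site_model(aln, tree, "M1a", n_restarts=1, seed=0,
                         branch_mode="fixed", lik=lik)
    m2a = fit_site_model(aln, tree, "M2a", n_restarts=1, seed=1,
                         warm_start_fit=m1a, lik=lik)
    return tree, aln, classes, m1a, m2a


class TestSiteModels:
    def test_nesting_dominance(self, fitted_pair):
        _, _, _, m1a, m2a = fitted_pair
        assert m2a.lnL >= m1a.lnL - 1e-6

    def test_m7_m8_nesting(self, fitted_pair):
        tree, aln, _, m1a, _ = fitted_pair
        m7 = fit_site_model(aln, tree, "M7", n_restarts=1, seed=0,
                            lik=m1a._lik)
        m8 = fit_site_model(aln, tree, "M8", n_restarts=1, seed=1,
                            warm_start_fit=m7, lik=m1a._lik)
        assert m8.lnL >= m7.lnL - 1e-6

    def test_positive_class_detected_with_reasonable_omega(self, fitted_pair):
        _, _, _, m1a, m2a = fitted_pair
        res = lrt(m1a.lnL, m2a.lnL, df=2)
        assert res.statistic > 5.99
        assert 2.0 < m2a.params.class_omegas[-1] < 8.0

    def test_m0_omega_recovery(self):
        """Median omega-hat under M0 within [0.4, 0.6] when the truth is
        omega = 0.5 (13 taxa, 500 codons, replicated)."""
        tree = make_study_tree(13, seed=2)
        hats = []
        for rep in range(8):
            aln, _ = simulate_codon_alignment(tree, [(1.0, 0.5)], 2.0, 500,
                                              seed=700 + rep)
            fit = fit_site_model(aln, tree, "M0", n_restarts=1, seed=rep,
                                 branch_mode="fixed")
            hats.append(float(fit.params.class_omegas[0]))
        assert 0.4 <= float(np.median(hats)) <= 0.6

    def test_restart_bookkeeping(self, fitted_pair):
        tree, aln, _, _, _ = fitted_pair
        fit = fit_site_model(aln, tree, "M0", n_restarts=3, seed=7,
                             branch_mode="fixed")
        assert fit.n_restarts_agreeing >= 1
        assert len(fit.restart_lnls) == 3


class TestSitePosteriors:
    def test_flagged_sites_are_mostly_truly_positive(self, fitted_pair):
        _, _, classes, _, m2a = fitted_pair
        post = site_posteriors(m2a)
        true_pos = set((np.nonzero(classes == 2)[0] + 1).tolist())
        flagged = set(int(s) for s in post.flagged_sites)
        assert flagged, "expected at least one flagged site"
        assert len(flagged & true_pos) / len(flagged) >= 0.7

    def test_pp_vector_covers_retained_sites(self, fitted_pair):
        _, aln, _, _, m2a = fitted_pair
        post = site_posteriors(m2a)
        assert len(post.pp) == aln.n_cols // 3
        assert np.all((post.pp >= 0) & (post.pp <= 1))

    def test_beb_lite_grid_is_available(self, fitted_pair):
        _, _, _, _, m2a = fitted_pair
        post = site_posteriors(m2a, method="beb-lite")
        assert post.method == "beb-lite"
        assert np.all((post.pp >= 0) & (post.pp <= 1))

    def test_model_without_positive_class_rejected(self, fitted_pair):
        _, _, _, m1a, _ = fitted_pair
        with pytest.raises(SelectionError):
            site_posteriors(m1a)


class TestBranchModels:
    def test_two_ratio_recovers_direction_of_foreground_shift(self):
        """Foreground simulated at omega 0.05 vs background 0.5: the fitted
        foreground omega comes out below the background one (replicated)."""
        tree = make_study_tree(8, seed=6)
        clade = _smallest_clade(tree)
        hits = 0
        for rep in range(5):
            aln = _simulate_branch_shift(tree, clade, w_bg=0.5, w_fg=0.05,
                                         n_codons=200, seed=30 + rep)
            h0, ha, res = fit_branch_model(aln, tree, clade, n_restarts=1,
                                           seed=rep, branch_mode="fixed")
            hits += ha.params.branch_omega_fg < ha.params.class_omegas[0]
        assert hits >= 4

    def test_null_rarely_rejects(self):
        tree = make_study_tree(8, seed=6)
        clade = _smallest_clade(tree)
        rejections = 0
        for rep in range(6):
            aln, _ = simulate_codon_alignment(tree, [(1.0, 0.4)], 2.0, 200,
                                              seed=60 + rep)
            _, _, res = fit_branch_model(aln, tree, clade, n_restarts=1,
                                         seed=rep, branch_mode="fixed")
            rejections += res.statistic > 3.84
        assert rejections <= 1

    def test_missing_foreground_clade_lists_alternatives(self):
        tree = make_study_tree(6, seed=2)
        aln, _ = simulate_codon_alignment(tree, [(1.0, 0.4)], 2.0, 60, seed=1)
        with pytest.raises(SelectionError, match="available clades"):
            fit_branch_model(aln, tree, {"t00", "nonexistent"},
                             branch_mode="fixed")


class TestBranchSite:
    def test_alternative_dominates_null(self):
        tree = make_study_tree(8, seed=6)
        clade = _smallest_clade(tree)
        aln, _ = simulate_codon_alignment(tree, [(0.7, 0.1), (0.3, 1.0)],
                                          2.0, 150, seed=2)
        h0, ha, res = fit_branch_site_A(aln, tree, clade, n_restarts=1,
                                        seed=0, branch_mode="fixed")
        assert ha.lnL >= h0.lnL - 1e-6
        assert res.statistic >= 0.0


class TestSelectionReport:
    def test_identical_alignments_give_identical_rows_and_full_overlap(self):
        tree = make_study_tree(6, seed=9)
        aln, _ = simulate_codon_alignment(
            tree, [(0.6, 0.1), (0.3, 1.0), (0.1, 4.0)], 2.0, 150, seed=3)
        table, overlap = selection_report(
            [aln, aln], [tree, tree], labels=["one", "two"],
            models=("M1a", "M2a"), n_restarts=1, seed=4, branch_mode="fixed")
        r1, r2 = table.rows
        assert r1["lnl_m2a"] == pytest.approx(r2["lnl_m2a"], abs=0.01)
        assert overlap.rows[0]["jaccard"] == pytest.approx(1.0)

    def test_report_schema(self):
        tree = make_study_tree(6, seed=9)
        aln, _ = simulate_codon_alignment(tree, [(0.7, 0.2), (0.3, 1.0)],
                                          2.0, 90, seed=8)
        table, _ = selection_report([aln], [tree], models=("M1a", "M2a"),
                                    n_restarts=1, seed=0, branch_mode="fixed")
        row = table.rows[0]
        for col in ("lnl_m1a", "lnl_m2a", "lrt_m1a_m2a", "sig_m1a_m2a",
                    "flagged_sites", "mean_jaccard_vs_others"):
            assert col in row


def _smallest_clade(tree):
    from alnsens.treecmp import nontrivial_bipartitions
    best = None
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None or nd.is_leaf():
            continue
        clade = frozenset(l.taxon.label for l in nd.leaf_iter())
        if len(clade) < (len(tree.leaf_nodes()) - 1) and \
                (best is None or len(clade) < len(best)):
            best = clade
    return set(best)


def _simulate_branch_shift(tree, clade, w_bg, w_fg, n_codons, seed):
    """Simulate a single-class codon process whose omega switches on the
    foreground subtree (direct simulation, no indels)."""
    import dendropy

    from alnsens.selection import _codon_eigen

    rng = np.random.default_rng(seed)
    pi = np.full(N_CODONS, 1 / N_CODONS)
    Qb = codon_q_matrix(2.0, pi, [1.0], [w_bg])[0]
    Qf = codon_q_matrix(2.0, pi, [1.0], [w_fg])[0]
    eb, ef = _codon_eigen(Qb, pi), _codon_eigen(Qf, pi)
    mrca = tree.mrca(taxon_labels=sorted(clade))
    fg_nodes = {id(n) for n in mrca.preorder_iter()}
    rows = {}

    def walk(node, state, in_fg):
        for child in node.child_nodes():
            fg = in_fg or id(child) in fg_nodes
            A, Ainv, lam = ef if fg else eb
            P = np.clip((A * np.exp(lam * (child.edge.length or 0))) @ Ainv,
                        0, None)
            cum = P.cumsum(axis=1)
            u = rng.random(n_codons)
            st = np.minimum((cum[state] < u[:, None]).sum(axis=1), N_CODONS - 1)
            if child.is_leaf():
                rows[child.taxon.label] = st
            else:
                walk(child, st, fg)

    root = rng.integers(0, N_CODONS, n_codons)
    walk(tree.seed_node, root, False)
    return codon_aln(["".join(CODONS[s] for s in rows[lab])
                      for lab in sorted(rows)], sorted(rows))
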