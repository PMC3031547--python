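"""Tree inference and scoring.

Distance corrections and BioNJ give starting topologies; maximum-likelihood
scoring uses Felsenstein pruning under LG with a proportion of invariable
sites and a 4-category discrete gamma; topology search is NNI hill-climbing
from several starts; support is nonparametric bootstrap (fast BioNJ
replicates).  Fitch parsimony, midpoint rooting and tree size round out the
per-alignment battery.

Trees are dendropy ``Tree`` objects throughout; leaf taxon labels must match
alignment row ids.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import gamma as gamma_dist

from .io_formats import GAP, MultipleAlignment, read_newick

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"  # classical rate-matrix state order
_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

MIN_BRLEN = 1e-8
MAX_BRLEN = 20.0


# ---------------------------------------------------------------------------
# Substitution model

@dataclass
class ProteinSubstModel:
    """Reversible amino-acid model: exchangeabilities, frequencies, +I+G."""

    exchangeabilities: np.ndarray
    equilibrium_freqs: np.ndarray
    alpha: float = 1.0
    p_inv: float = 0.0
    n_rate_cats: int = 4

    def __post_init__(self):
        S = np.asarray(self.exchangeabilities, float)
        pi = np.asarray(self.equilibrium_freqs, float)
        if S.shape != (20, 20) or not np.allclose(S, S.T):
            raise ValueError("exchangeabilities must be symmetric 20x20")
        if abs(pi.sum() - 1.0) > 1e-9 or (pi < 0).any():
            raise ValueError("equilibrium frequencies must be a distribution")
        if self.alpha <= 0 or not (0 <= self.p_inv < 1):
            raise ValueError("need alpha > 0 and 0 <= p_inv < 1")
        self.exchangeabilities = S
        self.equilibrium_freqs = pi

    def rate_categories(self) -> np.ndarray:
        """Mean rates of ``n_rate_cats`` equal-probability gamma categories,
        rescaled by 1/(1 - p_inv) so the overall mean rate is 1."""
        rates = discrete_gamma_rates(self.alpha, self.n_rate_cats)
        return rates / (1.0 - self.p_inv)

    def eigen(self):
        """Symmetric eigendecomposition of Q = S diag(pi), normalized to one
        expected substitution per unit time."""
        return _reversible_eigen(self.exchangeabilities, self.equilibrium_freqs)


def discrete_gamma_rates(alpha: float, k: int = 4) -> np.ndarray:
    """Category means of a mean-one gamma split into k equal-probability bins."""
    edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), alpha, scale=1.0 / alpha)
    upper = gamma_dist.cdf(edges[1:], alpha + 1, scale=1.0 / alpha)
    lower = gamma_dist.cdf(edges[:-1], alpha + 1, scale=1.0 / alpha)
    rates = k * (upper - lower)
    return rates / rates.mean() * 1.0


def _reversible_eigen(S: np.ndarray, pi: np.ndarray):
    """Eigen-decompose Q = S diag(pi) (off-diagonal), scaled to unit mean rate.

    Returns (A, Ainv, lam) with P(t) = A @ diag(exp(lam t)) @ Ainv.
    """
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(pi * np.diag(Q)).sum()
    Q = Q / mu
    sp = np.sqrt(pi)
    B = Q * (sp[:, None] / sp[None, :])
    B = (B + B.T) / 2.0
    lam, V = np.linalg.eigh(B)
    A = V / sp[:, None]
    Ainv = V.T * sp[None, :]
    return A, Ainv, lam


def lg_model(freqs: np.ndarray | None = None, alpha: float = 1.0,
             p_inv: float = 0.0, n_rate_cats: int = 4) -> ProteinSubstModel:
    """The LG replacement model, optionally with +F frequencies."""
    ref = importlib.resources.files("alnsens.data").joinpath("lg_model.txt")
    rows = [
        [float(x) for x in line.split()]
        for line in ref.read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    S = np.array(rows[:20])
    pi = np.array(rows[20]) if freqs is None else np.asarray(freqs, float)
    pi = pi / pi.sum()
    return ProteinSubstModel(S, pi, alpha=alpha, p_inv=p_inv, n_rate_cats=n_rate_cats)


def empirical_aa_freqs(aln: MultipleAlignment, pseudocount: float = 1.0) -> np.ndarray:
    counts = np.full(20, pseudocount)
    for rec in aln.records:
        for ch in rec.seq:
            i = _AA_INDEX.get(ch)
            if i is not None:
                counts[i] += 1
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# Distances

def protein_distance(a: str, b: str, correction: str = "poisson",
                     alpha: float = 1.0) -> float:
    """Pairwise distance from two aligned rows over shared non-gap columns."""
    shared = eq = 0
    for x, y in zip(a, b):
        if x in _AA_INDEX and y in _AA_INDEX:
            shared += 1
            if x == y:
                eq += 1
    if shared == 0:
        raise ValueError("no shared non-gap columns between rows")
    p = 1.0 - eq / shared
    if correction == "p":
        return p
    if p >= 1.0 - 1e-9:
        return float("inf")
    if correction == "poisson":
        return -np.log(1.0 - p)
    if correction == "gamma":
        return alpha * ((1.0 - p) ** (-1.0 / alpha) - 1.0)
    raise ValueError(f"unknown correction {correction!r}")


def distance_matrix(aln: MultipleAlignment, correction: str = "poisson",
                    alpha: float = 1.0, cap_factor: float = 2.0) -> tuple[np.ndarray, list[str]]:
    """All-pairs distance matrix; saturated (infinite) entries are capped at
    ``cap_factor`` times the largest finite distance."""
    n = aln.n_rows
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = protein_distance(aln.records[i].seq, aln.records[j].seq,
                                     correction, alpha)
            except ValueError:
                d = float("inf")
            D[i, j] = D[j, i] = d
    finite = D[np.isfinite(D)]
    cap = cap_factor * finite.max() if finite.size and finite.max() > 0 else 1.0
    D[~np.isfinite(D)] = cap
    return D, aln.ids


# ---------------------------------------------------------------------------
# BioNJ

def bionj(D: np.ndarray, labels: list[str]) -> dendropy.Tree:
    """Neighbor joining with BioNJ variance weighting.

    Ties in the selection criterion break toward the lowest index pair;
    negative branch estimates are clamped to zero.  Returns an unrooted tree
    (trifurcating seed node).
    """
    D = np.asarray(D, float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if np.abs(np.diag(D)).max() > 1e-12:
        raise ValueError("distance matrix must have a zero diagonal")
    if n < 3:
        raise ValueError("need at least 3 taxa")

    taxa = dendropy.TaxonNamespace(labels)
    nodes = [dendropy.Node(taxon=taxa.get_taxon(lab)) for lab in labels]
    D = D.copy()
    V = D.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        idx = np.array(active)
        sub = D[np.ix_(idx, idx)]
        r = sub.sum(axis=1)
        Qm = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Qm, np.inf)
        a, b = divmod(np.argmin(Qm), m)
        if a > b:
            a, b = b, a
        i, j = idx[a], idx[b]
        dij = D[i, j]
        li = 0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)

        parent = dendropy.Node()
        parent.add_child(nodes[i]); nodes[i].edge.length = li
        parent.add_child(nodes[j]); nodes[j].edge.length = lj

        rest = [k for k in active if k not in (i, j)]
        vij = V[i, j]
        if vij > 1e-12 and len(rest) > 0:
            lam = 0.5 + (V[i, rest].sum() - V[j, rest].sum()) / (2 * (m - 2) * vij)
            lam = min(1.0, max(0.0, lam))
        else:
            lam = 0.5
        for k in rest:
            dk = lam * (D[i, k] - li) + (1 - lam) * (D[j, k] - lj)
            vk = lam * V[i, k] + (1 - lam) * V[j, k] - lam * (1 - lam) * vij
            D[i, k] = D[k, i] = max(dk, 0.0)
            V[i, k] = V[k, i] = max(vk, 0.0)
        nodes[i] = parent
        active.remove(j)

    i, j, k = active
    root = dendropy.Node()
    dij, dik, djk = D[i, j], D[i, k], D[j, k]
    li = max(0.0, (dij + dik - djk) / 2)
    lj = max(0.0, (dij + djk - dik) / 2)
    lk = max(0.0, (dik + djk - dij) / 2)
    for node, ln in ((nodes[i], li), (nodes[j], lj), (nodes[k], lk)):
        root.add_child(node)
        node.edge.length = ln
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Pruning engine (shared by the protein and codon likelihoods)

def _alignment_to_ints(aln: MultipleAlignment) -> np.ndarray:
    mat = np.full((aln.n_rows, aln.n_cols), -1, dtype=np.int64)
    for r, rec in enumerate(aln.records):
        for c, ch in enumerate(rec.seq):
            mat[r, c] = _AA_INDEX.get(ch, -1)
    return mat


def compress_patterns(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique columns and their multiplicities."""
    patterns, counts = np.unique(mat.T, axis=0, return_counts=True)
    return patterns.T, counts.astype(float)


class PruningEngine:
    """Indexed topology + site patterns for repeated pruning passes.

    The tree is taken as rooted at its seed node (any multifurcation is
    fine for reversible models).  ``patterns`` is (n_rows, n_patterns) of
    state indices with -1 for missing; rows follow ``row_ids``.
    """

    def __init__(self, tree: dendropy.Tree, row_ids: list[str],
                 patterns: np.ndarray, n_states: int):
        self.n_states = n_states
        self.patterns = patterns
        row_index = {rid: i for i, rid in enumerate(row_ids)}
        post = list(tree.postorder_node_iter())
        self.nodes = post
        self.index = {id(nd): i for i, nd in enumerate(post)}
        self.parent = np.full(len(post), -1, dtype=int)
        self.children: list[list[int]] = [[] for _ in post]
        self.lengths = np.zeros(len(post))
        self.leaf_row = np.full(len(post), -1, dtype=int)
        leaf_labels = set()
        for i, nd in enumerate(post):
            if nd.parent_node is not None:
                p = self.index[id(nd.parent_node)]
                self.parent[i] = p
                self.children[p].append(i)
                self.lengths[i] = nd.edge.length if nd.edge.length else 0.0
            if nd.is_leaf():
                lab = nd.taxon.label
                leaf_labels.add(lab)
                if lab not in row_index:
                    raise ValueError(f"tree leaf {lab!r} missing from alignment")
                self.leaf_row[i] = row_index[lab]
        if leaf_labels != set(row_ids):
            raise ValueError("tree leaves and alignment rows differ: "
                             f"{sorted(set(row_ids) ^ leaf_labels)}")
        self.root = len(post) - 1
        self.n_pat = patterns.shape[1]

    def edge_indices(self) -> list[int]:
        return [i for i in range(len(self.nodes)) if self.parent[i] >= 0]

    def child_message(self, P: np.ndarray, i: int, B: list) -> np.ndarray:
        """Message P(t_i) applied to the partial below node i.

        Leaf partials are one-hot, so for a leaf this is a column gather of
        P (missing data gives a column of ones).
        """
        if self.leaf_row[i] >= 0:
            states = self.patterns[self.leaf_row[i]]
            M = np.ones((self.n_states, self.n_pat))
            ok = states >= 0
            M[:, ok] = P[:, states[ok]]
            return M
        return P @ B[i]

    def below(self, P: list[np.ndarray | None]):
        """Postorder partials for one rate class.

        ``P[i]`` is the transition matrix along the edge above node i.
        Returns (B, Bscale): B[i] is (S, n_pat) for internal nodes (leaves
        stay implicit one-hot); Bscale[i] is the per-pattern cumulative log
        rescaling applied within the subtree of i.
        """
        B: list[np.ndarray | None] = [None] * len(self.nodes)
        Bscale: list[np.ndarray | None] = [None] * len(self.nodes)
        for i in range(len(self.nodes)):
            if self.leaf_row[i] >= 0:
                continue
            acc = np.ones((self.n_states, self.n_pat))
            sc = np.zeros(self.n_pat)
            for c in self.children[i]:
                acc *= self.child_message(P[c], c, B)
                if Bscale[c] is not None:
                    sc += Bscale[c]
            mx = acc.max(axis=0)
            mx[mx == 0] = 1.0
            acc /= mx
            B[i] = acc
            Bscale[i] = sc + np.log(mx)
        return B, Bscale

    def site_loglikes(self, P: list[np.ndarray], pi: np.ndarray) -> np.ndarray:
        """Per-pattern log site likelihood for one rate class."""
        B, Bscale = self.below(P)
        site = pi @ B[self.root]
        site = np.maximum(site, 1e-300)
        return np.log(site) + Bscale[self.root]


def mix_site_loglikes(class_loglikes: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """log sum_k w_k exp(l_k) per pattern, computed stably."""
    m = class_loglikes.max(axis=0)
    return m + np.log(np.clip(
        (weights[:, None] * np.exp(class_loglikes - m[None, :])).sum(axis=0),
        1e-300, None))


# ---------------------------------------------------------------------------
# Protein likelihood

def _invariant_site_logl(patterns: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Per-pattern sum of pi over states compatible with a constant column."""
    n_pat = patterns.shape[1]
    out = np.zeros(n_pat)
    for p in range(n_pat):
        col = patterns[:, p]
        obs = set(col[col >= 0])
        if len(obs) == 0:
            out[p] = 1.0
        elif len(obs) == 1:
            out[p] = pi[obs.pop()]
        else:
            out[p] = 0.0
    return out


class ProteinLikelihood:
    """LG(+F)+I+G likelihood of an amino-acid alignment on a tree."""

    def __init__(self, tree: dendropy.Tree, aln: MultipleAlignment,
                 model: ProteinSubstModel):
        mat = _alignment_to_ints(aln)
        patterns, weights = compress_patterns(mat)
        self.engine = PruningEngine(tree, aln.ids, patterns, 20)
        self.weights = weights
        self.model = model
        self.A, self.Ainv, self.lam = model.eigen()
        self.pi = model.equilibrium_freqs
        self.inv_like = _invariant_site_logl(patterns, self.pi)

    def transition(self, t: float, rate: float = 1.0) -> np.ndarray:
        P = (self.A * np.exp(self.lam * rate * t)) @ self.Ainv
        return np.clip(P, 0.0, None)

    def _edge_P(self, lengths: np.ndarray, rate: float) -> list:
        eng = self.engine
        P: list[np.ndarray | None] = [None] * len(eng.nodes)
        for i in eng.edge_indices():
            P[i] = self.transition(lengths[i], rate)
        return P

    def site_logls(self, lengths: np.ndarray | None = None) -> np.ndarray:
        """Per-pattern log likelihoods mixing +I and the gamma categories."""
        eng = self.engine
        lengths = eng.lengths if lengths is None else lengths
        rates = self.model.rate_categories()
        cls = np.array([self.engine.site_loglikes(self._edge_P(lengths, r), self.pi)
                        for r in rates])
        mixed = mix_site_loglikes(cls, np.full(len(rates), 1.0 / len(rates)))
        p_inv = self.model.p_inv
        if p_inv == 0:
            return mixed
        return np.logaddexp(
            np.log(np.clip(p_inv * self.inv_like, 1e-300, None)),
            np.log1p(-p_inv) + mixed)

    def site_likelihoods(self, lengths: np.ndarray | None = None) -> np.ndarray:
        return np.exp(self.site_logls(lengths))

    def loglik(self, lengths: np.ndarray | None = None) -> float:
        return float(self.weights @ self.site_logls(lengths))

    # -- branch-length optimization with message caching -------------------

    def optimize_branch_lengths(self, max_cycles: int = 50, tol: float = 1e-6):
        """Coordinate-wise Brent over branches, cycling until the improvement
        drops below ``tol``.

        Each sweep recomputes subtree partials once (postorder), then walks
        the tree preorder keeping exact "rest-of-tree" contexts up to date,
        so every per-branch 1-D optimization is an exact coordinate ascent.
        """
        eng = self.engine
        lengths = np.maximum(eng.lengths.copy(), MIN_BRLEN)
        best = self.loglik(lengths)
        rates = self.model.rate_categories()
        K = len(rates)
        wk = np.full(K, 1.0 / K)
        inv_part = self.model.p_inv * self.inv_like
        for _ in range(max_cycles):
            Bs, Bscales, Ps = [], [], []
            for r in rates:
                P = self._edge_P(lengths, r)
                B, Bsc = eng.below(P)
                Bs.append(B); Bscales.append(Bsc); Ps.append(P)
            # preorder contexts per class; root context = pi, scale 0
            C = [[None] * len(eng.nodes) for _ in range(K)]
            Csc = [[None] * len(eng.nodes) for _ in range(K)]
            for k in range(K):
                C[k][eng.root] = np.tile(self.pi[:, None], (1, eng.n_pat))
                Csc[k][eng.root] = np.zeros(eng.n_pat)
            order = [i for i in reversed(range(len(eng.nodes)))
                     if eng.parent[i] >= 0]
            for i in order:
                p = eng.parent[i]
                tops, topscales = [], []
                for k in range(K):
                    top = C[k][p].copy()
                    tsc = Csc[k][p].copy()
                    for s in eng.children[p]:
                        if s != i:
                            top *= eng.child_message(Ps[k][s], s, Bs[k])
                            if Bscales[k][s] is not None:
                                tsc += Bscales[k][s]
                    mx = top.max(axis=0); mx[mx == 0] = 1.0
                    top /= mx
                    tops.append(top)
                    topscales.append(tsc + np.log(mx))
                own = [Bscales[k][i] if Bscales[k][i] is not None else 0.0
                       for k in range(K)]

                def edge_logl(t: float) -> float:
                    per = np.empty((K, eng.n_pat))
                    for k in range(K):
                        msg = eng.child_message(self.transition(t, rates[k]),
                                                i, Bs[k])
                        site = np.einsum("sp,sp->p", tops[k], msg)
                        per[k] = np.log(np.clip(site, 1e-300, None)) \
                            + topscales[k] + own[k]
                    mixed = mix_site_loglikes(per, wk)
                    tot = inv_part + (1 - self.model.p_inv) * np.exp(mixed)
                    return float(self.weights @ np.log(np.clip(tot, 1e-300, None)))

                cur = edge_logl(lengths[i])
                res = minimize_scalar(lambda t: -edge_logl(t),
                                      bounds=(MIN_BRLEN, MAX_BRLEN),
                                      method="bounded",
                                      options={"xatol": 1e-8})
                if -res.fun >= cur:
                    lengths[i] = float(res.x)
                # descend with the updated length
                for k in range(K):
                    Ps[k][i] = self.transition(lengths[i], rates[k])
                    Ci = Ps[k][i].T @ tops[k]
                    mx = Ci.max(axis=0); mx[mx == 0] = 1.0
                    C[k][i] = Ci / mx
                    Csc[k][i] = topscales[k] + np.log(mx)
            new = self.loglik(lengths)
            gain, best = new - best, max(new, best)
            if gain < tol:
                break
        eng.lengths = lengths
        return lengths, best

    def write_back(self, tree_lengths: np.ndarray | None = None) -> None:
        """Copy optimized lengths back onto the dendropy nodes."""
        eng = self.engine
        lengths = eng.lengths if tree_lengths is None else tree_lengths
        for i, nd in enumerate(eng.nodes):
            if eng.parent[i] >= 0:
                nd.edge.length = float(lengths[i])


def tree_loglik(tree: dendropy.Tree, aln: MultipleAlignment,
                model: ProteinSubstModel) -> float:
    """Log-likelihood of ``aln`` on ``tree`` under ``model`` (gaps missing)."""
    return ProteinLikelihood(tree, aln, model).loglik()


def optimize_branch_lengths(tree: dendropy.Tree, aln: MultipleAlignment,
                            model: ProteinSubstModel,
                            estimate_alpha: bool = False,
                            estimate_pinv: bool = False,
                            max_cycles: int = 50,
                            tol: float = 1e-6):
    """Optimize branch lengths (and optionally alpha / p_inv) in place.

    Returns (tree, lnL).  Alpha and p_inv use bounded 1-D searches
    interleaved with branch sweeps.
    """
    lik = ProteinLikelihood(tree, aln, model)
    _, best = lik.optimize_branch_lengths(max_cycles=5, tol=tol)

    def scan(setter, lo, hi, current):
        def neg(x):
            setter(float(x))
            return -lik.loglik()

        res = minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-4})
        if -neg(res.x) >= -neg(current):
            setter(float(res.x))
            return -neg(res.x)
        setter(current)
        return -neg(current)

    for _ in range(6):
        start = best
        if estimate_alpha:
            best = scan(lambda a: setattr(model, "alpha", a), 0.05, 50.0,
                        model.alpha)
        if estimate_pinv:
            best = scan(lambda p: setattr(model, "p_inv", p), 0.0, 0.7,
                        model.p_inv)
        _, best = lik.optimize_branch_lengths(max_cycles=3, tol=tol)
        if best - start < tol and not (estimate_alpha or estimate_pinv):
            break
        if best - start < tol:
            break
    lik.write_back()
    return tree, best


# ---------------------------------------------------------------------------
# NNI search

def _clone(tree: dendropy.Tree) -> dendropy.Tree:
    return dendropy.Tree(tree)


def _nni_neighbors(tree: dendropy.Tree):
    """Yield cloned trees one NNI move away (internal edges only)."""
    edges = []
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None and nd.is_internal():
            edges.append(nd)
    for v in edges:
        key = _node_key(v)
        for swap in (0, 1):
            nb = _clone(tree)
            _apply_nni(nb, key, swap)
            yield nb


def _node_key(v: dendropy.Node) -> frozenset:
    return frozenset(lf.taxon.label for lf in v.leaf_iter())


def _apply_nni(tree: dendropy.Tree, clade_key: frozenset, swap: int) -> None:
    v = None
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None and nd.is_internal() \
                and _node_key(nd) == clade_key:
            v = nd
            break
    if v is None:
        raise ValueError("internal edge not found for NNI")
    u = v.parent_node
    if u.parent_node is not None:
        tree.reroot_at_node(u, update_bipartitions=False)
        tree.suppress_unifurcations()
        u = v.parent_node
    sibs = [c for c in u.child_nodes() if c is not v]
    s = sibs[swap % len(sibs)]
    a = v.child_nodes()[0]
    la, ls = a.edge.length, s.edge.length
    v.remove_child(a)
    u.remove_child(s)
    v.add_child(s); s.edge.length = ls
    u.add_child(a); a.edge.length = la


def random_resolved_tree(labels: list[str], rng: np.random.Generator) -> dendropy.Tree:
    """Random topology by sequential addition, branch lengths 0.1."""
    labels = list(labels)
    order = list(rng.permutation(len(labels)))
    taxa = dendropy.TaxonNamespace(labels)
    root = dendropy.Node()
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    first = [dendropy.Node(taxon=taxa.get_taxon(labels[i])) for i in order[:3]]
    for nd in first:
        root.add_child(nd)
        nd.edge.length = 0.1
    for i in order[3:]:
        edges = [nd for nd in tree.preorder_node_iter() if nd.parent_node is not None]
        target = edges[int(rng.integers(len(edges)))]
        parent = target.parent_node
        mid = dendropy.Node()
        parent.remove_child(target)
        parent.add_child(mid)
        mid.edge.length = 0.05
        mid.add_child(target); target.edge.length = max(target.edge.length or 0.1, 0.05)
        leaf = dendropy.Node(taxon=taxa.get_taxon(labels[i]))
        mid.add_child(leaf); leaf.edge.length = 0.1
    tree.is_rooted = False
    return tree


def nni_search(tree: dendropy.Tree, aln: MultipleAlignment,
               model: ProteinSubstModel, n_starts: int = 5,
               seed: int = 0, max_rounds: int = 20):
    """NNI hill-climb; best of ``n_starts`` (given tree + random resolutions).

    Neighbor moves are scored with current branch lengths; each accepted
    move triggers a branch-length re-optimization.
    """
    if len(aln.ids) < 4:
        raise ValueError("NNI search needs at least 4 taxa")
    rng = np.random.default_rng(seed)
    starts = [_clone(tree)]
    for _ in range(max(0, n_starts - 1)):
        starts.append(random_resolved_tree(aln.ids, rng))
    overall_best, overall_lnl = None, -np.inf
    for start in starts:
        cur = start
        lik = ProteinLikelihood(cur, aln, model)
        _, cur_lnl = lik.optimize_branch_lengths(max_cycles=3)
        lik.write_back()
        for _ in range(max_rounds):
            best_nb, best_nb_lnl = None, cur_lnl
            for nb in _nni_neighbors(cur):
                lnl = tree_loglik(nb, aln, model)
                if lnl > best_nb_lnl + 1e-9:
                    best_nb, best_nb_lnl = nb, lnl
            if best_nb is None:
                break
            cur = best_nb
            lik = ProteinLikelihood(cur, aln, model)
            _, cur_lnl = lik.optimize_branch_lengths(max_cycles=3)
            lik.write_back()
        if cur_lnl > overall_lnl:
            overall_best, overall_lnl = cur, cur_lnl
    return overall_best, overall_lnl


# ---------------------------------------------------------------------------
# Bootstrap support

def _bipartition_set(tree: dendropy.Tree) -> set[frozenset]:
    labels = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = min(labels)
    out = set()
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None or nd.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if len(side) < 2 or len(labels) - len(side) < 2:
            continue
        out.add(side if ref not in side else labels - side)
    return out


def bootstrap_support(tree: dendropy.Tree, aln: MultipleAlignment,
                      model: ProteinSubstModel, n_reps: int = 100,
                      seed: int = 0) -> dendropy.Tree:
    """Nonparametric bootstrap: resample columns, fast BioNJ replicate trees,
    map bipartition frequencies onto the internal edges of ``tree``."""
    if n_reps == 0:
        return tree
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    cols = [aln.column(j) for j in range(aln.n_cols)]
    for _ in range(n_reps):
        pick = rng.integers(0, aln.n_cols, aln.n_cols)
        rows = ["".join(cols[j][r] for j in pick) for r in range(aln.n_rows)]
        rep = MultipleAlignment(tuple(
            type(rec)(rec.id, row, rec.moltype, gapped=True)
            for rec, row in zip(aln.records, rows)), method_label="boot")
        D, labels = distance_matrix(rep, correction="poisson")
        rep_tree = bionj(D, labels)
        for bp in _bipartition_set(rep_tree):
            counts[bp] = counts.get(bp, 0) + 1
    labels = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = min(labels)
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None or nd.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if len(side) < 2 or len(labels) - len(side) < 2:
            continue
        key = side if ref not in side else labels - side
        nd.edge.support = counts.get(key, 0) / n_reps
        nd.label = f"{nd.edge.support:.3f}"
    return tree


def mean_internal_support(tree: dendropy.Tree) -> float:
    vals = [nd.edge.support for nd in tree.preorder_node_iter()
            if nd.parent_node is not None and nd.is_internal()
            and getattr(nd.edge, "support", None) is not None]
    return float(np.mean(vals)) if vals else float("nan")


# ---------------------------------------------------------------------------
# Parsimony, rooting, tree size

def fitch_parsimony(tree: dendropy.Tree, aln: MultipleAlignment) -> int:
    """Fitch step count over columns; gaps and ambiguity are missing data
    (they behave neutrally in the set unions)."""
    mat = _alignment_to_ints(aln)
    rows = {rid: i for i, rid in enumerate(aln.ids)}
    leaf_set = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if leaf_set != set(aln.ids):
        raise ValueError("tree leaves and alignment rows differ")
    full = (1 << 20) - 1
    post = list(tree.postorder_node_iter())
    steps = 0
    for j in range(aln.n_cols):
        state: dict[int, int] = {}
        for nd in post:
            if nd.is_leaf():
                s = mat[rows[nd.taxon.label], j]
                state[id(nd)] = full if s < 0 else (1 << int(s))
            else:
                acc = full
                for c in nd.child_nodes():
                    inter = acc & state[id(c)]
                    if inter:
                        acc = inter
                    else:
                        acc = acc | state[id(c)]
                        steps += 1
                state[id(nd)] = acc
    return steps


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root at the midpoint of the longest leaf-to-leaf path (in place)."""
    total = sum(e.length or 0.0 for e in tree.preorder_edge_iter())
    if total <= 0:
        warnings.warn("zero-length tree: midpoint undefined, rooting at seed node")
        tree.is_rooted = True
        return tree
    tree.reroot_at_midpoint(update_bipartitions=False)
    tree.is_rooted = True
    return tree


def tree_size(tree: dendropy.Tree) -> float:
    """Sum of branch lengths."""
    return float(sum(e.length or 0.0 for e in tree.preorder_edge_iter()))


def leaf_distance_matrix(tree: dendropy.Tree) -> tuple[np.ndarray, list[str]]:
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    n = len(taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return D, [t.label for t in taxa]
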