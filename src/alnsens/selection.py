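"""Codon-model tests of positive selection.

A Goldman–Yang-style codon process (61 sense codons, universal code) with
F3x4 equilibrium frequencies underlies the classical site-model battery
(M0, M1a/M2a, M7/M8), two-ratio branch models, and branch-site model A on a
designated foreground branch.  Nested pairs are compared by likelihood-ratio
tests; sites in the positively selected class are identified by empirical
Bayes posteriors (naive EB at the MLEs by default, with a coarse-grid
"beb-lite" option that integrates over mixture-parameter uncertainty).

Implementation notes.  Site-class likelihoods are computed by Felsenstein
pruning with per-class rate matrices.  During optimization each class matrix
is normalized by the rate of the matching omega=1 matrix, which keeps the
relative speeds of the classes correct while making per-class site
likelihoods independent of the class proportions; the overall time scale is
absorbed by a free branch-scale multiplier, and reported branch lengths are
converted back to expected substitutions per codon at the fitted mixture
mean.  This is a pure reparametrization of the usual mixture-mean scaling
and allows aggressive caching across optimizer steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import beta as beta_dist
from scipy.stats import chi2
from scipy.stats import qmc
from Bio.Data import CodonTable

from .io_formats import GAP, MultipleAlignment, ReportTable
from .phylo import PruningEngine, compress_patterns, mix_site_loglikes

NT = "ACGT"
_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = tuple(sorted(_TABLE.stop_codons))
CODONS = tuple(sorted(c for c in ("".join((a, b, c))
                                  for a in NT for b in NT for c in NT)
                      if c not in STOP_CODONS))
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
AA_OF_CODON = "".join(_TABLE.forward_table[c] for c in CODONS)
N_CODONS = len(CODONS)  # 61

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _single_diff_pairs():
    pi_, pj_, ts_, ns_ = [], [], [], []
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            pi_.append(i); pj_.append(j)
            ts_.append(diffs[0] in _TRANSITIONS)
            ns_.append(AA_OF_CODON[i] != AA_OF_CODON[j])
    return (np.array(pi_), np.array(pj_), np.array(ts_), np.array(ns_))

_PAIR_I, _PAIR_J, _PAIR_TS, _PAIR_NS = _single_diff_pairs()


class SelectionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Frequencies and rate matrices

def f3x4(codon_aln: MultipleAlignment) -> np.ndarray:
    """F3x4 codon frequencies: empirical nucleotide frequencies at each codon
    position, multiplied per sense codon and renormalized over the 61."""
    if codon_aln.n_cols % 3 != 0:
        raise SelectionError("codon alignment length is not a multiple of 3")
    counts = np.zeros((3, 4))
    nt_index = {n: i for i, n in enumerate(NT)}
    for rec in codon_aln.records:
        for pos, ch in enumerate(rec.seq):
            i = nt_index.get(ch)
            if i is not None:
                counts[pos % 3, i] += 1
    if (counts.sum(axis=1) == 0).any():
        raise SelectionError("cannot estimate F3x4: empty codon position")
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array([freqs[0, nt_index[c[0]]]
                   * freqs[1, nt_index[c[1]]]
                   * freqs[2, nt_index[c[2]]] for c in CODONS])
    return pi / pi.sum()


def codon_rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """Unnormalized GY94-style generator: single-nucleotide changes only,
    proportional to the target frequency, times kappa for transitions and
    omega for nonsynonymous changes.  Rows sum to zero."""
    Q = np.zeros((N_CODONS, N_CODONS))
    rates = pi[_PAIR_J] * np.where(_PAIR_TS, kappa, 1.0) \
        * np.where(_PAIR_NS, omega, 1.0)
    Q[_PAIR_I, _PAIR_J] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _matrix_rate(Q: np.ndarray, pi: np.ndarray) -> float:
    return float(-(pi * np.diag(Q)).sum())


def codon_q_matrix(kappa: float, pi: np.ndarray,
                   class_proportions, class_omegas) -> list[np.ndarray]:
    """Per-class generators scaled jointly so the mixture mean rate is one
    expected substitution per codon per unit time."""
    props = np.asarray(class_proportions, float)
    if abs(props.sum() - 1.0) > 1e-9 or (props < 0).any():
        raise SelectionError("class proportions must lie on the simplex")
    Qs = [codon_rate_matrix(kappa, w, pi) for w in class_omegas]
    mean_rate = sum(p * _matrix_rate(Q, pi) for p, Q in zip(props, Qs))
    if mean_rate <= 0:
        raise SelectionError("degenerate codon model: zero mean rate")
    return [Q / mean_rate for Q in Qs]


def _codon_eigen(Q: np.ndarray, pi: np.ndarray):
    sp = np.sqrt(pi)
    B = Q * (sp[:, None] / sp[None, :])
    B = (B + B.T) / 2.0
    lam, V = np.linalg.eigh(B)
    A = V / sp[:, None]
    Ainv = V.T * sp[None, :]
    return A, Ainv, lam


# ---------------------------------------------------------------------------
# Encoding

def translate_codon_row(seq: str) -> str:
    out = []
    for s in range(0, len(seq), 3):
        codon = seq[s : s + 3]
        if codon == "---":
            out.append(GAP)
        elif GAP in codon or "N" in codon:
            out.append("X")
        else:
            out.append("*" if codon in STOP_CODONS else _TABLE.forward_table[codon])
    return "".join(out)


def encode_codon_alignment(aln: MultipleAlignment):
    """Integer codon matrix (-1 = missing); stop codons are an error.

    Returns (matrix, kept_site_indices); all-gap codon sites are dropped
    with a warning.
    """
    if aln.n_cols % 3 != 0:
        raise SelectionError("codon alignment length is not a multiple of 3")
    n_sites = aln.n_cols // 3
    mat = np.full((aln.n_rows, n_sites), -1, dtype=np.int64)
    for r, rec in enumerate(aln.records):
        for s in range(n_sites):
            codon = rec.seq[3 * s : 3 * s + 3]
            if GAP in codon or "N" in codon:
                continue
            if codon in STOP_CODONS:
                raise SelectionError(
                    f"stop codon {codon} in row {rec.id!r} at codon site {s + 1}")
            mat[r, s] = CODON_INDEX[codon]
    keep = np.nonzero((mat >= 0).any(axis=0))[0]
    if len(keep) < n_sites:
        warnings.warn(f"dropping {n_sites - len(keep)} all-gap codon sites")
    return mat[:, keep], keep


# ---------------------------------------------------------------------------
# Likelihood engine

class CodonLikelihood:
    """Pruning likelihood for codon site-class mixtures on a fixed topology.

    Branch lengths are ``scale * base_lengths``; per-class site log-likelihood
    vectors are cached across optimizer steps (they do not depend on the
    class proportions).
    """

    def __init__(self, tree: dendropy.Tree, codon_aln: MultipleAlignment,
                 pi: np.ndarray | None = None):
        self.tree = tree
        mat, self.kept_sites = encode_codon_alignment(codon_aln)
        patterns, weights = compress_patterns(mat)
        # pattern index per retained site (for site posteriors)
        _, inverse = np.unique(mat.T, axis=0, return_inverse=True)
        self.pattern_of_site = inverse
        self.engine = PruningEngine(tree, codon_aln.ids, patterns, N_CODONS)
        self.weights = weights
        self.pi = f3x4(codon_aln) if pi is None else np.asarray(pi, float)
        self.base_lengths = np.maximum(self.engine.lengths.copy(), 1e-8)
        self.fg_edges: set[int] = set()
        self._cache: dict = {}
        self._eigen_cache: dict = {}

    # -- foreground handling ------------------------------------------------

    def set_foreground(self, leaf_set) -> None:
        """Mark the edge subtending exactly ``leaf_set`` as foreground."""
        want = frozenset(leaf_set)
        eng = self.engine
        found = None
        clades = []
        for i in eng.edge_indices():
            clade = frozenset(
                lf.taxon.label for lf in eng.nodes[i].leaf_iter())
            clades.append(clade)
            if clade == want:
                found = i
        if found is None:
            listing = "; ".join(",".join(sorted(c)) for c in clades)
            raise SelectionError(
                f"no edge subtends {sorted(want)}; available clades: {listing}")
        self.fg_edges = {found}
        self._cache.clear()

    # -- per-class site log-likelihoods -------------------------------------

    def _eigen(self, kappa: float, omega: float):
        key = (round(kappa, 12), round(omega, 12))
        if key not in self._eigen_cache:
            Q = codon_rate_matrix(kappa, omega, self.pi)
            ref = _matrix_rate(codon_rate_matrix(kappa, 1.0, self.pi), self.pi)
            self._eigen_cache[key] = _codon_eigen(Q / ref, self.pi)
        return self._eigen_cache[key]

    def _edge_P(self, kappa: float, omega: float, scale: float,
                fg_omega: float | None):
        eng = self.engine
        edges = eng.edge_indices()
        t = scale * self.base_lengths[edges]
        A, Ainv, lam = self._eigen(kappa, omega)
        D = np.exp(np.outer(t, lam))
        block = np.einsum("ij,ej->eij", A, D) @ Ainv
        np.clip(block, 0.0, None, out=block)
        P: list[np.ndarray | None] = [None] * len(eng.nodes)
        for k, i in enumerate(edges):
            P[i] = block[k]
        if fg_omega is not None and self.fg_edges:
            Af, Ainvf, lamf = self._eigen(kappa, fg_omega)
            for i in self.fg_edges:
                tf = scale * self.base_lengths[i]
                P[i] = np.clip((Af * np.exp(lamf * tf)) @ Ainvf, 0.0, None)
        return P

    def class_site_loglikes(self, kappa: float, omega: float, scale: float,
                            fg_omega: float | None = None) -> np.ndarray:
        key = (round(kappa, 12), round(omega, 12), round(scale, 12),
               None if fg_omega is None else round(fg_omega, 12))
        hit = self._cache.get(key)
        if hit is None:
            P = self._edge_P(kappa, omega, scale, fg_omega)
            hit = self.engine.site_loglikes(P, self.pi)
            self._cache[key] = hit
        return hit

    def mixture_loglik(self, kappa: float, scale: float, props, omegas,
                       fg_omegas=None) -> float:
        cls = np.array([
            self.class_site_loglikes(
                kappa, w, scale,
                None if fg_omegas is None else fg_omegas[c])
            for c, w in enumerate(omegas)])
        return float(self.weights @ mix_site_loglikes(cls, np.asarray(props, float)))

    def class_posteriors(self, kappa, scale, props, omegas, fg_omegas=None) -> np.ndarray:
        """Per-class posterior probabilities per retained site (NEB)."""
        cls = np.array([
            self.class_site_loglikes(
                kappa, w, scale,
                None if fg_omegas is None else fg_omegas[c])
            for c, w in enumerate(omegas)])
        logw = np.log(np.clip(np.asarray(props, float), 1e-300, None))[:, None]
        lp = cls + logw
        lp -= lp.max(axis=0, keepdims=True)
        post = np.exp(lp)
        post /= post.sum(axis=0, keepdims=True)
        return post[:, self.pattern_of_site]

    # -- M0 branch-length optimization --------------------------------------

    def optimize_branches_m0(self, kappa: float, omega: float,
                             max_cycles: int = 3, tol: float = 1e-5) -> float:
        """Coordinate-wise branch optimization under a one-class model,
        exact contexts maintained along a preorder sweep."""
        eng = self.engine
        lengths = self.base_lengths.copy()
        A, Ainv, lam = self._eigen(kappa, omega)

        def trans(t):
            return np.clip((A * np.exp(lam * t)) @ Ainv, 0.0, None)

        def full(lengths_):
            P = [None] * len(eng.nodes)
            for i in eng.edge_indices():
                P[i] = trans(lengths_[i])
            return float(self.weights @ eng.site_loglikes(P, self.pi))

        best = full(lengths)
        for _ in range(max_cycles):
            P = [None] * len(eng.nodes)
            for i in eng.edge_indices():
                P[i] = trans(lengths[i])
            B, Bscale = eng.below(P)
            C = [None] * len(eng.nodes)
            Csc = [None] * len(eng.nodes)
            C[eng.root] = np.tile(self.pi[:, None], (1, eng.n_pat))
            Csc[eng.root] = np.zeros(eng.n_pat)
            for i in [k for k in reversed(range(len(eng.nodes)))
                      if eng.parent[k] >= 0]:
                p = eng.parent[i]
                top = C[p].copy()
                tsc = Csc[p].copy()
                for s in eng.children[p]:
                    if s != i:
                        top *= eng.child_message(P[s], s, B)
                        if Bscale[s] is not None:
                            tsc += Bscale[s]
                mx = top.max(axis=0); mx[mx == 0] = 1.0
                top /= mx
                tsc += np.log(mx)
                own = Bscale[i] if Bscale[i] is not None else 0.0

                def edge_logl(t):
                    msg = eng.child_message(trans(t), i, B)
                    site = np.einsum("sp,sp->p", top, msg)
                    return float(self.weights
                                 @ (np.log(np.clip(site, 1e-300, None)) + tsc + own))

                cur = edge_logl(lengths[i])
                res = minimize_scalar(lambda t: -edge_logl(t),
                                      bounds=(1e-7, 60.0), method="bounded",
                                      options={"xatol": 1e-7})
                if -res.fun >= cur:
                    lengths[i] = float(res.x)
                P[i] = trans(lengths[i])
                Ci = P[i].T @ top
                mx = Ci.max(axis=0); mx[mx == 0] = 1.0
                C[i] = Ci / mx
                Csc[i] = tsc + np.log(mx)
            new = full(lengths)
            gain, best = new - best, max(new, best)
            if gain < tol:
                break
        self.base_lengths = lengths
        self._cache.clear()
        return best


# ---------------------------------------------------------------------------
# Model parametrizations

@dataclass
class CodonSiteModelParams:
    """MLEs of a codon site/branch model in natural units."""

    model_tag: str
    kappa: float
    pi: np.ndarray
    class_proportions: np.ndarray
    class_omegas: np.ndarray
    beta_p: float | None = None
    beta_q: float | None = None
    branch_omega_fg: float | None = None
    tree_scale: float = 1.0

    def positive_class_mask(self) -> np.ndarray:
        if self.model_tag in ("M2a", "M8"):
            return self.class_omegas > 1.0
        if self.model_tag == "branchsiteA":
            return np.array([False, False, True, True])
        raise SelectionError(
            f"model {self.model_tag} has no positive-selection class")


@dataclass
class SiteModelFit:
    params: CodonSiteModelParams
    lnL: float
    converged: bool
    n_restarts_agreeing: int
    fg_omegas: np.ndarray | None = None
    restart_lnls: list = field(default_factory=list)


@dataclass
class LRTResult:
    lnl0: float
    lnl1: float
    statistic: float
    df: int
    p_chi2_df: float
    p_conservative: float


def lrt(lnl0: float, lnl1: float, df: int) -> LRTResult:
    """Likelihood-ratio test: statistic = max(0, 2(lnl1 - lnl0)); p-values at
    the stated df and, conservatively, at df = 1."""
    if df < 1:
        raise SelectionError("df must be >= 1")
    stat = max(0.0, 2.0 * (lnl1 - lnl0))
    return LRTResult(lnl0, lnl1, stat, df,
                     float(chi2.sf(stat, df)), float(chi2.sf(stat, 1)))


@dataclass
class SitePosterior:
    pp: np.ndarray                 # per retained codon site
    site_numbers: np.ndarray       # 1-based positions in the aa alignment
    flagged_sites: np.ndarray      # 1-based, PP >= threshold
    threshold: float
    method: str


_BETA_CATS = 10


def _beta_category_omegas(p: float, q: float, k: int = _BETA_CATS) -> np.ndarray:
    """Medians of k equal-probability bins of Beta(p, q)."""
    quantiles = (2 * np.arange(1, k + 1) - 1) / (2 * k)
    return beta_dist.ppf(quantiles, p, q)


def _model_spec(model_tag: str):
    """Free-parameter layout: names, bounds, default start."""
    lrho = (np.log(0.02), np.log(50.0))
    if model_tag == "M0":
        return (["kappa", "omega", "lrho"],
                [(0.1, 20.0), (1e-4, 50.0), lrho], [2.0, 0.4, 0.0])
    if model_tag == "M1a":
        return (["kappa", "p0", "omega0", "lrho"],
                [(0.1, 20.0), (1e-6, 1 - 1e-6), (1e-4, 0.999), lrho],
                [2.0, 0.7, 0.1, 0.0])
    if model_tag == "M2a":
        return (["kappa", "s1", "s2", "omega0", "omega2", "lrho"],
                [(0.1, 20.0), (1e-6, 1 - 1e-6), (1e-6, 1 - 1e-6),
                 (1e-4, 0.999), (1.0, 50.0), lrho],
                [2.0, 0.7, 0.9, 0.1, 2.0, 0.0])
    if model_tag == "M7":
        return (["kappa", "lp", "lq", "lrho"],
                [(0.1, 20.0), (np.log(0.05), np.log(99.0)),
                 (np.log(0.05), np.log(99.0)), lrho],
                [2.0, np.log(0.5), np.log(1.5), 0.0])
    if model_tag == "M8":
        return (["kappa", "p0", "lp", "lq", "omega_s", "lrho"],
                [(0.1, 20.0), (1e-6, 1 - 1e-6), (np.log(0.05), np.log(99.0)),
                 (np.log(0.05), np.log(99.0)), (1.0, 50.0), lrho],
                [2.0, 0.9, np.log(0.5), np.log(1.5), 2.0, 0.0])
    if model_tag == "branch2":
        return (["kappa", "omega_bg", "omega_fg", "lrho"],
                [(0.1, 20.0), (1e-4, 50.0), (1e-4, 50.0), lrho],
                [2.0, 0.4, 0.4, 0.0])
    if model_tag == "branchsiteA0":
        return (["kappa", "s1", "s2", "omega0", "lrho"],
                [(0.1, 20.0), (1e-6, 1 - 1e-6), (1e-6, 1 - 1e-6),
                 (1e-4, 0.999), lrho],
                [2.0, 0.8, 0.8, 0.1, 0.0])
    if model_tag == "branchsiteA":
        return (["kappa", "s1", "s2", "omega0", "omega2", "lrho"],
                [(0.1, 20.0), (1e-6, 1 - 1e-6), (1e-6, 1 - 1e-6),
                 (1e-4, 0.999), (1.0, 50.0), lrho],
                [2.0, 0.8, 0.8, 0.1, 2.0, 0.0])
    raise SelectionError(f"unknown model tag {model_tag!r}")


def _unpack(model_tag: str, x: np.ndarray):
    """x -> (kappa, scale, props, omegas, fg_omegas)."""
    if model_tag == "M0":
        kappa, omega, lrho = x
        return kappa, np.exp(lrho), np.array([1.0]), np.array([omega]), None
    if model_tag == "M1a":
        kappa, p0, w0, lrho = x
        return (kappa, np.exp(lrho), np.array([p0, 1 - p0]),
                np.array([w0, 1.0]), None)
    if model_tag == "M2a":
        kappa, s1, s2, w0, w2, lrho = x
        p0 = s1; p1 = (1 - s1) * s2; p2 = 1 - p0 - p1
        return (kappa, np.exp(lrho), np.array([p0, p1, p2]),
                np.array([w0, 1.0, w2]), None)
    if model_tag == "M7":
        kappa, lp, lq, lrho = x
        omegas = _beta_category_omegas(np.exp(lp), np.exp(lq))
        props = np.full(_BETA_CATS, 1.0 / _BETA_CATS)
        return kappa, np.exp(lrho), props, omegas, None
    if model_tag == "M8":
        kappa, p0, lp, lq, ws, lrho = x
        omegas = np.append(_beta_category_omegas(np.exp(lp), np.exp(lq)), ws)
        props = np.append(np.full(_BETA_CATS, p0 / _BETA_CATS), 1 - p0)
        return kappa, np.exp(lrho), props, omegas, None
    if model_tag == "branch2":
        kappa, wbg, wfg, lrho = x
        return (kappa, np.exp(lrho), np.array([1.0]), np.array([wbg]),
                np.array([wfg]))
    if model_tag in ("branchsiteA", "branchsiteA0"):
        if model_tag == "branchsiteA":
            kappa, s1, s2, w0, w2, lrho = x
        else:
            kappa, s1, s2, w0, lrho = x
            w2 = 1.0
        pm = s1          # p0 + p1
        p0 = pm * s2; p1 = pm * (1 - s2)
        rest = 1 - pm
        p2a = rest * s2; p2b = rest * (1 - s2)
        props = np.array([p0, p1, p2a, p2b])
        bg = np.array([w0, 1.0, w0, 1.0])
        fg = np.array([w0, 1.0, w2, w2])
        return kappa, np.exp(lrho), props, bg, fg
    raise SelectionError(f"unknown model tag {model_tag!r}")


def _params_from_x(model_tag: str, x, pi) -> CodonSiteModelParams:
    kappa, scale, props, omegas, fg = _unpack(model_tag, x)
    beta_p = beta_q = None
    if model_tag == "M7":
        beta_p, beta_q = np.exp(x[1]), np.exp(x[2])
    elif model_tag == "M8":
        beta_p, beta_q = np.exp(x[2]), np.exp(x[3])
    fg_w = None
    if model_tag == "branch2":
        fg_w = float(fg[0])
    elif model_tag in ("branchsiteA", "branchsiteA0"):
        fg_w = float(fg[2])
    return CodonSiteModelParams(
        model_tag="branchsiteA" if model_tag == "branchsiteA0" else model_tag,
        kappa=float(kappa), pi=pi,
        class_proportions=props, class_omegas=omegas,
        beta_p=beta_p, beta_q=beta_q,
        branch_omega_fg=fg_w, tree_scale=float(scale))


def _fit(lik: CodonLikelihood, model_tag: str, n_restarts: int, seed: int,
         warm_start: np.ndarray | None = None,
         null_anchor: np.ndarray | None = None, maxfun: int = 400):
    names, bounds, default = _model_spec(model_tag)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    starts = []
    if warm_start is not None:
        starts.append(np.clip(np.array(warm_start, float), lo, hi))
    starts.append(np.array(default, float))
    n_draw = max(0, n_restarts - len(starts))
    if n_draw > 0:
        sampler = qmc.LatinHypercube(d=len(names), seed=seed)
        for row in sampler.random(n_draw):
            starts.append(lo + row * (hi - lo))
    starts = starts[: max(1, n_restarts)]

    def neg(x):
        kappa, scale, props, omegas, fg = _unpack(model_tag, x)
        return -lik.mixture_loglik(kappa, scale, props, omegas, fg)

    results = []
    for x0 in starts:
        res = minimize(neg, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxfun": maxfun, "ftol": 1e-10})
        results.append((float(-res.fun), res.x))
    if null_anchor is not None:
        # the general model contains the nested null exactly: keep the
        # embedded null point as a candidate so nesting dominance holds
        x_null = np.array(null_anchor, float)
        results.append((float(-neg(x_null)), x_null))
    results.sort(key=lambda t: -t[0])
    best_lnl, best_x = results[0]
    agree = sum(1 for lnl, _ in results if best_lnl - lnl <= 0.01)
    converged = agree >= 2 if len(results) >= 2 else True
    return best_lnl, best_x, converged, agree, [r[0] for r in results]


def fit_site_model(codon_aln: MultipleAlignment, tree: dendropy.Tree,
                   model_tag: str, n_restarts: int = 3, seed: int = 0,
                   branch_mode: str = "m0", foreground=None,
                   warm_start_fit: SiteModelFit | None = None,
                   lik: CodonLikelihood | None = None) -> SiteModelFit:
    """Fit a codon site/branch model on a fixed topology.

    ``branch_mode='m0'`` first optimizes branch lengths under M0 and then
    holds them proportional (a single scale factor is re-optimized per
    model); ``'fixed'`` keeps the tree's lengths, rescaled the same way.
    A ``CodonLikelihood`` may be passed to share the M0 branch lengths and
    caches across the model battery.
    """
    if lik is None:
        lik = CodonLikelihood(tree, codon_aln)
        if branch_mode == "m0":
            prefit = _fit(lik, "M0", 1, seed)
            k0, w0 = prefit[1][0], prefit[1][1]
            lik.base_lengths = lik.base_lengths * np.exp(prefit[1][2])
            lik._cache.clear()
            lik.optimize_branches_m0(k0, w0)
        elif branch_mode != "fixed":
            raise SelectionError(f"unknown branch_mode {branch_mode!r}")
    if foreground is not None:
        lik.set_foreground(foreground)
    tag = model_tag
    if model_tag in ("branch2", "branchsiteA", "branchsiteA0") \
            and not lik.fg_edges:
        raise SelectionError("branch models need a foreground clade")
    warm = anchor = None
    if warm_start_fit is not None:
        warm = _warm_start_vector(model_tag, warm_start_fit)
        anchor = _null_anchor_vector(model_tag, warm_start_fit)
    lnl, x, converged, agree, all_lnls = _fit(
        lik, tag, n_restarts, seed, warm_start=warm, null_anchor=anchor)
    kappa, scale, props, omegas, fg = _unpack(tag, x)
    params = _params_from_x(tag, x, lik.pi)
    fit = SiteModelFit(params=params, lnL=lnl, converged=converged,
                       n_restarts_agreeing=agree,
                       fg_omegas=fg, restart_lnls=all_lnls)
    fit._lik = lik  # share engine for posteriors / nested fits
    fit._x = x
    return fit


def _warm_start_vector(model_tag: str, simpler: SiteModelFit) -> np.ndarray | None:
    """Seed a general model from its nested null's MLEs."""
    sp = simpler.params
    sx = getattr(simpler, "_x", None)
    if sx is None:
        return None
    if model_tag == "M2a" and sp.model_tag == "M1a":
        kappa, p0, w0, lrho = sx
        # a little mass on an omega > 1 class so the new dimensions have
        # nonzero gradient at the start
        return np.array([kappa, p0 * 0.97, 1 - 0.03, w0, 2.0, lrho])
    if model_tag == "M8" and sp.model_tag == "M7":
        kappa, lp, lq, lrho = sx
        return np.array([kappa, 0.97, lp, lq, 2.0, lrho])
    if model_tag == "branch2" and sp.model_tag == "M0":
        kappa, w, lrho = sx
        return np.array([kappa, w, w, lrho])
    if model_tag == "branchsiteA" and sp.model_tag == "branchsiteA":
        kappa, s1, s2, w0, lrho = sx
        return np.array([kappa, s1, s2, w0, 1.5, lrho])
    return None


def _null_anchor_vector(model_tag: str, simpler: SiteModelFit) -> np.ndarray | None:
    """The nested null's MLEs embedded exactly in the general model."""
    sp = simpler.params
    sx = getattr(simpler, "_x", None)
    if sx is None:
        return None
    if model_tag == "M2a" and sp.model_tag == "M1a":
        kappa, p0, w0, lrho = sx
        return np.array([kappa, p0, 1.0, w0, 1.0, lrho])
    if model_tag == "M8" and sp.model_tag == "M7":
        kappa, lp, lq, lrho = sx
        return np.array([kappa, 1.0, lp, lq, 1.0, lrho])
    if model_tag == "branch2" and sp.model_tag == "M0":
        kappa, w, lrho = sx
        return np.array([kappa, w, w, lrho])
    if model_tag == "branchsiteA" and sp.model_tag == "branchsiteA":
        kappa, s1, s2, w0, lrho = sx
        return np.array([kappa, s1, s2, w0, 1.0, lrho])
    return None


# ---------------------------------------------------------------------------
# Site posteriors

def site_posteriors(fit: SiteModelFit, codon_aln: MultipleAlignment | None = None,
                    tree: dendropy.Tree | None = None, threshold: float = 0.95,
                    method: str = "neb") -> SitePosterior:
    """Posterior membership in the positive-selection class per codon site.

    NEB evaluates class posteriors at the MLEs; "beb-lite" averages them
    over a coarse grid (5 points per free mixture parameter) weighted by
    the likelihood, a light approximation to full BEB.
    """
    p = fit.params
    mask = p.positive_class_mask()
    lik: CodonLikelihood | None = getattr(fit, "_lik", None)
    if lik is None:
        if codon_aln is None or tree is None:
            raise SelectionError("need codon_aln and tree to rebuild engine")
        lik = CodonLikelihood(tree, codon_aln, pi=p.pi)
    if method == "neb":
        post = lik.class_posteriors(p.kappa, p.tree_scale,
                                    p.class_proportions, p.class_omegas,
                                    fit.fg_omegas)
        pp = post[mask].sum(axis=0)
    elif method == "beb-lite":
        pp = _beb_lite(lik, fit, mask)
    else:
        raise SelectionError(f"unknown method {method!r}")
    sites = lik.kept_sites + 1  # 1-based aa-alignment numbering
    flagged = sites[pp >= threshold]
    return SitePosterior(pp=pp, site_numbers=sites, flagged_sites=flagged,
                         threshold=threshold, method=method)


def _beb_lite(lik: CodonLikelihood, fit: SiteModelFit, mask: np.ndarray,
              n_grid: int = 5) -> np.ndarray:
    """Average NEB posteriors over a likelihood-weighted mixture-parameter grid."""
    p = fit.params
    tag = p.model_tag
    if tag == "M2a":
        grids = [np.linspace(0.05, 0.95, n_grid),    # s1
                 np.linspace(0.05, 0.95, n_grid),    # s2
                 np.linspace(0.02, 0.9, n_grid),     # omega0
                 np.linspace(1.05, 8.0, n_grid)]     # omega2
        def build(g):
            s1, s2, w0, w2 = g
            props = np.array([s1, (1 - s1) * s2, 1 - s1 - (1 - s1) * s2])
            return props, np.array([w0, 1.0, w2]), None
    elif tag == "M8":
        grids = [np.linspace(0.5, 0.99, n_grid),     # p0
                 np.linspace(1.05, 8.0, n_grid)]     # omega_s
        def build(g):
            p0, ws = g
            omegas = np.append(
                _beta_category_omegas(p.beta_p, p.beta_q), ws)
            props = np.append(np.full(_BETA_CATS, p0 / _BETA_CATS), 1 - p0)
            return props, omegas, None
    elif tag == "branchsiteA":
        grids = [np.linspace(0.05, 0.95, n_grid),
                 np.linspace(0.05, 0.95, n_grid),
                 np.linspace(1.05, 8.0, n_grid)]
        def build(g):
            s1, s2, w2 = g
            pm = s1
            props = np.array([pm * s2, pm * (1 - s2),
                              (1 - pm) * s2, (1 - pm) * (1 - s2)])
            w0 = p.class_omegas[0]
            bg = np.array([w0, 1.0, w0, 1.0])
            fg = np.array([w0, 1.0, w2, w2])
            return props, bg, fg
    else:
        raise SelectionError(f"beb-lite unsupported for {tag}")
    mesh = np.meshgrid(*grids, indexing="ij")
    points = np.stack([m.ravel() for m in mesh], axis=1)
    logls, posts = [], []
    for g in points:
        props, omegas, fg = build(g)
        logls.append(lik.mixture_loglik(p.kappa, p.tree_scale, props, omegas, fg))
        post = lik.class_posteriors(p.kappa, p.tree_scale, props, omegas, fg)
        posts.append(post[mask].sum(axis=0))
    logls = np.array(logls)
    w = np.exp(logls - logls.max())
    w /= w.sum()
    return np.tensordot(w, np.array(posts), axes=1)


# ---------------------------------------------------------------------------
# Branch and branch-site tests

def fit_branch_model(codon_aln: MultipleAlignment, tree: dendropy.Tree,
                     foreground, n_restarts: int = 2, seed: int = 0,
                     branch_mode: str = "m0"):
    """Two-ratio branch test on the edge subtending ``foreground`` leaves.

    Returns (H0 one-ratio fit, Ha two-ratio fit, LRT at df=1).  A
    significant LRT with foreground omega < 1 indicates relaxed or shifted
    purifying selection, not positive selection.
    """
    h0 = fit_site_model(codon_aln, tree, "M0", n_restarts=n_restarts,
                        seed=seed, branch_mode=branch_mode)
    lik = h0._lik
    lik.set_foreground(foreground)
    ha = fit_site_model(codon_aln, tree, "branch2", n_restarts=n_restarts,
                        seed=seed + 1, warm_start_fit=h0, lik=lik)
    return h0, ha, lrt(h0.lnL, ha.lnL, df=1)


def fit_branch_site_A(codon_aln: MultipleAlignment, tree: dendropy.Tree,
                      foreground, n_restarts: int = 2, seed: int = 0,
                      branch_mode: str = "m0"):
    """Branch-site model A: H0 fixes the foreground extra class at omega = 1,
    Ha frees it (>= 1).  Returns (H0 fit, Ha fit, LRT at df=1)."""
    h0 = fit_site_model(codon_aln, tree, "branchsiteA0", n_restarts=n_restarts,
                        seed=seed, branch_mode=branch_mode, foreground=foreground)
    ha = fit_site_model(codon_aln, tree, "branchsiteA", n_restarts=n_restarts,
                        seed=seed + 1, warm_start_fit=h0, lik=h0._lik)
    return h0, ha, lrt(h0.lnL, ha.lnL, df=1)


# ---------------------------------------------------------------------------
# Cross-alignment report

SITE_LRT_5PCT = 3.84
SITE_LRT_1PCT = 6.63


def chi2_critical(level: float, df: int = 1) -> float:
    """Upper-tail chi-square critical value used by the significance calls."""
    if df < 1:
        raise SelectionError("df must be >= 1")
    return float(chi2.isf(level, df))


def _stars(stat: float) -> str:
    if stat > SITE_LRT_1PCT:
        return "**"
    if stat > SITE_LRT_5PCT:
        return "*"
    return ""


def flagged_site_tokens(aln_nt: MultipleAlignment, flagged_sites) -> frozenset:
    """Map flagged codon-alignment columns to (row id, residue ordinal)
    tokens so flags are comparable across alignments of the same sequences."""
    tokens = set()
    for site in flagged_sites:
        j = int(site) - 1
        for rec in aln_nt.records:
            codon = rec.seq[3 * j : 3 * j + 3]
            if GAP in codon:
                continue
            ordinal = sum(1 for s in range(j)
                          if GAP not in rec.seq[3 * s : 3 * s + 3])
            tokens.add((rec.id, ordinal))
    return frozenset(tokens)


def jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def selection_report(alignments: list[MultipleAlignment],
                     trees: list[dendropy.Tree],
                     labels: list[str] | None = None,
                     models=("M1a", "M2a", "M7", "M8"),
                     n_restarts: int = 2, seed: int = 0,
                     branch_mode: str = "m0") -> tuple[ReportTable, ReportTable]:
    """Site-model battery per alignment plus a cross-alignment overlap
    summary of flagged positively selected sites.

    Returns (per-alignment table, pairwise Jaccard-overlap table).
    """
    if len(alignments) != len(trees):
        raise SelectionError("alignments and trees must be parallel lists")
    labels = labels or [a.method_label or f"aln{i}" for i, a in enumerate(alignments)]
    cols = ["alignment", "lnl_m1a", "lnl_m2a", "lrt_m1a_m2a", "sig_m1a_m2a",
            "omega2", "lnl_m7", "lnl_m8", "lrt_m7_m8", "sig_m7_m8",
            "flagged_sites", "mean_jaccard_vs_others"]
    token_sets: list[frozenset] = []
    rows = []
    for i, (aln, tree) in enumerate(zip(alignments, trees)):
        m1a = fit_site_model(aln, tree, "M1a", n_restarts=n_restarts,
                             seed=seed + 7 * i, branch_mode=branch_mode)
        m2a = fit_site_model(aln, tree, "M2a", n_restarts=n_restarts,
                             seed=seed + 7 * i + 1, warm_start_fit=m1a,
                             lik=m1a._lik)
        t12 = lrt(m1a.lnL, m2a.lnL, df=2)
        use78 = "M7" in models and "M8" in models
        if use78:
            m7 = fit_site_model(aln, tree, "M7", n_restarts=n_restarts,
                                seed=seed + 7 * i + 2, lik=m1a._lik)
            m8 = fit_site_model(aln, tree, "M8", n_restarts=n_restarts,
                                seed=seed + 7 * i + 3, warm_start_fit=m7,
                                lik=m1a._lik)
            t78 = lrt(m7.lnL, m8.lnL, df=2)
        post = site_posteriors(m2a)
        tokens = flagged_site_tokens(aln, post.flagged_sites) \
            if len(post.flagged_sites) else frozenset()
        token_sets.append(tokens)
        rows.append({
            "alignment": labels[i],
            "lnl_m1a": m1a.lnL, "lnl_m2a": m2a.lnL,
            "lrt_m1a_m2a": t12.statistic, "sig_m1a_m2a": _stars(t12.statistic),
            "omega2": float(m2a.params.class_omegas[-1]),
            "lnl_m7": m7.lnL if use78 else float("nan"),
            "lnl_m8": m8.lnL if use78 else float("nan"),
            "lrt_m7_m8": t78.statistic if use78 else float("nan"),
            "sig_m7_m8": _stars(t78.statistic) if use78 else "",
            "flagged_sites": ",".join(str(s) for s in post.flagged_sites),
        })
    table = ReportTable(cols)
    n = len(alignments)
    for i, row in enumerate(rows):
        others = [jaccard(token_sets[i], token_sets[j])
                  for j in range(n) if j != i]
        row["mean_jaccard_vs_others"] = float(np.mean(others)) if others else 1.0
        table.add_row(**row)
    overlap = ReportTable(["alignment_a", "alignment_b", "jaccard"])
    for i in range(n):
        for j in range(i + 1, n):
            overlap.add_row(alignment_a=labels[i], alignment_b=labels[j],
                            jaccard=jaccard(token_sets[i], token_sets[j]))
    return table, overlap
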