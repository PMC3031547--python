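"""Independent brute-force oracles used by the test suite.

Everything here recomputes a quantity by direct enumeration or a literal
re-scan, deliberately sharing no code with the implementations it checks.
"""

import itertools

import numpy as np

from alnsens.io_formats import GAP


# ---------------------------------------------------------------------------
# Pairwise alignment score by exhaustive enumeration

def brute_pairwise_score(a: str, b: str, S, idx, go: float, ge: float) -> float:
    """Best global alignment score over all monotone alignments.

    Gap runs cost go + (L-1)*ge; enumeration over interleavings of the two
    sequences (feasible for lengths <= 4).
    """
    best = -np.inf
    # an alignment is a sequence of ops: 0 both, 1 consume a, 2 consume b
    def rec(i, j, ops):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score(ops))
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, ops + [0])
        if i < len(a):
            rec(i + 1, j, ops + [1])
        if j < len(b):
            rec(i, j + 1, ops + [2])

    def score(ops):
        s = 0.0
        i = j = 0
        prev = None
        for op in ops:
            if op == 0:
                s += S[idx[a[i]], idx[b[j]]]
                i += 1; j += 1
            else:
                s += ge if prev == op else go
                if op == 1:
                    i += 1
                else:
                    j += 1
            prev = op
        return s

    rec(0, 0, [])
    return best


# ---------------------------------------------------------------------------
# Exhaustive-state pruning likelihood

def brute_tree_loglik(tree, rows, state_index, pi, trans_of, rates=None,
                      p_inv=0.0):
    """Sum over all internal-state assignments, vectorized over assignments.

    ``rows``: dict leaf-label -> string of states; ``trans_of(t, rate)``
    returns the transition matrix for a branch; gaps/unknowns in
    ``state_index`` map to None (missing).
    """
    rates = rates if rates is not None else [1.0]
    S = len(pi)
    post = list(tree.postorder_node_iter())
    internal = [n for n in post if not n.is_leaf()]
    n_int = len(internal)
    int_pos = {id(n): k for k, n in enumerate(internal)}
    assigns = np.array(list(itertools.product(range(S), repeat=n_int)))
    ncols = len(next(iter(rows.values())))
    total = 0.0
    for col in range(ncols):
        site = 0.0
        for r in rates:
            like = pi[assigns[:, int_pos[id(post[-1])]]].copy()
            for n in post:
                if n.parent_node is None:
                    continue
                P = trans_of(n.edge.length, r)
                pa = assigns[:, int_pos[id(n.parent_node)]]
                if n.is_leaf():
                    s = state_index.get(rows[n.taxon.label][col])
                    if s is not None:
                        like *= P[pa, s]
                else:
                    like *= P[pa, assigns[:, int_pos[id(n)]]]
            site += like.sum() / len(rates)
        if p_inv > 0:
            chars = {state_index.get(rows[lab][col])
                     for lab in rows}
            chars.discard(None)
            inv = 0.0
            if len(chars) == 0:
                inv = 1.0
            elif len(chars) == 1:
                inv = pi[chars.pop()]
            site = p_inv * inv + (1 - p_inv) * site
        total += np.log(site)
    return float(total)


# ---------------------------------------------------------------------------
# Fitch parsimony by exhaustive internal labeling

def brute_fitch(tree, rows, alphabet):
    post = list(tree.postorder_node_iter())
    internal = [n for n in post if not n.is_leaf()]
    ncols = len(next(iter(rows.values())))
    total = 0
    for col in range(ncols):
        best = None
        for assign in itertools.product(alphabet, repeat=len(internal)):
            amap = {id(n): s for n, s in zip(internal, assign)}
            steps = 0
            for n in post:
                if n.parent_node is None:
                    continue
                pa = amap[id(n.parent_node)]
                if n.is_leaf():
                    ch = rows[n.taxon.label][col]
                    if ch in alphabet and ch != pa:
                        steps += 1
                elif amap[id(n)] != pa:
                    steps += 1
            best = steps if best is None else min(best, steps)
        total += best
    return total


# ---------------------------------------------------------------------------
# RF by independent bipartition enumeration

def brute_rf(t1, t2):
    def splits(tree):
        leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
        out = set()
        for e in tree.preorder_edge_iter():
            if e.head_node is None or e.head_node.parent_node is None:
                continue
            below = frozenset(l.taxon.label
                              for l in e.head_node.leaf_iter())
            if 1 < len(below) < len(leaves) - 1:
                out.add(min(below, leaves - below,
                            key=lambda s: sorted(s)))
        return out

    return len(splits(t1) ^ splits(t2))


# ---------------------------------------------------------------------------
# Literal re-scans of the alignment metrics

def rescan_core_length(rows, anchor="C", majority=0.5):
    ncols = len(rows[0])
    hits = []
    for j in range(ncols):
        cells = [r[j] for r in rows if r[j] != GAP]
        if cells and sum(c == anchor for c in cells) >= majority * len(cells):
            hits.append(j)
    if len(hits) < 2:
        return 0
    return max(hits) - min(hits) + 1


def rescan_percent_identity(rows):
    vals = []
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            num = den = 0
            for x, y in zip(rows[i], rows[j]):
                if x != GAP and y != GAP:
                    den += 1
                    num += x == y
            vals.append(num / den if den else 0.0)
    return sum(vals) / len(vals)


def rescan_parsimony_informative(rows):
    count = 0
    for j in range(len(rows[0])):
        col = [r[j] for r in rows if r[j] != GAP]
        multi = [s for s in set(col) if col.count(s) >= 2]
        if len(multi) >= 2:
            count += 1
    return count


# ---------------------------------------------------------------------------
# Direct amino-acid simulator (for branch-length recovery tests)

def simulate_protein_alignment(tree, model, n_cols, seed):
    """Sample an amino-acid alignment directly under the substitution model
    (single rate), independent of the package's codon machinery."""
    rng = np.random.default_rng(seed)
    A, Ainv, lam = model.eigen()
    pi = model.equilibrium_freqs

    def P(t):
        return np.clip((A * np.exp(lam * t)) @ Ainv, 0, None)

    rows = {}

    def walk(node, state):
        for child in node.child_nodes():
            Pm = P(child.edge.length or 0.0)
            cum = Pm.cumsum(axis=1)
            u = rng.random(n_cols)
            st = np.minimum((cum[state] < u[:, None]).sum(axis=1), 19)
            if child.is_leaf():
                rows[child.taxon.label] = st
            else:
                walk(child, st)

    root = rng.choice(20, size=n_cols, p=pi)
    walk(tree.seed_node, root)
    return rows
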