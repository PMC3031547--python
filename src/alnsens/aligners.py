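"""Progressive multiple alignment with switchable presets.

A battery of presets (substitution matrix x gap-cost regime x guide-tree
strategy) produces alternative alignments of the same sequences, standing in
for the behaviorally diverse external MSA programs a sensitivity analysis
would compare; externally computed alignments can be ingested alongside via
the I/O layer.  The scheme is deliberately plain: global affine-gap
(Gotoh) dynamic programming, sum-of-pairs profile scoring from column
residue frequencies, leaf-to-root merging along a k-mer guide tree, no
iterative refinement.

The row dimension of the dynamic program is vectorized with numpy; the
within-row dependency of the gap state is resolved with a max-plus prefix
scan, so alignments of a few hundred residues take milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .io_formats import GAP, MultipleAlignment, SequenceRecord
from .phylo import AA_ORDER, bionj

NEG = -1e30


class AlignerError(ValueError):
    pass


@dataclass(frozen=True)
class AlignerPreset:
    name: str
    matrix_name: str
    gap_open: float
    gap_extend: float
    guide: str  # "identity-kmer" (UPGMA) or "distance-NJ" (BioNJ)

    def __post_init__(self):
        if not (self.gap_open <= self.gap_extend < 0):
            raise AlignerError("need gap_open <= gap_extend < 0")
        if self.guide not in ("identity-kmer", "distance-NJ"):
            raise AlignerError(f"unknown guide strategy {self.guide!r}")

    @property
    def subst_matrix(self) -> np.ndarray:
        return _matrix(self.matrix_name)


_MATRIX_CACHE: dict[str, np.ndarray] = {}


def _matrix(name: str) -> np.ndarray:
    if name not in _MATRIX_CACHE:
        raw = substitution_matrices.load(name)
        S = np.zeros((20, 20))
        for i, a in enumerate(AA_ORDER):
            for j, b in enumerate(AA_ORDER):
                S[i, j] = raw[a, b]
        _MATRIX_CACHE[name] = S
    return _MATRIX_CACHE[name]


#: six shipped presets: strict/loose gap costs x two matrices x two guides
PRESETS = {
    p.name: p for p in (
        AlignerPreset("b62-strict-kmer", "BLOSUM62", -11.0, -1.0, "identity-kmer"),
        AlignerPreset("b62-loose-kmer", "BLOSUM62", -4.0, -0.5, "identity-kmer"),
        AlignerPreset("b62-strict-nj", "BLOSUM62", -11.0, -1.0, "distance-NJ"),
        AlignerPreset("b45-strict-nj", "BLOSUM45", -10.0, -1.0, "distance-NJ"),
        AlignerPreset("b45-loose-nj", "BLOSUM45", -3.0, -0.5, "distance-NJ"),
        AlignerPreset("b45-loose-kmer", "BLOSUM45", -3.0, -0.5, "identity-kmer"),
    )
}


# ---------------------------------------------------------------------------
# Profile DP

_AA_IDX = {a: i for i, a in enumerate(AA_ORDER)}


def _profile_freqs(rows: list[str]) -> np.ndarray:
    L = len(rows[0])
    F = np.zeros((L, 20))
    for row in rows:
        for j, ch in enumerate(row):
            i = _AA_IDX.get(ch)
            if i is not None:
                F[j, i] += 1.0
    return F / len(rows)


def _gotoh(M: np.ndarray, go: float, ge: float):
    """Global affine-gap DP on a column-pair score matrix.

    Returns (score, ops) where ops is a list over alignment columns of
    0 = consume both, 1 = consume first profile (gap in second),
    2 = consume second profile (gap in first).  Ties during traceback prefer
    0 > 1 > 2.
    """
    La, Lb = M.shape
    D = np.full((La + 1, Lb + 1), NEG)
    IA = np.full((La + 1, Lb + 1), NEG)
    IB = np.full((La + 1, Lb + 1), NEG)
    D[0, 0] = 0.0
    if Lb > 0:
        IB[0, 1:] = go + ge * np.arange(Lb)
    if La > 0:
        IA[1:, 0] = go + ge * np.arange(La)
    js = np.arange(Lb + 1)
    for i in range(1, La + 1):
        prev_best = np.maximum(np.maximum(D[i - 1], IA[i - 1]), IB[i - 1])
        D[i, 1:] = M[i - 1] + prev_best[:-1]
        IA[i] = np.maximum(np.maximum(D[i - 1] + go, IB[i - 1] + go),
                           IA[i - 1] + ge)
        # IB[i, j] = ge*j + max_{k <= j-1} (max(D[i,k], IA[i,k]) + go - ge*(k+1))
        base = np.maximum(D[i], IA[i]) + go - ge * (js + 1)
        run = np.maximum.accumulate(base)
        IB[i, 1:] = ge * js[1:] + run[:-1]
    # traceback
    ops = []
    i, j = La, Lb
    state = int(np.argmax([D[i, j], IA[i, j], IB[i, j]]))
    score = [D[i, j], IA[i, j], IB[i, j]][state]
    tol = 1e-9
    while i > 0 or j > 0:
        if state == 0:
            ops.append(0)
            prev = [D[i - 1, j - 1], IA[i - 1, j - 1], IB[i - 1, j - 1]]
            target = D[i, j] - M[i - 1, j - 1]
            state = _pick(prev, target, tol)
            i, j = i - 1, j - 1
        elif state == 1:
            ops.append(1)
            cands = [D[i - 1, j] + go, IA[i - 1, j] + ge, IB[i - 1, j] + go]
            state = _pick(cands, IA[i, j], tol)
            i -= 1
        else:
            ops.append(2)
            cands = [D[i, j - 1] + go, IA[i, j - 1] + go, IB[i, j - 1] + ge]
            state = _pick(cands, IB[i, j], tol)
            j -= 1
        if i == 0 and j > 0:
            state = 2
        elif j == 0 and i > 0:
            state = 1
    ops.reverse()
    return float(score), ops


def _pick(cands, target, tol):
    for s, v in enumerate(cands):
        if abs(v - target) <= tol:
            return s
    return int(np.argmax(cands))


def _merge(rows_a: list[str], rows_b: list[str], preset: AlignerPreset):
    S = preset.subst_matrix
    FA = _profile_freqs(rows_a)
    FB = _profile_freqs(rows_b)
    M = FA @ S @ FB.T
    score, ops = _gotoh(M, preset.gap_open, preset.gap_extend)
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op in (0, 1):
            for r, row in enumerate(rows_a):
                out_a[r] += row[ia]
            ia += 1
        else:
            for r in range(len(rows_a)):
                out_a[r] += GAP
        if op in (0, 2):
            for r, row in enumerate(rows_b):
                out_b[r] += row[ib]
            ib += 1
        else:
            for r in range(len(rows_b)):
                out_b[r] += GAP
    return score, out_a, out_b


def pairwise_align(a: SequenceRecord, b: SequenceRecord,
                   preset: AlignerPreset):
    """Optimal global affine-gap alignment of two amino-acid sequences.

    Returns (aligned_a, aligned_b, score).  A gap run of length L costs
    gap_open + (L-1) * gap_extend.
    """
    if not a.seq or not b.seq:
        raise AlignerError("cannot align an empty sequence")
    score, out_a, out_b = _merge([a.seq], [b.seq], preset)
    return out_a[0], out_b[0], score


# ---------------------------------------------------------------------------
# Guide trees

def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    if not ka or not kb:
        return 1.0
    denom = min(len(a), len(b)) - k + 1
    return 1.0 - len(ka & kb) / max(denom, 1)


def _kmer_matrix(records) -> np.ndarray:
    n = len(records)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = _kmer_distance(records[i].seq, records[j].seq)
    return D


def _upgma_order(D: np.ndarray):
    """UPGMA agglomeration; returns a nested-tuple merge tree of indices."""
    clusters = {i: (i,) for i in range(len(D))}
    trees: dict[int, object] = {i: i for i in range(len(D))}
    sizes = {i: 1 for i in range(len(D))}
    W = D.astype(float).copy()
    np.fill_diagonal(W, np.inf)
    active = list(range(len(D)))
    nxt = len(D)
    while len(active) > 1:
        best = (np.inf, None, None)
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                if W[i, j] < best[0]:
                    best = (W[i, j], i, j)
        _, i, j = best
        W = np.pad(W, ((0, 1), (0, 1)), constant_values=np.inf)
        for k in active:
            if k not in (i, j):
                W[nxt, k] = W[k, nxt] = (
                    sizes[i] * W[i, k] + sizes[j] * W[j, k]) / (sizes[i] + sizes[j])
        trees[nxt] = (trees[i], trees[j])
        sizes[nxt] = sizes[i] + sizes[j]
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1
    return trees[active[0]]


def _nj_order(D: np.ndarray, labels: list[str]):
    """Merge tree (nested index tuples) from a BioNJ topology."""
    tree = bionj(D, labels)
    index = {lab: i for i, lab in enumerate(labels)}

    def collapse(node):
        if node.is_leaf():
            return index[node.taxon.label]
        parts = [collapse(c) for c in node.child_nodes()]
        out = parts[0]
        for p in parts[1:]:
            out = (out, p)
        return out

    return collapse(tree.seed_node)


def progressive_align(seqs, preset: AlignerPreset) -> MultipleAlignment:
    """Progressive profile alignment along the preset's guide tree.

    Input order is canonicalized (rows sorted by id) so the result is a
    deterministic function of the sequence set.
    """
    seqs = sorted(seqs, key=lambda r: r.id)
    if len(seqs) < 2:
        raise AlignerError("need at least 2 sequences")
    if len({r.id for r in seqs}) != len(seqs):
        raise AlignerError("duplicate sequence ids")
    D = _kmer_matrix(seqs)
    if preset.guide == "identity-kmer" or len(seqs) < 3:
        merge_tree = _upgma_order(D)
    else:
        merge_tree = _nj_order(D, [r.id for r in seqs])

    def build(node):
        if isinstance(node, int):
            return [node], [seqs[node].seq]
        (ids_a, rows_a) = build(node[0])
        (ids_b, rows_b) = build(node[1])
        _, out_a, out_b = _merge(rows_a, rows_b, preset)
        return ids_a + ids_b, out_a + out_b

    ids, rows = build(merge_tree)
    by_id = dict(zip(ids, rows))
    records = tuple(
        SequenceRecord(seqs[i].id, by_id[i], seqs[i].moltype, gapped=True)
        for i in range(len(seqs)))
    return MultipleAlignment(records, method_label=preset.name)


def align_battery(seqs, presets=None) -> list[MultipleAlignment]:
    presets = presets or list(PRESETS.values())
    return [progressive_align(seqs, p) for p in presets]


# ---------------------------------------------------------------------------
# Codon back-mapping

def codon_backmap(aa_alignment: MultipleAlignment, nt_records) -> MultipleAlignment:
    """Expand an amino-acid alignment to codons using the in-frame nucleotide
    records (one per row; translations must match the gap-stripped rows)."""
    nt_by_id = {r.id: r for r in nt_records}
    out = []
    for rec in aa_alignment.records:
        nt = nt_by_id.get(rec.id)
        if nt is None:
            raise AlignerError(f"no nucleotide record for row {rec.id!r}")
        aa_res = rec.seq.replace(GAP, "")
        if len(nt.seq) != 3 * len(aa_res):
            raise AlignerError(
                f"row {rec.id!r}: nucleotide length {len(nt.seq)} does not "
                f"match {len(aa_res)} residues")
        trans = str(Seq(nt.seq).translate())
        for k, (x, y) in enumerate(zip(trans, aa_res)):
            if x != y and y != "X":
                raise AlignerError(
                    f"row {rec.id!r}: translation mismatch at codon {k + 1} "
                    f"({x} vs {y})")
        codons = [nt.seq[3 * k : 3 * k + 3] for k in range(len(aa_res))]
        row = []
        k = 0
        for ch in rec.seq:
            if ch == GAP:
                row.append("---")
            else:
                row.append(codons[k])
                k += 1
        out.append(SequenceRecord(rec.id, "".join(row), "nt", gapped=True))
    return MultipleAlignment(tuple(out), method_label=aa_alignment.method_label)
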