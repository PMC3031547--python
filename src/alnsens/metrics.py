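"""Per-alignment statistics for the comparison battery.

Covers the classical descriptive battery for a divergent-family alignment:
total and cysteine-anchored core length, mean pairwise percent identity,
parsimony-informative column count, per-row anchor census, column-level
congruence between alternative alignments of the same sequences (the
heat-map analog of alignment certainty), and an entropy-based substitution
saturation test with a Monte-Carlo critical value.

All metrics are pure functions of their alignment inputs; gap cells are
excluded from identity and entropy computations rather than treated as an
extra character state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import GAP, MultipleAlignment


class MetricsError(ValueError):
    pass


@dataclass
class AlignmentStats:
    length: int
    core_length: int
    pct_identity: float
    n_parsimony_informative: int
    anchor_census: dict | None = None

    def __post_init__(self):
        if not (0 <= self.core_length <= self.length):
            raise MetricsError("core_length out of range")
        if not (0 <= self.pct_identity <= 1):
            raise MetricsError("pct_identity out of range")


@dataclass
class SaturationResult:
    iss: float
    iss_c: float
    p_value: float
    saturated: bool


@dataclass
class CongruenceProfile:
    per_column_score: np.ndarray

    @property
    def overall(self) -> float:
        return float(np.mean(self.per_column_score))


def _residue(ch: str) -> bool:
    return ch != GAP and ch != "X" and ch != "N"


# ---------------------------------------------------------------------------
# Table-battery metrics

def anchor_column_scan(aln: MultipleAlignment, anchor: str = "C",
                       majority: float = 0.5) -> list[int]:
    """Columns where at least ``majority`` of the non-gap cells equal the
    anchor residue."""
    hits = []
    for j in range(aln.n_cols):
        col = aln.column(j)
        nongap = [c for c in col if c != GAP]
        if nongap and sum(1 for c in nongap if c == anchor) >= majority * len(nongap):
            hits.append(j)
    return hits


def core_length(aln: MultipleAlignment, anchor: str = "C",
                majority: float = 0.5) -> int:
    """Inclusive column span from the first to the last anchor column
    (0 when fewer than two anchor columns are found)."""
    hits = anchor_column_scan(aln, anchor, majority)
    if len(hits) < 2:
        return 0
    return hits[-1] - hits[0] + 1


def percent_identity(aln: MultipleAlignment) -> float:
    """Mean over unordered row pairs of matches / shared non-gap columns;
    a pair with no shared columns contributes 0."""
    rows = [r.seq for r in aln.records]
    n = len(rows)
    if n < 2:
        raise MetricsError("need at least 2 rows")
    vals = []
    for i in range(n):
        for j in range(i + 1, n):
            shared = eq = 0
            for x, y in zip(rows[i], rows[j]):
                if x != GAP and y != GAP:
                    shared += 1
                    if x == y:
                        eq += 1
            vals.append(eq / shared if shared else 0.0)
    return float(np.mean(vals))


def parsimony_informative_count(aln: MultipleAlignment) -> int:
    """Columns with at least two distinct non-gap states each in >= 2 rows."""
    count = 0
    for j in range(aln.n_cols):
        tally: dict[str, int] = {}
        for ch in aln.column(j):
            if ch != GAP:
                tally[ch] = tally.get(ch, 0) + 1
        if sum(1 for v in tally.values() if v >= 2) >= 2:
            count += 1
    return count


def anchor_census(aln: MultipleAlignment, anchor_columns,
                  anchor: str = "C") -> dict[str, int]:
    """Per row, how many of the given anchor columns hold the anchor residue."""
    for j in anchor_columns:
        if not (0 <= j < aln.n_cols):
            raise MetricsError(f"anchor column {j} out of range")
    return {rec.id: sum(1 for j in anchor_columns if rec.seq[j] == anchor)
            for rec in aln.records}


def alignment_stats(aln: MultipleAlignment,
                    anchor_columns=None) -> AlignmentStats:
    return AlignmentStats(
        length=aln.n_cols,
        core_length=core_length(aln),
        pct_identity=percent_identity(aln),
        n_parsimony_informative=parsimony_informative_count(aln),
        anchor_census=anchor_census(aln, anchor_columns)
        if anchor_columns is not None else None)


# ---------------------------------------------------------------------------
# Congruence (homology-pair agreement between alignments)

def _homology_pairs_by_column(aln: MultipleAlignment):
    """Per column, the set of ((row_a, ordinal_a), (row_b, ordinal_b)) residue
    pairs the column co-aligns; ordinals count residues in the ungapped row."""
    ordinals = []
    for rec in aln.records:
        k = -1
        row = []
        for ch in rec.seq:
            if ch != GAP:
                k += 1
                row.append(k)
            else:
                row.append(-1)
        ordinals.append(row)
    per_col = []
    n = aln.n_rows
    for j in range(aln.n_cols):
        cells = [(r, ordinals[r][j]) for r in range(n) if ordinals[r][j] >= 0]
        pairs = {(cells[a], cells[b])
                 for a in range(len(cells)) for b in range(a + 1, len(cells))}
        per_col.append(pairs)
    return per_col


def column_congruence(ref: MultipleAlignment,
                      alt: MultipleAlignment) -> CongruenceProfile:
    """Fraction of each reference column's residue pairs that are co-aligned
    somewhere in the alternative alignment (1 by convention for columns with
    fewer than two residues)."""
    ref_ids = ref.ids
    if set(ref_ids) != set(alt.ids):
        raise MetricsError("alignments cover different sequence sets")
    for rid in ref_ids:
        if ref.row(rid).replace(GAP, "") != alt.row(rid).replace(GAP, ""):
            raise MetricsError(f"row {rid!r} differs between alignments")
    # reindex alt rows to ref row order
    alt_reordered = MultipleAlignment(
        tuple(next(r for r in alt.records if r.id == rid) for rid in ref_ids),
        method_label=alt.method_label)
    ref_cols = _homology_pairs_by_column(ref)
    alt_pairs = set().union(*_homology_pairs_by_column(alt_reordered)) \
        if alt_reordered.n_cols else set()
    scores = np.ones(ref.n_cols)
    for j, pairs in enumerate(ref_cols):
        if pairs:
            scores[j] = sum(1 for p in pairs if p in alt_pairs) / len(pairs)
    return CongruenceProfile(scores)


def uncertainty_profile(alignments: list[MultipleAlignment],
                        ref_index: int = 0) -> CongruenceProfile:
    """Mean congruence of one reference alignment against all others — the
    per-column certainty heat map."""
    if len(alignments) < 2:
        raise MetricsError("need at least 2 alignments")
    ref = alignments[ref_index]
    profiles = [column_congruence(ref, alt).per_column_score
                for k, alt in enumerate(alignments) if k != ref_index]
    return CongruenceProfile(np.mean(profiles, axis=0))


# ---------------------------------------------------------------------------
# Saturation

def _column_entropies(cols: list[str], alphabet_size: int,
                      min_cells: int = 4) -> np.ndarray:
    out = []
    for col in cols:
        chars = [c for c in col if _residue(c)]
        if len(chars) < min_cells:
            continue
        _, counts = np.unique(list(chars), return_counts=True)
        p = counts / counts.sum()
        h = -(p * np.log(p)).sum() / np.log(alphabet_size)
        out.append(h)
    return np.array(out)


def saturation_test(aln: MultipleAlignment, alphabet_size: int = 20,
                    n_reps: int = 500, seed: int = 0) -> SaturationResult:
    """Entropy-index saturation test.

    The observed index Iss is the mean per-column Shannon entropy (log base
    = alphabet size, gap cells excluded, columns with >= 4 residues).  The
    null of full saturation fills columns i.i.d. from the empirical residue
    frequencies; the critical value Iss.c is the null's 5th percentile, so
    an alignment is called saturated when its index is not significantly
    below what saturated data would show.  Small p-values mean structure
    remains.
    """
    if aln.n_rows < 4:
        raise MetricsError("saturation test needs at least 4 rows")
    cols = [aln.column(j) for j in range(aln.n_cols)]
    obs_cols = [[c for c in col if _residue(c)] for col in cols]
    usable = [c for c in obs_cols if len(c) >= 4]
    if len(usable) < 10:
        raise MetricsError("too few usable columns for the saturation test")
    iss = float(np.mean(_column_entropies(cols, alphabet_size)))
    pool = [c for col in usable for c in col]
    symbols, counts = np.unique(pool, return_counts=True)
    freqs = counts / counts.sum()
    rng = np.random.default_rng(seed)
    shape = [len(c) for c in usable]
    null = np.empty(n_reps)
    for rep in range(n_reps):
        vals = []
        for m in shape:
            draw = rng.choice(len(symbols), size=m, p=freqs)
            _, cnt = np.unique(draw, return_counts=True)
            p = cnt / m
            vals.append(-(p * np.log(p)).sum() / np.log(alphabet_size))
        null[rep] = np.mean(vals)
    iss_c = float(np.quantile(null, 0.05))
    p_value = float((null <= iss).mean())
    return SaturationResult(iss=iss, iss_c=iss_c, p_value=p_value,
                            saturated=bool(iss >= iss_c))
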