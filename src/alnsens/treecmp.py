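"""Tree concordance and the alignment-method ranking table.

Robinson–Foulds distance is the symmetric difference between the
non-trivial bipartition sets of two unrooted leaf-labeled trees; the
ranking of alignment methods sorts by RF to a designated reference tree
(simulation truth, or any supplied anchor topology), breaking ties by
log-likelihood and then mean branch support.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .io_formats import ReportTable


class TreeCompareError(ValueError):
    pass


@dataclass
class TreeComparison:
    rf: int
    normalized_rf: float
    shared_bipartitions: int
    n_leaves: int


def nontrivial_bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial splits as canonical frozensets (the side not containing
    the lexicographically smallest leaf)."""
    labels = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = min(labels)
    out: set[frozenset] = set()
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None or nd.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if len(side) < 2 or len(labels) - len(side) < 2:
            continue
        out.add(side if ref not in side else labels - side)
    return out


def _restrict(tree: dendropy.Tree, keep: set[str]) -> dendropy.Tree:
    sub = dendropy.Tree(tree)
    sub.retain_taxa_with_labels(sorted(keep))
    return sub


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree,
                prune_to_common: bool = False) -> TreeComparison:
    """Robinson–Foulds symmetric bipartition distance (unrooted; branch
    lengths ignored).  Leaf sets must match unless ``prune_to_common``."""
    l1 = {lf.taxon.label for lf in t1.leaf_node_iter()}
    l2 = {lf.taxon.label for lf in t2.leaf_node_iter()}
    if l1 != l2:
        if not prune_to_common:
            raise TreeCompareError(
                f"leaf sets differ: only in first {sorted(l1 - l2)}, "
                f"only in second {sorted(l2 - l1)}")
        common = l1 & l2
        if len(common) < 3:
            raise TreeCompareError("fewer than 3 shared leaves")
        t1, t2 = _restrict(t1, common), _restrict(t2, common)
        l1 = common
    b1 = nontrivial_bipartitions(t1)
    b2 = nontrivial_bipartitions(t2)
    rf = len(b1 ^ b2)
    n = len(l1)
    denom = 2 * (n - 3) if n > 3 else 1
    return TreeComparison(rf=rf, normalized_rf=rf / denom,
                          shared_bipartitions=len(b1 & b2), n_leaves=n)


# ---------------------------------------------------------------------------
# Ranking

RANK_COLUMNS = ["rank", "alignment", "length", "core_length", "lnl",
                "parsimony", "tree_size", "support", "rf", "normalized_rf",
                "pct_identity", "tied_with"]


def rank_alignments(battery: list[dict]) -> ReportTable:
    """Assemble and rank the per-alignment battery.

    Each entry needs: label, stats (AlignmentStats), lnl, parsimony,
    tree_size, mean_support, comparison (TreeComparison vs the reference).
    Sort: RF ascending, then lnl descending, then support descending; ties
    share a rank and are reported in the ``tied_with`` column.
    """
    required = ("label", "stats", "lnl", "parsimony", "tree_size",
                "mean_support", "comparison")
    for entry in battery:
        missing = [k for k in required if k not in entry or entry[k] is None]
        if missing:
            raise TreeCompareError(
                f"battery entry {entry.get('label')!r} missing {missing}")

    def key(e):
        return (e["comparison"].rf, -e["lnl"], -np.nan_to_num(e["mean_support"]))

    ordered = sorted(battery, key=key)
    table = ReportTable(RANK_COLUMNS)
    ranks = []
    for i, e in enumerate(ordered):
        ranks.append(i + 1 if i == 0 or key(e) != key(ordered[i - 1])
                     else ranks[-1])
    for i, e in enumerate(ordered):
        ties = [o["label"] for j, o in enumerate(ordered)
                if j != i and ranks[j] == ranks[i]]
        st = e["stats"]
        table.add_row(
            rank=ranks[i], alignment=e["label"], length=st.length,
            core_length=st.core_length, lnl=float(e["lnl"]),
            parsimony=int(e["parsimony"]), tree_size=float(e["tree_size"]),
            support=float(e["mean_support"]),
            rf=e["comparison"].rf,
            normalized_rf=float(e["comparison"].normalized_rf),
            pct_identity=float(st.pct_identity),
            tied_with=",".join(ties))
    return table
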