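"""End-to-end orchestration of the alignment-sensitivity analysis.

One run: obtain sequences (simulated family or user FASTA), align them under
several presets (and/or ingest external alignments), score each alignment
(battery metrics + saturation), infer and score a tree per alignment,
compare every tree to a reference topology, rank the methods, and — when a
codon alignment is available — run the positive-selection battery per
alignment and summarize how the flagged sites agree across methods.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import aligners, metrics, phylo, selection, simulate, treecmp
from .io_formats import (MultipleAlignment, ReportTable, read_alignment,
                         read_fasta, read_newick, write_alignment,
                         write_newick, write_report)


@dataclass
class PipelineConfig:
    simulate: simulate.FamilySimConfig | None = None
    input_aa: str | None = None
    input_nt: str | None = None
    presets: list = field(default_factory=lambda: list(aligners.PRESETS))
    external_alignments: list = field(default_factory=list)
    reference: str = "truth"        # "truth" or a Newick path
    tree_method: str = "nni"        # "nni" or "bionj"
    nni_starts: int = 5
    bootstrap_reps: int = 100
    do_selection: bool = False
    selection_models: tuple = ("M1a", "M2a")
    foreground: str | list = "expansion"
    seed: int = 0
    output_dir: str = "alnsens_out"

    def validate(self):
        if self.simulate is None and self.input_aa is None:
            raise ValueError("need either a simulation config or input FASTA")
        if not self.presets and not self.external_alignments:
            raise ValueError("need at least one alignment source")
        if self.tree_method not in ("nni", "bionj"):
            raise ValueError(f"unknown tree method {self.tree_method!r}")


def config_from_yaml(path: str) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = raw.pop("simulate", None)
    cfg = PipelineConfig(**raw)
    if sim is not None:
        cfg.simulate = simulate.FamilySimConfig(**sim)
    return cfg


def _infer_tree(aln: MultipleAlignment, model, config: PipelineConfig,
                seed: int):
    D, labels = phylo.distance_matrix(aln, correction="gamma",
                                      alpha=model.alpha)
    tree = phylo.bionj(D, labels)
    if config.tree_method == "nni" and aln.n_rows >= 4:
        tree, lnl = phylo.nni_search(tree, aln, model,
                                     n_starts=config.nni_starts, seed=seed)
    phylo.optimize_branch_lengths(tree, aln, model,
                                  estimate_alpha=True, estimate_pinv=True,
                                  max_cycles=10)
    lnl = phylo.tree_loglik(tree, aln, model)
    return tree, lnl


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the report artifacts.

    Returns a dict with the in-memory results (alignments, trees, tables)
    and the paths written.
    """
    config.validate()
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    os.makedirs(os.path.join(out, "trees"), exist_ok=True)
    log_lines = [f"seed: {config.seed}"]

    # -- stage 1: sequences -------------------------------------------------
    family = None
    ref_alignment = None
    nt_records = None
    if config.simulate is not None:
        family = simulate.simulate_family(config.simulate)
        seqs = family.unaligned_aa
        nt_records = family.unaligned_nt
        ref_alignment = family.true_alignment_aa
        write_alignment(family.true_alignment_aa,
                        os.path.join(out, "true_alignment.faa"))
        with open(os.path.join(out, "trees", "true_tree.nwk"), "w") as fh:
            fh.write(write_newick(family.true_tree))
        log_lines.append(f"simulated family: {config.simulate}")
    else:
        seqs = read_fasta(config.input_aa, "aa")
        if config.input_nt:
            nt_records = read_fasta(config.input_nt, "nt")

    if config.reference == "truth":
        if family is None:
            raise ValueError("reference 'truth' requires a simulated family")
        ref_tree = family.true_tree
    else:
        ref_tree = read_newick(config.reference)

    # -- stage 2: alignments ------------------------------------------------
    alignments = []
    for name in config.presets:
        alignments.append(aligners.progressive_align(
            seqs, aligners.PRESETS[name]))
    for path in config.external_alignments:
        alignments.append(read_alignment(path, "aa",
                                         method_label=os.path.basename(path)))
    for aln in alignments:
        write_alignment(aln, os.path.join(out, f"aln_{aln.method_label}.faa"))

    # -- stage 3: metrics + saturation -------------------------------------
    stats = [metrics.alignment_stats(a) for a in alignments]
    saturation = []
    for i, a in enumerate(alignments):
        try:
            saturation.append(metrics.saturation_test(
                a, alphabet_size=20, seed=config.seed + 1000 + i))
        except metrics.MetricsError:
            saturation.append(None)

    # -- stage 4: trees -----------------------------------------------------
    battery = []
    trees = []
    for i, (aln, st) in enumerate(zip(alignments, stats)):
        model = phylo.lg_model(freqs=phylo.empirical_aa_freqs(aln),
                               alpha=1.0, p_inv=0.0)
        tree, lnl = _infer_tree(aln, model, config, seed=config.seed + i)
        phylo.bootstrap_support(tree, aln, model,
                                n_reps=config.bootstrap_reps,
                                seed=config.seed + 500 + i)
        trees.append(tree)
        comparison = treecmp.rf_distance(tree, ref_tree)
        battery.append({
            "label": aln.method_label,
            "stats": st,
            "lnl": lnl,
            "parsimony": phylo.fitch_parsimony(tree, aln),
            "tree_size": phylo.tree_size(tree),
            "mean_support": phylo.mean_internal_support(tree),
            "comparison": comparison,
        })
        rooted = phylo.midpoint_root(phylo._clone(tree))
        with open(os.path.join(out, "trees", f"{aln.method_label}.nwk"), "w") as fh:
            fh.write(write_newick(rooted))
        log_lines.append(
            f"tree[{aln.method_label}]: lnl={lnl:.4f} rf={comparison.rf}")

    # -- stage 5: ranking ---------------------------------------------------
    table2 = treecmp.rank_alignments(battery)
    write_report(table2, os.path.join(out, "table2.tsv"))

    # -- stage 6: uncertainty heat map -------------------------------------
    uncertainty = None
    pool = ([ref_alignment] if ref_alignment is not None else []) + alignments
    if len(pool) >= 2:
        uncertainty = metrics.uncertainty_profile(pool, ref_index=0)
        prof = ReportTable(["column", "score"])
        for j, s in enumerate(uncertainty.per_column_score):
            prof.add_row(column=j + 1, score=float(s))
        write_report(prof, os.path.join(out, "uncertainty.tsv"))

    # -- stage 7: selection battery ----------------------------------------
    table3 = overlap = None
    if config.do_selection:
        if nt_records is None:
            raise ValueError("selection stage needs nucleotide records")
        codon_alns = [aligners.codon_backmap(a, nt_records) for a in alignments]
        table3, overlap = selection.selection_report(
            codon_alns, trees, labels=[a.method_label for a in alignments],
            models=config.selection_models, seed=config.seed + 2000)
        write_report(table3, os.path.join(out, "table3.tsv"))
        write_report(overlap, os.path.join(out, "site_overlap.tsv"))

    # -- stage 8: saturation report + log ----------------------------------
    sat_table = ReportTable(["alignment", "iss", "iss_c", "p_value", "saturated"])
    for aln, sat in zip(alignments, saturation):
        if sat is not None:
            sat_table.add_row(alignment=aln.method_label, iss=sat.iss,
                              iss_c=sat.iss_c, p_value=sat.p_value,
                              saturated=sat.saturated)
    write_report(sat_table, os.path.join(out, "saturation.tsv"))
    with open(os.path.join(out, "run.log"), "w") as fh:
        fh.write("\n".join(log_lines) + "\n")

    return {
        "family": family,
        "alignments": alignments,
        "stats": stats,
        "saturation": saturation,
        "trees": trees,
        "battery": battery,
        "table2": table2,
        "table3": table3,
        "overlap": overlap,
        "uncertainty": uncertainty,
        "output_dir": out,
    }
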