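# Methods

This note documents the models behind `alnsens`, the defaults and why they
were chosen, what the synthetic data do and do not emulate, and the
numerical choices that matter for reproducibility.

## The problem setting

Divergent protein families such as insect odorant-binding proteins (OBPs)
sit near the limit of alignability: ~20% mean pairwise amino-acid identity,
a handful of structurally conserved cysteines, frequent lineage-specific
expansions of recent paralogs, and substitutional saturation deep in the
tree.  In this regime every downstream inference — the tree, its support,
and especially codon-model tests of positive selection — inherits the
choices of the alignment step.  The package's purpose is to quantify that
inheritance on data where the truth is known.

## Synthetic families (`simulate`)

A family is a codon-level simulation along a gene tree:

* **Topology.** Random sequential-addition topologies with exponential
  branch-length draws stand in for a birth–death gene tree.  The expansion
  clade is grafted as a monophyletic subtree and then renormalized so its
  mean root-to-leaf depth is `radiation_factor` (default 0.15) times the
  whole tree's, capped at 1.2 substitutions/codon: a young radiation whose
  members remain mutually alignable however saturated the backbone.  The
  cap reflects what a recent paralog expansion looks like; without it a
  depth-calibrated backbone would drag the "young" clade into saturation
  and no method (nor the truth-based check) could recover it.
* **Substitution process.** Goldman–Yang-style codon process over the 61
  sense codons (universal code): single-nucleotide changes only, target
  frequency π_j, ×κ for transitions (default κ = 2), ×ω for nonsynonymous
  changes.  Each column is assigned one of the configured (proportion, ω)
  site classes; class generators share a common scaling so the mixture
  mean rate is one substitution per codon per unit branch length.
  Default classes: (0.35, 0.08), (0.35, 0.5), (0.20, 1.0), (0.10, 2.0) —
  a purifying-dominated mix with a modest positively selected fraction,
  the kind of regime the family's published ω estimates (point estimates
  around 2–3 for small site fractions) suggest.  Simulation frequencies
  are uniform over sense codons.
* **Anchors and signal peptide.** Six cysteine anchor columns (evenly
  spread through the mature region by default) plus the initial methionine
  are frozen.  With probability `cminus_fraction` (default 0.11 ≈ 2/18) a
  lineage loses the 2nd and 5th anchors — which pair is lost is a
  convention; the biology only says "a pair".  The signal peptide
  (19 codons) is ordinary sequence with a frozen initial M; no
  hydrophobicity modeling — the relevant property downstream is only that
  signal regions still contain alignable blocks.
* **Indels.** Whole-codon events (so nucleotide and protein alignments
  stay consistent) at `indel_rate` events per substitution, geometric
  length with mean 2 codons, never touching frozen columns; insertion
  content is drawn at the insertion point and evolves onward.  The event
  rate is referenced to the configured base length so the column count
  stays bounded on deep trees.  Default 0.01 events/substitution: there
  is no empirical OBP indel rate, and this value keeps 20% identity
  reachable while producing true alignments of roughly 250–450 columns
  from 150-codon sequences — the same relative spread real OBP alignments
  show.  Higher rates (≳0.05) make realized identity non-monotone in
  depth (shared columns become dominated by young insertions) and 20%
  unreachable.
* **Depth calibration.** The probability that two codons separated by time
  t encode the same residue has the closed form Σ_k c_k e^{λ_k t} per
  class (from the eigendecomposition of the class generator), so the
  expected mean pairwise identity of a candidate tree is cheap to
  evaluate.  A bisection on a global depth multiplier solves the analytic
  curve first; because the analytic expectation ignores indels and the
  expansion renormalization, a short second stage bisects on *realized*
  identity from pilot simulations (2 pilots per step).  Over 30 default
  seeds the realized mean identity is ≈ 0.20–0.23; family shapes whose
  attainable floor is above the target (many tight paralog pairs, short
  sequences) settle at the closest attainable value with a warning rather
  than failing.  When identity is insensitive to depth (e.g. ω = 0
  everywhere) calibration is skipped in favor of a fixed moderate depth.
* **Randomness.** One master seed; every operation (topology, class
  assignment, substitution, indels, C-minus choice, pilot calibration)
  draws from its own named child stream, so stages are independently
  reproducible.

What passing tests on these data show: that the *pipeline* behaves
correctly and that alignment sensitivity is a property of the divergence
regime, not of any particular program.  What they do not show: anything
about real OBP biology — the simulator has no base composition bias, no
within-codon indels, no rate variation along branches, no alignment-free
domain structure beyond the frozen anchors.

## Alignment battery (`aligners`)

Global affine-gap (Gotoh) dynamic programming; profiles are column residue
frequency vectors, profile pairs scored by sum-of-pairs through the
substitution matrix; merging proceeds leaf-to-root along a guide tree
built from 3-mer distances (UPGMA or BioNJ).  No iterative refinement —
deliberately, since the point of the battery is the *spread* of plausible
methods, obtained here by crossing BLOSUM62/BLOSUM45 with strict (−11/−1)
and loose (−2…−4/−0.5) gap costs and the two guide strategies.  A gap run
of length L costs `gap_open + (L−1)·gap_extend`; traceback ties prefer
match, then consume-first-profile, then consume-second.  Input order is
canonicalized by sequence id, so each preset is a deterministic function
of the sequence set.  The row dimension of the DP is vectorized and the
within-row gap-state dependency is resolved with a max-plus prefix scan,
which keeps pure-numpy alignments at millisecond scale.

## Alignment metrics (`metrics`)

* Percent identity: mean over unordered row pairs of matches over shared
  non-gap columns (pairs with no shared columns contribute 0).  The
  gap convention is declared, not inferred — published tables rarely state
  theirs.
* Core length: inclusive column span from the first to the last
  majority-cysteine column (threshold 0.5, so C-minus rows cannot break
  detection); columns, not residues.
* Congruence: each reference column induces a set of residue pairs
  ((row, ordinal), (row, ordinal)) it co-aligns; its score is the fraction
  of those pairs co-aligned anywhere in the other alignment.  Columns with
  fewer than two residues score 1 by convention.  The mean profile over a
  battery is the alignment-certainty heat map.
* Saturation: the index is the mean per-column Shannon entropy over
  non-gap cells (log base = alphabet size, columns with ≥4 residues), and
  the critical value is the 5th percentile of the same statistic on
  alignments whose columns are filled i.i.d. from the pooled residue
  frequencies — the full-saturation null.  An alignment is called
  saturated when its index is *not* significantly below that null
  (one-sided, 5%).  This is a deterministic, testable criterion in the
  spirit of the classical saturation tests, with no claim of numerical
  fidelity to their published implementations.

## Phylogenetics (`phylo`)

LG exchangeabilities and frequencies ship as packaged data (the standard
published values); +F (alignment frequencies) is the default in the
pipeline.  Rate variation: proportion of invariable sites plus 4
equal-probability discrete-gamma categories at category means, rescaled by
1/(1−p_inv) so the mean rate is 1.  Likelihoods by Felsenstein pruning
over unique site patterns with per-subtree log rescaling; gaps and
ambiguity codes are missing data.  Leaf partials are one-hot, so messages
from leaves are column gathers of P(t) rather than matrix products —
roughly half the pruning cost at these sizes.

Branch lengths are optimized coordinate-wise (bounded Brent per edge,
bounds [1e−8, 20]); each sweep recomputes subtree partials once, then
walks the tree preorder maintaining exact rest-of-tree contexts, so each
1-D optimization is an exact coordinate ascent and improvement is
monotone; cycles stop below a 1e-6 log-likelihood gain.  Alpha and p_inv
are bounded 1-D searches interleaved with sweeps.  Topology search is NNI
hill-climbing (neighbors scored with current lengths, lengths re-optimized
after each accepted move) from the BioNJ tree plus seeded random
resolutions; ties break first-found.  Distance input to BioNJ uses the
gamma correction d = α((1−p)^{−1/α}−1); saturated pairs (p → 1) are capped
at twice the largest finite distance.  Support is nonparametric bootstrap
with fast BioNJ replicates — a deliberate substitution for approximate
likelihood-ratio support: the sensitivity analysis only needs a
consistent per-edge support to average, and the report column is named
plainly `support`.

## Tree comparison and ranking (`treecmp`)

RF is the symmetric difference of non-trivial bipartition sets
(frozensets canonicalized by the side not containing the smallest leaf
label); multifurcations simply contribute fewer bipartitions.  Trees on
different leaf sets are refused unless pruning to the common set is
requested explicitly.  The ranking sorts by RF to the reference
(simulation truth, or any supplied anchor), breaking ties by
log-likelihood and then mean support; full ties share a rank and are
listed, not hidden.

## Selection machinery (`selection`)

F3×4 codon frequencies (per-position nucleotide frequencies multiplied and
renormalized over the 61 sense codons).  Site models:

* M0 (one ω), M1a (ω0 < 1, ω1 = 1), M2a (adds ω2 ≥ 1), M7 (beta, 10
  equal-probability categories at medians), M8 (beta + spike ω_s ≥ 1).
* Two-ratio branch model and branch-site model A (four classes; the null
  fixes the foreground extra class at ω2 = 1) on a foreground edge
  identified by the leaf set it subtends.

Likelihood-ratio tests report the statistic max(0, 2ΔlnL) with the p-value
at the nominal df *and* the conservative χ²₁ p-value; the significance
stars use the classical 3.84 / 6.63 thresholds.  Site identification is
naive empirical Bayes at the MLEs (PP of the ω > 1 classes, flag at
PP ≥ 0.95, sites numbered 1-based in the amino-acid alignment); a
"beb-lite" option averages NEB posteriors over a likelihood-weighted
coarse grid (5 points per free mixture parameter) as a light approximation
to the full hierarchical treatment, and reports which method produced each
PP.

Numerical design: during optimization each class generator is normalized
by the rate of the matching ω = 1 generator, which preserves the classes'
relative speeds while making per-class site likelihood vectors independent
of the class proportions; the overall time unit is absorbed by a free
branch-scale multiplier and converted back to the usual mixture-mean
scaling for reporting.  This is a pure reparametrization whose payoff is
caching: proportion-only optimizer steps cost almost nothing.  Parameters
are box-bounded (κ ∈ [0.1, 20], ω ∈ [1e−4, 50], beta shapes ∈ [0.05, 99],
proportions by stick-breaking), optimized with L-BFGS-B; restarts draw
from a seeded Latin hypercube, and a fit counts as converged when the best
two restarts agree within 0.01 lnL.  Nested alternatives are warm-started
from their null's MLEs with a little interior mass on the extra class (the
exact boundary is a flat point), and the null's exact embedding is always
kept as a candidate so nesting dominance (lnL_alt ≥ lnL_null) holds by
construction.  Branch lengths follow the standard protocol: estimated
under M0, then held proportional with a single re-optimized scale per
model (`branch_mode="m0"`); simulation studies pass the true tree and use
`branch_mode="fixed"`.  Stop codons in input are an error; all-gap codon
sites are dropped with a warning.

A reporting rule worth stating: a significant two-ratio branch test with
foreground ω̂ < 1 is evidence of *relaxed or shifted purifying* selection,
never of positive selection.

## Calibration and sensitivity studies

The packaged studies (test suite and `scripts/acceptance.py`) use:

* **LRT calibration**: 13 taxa, 300 codons, random topology with total
  length 5 substitutions/codon; null M1a (p0 = 0.7, ω0 = 0.1), alternative
  adds ω2 = 3 on 15% of sites.  Fits use the generating codon frequencies:
  with per-replicate F3×4 plug-in the measured false-positive rate at the
  χ²₂ 5% threshold is ≈8% (the extra M2a class partially absorbs
  frequency-estimation noise — itself a finding worth knowing), while
  under the generating frequencies the test shows the conservative
  boundary behavior the theory predicts.  The study isolates LRT
  calibration; the pipeline proper estimates F3×4 from data.
* **Sensitivity battery**: default 18-member families under three presets
  (strict/loose BLOSUM62, loose BLOSUM45-NJ), BioNJ trees, M1a→M2a fits
  per back-mapped codon alignment, NEB flags mapped to residue tokens so
  flagged sets are comparable across alignments (Jaccard overlap).
  Problem sizes (20 families in the test suite, 6 in the acceptance
  script; single-restart fits) are the package's desk-scale choices.

## Known limitations

* The progressive aligner has no iterative refinement or
  phylogeny-aware gap placement; it brackets, rather than reproduces, the
  behavior of specific MSA programs.
* NEB posteriors understate uncertainty in the mixture parameters;
  "beb-lite" mitigates but does not reproduce the full hierarchical
  method.
* SPR moves, Bayesian tree inference, model selection across amino-acid
  matrices, and joint alignment-tree sampling are out of scope; the
  "reference" anchor generalizes whatever gold standard the user trusts.
* The saturation index is a self-contained criterion, not a reimplementation
  of the classical published tests.
* Branch lengths under site models are rescaled, not re-optimized, per
  model — standard practice, but a known approximation.
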