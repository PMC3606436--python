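# Methods

## Overview

`mirlassonet` treats disease–miRNA association as a sparse regression
problem: the response is a disease's gene signature over a shared gene
universe, the predictors are per-miRNA binary influence profiles, and the
nonzero (positive) Lasso coefficients define the predicted association
network. This note documents each stage, the defaults and why they were
chosen, the numerical details of the solver, what the synthetic benchmark
does and does not show, and known limitations.

## Disease gene signatures

**Expression signatures.** For a genes × samples matrix with a two-group
(control/case) design, each gene gets a moderated mean-difference score

    d_i = (mean_case_i − mean_control_i) / (s_i + s0),
    s_i = sqrt((1/n1 + 1/n2) · (SS_control + SS_case) / (n1 + n2 − 2)),

the pooled standard error of the group difference. The fudge factor `s0`
(default `"auto"` = the median of the `s_i`) keeps low-variance genes from
dominating the ranking. Genes are then selected purely by rank — the `k_up`
largest positive and `k_down` most negative scores (defaults 100/100, i.e. a
top-200 signature), ties broken by |d| descending then gene id ascending —
so the permutation/FDR machinery of full SAM is unnecessary and deliberately
omitted. Both groups need at least two samples. When one disease has several
experiments, each is scored independently and the per-experiment signatures
are unioned.

**Text signatures.** A relevance table (disease, gene, relevance score,
citation count) is filtered to genes with relevance strictly greater than
`min_relevance` (default 0) and at least `min_citations` citations (default
11, i.e. strictly more than ten). Text mining carries no direction, so these
genes are direction-unknown.

**Merging and encoding.** The merged signature is the set union; expression
direction wins for genes present in both. Because text genes have no
direction and the union step mixes provenances, the response is encoded as
binary membership {0,1} over the universe by default; a signed {−1,0,+1}
encoding (down-regulated genes −1) is available via `Config.signed_response`
for purely expression-derived analyses.

## The miRNA influence matrix

Direct miRNA→gene target predictions (e.g. a TargetScan or PITA export) are
augmented with *indirect* targets propagated one step through an undirected
PPI network: gene g is an indirect target of miRNA j when g is not a direct
target of j but at least `min_neighbors` (default 5) of g's PPI neighbors
are. Multiple PPI sources are unioned into one network before propagation.

The "not targeted" clause is read **per miRNA** by default: each column of
the influence matrix must be a profile of miRNA j specifically, and excluding
genes targeted by *any* miRNA would make columns depend on the whole miRNA
complement. The literal any-miRNA reading is available
(`Config.any_mirna_indirect`, CLI `--any-mirna`). Propagation is exactly one
PPI step; multi-hop diffusion is out of scope.

The regression operates on the intersection of the influence-matrix gene
universe (genes with at least one direct or indirect entry) and the
signature universe (genes in at least one disease signature), with identical
row order in both matrices.

## The penalized regression

Objective, for one disease with response y (n genes) and predictor matrix X
(n × p miRNAs):

    minimize over (β0, β):  (1/2n) ‖y − β0 − Xβ‖² + (λ/2) ‖β‖₁.

The ½ inside the penalty mirrors the model's parameterization
P(β) = Σ ½|β_j|; it is absorbed as an effective L1 level λ_eff = λ/2, so the
solver is a standard Lasso while reported λ values stay on the model's own
scale. The 1/(2n) normalization makes λ_max well-scaled and cross-validation
errors comparable across gene universes of different size.

**Solver.** Cyclic coordinate descent with soft-threshold updates,
implemented on the Gram matrix (G = X'X/n is computed once per design; each
coordinate update is O(p)). Full sweeps alternate with iteration restricted
to the active set; convergence requires a full sweep whose largest
coefficient change is below `tol` (default 1e−8), with a hard `max_iter`
sweep cap that raises rather than returning silently. The objective is
non-increasing across sweeps (asserted in tests via an optional per-sweep
objective trace). Constant predictor columns are pinned to zero with a
warning. The intercept is unpenalized.

**Standardization.** Predictors are centered and scaled to unit standard
deviation inside the solver by default (`Config.standardize`) because binary
target columns have very different densities and would otherwise be
penalized unevenly; coefficients are always reported on the original scale.

**λ path and selection.** The path is log-spaced from
λ_max = (2/n)·max_j |x̃_j'(y − ȳ)| (the smallest penalty with an all-zero
solution; x̃ is the standardized column) down to λ_max·`lambda_min_ratio`
(default 1e−3), with `lambda_grid_size` = 100 points, warm-started in
decreasing order. λ is selected by `n_folds` = 10-fold cross-validation:
genes are shuffled with a recorded seed (default 17), split into contiguous
blocks, and the mean held-out squared error is minimized; exact ties go to
the larger (sparser) λ. Genes are treated as exchangeable units for folding.

**Association extraction.** Edges are coefficients at the selected λ;
negative coefficients are dropped by default (`keep_sign="positive"`) since a
miRNA whose targets are *depleted* in a disease signature has no
interpretation as a functional driver in this framework. No clipping or
rescaling of scores is applied.

**Gene-list mode.** Any gene list can replace a disease signature: the
response becomes the list's membership indicator over the influence-matrix
universe and miRNAs are ranked by coefficient (`fit_gene_list`, CLI
`enrich --method lasso`), with Fisher and hypergeometric rankings as
baselines.

## Validation

Predicted edges are compared with a gold-standard edge set over the full
disease × miRNA grid: positives are gold pairs, negatives all other grid
pairs, and pairs without a prediction score 0 (the Lasso zeroes
non-associations by construction, so absence is a genuine zero score). ROC
curves come from a threshold sweep with tied scores collapsed into single
segments; the trapezoidal area equals the Mann–Whitney rank AUC with midrank
tie handling (asserted to 1e−12 in tests). Per-disease ROC is the default
report; a pooled ROC over the whole grid is also computed. Fisher's exact
test is two-sided by default (one-sided available); the hypergeometric test
is the upper tail P(overlap ≥ observed). Enrichment p-values are reported
uncorrected.

## The synthetic benchmark

The generator (`synth`) produces every input the pipeline consumes from one
master seed: an Erdős–Rényi PPI network (edge probability mean_degree/(n−1)),
uniform direct target draws, per-disease expression, a text table and a gold
standard. Per disease, a few *planted* miRNAs are drawn; the true signature
is the union of their direct and indirect targets, thinned by a dropout
fraction and polluted by a noise fraction of random genes; case samples shift
signature-gene expression by ±`effect_size` within-group standard deviations
(sign fixed per gene); the text table covers a seeded half of the signature
plus decoy records that must fail the relevance/citation filters; the gold
standard is exactly the planted pairs.

Defaults — 600 genes, 50 miRNAs with 30 targets each, PPI mean degree 6,
8 diseases × 3 planted miRNAs, dropout 0.3, noise 0.2, effect size 2.0,
10 samples per group — keep a full pipeline run at a few seconds while
exercising every stage; they are the conditions under which the recovery
properties in the test suite are stated. An effect size of 2 with n = 10 per
group is a strong but realistic microarray contrast; recovery degrades
monotonically as the signature noise fraction rises (tested across
0/0.3/0.6).

**What the benchmark does not emulate.** Expression is i.i.d. normal per
gene — no gene–gene covariance, batch effects or probe-level artifacts — and
signatures are generated directly from the planted miRNAs' target sets, so
the benchmark measures the pipeline's ability to invert its own generative
assumptions, not performance on real tissue data. One structural consequence
of the Erdős–Rényi default deserves note: with mean degree 6 and a 30/600
target density, essentially no gene has ≥5 neighbors among one miRNA's
targets, so the *indirect* target set is empty or near-empty and the
with/without-propagation comparison typically ties. Indirect targets matter
on hub-rich networks; the `barabasi-albert` PPI option exists precisely
because hubs interact with the ≥k-neighbor rule, and the propagation rule
itself is verified directly against brute-force neighbor counting on dense
random graphs.

## Degenerate inputs and tie-breaks (summary)

* Zero-variance response column → error naming the disease; a constant
  training fold simply yields the null model and contributes the held-out
  variance.
* Constant predictor columns → coefficient pinned to 0, warning.
* λ ≥ λ_max → exactly zero coefficients (soft threshold, not tolerance).
* Signature-selection ties → |d| descending, then gene id ascending.
* CV ties → larger λ. Equal scores in ROC → one sweep segment (diagonal),
  equivalent to half-credit for tied positive–negative pairs.
* Self-loops in undirected edge lists dropped with a warning; duplicate
  expression rows keep the first occurrence.

## Limitations

* Identifier handling is symbol-level uppercase normalization; no alias or
  cross-database resolution.
* One PPI propagation step, unweighted edges, binary influence values.
* No inference on coefficients (no p-values, stability selection or
  confidence intervals); scores are comparable within a run, not across
  datasets.
* The ROC negative set (all non-gold grid pairs) treats unknown associations
  as negatives, so reported AUCs are conservative on incomplete gold
  standards.
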