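# Methods

This note documents the statistical procedures implemented in `assocnet`,
the defaults and the reasoning behind the genuinely open design choices.

## Normalization and filtering

Raw intensities are shifted by `1 − min` when non-positive values are
present (background subtraction can produce negatives), log2(x+1)
transformed, and quantile-normalized across samples: every column is
mapped onto the mean of the sorted columns, with rank ties receiving the
mean of the target quantiles they span. Tie handling is deterministic so
identical inputs give byte-identical outputs on any platform. Quantile
normalization forces identical per-sample distributions; when a large
fraction of probes genuinely shifts in one class this slightly attenuates
fold changes — a known, accepted property of the method.

Probe filters: `variance` keeps probes at or above the q-th variance
quantile (default q = 0.5); `factorial` keeps probes whose overall F from
the two-factor fit has nominal p < 0.05, capped at the top 5000 by F. A
filter leaving fewer than 10 probes is an error. Neither filter reorders
retained probes.

## Differential expression

Per probe, OLS on the design `[1, class, strat, class:strat]` with
treatment coding. The reference level of each factor is the control-like
level (`control`, `ctrl`, `healthy`, `baseline`, ...) when one exists,
otherwise the alphabetically first level — so the class coefficient always
reads case minus control with conventional labels, and is still
deterministic for arbitrary ones. The reported contrast defaults to the
class main effect (the class difference within the reference stratum);
any coefficient can be named explicitly in the run configuration.

Empirical-Bayes moderation uses the classic closed forms: with residual
variances s²_g on d_g degrees of freedom, the prior (d₀, s₀²) is obtained
by matching the mean and variance of log s²_g using digamma/trigamma
identities; the trigamma equation is inverted by Newton iteration. When
the observed spread of log s² does not exceed its sampling spread the
moment equations have no finite solution; d₀ is then capped at 10⁶, which
numerically reproduces the infinite-prior limit (all posterior variances
collapse to s₀²). Moderated t = β̂ / (s̃ √v) on d₀ + d_g df; forcing d₀ = 0
recovers the ordinary t exactly (asserted against an independent OLS
oracle). BH adjustment is implemented directly (step-up with NaN
propagation) and cross-checked against statsmodels on random vectors.

## Co-expression modules

Unsigned network: a_ij = |cor|^β, zero diagonal; Pearson throughout, with
Spearman available where correlations face the phenotype. The soft power β
is the smallest value in 1..20 whose signed scale-free fit R² (log10 p(k)
vs log10 k over 10 connectivity bins) reaches 0.8, default 6 otherwise.
TOM as given in the README; symmetric, unit diagonal, entries in [0, 1],
verified against a triple-loop oracle.

Module detection is a static cut of the average-linkage tree of 1 − TOM at
0.99 × the maximum merge height, followed by a minimum-size filter
(default 30 probes for array-scale data, 10 at synthetic scale) and
iterative merging of modules whose eigengenes correlate at ≥ 0.75 (the
most correlated pair merges first, until no pair qualifies). This replaces
the dynamic hybrid tree cut with a reproducible desk-scale equivalent; on
planted two-module structure it recovers membership with ARI 1.0, and
labels are stable under probe permutation. Module labels follow the
conventional colour sequence in decreasing size order; `grey` collects
unassigned probes.

The eigengene is the first right-singular vector of the per-probe
standardized member matrix, unit norm, sign-oriented to correlate
non-negatively with the mean standardized member profile. Metrics:
modAUC1/modAUC2 are rank-statistic AUCs of the eigengene scoring the
case-like class and second-factor level, reported unflipped (values below
0.5 carry direction information alongside diffME); diffME is the
case-minus-control difference of median eigengene values; sigenrich is
−log10 of the smallest BH q over the module's hypergeometric tests against
the designated marker collection (a declared stand-in where no published
formula exists; 0 when no collection is configured).

Intra-module connectivity edges: pairs ranked by TOM descending, retaining
min(2000, max(1, ceil(0.10 × #pairs))) edges ("at least the top 10 %,
capped at 2000" read literally: the ceil applies first, the cap binds
after), lexicographic tie-breaks.

## Pre-defined module repertoire

Module definitions come from a GMT and are identical across datasets,
which is what makes the score matrix directly comparable in meta-analysis.
The per-contrast score is pct_up − pct_down of member probes with q < 0.05
(configurable threshold); the per-dataset test applies the same factorial
moderated-t machinery to per-module mean log2 expression, BH across
modules. The direction-consistent subset requires a strictly common
nonzero sign in every dataset; zero scores are sign-less and excluded.
Whether the original heatmap statistic was percent-significant or mean
fold change is not documented anywhere accessible; percent-up minus
percent-down is the declared choice here.

## Deconvolution

Bulk mixtures are linear on the intensity scale, so fitting happens on
2^x − 1 when the input is log2 data. Per sample, non-negative least
squares against the basis restricted to shared probes (at least half the
basis probes must be present, and ≥ 2 per cell type), then renormalized to
the unit simplex; an all-zero solution falls back to uniform proportions
with a warning. Class differences per cell type use the two-sided Wilcoxon
rank-sum (Kruskal–Wallis beyond two levels), BH across cell types; these
are the diffP/diffQ properties of `cellprop` nodes. Noiseless mixtures are
recovered to < 1e-6 per component; proportions are invariant to probe
order and to per-sample scaling.

## Enrichment and the retention policy

One-sided hypergeometric over-representation with the universe fixed to
the symbols of filtered probes (enrichment must condition on what was
measurable). The multiple-testing family is one module × one collection —
never across collections — matching per-run correction behaviour of the
classic list-enrichment tools. Retention per module: BH-significant sets
ranked by p, truncated at 10; when fewer than the minimum (3, or 4 for the
curated-pathway collection) pass, the top nominally significant sets
(p < 0.05) are retained instead and flagged `relaxed`; with no nominal hits
nothing is retained. The corrected q is stored on every retained edge
either way, so downstream filtering stays possible.

## Graph store

An in-process property graph replaces a database server while preserving
the data model: node identity is (label, name, square, edge) where
`square` is the dataset id ("" for annotation nodes shared across
datasets) and `edge` the contrast id; edge identity is (source, target,
type, graph index). MERGE is idempotent with last-write-wins property
overlay, making union a fold of merges — associative and repeat-safe,
asserted on randomized fixtures. Pattern matching is undirected simple-path
search with property predicates (a predicate on a missing property fails
that candidate); paths are reported once per node sequence in
lexicographic order and verified against brute-force enumeration.
Exports (GraphML via networkx, node/edge TSVs, Cypher MERGE script) are
sorted by identity key, so re-exported files are byte-identical.

## Virtual cells and activity

A module links to a cell type only when both lines of evidence hold:
BH-significant correlation of its eigengene with that cell's estimated
proportion (family = all module × cell pairs in the dataset) and at least
one retained marker enrichment resolving to that cell via the consensus
name map. The virtual cell is the probe union of linked modules with its
correlation matrix, pathway annotations and DE overlay. Activity entries
are means of positive (resp. negative) log2 fold changes over the probes
shared by the virtual cell and a pathway; all probes in the intersection
contribute by default (a q-threshold flag restricts to significant ones);
empty intersections are absent, not zero. Rankings are row/column sums
with signs kept separate. Cross-dataset comparison clusters cell instances
by average linkage on Euclidean distance, imputing absent entries as 0
inside the distance only — exports keep them missing, because no evidence
is not zero activity.

## Phenotype association

Categorical variables are encoded as integers in alphabetical level order
(recorded), identifiers never, constants dropped. Univariate screening:
rank-sum for numeric variables, Fisher exact (2×2) or chi-square for
categorical, BH across variables. Eigengene correlations are Pearson by
default (Spearman by flag), BH over all module × target pairs per
bipartite family, edges kept at q < 0.05 with R as weight.

## Synthetic data

The generator emulates a blood-transcriptomics cohort: Dirichlet(5)
cell proportions per sample with one cell type shifted by +0.15 (then
renormalized) in cases; a signature basis with marker probes 10× brighter
in their own cell type and dimmed 10× elsewhere; mixture expression
signature·proportions on the linear scale; planted modules riding
per-sample latent factors with 0.5 log2 loadings, module 0 carrying the
disease effect (+1 log2 by default) and module 1 the sex effect;
log-normal noise (SD 0.5 log2 units by default); and a numeric covariate
tracking the disease module's latent signal (noise chosen so R ≥ 0.8 by
construction). Latent factors are centered within each class × sex stratum
so planted effects equal the stated shifts exactly. Defaults produce 1850
probes × 60 samples. Platform structure (probe set, baselines, basis,
annotations) follows `seed`; sampling can follow a separate `sample_seed`,
letting several datasets share one platform as real multi-cohort studies
do. All outputs are byte-identical under a fixed configuration.

The annotation fixtures include corrupted marker collections (20 % dropout
and 20 % decoy swap-in) to exercise enrichment robustness, pathway
collections that copy or subsample planted modules plus decoys, and a
pre-defined repertoire mixing planted-module copies, cell-marker sets and
random sets — cell-derived sets are included because real blood-module
repertoires contain them and the repertoire × marker enrichment graphs
would otherwise be structurally empty.

What the generator does **not** emulate: platform-specific bead-level
noise, batch effects, detection p-values, correlated marker expression
across cell types, or non-factorial designs. Passing tests demonstrate
correctness of the machinery and recoverability of planted structure
under this model — not performance on any real cohort.

## Problem sizes and numerics

Tests and the acceptance script run at desk scale by design: ~1850–2000
probes × 60 samples per dataset, two datasets in the structural build,
20 000 probes for the null-calibration check, oracle comparisons at
N ≤ 200 (hypergeometric), 30 probes (TOM), 50 samples (AUC) and ≤ 50-node
graphs (pattern matching). Oracle agreement is required to 1e-12.
Degenerate inputs: constant probes are fatal for the network stage
(filter first), zero-variance eigengene members are dropped with a
warning, fully tied rank tests return p = 1, and rank-deficient designs
fail naming the aliased column.

## Known limitations

- No blockwise module detection; the TOM is dense, so inputs beyond
  ~20 000 filtered probes are impractical.
- No RNA-seq support (count models), no batch correction, no consensus
  modules across datasets.
- The Cypher export targets import into a graph database; the in-process
  query engine supports the path-pattern/predicate subset only, not full
  Cypher.
- modAUC confidence is not quantified; at small n an AUC near a decision
  threshold should be interpreted with its sampling error (~0.05 at
  20 per group) in mind.
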