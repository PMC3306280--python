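# Methods

This note documents the models, numerical choices and limitations of
`modprog` in the order the pipeline runs.

## Preprocessing

Expression matrices are tab-delimited, genes × samples, log-scale values.
Empty cells and the literal `NA` are treated as missing — this covers the
common exports of the microarray platforms the method targets. Multiple
probe rows per gene are collapsed by the arithmetic mean, computed per
sample over the observed entries only (the collapse is idempotent).
Remaining missing entries are filled by k-nearest-neighbour imputation
(default k = 10, the long-standing default of the classic kNN imputers for
microarray data): neighbours are other gene rows, nearness is Euclidean
distance over mutually observed positions scaled by the fraction observed
(nan-Euclidean), and the imputed value is the neighbours' mean at that
position. Observed entries are never modified; a fully missing gene row is
an error rather than a silent column-mean fill. Sample curation (for
example dropping higher-stage tumours from a validation set) is expressed
as a configuration-level include/exclude list, never hard-coded.

Gene identifiers are assumed to be symbols in a single namespace shared by
the expression matrix, gene sets, interaction list and catalogs; no
identifier mapping is performed.

## Co-expression networks

One network per gene set, for three reasons: prior pathway information
focuses module discovery; multi-functional genes may appear in several
modules; and restricting interactions to within a functional set suppresses
in-vitro-only false-positive edges. Weights are |Pearson r| over exactly
the samples of the current analysis subset — the classifier re-derives
weights for every half-cohort it builds, since correlations legitimately
change with the samples present. Which samples feed the weights is
therefore a parameter, defaulting to the subset under analysis. A
zero-variance gene (possible after filtering, and in synthetic data) gets
weight 0 on all its edges with a warning instead of aborting the build.
Computed |r| is clamped to 1 to absorb a few ulp of rounding on collinear
vectors. Sets whose measured genes induce no interaction edge are skipped
and logged; isolated in-set genes remain as vertices and end up as
discarded singletons.

## Module discovery

Edge score = (unweighted-topology shortest-path edge betweenness, unordered
pairs, equal fractional credit among co-shortest paths) / edge weight.
Paths are counted on the topology and only the final division uses the
weight; a weighted-distance variant (path lengths 1/w) exists behind
`weighted_paths` but is not the default. Zero-weight edges use an epsilon
floor of 1e-6 in the divisor so they score high but finitely.

Removal loop: recompute scores, delete the single highest-scoring edge,
repeat until every connected component has at most 20 genes (the
`module_cap`). The classical modularity-Q dendrogram cut is deliberately
not used — it produces size-unstable, sometimes huge modules; the hard size
cap is the stopping rule. Removal candidates are restricted to components
still above the cap: the loop exists to break oversized components, and a
near-zero-weight edge inside an already-compliant component would otherwise
score ~1/epsilon and needlessly fragment finished modules. Exact score
ties are broken by the lexicographically smallest node pair, making the
partition reproducible across platforms; a `batch_removal` flag removes all
co-maximal edges at once for users who prefer that variant. Components of
≥ 2 genes become modules; singletons are counted and discarded.

Raw betweenness counts come from igraph's C implementation (verified in the
test suite against an independent all-shortest-paths enumeration oracle and
against networkx); the weight division, stopping rule and tie-breaking are
implemented here.

## Module ranking

Per-gene statistics are Welch two-sample t by default — tumour cohorts
routinely violate equal-variance assumptions — with a pooled-variance
option. Degenerate genes (both groups constant): t = 0 when means agree,
|t| capped at 1e6 with a warning when they differ. SDS = Σ t² over the
module's genes is calibrated by the upper tail of chi-square with k = module
size degrees of freedom, and modules sort ascending by p with the
deterministic tie chain (p, −SDS, set id, gene list). The chi-square
reference treats each t as approximately standard normal under the null;
with ≥ 25 samples per class the realised false-positive rate of p < 0.05 is
0.05–0.07 (slightly anti-conservative for large k because t² has heavier
tails than χ²₁) — checked, not assumed, in the test suite. Duplicate
modules arising from overlapping gene sets are intentionally not
deduplicated. The observation that practical top lists have p ≤ 0.005 is
surfaced as a diagnostic (`top20_max_p`), not enforced as a filter.

## The overlap classifier

Training samples are split into two halves, each class divided as evenly as
possible (odd counts favour half 1), fully determined by a seed; per-split
seeds derive deterministically from one master seed (seed + split index).
Each half is pushed through the full pipeline to a top-N module gene union;
OP_old(N) is the two unions' intersection-over-union. The test tumour is
assumed recurrent, added to both halves, the pipeline re-run, and
OP_new(N)/OP_old(N) recorded; ⟨OP⟩ averages these components over the N
grid and the splits (all components equally weighted — both averaging
orders coincide when nothing is dropped). Components with OP_old = 0 are
dropped with a warning rather than mapped to infinity.

Two modes:

* `full` — networks, modules and rankings are recomputed whenever the test
  tumour is added (faithful; expensive);
* `rank_only` — each half's modules are frozen and only t statistics and
  the ranking are recomputed (a clearly labelled approximation, orders of
  magnitude faster; used for the large synthetic evaluations).

**Where the signal lives.** ⟨OP⟩ carries label information only where
top-N membership is sensitive to the test tumour: modules far above the
boundary stay ranked top whatever one sample does. With synthetic cohorts
whose five planted modules are individually very strong, the extreme top of
the ranking is saturated, so the N grid for synthetic-scale runs is
(30, 40, 50, 60, 80) — the mid-depth of a ~150-module ranking, where
partially-planted modules (planted genes recurring in other gene sets'
modules) cross the boundary. The library default grid (100…500) matches
cohorts with thousands of modules, where it occupies the same mid-depth
band. n_splits defaults to 10.

Evaluation: ROC over all score thresholds with recurrent as positive, AUC
by the trapezoidal rule, and accuracy/sensitivity/specificity read off at
the ROC point nearest (0, 1) (ties resolved toward higher sensitivity).
Leave-one-out scores every labelled sample against the rest;
fixed-training-set validation draws training sets of a given size (redrawing
up to 100 times until both classes have the 4 samples each the split
needs) and summarises mean/min/max over repeats. In pure prediction mode no
threshold is imposed — the score is reported and thresholding is the
caller's decision.

## Validation statistics

* Known-gene enrichment: fraction of the top-N module gene union found in a
  catalog, compared with (a) the equally sized list of individually most
  differentially expressed genes ("t-test genes") and (b) whole gene sets
  ranked by the same SDS/χ² machinery over all their measured members.
* Mutated modules: one-sided Fisher exact (hypergeometric upper tail) per
  module against the universe of all network genes; modules with p < 0.05
  are MMs. The enrichment ratio is the MM fraction in the top N over the MM
  fraction in the rest, with a Fisher p for the 2×2 top/rest × MM/non-MM
  table. A Haldane-corrected ratio (+0.5 cells) is reported alongside, and
  used for permutation nulls, because the exact ratio is infinite when the
  rest of the ranking holds no MMs.
* Label permutations preserve class sizes; empirical p uses the add-one
  rule (r+1)/(n+1) to avoid zero p from finite permutations.
* Grubbs outlier test: one-sided for a single high outlier, the observed
  value appended to the null sample; p = min(1, n·P(T_{n−2} > t)) with the
  standard critical-value inversion. Approximate normality of the null is
  the caller's responsibility.
* Gene appearance frequency: over repeated class-balanced bisections
  (default 1000; tests and the acceptance script use fewer splits at their
  smaller problem sizes), a gene counts when it lies in the top-N union of
  both halves; raw counts divide by interaction-network degree since hubs
  reach more modules by chance.

## Synthetic cohorts

The generator emulates the statistical structure the method assumes, not
microarray artefacts. Defaults (the recoverability condition used
throughout): 500 genes, 30 gene sets of 10–80 genes drawn with natural
overlap, 25 samples per class, 5 planted 8-gene modules, within-module
correlation ρ = 0.6, class shift 1.5 noise-sd, unit noise on an N(8, 2)
log2-like baseline.

Expression follows a Gaussian one-factor model per planted module:
x = baseline + noise_sd·(√ρ·f + √(1−ρ)·ε) + shift·noise_sd·1[recurrent],
giving pairwise within-module correlation ≈ ρ — the simplest generator
matching the Pearson-weight assumption. Planted modules are embedded
inside host gene sets with dense internal wiring (edge probability 0.8 plus
a random spanning path, so they are connected by construction) against a
sparse background (0.05 within sets): the algorithm can only find modules
that are topologically present. Mutation flags are Bernoulli 0.05
background / 0.4 inside planted modules. Structure (sets, edges, planting,
mutations) and expression use separate streams derived from one seed, so
two cohorts can share a structure while drawing independent noise — the
cross-dataset reproducibility setting.

What passing synthetic tests does **not** show: robustness to batch
effects, platform differences, probe-level artefacts, non-Gaussian
expression, mislabelled follow-up, or signal spread over hundreds of weak
modules rather than a few strong ones.

## Problem sizes

The test suite and `scripts/acceptance.py` run at the synthetic scales
above: 2000 modules per k for null calibration (30 samples/class), 10
cohorts for planted recovery, 3 seeds × (40 training + 20 held-out) for
classifier AUC in rank-only mode, 50 label permutations for the overlap
null, 20 for the enrichment null. These sizes were chosen as the smallest
at which the checked quantities are stable.

## Known limitations

* The chi-square calibration is slightly anti-conservative for large
  modules and small cohorts (t² vs χ²₁ tails); ranking, the quantity the
  pipeline actually consumes, is unaffected.
* `rank_only` mode never updates module composition for the test tumour;
  with strong co-expression changes between classes the full mode can
  differ.
* The classifier's discriminative power depends on the N grid sitting in
  the label-sensitive mid-depth of the ranking; a grid entirely inside the
  saturated top (or deep in the noise tail) degrades toward AUC 0.5.
* Identifier mapping, upstream normalisation and resource curation
  (interaction databases, gene-set releases, mutation catalogs) are out of
  scope; files are consumed as given.
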