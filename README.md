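# modprog — multi-gene-module prognosis prediction

`modprog` predicts post-surgical tumour recurrence (colorectal cancer being
the motivating setting) from expression profiles of **multi-gene functional
modules** rather than individual signature genes. Single-gene signatures
transfer poorly between cohorts and platforms; module-level expression
changes are far more reproducible, and `modprog` turns that reproducibility
itself into the classification signal.

## Method

For a cohort of tumours labelled *recurrent* / *non-recurrent*:

1. **Per-gene-set co-expression networks.** For every functional gene set
   (e.g. a GO collection in GMT form), measured member genes become
   vertices, protein-interaction pairs inside the set become edges, and
   each edge *(i, j)* is weighted by

   w_ij = | corr(x_i, x_j) |,

   the absolute Pearson correlation of the two genes' expression vectors.

2. **Size-capped weighted Girvan–Newman modules.** Each edge is scored by
   its shortest-path betweenness divided by w_ij, so topologically central
   but weakly co-expressed edges are cut first. The highest-scoring edge is
   removed and scores recomputed until no connected component exceeds 20
   genes; components of ≥ 2 genes are the modules, singletons are
   discarded.

3. **Module ranking by differential expression.** Each gene *i* gets a
   Welch two-sample *t* statistic t_i between the classes. A module *s*
   with *k* genes gets the score of differential significance

   SDS(s) = Σ_{i∈s} t_i²,   p(s) = P(χ²_k ≥ SDS(s)),

   and modules are ranked ascending by p.

4. **The overlap classifier.** The training set is split into two
   class-balanced halves; each half yields a top-*N* module gene union, and
   the two unions' overlap percentage (intersection / union) is the
   baseline OP_old(N). A test tumour X is then *assumed recurrent*,
   inserted into both halves, and the pipeline re-run to give OP_new(N).
   The score

   ⟨OP⟩(X) = mean over random splits and N of OP_new(N) / OP_old(N)

   is high when X genuinely reinforces the shared recurrence signal —
   higher ⟨OP⟩ means higher recurrence risk. Evaluation uses ROC/AUC with
   the operating point nearest (0, 1).

Validation statistics (enrichment of known recurrence genes versus t-test
gene and whole-gene-set controls, Fisher-exact *mutated module* enrichment
with label-permutation nulls, cross-cohort top-module overlap with Grubbs
outlier testing, and connectivity-normalised gene appearance frequencies
over repeated splits) are provided in `modprog.validation`, and a synthetic
cohort generator with planted, correlated, class-shifted modules in
`modprog.simulate`.

## Worked example

```python
import modprog as mp

cohort = mp.generate_cohort(mp.SyntheticConfig(seed=1))   # 500 genes, 25+25 samples
model = mp.ModulePrognosis.from_cohort(cohort)
results = model.fit()
print(results.summary(top=5))
```

```
Module-based prognosis fit
============================================================
samples:            50 (25 recurrent, 25 non-recurrent)
gene sets:          30
networks built:     30
modules (<= 20):     164 (+107 singletons discarded)
median module size: 6.5
max p in top 20:    3.55e-10
------------------------------------------------------------
rank set_id         k        SDS          p  genes
   1 SET000         9     283.20   9.48e-56  G0048,G0085,G0158,G0190,...
   2 SET004        20     259.40   1.44e-43  G0078,G0122,G0173,G0174,...
   3 SET003        13     210.53   9.36e-38  G0021,G0049,G0076,G0167,...
   4 SET001        11     179.90   1.07e-32  G0014,G0033,G0035,G0109,...
   5 SET028        11     175.85   7.37e-32  G0085,G0087,G0318,G0327,...
============================================================
```

The 164 discovered modules are ranked by their chi-square-calibrated SDS;
the top entries are the planted differentially expressed modules (SET000 is
a planted 8-gene module embedded in a 9-gene component). Scoring four
held-out tumours:

```python
held_out = ["R020", "R021", "N020", "N021"]
train = [s for s in cohort.dataset.sample_ids if s not in held_out]
print(model.predict(held_out, training_samples=train,
                    n_splits=10, n_grid=(30, 40, 50, 60, 80),
                    seed=7, mode="rank_only"))
```

```
           score
sample
R020    1.012718
R021    1.000195
N020    0.981304
N021    0.990623
```

The two truly recurrent tumours (R020, R021) keep the cross-half module
overlap at or above its baseline (⟨OP⟩ ≥ 1), the two non-recurrent tumours
dilute it (⟨OP⟩ < 1) — exactly the separation the classifier thresholds.

## Command line

```bash
modprog simulate --seed 1 --out-dir fixture/
modprog predict  --expression fixture/expression.tsv --labels fixture/labels.tsv \
                 --gene-sets fixture/gene_sets.gmt --interactions fixture/interactions.tsv \
                 --test-samples R020,N020 --fast-rank-only --out-dir out/
modprog evaluate-loo ... / evaluate-fixed --train-size 34 ... / validate ...
modprog run --config run.yaml        # any subcommand from one YAML config
```

Every run writes TSV/JSON artifacts plus a `manifest.json` with input
checksums, parameters and the seed; fixed seeds make runs bit-reproducible.

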