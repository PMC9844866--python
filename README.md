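# writersig

Prognostic-signature construction for low-grade glioma (LGG) bulk
expression cohorts, built around the RNA-modification "writer" gene
program: enzymes depositing m6A/m1A marks, alternative-polyadenylation
factors, and A-to-I editing enzymes whose expression patterns stratify
glioma outcome.

The package implements the full analysis chain as a tested, reusable
library plus CLI:

1. **Consensus non-negative matrix factorization (CNMF) subtyping** —
   repeated multiplicative-update NMF runs aggregated into a sample
   co-clustering matrix, cut by average-linkage clustering; cluster
   consistency is summarized by the average silhouette width (ASW) on
   `1 − consensus` and the cophenetic correlation.
2. **Moderated differential expression** — per-gene pooled-variance
   t-tests with empirical-Bayes shrinkage of the gene-wise variances
   toward a fitted inverse-gamma prior; DEGs are genes with
   `|log2FC| ≥ 0.5` and `p < 0.05`.
3. **VNLHHO gene selection** — a binary Harris Hawks optimizer with
   variable-neighborhood learning.  Hawks (candidate gene subsets encoded
   as positions in `[0,1]^G`) explore while the escaping energy
   `E = 2·E0·(1 − t/T)` satisfies `|E| ≥ 1` and besiege the best solution
   (the rabbit) otherwise, with Lévy-flight rapid dives accepted only on
   improvement; every hawk additionally learns from the best neighbor
   within ±k ring positions.  Fitness is
   `α · err_cv + (1 − α) · |subset|/G` with a stratified k-NN
   cross-validated error, α = 0.99.
4. **Prognostic screening** — univariate Cox (Wald) and median-split
   log-rank tests at `p < 0.001`; a gene must pass both.
5. **PCA score** — the signature submatrix (screen ∩ selected genes) is
   z-scored, its first two principal components extracted, and each
   sample scored as `PCA_score = PC1 + PC2` (its projections).  Samples
   split into low/high strata at the maximally selected rank-statistic
   cutpoint.
6. **Survival evaluation** — Kaplan–Meier curves, the two-group log-rank
   test, Cox proportional-hazards models (Efron ties, Newton–Raphson),
   IPCW cumulative/dynamic time-dependent AUC at 1/3/5/7 years, and
   Harrell's C-index — all implemented from first principles and
   cross-checked against lifelines / scikit-survival / statsmodels in the
   test suite.

Because the real CGGA/TCGA cohorts require controlled-access downloads,
the package ships a first-class synthetic-cohort generator
(`writersig.datasets`) that emulates their statistical structure: two
latent molecular subtypes separated by a planted informative gene set, a
large uninformative background, exponential survival whose hazard follows
the signature (`rate = λ0 · exp(β · risk)`), independent exponential
censoring, and clinical covariates correlated with subtype.  Every stage
is therefore testable against known ground truth.

## Worked example

```sh
writersig run-all --seed 7 --config config.yaml --out out/
```

with `config.yaml`:

```yaml
synthetic:
  n_samples: 120
  n_genes: 500
  n_informative: 20
  effect_size: 2.0
  log_hazard_ratio: 1.0
  seed: 11
```

prints the per-stage summary (formatted here for readability):

```
subtype    asw: 0.852  sizes: [70, 50]
de         n_degs: 23
select     n_selected: 4
screen     n_prognostic: 20
signature  n_signature: 4
score      cutpoint: 0.915  risk_direction: high_score_high_risk
```

and writes `out/evaluation.json` containing, for the training cohort:

```
logrank_p     5.7e-17          # low vs high PCA_score strata
median_os     14.72 vs 1.03    # years, low vs high stratum
c_index       0.737
td_auc        1y 0.752 / 3y 0.785 / 5y 0.849 / 7y 0.880
```

Reading: consensus clustering recovered two clean subtypes (ASW 0.85);
23 genes passed the DEG filter; the optimizer kept 4 of them, all of
which also passed the prognostic screen, so the fitted 4-gene PCA score
separates survival sharply (log-rank p < 1e-16) and predicts yearly
survival with AUC 0.75–0.88.  Every artifact (consensus matrix, DEG
table, selection trace, score model, manifest with content digests) is
written as plain TSV/JSON, and a second invocation with the same config
and seed reproduces all of them byte for byte.

The same stages are available individually (`simulate`, `subtype`, `de`,
`select`, `score`, `evaluate`) and as library functions — see
`docs/methods.md` for the statistical details and design choices.

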