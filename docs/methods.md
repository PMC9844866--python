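# Methods

This note records the statistical model behind each stage, the defaults
and why, and the design choices made where the construction was genuinely
open.  It states nothing the test suite or `scripts/acceptance.py` does
not itself compute.

## Synthetic cohorts

`generate_cohort` draws a genes × samples log2-scale matrix in which
every background gene is i.i.d. Gaussian with mean 8.0 (a typical log2
microarray/RNA-seq intensity) and standard deviation `noise_sd` in both
subtypes, while each of `n_informative` planted genes gains
`effect_size · noise_sd` in subtype 2.  The latent risk of a sample is
the standardized mean of its informative-gene expression; survival is
exponential with hazard `baseline_hazard · exp(log_hazard_ratio · risk)`
and censoring is independent exponential at `censoring_rate` (0 disables
censoring).  Categorical clinical covariates copy the subtype label and
flip independently with `covariate_flip_prob`, so covariate–subtype
association is tunable; age is Gaussian and uninformative.

Defaults (n = 300 samples, 500 genes, 20 informative, effect size 2,
noise sd 1, baseline hazard 0.12/yr, log-HR 1, censoring 0.08/yr, flip
probability 0.1) were fixed once: the expression geometry matches the
planted-structure conditions used throughout the tests, and the hazard
gives a median overall survival of roughly six years with a realistic
LGG-like censoring fraction.

What the generator does *not* emulate: heavy-tailed or count-based
expression noise, gene–gene correlation beyond the planted subtype
contrast, non-proportional or non-constant hazards, covariate-dependent
censoring, and batch structure.  Tests passing on these cohorts
demonstrate algorithmic correctness under the stated model, not
robustness to real-data pathologies.

The exponential survival model was chosen for closed-form checkability
(the true hazard ratio of any construct is known exactly); the hazard
shape of the real cohorts is unknown.

## Consensus NMF subtyping

`nmf` minimizes squared Frobenius error with the classical multiplicative
updates, whose objective is non-increasing at every iteration (asserted
in tests); random uniform initialization from the seed, `max_iter` 500,
relative-improvement tolerance 1e-6.  `consensus_matrix` aggregates
`n_runs` = 30 re-initialized runs (run r seeded `seed + r`); a sample is
assigned to the arg-max row of H, ties toward the lower factor index.
Re-initialization, not sub-sampling, is the consensus mechanism.  Samples
are partitioned by average-linkage hierarchical clustering of
`1 − consensus`, cut at k clusters (k = 2 by default — the two-subtype
structure this analysis targets), with deterministic first-occurrence
relabeling so label 1 always contains the lowest-index sample.

Log-scale input may be negative; it is shifted by its global minimum
before factorization.  The shift preserves all between-sample contrasts
and is recorded in the run metadata.  ASW is computed on `1 − consensus`
(the clustering-consistency reading) rather than on raw expression; the
cophenetic correlation of the consensus dendrogram is reported alongside.
An all-ones consensus cannot support k ≥ 2 clusters and is flagged
degenerate rather than silently split.

## Moderated differential expression

Per-gene pooled-variance t-tests between the two subtypes, with gene-wise
variances shrunk toward a scaled inverse-chi-square prior fitted across
genes by matching the moments of log sample variances (digamma/trigamma
inversion); posterior variance `(d0·s0² + df·s²)/(d0 + df)` with
`df + d0` degrees of freedom.  When the observed log-variances are less
dispersed than pure chi-square noise the prior degrees of freedom are
infinite and every posterior variance equals s0².  Setting the prior df
to 0 recovers the ordinary pooled t-test exactly, which the tests verify
against scipy.

The DEG filter keeps `|log2FC| ≥ 0.5` (inclusive) AND raw `p < 0.05`
(strict), ordered by ascending p.  Raw p, not FDR, is the filter
criterion; BH-adjusted FDR is reported in the table for transparency.
No covariates enter the DE model.  Genes with no within-group variation
are assigned p = 1 and flagged.

## VNLHHO gene selection

Binary wrapper selection over the DEGs.  Encoding: continuous positions
in `[0,1]^G`, binarized stochastically through the sigmoid transfer
`S(v) = 1/(1 + exp(−slope·(v − 0.5)))`, slope 10.  The Harris Hawks
phases follow the canonical formulation: exploration while
`|E| = |2·E0·(1 − t/T)| ≥ 1` (perch on a perturbed random hawk, or move
relative to the population mean and the bounds), soft/hard besiege of the
rabbit for `|E| < 1`, and progressive rapid dives with Mantegna
Lévy-flight steps (exponent 1.5) kept only on fitness improvement.  The
variable-neighborhood learning step arranges hawks on a ring; each moves
a random half of its coordinates toward the best hawk within ±k
positions, with k growing by 1 (to `vnl_k_max` = 3) after 5 iterations
without global improvement and resetting to 1 on improvement.

Fitness is `α · err + (1 − α) · |mask|/G` with α = 0.99, where err is the
stratified 5-fold cross-validated error of a 5-NN classifier (Euclidean,
features z-scored once on the full matrix) on the masked submatrix.  Fold
membership is drawn once per run from the run RNG, so fitness is a
deterministic, memoizable function of the mask and the best-so-far
trajectory is provably non-increasing.  The empty mask carries an
infinite sentinel fitness.  Defaults: population 30, 100 iterations.

Two behaviors worth knowing.  First, the canonical update equations
clipped to the unit box concentrate positions near the lower corner, so
mask-space coverage collapses once the population converges; on ambiguous
landscapes (fitness gaps of a single CV error) the optimizer can settle a
few errors short of the global optimum, while on clearly separable
instances it reliably attains it up to at least a dozen genes.  Second,
with α = 0.99 the sparsity term dominates among zero-error masks, so on
strongly separable cohorts the optimum is a *minimal* zero-error subset:
when many planted genes are individually redundant (a handful already
classify perfectly), the selected set is legitimately much smaller than
the full planted set.  Selection recovers a discriminative subset, not
the complete causal set.

## Survival statistics

All estimators are implemented from the counting-process definitions;
lifelines, scikit-survival and statsmodels serve as independent oracles
in the tests, never as the implementation.

- **Kaplan–Meier**: product-limit with the censored-still-at-risk
  convention at tied times; the running product uses exact rational
  arithmetic so every survival value is correctly rounded (without
  censoring the curve equals `(n − D_t)/n` exactly).  Median = first time
  survival ≤ 0.5, undefined if never reached.
- **Log-rank**: two-group 1-df chi-square from hypergeometric
  observed-minus-expected sums; the standardized form `(O−E)/√V` is
  reused for cutpoint scanning.
- **Cox PH**: Newton–Raphson with step-halving on the Efron partial
  likelihood (Efron chosen as the modern tie-handling default),
  covariates centered, Wald CIs/p-values; non-convergence within 100
  iterations and monotone likelihood (|coef| > 15) are flagged rather
  than raised.
- **Prognostic screen**: standardized univariate Cox AND median-split
  log-rank, both at p < 0.001.  The conjunction is the stricter reading
  of a two-method screen and is configurable (`require_both=False` for
  the disjunction).  The median split was chosen because the screen's
  dichotomization convention is otherwise unspecified.
- **Maximally selected rank statistic**: candidate cutpoints are
  midpoints between consecutive distinct score values with both groups
  holding ≥ `minprop` = 0.1 of the samples; the cutpoint maximizing
  |standardized log-rank| is returned, ties toward the lower cutpoint
  (exactly reproducible by brute force, which the tests do).  The
  selection-adjusted p-value uses score permutations; it is off by
  default in the pipeline because the cutpoint itself never depends on
  it and the scan cost scales with permutations × candidates.
- **Time-dependent AUC**: cumulative-case/dynamic-control with inverse
  probability-of-censoring weights from the reverse Kaplan–Meier
  estimate, `G(T⁻)` for cases and `G(τ)` for controls; equals the
  Mann–Whitney statistic exactly when censoring is absent.
- **C-index**: Harrell's concordance over pairs whose shorter time is an
  observed event; score ties count one half; tied times are not
  comparable.

## PCA score

The signature genes are z-scored across training samples, the gene-gene
covariance of the standardized matrix eigendecomposed, and the top two
eigenvectors kept as loadings.  The per-sample score is the **sum of its
PC1 and PC2 projections** — the GGI-style reading of a two-component
summary score; the alternative reading (a loading-weighted sum over
genes) is a linear functional of the same projections and is not
implemented separately.  Sign indeterminacy is fixed by orienting each
loading vector so its largest-absolute entry is positive, making the fit
bit-deterministic; whether high score means high risk is then *learned*
from training survival (comparing stratum medians, falling back to final
survival levels when a median is undefined) and stored on the model.
Validation cohorts are always scored with the frozen training means,
standard deviations and loadings — refitting on validation data would
leak information.  A sample exactly at the cutpoint is "low".

## Pipeline

Stage order: cohort → consensus subtyping → DE → VNLHHO on DEGs →
prognostic screen of DEGs → signature = screen ∩ selected (kept in
selection order) → score fit + cutpoint + stratification → evaluation
(log-rank, stratum medians, univariate and covariate-adjusted Cox,
1/3/5/7-year AUC, C-index), plus an optional CNMF re-clustering of the
prognostic DEGs (the "gene subtype" view) and an optional validation
cohort scored by the frozen model.  Each stage derives its seed from the
global seed by a fixed offset, so reconfiguring one stage never perturbs
another's random stream.  All outputs are plain TSV/JSON written with
shortest round-trip float formatting and re-read with round-trip parsing;
arrays are forced C-contiguous before reductions, so results are
byte-reproducible regardless of whether data arrived from the generator
or from files.  An empty DEG set or a signature smaller than two genes
aborts with a stage-named error — a cohort without subtype signal must
fail loudly, not produce a vacuous signature.

## Problem sizes in the tests

The default suite exercises cohorts of 60–400 samples and 10–500 genes,
consensus clustering with 30 runs, optimizer budgets up to population 30
× 100 iterations, 2000-replicate log-rank calibration at n = 100, and
brute-force enumeration up to 2^12 masks and 50-sample cutpoint scans —
sizes at which every oracle (exhaustive search, hand computation,
independent packages) is exact and the whole suite runs in about a
minute.

## Known limitations

- The generator's independence assumptions (see above) make the planted
  cohorts easier than real LGG data; ASW and ARI values reached here do
  not transfer to real cohorts.
- The optimizer's exploration collapse near the unit-box corners is
  inherited from the canonical position equations; a rank-based or
  V-shaped transfer would trade exploitation for coverage and can be
  restored via `transfer_slope`.
- Cox standard errors assume the usual asymptotics; no robust/sandwich
  option.
- The cutpoint permutation p-value is exchangeable-permutation based and
  ignores tied-score structure.
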