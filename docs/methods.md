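# Methods

`omicsurv` detects survival subtypes in a cancer cohort from paired
tumor-microbiome abundances and host gene expression, and provides the
downstream association, network, and transfer analyses that typically
accompany such a stratification. This note documents the model, its
assumptions, the tunable parameters, the synthetic-data generator used for
validation, and the numerical choices made where the design was open.

## Pipeline

For a cohort of `n` samples with an expression matrix (samples × genes) and
a microbiome count matrix (samples × taxa), the pipeline is:

1. **Normalization.** Each gene is rank-based inverse-normal transformed
   across samples: values are ranked (average rank on ties) and mapped
   through Φ⁻¹((r − 0.5)/n). This makes every gene marginally standard
   normal and damps extreme FPKM values. Microbiome counts become
   per-sample relative abundances (proportions), removing sequencing-depth
   differences. Both layers are then z-scored per feature (population sd;
   zero-variance features map to all-zero columns rather than being
   dropped, so column indices stay aligned with a trained encoder's input
   layer).
2. **Latent feature extraction.** Per omic layer, an ensemble of
   `ensemble_size` autoencoders (default 30) is trained, each from a
   different seed; their 100-unit bottleneck activations are pooled into
   `ensemble_size × 100` latent features per omic. A PCA extractor (100
   components per omic) is available as a baseline, as is a direct
   ridge-Cox median-split baseline that skips clustering entirely.
3. **Cox screening.** Every pooled latent feature is tested univariately
   against survival with a Cox proportional-hazards model; features with a
   two-sided Wald p < 0.05 are retained.
4. **Clustering.** Gaussian mixtures with K = 2…5 are fit to the selected
   features; the K with the highest Euclidean silhouette wins. Clusters are
   renamed ASD-1…ASD-K by decreasing median Kaplan-Meier survival (ties:
   restricted-mean survival, then cluster size).
5. **Evaluation.** Multivariate log-rank test across subtypes; Harrell's
   concordance index from a Cox model with the (dummy-encoded) subtype
   label as the only covariate; per-subtype Kaplan-Meier curves.
6. **Associations.** Chi-square test of subtype × AJCC stage; leave-one-out
   random-forest prediction of subtype (AUROC) and stage (accuracy) from
   six feature sets (all/top-20 per omic, and their combinations, the
   40-feature set being the union of the per-omic top-20 importance lists);
   Shannon alpha-diversity comparison between subtypes (Mann-Whitney U for
   two groups, Kruskal-Wallis beyond).
7. **Network.** All gene × taxon Pearson correlations, computed in
   memory-bounded blocks; pairs with |r| > 0.9 become edges (a signed mode
   is available).

## Autoencoder

Each autoencoder is a fixed architecture: encoder
`linear(d→500) → dropout(0.2) → tanh → linear(500→100)`, decoder mirroring
back to `d`. Training minimizes mean squared reconstruction error with Adam
(lr 1e-3, batch `min(32, n_train)`, ≤ 200 epochs); 20% of samples are held
out as a validation split, and training stops once validation loss has
failed to improve for 5 consecutive epochs, restoring the best-epoch
weights. Dropout (inverted) is active only during training, so encoding is
deterministic. The implementation is plain numpy with manual
backpropagation; all randomness — initialization, the split, batch order,
dropout masks — derives from one integer seed, making training exactly
reproducible. Model bundles persist as a directory of JSON metadata plus
`.npz` weight archives (no pickled code), so a bundle trained on one cohort
can be reloaded and applied to another.

## Univariate Cox screening

Screening thousands of latent features means thousands of single-covariate
Cox fits, so these are vectorized: one Newton iteration per step for *all*
features simultaneously, with Efron's correction for tied event times and
step-halving for stability. Covariates are standardized internally;
coefficients are reported on the original scale. A covariate that perfectly
orders the deaths has a monotone partial likelihood and no finite MLE;
iterating toward it only collapses the observed information and, with it,
the Wald statistic. The solver therefore stops at |β| = 12 on the
standardized scale and reports the Wald p there, flagging the feature as
`boundary` — such features remain selectable (their evidence is real),
while `zero_variance` features and numerically failed fits never are.
Coefficients and p-values agree with per-feature lifelines fits and with a
permutation oracle on small instances (tested).

## Selection-induced optimism of in-sample evaluation

The log-rank p and concordance index are computed on the same cohort used
to screen features and fit clusters. This is optimistically biased by
construction: on a cohort with *no* survival structure at all, the screen
still passes ~5% of latent features — precisely those that correlate with
survival by chance — and their shared component is the chance survival
direction, so the subsequent clustering stratifies survival "significantly"
(log-rank p below 1e-10 is typical on pure noise). The screen itself is
correctly calibrated (selected fraction ≈ α under the null, verified); the
bias enters when clustering and testing reuse the selected features. Users
should treat in-sample log-rank p values as descriptive, and rely on
transfer to an independent cohort (provided here) or sample-splitting for
confirmatory claims. The same caveat applies to the direct-Cox baseline's
median split.

## Synthetic-data generator

The generator emulates the data structure the pipeline assumes, with full
ground truth:

- Subtype `z` uniform over K_true (default 2).
- Informative genes: N(effect·z, 1), effect 1.5 sd (50 of 500 genes);
  remaining genes N(0, 1).
- Microbiome: multinomial counts over a softmax composition — taxon base
  log-abundances N(0, 1), per-sample lognormal noise (σ = 0.3), informative
  taxa shifted by 1.0·z on the log scale (20 of 150 taxa), lognormal library
  sizes (mean 5×10⁴, σ = 0.3).
- Survival: exponential with hazard `h₀·HRᶻ` (h₀ = 10⁻³, HR = 3);
  independent Uniform(0, u) censoring with `u` solved by bisection so the
  marginal censoring probability hits the target (30%); closed form
  P(C<T) = (1 − e^{−hu})/(hu) per subtype.
- Stage: with probability `stage_association` (0.7) the subtype's target
  stage (best-prognosis subtype → I, worst → IV), otherwise a fixed
  early-stage-skewed base distribution; `0` gives independence, `1`
  determinism.
- Planted gene–taxon pairs (10, population r = 0.95): a shared N(0,1)
  factor becomes the gene directly, and the paired taxon's relative
  abundance is lognormal in the factor (loading 0.25, mean share 2%),
  assigned directly rather than through the softmax — the softmax
  normalizer would couple the taxon to every other taxon's noise and cap
  the reachable correlation below target. Attenuation from the exp link
  (s/√(e^{s²}−1)) and from multinomial counting noise is divided out
  analytically; the realized population r is 0.949 for a 0.95 target.
  Pair features are disjoint from informative features so correlation
  recovery and subtype recovery are separable tests.

What the generator does **not** emulate: real taxonomies or gene
identifiers, contamination structure, batch effects, zero-inflation beyond
the multinomial, overdispersion (no Dirichlet-multinomial), non-proportional
hazards, or informative censoring. Passing tests therefore demonstrate the
machinery recovers planted structure of the assumed form — not performance
on real tumor data.

## Problem sizes and defaults used in validation

Tests and the acceptance script run the ensemble at size 5 (500 latent
features per omic) on the standard n=200 cohort, which preserves the
pipeline's qualitative behavior while keeping a full multi-seed validation
suite fast; the published default remains `ensemble_size=30` and is a flag
away. Random forests default to 500 trees (√p features per split, impurity
importance); null-calibration repeats use the logistic model, whose
leave-one-out fits are cheap and whose AUROC null behavior is identical in
expectation. Leave-one-out AUROC is mildly pessimistic under the null
(each held-out sample's class is under-represented in its training fold),
so null means fall slightly below 0.5.

## Numerical choices

- Rank direction: genes are ranked **across samples** (per gene); ties get
  average rank and map to the median quantile.
- Scaling uses the population sd convention (÷ n).
- GMM: full covariance, 10 initializations, ≤ 200 EM iterations, 1e-6
  covariance regularization, seeded; silhouette ties prefer smaller K.
- Log-rank is the K-group multivariate test; no pairwise tests.
- Cox ties: Efron. Direct-Cox baseline: L2 penalty 0.1, features reduced to
  ≤ 100 principal components when p ≥ n; exact median ties fall back to a
  rank split.
- Relative-abundance rows must sum to 1 within 1e-9; zero-sum samples are
  an error, not silently dropped.
- Mann-Whitney uses the asymptotic normal approximation without continuity
  correction so that identical groups give p = 1 exactly.
- Transfer: the new cohort is normalized on itself (rank transforms are
  cohort-internal by construction) but z-scored with the *training*
  scaler; features absent from the new cohort are filled with 0 (the
  scaled training mean) and the filled fraction reported; below 50%
  feature overlap the transfer refuses to run. Fine-tuning of encoder
  weights on the new cohort is available but off by default
  (`fine_tune_epochs=0`), which leaves the bundle bit-unchanged and makes
  self-transfer reproduce the native run exactly.

## Known limitations

- The in-sample significance optimism discussed above.
- The concordance index is tied to a subtype-label Cox model; with K=2 the
  risk score has two levels, so ties between same-label pairs bound C
  below 1 in most configurations.
- No batch-effect correction, compositional (CLR) treatment, competing
  risks, or clinical-covariate-adjusted models.
- The ensemble-size consistency sweep retrains the full pipeline
  `repeats` times per size and is the only genuinely expensive operation.
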