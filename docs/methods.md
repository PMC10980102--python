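# Methods

This note documents the models, conventions and numerical choices behind
`survmr`, and what the synthetic-data studies do and do not establish.

## The additive hazard model and why it carries the causal analysis

The conditional hazard is modeled additively,

    h(t | x) = α0(t) + Σ_j x_j α_j(t),

and estimated through the cumulative coefficients B_j(t) = ∫0^t α_j(s) ds.
At each ordered event time t the increment is the least-squares solve
dB(t) = (X_r'X_r)⁻¹ X_r' dN(t) over the at-risk set r(t); tied event times
are handled in one solve with dN carrying the multiplicities. The
optional-variation estimator dΩ(t) = X⁻(t) diag(dN) X⁻(t)' accumulates the
increment covariance. Two properties make this model the right vehicle for
instrumental-variable survival analysis: effects are collapsible (no
non-collapsibility bias when marginalizing over covariates, unlike hazard
ratios), and time-varying coefficients are estimated rather than assumed
away.

**Identifiable range.** Estimation stops at the last event time where
X_r'X_r is invertible at reciprocal condition number 1e-10; later events
are dropped and counted on the fit (`n_dropped_events`). An intercept-only
fit reduces exactly to the Nelson–Aalen estimator.

**Testing α_j ≡ 0.** The test statistic is U_j = Σ_t K(t) dB_j(t) with
variance Σ_t K(t)² dΩ_jj(t), referred to N(0,1). The default weight is the
design information K_j(t) = 1/[(X_r'X_r)⁻¹]_jj, which reduces to the number
at risk in one dimension and is near-optimal against a time-constant
alternative — the effect the pipeline screens for. The unweighted (K = 1)
statistic, i.e. the terminal cumulative coefficient, is available
(`weight="flat"`) but is dominated by the last few increments, where risk
sets are tiny and variance explodes; simulation shows it has essentially no
power at realistic sample sizes, so it is not the default. A number-at-risk
weight (`"atrisk"`) is also provided. All weights give statistics invariant
to uniform rescaling of K.

**Cox engine.** The pleiotropy screen needs per-variant hazard-ratio tests;
these use a hand-rolled Breslow partial-likelihood Newton–Raphson (max 50
iterations, step-halving, relative log-likelihood tolerance 1e-9,
covariates standardized internally). Monotone likelihood (|β| drifting
beyond 50 on the standardized scale) is flagged as separation and reported
as non-convergence. Breslow ties were chosen for consistency with the
risk-set prefix formulation; with continuous simulated times ties are rare
and Breslow agrees with Efron, which is verified against lifelines in the
tests.

## cis-eQTL mapping and the permutation gene-level p

For each gene, every variant within ±1 Mb of the TSS is tested by OLS of
log2 expression on dosage with covariates. Covariates are residualized out
of expression and dosage once (Frisch–Waugh; identical slopes and t
statistics to the joint fit, with the degrees of freedom adjusted) and the
same residualization is reused across permutations, which preserves the
permutation null and makes the loop a single matrix product per batch.
Because all cis variants of a gene share one residual df, the minimum
nominal p equals the maximum squared correlation, which is what the
permutation loop tracks. The estimator is

    p_gene = (1 + #{perm max-r² ≥ observed}) / (1 + n_perm),

optionally stopping early once a configured hit count (default 100) is
reached — the estimator is unchanged, only the number of draws. A
beta-approximation of the permutation null was considered and not
implemented: at the package's operating scale the direct estimator is exact
enough and simpler to audit. Per-gene generators are derived from
(global seed, CRC32 of the gene id), so results are reproducible under any
execution order.

## The MR pipeline

* **Screen.** Genes are clustered (k-means, k = 4, genes as points on
  z-scored profiles) and each cluster enters one multivariable additive-
  hazard fit per treatment arm alongside the clinical covariates; genes at
  p < 0.1 advance. A cluster larger than events/5 is sub-split with a
  warning (overfitting guard). Arm stratification is by subsetting, never
  interaction terms.
* **Pleiotropy.** Candidate instruments (nominally significant cis-eQTLs of
  screened genes) are tested for direct OS effects with Cox fits on the
  pooled arms, adjusted for clinical covariates and expression PC1;
  variants at Wald p < 1e-4 are excluded. Non-converging fits exclude the
  variant conservatively.
* **Pruning.** Within a gene, complete-linkage hierarchical clustering on
  1 − r² is cut so merged clusters have all pairwise r² strictly above 0.1;
  each cluster's proxy is its smallest-nominal-p variant (ties broken by
  variant id), weighted by its marginal eQTL slope.
* **One-sample test.** ĝ = QW enters an arm-specific multivariable
  additive-hazard fit with all predicted genes plus covariates; predictions
  are centered; later genes collinear with earlier ones are dropped with a
  warning. The causal call is p < 0.05 (the stricter of the two thresholds
  in circulation for this stage; configurable).
* **Two-sample replication.** ĝ* = Q*(Q'Q)⁻¹Q'g — the joint least-squares
  fit of observed expression on proxy dosages in the discovery cohort
  applied to validation dosages. The projection formula carries no
  intercept, so expression and dosages are centered (validation dosages by
  the *discovery* means); without centering the through-origin fit is
  dominated by the dosage means, destroying both the sign of the prediction
  and allele-flip invariance. With centering, flipping an allele's coding
  (dosage → 2 − dosage, weight sign flipped) changes predictions only by an
  additive constant and leaves every p-value unchanged, which the tests
  verify. Validation cohorts lack RNA-seq, so only clinical covariates are
  adjusted for there. A singular Q'Q falls back to ridge with penalty
  1e-8 · trace(Q'Q)/p, with a warning. The asymmetry between marginal
  weights (one-sample) and joint weights (two-sample) is preserved
  deliberately; `predict_expression_two_sample` on the discovery cohort
  itself reproduces the joint-weight one-sample prediction exactly.

## Subtype enrichment

Causal genes are dichotomized at the all-sample median; samples exactly at
the median go to the "low" side (documented convention, tested). The
"beneficial" side is derived from the sign of the MR hazard effect:
direction −1 (high expression lowers the hazard) makes high expression
beneficial. A subtype is enriched when strictly more than 70% of its
patients fall in one category. Enrichment depends only on median ranks, so
it is invariant to monotone transforms of expression. By default all
samples with expression are used (not per-arm subsets); this is
configurable.

## The synthetic-data generator

The generator emulates the data-generating structure the pipeline assumes:

* **Genotypes.** One LD block per gene; haplotypes from an equicorrelated
  Gaussian copula (latent correlation = `ld_block_rho`), thresholded at the
  MAF quantile, summed to HWE dosages. Blocks with any empirical MAF below
  0.05 are resampled whole. Gene TSSs are spaced 2.5 Mb apart on one
  chromosome so ±1 Mb cis windows never overlap.
* **Expression.** Negative-binomial counts (gamma–Poisson) with log-mean
  intercept + Σβ·dosage + γ'covariates + subtype shifts. The default
  dispersion (size 3) gives a log2-scale SD of ~0.8 — overdispersed enough
  that simulated genes clear the SD ≥ 0.5 expression filter, as real
  variable genes would. NB size = ∞ gives Poisson counts.
* **Survival.** h = λ0 + x'α with exact exponential sampling; piecewise-
  constant α(t) on a user grid is sampled by piecewise-exponential
  inversion. Censoring is independent exponential (default rate 0.15
  against λ0 = 1, ~13% censored). Arms are assigned Bernoulli(0.5); only
  the two monotherapy arms are simulated.
* **Hazard positivity.** A linear additive hazard with an unbounded
  continuous exposure is negative with positive probability, so the
  generator saturates the linear predictor at −(1 − floor)·λ0 (default
  floor 0.05) — effects flatten in the extreme tail, the hazard stays
  positive, and the bulk-data effect slope is unchanged. Setting
  `hazard_floor=None` enforces strict positivity and fails hard naming the
  offending row.
* **CMS labels.** Largest-remainder apportionment of the requested
  proportions (deterministic subtype sizes), shuffled; planted expression
  shifts are applied inside count generation so enrichment is recoverable.
* **Validation cohorts.** Expression is simulated (and drives the hazard)
  for *all* samples — tumors express genes whether or not RNA-seq was
  performed — but only discovery samples expose their counts.

What the generator does **not** emulate: realistic human LD maps,
imputation uncertainty, tumor purity, batch structure, library-size
variation beyond the NB noise, or a combination-therapy arm. Passing tests
therefore establish the pipeline's statistical correctness under its own
assumptions, not robustness to those real-data complications.

## Simulation studies and their conditions

`survmr.studies` fixes the scenarios the package reports
(`scripts/acceptance.py` re-runs them):

* **Type-I error** of the one-sample MR causal test: 500 cohorts, 300 per
  arm, 6 genes with two fixed-strength instruments each (β = 0.32 on the
  natural-log count scale, prediction R² ≈ 0.2 at MAF ~0.3 against NB size
  3 noise), no causal effects. The association screen is deliberately
  bypassed here: it shares the outcome with the causal test, so the
  *conditional* rejection rate after screening is not the test's size; the
  study reports the unconditional level, which lands in the nominal
  0.03–0.08 band.
* **Power and replication**: one causal gene (slope 0.6·λ0 per log2 unit,
  bevacizumab arm), 400 per arm discovery, 600-sample genotype-only
  validation; detection requires the correct arm and sign.
* **Pleiotropy screen**: a variant with additive slope (e^0.6 − 1)·λ0
  (per-allele log-HR ≈ 0.6 near zero dosage) at n = 800 must be excluded;
  1500 null variants estimate the nominal exclusion rate at 1e-4.
* **Enrichment recovery**: a 1.5-natural-log shift up in CMS1 and down in
  CMS4 (balanced so unshifted subtypes stay near 50%), 100 patients per
  subtype, 20 genes — a realistic gene count keeps the per-sample upper
  quartile stable so the planted shift does not bleed into other genes
  through normalization.
* **Permutation calibration**: 500 null genes, 150 samples, 1000
  permutations.

Problem sizes were chosen so each study gives stable rates at desk scale;
the whole battery runs in a few minutes on one CPU.

## Numerical conventions

* Gene-filter SD is evaluated on log2(count+1) — an SD threshold of 0.5 is
  only meaningful on a log scale; `sd_scale="raw"` is available.
* Upper-quartile normalization uses linear-interpolation percentiles of
  nonzero counts and rescales to the across-sample mean quartile; it is
  invariant to per-sample rescaling up to one global factor.
* All boundary comparisons are strict exactly as documented: SD < 0.5
  excluded, > 30% zeros excluded, abundance SD > 0.12 required,
  permutation p < 0.05, screen p < 0.1, GWAS p < 1e-4, enrichment
  rate > 0.70.
* Duplicate samples are reported (exact id duplication and expression
  Pearson r ≥ 0.999), never silently dropped.
* PCA signs are fixed by making each component's largest-magnitude gene
  loading positive.
* Dosages are used as-is (no rounding to hard calls); effect-allele
  harmonization between cohorts flips ref/alt-swapped variants and aborts
  on any other mismatch.

## Known limitations

* The additive-hazard test targets time-constant alternatives; a purely
  time-varying effect integrating to zero has little power under the
  default weight (the cumulative-coefficient path is available for
  inspection).
* The pleiotropy screen tests marginal direct effects; correlated
  instruments can mask each other.
* Instrument weights are estimated in the same cohort used for the
  one-sample test (as in the workflow this package implements); weak
  instruments therefore bias toward the observational association rather
  than the null.
* k-means clustering of genes controls model size but makes per-gene screen
  p-values dependent on cluster composition.
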