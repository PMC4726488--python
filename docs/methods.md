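# Methods

`dopametab` re-implements, as a tested and reusable pipeline, a serum-
metabolomics case-control analysis of two dopaminergic movement
disorders — Parkinson's disease (PD) and restless legs syndrome (RLS) —
against a large population control arm. This note records the models,
the parameters that matter, the numerical choices, and what the
synthetic cohort does and does not emulate.

## Study structure

The emulated design has three arms: ~1272 population controls,
~82 PD cases and ~95 RLS cases, each profiled for 456 serum metabolites
by untargeted LC/GC–MS (semi-quantitative relative intensities), plus a
panel of 32 candidate SNPs genotyped in the control arm. Covariates are
age, sex, BMI, the lipid panel (HDL, LDL, total cholesterol,
triglycerides) and hypertension/diabetes indicators.

## Preprocessing

**Run-day normalization.** Untargeted MS intensities drift by
measurement day. Each observed value is divided by the median of its
metabolite on its run day and multiplied by the metabolite's overall
median (medians over observed values only; sample median with midpoint
interpolation for even counts). Afterwards every day's median equals the
metabolite's overall pre-normalization median. Two properties worth
stating precisely: the operation is idempotent, and rescaling one day's
raw values by any c > 0 cancels inside the day-median ratio — the output
changes only through the metabolite-wide overall-median factor, so the
centered log matrix is exactly invariant. Per-day medians of zero are an
error (raw intensities must be positive); a (day, metabolite) cell with
no observations at all stays missing with a warning.

**Order of operations.** normalize → natural log → missingness filter →
imputation → standardization, with the filter and imputation on the log
scale where the imputation regressions' normality assumption is closest
to holding.

**Missingness QC.** Metabolites with strictly more than 20% missing
values are dropped first, then samples with strictly more than 10%
missing over the retained metabolites. Note that dropping a sample can
slightly *raise* an individual retained metabolite's missing fraction
(its denominator shrinks); the monotone guarantee is on the per-sample
fraction over retained metabolites.

**Imputation.** Remaining gaps are filled by chained-equations
regression: missing cells start at per-metabolite observed means and are
refined by sweeps of per-metabolite linear regressions on all other
metabolites, each fitted on the rows where its target metabolite is
*observed* — the standard chained-equations discipline. For efficiency
one Gram matrix and its inverse are shared per sweep, and every
column's observed-row fit is recovered from them by a low-rank Woodbury
downdate (removing that column's missing rows and re-centering on its
observed-row means), which is algebraically identical to fitting the
regression separately but avoids hundreds of full solves per sweep.
Sweeps stop at `max_iter` (default 20), when the largest change of any
imputed cell falls below 1e-4, or — important at high p/n — when the
sweep-to-sweep change stops decreasing: deterministic conditional-mean
iteration makes imputed cells satisfy their regressions exactly, which
deflates the completed matrix's smallest covariance eigenvalues sweep
after sweep and, iterated to a fixed point, collapses it onto a
degenerate subspace (inflating correlations and, downstream, spurious
network edges). The guard keeps the best (minimum-change) state, which
at 5% missingness moves imputed cells by well under the imputation
error itself. The default is deterministic conditional-mean imputation,
chosen so downstream networks are exactly reproducible; `draws=True`
adds a residual-scale Gaussian draw (seeded) for stochastic multiple
imputation. Singular designs (perfectly collinear metabolites) fall
back to a tiny ridge (1e-10 of the mean diagonal) with a logged
warning; in the small-p contractive regime convergence is geometric
with rate roughly the leverage of the imputed rows.

## Association scans

For each contrast (PD vs control, RLS vs control, PD vs RLS), each
metabolite's log concentration is modelled by OLS on an intercept, a
case indicator, and covariates (age and sex by default; sex coded
MALE = 0, FEMALE = 1). The two-sided t-test on the case coefficient is
compared against the Bonferroni threshold α/m with m the number of
metabolites profiled (0.05/456 ≈ 1.09 × 10⁻⁴), applied with strict
inequality. Missing responses or covariates are handled by listwise
deletion. The scan path solves all metabolites against one design in a
single QR factorization; it is tested to agree with statsmodels OLS to
ten significant digits.

Set logic over the three contrasts classifies metabolites as
shared-unidirectional (significant versus controls in both diseases,
same direction), PD-unique, RLS-unique, or discordant (significant in
both with opposite signs — a category the shared/unique sets exclude).

## Ratio scan and p-gain

On the log scale a metabolite ratio is a difference of logs, so the
ratio response for pair (a, b) is log a − log b with the same
case-indicator regression. All p(p−1)/2 unordered pairs are scanned;
because every pair shares one design matrix, the pair coefficients are
differences of single-metabolite coefficients, and pair residual sums of
squares come from one p × p residual cross-product — so 456 metabolites
(103,740 pairs) stay desk-scale without 10⁵ separate regressions. The
p-gain, min(p_a, p_b)/p_ratio, measures the information a ratio carries
beyond its constituents (large values arise when, e.g., correlated noise
cancels in the ratio, the classical proxy for a shared enzymatic step).
Significance uses α over the number of pairs; constant ratio responses
(a ≡ b) are flagged degenerate and never significant.

## Gaussian graphical model

Edges of the metabolite network are nonzero partial correlations of the
(approximately multivariate normal) log metabolome. Confounders — age,
sex and the PD and RLS indicators — are first regressed out of every
metabolite, and the residuals are re-standardized. Because p approaches
the usable n, the sample correlation matrix R is shrunk toward the
identity with the analytic intensity

λ* = Σ_{i<j} Var̂(r_ij) / Σ_{i<j} r_ij²  (clamped to [0, 1]),

where Var̂(r_ij) is the unbiased empirical variance of the standardized
product terms; partial correlations come from the scaled inverse of the
shrunk matrix. λ* is computed with two matrix products (the Σ_k w² term
is an elementwise-squared cross-product), not an n × p × p tensor.

**Edge significance.** The original analysis used an empirical-null
mixture fit; here edge p-values are fully reproducible from first
principles instead: Fisher's z (default), z = atanh(r)·√(n − 3 − q) with
q = 0 for Pearson and q = p − 2 for full-order partial correlations, or
a permutation test (B = 1000, add-one correction p = (b+1)/(B+1)) that
permutes one variable of a pair and recomputes both correlation kinds.
Fisher and permutation p-values agree within a factor of two for
p > 0.01 on small instances; infeasible Fisher degrees of freedom fall
back to permutation automatically.

**Dual rule.** A pair becomes an edge only when *both* its Pearson and
its partial correlation pass the Bonferroni level α/n_pairs (read as
corrected over metabolite pairs). Pairs with |pearson r| < 0.05 and
negative partial correlation are flagged as collider artifacts and
excluded; 0.05 operationalizes "Pearson correlation is zero", for which
no numeric cutoff is stated anywhere. The full all-pairs audit table is
retained alongside the passing edges. Node attributes for export carry
each contrast's effect direction, coefficient and −log₁₀ p.

## Candidate-SNP metabogenomic scan

In the control arm only, each (SNP, metabolite) pair is tested by OLS of
the log concentration on the additive allele dosage plus nine cofactors
(BMI, age, sex, HDL, LDL, total cholesterol, triglycerides,
hypertension, diabetes), with listwise deletion of incomplete cofactor
records. SNPs below 1% minor-allele frequency or failing a 1-df
Hardy–Weinberg chi-square test (p < 5 × 10⁻⁶; hard calls required,
fractional dosages skip the filter with a warning) are excluded first.
The Bonferroni threshold is α/(SNPs tested × metabolites); at 32 × 456
and α = 0.05 this is 3.43 × 10⁻⁶. Only the additive genetic model is
implemented. Flipping allele coding negates the coefficient and
preserves the p-value exactly.

## Synthetic cohort

The generator draws latent log abundances from the multivariate normal
implied by a sparse precision matrix, then layers on the study's
nuisance structure.

* **Precision matrix.** With unit diagonal, Ω = I − R has partial
  correlation matrix exactly R, so the generator specifies R directly:
  Bernoulli(density) support (default 0.02) with uniform magnitudes
  |0.15–0.45| and random signs, rescaled spectrally when needed to keep
  the minimum eigenvalue ≥ 0.1. The magnitude range is sized by power
  analysis: at n ≈ 1400 under Bonferroni over ~10³ pairs and shrinkage
  attenuation, the detection point is a true partial correlation of
  about 0.18, so roughly three quarters of planted edges are
  recoverable — which is what the recovery tests (precision ≥ 0.9,
  recall ≥ 0.6 at 50 metabolites) exercise. The covariance is rescaled
  to unit marginal variances (partial correlations are invariant), so
  injected standardized shifts are exact log-unit shifts.
* **Group and genotype effects.** Disjoint metabolite subsets (30 each
  by default) carry PD and RLS mean shifts drawn N(0, 0.5²) on the log
  scale; four (SNP, metabolite) pairs carry ±0.3 per-allele slopes.
  Genotypes are binomial(2, MAF) with MAF uniform in [0.1, 0.5].
* **Demographics.** Ages are truncated normal (≥ 18 years) with the
  study's arm means/SDs (controls 64.1 ± 5.5, PD 70.0 ± 8.7, RLS
  60.6 ± 17.0 — the heavy RLS truncation lifts its realized mean by
  about a year); female proportions 47.7%/50.0%/70.5%. BMI, lipids and
  comorbidity rates are plausible for an elderly central-European
  cohort; they exist so the metabogenomic cofactor adjustment is
  exercised, not to match any printed table.
* **Batch and missingness.** Per-(day, metabolite) multiplicative
  log-normal factors (20 days, SD 0.3) emulate instrument drift; run
  days are assigned uniformly at random so day is not confounded with
  group. Missingness is dominantly left-censoring — values below each
  metabolite's 5% quantile of the control raw distribution are removed,
  the intensity-dependent mechanism typical of MS — plus 1% uniform
  random dropout.

**What passing tests do and do not show.** The generator draws exactly
multivariate-normal latents with linear effects; real MS data have
heavier tails, nonlinear covariate effects and correlated assay noise,
so recovery rates here bound the idealized, not the practical, regime.
One consequence the tests *do* surface: left-censoring truncates the low
tail, which biases case-control mean differences toward zero by roughly
the censored-tail mass (≈ 0.27 log-units for a 1-SD downward shift at 5%
censoring — observed mean of a censored group equals its truncated mean
no matter how the gaps are imputed, since regression imputation places
censored cells near the conditional mean rather than in the tail).
Detection and sign of strong shifts survive; unbiased effect recovery is
therefore asserted on an uncensored cohort, and detection thresholds on
the censored one come from the truncation algebra (certain detection
needs |shift| ≥ ~1.0; at 0.8 per-metabolite power is ≈ 0.85).

## Numerical choices and degenerate inputs

* Medians: sample median, midpoint interpolation; observed values only.
* OLS: economy QR; rank deficiency detected from the R diagonal
  (tolerance 1e-10 relative) and reported with the collinear columns.
* p-values are computed in log space (`t.logsf`) so the ratio scan's
  p-gain survives double underflow, and floored at 1e-300 to keep them
  strictly positive.
* Partial correlation matrices are symmetrized and clipped to [−1, 1];
  |r| is clipped below 1 before atanh.
* Zero-variance metabolites (before standardization or after
  residualization) are hard errors naming the metabolite.
* Degenerate ratio pairs (zero residual variance) report p = 1 with a
  flag rather than dividing by zero.

## Problem sizes

The test and acceptance runs use the study's arm sizes throughout
(1449 samples); network recovery runs at 50 metabolites and the full
456-metabolite matrix drives the association, classification and
metabogenomic checks, with 20-replicate null simulations for family-wise
error. These sizes keep the whole suite to well under a minute while the
quantities being checked (thresholds, error rates, recovery) are already
stable at them.

## Known limitations

* The day-median scheme is the only batch correction (no empirical-Bayes
  or quantile alternatives), by design.
* Imputation is not censoring-aware (no tobit/QRILC variant); see the
  attenuation discussion above.
* The mGWAS stage accepts any pre-made candidate-SNP dosage file and
  applies only MAF and HWE filters; call-rate QC, phasing and imputation
  belong upstream.
* The shrinkage edge test differs from the original empirical-null
  mixture; both control the family-wise rate, but edge counts on the
  same data would not be identical.
* Whether the original study imputed on the raw, normalized or log scale
  is not stated; the log-scale default here is documented, not inferred.
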