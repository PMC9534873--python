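# Methods

## The copy-number model of the C4 locus

A structural haplotype of the C4 locus is one chromosome's arrangement of
C4 gene copies.  Each copy is either *C4A* or *C4B* (paralogous isotypes
differing in target affinity) and either *long* — carrying the 6.4-kb
HERV-K insertion in intron 9, which suppresses expression of its host
gene — or *short*.  A haplotype is summarised by four non-negative copy
counts (AL, AS, BL, BS); by construction

    C4A = AL + AS,   C4B = BL + BS,   HERV-K = AL + BL,   C4 = C4A + C4B.

Given per-individual haplotype dosages `D` (expected haplotype counts,
fractional after probabilistic imputation) and a composition matrix `L`
(haplotypes × form channels), the copy-number profile is the linear map
`D·L`.  Linearity is an invariant, not an approximation, and the four
channel identities above hold for every input; both are enforced by
property tests.

### Long/short decomposition of ambiguous haplotypes

Composition tables sometimes record only isotype totals (C4A, C4B,
HERV-K).  The three marginal constraints pin the long/short split
uniquely whenever `max(0, HERV-K − C4B) = min(C4A, HERV-K)`; otherwise
the split is ambiguous and `decompose_long_short` returns the expected
counts under the population consensus that ~95% of C4A copies are long,
clipped to the feasible interval so that all three marginals remain
exact.  For totals (1, 1, 1) this yields (0.95, 0.05, 0.05, 0.95).
Outputs are rounded at the 12th decimal so consensus weights are exact in
binary floating point.  The uniform 0.95 prior is applied to every
ambiguous haplotype; haplotype-specific literature priors could be
supplied through an explicit-column composition table instead.

## Case-control risk models

Four nested logistic models are built over unrounded copy-number dosages
(rounding is exposed separately, half-to-even, for plotting/grouping
only):

    a: status ~ C4 + HERV-K + PC1-5 + cohort + sex
    b: status ~ C4A + C4B + HERV-K + PC1-5 + cohort + sex
    c: status ~ AS + AL + BS + BL + PC1-5 + cohort + sex
    d: b + C4A:C4B + C4A:HERV-K + C4B:HERV-K + C4A:sex + C4B:sex

Sex is coded female = 0, male = 1.  Cohort labels expand to K−1
indicators against the lexicographically first level.  Sex-stratified
fits drop the sex column and any interaction containing it (constant
within a stratum).  Rows with any missing model column are excluded
listwise with a logged count.

Fitting is maximum likelihood by iteratively reweighted least squares
(Newton steps with step-halving to keep the likelihood monotone).
Convergence requires max |score| < 1e-8 or a relative log-likelihood
change < 1e-10 within 100 iterations.  Wald standard errors come from the
observed information at the optimum and p-values from the normal closed
form 2·Φ(−|β/se|).  A rank-deficient design raises an error naming the
collinear columns (detected by pivoted QR on norm-scaled columns);
coefficients diverging past |β| > 30 are taken as (quasi-)complete
separation and flag the fit non-converged rather than raising.  The
fitter is cross-checked in the test suite against statsmodels and against
a generic BFGS search on the negative log-likelihood to 1e-6.

Derived quantities: odds ratios `exp(β)` with Wald intervals
`exp(β ∓ 1.959964·se)`; per-individual composite risk scores
`S_i = Σ_t β_t x_it` over a term subset with `risk_i = expit(S_i)`
(presets for the three standard views: the C4A/C4B interaction, the
HERV-K interactions, and the male-risk view); and the risk fold range
max(risk)/min(risk) over evaluated copy-number combinations.
Meta-analysis is fixed-effect inverse variance: weights `se⁻²`, combined
`se* = (Σ w)^{-1/2}`; random-effects models are out of scope.

## Conditional MHC deconvolution

`conditional_scan` fits, per variant, `status ~ variant + base +
conditioning` and reports the variant term only, with the genome-wide
reference line at p = 5e-8.  Variants collinear with the conditioning
set are reported missing with a reason, never as p = 0 or 1.  Eight
conditioning schemes mirror the standard analysis ladder: (1) nothing,
(2) the SLE/SjS score 2.3·C4A + C4B, (3) the C4A/C4B/HERV-K channels,
(4) the composite score from the fitted interaction model, (5–7)
forward-selected eQTL dosages (all / C4A-specific / C4B-specific), and
(8) expression-model eQTL dosages.  eQTL specificity follows the
reported-association rule: a variant is C4A-specific iff it has a
reported C4A association and no C4B association with p < 0.01 (missing
entries count as no evidence), symmetrically for C4B, remainder shared.

Forward selection greedily adds the candidate with the smallest
conditional p-value (logistic for binary outcomes, OLS t-test for
quantitative traits), after pre-filtering candidates by their marginal
conditional p against the baseline.  It stops when no remaining candidate
reaches the stop threshold.  Both thresholds are exposed because the two
conventions in circulation differ (filter at 1e-5 then stop at 0.01
versus stop at the filter level itself).  Ties on p break on larger |β|,
then lexicographic id — fully deterministic.  Candidates whose addition
drives the design condition number above 1e10 are skipped with a recorded
reason.  The engine is verified step-by-step against a brute-force greedy
oracle that refits every remaining candidate at every step.

## Quantitative-trait layer

Expression residualization is two-step: the configured genetic PCs are
regressed out of every gene globally, then within each group (cases and
controls separately) the leading eigenvectors of the inter-sample
correlation matrix are regressed out.  Because the second step's
components are data-derived, re-running the procedure extracts *new*
components; idempotence holds when the extracted components are re-used,
and the API supports exactly that (`return_components` / `components`).

Variance explained uses OLS with adjusted
r² = 1 − (1 − r²)(n − 1)/(n − p − 1); cross-channel designs (C4B copy
numbers inside the C4A expression model) are supported directly.  The
serum-protein model regresses protein on disease, sex, age and the four
long/short channels; constant predictors are dropped with a warning
(with the default haplotype table the AS channel is identically zero —
see below).  Group comparisons report both the t test and the
Mann-Whitney test; the latter uses exact enumeration for small tie-free
samples and the tie- and continuity-corrected normal approximation
otherwise, matching R's `wilcox.test` behaviour.

Between-center protein normalization is multiplicative: each center's
factor scales its control-sample median onto the pooled control median.
The exact correction used upstream of the published serum data is not
public; control-median equalization was chosen as a transparent,
rank-preserving stand-in, and factors are always reported.  Centers
without controls fall back to all their samples and are flagged.
Copy-number-corrected protein divides by total C4 dosage floored at 0.5
(floored individuals flagged) to avoid division blow-ups.

## Power analytics

**Additive model.**  With risk-allele frequency p and genotype relative
risk γ (additive on relative risk: penetrances f0, γ·f0, (2γ−1)·f0
constrained to prevalence K), expected case/control genotype and allele
frequencies follow by Bayes' rule.  Two-sided power uses the normal
approximation of the two-proportion allele test with the variance
evaluated at the alternative:

    power = Φ(−z_{α/2} + λ) + Φ(−z_{α/2} − λ),
    λ = (p_case − p_ctrl) / sqrt(p_case q_case/2N_case + p_ctrl q_ctrl/2N_ctrl).

This is the convention of the standard GWAS power calculators.  At the
default parameters (p = 0.26, γ = 1.09, K = 0.00034, 1278/6875,
α = 0.05) it gives 0.406.  The formula is first-order: measured at 10k+
Monte-Carlo replicates, the exact Wald-logistic rejection rate is ≈0.415
and the exact allele-test rate ≈0.400, bracketing the analytic value.
Oracle comparisons therefore allow the Monte-Carlo half-width plus a
0.01–0.02 approximation margin.

**Gene-by-environment interaction.**  G is a binary carrier indicator
(frequency pGene) and E binary (prevalence pEnv), jointly distributed
with a configurable population odds ratio; disease follows
`logit P(D|G,E) = β0 + βg G + βe E + βge G·E` with β0 solved so the
population prevalence matches.  With both factors binary the interaction
MLE in a case-control sample is a difference of log odds ratios whose
variance is the sum of reciprocal expected counts over the eight
case/control × G × E cells, giving the 1-df Wald non-centrality in
closed form.  At the default parameters (pGene 0.73, pEnv 0.306, betas
−0.04/−1.35/0.13, OR_GE 1.03, N = 26,633 at case fraction 0.34,
single-stage α = 0.05) the power is 0.33.  Both calculations are checked
against grouped-logistic Monte-Carlo oracles across a parameter grid.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes —
it is the package's substitute for access-restricted cohort genotypes,
with a truth record enabling parameter-recovery tests.

* **Haplotypes.**  2N draws i.i.d. from a frequency table.  The shipped
  default covers eight common European structural haplotypes (BS 0.09,
  AL-BS 0.35, AL-BL 0.43, AL-AL-BL 0.08, AL-BL-BL 0.02, AL-AL 0.01,
  AL-AL-BS 0.01, AL 0.01).  These are configurable defaults in the style
  of published European estimates, not measurements from any one study
  population.  Note the default set contains no AS-bearing haplotype, so
  the AS channel is identically zero under defaults (short C4A is rare in
  European populations); analyses over the AS channel need a custom
  table.  Dosage rows sum to exactly 2; an optional imputed-style noise
  switch perturbs dosages and renormalizes rows to sums below 2.
* **Covariates.**  Sex ~ Bernoulli(male fraction; default 0.306), age ~
  Uniform(18, 80), cohort label uniform over a configurable count with no
  true effect unless betas are configured, five genetic PCs ~ N(0, 1)
  uncorrelated with genotype (no population-structure confounding by
  default).
* **LD variants.**  A variant anchored on a haplotype name (or on a
  copy-number channel, via the per-haplotype carrier indicator) copies
  the anchor indicator per chromosome with the symmetric flip probability
  that solves the target diploid r² in closed form (monotone bisection);
  realized r² is recorded.  There is no coalescent or recombination
  model — LD is anchor-copy-with-flip only, which suffices to pose the
  conditional-analysis problem but does not reproduce haplotype-block
  structure.  For channels whose per-haplotype copy count can exceed 1
  (AL, C4A, HERV-K on duplicated-A haplotypes) the carrier indicator and
  the copy count differ; anchor channels with 0/1 counts (BS, BL, AS)
  give exact copy-count proxies.
* **Case status.**  Bernoulli(expit(S)) with S the linear predictor of
  the interaction risk model.  Default betas are the published-scale
  effects (c4a −0.31, c4b −0.20, hervk 0.16, sex −1.35, c4a:c4b −0.14,
  c4a:hervk 0.042, c4b:hervk 0.085, c4a:sex −0.17, c4b:sex 0.13); the
  intercept (−0.05) was calibrated once so the default cohort shows the
  study-scale ~34% case fraction.
* **Traits.**  Expression is linear in the long/short channels with
  small cross-isotype terms and a larger coefficient on short than long
  forms (HERV-K suppresses its host gene); protein is linear in total
  C4, HERV-K (negative), sex (males higher), age and disease (negative).
  Default noise SDs (expression 0.35, protein 0.4) were calibrated once
  so copy number explains ~20–25% of expression variance and the protein
  model ~10–12% of protein variance, the magnitudes reported for real
  blood data.
* **Determinism.**  Every stage draws from an independent
  `default_rng([seed, stage])` stream, so outputs are bit-identical given
  the config seed and insensitive to call order.

What passing tests on synthetic data do **not** show: robustness to
imputation error structure, to LD with unmodelled causal variants, to
population stratification correlated with genotype, or to non-Gaussian
trait noise — none of which the generator emulates.

## Quality control and I/O

Variant QC evaluates all filters jointly on the input matrix (so the
surviving set is order-independent): pre-imputation — call rate < 0.98,
MAF < 0.01, Hardy-Weinberg disequilibrium with p < 0.001 in *both* cases
and controls; post-imputation — imputation r² ≤ 0.3, MAF ≤ 0.05, and the
same HWE rule (the pre-stage 0.001 cutoff is reused since no separate
post-stage cutoff is established).  HWE uses a 1-df Pearson chi-square on
hard calls from half-to-even-rounded dosages; an exact test is not used,
matching common practice at GWAS sample sizes.  Every removal is reported
with its reason and offending value.

Dosages travel as VCF 4.2 with the `DS` FORMAT field (structural
haplotypes as symbolic-ALT pseudo-variants), falling back to GT hard
calls on read; out-of-range dosages raise in strict mode and clamp to
[0, 2] otherwise.  Coordinates are 1-based (VCF convention).  TSV
matrices use a `sample_id` key and `.` for missing.  CLI runs write a
`run_log.json` with the seed and input digests.

## Problem sizes used in validation

Parameter recovery runs 20 seeds at N = 25,000 for both the additive and
the interaction risk model; conditional-scan properties use N = 25,000
with proxies at r² ∈ {0.85, 0.90, 0.95}; null calibration uses 120
variants at N = 10,000; Monte-Carlo power oracles use 500–2000
replicates.  These sizes put the recovery standard errors at the scale of
the published cohort while keeping the full suite around a minute.

## Known limitations

* No Firth or penalized logistic regression: separated fits are flagged,
  not rescued.
* No random-effects meta-analysis; heterogeneity is not quantified.
* The LD model is single-anchor; multi-locus haplotype structure and
  phased conditional analysis are out of scope.
* The GTEx-style eQTL inputs are user-supplied tables; no database
  access.
* Wald inference throughout; likelihood-ratio p-values can differ in
  small strata.
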