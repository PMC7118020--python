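# Methods

`vusclinlr` implements a multifactorial, clinical-history-based evidence
pipeline for classifying variants of uncertain significance (VUS) in *BRCA1*
and *BRCA2*, together with a synthetic-cohort generator that reproduces the
statistical structure such an analysis assumes. This note records the models,
the tunable parameters, the numerical choices, and the limits of what the
synthetic experiments demonstrate.

## Carrier-status prediction model

For each gene and each of four race/ethnicity strata (European plus
mixed/unknown, African American, Asian, Hispanic) a logistic regression
compares the clinical histories of probands carrying a known pathogenic
variant (cases) against probands with no reportable variant (controls):

    logit P(carrier | x) = b0 + x . beta

where `x` is a vector of 29 binary indicators: 14 for personal cancer
history (DCIS; invasive breast cancer split into six triple-negative-status
by age-at-diagnosis cells, with cuts at 50 years for breast and 60 years for
ovarian/prostate cancer; bilateral breast cancer; ovarian cancer by age;
pancreatic cancer, no age cut; male breast cancer; prostate cancer by age)
and 15 for family history (counts of affected first/second-degree relatives
capped into 0/1/2/3+ categories for breast cancer and 0/1/2+ for ovarian,
pancreatic and prostate cancers, plus any male breast cancer in the family).

Carriers of VUS or likely-pathogenic (VLP) variants are scored by the fitted
model but never used in fitting. Probands are excluded, in fixed order, when
(1) their history information is insufficient, (2) they carry a
pathogenic/likely-pathogenic variant in another susceptibility gene, or
(3) they carry any reportable variant in the opposite BRCA gene.

Fitting uses maximum likelihood (statsmodels `Logit`, Newton iterations to
tolerance 1e-10, BFGS fallback). An indicator with no exposed cases or no
exposed controls has an infinite MLE; such cells are removed from the
likelihood before fitting, pinned at log-odds 0, and recorded in the
coefficient set's `dropped` list. This mirrors the inestimable cells of the
published per-stratum odds-ratio tables and doubles as a
complete-separation guard.

Design choices that the published category definitions leave open:

* male breast cancer sets the `male_bc` indicator *and* the appropriate
  TN-by-age cell (the predictors are treated as parallel, not exclusive);
* DCIS is an independent indicator and may co-occur with invasive disease;
* bilateral breast cancer is additive on top of the TN-by-age cell;
* a breast tumour routes to the `tn_unknown` cells unless its
  triple-negative status is affirmatively recorded.

Model discrimination is summarized by the rank-based (Mann-Whitney) AUC with
midrank tie handling, and a 95% CI from the Hanley-McNeil closed-form
variance.

## From predicted probabilities to evidence

With `r_k` the model's predicted carrier probability for proband *k* and
`r0` the null carrier probability of the proband's stratum (the case
fraction, cases/(cases+controls)), the likelihood ratio in favour of
pathogenicity contributed by that proband's clinical history is

    LR_k = r_k (1 - r0) / ((1 - r_k) r0)

i.e. the predicted carrier odds against the null odds. Per-variant evidence
is the product of LR_k over all probands carrying the variant, each scored
with their own stratum's coefficients and r0. All accumulation is in log10
space; the linear-scale product is materialized only on output and clamped
to an overflow sentinel beyond 10^±300. Probands carrying two distinct VUS
in the same gene contribute to both variants and the variants are flagged
(`shared_proband`).

## Admixture (heterogeneity) analysis

For a class C of N variants with combined likelihood ratios LR_i, the
fraction alpha of pathogenic variants in the class has likelihood

    L(alpha) = prod_{i=1..N} [ alpha LR_i + (1 - alpha) ]

Each term is evaluated as `logaddexp(ln alpha + ln LR_i, ln(1-alpha))`, so
extreme evidence never overflows. The MLE is found by bounded Brent search
on [0, 1] (tolerance 1e-8) with the endpoints checked explicitly; estimates
within 1e-7 of an endpoint are reported as boundary maxima. A flat
likelihood (all LR_i = 1) is unidentifiable and reported as alpha = 0 with
CI [0, 1] and a warning.

95% confidence limits are profile-likelihood endpoints: the alpha values
where 2[l(alpha_hat) - l(alpha)] = 3.84 (chi-square_1, 95%), located by
Brent root-finding to xtol 1e-12 and truncated at the parameter bounds.
No mixture-boundary chi-square correction is applied to the CI; partition
tests flag when a boundary is involved (`boundary_involved`), where the
chi-square reference is conservative.

Differences of alpha across a partition of the variant space are tested by
the likelihood-ratio statistic 2[sum of part maxima - pooled maximum] on
(number of parts - 1) degrees of freedom; p-values are reported unadjusted.

The class table is produced in two modes, mirroring the published paired
analyses: including laboratory-pathogenic variants, and VLP+VUS only.

## Posterior classification

Posterior probability of pathogenicity is Bayes' rule on the odds scale,
`posterior odds = prior odds x combined LR`, computed in log space. The
prior comes from a per-class prior table (external calibration values are
packaged as defaults, clearly labelled); the qualitative evidence labels use
strict 10:1 odds thresholds (`supports_pathogenic` above 10, `supports_benign`
below 1/10), and variants whose evidence rests on at least five probands are
flagged as meeting the families-count rule. IARC-style posterior tiers are
deliberately not the default output; odds thresholds are.

## Synthetic-cohort generator

The generator mirrors exactly what the inference assumes instead of
simulating pedigrees causally:

1. Phenotypes are drawn from baseline marginal frequencies typical of a
   hereditary-cancer testing population (default: 95% female; 45% of women
   with personal breast cancer, of which 12% triple-negative, half diagnosed
   before 50; 6% ovarian cancer; family-history count categories with a
   70/21/6/3 split for breast cancer <50, etc.). Phenotype blocks are drawn
   independently — the joint distribution of real testing cohorts is not
   public — so correlations between, say, personal ovarian cancer and family
   breast cancer history are absent. Passing tests therefore demonstrate
   calibration of the inferential machinery under its own assumptions, not
   robustness to the dependence structure of real clinical data.
2. Carrier status is Bernoulli from the logistic model with beta fixed to the
   published per-stratum odds-ratio grids (inestimable cells treated as OR 1)
   and intercept calibrated per stratum by root-finding so the realized
   prevalence matches the configured value (default 0.015 per gene, the
   published European-stratum null probability). Under these defaults the
   refitted BRCA1 European model has AUC ~ 0.82, consistent with the
   published 0.79-0.83 range for that gene.
3. Synthetic VUS are attached afterwards: each variant is latently
   pathogenic with class-specific probability `alpha_true` (defaults shaped
   like the published class estimates); its carrier count is geometric with
   P(singleton) = 0.65 (hence mean ~1.54 probands/variant — the singleton
   share is the anchored quantity); carriers of pathogenic-latent variants
   are sampled from the non-carrier pool weighted by their generative
   carrier probability (the carrier-conditional phenotype distribution, up
   to an O(prevalence) tilt), benign-latent carriers by the complement.
   Latently pathogenic variants receive a laboratory label of pathogenic
   (rate 0.20), VLP (0.10) or VUS; benign-latent variants are always VUS.
   The latent truth table is emitted separately and never read by inference.

All randomness flows from one integer seed through `numpy` `SeedSequence`
spawning, so cohorts are byte-identical across runs and platforms.

For estimator-level experiments the package also draws per-variant combined
LRs directly from the admixture model with lognormal evidence:
benign `ln LR ~ N(-sigma^2/2, sigma^2)` (so E[LR] = 1, as any calibrated
likelihood ratio must satisfy under the benign hypothesis) and pathogenic
variants from the exponentially tilted density `N(+sigma^2/2, sigma^2)`.
The default sigma = 2 matches the spread of real combined log-LRs (roughly
10^-3 to 10^3).

### Boundary behaviour of the admixture MLE

Because E[LR | benign] = 1, the score of the admixture likelihood at
alpha = 0 is `sum_i (LR_i - 1)`, which has mean exactly zero when every
variant is benign. The probability that the MLE sits exactly on the zero
boundary is therefore P(that mean-zero sum is non-positive): about 0.5 + a
skewness term, approaching 0.5 as the number of variants grows (CLT) and
approaching 1 only as the evidence becomes extremely discriminating (the sum
becomes dominated by rare huge LRs that are absent under benign truth).
Measured at 500 variants: ~0.57 at sigma = 2, ~0.93 at sigma = 5, ~0.99 at
sigma = 7. The acceptance test of boundary detection accordingly uses
strongly informative evidence (sigma = 7); under study-like evidence a pure
benign class typically yields a small positive alpha_hat with a CI reaching
0 — which is how such classes present in real class tables too (estimates
like 0.019 with CI 0.0-0.05).

## Problem sizes and determinism

The packaged experiments use cohorts of 20,000-200,000 probands and
100-500 variants per class: 200,000 x 100 replicates for Wald-CI coverage of
the generating odds ratio, 100,000 for AUC and null-calibration checks,
400 replicates for partition-test type-I error. These sizes give Monte-Carlo
error comfortably inside the asserted bands while keeping a full run in the
low minutes on one core. Every stochastic test fixes its seed; the
acceptance script derives all sub-seeds from its `--seed` argument.

## Known limitations

* Phenotype independence in the generator (see above); no pedigree
  segregation, allele frequencies, or mutation model.
* The bioinformatic class and prior probability of each variant are inputs;
  the package never computes conservation or splice-prediction scores.
* Only an intercept-level distinction between race/ethnicity strata is
  simulated beyond their separate coefficient grids; within-stratum
  phenotype marginals are shared.
* The admixture model treats per-variant LRs as exact; uncertainty in the
  fitted carrier-model coefficients propagates into the LRs but is ignored
  by the alpha likelihood (as in the source methodology), which slightly
  attenuates alpha estimates from small fitted cohorts.
* Probands with both a pathogenic variant and a VUS in the same gene are not
  modelled; exclusion rules address opposite-gene carriers only.
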