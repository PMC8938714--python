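# Methods

This note documents the models behind each pipeline stage, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions a user should know before trusting or
modifying results.

## Study design emulated by the generator

`finerisk.synthio` simulates the ingredients of a consortium-style
case-control PRS analysis: several genotyped studies drawn from one base
population, split into a **training** partition (GWAS and fine-mapping), a
**validation** partition (panel selection), an age-matched **prospective
test** partition (final out-of-sample evaluation; controls individually
matched to cases within a 5-year caliper, two per case), an **NGRS training**
partition (covariate-weight estimation, disjoint from the test set), and an
**external** study standing in for an independent consortium of different
ancestry.  The default scheme uses 1,800/2,200 training, 450/450 validation,
180/360 prospective-test and 200/700 NGRS-training cases/controls from a base
population sampled at 16% prevalence — a deliberately reduced replica of the
multi-study structure this kind of analysis uses at consortium scale, chosen
so the complete pipeline executes in seconds while every downstream estimator
still has reasonable power.

### Genotypes and LD

Within a locus, haplotypes come from a first-order autoregressive latent
Gaussian chain thresholded at each SNV's allele-frequency quantile; a
genotype is the sum of two independent haplotypes.  Because thresholding
attenuates correlation, the latent AR coefficient of each adjacent pair is
calibrated by solving the bivariate-normal orthant equation (via Owen's T
function) so that the **realized adjacent-genotype correlation equals the
configured `ld_decay`**.  When a requested correlation exceeds the Fréchet
bound for an unequal MAF pair, the latent coefficient is clamped and the
realized LD sits at that bound (logged at debug level).  Genotypes are
integer {0,1,2}; fractional imputed dosages are supported on input but not
simulated.  Loci live on separate chromosome labels and are mutually
independent — no long-range LD, no population structure, no X chromosome.

Defaults: 8 loci x 25 SNVs, `ld_decay = 0.35`, MAF ~ U(0.1, 0.45), 2 causal
SNVs per locus with log-OR ~ N(0.25, 0.10²).  The effect-size spread is the
point: it produces a mix of loci that clear the fine-mapping threshold and
loci that stay "ineligible" but carry a nominally significant lead SNV, which
is exactly the situation the three-tier panel construction exists for.

### Phenotype and covariates

Disease status follows a logistic model whose linear predictor sums centered
causal-dosage effects and centered covariate effects; the intercept is solved
numerically so the base population hits the configured prevalence, and each
study then samples its exact case/control counts without replacement.
Covariates: BMI ~ N(24, 3²) kg/m², WHR ~ N(0.81, 0.05²), age at menarche
~ N(14.8, 1.7²) y, age at first live birth ~ N(26, 4²) y, family history
Bern(0.03), benign breast disease Bern(0.2); age at enrollment ~ N(52, 9²)
and menopause = age exceeding a N(49.5, 4²) age at menopause, giving the
age-menopause dependence real cohorts show.  The BMI-by-menopause interaction
acts on **mean-centered** BMI, i.e. it is effect modification of the BMI
slope, not a huge main shift between menopause strata; an interaction on raw
BMI units would make premenopausal cases vanishingly rare and the model
unfittable.  Missingness is injected completely at random, only into the two
age-at-event covariates (rate 0.04), matching the observed pattern in this
kind of questionnaire data.

What passing tests on these cohorts do **not** show: robustness to realistic
human LD maps, imputation error, population stratification, covariate
measurement error, or non-MCAR missingness.  The generator is a correctness
harness, not a population-genetics simulator.

## Association and meta-analysis

Per-SNV association is a logistic (case-control) or OLS (quantitative)
regression of phenotype on dosage, Wald-tested; monomorphic SNVs are excluded
with a logged count.  The unadjusted logistic path uses a batched
Newton-Raphson solver over all SNVs simultaneously (verified against
statsmodels to 1e-7); adjusted fits fall back to statsmodels per SNV.
Adjustment covariates default to none and are a config choice.

Fixed-effects inverse-variance meta-analysis operates on the log-OR scale;
no heterogeneity statistics are computed.  Studies are first harmonized to a
common effect-allele convention: swapped alleles flip the sign and complement
the frequency, strand flips resolve through base complements, and
strand-ambiguous A/T, C/G SNVs are handled by policy — `drop` (default for
external data), `keep-if-freq-informative` (orientation from allele
frequencies when both are at least 0.1 from 0.5), or `same-strand` (default
inside `fixed_effects_meta`, appropriate for studies of one consortium that
share orientation; ambiguity then needs no special treatment).

## Conditional and joint analysis

From marginal statistics and a reference panel the normal equations are
reconstructed as

    D_j       = (n_j - 1) * var_j            (reference dosage variance)
    (X'X)_jk  = r_jk sqrt(var_j var_k) (min(n_j, n_k) - 1)
    (X'y)_j   = D_j b_j
    b_joint   = (X'X)^{-1} X'y

with the residual variance recovered from each SNV's marginal triplet,
`Syy_j = D_j (se_j² (n_j - 2) + b_j²)` (median across the set), and joint
standard errors `sqrt(sigma² diag((X'X)^{-1}))` with sigma² =
(Syy − b'X'y)/(n − k − 1).  Using the reference panel's *empirical* variances
rather than the Hardy-Weinberg expression 2f(1−f), and t-distributed
p-values with n − k − 1 degrees of freedom, makes the reconstruction exact:
when the LD reference is the association sample and n is uniform, joint
estimates equal full-data multiple regression to machine precision (the
binding contract, enforced at 1e-6 in the tests).  With an external
reference or case-control log-ORs the method is the standard summary-
statistics approximation and is tested at statistical tolerances.

Stepwise selection starts from the smallest marginal p below the threshold,
repeatedly adds the candidate with the smallest conditional p below the
threshold while skipping candidates above the r² collinearity guard, and
back-eliminates any selected SNV whose joint p rises above the threshold.
Choices where the field is silent, each configurable: r² guard 0.9 (the
conventional default), locus half-width 500 kb around an index SNV with
overlapping windows merged, ties in p broken by larger |b| then lexicographic
SNV id (determinism over arbitrariness), SNVs whose summary frequency differs
from the reference by more than 0.2 dropped with a warning.  Relaxing the
threshold usually, but not provably, enlarges the selected set —
back-elimination can break strict nesting, so that property is asserted
statistically, not absolutely.

## Tiered panels and scoring

Tier 1 collects every selected SNV with its joint weight; tier 2 keeps those
whose external association shares the joint weight's sign with external
p < .05 (an SNV absent from the external data fails the filter); tier 3 adds,
for each ineligible locus, its lead SNV (smallest marginal training p, same
tie-break) when training p < .05, weighted by the training marginal beta.
The sign consistency deliberately uses the *joint* weight's sign; marginal
sign is a config away if a user prefers it.  Externally reported SNV lists
can instead be reweighted with external, internal, or meta-analysed weights;
requested SNVs missing from the data are dropped with a logged count.

PRS scoring is the plain weighted dosage sum with allele reorientation
(2 − d when the panel lists the other allele).  A panel SNV missing from the
dosage data is a **hard error** listing the ids — silent skipping would
corrupt score provenance; opt-in frequency imputation (2·freq) exists for
panels that carry frequencies.  Standardization subtracts the mean and
divides by the SD (ddof = 1) of a reference group — by default the control
participants of the evaluation partition, configurable — so "OR per SD" is
anchored to a stated population.

## Nongenetic score and integrated model

The NGRS is a logistic model of status on BMI, WHR, menopause, age at
menarche, age at first live birth, family history, benign breast disease and
BMI x menopause; weights come from maximum likelihood and the score is the
weighted sum without the intercept.  Internally the fit centers BMI (the raw
interaction column is nearly collinear with the menopause indicator and
destabilizes Newton steps) and maps coefficients back exactly.  Missing
values in the two age fields are filled by deterministic chained regression —
each incomplete field regressed on the complete covariates among observed
rows, predictions clipped to the observed range, the first imputed field
joining the predictors of the second.  This is a single-imputation variant of
chained equations; it trades the between-imputation variance of multiple
imputation for bitwise reproducibility of every downstream score, and is
documented as such.

The integrated model refits status on the standardized PRS and NGRS jointly;
a constant predictor is excluded (the model degenerates gracefully to the
informative component), and the combined linear predictor is scored and
AUC'd.  Evaluation uses Mann-Whitney concordance (ties ½) with DeLong
confidence intervals (validated against pROC to 1e-12) and Wald ORs per SD.
Percentile groups are cut on the control distribution of the same partition
(configurable to all-sample) with default edges
{0,1,5,10,20,40,60,80,90,95,99,100} and the 40-60 bin as reference; group ORs
come from one logistic fit with the reference indicator omitted.  Best-panel
selection takes the maximum validation AUC with exact ties resolved toward
the smaller panel.

## Absolute risk

Group ORs are used directly as relative risks (rare-disease approximation —
adequate at breast-cancer incidence levels, increasingly anti-conservative
for common outcomes).  The baseline hazard is constrained so the
proportion-weighted group hazards reproduce the population incidence at every
age (checked to 1e-12); proportions default to percentile-bin widths.  The
10-year risk uses a discrete annual life table with exponential within-year
survival and the within-year event probability apportioned to the
cause-specific hazard; with zero mortality and constant hazard this equals
1 − exp(−Yh) exactly, which pins the convention down.  Five-year rate tables
are expanded to annual bins by repetition (interpolation would be the
alternative; repetition keeps inputs and outputs in exact correspondence).
The bundled `shanghai_like_rates()` is a synthetic stand-in with plausible
urban-Chinese magnitudes (incidence ramping to ~1.4/1000 person-years around
age 60, Gompertz-like all-cause mortality); it is not registry data, and
absolute-risk outputs under it demonstrate the machinery, not real risks.

## Numerical conventions and degenerate inputs

Coordinates are 1-based in files, 0-based half-open internally.  p-values
are clipped to [tiny, 1].  Logistic fits require convergence and flag
separation (coefficient magnitude > 50) as errors rather than returning
garbage.  Zero-variance scores, single-status groups, empty reference bins,
rate-table coverage gaps, and panel/dosage mismatches all raise typed
exceptions.  Randomness flows from explicit seeds through
`numpy.random.Generator`; the same seed reproduces every table bit for bit.

## Problem sizes

The demonstration pipeline and acceptance measurements run at the reduced
scales above (hundreds of SNVs, thousands of individuals; 20 replicate loci
of 50 SNVs at n = 20,000 for fine-mapping recovery; 100 replicates of
n = 10,000 for CI coverage).  These sizes were chosen as the smallest at
which the statistical claims are comfortably testable; all of them are plain
config values and scale up unchanged.

## Known limitations

No plotting utilities are bundled — outputs are tidy tables intended for the
user's own tooling.  The LD model cannot express between-locus correlation
or realistic recombination maps.  The NGRS factor coding is continuous where
a published analysis might bin; binnings are config options.  Back-elimination
cycling in stepwise selection is cut off by an iteration cap with a logged
warning.  The age-by-PRS interaction analysis is exposed as a configuration
of the integrated model but has no reference values to check against.
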