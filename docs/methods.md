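# Methods

This note documents the statistical models implemented in `hetfit`, the
choices made where several defensible readings exist, and what the
synthetic-data generator does and does not emulate.

## Data model

Genotypes are codominant microsatellite calls: an unordered pair of
opaque allele labels per (individual, locus), or a wholly missing call.
Half-calls are rejected at load time. Individuals carry sex, calendar
year of capture, age (years, from tooth wear in the motivating system)
and litter size 0–4 (Tasmanian devils carry at most four pouch young);
`bred` is derived as litter ≥ 1. Allele labels are never interpreted as
fragment sizes — no downstream statistic needs them.

Missing-value codes default to `{"", "0", "NA", "na"}` and are
configurable. Allele frequencies are estimated by gene counting over
all non-missing calls, pooled across sexes and years by default (to
minimise the impact of yearly frequency fluctuations on IR); per-cohort
frequencies are available through a grouping argument and are used for
the per-year null-allele columns.

## Per-locus diversity

For each locus: Na (distinct observed alleles), observed heterozygosity
H_O = heterozygous calls / typed calls, and Nei's unbiased expected
heterozygosity H_E = (2n/(2n−1))·(1 − Σp²).

**Hardy–Weinberg testing.** The conditional exact test: given the
observed allele counts, the p-value is the total probability of
genotype configurations whose conditional probability
P ∝ N!/(Πn_ij!) · 2^H · Πn_a!/(2N)! does not exceed the observed
configuration's. Configurations are enumerated completely for up to 3
alleles; beyond that the null is sampled by shuffling the allele vector
(default 10,000 draws) with the add-one correction, so p is never 0.
The test family is recorded in the run manifest because spreadsheet
toolkits that popularised this summary table do not document theirs;
numerical reproduction of any particular tool's p column is therefore
not promised.

**F_IS.** Per locus and cohort, F_IS = 1 − H_O/H_S with the
small-sample-corrected gene diversity
H_S = (n/(n−1))·(1 − Σp̄² − H_O/(2n)). Monomorphic locus–cohorts are
undefined and excluded from the unweighted cohort mean.

**Null alleles.** Brookfield's heterozygote-deficit estimator
r = (H_E − H_O)/(1 + H_E), clamped to 0 when negative. Only this form
(no observed null homozygotes) is implemented: the data model does not
distinguish a failed amplification from ordinary missingness, which is
exactly the situation the estimator was designed for. Per-cohort
estimates use that cohort's own frequencies and H_O/H_E.

## Multilocus heterozygosity indices

* IR = (2H − Σf)/(2N − Σf) over typed polymorphic loci (N typed, H
  homozygous, Σf the pooled population frequencies of the 2N carried
  copies). Monomorphic loci are excluded; they carry no inbreeding
  information and would bias every individual toward homozygosity.
  Frequencies include the focal individual by default (they are the
  full-sample pooled frequencies); a leave-one-out switch exists.
* sMLH = Σ(0/1 het) / Σ(sample mean H_O of the same loci) — the
  conventional standardized multilocus heterozygosity, which handles
  missingness by standardizing over the loci the individual was typed
  at. Population mean 1 on complete data.
* HL = ΣE_hom/(ΣE_hom + ΣE_het), weighting loci by unbiased expected
  heterozygosity; 0 for a fully heterozygous and 1 for a fully
  homozygous genotype.

Temporal trends in an index are ordinary least squares on **raw
calendar year** with t-based inference (an intercept at "year 0" is
then literally the extrapolated value at 1 CE — harmless, and it keeps
slopes in per-calendar-year units). The GLM stages instead code year 0
at the first study year (2006) before standardizing.

## Identity disequilibrium (g2)

g2 is estimated from the 0/1 heterozygosity matrix over ordered locus
pairs, each pair restricted to the individuals typed at both loci
(pairwise-complete missing-data handling; the per-pair sample sizes
N_ij appear explicitly in both numerator and denominator). The
implementation is closed-form matrix algebra and is tested to 1e−12
against a four-nested-loop reference, with and without missing
entries. Precision: bootstrap over individuals (SE = SD of the
resampled estimates). Significance: every locus column permuted
independently across individuals — this destroys the between-locus
association that constitutes identity disequilibrium while preserving
each column's heterozygosity rate and missingness count — with
p = (1 + #{g2_perm ≥ g2_obs})/(n_iter + 1). Whole-individual
permutation would preserve the very signal under test and is not
offered. Default 1,000 iterations; below 100 a warning flags unstable
tails. Ordered pairs (i, j) and (j, i) are both summed, which
symmetrizes the asymmetric denominator term.

Under the multiplicative model (per-locus heterozygosity probability
scaled by 1 − f), the population value is Var(f)/(1 − E[f])², which is
the generator's closed-form truth.

## Heterozygosity–fitness models

Three binomial logit GLM families on female reproductive success, with
candidate predictors {age, IR, year}:

1. litter size as events out of 4 trials, all females;
2. bred (0/1), all females;
3. litter size, breeders only.

Predictors are standardized to mean 0, SD 0.5 (centred, divided by two
sample SDs) so continuous and binary effects are comparable. The
log-likelihood includes the log C(4, y) constant, so AIC matches
mainstream GLM output and is invariant (up to that constant) to
events/trials vs expanded-Bernoulli encoding — a tested identity.

All 8 predictor subsets are fitted and weighted by
w = exp(−Δ/2)/Σexp(−Δ/2). The selection criterion defaults to AICc for
this stage (standard in small-sample information-theoretic workflows;
plain AIC is a config option). Coefficients are **conditional
(natural) averages**: weighted means over the models containing the
term with renormalized weights, adjusted SE
Σw̃·sqrt(var_m + (β_m − β̄)²), 95% CI = estimate ± 1.96·adjSE (fixed
normal quantile, not t), and RI = Σ full-set weights of models
containing the term. Averaging uses the full candidate set by default;
a Δ-threshold subset is a config option since published workflows vary.
Rows missing any predictor are dropped from every candidate model of a
response so criteria are comparable across the set.

The global-model R² defaults to the variance-function-based form
1 − Σ[(y/n − μ̂)²/V(μ̂)] / Σ[(y/n − μ̄)²/V(μ̄)], with the
deviance-based (KL) form 1 − D/D₀ as a config option; the flavour used
is recorded in output.

## Local vs general effects

On the complete-case subset (females with litter data and zero missing
genotypes): a base model (litter ~ year, raw units, year 0 at 2006),
one model per locus adding that locus's 0/1 heterozygosity, and an HO
model adding the individual's mean heterozygosity across loci (same
measurement scale as the single-locus predictors, unlike IR). Plain
AIC throughout, unstandardized predictors; AIC ties sort
alphabetically for deterministic output. Loci monomorphic within the
subset are excluded with a warning (their model duplicates the base).

Interpretation: a locus is a *local-effects* candidate only if its
model beats the HO model by more than 4 AIC **and** its slope exceeds
the multilocus slope in magnitude; |ΔAIC| < 2 counts as equivalent
support. Because single-locus heterozygosities are mutually correlated
under inbreeding, relative effect magnitudes — not significance of
individual slopes — carry the inference. Negative-slope loci
(heterozygotes less fit) are flagged: that direction is opposite to
the inbreeding-depression prediction. A simultaneous all-loci multiple
regression is deliberately not offered: with ~2 cases per predictor it
would be uninterpretable.

## Synthetic-data generator

Per individual, f is drawn from a zero-inflated mixture (point mass at
0 with probability π0, remainder on discrete values or a Beta); per
locus, with probability f a single allele is drawn and duplicated
(identity by descent), otherwise two independent draws. Loci are
independent given f — no linkage — which suffices for every statistic
in scope, all of which assume unlinked neutral markers. Missingness is
iid per call. Litter sizes are Binomial(4, p) with
logit(p) = b0 + b_f·f + b_year·(year − 2006) + b_age·age, females
only.

Defaults (chosen once, as study-scale conditions): 168 individuals,
~54% female, 32 loci with 2–7 alleles (Dirichlet(1) frequencies), six
sampling years {2006, 2007, 2009, 2014, 2015, 2016} uniformly, 5%
missing calls, f mixture π0 = 0.5 / point 0.23 giving
g2 = Var(f)/(1 − E[f])² ≈ 0.017, b0 = 1.09 and b_year = −0.36 (the
base-model intercept and decline observed in such populations on the
raw-year logit scale), b_age = 0, and b_f = −3 — a mid-range mammalian
fecundity load per unit f. Null alleles can be planted at chosen loci:
a hidden allele of frequency r that never amplifies, so null
heterozygotes score homozygous and null homozygotes go missing.

What the generator does **not** emulate: linkage and physical
clustering of markers; age–year–cohort dependence; per-individual
missingness concentration (real datasets lose whole individuals, so
e.g. the complete-case count under flat 5% missingness is smaller than
a real panel with the same overall rate would give); yearly allele
frequency drift; and genotyping error. Tests passing on these data
show estimator correctness and calibration under the stated model, not
robustness to those artefacts.

## Numerical choices and edge cases

* Negative Brookfield estimates clamp to 0; monomorphic cohorts are NA.
* g2 locus pairs observed in < 2 individuals are dropped with a
  warning; bootstrap resamples on which g2 is undefined are skipped in
  the SE.
* Degenerate trend inputs: a constant index returns slope 0 with p = 1
  (no-trend) rather than an OLS failure; a single distinct year raises.
* Zero-variance vectors cannot be standardized (hard error).
* HWE enumeration treats configurations within 1e−9 log-probability of
  the observed one as ties counted into p.
* All Monte-Carlo stages take explicit seeds; the pipeline derives
  per-stage seeds from one manifest seed, and identical
  config + seed + input reruns are byte-identical.

## Problem sizes used in the validation suite

Estimator-consistency checks run at N = 2000 individuals × 32 loci;
calibration of the g2 permutation test uses 500 null datasets of 90
individuals at 200 permutations each; model-averaging recovery and
coverage use 200 replicates at the 168-individual study scale; oracle
equivalence checks use 50 random 20×6 matrices (g2) and 30-row tables
(GLM/IRLS).

## Known limitations

* The HWE Monte-Carlo p-value is itself an estimate; at the default
  10,000 draws its SE near p = 0.05 is ~0.002.
* Conditional model averaging is reported with a fixed 1.96 quantile;
  for n ≪ 50 a t-quantile CI would be wider.
* The g2 estimator's pairwise-complete missing-data handling can
  differ from other published estimators by small constant-order terms
  when missingness is heavy; on near-complete matrices the estimators
  agree.
* Under weak inbreeding load and realistic inbreeding variance
  (g2 ≈ 0.017), a ~90-female sample has limited power: the sign of the
  model-averaged IR coefficient is recovered in roughly three quarters
  of replicates at a load of −1 per unit f, and reliable recovery
  requires loads several times larger. This is a property of the
  design, not of the estimator.
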