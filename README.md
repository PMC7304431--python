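# hetfit

Heterozygosity–fitness correlation (HFC) analysis for codominant
microsatellite data, built for small, isolated wildlife populations
where inbreeding depression is a management concern (the motivating
case is a declining marsupial population genotyped at 32 neutral
markers over six monitoring years, with female litter size 0–4 as the
fitness trait).

The package implements the full inferential chain a population
geneticist needs to argue "this population is inbreeding, and
inbreeding is costing it offspring":

1. **Diversity screening** — per-locus Na, H_O, unbiased
   H_E = (2n/(2n−1))(1 − Σp²), conditional exact Hardy–Weinberg tests,
   Nei's F_IS = 1 − H_O/H_S per year, and Brookfield null-allele
   frequencies r = (H_E − H_O)/(1 + H_E) per locus and year.
2. **Multilocus heterozygosity** — internal relatedness
   IR = (2H − Σf)/(2N − Σf), standardized multilocus heterozygosity
   (sMLH) and heterozygosity-by-loci (HL), their correlations, and
   OLS trends over calendar year.
3. **Identity disequilibrium** — the g2 statistic over locus pairs
   (pairwise-complete in the presence of missing data) with bootstrap
   SE and a column-permutation p-value. A significant g2 > 0 is the
   precondition for reading an HFC as inbreeding depression; under the
   multiplicative model g2 = Var(f)/(1 − E[f])².
4. **HFC models** — binomial logit GLMs of litter size (events out of
   4 trials) and breeding probability on {age, IR, year}, predictors
   standardized to SD 0.5, all 2³ subsets ranked by AICc, conditional
   model-averaged coefficients with adjusted SE, 95% CI
   (±1.96·adjSE), relative importance, and global-model R².
5. **Local effects** — a 34-model AIC scan (base model, one model per
   locus, a multilocus-H_O model) that asks whether the HFC is driven
   genome-wide or by individual loci, using ΔAIC support bins and
   slope-magnitude comparisons.
6. **Synthetic data** — a generator that draws per-individual
   inbreeding coefficients, simulates identity-by-descent genotypes,
   missingness, optional null alleles, and a logit-scale litter-size
   load, so every stage is testable against known truth without any
   download.

## Worked example

Simulate a study-scale dataset and test for identity disequilibrium:

```bash
hetfit simulate --out demo --seed 7
# wrote demo/genotypes.csv (168 x 32)
hetfit g2 demo/genotypes.csv --out demo/g2.json --n-iter 1000 --seed 1
# g2=0.013896430863966636  se=0.004262390226797223  p=0.000999000999000999 ...
```

g2 ≈ 0.014 with bootstrap SE ≈ 0.004 and permutation p ≈ 0.001: the
markers carry significant variance in inbreeding (the generating
mixture has a closed-form g2 of ≈ 0.017), so an HFC on these data can
be interpreted as inbreeding depression. Then fit the reproductive
models:

```python
from hetfit import load_genotype_table, compute_mlh, run_reproductive_models
from hetfit.hfc_models import averaged_model_frame

table = load_genotype_table("demo/genotypes.csv")
models = run_reproductive_models(compute_mlh(table))
print(averaged_model_frame(models).to_string(index=False))
```

```
          Model  N Predictor  Estimate       SE       RI       R2
     litter_all 94 Intercept -1.290905 0.161632      NaN 0.385954
     litter_all 94       Age  0.078577 0.269440 0.261447      NaN
     litter_all 94        IR -0.508523 0.283804 0.635757      NaN
     litter_all 94      Year -2.805928 0.324938 1.000000      NaN
       breeding 94 Intercept  0.529533 0.283776      NaN 0.107439
       ...
```

Reading the `litter_all` block: across the 94 simulated females the
standardized IR coefficient is −0.51 (adjusted SE 0.28) with relative
importance 0.64 — more-homozygous females produce smaller litters —
while the year effect (−2.81, RI 1.00) captures the simulated decline
in reproductive output; the global model explains R² ≈ 0.39 of the
variance. The locus-by-locus scan (`hetfit local-effects`) then checks
whether such a signal is genome-wide or carried by single loci, and
`hetfit run-all --config config.yaml --out results/` produces all
report tables (locus summary, F_IS by year, MLH, g2, model averages,
local effects) plus a manifest with hashes and seeds in one call.

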