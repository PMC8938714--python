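# finerisk

Breast-cancer risk prediction from case-control GWAS data: summary-statistics
fine-mapping, tiered polygenic risk scores (PRS), a nongenetic risk score
(NGRS), an integrated model, and 10-year absolute risks — with a synthetic
multi-study cohort generator so the whole pipeline runs end-to-end without any
private data.

The package is aimed at statistical geneticists and epidemiologists who want a
tested, importable implementation of this analysis pattern: per-study
case-control GWAS combined by fixed-effects meta-analysis, conditional/joint
fine-mapping of known susceptibility loci from summary statistics plus an LD
reference, tier-based SNV selection for a compact PRS, evaluation by OR per SD
and AUC with validation-then-test panel selection, and conversion of
percentile-group odds ratios into absolute risks against registry-style rate
tables.

## The statistics in brief

- **PRS**: `PRS_i = sum_k beta_k * d_ik`, where `d_ik` is individual *i*'s
  dosage of SNV *k*'s effect allele and `beta_k` a per-allele log odds ratio.
- **Fine-mapping** (conditional-and-joint analysis): from marginal estimates
  `b_j, se_j, n_j` and a reference correlation matrix `r_jk`, the
  multiple-regression normal equations are reconstructed with
  `D_j = (n_j - 1) var_j`, `(X'X)_jk = r_jk sqrt(var_j var_k)(min(n_j, n_k) - 1)`,
  `(X'y)_j = D_j b_j`; joint effects are `(X'X)^{-1} X'y`.  Forward stepwise
  selection at a p-value threshold (1e-5 / 1e-4 / 1e-3) with an r² = 0.9
  collinearity guard and backward elimination defines the selected SNVs per
  locus.  When the LD reference *is* the GWAS sample this reproduces
  full-data multiple regression exactly.
- **Tiered panels**: (1) all fine-mapped SNVs with joint weights; (2) those
  direction-consistent in an external dataset at p < .05; (3) tier 2 plus
  lead SNVs of fine-mapping-ineligible loci with training p < .05.
- **NGRS**: `NGRS_i = sum_k w_k F_ik + w_i * BMI_i * menopause_i` with weights
  from a logistic fit of the seven factors plus interaction.
- **Meta-analysis**: inverse-variance fixed effects,
  `b = sum(b_j / se_j²) / sum(1 / se_j²)`, `se = 1 / sqrt(sum(1 / se_j²))`.
- **Absolute risk**: group ORs act as relative risks; baseline hazard
  `h0(t) = h_pop(t) / sum_g pi_g RR_g` guarantees
  `sum_g pi_g h_g(t) = h_pop(t)`, and the 10-year risk is a discrete annual
  life table with competing mortality,
  `risk = sum_t exp(-sum_{u<t}(h_g+m)) (1-exp(-(h_g+m)_t)) h_g/(h_g+m)`.

## Worked example

```python
from finerisk import run_demo

res = run_demo(seed=7)
chosen = res.test_reports[res.chosen_label]
print(res.chosen_label, chosen.auc, chosen.or_per_sd)
print(res.irpm.auc)
```

Running `python examples/04_tiered_prs.py` (which does the above and prints
each candidate panel) ends with:

```
best panel in validation: finemap_all@0.001
prospective-test AUC 0.716 (95% CI 0.670-0.761), OR per SD 2.13
```

meaning the panel with the highest validation AUC was a fine-mapping panel,
and in the untouched, age-matched prospective test set one standard deviation
of that PRS multiplies breast-cancer odds by ~2.1 with an AUC of 0.72.
`examples/05_ngrs_and_irpm.py` then shows both the PRS and the NGRS remaining
independently associated inside the integrated model, and
`examples/06_absolute_risk.py` converts percentile-group ORs into a 10-year
absolute-risk spread at age 60 (0.24% for the bottom percentile group to 7.4%
for the top 1% under the synthetic rate table).  Each script in `examples/`
exercises one capability and explains its printout.

A thin CLI mirrors the stages for shell use:

```bash
finerisk simulate --seed 7 --outdir work/
finerisk assoc --dosages work/dosages.tsv --snvs work/snvs.tsv \
    --cohort work/cohort.tsv --study study_a --out work/a.ma
finerisk meta work/a.ma work/b.ma --out work/meta.ma
finerisk finemap --ma work/meta.ma --dosages work/dosages.tsv \
    --snvs work/snvs.tsv --threshold 1e-5 --out work/selection.tsv
finerisk demo --seed 7 --outdir work/demo   # everything at once
```

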