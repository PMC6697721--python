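# svmetpk

Joint population pharmacokinetics of oral simvastatin and its four measured
metabolites in children and adolescents.

Simvastatin (SV) is dosed as an inactive lactone and activated by
hydrolysis to simvastatin acid (SVA); CYP3A-mediated oxidation gives
6-hydroxymethyl SV (HMSV) and its acid (HMSVA), and 3,5-dihydrodiol SV
(DHSV). SVA exposure varies enormously between paediatric patients — the
loss-of-function SLCO1B1 c.521T>C variant of the hepatic uptake transporter
OATP1B1 raises it several-fold per allele, and a sizeable fraction of
children show almost no measurable SVA at all. This package implements, as
reusable and tested code, the modelling workflow for a single-dose
(10 mg < 18 y / 20 mg ≥ 18 y), genotype-stratified study of 32
hyperlipidemic children and adolescents sampled over 8 h with a 0.5 nM
quantification limit for all five analytes:

* a seven-state structural model — dual sequential zero-/first-order
  absorption with lag, one-compartment disposition for SV and each
  metabolite on the apparent (CL/V-ratio) scale, HMSVA formed from both SVA
  and HMSV, and saturable (sigmoid Imax) HMSV elimination;
* covariate models: additive c.521T>C effects on the latent SVA formation
  clearance (θ562) and volume (θ561), and sigmoid-Imax age effects on the
  HMSVA and DHSV elimination ratios,
  `CL_HSVAe/V_HSVA = 4.91·(1 − Age/(5.34 + Age))` and
  `CL_DHSe/V_DHSV = 12.9·(1 − 0.90·Age/(6.3 + Age))`;
* exponential between-subject variability on 14 parameters, a
  double-exponential (proportional + near-LLOQ additive) residual model,
  and censored-likelihood (M3) handling of below-LLOQ observations;
* marginal-likelihood estimation by the Laplace approximation with a
  batched, warm-started inner mode search; empirical Bayes estimates,
  shrinkage, standard errors;
* covariate screening (regression/ANOVA on EBEs with the >40% shrinkage
  rule) and stepwise forward-inclusion (ΔOFV > 3.84) / backward-elimination
  (ΔOFV > 7.88) search with per-degree-of-freedom χ² thresholds;
* a synthetic-trial generator reproducing the study design, and model
  evaluation: visual predictive checks with below-LLOQ fraction panels,
  nonparametric bootstrap, conditional weighted residuals.

The clinical dataset behind the original analysis is not public, so the
trial simulator is a first-class component: every estimation and diagnostic
feature is exercised end-to-end on virtual trials generated from the
published final-model parameters. `docs/methods.md` describes the model,
the estimation machinery and its numerical choices in detail.

## Worked example

Simulate one virtual trial of the study design and summarise censoring
(`python analysis/01_simulate_trial.py`):

```
simulated 32 subjects, 1280 observation rows -> results/trial_seed1.csv

below-quantification fractions (post-dose):
analyte   n  n_blq  fraction_blq
     SV 256     50      0.195312
    SVA 256    137      0.535156
   HMSV 256    130      0.507812
  HMSVA 256    170      0.664062
   DHSV 256     63      0.246094
```

Half the SVA data falls below 0.5 nM — exactly why the likelihood treats
those points as censored rather than discarding them. The covariate
relationships of the final model
(`python analysis/02_covariate_effects.py`):

```
c.521T>C effect on the SVA sub-model (age 14 y):
genotype  CLLA_VSVA  CLSVAe_VSVA  AUC_ratio_vs_TT
      TT     0.0430       0.1300             1.00
      TC     0.1317       0.2063             1.93
      CC     0.4730       0.5000             2.86

CLHSVAe_VHSVA: 60.0% lower at 18 y than at 4 y; 50% of the maximal reduction is reached at 5.34 y
CLDHSe_VDHSV: 48.8% lower at 18 y than at 4 y; 50% of the maximal reduction is reached at 6.30 y
```

Each c.521C allele nearly doubles the SVA area under the curve, and the two
age-dependent elimination ratios fall by 60% and 49% between 4 and 18
years. `analysis/03_fit_sv_sva.py` re-estimates the SV–SVA sub-model from a
200-subject virtual cohort, `analysis/04_select_covariates.py` runs the
screening and stepwise search (the genotype effect on the formation ratio
survives backward elimination with ΔOFV ≈ 57 in the example replicate), and
`analysis/05_diagnostics.py` produces the VPC, CWRES and bootstrap tables
under `results/`.

The same functionality is available from the command line:

```
svmetpk simulate --seed 1 --out-dir out
svmetpk fit --data out/trial.csv --analytes SV,SVA --free CLLA_VSVA,CLSVAe_VSVA --out-dir out
svmetpk vpc --data out/trial.csv --out-dir out
svmetpk summarize-blq --data out/trial.csv --out-dir out
```

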