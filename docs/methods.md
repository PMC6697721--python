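# Methods

## The model

`svmetpk` implements a joint population pharmacokinetic model for oral
simvastatin (SV) and four metabolites — simvastatin acid (SVA, the active
species), 6-hydroxymethyl simvastatin (HMSV), 6-hydroxymethyl simvastatin
acid (HMSVA) and 3,5-dihydrodiol simvastatin (DHSV) — in children and
adolescents after a single dose (10 mg below 18 years, 20 mg otherwise).

**Absorption.** The dose splits between two parallel pathways,
F1 = 1/(1+BA) and F2 = BA/(1+BA). Each pathway is a sequential zero-order /
first-order process: the dose fraction is released at a constant rate for a
duration D (D1, D2) into a depot, which drains into the SV central
compartment at a first-order rate (ka1, ka2). The second pathway starts
after a lag ALAG. We read "sequential zero- and first-order" as zero-order
release *into the depot* because the model diagram draws both depots feeding
the central compartment; the alternative (zero-order directly into central)
is rejected on that basis.

**Disposition.** One-compartment kinetics for SV (V_SL/F, CL_SLe/F) and for
each metabolite. Metabolite volumes are not structurally identifiable from
plasma data, so all metabolite parameters are apparent ratios (for example
CL_LA/V_SVA, 1/h). Formation terms draw on the SV plasma concentration
C_SV = A_SV/V_SL; no mass is subtracted from the parent for metabolite
formation, which is the standard apparent-parameter convention when only
ratios are estimable. HMSVA forms from both SVA and HMSV. HMSV is
eliminated by a saturable Hill process V_max·C^γ/(EC50^γ + C^γ); the source
material names the model (inhibitory sigmoid Emax) without printing the
equation, and this form is the one consistent with a maximum elimination
rate in nM/h. Back-conversion of the acids to the lactones through the
acyl-glucuronide is deliberately not modelled (unidentifiable here).

Doses are converted mg → nmol with the simvastatin molar mass
418.57 g/mol, so amounts divided by V_SL are directly on the nM scale of
the concentration data.

**Covariates.** The final model carries two effects:

* SLCO1B1 c.521T>C (rs4149056), additive per C allele, on the latent CL_LA
  (coefficient θ562 = 0.93) and V_SVA (θ561 = −0.37). On the apparent scale:
  CL_LA/V_SVA × (1+rs·θ562)/(1+rs·θ561) and CL_SVAe/V_SVA / (1+rs·θ561).
* a sigmoid Imax age effect value·(1 − Fra·age/(T50+age)) on CL_HSVAe/V_HSVA
  (Fra fixed at 1, T50 = 5.34 y) and CL_DHSe/V_DHSV (Fra = 0.90,
  T50 = 6.3 y). The published typical values are therefore age-0 intercepts.

The published parameter table describes its typical subject as a 14-year-old
CC homozygote, which contradicts the printed covariate equations (reference
rs = 0, age explicit). We follow the equations; the footnote is treated as
an erratum. Machinery for the relationships that were screened and rejected
(allometric body size with exponents 0.75/1, dominant/recessive genetic
forms, log-linear continuous covariates) exists for the covariate search but
is not applied by default.

**Variability.** Between-subject variability is exponential
(parameter = typical·exp(η), η ~ N(0, ω²)) on 14 parameters, with diagonal
Ω only (correlations destabilise estimation on this design). Published
magnitudes are CVs with CV = sqrt(exp(ω²)−1), so ω² = ln(1+CV²). Residual
error is the double-exponential model on log-transformed data,

    ln y = ln(f+m) + (f/(f+m))·ε1 + (m/(f+m))·ε2,

proportional where the prediction f dominates, additive (scale m) near the
quantification limit. For SV, HMSV and DHSV the ε1 variance differs between
the absorption phase [0, 2) h and the elimination phase [2, 8] h (the 2 h
boundary belongs to the elimination phase). m is estimated for SV and SVA
and fixed at 1e-4 nM for the three low-level metabolites.

**Censoring.** The LLOQ is 0.5 nM for all five analytes and a large share
of the metabolite data is below it. Below-limit observations contribute
their censoring probability Φ((ln LLOQ − μ)/w) to the likelihood (the M3
method) rather than being discarded. A value exactly at the limit is
reported, not censored.

## Estimation

The marginal likelihood integrates the censored observation model over each
subject's random effects. We use the Laplace approximation: per subject,
−2 ln L ≈ 2·negjoint(η̂) + ln det Ω + ln det H, with η̂ the joint mode and H
the curvature of the negative joint log-density at the mode. Objective
values follow the NONMEM constant convention (the per-observation ½ln 2π is
dropped), so ΔOFV is comparable to χ² quantiles.

Two curvature treatments are available. The default uses a Gauss–Newton
surrogate assembled from the prediction sensitivities ∂μ/∂η (finite
differences, step 1e-4) with exact per-row curvature weights — 1/w² for
quantified rows and the analytic second derivative of −ln Φ for censored
rows — plus the exact prior curvature. This is the same first-order
linearisation that conditional-estimation methods use, and it comes almost
free because the same perturbed evaluations yield the objective gradient.
`hessian="exact"` switches to full finite-difference Hessians (slower; on
simulated study data the two differ by a systematic OFV offset of order
0.5–1 per subject but rank parameter values the same way).

The inner mode search is batched across subjects: damped Newton with
Levenberg–Marquardt damping and a direction-preserving trust region,
warm-started from the previous outer iteration. Subjects the sweep leaves
unconverged are refined by exact-Hessian Newton and, as a last resort, a
per-subject BFGS polish. One genuine pathology deserves note: the zero-order
absorption windows make each subject's joint density only piecewise smooth
in η — when an observation time coincides with a window boundary
(t = ALAG·e^η or ALAG·e^η + D2·e^η), the gradient jumps and the mode can sit
exactly at the kink, where no gradient criterion can be met. The refinement
therefore also stops on value stagnation (joint value converged even though
the gradient does not vanish); the residual OFV error is below 1e-6 per
subject. The inner tolerance is 1e-5 on the scaled gradient norm, the
practical floor set by finite-difference noise; a tighter 1e-6 target is
unreachable there and indistinguishable in the OFV.

The outer optimisation works on transformed parameters: log for positive
quantities, logit on (−0.5, 5) for the fractional genotype coefficients
(keeping 1+2θ > 0), logit on (0, 1) for Imax fractions. The default
optimiser is L-BFGS-B with finite-difference gradients (step 1e-3 on the
transformed scale, chosen above the ~1e-3 warm-start OFV noise);
Nelder–Mead followed by BFGS polish is available as `method="nm-bfgs"`.
Quasi-Newton on the smooth transformed objective converges in a few dozen
evaluations, which is what makes the replicated recovery studies
affordable; this is the package's deliberate departure from a
derivative-free default.

Standard errors come from a central finite-difference Hessian of the OFV
(covariance 2H⁻¹) mapped to the natural scale by the delta method. EBEs are
the inner modes at the estimates; shrinkage is 100·(1 − SD(η̂)/ω), with
covariates on parameters above 40% shrinkage routed to direct model testing
during screening.

Bootstrap confidence intervals resample subjects with replacement. Because
subjects are independent, a resample's likelihood is exactly a
frequency-weighted sum of per-subject marginal contributions, so replicates
re-use one estimator with integer weights, warm-started from the point
estimate, and run the inner search at a relaxed tolerance (1e-4) without the
exact refinement stage — percentile intervals are far wider than the
parameter noise this introduces.

## The trial simulator

The generator reproduces the study design: 32 subjects stratified
TT/TC/CC = 15/15/2 on c.521T>C, ages uniform on [8, 20] y (the source gives
only the range; about a sixth of subjects therefore receive the 20 mg adult
dose), sampling at 0, 0.5, 1, 1.5, 2, 3, 4, 6, 8 h, LLOQ 0.5 nM. Weights are
log-normal around an age-proportional paediatric median shifted 1.3-fold
(the cohort was predominantly overweight); heights, sex and the five
non-design SNPs (plausible allele frequencies, CYP3A5*1 rare as in the
cohort) are cosmetic inputs for the covariate-search machinery. Noise is
applied as BSV draws, then the double-exponential residual error on the
noise-free prediction, then censoring of the noisy value. Random streams
are split per subject, so enlarging a design never perturbs earlier
subjects. Pre-dose rows are structurally zero and certainly censored; they
are excluded from the default likelihood dataset (they carry no
information) and can be emitted on request.

What the simulator does not emulate: multiple dosing, dropout, assay
failures, covariate correlations beyond the weight-age link, ethnicity
(30/32 Caucasian in the study, no effect modelled), or any misspecification
of the structural model — passing recovery tests therefore demonstrates
internal consistency of simulator and estimator, not correctness of the
model for real patients.

## Numerical choices

* The linear cascade (depots, SV, SVA, DHSV) is solved in closed form as
  sums of exponentials (numba-compiled); rate-constant collisions are
  nudged apart by 8e-8 relative, far below every downstream tolerance.
* HMSV/HMSVA are integrated by fixed-step RK4 (dt = 0.005 h) on the
  analytic forcing; γ = 0.86 < 1 makes the Hill term non-Lipschitz at
  C = 0, regularised as C^γ → (C+δ)^γ − δ^γ with δ = 1e-12 nM.
* The independent route (`method="ivp"`) integrates the full seven-state
  system with LSODA at rtol 1e-8 / atol 1e-10, with all dose-event
  discontinuities registered as interval breakpoints; both routes agree
  with a brute-force RK4 oracle at 1e-6 relative tolerance in the tests.
* Negative state excursions beyond solver tolerance raise; small negatives
  clip to zero.

## Problem sizes in the test and acceptance suites

Replicated studies are sized to what the checks need rather than to the
original publication scale: the below-limit fraction uses 500 replicate
trials; parameter recovery uses ten 200-subject cohorts (TT/TC/CC
90/90/20) with absorption fixed at truth and five free parameters; the
selection-calibration study uses 150 null replicates of a closed-form
log-linear toy model driven through the same Laplace machinery; bootstrap
coverage uses seven study-sized (32-subject) datasets with 50 resamples;
the acceptance script reports the recovery targets from three cohorts.

## Known limitations and honest disagreements

* Simulating the stated design from the published final model censors
  ~56% of post-dose SVA observations, clearly above the ~40% reported for
  the original data (the acceptance script computes this as target `t4`).
  The typical TT subject's SVA profile peaks near 0.24 nM — below the
  0.5 nM limit — so the discrepancy traces to the published typical values
  plus the TT-reference covariate equations, not to a simulator choice;
  no parameter of the generator was moved to close the gap.
* The genotype coefficient θ562 and the formation ratio CL_LA/V_SVA are
  nearly ridge-coupled when the TT stratum is mostly censored: a lower
  formation ratio with a larger fractional increase fits almost equally
  well. At 200 subjects the spread of θ562 across replicate cohorts
  exceeds the published bootstrap interval width, so the corresponding
  recovery check does not reach its 8-of-10 bar; the same mechanism
  (flat TT information) explains it.
* FOCE-I (used originally) and the Laplace/Gauss-Newton treatment here
  differ in third-decimal OFV terms; original-data objective values are
  not reproducible in any case because the clinical dataset is not
  deposited.
* The kink non-smoothness of the absorption windows means per-subject
  modes near window boundaries are value-converged rather than
  gradient-converged; warm-start path dependence leaves OFV noise of
  order 1e-3, which the outer finite-difference step is sized to tolerate.
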