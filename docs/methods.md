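# Methods

This note records the modelling assumptions, parameter choices and numerical
conventions behind `cypddi`, and what the synthetic-data generators do and do
not emulate.

## In-vitro inhibition analysis

Remaining enzymatic activity is %REA = 100·Aᵢ/A₀, where Aᵢ and A₀ are
metabolite-to-internal-standard peak-area ratios with and without inhibitor.
The inhibition curve is the two-parameter log-logistic
%REA(c) = 100/(1 + (c/IC50)^h) with the top fixed at 100% and bottom at 0%
(the assay normalises to its own control).

Two fitters are provided:

- `fit_ic50` regresses %REA against log10 concentration with free
  (log10 IC50, h), for inputs that only exist as normalised activities.
- `fit_ic50_from_plate` (preferred, used by the pipeline) fits the raw area
  ratios of a whole plate on the natural-log scale with a free control
  plateau A₀: a(c) = A₀/(1 + (c/IC50)^h). Log-scale least squares is the
  maximum-likelihood estimator under the assay's multiplicative log-normal
  error, and treating A₀ as a fitted nuisance propagates control-replicate
  noise into the IC50 confidence interval instead of biasing the curve
  against an exactly-known 100% top. In simulation at the assay's design
  (five half-log concentrations, triplicates, 10% CV) this halves the median
  IC50 error (≈7–8% vs ≈13%) and restores near-nominal 95% CI coverage
  (≈93–96% vs ≈68%) relative to the normalised fixed-top fit.

Confidence intervals come from the t-distribution on the log-IC50 standard
error (delta method for the µM-scale SE). A fit is flagged non-converged when
the optimizer fails or the IC50 falls outside the tested concentration range
by more than 100-fold; non-converged fits are blocked from downstream use.

Because the probe substrates are incubated at concentrations near their Km,
the competitive-inhibition relation reduces to Ki = IC50/2; Ki,u = Ki·fu,inc
with fu,inc = 0.94 (human microsomes). In-vitro potency bands: high
(IC50 < 1 µM), moderate (1–10 µM, boundaries inclusive), low (> 10 µM).

## Static DDI model

R1 = 1 + Imax,u/Ki,u with Imax,u = Cmax·fu. Two conventions existed for
Imax,u (with or without the blood-to-plasma ratio Rb = 6.08); only
Cmax·fu reproduces the full reference R1 panel, so that is the default and
the Rb-multiplied variant is an explicit option. Likewise the unbound plasma
fraction for the static calculation defaults to 0.037 (the value consistent
with the reference panel) while the human distribution table's 0.077 remains
configurable. Cmax = 9.5 µM is the steady-state total concentration of the
500 mg q8h IV regimen.

The basic static AUC-ratio model is

    AUCR = 1 / ( fm/(1 + [I]/Ki) + (1 − fm) ),

the constant-exposure limit of competitive inhibition of a fraction fm of the
victim's clearance: it lies in [1, 1/(1−fm)), is monotone in [I] and fm, and
tends to 1 + [I]/Ki as fm → 1. (An algebraic variant that places the
(1 + [I]/Ki) factor in the numerator of the inhibited fraction circulates in
print; it yields AUCR ≤ 1 for any inhibition and is not meaningful for a pure
inhibitor, so the reciprocal form above is implemented.) The pipeline
evaluates the static model at ([I], Ki) = (Imax,u, Ki,u), consistent with R1.
Near-complete inhibition of an fm = 1 pathway is capped at 1e6 with a
warning.

## Minimal PBPK + SAC disposition model

State is amounts (mg) in (systemic, SAC, eliminated); plasma concentration is
A_sys/V_sys. SAC exchange acts on amounts (kin·A_sys, kout·A_sac); the
apparent SAC volume V_sac only converts the SAC amount to a reported
concentration. Parameters (per kg): Vss 6.359 L/kg, V_sac 3.883 L/kg,
kin 0.0262 h⁻¹, kout 0.01582 h⁻¹ — shared by the dog (10 kg) and human
(73 kg) models.

**Systemic-volume convention.** The distribution input is the steady-state
volume Vss, not V_sys, and the platform that produced the reference
simulations does not document its internal convention. Two are implemented:

- `vss_scaled` (default): V_sys = Vss/(1 + kin/kout), so the apparent
  steady-state volume of the two-compartment system equals the stated Vss.
- `vss_minus_vsac`: V_sys = Vss − V_sac. Used as the template convention for
  parameter estimation, because it makes (V_sac, kin, kout) exactly
  identifiable from plasma data with Vss fixed — mirroring how the SAC
  triplet was originally estimated with Vss held at its predicted value.

Both reproduce the reference dog Cmax at 2 mg/kg within ~4% (the naive
V_sys = Vss choice misses it ~2.6-fold). An explicit V_sys can also be given.

**Dosing and integration.** IV doses default to boluses (state jumps);
zero-order infusion is available. Integration is piecewise between dose
events with LSODA (rtol 1e-10, atol 1e-10 by default; 1e-8 during iterative
fitting and co-simulation, where speed matters). Mass balance
(dosed = Σ amounts + eliminated) holds to ≲1e-9 relative on all simulations
and is asserted at ≤1e-6. The linear system is independently cross-checked
against its matrix-exponential closed form in the tests.

**Elimination.** In-vivo mode uses the observed plasma clearance (dog:
543.5 mL/min at 1–2 mg/kg, 454.7 mL/min at 20 mg/kg; human: 35.5 L/h from
allometry). Microsomal mode scales CLint (µL/min/mg ÷ fu,inc × MPPGL × liver
weight) and converts to plasma clearance with the well-stirred model
(fu,b = fu/Rb; CL_b = Q·fu,b·CLint/(Q + fu,b·CLint); CL_p = CL_b·Rb). The
liver model choice, MPPGL (dog 48, human 40 mg/g), liver weights (320 g,
1800 g) and hepatic blood flows (18.5, 90 L/h) are documented
literature-typical defaults and fully configurable; with them the dog
microsome route predicts ~100 mL/min, qualitatively reproducing the known
several-fold under-prediction of the in-vivo clearance that motivates the
middle-out approach.

**Vss prediction.** The Rodgers–Rowland moderate-to-strong-base equations
predict per-tissue Kpu from fractional tissue water/lipids and the
electrostatic interaction of the ionised base (pKa 6.77) with acidic
phospholipids; the association constant is back-calculated from blood-cell
partitioning. For this compound (logP 5.63, fu 0.037, Rb 1) the neutral-lipid
term alone exceeds the observed blood-cell partition, so the
acidic-phospholipid constant clamps at zero, and the unscaled prediction is
far above the reported 6.359 L/kg — consistent with the reported best-fit Kp
scalar of 0.01, which the package applies as a plain multiplier inside
Vss = V_plasma + Σ kp_scalar·Kp_t·V_t. The predicted and reported Vss are
both surfaced; neither is asserted as the other's consequence.

**Parameter estimation.** Bounded least squares on log concentrations
(trust-region reflective), restarted from a fixed geometric grid over the
bounds plus the template values — deterministic by construction. Standard
errors by the delta method from the log-scale Jacobian. Noise-free recovery
of (V_sac, kin, kout) is exact to <0.01%.

## NCA

AUC(0–t) uses linear-up/log-down trapezoids by default (log interpolation on
declining segments with positive endpoints). λz is the best-adjusted-R²
log-linear suffix of the post-Tmax positive tail (≥3 points, Tmax excluded);
AUC(0–∞) = AUC(0–t) + C_last/λz with the observed last concentration.
CL = dose/AUC(0–∞) with mg and ng·h/mL converting to mL/min via 1e6/60.
Model qualification reports observed/predicted ratios with the conventional
0.5–2-fold acceptance window; the observed dog values ship as reference
constants (the underlying raw IV study is external to this package).

Note the simulated dog terminal half-life is the slow SAC phase (~45 h,
small amplitude), not the ~1.9 h dominant phase the reference table lists;
qualification therefore compares AUC and Cmax, which are
convention-independent.

## Allometric scaling

Single-species rule: CL_hum = b·CL_dog·(BW_hum/BW_dog)^a with a = 0, b = 1
(identical absolute clearance per unit time), converted mL/min → L/h exactly
once (×0.06): 591.7 mL/min → 35.50 L/h. Vss_hum = a·Vss_dog with a = 1 on
the L/kg basis: 6.359 L/kg carries over unchanged. These are the only
interpretations that reproduce both reference human values from the dog
values; general (a, b) remain available.

## Dynamic DDI co-simulation

Perpetrator: human minimal-PBPK + SAC model, 500 mg IV bolus q8h × 8 doses
(60-h protocol), victim dosed at t = 48 h (day 3). The victim is a
one-compartment first-order-absorption model (ka, V/F, CL/F, dose);
the inhibited pathway clearance is modulated instantaneously,
CL(t) = CL·(fm/(1 + I_u(t)/Ki,u) + (1 − fm)), with I_u(t) = fu·C_plasma(t)
interpolated from the perpetrator simulation. fu defaults to the static
convention (0.037) so the static and dynamic routes share one exposure basis.

Victim AUCs integrate over `horizon_half_lives` (default 7) of the *slowest*
effective kinetics — the control half-life divided by the worst-case
clearance factor fm·s_min + (1 − fm), s_min evaluated at the peak unbound
exposure — plus an analytic tail correction C(T)/k_eff(T). Without the
slow-kinetics horizon the inhibited arm is truncated and AUCR badly
under-estimated for strong inhibition; with it, the co-simulation collapses
onto the static model within <0.05% under constant perpetrator exposure, and
never exceeds the static value at the profile's unbound Cmax (competitive
inhibition is monotone in exposure).

The victim library (phenacetin, repaglinide, tolbutamide, S-mephenytoin,
bufuralol, midazolam, nifedipine; fm per the reference DDI table) uses
literature-typical one-compartment oral constants and is deliberately
editable config, not a claim about any proprietary substrate file; dynamic
AUCRs are therefore expected to agree with the reference only in class, not
in digits.

Classification takes the worst case (larger) of static and dynamic AUCR:
none (≤1.25), weak (>1.25 and <2), moderate (2–5, boundary 2 inclusive),
strong (≥5). A worst case ≥1.25 sets a clinical-study-recommended flag.

## Synthetic data generators

Incubation plates: expected %REA follows the generating log-logistic exactly;
each replicate multiplies in mean-one log-normal noise (CV = `noise_cv`) —
positive, right-skewed, the standard bioanalytical error model. The default
concentration grid is 0.01/0.1/1/10/100 µM plus a zero-inhibitor control,
triplicates. Dog PK: C(t) = dose·(A·e^{−αt} + B·e^{−βt}) with the same
multiplicative noise. Seeds are explicit everywhere; no global random state.
Published information on assay replicate variability is thin, so the
noise-CV defaults (10% plates, 15% PK) are package choices.

What the generators do **not** emulate: chromatographic peak integration,
heteroscedastic lower-limit-of-quantification behaviour, inter-occasion or
inter-subject variability, and assay plate effects. Passing recovery tests on
these generators shows estimator correctness under the assumed error model,
not robustness to real-assay pathologies.

## Problem sizes and numerical choices

Simulation studies use 200 seeded plates for IC50 recovery/coverage, 15
seeds for noisy SAC-parameter recovery, and dense (≈450-point) grids over
120 h for dog NCA round trips — sizes chosen so the whole suite runs in well
under a minute while the Monte-Carlo medians are stable. Tie-breaks:
potency-band boundaries (1, 10 µM) are moderate; AUCR boundaries 2 and 5
round up to moderate/strong; R1 flag threshold 1.02 and clinical-study
threshold 1.25 are inclusive. Degenerate inputs (α = β bi-exponentials,
fm = 1 with unbounded exposure, empty λz windows, singular Jacobians) raise
or flag rather than silently producing numbers.

## Known limitations

- Single deterministic subject; no population variability, so dynamic AUCR
  percentile behaviour is out of reach by design.
- No gut-wall interaction term (the perpetrator is intravenous) and no
  time-dependent inhibition or induction.
- The static and dynamic AUCR columns of the reference table are not
  reproducible from the published equations under any single ([I], Ki)
  convention; they are treated as comparison constants, and only the R1 and
  Ki columns are reproduced quantitatively.
- Physiological constants (MPPGL, liver weight, hepatic blood flow, tissue
  composition) are literature-typical, not fitted; absolute microsome-scaled
  clearances inherit their uncertainty.
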