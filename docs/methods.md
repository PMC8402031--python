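# Methods

## Structural model

Ciprofloxacin disposition is described by a one-compartment model with
zero-order input (constant-rate IV infusion) and first-order elimination.
For a single infusion of amount *D* over *T*inf starting at *t*₀, with
elimination rate constant *k*e = CL/Vd and elapsed time τ = *t* − *t*₀:

- during the infusion: C = (R₀/CL)·(1 − e^(−keτ)), R₀ = D/Tinf;
- after the infusion: C = (R₀/CL)·(1 − e^(−ke·Tinf))·e^(−ke·(τ−Tinf)).

Repeated doses superpose linearly. The internal clock starts at the first
infusion; sampling schedules quoted as "h after end of infusion" are
converted by adding the infusion duration (0.5 h). At steady state the 24-h
exposure is AUC24 = daily dose / CL, independent of Vd — which is why the
target-attainment machinery needs only the clearance distribution.

Within a subject, renal function is re-measured on each sampling occasion
and clearance follows it: concentrations in an occasion are computed by
superposing all prior doses with that occasion's clearance. The two
occasions are ~10 half-lives apart, so carry-over from doses evaluated
under the other occasion's clearance is negligible.

## Population model

```
CL(CLcr) = CL_pop + θ_CLcr · (CLcr / 1.25)        (linear covariate law)
CL_i     = CL(CLcr_i) · exp(η_CL,i),  η ~ N(0, ω²)   (likewise Vd, no covariate)
y_ij     = f_ij · (1 + ε_prop,ij) + ε_add,ij
```

The covariate is scaled by a reference CLcr of 1.25 mL/s so that linear and
power laws coincide with the typical-individual parameters at the
reference. Between-subject variability is reported as CV% = 100·ω, i.e. the
SD of the log-normal effect — the convention under which the reference
value ω_CL = 0.449 corresponds to "44.9 %". Between-occasion effects (IOV)
are supported by the simulator but default to zero and are not estimated;
they were not supported by the data this model family was built for.

### Reference estimates

`PopModel.final_estimates()` carries the fitted values used as the
generating truth throughout the simulation studies: CL_pop 5.4 L/h,
θ_CLcr 16.1 L/h per scaled unit, Vd_pop 143 L, ω_CL 0.449, ω_Vd 0.348,
additive residual SD 0.981 mg/L, proportional residual 4.78 %. The additive
component is in mg/L; the "%" sometimes attached to it in summary tables is
a formatting artifact, since 0.981 mg/L reproduces the observed trough
spread while an 0.981 % proportional-like term could not.

## Estimation (nonlinear mixed effects)

The marginal likelihood is approximated by a Laplace expansion around the
per-subject conditional modes η̂ᵢ — the same family as first-order
conditional estimation with interaction (FOCE-I). The reported objective is

OFV = Σᵢ { Σⱼ [ ln g²ᵢⱼ + (yᵢⱼ − fᵢⱼ)²/g²ᵢⱼ ] + η̂ᵢ'Ω⁻¹η̂ᵢ + ln det(Ω Hᵢ/2) }

with g² = σ_add² + (σ_prop·f)² evaluated at the conditional prediction
(the "interaction") and Hᵢ the Gauss–Newton curvature of the conditional
objective, i.e. −2·log marginal likelihood up to the constant n·ln 2π.
No numerical identity with any particular reference implementation is
claimed; correctness is established by parameter-recovery simulation, by
the no-random-effects limit (ω = 0 reduces the fit to nonlinear least
squares, verified against an independent least-squares oracle), and by the
χ²₁ calibration of nested-model OFV differences on null simulations
(observed 95th percentile of the OFV drop ≈ 3.95 vs the nominal 3.84).

Implementation details:

- **Inner problem.** The conditional modes solve a 2-D optimisation per
  subject, done by damped Newton with analytic derivatives of the infusion
  model with respect to the log-scale random effects (∂f/∂η_CL = −f + ke·S,
  ∂f/∂η_Vd = −ke·S, where S = ∂f/∂ke is closed-form). Two equivalent
  implementations exist — a vectorised numpy reference and a numba kernel
  (used when numba imports; agreement ~1e−6 is a test).
- **Outer problem.** Nelder–Mead over transformed parameters: log for
  CL_pop, Vd_pop, ω's and σ's (positivity), raw for covariate coefficients —
  deliberately unconstrained so that likelihood-ratio tests of a null effect
  keep their two-sided χ² behaviour. Multi-start (default 3 jittered starts
  derived from a seed) with best-OFV selection; fits are deterministic given
  data, starting values and seed. Starting values default to the
  individual-analysis scale (CL 18.59, Vd 136.9 L; a linear covariate start
  splits the clearance evenly between intercept and covariate term).
- **ω floor.** SDs of random effects are floored at 1e−6 inside the
  likelihood, which reproduces the ω → 0 limit exactly (penalty drives
  η → 0 and the log-det correction vanishes).
- **Standard errors.** Observed information: central finite-difference
  Hessian of the OFV at the optimum (step 0.05 on the transformed scale,
  sized against the inner-solver noise floor), symmetrised and
  eigenvalue-clipped to positive definite; Cov = 2·H⁻¹. RSE% of log-scale
  parameters is 100·SE on the log scale; clipping marks the information as
  near-singular in the output.
- **Covariate selection.** Forward stepwise inclusion while the best OFV
  drop exceeds 3.84 — the 5 % point of χ²₁. (That threshold is sometimes
  quoted alongside "p < 0.01"; 3.84 is in fact the 5 % point, and the
  threshold is configurable.) Every tested candidate and its ΔOFV is
  recorded in a ledger together with the unexplained CL variability before
  and after inclusion. Selection uses the OFV gate only; precision
  (RSE < 30 %) and plausibility are reported alongside for the analyst, as
  in `analysis/03_population_fit.py`.

## MAP-Bayesian individual estimation

Each patient-occasion is fitted by minimising

J(CL, Vd) = Σⱼ ((yⱼ − fⱼ)/σⱼ)² + Σₚ ((ln p − ln p_prior)/ω_prior,p)²

in log-parameter space from a 5×5 multi-start grid around the prior
(ties broken by objective, then by lower CL). Weights σⱼ =
√((prop·yⱼ)² + add²) are computed from the *observed* concentrations, so the
flat-prior limit is exactly weighted least squares (tested against an
independent least-squares oracle). Defaults are 10 % proportional with a
0.05 mg/L additive floor — appropriate when residual error is assay-limited;
for data whose residual magnitude is known (e.g. the synthetic cohorts), the
weights should be set to match it, as the analysis drivers do. WSS is the
data term at the optimum and RMS = √(WSS/n). The shipped prior
(`data/prior_default.yaml`) uses the cohort-scale central values (CL
18.59 L/h, Vd 136.9 L) with a conservative 50 % CV; users reproducing the
behaviour of TDM software initialised from a literature population must
substitute that prior — no literature values are hard-coded.

With an informative prior and *no* observations the prior mode is returned
(the no-data limit used when initialising therapy); otherwise at least two
observations per occasion are required.

The second stage mirrors classical practice: univariate least-squares
regression for continuous covariates, Mann–Whitney U for categorical ones
(exact enumeration for min(n) ≤ 8 without ties, tie- and
continuity-corrected normal approximation otherwise), CV% = 100·SD/mean of
the weight-normalised parameters, and an early-versus-delayed comparison
that deliberately applies the *unpaired* U test to paired subjects — the
choice made in the original analysis — rather than a paired test.

## Synthetic cohorts: what they emulate, what they do not

The generator reproduces the study design: 30-min infusions of 400 mg q12h,
400 mg q8h or 600 mg q12h (800–1200 mg/day, random mix by default); three
samples per occasion at 1 h, 4 h and trough (7.5 h after a q8h infusion,
11.5 h after q12h) following the end of an infusion; an early occasion after
the second dose (within 36 h) and a delayed occasion after the dose nearest
84 h. Covariates are drawn from log-normal marginals calibrated so the
published medians are reproduced and the published ranges sit at ~95 %
intervals (CLcr early: median 1.16 mL/s, range 0.12–3.32; delayed: 1.36,
0.66–2.49 — the delayed spread is deliberately narrower, matching the
stabilisation of renal function after the first days of ICU care), clipped
at the range bounds. Urine chemistry is back-solved so that measured CLcr =
Ucr·V/Scr holds exactly in the generated records.

Deliberate idealisations — and therefore things that passing tests do *not*
establish about real data:

- **No truncation of the residual tail.** Simulated concentrations follow
  y = f(1+ε_prop) + ε_add exactly, including occasional small negative
  values at troughs, the standard convention when simulating for predictive
  checks. Clipping at zero (`truncate_negative=True`) is available for
  sensitivity analyses: at an additive SD near 1 mg/L it affects ~10 % of
  observations, heaps them at a value a bioanalytical assay would never
  report, inflates the fitted proportional error several-fold and pushes the
  covariate-step type-I rate to ~10 %, precisely because the data then no
  longer follow the likelihood being fitted.
- No LLOQ censoring, no dropout, no missed samples (the real study excluded
  incomplete profiles; here every subject completes both occasions).
- Covariates other than CLcr are marginally realistic but independent of the
  PK; early/delayed CLcr are independent redraws by default (an optional
  log-scale correlation exists but there is no joint distribution to
  calibrate it against).
- No CVVHD clearance mechanics; the flag exists as a covariate only.

## Target attainment and nomogram

Attainment of AUC24/MIC ≥ 125 depends only on clearance:
CLᵢ ≤ dose/(125·MIC). The Monte Carlo engine draws CLᵢ log-normally around
the renal-function-adjusted typical value; the closed-form companion
Φ((ln(dose/(125·MIC)) − ln tvCL)/ω_CL) is exact for that generative model
and is used as the oracle in tests (agreement within 0.5 percentage points
at 10⁵ draws). Only CL variability is simulated: Vd moves the concentration
peaks and troughs but not the steady-state AUC. The MIC grid defaults to
the doubling dilutions 0.0625–1 mg/L.

The nomogram inverts the individual-analysis regression CL = 18.54·CLcr +
3.261 through AUC = dose/CL: MIC_max(CLcr) = dose/(125·(a·CLcr+b)), with
the inverse CLcr_max(MIC); a negative CLcr_max means the target is
unattainable at any renal function. A regimen-success PTA threshold is
configurable with default 100 % — the strictest reading of "successful"
(a literal "PTA > 100 %" is unsatisfiable) — with 90 % as the conventional
alternative.

## Renal-function equations

CKD-EPI uses the 2009 creatinine equation without the race coefficient
(never recorded in the emulated population); MDRD is the 4-variable
IDMS-traceable form; Lund–Malmö is the 2011 revision; Cockcroft–Gault uses
serum creatinine in µmol/L (factor 0.814). Indexed results (mL/min/1.73 m²)
are returned divided by 60 as mL/s per 1.73 m² *without* BSA de-indexing —
consistent with the magnitudes of the cohort summaries — while
Cockcroft–Gault is absolute mL/s. Missing covariates raise a named error
and are never imputed.

## Problem sizes and runtime choices

The simulation studies are sized for routine re-running: parameter recovery
and covariate-selection power use 20 replicate cohorts of 30 subjects × 2
occasions (medians over replicates; the study design itself fixes 6
observations per subject), type-I calibration uses 100 null replicates, the
diagnostics self-checks use 200 simulation replicates (VPC) and K = 200
(NPDE), and the bootstrap examples use 100–200 resamples. These sizes give
Monte Carlo error comfortably inside the tolerances being checked; all are
parameters, not constants.

## Known limitations

- Fixed-effect precision at n = 30 is modest: the intercept/slope split of
  the clearance–CLcr relation is strongly anti-correlated (the typical CL at
  the reference is estimated far more precisely than either component), so
  single-dataset intercepts scatter widely even though medians over
  replicates are unbiased.
- The base (no-covariate) model absorbs the within-subject, between-occasion
  clearance differences driven by changing renal function into the
  proportional residual, which dampens the apparent variability shrinkage
  when the covariate is added; the shrinkage direction holds at the median
  over replicates.
- MAP estimates from 3-point occasions with ~1 mg/L additive error are
  substantially shrunk toward the prior; the two-stage regression slope is
  attenuated accordingly (its significance survives, its magnitude does
  not). This is a property of sparse TDM data, reproduced rather than
  hidden.
- No censoring likelihood, no η covariance, no estimated IOV, no
  two-compartment alternative — the distribution phase is not identifiable
  from sampling that starts 1 h after the infusion ends.
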