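# Methods

## The model

`remipk` implements a population pharmacokinetic analysis of remifentanil
given by continuous intravenous infusion to adults on venoarterial ECMO.
The structural model is a single compartment with zero-order input and
first-order elimination.  For an infusion segment of rate R (mg/h) active on
[t0, t1], clearance CL (L/h), volume V (L) and k = CL/V, the closed-form
contribution to the plasma concentration is

    C(t) = 1000 (R/CL) (1 - e^{-k (min(t,t1)-t0)}) e^{-k max(0, t-t1)}   [ng/mL]

and profiles superpose over segments.  The units contract is fixed globally:
rates mg/h, volumes L, clearances L/h, time h, concentrations ng/mL, with the
conversion factor exactly 1000 (mg/L to ng/mL).

Typical clearance is a product of a reference value and multiplicative
covariate factors.  The shipped `final_2017` preset is

    CL (L/h) = 366 x 0.502^sex x (pump/2350)^2.04,   V = 41 L

(female = 0, male = 1; pump speed in RPM).  Between-subject variability is
log-normal on CL only (CL_i = TVCL_i e^{eta_i}, eta ~ N(0, omega^2));
volume carries no random effect.  The residual model is combined:
y = f (1 + eps_p) + eps_a with independent zero-mean normal errors.

**A convention decision**: the published random-effect table lists
`omega_CL 0.124` and `sigma_proportional 0.387` / `sigma_additive
0.111 ng/mL` without stating whether entries are SDs or variances.  Following
the NONMEM convention that OMEGA is reported as a variance and the residual
entries as SDs, `omega2_cl = 0.124` (SD 0.352) and the sigmas are SDs.  The
choice is isolated in `structural.random_effect_sd` and the
`PopulationModel` field semantics, so it is changeable in one place.

## Estimation (FOCE-I)

With a single random effect the subject marginal likelihood is a 1-D
integral.  Writing l(eta) for a subject's joint -2 log density (observations
plus prior, residual variance evaluated at the *individual* prediction — the
"interaction"), the objective is the Laplace expansion about the conditional
mode:

    -2 log L_i ~= l(eta_hat) + log l''(eta_hat) - log(4 pi),

summed over subjects.  This is exact when the model is linear in eta with
additive Gaussian error, and on small instances it agrees with a 64-node
adaptive Gauss–Hermite quadrature of the same integral (shipped as
`foce.agq_objective`, used as an independent oracle in the tests) to well
under 0.1 OFV units.

Numerical choices:

- **Inner problem.** Safeguarded Newton on eta per subject, vectorised
  across subjects: analytic first derivative (the concentration gradient in
  CL is closed-form), Gauss–Newton curvature for the step (always positive),
  backtracking on the joint density, convergence at |l'| < 1e-8 (1 + |l|),
  and a bounded scalar search fallback for stragglers.  The curvature used
  in the Laplace term is a central finite difference of the analytic
  gradient, falling back to Gauss–Newton when non-positive.
- **Outer problem.** L-BFGS-B with numerical gradients on transformed
  parameters: positive parameters (typical values, variance components,
  power-form categorical coefficients) on the log scale, power exponents and
  signed coefficients untransformed.  Tolerances `ftol=1e-9`, `gtol=1e-5`.
  Conditional modes are warm-started between objective evaluations.  The
  fit is deterministic: identical inits give bit-identical results.
- **omega^2 -> 0.** Below 1e-12 the degenerate limit is used: the
  fixed-effects -2 log-likelihood at eta = 0 (the analytic limit of the
  Laplace expression, verified by a continuity test).
- **BLQ.** Observations below the assay LLOQ (0.05 ng/mL) are flagged in
  datasets and excluded from the likelihood (the M1 policy).  Subjects left
  without usable observations are a packing error.
- **Standard errors.** Central-difference Hessian of the OFV on the natural
  scale (relative step 1e-3); covariance 2 H^{-1}; RSE% = 100 SE/|estimate|.
  A non-positive-definite Hessian yields a warning and no SEs.
- **CWRES.** FOCE linearisation about the conditional mode: per subject,
  mean f(eta_hat) - G eta_hat and covariance diag(var at IPRED) +
  omega^2 G G', decorrelated by the inverse matrix square root.  Under the
  true model the suite checks mean within 0.1 of 0 and variance within 0.15
  of 1.  Note that with proportional error the conditional mode of a
  perfectly predicted subject is *not* zero — the log-variance term rewards
  higher clearance; this interaction effect is asserted in the tests rather
  than suppressed.

## Covariate selection

Continuous covariates are centred at the dataset median and may enter
through power, exponential or linear forms; categorical (0/1) covariates
through power, exponential or proportional forms.  Selection is greedy
forward inclusion: every remaining (candidate, form) pair is refit from the
current optimum (coefficient initialised at its null value, which also makes
the nested-model ΔOFV non-negative by construction), the largest OFV drop
exceeding 3.84 (chi-square(1), 95%) enters, ties broken lexicographically by
covariate then form, and the search stops when nothing is significant.
Backward elimination is out of scope.  Candidate fit failures are recorded
in the trace and skipped.

## Validation

- **Bootstrap.** Plain (unstratified) subject resampling to the original
  subject count, refit per replicate from the point estimates, percentile
  summaries (median, 2.5–97.5) over converged replicates, with the
  non-converged count reported.  5000 replicates is the publication-fidelity
  setting; tests use tens.
- **pcVPC.** Replicate datasets are simulated on the original design (same
  subjects, times, doses, covariates; fresh etas and residuals), both
  observed and simulated values are scaled by bin-median population
  prediction (pcY = Y · med(PRED)/PRED), simulated values below the LLOQ are
  censored the way observed BLQ values are, and observed 2.5/50/97.5
  percentile curves are compared with the 95% interval of the simulated
  percentiles per bin.  Default bins follow the design windows ([0,12],
  (12,30], (30,48] h, plus one post-discontinuation bin); quantile binning
  is available by passing an integer.  One caution: the simulated band
  estimates a *fixed* interval, so it does not narrow as `n_sim` grows —
  only the Monte-Carlo error of its edges does, which is what the suite
  asserts.

## Dosing simulation

Steady state under constant infusion is Css = 1000 R / CL; simulation uses
the concentration at the end of a 48-h infusion, which exceeds 99.9% of the
plateau for every parameter draw (half-lives are minutes).  With log-normal
between-subject variability the attainment fraction has the closed form
Phi(ln(Css_typ/C*) / omega), which the Monte Carlo route (n = 5000 per cell
by default) reproduces within 0.02.  Attainment is judged on true individual
concentrations (no residual error) by default; a flag adds residual noise.
The minimum-rate recommendation at coverage 0.5 reduces to the
typical-subject criterion Css_typ >= target because the log-normal median is
the typical value.  At the cohort-median pump speed (2350 RPM) and a 1.5
ng/mL sedation target the grid yields 0.63 mg/h (female) and 0.42 mg/h
(male).  At other pump speeds the package reports its own attainment tables
computed from the typical-value model; these need not coincide with every
published per-band dose bullet, which could not be reproduced exactly from
the printed model at the upper speeds.

## Synthetic data

The generator emulates the study: 15 subjects by default; constant-rate
open-ended infusion with rates resampled from the published individual
table; sparse samples at T1 ~ U(8,12) h, T2 = 24 h, T3 ~ U(36,48) h; an
optional post-discontinuation series at 5/10/15/25/30/40 min after the
infusion stops (off by default, on for two subjects in the paper-like
convenience study, giving ~55–57 observations); log-normal IIV on CL;
combined residual error; LLOQ censoring at 0.05 ng/mL with flags.

Covariates: age, weight, BMI and total protein are resampled with
replacement, column-wise, from the 15 published individual values — faithful
to the only individual-level data in print, at the cost of losing
between-covariate correlation.  Sex is Bernoulli(0.67) (the published male
fraction) and CRRT Bernoulli(9/15) (the individual table lists nine
recipients; the running text says ten — the table wins for the fixture).
Pump speed, published only as median 2350 RPM with IQR (2302, 2532), is
log-normal calibrated to those two summaries (sigma ~= 0.071).  ECMO flow,
creatinine and temperature were not tabulated per patient; they are drawn
from plausible ICU distributions and are synthetic stand-ins.

The rich design used for estimation experiments places four of its eight
samples in the onset phase (0.05–0.6 h): with elimination half-lives of
3–10 minutes, volume is structurally unidentifiable from steady-state-only
samples, so a "spread over 0–48 h" schedule must include early points.

What the generator does **not** emulate: circuit adsorption or CRRT drug
removal kinetics, within-subject covariate evolution (pump-speed changes
over days), correlated covariates, or clinician-driven dose titration.
Passing tests therefore demonstrate statistical correctness of the machinery
under the stated model, not clinical validity on real ECMO data.

## Cohort summaries

Quantiles use Hyndman–Fan type-6 (the SPSS (n+1)p rule): for this cohort of
15 it reproduces every published median *and* IQR exactly (type-7 does not —
e.g. it puts the age lower quartile at 46 instead of the published 45).

## Problem sizes and known limitations

Replication-based checks run at sizes chosen to keep a full run in minutes:
parameter recovery at 200 subjects (single experiment) and 80 subjects
(bias over 6 replicates); null calibration of the covariate rule at 200
replicates of 15 subjects; bootstrap checks at 60 resamples of 25 subjects;
pcVPC bands from 150–800 simulations in tests and 1000 by default in the
CLI.

The ΔOFV > 3.84 inclusion rule is anticonservative at this study's size:
over 200 null replicates of 15 sparsely sampled subjects the empirical
type-I error is ~0.09–0.11, not 0.05.  Probes show this is not an artifact
of the Laplace approximation (exact-quadrature deltas agree) nor of the
optimiser (polishing changes nothing): fixing the variance components at
truth brings the rate to ~0.067, implicating maximum-likelihood (non-REML)
variance estimation plus the small denominator degrees of freedom.  The
rate falls toward nominal (~0.075) at 50 subjects with rich sampling.
Users applying the rule to cohorts of this size should expect its true
significance level to be nearer 0.1 than 0.05.

The published real-data quantities that require the undeposited 55
concentrations (the exact parameter estimates, their OFVs, and the
goodness-of-fit correlations) are not reproducible and are not claimed;
simulation-based recovery of the published model is the supported check.
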