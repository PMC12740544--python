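# Methods

## Kinetic model

Kidney activity after injection of a 177Lu-labelled radiopharmaceutical is
described as a fraction of the injected activity by a six-parameter sum of
exponentials constrained to zero at the time of injection:

    f(t) = A1 e^{-(λ1+λph)t} + A2 e^{-(λ2+λph)t} − A3 e^{-(λ3+λph)t}
           − (A1+A2−A3) e^{-(λbc+λph)t}

* `A1..A3` (dimensionless) and `λ1..λ3` (1/h) are the biological
  prefactors and uptake/clearance rates, all constrained positive (the
  fit works on the log scale, so positivity holds by construction);
* `λph = ln 2 / 159.4632 h ≈ 4.347e-3 /h` is the physical decay constant
  of 177Lu (half-life 6.6443 d) and `λbc = ln 2 × 60 ≈ 41.59 /h` the fast
  blood-circulation uptake rate (half-life 1 min); both are fixed
  constants, never estimated, though configurable for other nuclides;
* the tied fourth prefactor `A1+A2−A3` makes `f(0) = 0` exactly.  Its
  sign is not constrained; a negative value is flagged with a warning but
  accepted, since only the six named parameters carry a positivity
  requirement.

The time-integrated activity (TIA, units: fraction of injected activity ×
hours) is the closed-form integral of `f` over `[0, ∞)`:

    TIA = A1/(λ1+λph) + A2/(λ2+λph) − A3/(λ3+λph) − (A1+A2−A3)/(λbc+λph)

TIA uncertainty is propagated from a 6×6 parameter covariance matrix `C`
by the delta method, `SD = sqrt(gᵀ C g)`, with the *analytic* gradient `g`
of the integral (validated against central finite differences in the
tests); an analytic gradient avoids finite-difference step-size fragility
across the four decades the rates span.

## Population model

Inter-individual variability is log-normal: subject parameters are
`p_j = θ_j exp(η_j)` with `η ~ N(0, diag(Ω))`.  The distribution is a
modelling choice — it enforces positivity and is the convention in
population pharmacokinetics.  `Ω` is diagonal (six variances, no
correlations), which matches the parameter count of six random effects.

The residual error is proportional by default:
`y = f(t)(1 + ε)`, `ε ~ N(0, σ²)`, motivated by the percent-scale
character of SPECT quantification noise.  Additive and combined variants
are implemented behind the `error_model` tag for sensitivity analyses.  A
prediction floor `f_min = 1e-9` keeps the proportional variance bounded
away from zero; observations in the floored region contribute with the
floor variance and a logged warning.

Altogether the model exposes 13 estimated quantities: 6 fixed effects, 6
IIV variances, 1 residual SD.  `fit_population` refuses datasets with
fewer than 14 observations (estimated parameters + 1).

## Estimation

Each subject's marginal likelihood is approximated with the Laplacian
conditional method.  Writing `Q(η)` for the joint −2 log-likelihood
(observations given `η`, plus the `η` prior), the marginal contribution is

    −2 log Lᵢ ≈ Q(η̂) − d·log 2π + log det(H/2),

where `η̂` minimises `Q` and `H = ∇²Q(η̂)` (so `H/2` is the Hessian of the
negative log joint density).  The inner minimisation is a damped Newton
iteration with *analytic* gradient and Hessian of `Q` (the sum-of-
exponentials second derivatives are closed-form), Levenberg damping when
the Hessian is indefinite, Armijo backtracking, and a clamp `|η| ≤ 60`
so directions the data do not inform cannot drift to overflow.
Convergence is declared at a value-scaled gradient norm below 1e-9·(1+|Q|).
The approximation is exact for models linear in `η` with additive Gaussian
error — asserted against the closed-form Gaussian marginal — and collapses
to the η=0 conditional likelihood as `Ω → 0` (the prior normalisation
cancels against the Laplace determinant).

The population objective (OFV = Σᵢ −2 log Lᵢ) is minimised over
`(log θ, log Ω, log σ)` with L-BFGS-B using finite-difference gradients
(step 1e-6 on the log scale).  Two implementation points matter in
practice:

* **Equal-length stacking.**  When every subject has the same number of
  observations the inner Newton runs vectorised over the whole cohort;
  tests assert bit-level agreement (to 1e-9 relative) with the
  subject-by-subject reference path.  Conditional modes are cached between
  objective evaluations as warm starts.
* **Restarted optimisation.**  With finite-difference gradients L-BFGS-B
  can terminate early on its relative-reduction test; each start is
  therefore re-launched from its terminus until the OFV stops improving
  (at most 8 rounds).  Multi-start: start 0 is a curve-peeling initial
  guess (log-linear fit to the decay-corrected late phase for `A1, λ1`;
  the peeled early residual for `A2, λ2`; `A3 = 0.8(A1+A2)`, `λ3 = 2/h`
  since the fast phase is over before the first sample), and the
  remaining starts jitter it log-uniformly within ±1 decade, seeded.  The
  best final OFV wins; equal OFVs resolve to the lowest start index.

The model is invariant under exchanging components 1 and 2; fits are
reported in the canonical order `λ1 ≤ λ2`.

The covariance of the 13 estimates is the inverse of a central
finite-difference Hessian of half the OFV (step 1e-4 on the log scale),
mapped to the natural scale by the delta method.  It is optional
(`compute_cov`) because the workflow's TIA uncertainties use the
individual-level covariance, not the population one.

Individual (empirical-Bayes) estimates hold the population model fixed
and reuse the inner Newton on an arbitrary subset of a subject's
sessions; the prior makes the problem well-posed even with a single
observation.  The posterior covariance of `η` is `2H⁻¹`, mapped through
the Jacobian of the log-normal map (`∂p/∂η = diag(p)`) to give the 6×6
parameter covariance that feeds the delta-method TIA SD.

## Evaluation protocol

* **Reference (rTIA).**  One population fit of the full cohort with all
  sessions; each subject's empirical-Bayes parameters give rTIA, SD and
  CV.  The evaluated subject is part of this fit, which is what the
  all-session reference is defined to be.  Subjects missing sessions stay
  in the fit but enter the reference table only with ≥ 4 sessions (with a
  warning).
* **Few-time-point (eTIA).**  For every proper subset of the five
  sessions: leave-one-out estimation.  The population model is refitted
  on the other N−1 subjects' all-session data — cached, so at most N
  training fits happen no matter how many subsets are evaluated — and the
  left-out subject is estimated from the subset's samples only, with the
  training model as a fixed prior (no population re-estimation with the
  subset appended; this keeps the single-session case well-posed).
  Training fits are initialised from the fold's *own* peeling heuristic,
  never from the full-cohort fit, so the left-out subject cannot touch
  its own prior even through a warm start; this makes the leakage
  guarantee exact and testable to the bit.  An alternative reading in
  which the full-cohort fit serves as everyone's prior is available as
  `jackknife="include"`.
* **No-time-point surrogates.**  NTPme/NTPmd assign the componentwise
  mean/median of the reference individual parameters — hence one common
  eTIA — to every subject.  Their reported SD propagates the cohort
  spread of the individual parameters through the TIA gradient, a
  descriptive rather than inferential uncertainty.
* **Best subset.**  Per subset size, lowest RMSE wins; if the MAPE
  minimiser differs, a disagreement flag is set and RMSE still decides.
  Ties break to the lexicographically smallest name.

## Accuracy and precision statistics

Per subject `m` and method `k`: `RD = (eTIA − rTIA)/rTIA`, with
first-order SD treating eTIA and rTIA as uncorrelated (they share data in
truth; the correlation is neglected as a first-order simplification).
Cohort summaries:

* `RMSE = sqrt(SD(RD)² + mean(RD)²)` with the N-denominator SD, which
  makes it identically `sqrt(mean(RD²))` — the estimator matching the
  quantity's name; at N ≥ 20 the N−1 difference is below 1%.
* `MAPE = (100/N) Σ |RD|` (percent).
* SDs of RMSE and MAPE by the delta method from the per-subject RD SDs;
  the RMSE gradient `rd_m/(N·RMSE)` is replaced by its `1/√N` bound when
  RMSE = 0, and the MAPE derivative treats `sign(rd_m)` as locally
  constant (magnitude 1 at `rd_m = 0`).  The RMSE propagation is checked
  against a Monte-Carlo oracle in the tests.
* RD10/RD20: counts of subjects with `|RD|` strictly above 10% / 20%.
* Precision: `CV = SD(TIA)/TIA` per subject, summarised as mean (SD) and
  median [min, max] per method.
* Ordinary least squares of eTIA on rTIA with a two-sided t-test of the
  slope; p < 0.05 is called significant.

RD, RMSE and CV are stored as fractions and rendered as one-decimal
percentages in the report tables; MAPE is a percentage throughout.

## Synthetic cohorts

The generator emulates the study conditions the estimator assumes:

* five imaging sessions at nominal (1.8, 18.7, 42.6, 66.3, 160.3) h with
  truncated-normal jitter SDs (0.8, 0.9, 1.0, 0.9, 24.2) h, clipped to
  the observed span [0.69, 235.66] h, re-sorted, and redrawn when two
  sessions fall within 0.1 h;
* log-normal individual parameters around typical values
  `θ = (A1=0.02, A2=0.01, A3=0.025, λ1=0.005, λ2=0.05, λ3=2.0)` with
  variances `Ω = 0.09` (≈30% CV) — invented plumbing chosen for
  qualitative plausibility (percent-range kidney uptake decaying over
  days) and identifiability at the clinical schedule, not estimates from
  any patient cohort;
* proportional noise `σ = 0.10`, inflated ×1.5 at the last session so
  late-session SDs reach the 15% scale typical of low-count SPECT;
  negative draws are clipped to zero and counted (none occur at the
  default noise).

All randomness flows from one seed through named substreams (schedule,
parameters, noise), so changing the noise level cannot perturb the
schedule draw.

What the generator does *not* emulate: image formation and reconstruction
(attenuation, scatter, partial volume enter only as an aggregate
proportional SD), calibration-factor drift, correlated intra-subject
errors, missing sessions, or model misspecification — the data really
come from the fitted family.  Passing recovery and ordering tests
therefore demonstrates internal consistency of the estimation machinery
under the stated noise model, not performance on real patient data.

## Problem sizes and defaults

The recovery analyses use the full design (63 subjects × 5 sessions =
315 observations, `n_starts = 3`).  The jackknife evaluation — N + 1
population fits plus 32 estimation passes — uses a 20-subject cohort,
chosen so the complete protocol runs in a few minutes on one core while
every qualitative ordering (RMSE and CV falling with the number of
sessions; no-imaging surrogates far worse than any imaging schedule)
remains stable.  Key defaults: `n_starts = 10` (3 in the scripted
analyses), inner gradient tolerance 1e-9 (value-scaled), outer FD step
1e-6, covariance step 1e-4, prediction floor 1e-9.

## Known limitations

* Accuracy is measured against the model-based all-session reference, not
  against ground truth doses; absorbed dose (Gy) is out of scope.
* The eTIA/rTIA correlation is ignored in the RD uncertainty.
* `A3` and `λ3` are weakly identified at clinical sampling times (the
  fast phase ends before the first scan); their recovery is not asserted,
  and their IIV variances can drift toward vague values without degrading
  the TIAs, which they barely influence.
* The Laplace approximation is second-order; no SAEM or adaptive
  quadrature alternative is provided.
* NTP surrogate SDs describe cohort spread, not estimation uncertainty.
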