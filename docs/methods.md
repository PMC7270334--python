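# Methods

`dosecontrol` designs discrete oral-dose schedules by optimal control over
patient-specific pharmacokinetic (PK) and pharmacodynamic (PD) models. This
note records the models, the numerical choices, and the design decisions
that were genuinely open, together with what the synthetic-data studies do
and do not demonstrate.

## Pharmacokinetics

The forward model is a one-compartment oral-absorption (Bateman) system: a
gastro-intestinal depot with first-order absorption rate `ka` (1/h) feeding
a blood compartment of volume `v` (L) cleared at rate `CL` (L/h), with
bioavailability `f`. For a dose `D` at time `t_i`,

    C(t) = f·D·ka / (v·(ka − ke)) · (e^{−ke(t−t_i)} − e^{−ka(t−t_i)}),
    ke = CL/v,

and multi-dose profiles are sums of such terms (the system is linear). The
closed form — not a numerical integrator — is the production path: it is
exact, and cheap enough to be called thousands of times inside the
optimizer. A high-accuracy ODE integration exists only as an independent
oracle in the tests (agreement ≤ 1e−6 relative on 14-day multi-dose
profiles). The degenerate case `ka = ke` uses the analytic limit
`f·D·ka/v · (t−t_i)·e^{−ka(t−t_i)}` rather than erroring; it is triggered by
a relative gap below 1e−10.

Patient covariates enter through

    CL = θa + θ1·(BW−BW̄)/BW̄ + θ2·q − θ2·(1−q) + θ3·(AGE−AGE̅)/AGE̅
    v  = θb + θ4·q − θ4·(1−q)        (q = 1 male, 0 female).

The bundled coefficient file (`data/pk_constants.json`) carries
representative values anchored to the published population-PK literature
for imatinib (typical CL 14.3 L/h, v 347 L, ka 0.61 /h, f 1.0) with
plausible covariate effect sizes; it documents its own provenance and every
value can be overridden through a user-supplied JSON file, so the engine is
parameter-agnostic. Missing body weights are imputed from a bundled
piecewise-constant age×sex table of adult population means (no
interpolation, for reproducibility; out-of-range ages clamp with a logged
warning).

Time units are hours and mg/L throughout the PK layer; day-denominated
quantities convert at the module boundary (`units.py`). AUC and the
target-distance cost integrals are computed from the analytic
antiderivative of the closed form — segment boundaries at threshold
crossings are bracketed on a 1-minute grid and refined by inverse linear
interpolation, after which each constant-sign segment integrates exactly.
The fraction of time above a target is deliberately a grid quantity
(1-minute default): it is reported to users exactly as measured.

## Tumor dynamics and fitting

Leukemic cells are split into cancer stem cells (CSC) `l1` and
differentiated cells `l2`:

    dl1/dt = λ·l1,              λ = (2a1 − 1)·p1 − d1
    dl2/dt = γ·l1 + τ·l2,       γ = 2(1 − a1)·p1,  τ = −d2

with closed-form solution `l1(t) = l1(0)e^{λt}` and
`l2(t) = l2(0)e^{τt} + γ·l1(0)·(e^{λt} − e^{τt})/(λ − τ)` (with the
`t·e^{λt}` limit when `λ = τ`). Defaults `a1 = 0.87`, `p1 = 0.45`/day are
literature stem-cell estimates and overridable.

BCR-ABL burden series under effective therapy decay biphasically in log10
scale. `fit_biphasic` scans every integer-day breakpoint leaving at least
two points per side, fits two independent lines by least squares (four free
parameters; a continuity-constrained variant is available), and keeps the
split with the highest pooled R² (pooled residuals over both segments — the
per-segment-averaged alternative is not used). When several splits tie —
guaranteed for noiseless data, since any split day inside a sampling gap
partitions the points identically — the reported breakpoint is the one
nearest the fitted lines' intersection, and the intersection itself when it
falls inside the tied gap; this recovers a generating breakpoint exactly
from noiseless data, while with noise ties essentially never occur. One-
and three-segment fits are available behind a segment-count selector using
adjusted R²; the three-segment double scan coarsens the candidate grid to
at most 100 days per breakpoint to stay tractable.

Only the rightmost slope β feeds estimation: it is read as pure CSC decay
against a recovered, constant healthy pool, giving

    d1 = (2a1 − 1)·p1 − β / log10(e).

The leftmost slope entangles differentiated-cell clearance with healthy
recovery and is reported but never used. Ratios above 1 on the
international scale are not clipped before the log transform.

## Pharmacodynamics

Effect follows the Emax curve `E(C) = Emax·C^n/(EC50^n + C^n)`. The
cohort-level link between effect and CSC kill is linear, `⟨d1⟩ = K⟨E⟩`. K
is estimated by pairing each patient's 40-day time-average concentration
under standard 400 mg/day therapy (window length configurable) with their
fitted `d1`, using a single benchmark PD curve (`Emax = 1`, `n = 1`,
`EC50 = 0.123` mg/L) for everyone; its confidence half-width propagates the
per-patient `d1` standard errors linearly, treating patients as
independent. Patient-specific EC50 then follows by exact inversion:

    EC50_j = C̄_j · (K·Emax/d1_j − 1)^{1/n},

with `Emax = 1`, `n = 1` fixed during estimation (overridable). The
inversion requires `0 < d1 < K·Emax`; violations raise an estimation error
rather than returning a clipped value.

## The control problem

The control variable is a dose-rate function `D(t)` (mg/h) over the horizon.
The reference `D0(t)` is the standard regimen expressed as a constant rate
(400 mg/day ÷ 24 h), the only form compatible with recovering the standard
doses by interval integration. The optimizer searches a correction expanded
in `n_c` randomized Fourier modes, `ω_k = 2π(k + r_k)/T` with
`r_k ~ U[−0.5, 0.5]`, under a fixed envelope `Γ(t)` that vanishes at both
horizon ends. Negative total rates clamp to zero.

Schedules are scored, not rate functions: candidate rates are integrated
over uniform dose intervals (composite 32-point Gauss–Legendre panels),
rounded to integer mg, clamped to the per-dose cap (default 800 mg/day
scaled by the dose interval), and only then run through the concentration
model and the cost. Optimizing the prescribable object avoids converging to
an unreachable continuous solution; the pre-rounding interval integrals are
kept so dose-mass conservation is checkable to 1e−9.

Each frequency gets one "super-iteration": a Nelder–Mead direct search over
its `(A_k, B_k)` pair (budget 200 evaluations, initial simplex edge 10% of
the reference rate) with earlier pairs frozen at their accepted optima. A
candidate is accepted only if it improves the best cost seen, so the trace
is non-increasing by construction, and the whole run is deterministic given
the seed. Defaults are `n_c = 8` super-iterations; all budgets are exposed
in `OptimizerConfig`. An optional mode also perturbs dose times (kept
sorted) by the same direct search; it is off by default.

**Envelope choice.** The envelope is config-selectable between a flat-top
trapezoid (cosine ramps over 5% of the horizon at each end — the default)
and a half-sine. The default is deliberate: over a 14-day horizon a
half-sine is ≈0.11 at mid-day-1, i.e. it suppresses the correction exactly
where a therapy-initiation problem needs authority, since the only
persistent deficit of the standard regimen against a concentration floor is
the ramp-in over the first days. The trapezoid keeps the boundary values
untouched while leaving the optimizer full authority one ramp-width into
the horizon.

Three cost functionals:

* `optimal_target`: ∫|C(t) − C_tg| dt — hit a target concentration
  (default 1 mg/L for imatinib) with no preference for overshoot vs
  undershoot;
* `lower_bound`: |C − C_tg| where C ≥ C_tg and a flat `G` where C < C_tg
  (default floor 0.57 mg/L; `G` defaults to 10·C_tg so sub-floor time
  dominates any realistic distance term);
* `burden_auc`: ∫ dt_days [W1·log10(e)·((2a1−1)p1 − K·E(C(t))) + W2·C(t)] —
  the instantaneous CSC log-slope plus an exposure penalty, integrated in
  days. Using the growth rate rather than the cell count avoids needing the
  unobservable initial CSC number. The ratio φ = W1/W2 sets aggressiveness;
  defaults φ = 60 (male) and 75 (female), with `phi_scan` producing the
  AUC/efficacy table that motivates such choices for any cohort. With the
  bundled PK constants, φ ≈ 68 makes the cost's preferred exposure match
  the standard regimen's, below that the optimizer shaves exposure, above
  it trades extra drug for faster predicted decay.

The burden integrand is nonlinear in C, so it is integrated by composite
Gauss–Legendre between dose times (smooth panels) rather than analytically.

## Robustness studies

Both studies hold the optimized schedule fixed. Intra-patient variability
perturbs one PK parameter (`ka`, `CL` or `v`) multiplicatively by
`1 + u`, `u ~ U[−σ, σ]`, independently at every evaluation grid point — the
temporal correlation of physiological noise is not identified by the data,
and independent draws are the conservative, documented choice (relative
rather than absolute perturbation, since σ is a fraction). The cost is then
recomputed per replicate (default 700; the test suite uses 100) on the same
grid code path as the unperturbed reference, so ΔL/L0 is exactly zero at
σ = 0. The mean trend over the default grid σ ∈ {0.05…0.30} is fitted with
`b + a·σ²`; first-order terms average out, leaving a quadratic response.
The systematic-error study re-scores the schedule under a constant
parameter bias across a grid of relative errors; it is deterministic.

## Synthetic data

The cohort generator draws demographics from truncated normals (defaults:
22 patients, 18/22 male, age 50 ± 15 y, body weight 85 ± 12 kg male /
72 ± 12 kg female) — the shape, not a reconstruction, of published CML
monitoring cohorts. Burden series follow the two-line log10 model
(defaults: slopes −0.01 and −0.001 /day, breakpoint day 300, initial ratio
1.0) sampled every 90 days over 2700 days with additive Gaussian log10
noise (default SD 0.15; the fit-recovery study uses 0.2). The noiseless
curve is continuous at the breakpoint.

What passing synthetic tests show: the estimation path is consistent (it
recovers what generated the data), the closed forms equal their ODEs, the
optimizer is deterministic, monotone and respects its constraints, and the
optimized schedules are robust to PK error *of the modeled kind*. What they
do not show: that real BCR-ABL series are two-line with i.i.d. Gaussian
log-noise (real assay noise is heteroscedastic near the detection limit),
that the linear effect-to-kill link holds across a real cohort, or that the
bundled covariate coefficients match any particular population — for real
use those must be supplied from a fitted population-PK model.

## Numerical notes and limitations

* Threshold-crossing detection assumes the concentration does not cross a
  target twice within one grid minute; with hourly PK time constants this
  is safe by orders of magnitude.
* A concentration starting at zero can never satisfy a positive floor from
  `t = 0`: with an 800 mg first dose and ka = 0.61/h the first ~30–60 min
  of therapy are necessarily sub-floor, bounding time-above-target at
  ≈99.8% of a 14-day horizon. Reported coverage is therefore the honest
  grid measure, which rounds to 100%.
* Problem sizes in the shipped studies (14-day horizons, 1–3 doses/day,
  8 super-iterations × 200 evaluations, 100-replicate noise studies) keep a
  full optimization under ~10 s; they are the package's default study
  conditions, and all are configurable upward.
* The optimizer is heuristic: it returns the best schedule found, with no
  global-optimality claim (deliberately — the search-space structure with
  integer doses makes gradient methods unattractive).
* Out of scope: multi-compartment or nonlinear PK, resistant-subclone
  dynamics, closed-loop (feedback) control, and any remote optimization
  service; the optimizer here is entirely local.
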