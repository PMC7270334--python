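# dosecontrol

Optimal-control design of personalized drug-dosing schedules from
patient-specific pharmacokinetic (PK) and pharmacodynamic (PD) models,
built around oral imatinib therapy of chronic myeloid leukemia (CML).

Standard regimens prescribe one dose for an "average" patient, but
clearance and volume of distribution vary with age, sex and body weight —
the same 400 mg/day leaves some patients under the therapeutic floor and
others needlessly over it. `dosecontrol`:

* builds per-patient PK models from demographics,
  `CL = θa + θ1·(BW−BW̄)/BW̄ + θ2·q − θ2·(1−q) + θ3·(AGE−AGE̅)/AGE̅` and
  `v = θb + θ4·q − θ4·(1−q)`, with closed-form (Bateman) multi-dose
  concentration curves `C(t)`;
* fits biphasic BCR-ABL tumor-burden series (two intersecting lines in
  log10 scale, breakpoint found by a 1-day scan) and converts the
  rightmost slope β into a cancer-stem-cell death rate
  `d1 = (2a1−1)p1 − β/log10(e)`, from which a cohort conversion constant
  `K = ⟨d1⟩/⟨E⟩` and patient-specific Emax parameters
  `EC50 = C̄·(K·Emax/d1 − 1)^{1/n}` follow;
* optimizes discrete, integer-mg dose schedules by a chopped-random-basis
  method: a randomized truncated Fourier correction to the standard
  dose-rate, one frequency per Nelder–Mead "super-iteration", scored
  through the full discretize → concentration → cost pipeline under three
  cost functionals (distance to an optimal target, step-penalty distance to
  a lower-bound target, and a tumor-burden + AUC trade-off with weight
  ratio φ = W1/W2);
* quantifies robustness of an optimized schedule to intra-patient PK noise
  and systematic parameter error.

It is a library first (see `examples/`), with a thin CLI
(`dosecontrol optimize-diagnosis | fit-burden | optimize-adjust |
robustness | simulate-cohort`) for shell use. A seeded synthetic-cohort
module generates demographics and burden series with the structure the
pipeline assumes, so everything is testable without patient data.

## Worked example

Design a 14-day, one-dose-per-day schedule for the population-average male
patient that stays above the clinical imatinib floor of 0.57 mg/L
(`examples/optimize_at_diagnosis.py`):

```python
import dosecontrol as dc
from dosecontrol.control import ControlProblem, OptimizerConfig, dcrab_optimize

coeffs = dc.load_pk_constants()
pk = dc.pk_from_covariates(dc.reference_patient(sex=1, coeffs=coeffs), coeffs)
problem = ControlProblem(horizon=(0.0, 336.0), n_doses=14,
                         cost_kind="lower_bound", pk=pk, target_conc=0.57)
result = dcrab_optimize(problem, OptimizerConfig(), seed=1)
```

which prints:

```
optimized: doses (mg) = [535, 426, 436, 450, 297, 392, 345, 308, 338, 323, 391, 400, 530, 403]
           time above 0.57 mg/L =  99.7%   AUC =  350.6 mg*h/L
standard : doses (mg) = [400, 400, 400, 400, 400, 400, 400, 400, 400, 400, 400, 400, 400, 400]
           time above 0.57 mg/L =  97.6%   AUC =  353.7 mg*h/L
cost: 209.6 (standard) -> 164.1 (optimized)
```

The optimizer raises the first dose — a de-facto loading dose — which
removes nearly all of the sub-floor time the flat regimen spends while the
drug accumulates (only the first ~50 minutes of absorption remain below the
floor, the physical minimum), at slightly *lower* total exposure. The other
examples cover PK heterogeneity, burden fitting + PD estimation, therapy
adjustment for faster predicted tumor decay, and the robustness studies.

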