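"""From tumor-burden series to patient-specific pharmacodynamics.

A synthetic cohort's BCR-ABL series decay biphasically in log10 scale.
The rightmost slope reflects pure cancer-stem-cell decay, which gives each
patient a death rate d1; pairing d1 with the standard-therapy average
concentration (through a benchmark Emax curve) yields the cohort conversion
constant K and, inverting, a personal EC50 per patient.
"""

from dosecontrol import reports
from dosecontrol.cohort import BurdenGenSpec, CohortSpec, generate_burden_series, generate_cohort

patients = generate_cohort(CohortSpec(n_patients=6, seed=7))
series = {
    p.id: generate_burden_series(BurdenGenSpec(noise_sd=0.1, seed=100 + i),
                                 patient_id=p.id)
    for i, p in enumerate(patients)}

rep = reports.fit_burden_report(series, patients)
print(f"cohort conversion constant K = {rep['conversion_k_per_day']:.4f} "
      f"+/- {rep['conversion_k_ci']:.4f} /day")
print(f"{'patient':8s} {'slope2':>9s} {'d1 /day':>8s} {'Cbar mg/L':>10s} "
      f"{'EC50 mg/L':>10s}")
for pid, f in rep["patients"].items():
    ec50 = f["ec50_mg_per_L"]
    print(f"{pid:8s} {f['slope2']:9.5f} {f['d1_per_day']:8.4f} "
          f"{f['c_bar_mg_per_L']:10.3f} "
          f"{ec50 if ec50 is None else round(ec50, 4)!s:>10s}")
# K converts drug effect (0..1) into a kill rate; a patient's EC50 says how
# much concentration they personally need for half-maximal effect.
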