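{
  "description": "Covariate coefficients for the one-compartment oral imatinib PK model: CL = theta_a + theta_1*(BW-bw_mean)/bw_mean + theta_2*q - theta_2*(1-q) + theta_3*(AGE-age_mean)/age_mean ; v = theta_b + theta_4*q - theta_4*(1-q), with q=1 male, q=0 female.",
  "provenance": "Representative values anchored to the published population-PK study of imatinib by Widmer et al. (Br J Clin Pharmacol 2006; typical clearance 14.3 L/h, volume of distribution 347 L, first-order absorption rate 0.61 /h, near-complete oral bioavailability). Covariate effect sizes are plausible literature-scale defaults, not a transcription of any single fitted model; override via config for a specific cohort.",
  "theta_a": 14.3,
  "theta_b": 347.0,
  "theta_1": 5.5,
  "theta_2": 0.8,
  "theta_3": -1.3,
  "theta_4": 25.0,
  "bw_mean": 70.0,
  "age_mean": 50.0,
  "ka": 0.61,
  "f": 1.0
}
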