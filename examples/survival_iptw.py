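"""Propensity-weighted survival contrast for surveillance exposure.

Simulates a confounded cohort (stage and comorbidity drive both who gets
surveillance and the death hazard), balances the arms with stabilized
inverse-probability-of-treatment weights, and estimates the marginal hazard
ratio with a weighted Cox model; finishes by raking the cohort to an
external reference's sex margin.
"""

import numpy as np

from ctsurveil.survival import (
    fit_propensity_and_weights,
    standardize_to_reference,
    weighted_cox,
    weighted_km,
)
from ctsurveil.synthetic import GeneratorConfig, generate_cohort, generate_outcomes

config = GeneratorConfig(n_patients=4000, seed=5)  # true marginal HR 0.6
rng = np.random.default_rng(99)
cohort = generate_cohort(config)
outcomes = generate_outcomes(cohort, cohort["engaged"].to_numpy(), config, rng)
records = cohort.merge(outcomes, on="patient_id")
records["exposure"] = records["engaged"].astype(int)
records["comorbidity"] = records["comorbidity"].astype(float)
records = records[records["time_days"] > 0].reset_index(drop=True)

covariates = ("sex", "race_ethnicity", "stage", "histology", "comorbidity")
naive = weighted_cox(records, covariates=())
print(f"unadjusted HR {naive.hazard_ratio:.2f} "
      f"(95% CI {naive.ci[0]:.2f}-{naive.ci[1]:.2f})  <- confounded")

pw = fit_propensity_and_weights(records, covariates=covariates)
print("\ncovariate balance (standardized mean differences):")
print(pw.balance.round(3).to_string(index=False))

fit = weighted_cox(records, weights=pw.weights, covariates=covariates)
print(f"\nIPTW-weighted HR {fit.hazard_ratio:.2f} "
      f"(95% CI {fit.ci[0]:.2f}-{fit.ci[1]:.2f})  <- recovers the true 0.60")

km = weighted_km(records, weights=pw.weights)
for arm, curve in km.items():
    tail = curve["survival"].iloc[-1]
    print(f"weighted KM, arm {arm}: S(end of follow-up) = {tail:.2f}")

sw = standardize_to_reference(records, {"sex": {"male": 0.5, "female": 0.5}})
print(f"\nraking to a 50/50 sex margin converged in {sw.n_iter} iterations; "
      f"achieved male share {sw.achieved_margins['sex']['male']:.3f}")

# The unadjusted estimate exaggerates the benefit because healthier patients
# are the ones under surveillance; weighting removes the measured-confounder
# imbalance and the estimate returns to the configured truth.
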