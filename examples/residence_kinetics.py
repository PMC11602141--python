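"""Delayed-dissociation residence times: model, fit, condition comparison.

A DNA-clamped ParB dimer releases only after both of its CTP nucleotides
hydrolyse (rate k_ctp each) and the opened clamp dissociates (rate k_off),
so dwell times follow a hypoexponential, not an exponential. This script
prints the model summary statistics at measured rate pairs, fits simulated
dwell times by maximum likelihood, and compares two supercoiling
conditions with nonparametric tests.
"""

import numpy as np

from parbkymo import (ResidenceModel, compare_conditions, fit_residence,
                      model_mean, model_median, model_mode,
                      sample_residence_time)

conditions = {
    "non-coiled":          ResidenceModel(0.016, 0.020),
    "positive supercoiled": ResidenceModel(0.017, 0.047),
    "negative supercoiled": ResidenceModel(0.021, 0.028),
}

print("model summaries (independent-hydrolysis variant):")
for name, m in conditions.items():
    print(f"  {name:22s} mean {model_mean(m):6.1f} s   "
          f"median {model_median(m):6.1f} s   mode {model_mode(m):5.1f} s")

# maximum-likelihood recovery from simulated dwells (sequential variant,
# which is the identifiable parameterisation for rate estimation)
true = ResidenceModel(0.017, 0.047, variant="sequential")
times = sample_residence_time(true, np.random.default_rng(12), size=5000)
fit = fit_residence(times, variant="sequential")
# note: the likelihood surface has a near-mirror second mode that swaps
# which stage is rate-limiting; a minority of samples at this n land there
print(f"\nMLE on 5000 simulated dwells (truth k_ctp=0.017, k_off=0.047):")
print(f"  k_ctp = {fit.model.k_ctp:.4f} +/- {fit.stderr_k_ctp:.4f} 1/s")
print(f"  k_off = {fit.model.k_off:.4f} +/- {fit.stderr_k_off:.4f} 1/s")

# are the non-coiled and positively supercoiled dwells distinguishable at
# experimental sample sizes?
rng = np.random.default_rng(1)
a = sample_residence_time(conditions["non-coiled"], rng, size=59)
b = sample_residence_time(conditions["positive supercoiled"], rng, size=80)
(mw_u, mw_p), (ks_d, ks_p) = compare_conditions(a, b)
print(f"\nnon-coiled (n=59) vs positive (n=80):")
print(f"  Mann-Whitney p = {mw_p:.4f}, KS p = {ks_p:.4f}")
# a shorter residence on supercoiled DNA shows up as small p-values
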