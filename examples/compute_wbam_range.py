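"""Compute the frontal WBAM range of a (synthetic) gait trial.

Generates a 12-segment gait trial with known analytic frontal
whole-body angular momentum, runs the kinematics pipeline (contact
detection, per-cycle time normalisation, mass x height x speed
normalisation) and compares the per-cycle range with the closed form.
"""

import numpy as np

from wbam import SyntheticGaitConfig, analyze_trial, generate_synthetic_gait

config = SyntheticGaitConfig(asymmetry_factor=1.5)
trial, truth = generate_synthetic_gait(config)
result = analyze_trial(trial, lowpass=False)

print(f"paretic foot contacts at samples: {result.contacts.tolist()}")
print(f"gait cycles found:               {len(result.ranges)}")
for k, r in enumerate(result.ranges, 1):
    print(f"  cycle {k}: normalized WBAM range = {r:.6f}")
print(f"analytic range (closed form):     {truth['analytic_range_dimensionless']:.6f}")
rel = abs(result.mean_range - truth["analytic_range_dimensionless"])
rel /= truth["analytic_range_dimensionless"]
print(f"relative error:                   {rel:.2e}")

# The range is dimensionless (normalized by body mass x height x walking
# speed); values around 0.01-0.1 are the physiological order of magnitude.
# The tiny relative error shows the 101-point cycle grid loses < 1% of the
# true peak-to-peak excursion.
peak = np.abs(result.cycles[0].values).max()
print(f"peak |WBAM| over the first cycle: {peak:.6f} (dimensionless)")
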