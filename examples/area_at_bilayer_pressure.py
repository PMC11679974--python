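"""Read the area per lipid at the bilayer-equivalent pressure (30 mN/m).

Fits a cubic to the compressed branch (< 100 A^2) of a pi-A isotherm and
inverts it at 30 mN/m, the lateral pressure at which monolayers are
conventionally compared with bilayers.
"""

import numpy as np

from monofilm import (
    area_at_pressure,
    fit_isotherm_polynomial,
    popc_like_truth,
    simulate_area_isotherm,
)

truth = popc_like_truth(seed=7, noise_sd_pi_mNm=0.2)
isotherm = simulate_area_isotherm(truth, np.linspace(50.0, 100.0, 35))
model = fit_isotherm_polynomial(isotherm, max_area_A2=100.0, degree=3)
a30 = area_at_pressure(model, 30.0)

print(f"fitted polynomial degree   : {model.degree}")
print(f"fit residual RMS           : {model.residual_rms:.3f} mN/m")
print(f"area per lipid at 30 mN/m  : {a30:.1f} A^2  (constructed truth: 64.5)")
print()
print("The root is taken on the branch where pressure falls with area,")
print("i.e. ordinary compression behaviour.")
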