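"""Locate the saturation point of a constant-area surface-pressure trace.

Generates a POPC-like pi(n) trace (pressure vs amount of lipid spread on
a 100 cm^2 trough) with realistic noise, then extracts the saturation
point as the intersection of the steepest-rise and plateau lines.
"""

from monofilm import detect_saturation, popc_like_truth, simulate_pressure_amount

truth = popc_like_truth(seed=42)
trace = simulate_pressure_amount(truth, trough_area_cm2=100.0)
sat = detect_saturation(trace)

print(f"true area per lipid at saturation : {truth.A_sat_A2:.1f} A^2")
print(f"recovered saturation amount       : {sat.n_sat_nmol:.2f} nmol")
print(f"recovered saturation pressure     : {sat.pi_sat_mNm:.1f} mN/m")
print(f"recovered area per lipid          : {sat.A_sat_A2:.1f} A^2")
print()
print("The recovered area divides the fixed trough area by the number of")
print("molecules present when the film saturates; agreement with the true")
print("value shows the two-line construction locates the knee correctly.")
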