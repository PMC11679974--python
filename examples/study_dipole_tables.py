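"""Analyze the packaged study films end to end.

For each of the eleven lipid compositions: Gouy-Chapman correction at the
saturation area, transverse dipole moment under both capacitor variants
(with and without the 100 mV area-independent offset), and the dipole
potential extrapolated to 30 mN/m.
"""

from monofilm import study_records
from monofilm.io import report_table

records = study_records()
table = report_table(records)
print(table.to_string(index=False))
print()
print("mu_eq1/psi30_eq1: plain capacitor (dV0 = 0); mu_eq2/psi30_eq2:")
print("with a 100 mV area-independent offset.  Films with cholesterol")
print("show the largest 30 mN/m potentials because their area barely")
print("changes between saturation and 30 mN/m.")
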