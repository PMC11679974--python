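"""Correct a charged film's measured potential for the diffuse layer.

A pure POPS monolayer (one -e per lipid) at 49.4 A^2 in 150 mM NaCl
carries a strongly negative surface potential psi0; the dipole potential
is the measured interfacial potential minus psi0 and therefore exceeds
the raw reading.
"""

from monofilm import (
    Composition,
    correct_measured_potential,
    grahame_psi0,
    make_study_registry,
    surface_charge_density,
)

registry, subphase = make_study_registry()
pops = Composition.pure(registry["POPS"])

sigma = surface_charge_density(49.4, pops)
psi0 = grahame_psi0(sigma, subphase)
psi_measured = 330.0  # mV, a typical raw reading for an anionic film
psi_dipole = correct_measured_potential(psi_measured, psi0)

print(f"surface charge density : {sigma:+.4f} C/m^2")
print(f"surface potential psi0 : {psi0:+.1f} mV   (Grahame equation, 150 mM 1:1)")
print(f"measured potential     : {psi_measured:+.1f} mV")
print(f"dipole potential       : {psi_dipole:+.1f} mV")
print()
print("The ~137 mV diffuse-layer term would otherwise be misread as a")
print("smaller lipid dipole contribution.")
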