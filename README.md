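# monofilm

Electrostatics of lipid monolayers at the air–water interface: from raw
surface-pressure traces and interfacial-potential readings to areas per
lipid, transverse dipole moments, Gouy–Chapman-corrected dipole
potentials, ideal-mixing deviations, and the transbilayer dipole
potential of asymmetric membrane leaflet compositions.

## Who this is for

Membrane biophysicists working with Langmuir films who measure surface
pressure π (mN/m) and interfacial potential (mV) for pure and mixed
lipid compositions — e.g. POPC, POPE, POPS, sphingomyelin and
cholesterol mixtures mimicking the leaflets of eukaryotic plasma
membranes — and want the derived electrostatic quantities with a
reproducible, tested pipeline instead of a spreadsheet.

## The models

**Saturation (constant-area) method.** Lipid is spread on a trough of
fixed area until π stops rising; the saturation point is the
intersection of two least-squares lines through the steepest-rise and
plateau regions of the π(n) trace, and the mean area per lipid is
A_sat = trough area / (N_A · n_sat).  The area at the
bilayer-equivalent pressure of 30 mN/m is read from a low-order
polynomial fitted to the π–A isotherm below 100 Å².

**Helmholtz parallel-plate capacitor.** The film is a sheet of aligned
dipoles:

    ΔV = 12π·μ⊥/A            (plain)
    ΔV = 12π·μ⊥/A + ΔV0      (with an area-independent offset, ≈100 mV
                              for zwitterionic phospholipids)

with ΔV in mV, μ⊥ (transverse dipole moment) in millidebye and A in Å².

**Gouy–Chapman correction.** For films with charged lipids the measured
potential contains the diffuse-layer surface potential ψ0, obtained from
the Grahame equation

    σ² = 2000·ε0·εr·R·T · Σᵢ Cᵢ·(exp(−zᵢ·F·ψ0/(R·T)) − 1)

solved by bracketed root finding for arbitrary electrolyte mixtures;
the dipole potential is ψ_dipole = ψ_measured − ψ0.

**Mixtures and bilayers.** Ideal-mixing (additive) and
replacement-scheme predictions quantify condensation/expansion of mixed
films; two analyzed leaflets give a transbilayer dipole potential
Δψ = ψ(inner) − ψ(outer).

## Worked example

```python
from monofilm import (Composition, make_study_registry,
                      surface_charge_density, grahame_psi0,
                      correct_measured_potential, helmholtz_dipole)

registry, subphase = make_study_registry()   # POPC/POPE/POPS/SpM/chol, 150 mM NaCl
pops = Composition.pure(registry["POPS"])

sigma = surface_charge_density(49.4, pops)   # -0.3243 C/m^2
psi0 = grahame_psi0(sigma, subphase)         # -136.8 mV
psi_d = correct_measured_potential(330.0, psi0)   # 466.8 mV
mu = helmholtz_dipole(psi_d, 49.4)           # 611.7 mD
```

A pure POPS film carries one negative elementary charge per lipid, so at
49.4 Å² per molecule the diffuse double layer in 150 mM salt sits at
−136.8 mV; a raw reading of 330 mV therefore corresponds to a dipole
potential of 466.8 mV, and inverting the capacitor relation at the
saturation area gives the transverse dipole moment.  The
`examples/` directory contains one short script per capability
(saturation-point extraction, isotherm inversion at 30 mN/m, the
Gouy–Chapman correction, the full per-film analysis table, mixture
additivity, transbilayer asymmetry); each prints the numbers it computes
and a line on what they mean.  Running
`python examples/study_dipole_tables.py` prints, for instance, the POPC
row `mu_eq1 = 546 mD, psi30_eq1 = 319 mV` and the plasma-membrane
leaflet difference of +26 mV at 30 mN/m appears in
`python examples/transbilayer_asymmetry.py`.

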