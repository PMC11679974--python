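"""Quantify condensation and expansion in mixed films.

Compares observed areas per lipid (at 30 mN/m) with ideal-mixing
predictions: the mole-fraction linear combination of pure-film values
(additive scheme) and the substitution of lipids into a measured
PC:cholesterol 7:3 reference (replacement scheme).
"""

from monofilm import (
    Composition,
    additive_prediction,
    deviation_report,
    make_study_registry,
    replacement_prediction,
)
from monofilm.mixtures import MixturePrediction

registry, _ = make_study_registry()
pure_area30 = {"POPC": 64.5, "POPE": 56.0, "POPS": 55.0, "SpM": 48.0,
               "cholesterol": 30.0}
observed = {
    ("POPC:cholesterol", (7, 3)): 48.0,
    ("SpM:cholesterol", (6, 4)): 39.0,
    ("POPC:POPE", (8, 2)): 59.6,
    ("POPC:POPS", (9, 1)): 69.8,
    ("POPC:cholesterol:POPE:POPS", (4, 3, 2, 1)): 61.5,
}

predictions = []
for (names, ratio), obs in observed.items():
    comp = Composition.from_ratio([registry[n] for n in names.split(":")], ratio)
    predictions.append(
        MixturePrediction(comp, "area_A2", "additive",
                          additive_prediction(comp, pure_area30), obs)
    )

print(deviation_report(predictions).round(2).to_string(index=False))
print()
print("sign -1: condensed below ideal mixing (cholesterol effect);")
print("sign +1: expanded (electrostatic repulsion of charged PS).")
print()

# replacement scheme: substitute PE+PS into the measured PC:Chol 7:3 film
quaternary = replacement_prediction(48.0, 0.7,
                                    {"POPE": (0.2, 56.0), "POPS": (0.1, 55.0)})
print(f"replacement prediction for the quaternary film: {quaternary:.1f} A^2")
print("observed 61.5 A^2 -> PE (and PS) disrupt the cholesterol")
print("condensation preserved in the reference binary.")
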