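"""Ideal-mixing predictions for monolayer mixtures.

Two prediction schemes for a per-lipid property v (area per molecule or
transverse dipole moment) of a mixed film:

* **additive** — the mole-fraction-weighted linear combination of the
  pure-component values, Σ xᵢ·vᵢ.  Observed < predicted signals
  condensation (the classic cholesterol effect); observed > predicted
  signals expansion/non-ideal mixing.
* **replacement** — keep a reference binary's measured per-lipid value
  for the fraction of the film it still occupies and substitute the
  replaced lipid's pure value for the remainder.  This isolates whether a
  substituent disrupts the reference pair's packing (e.g. whether PE
  abolishes the cholesterol condensation of PC:Chol 7:3).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .core import Composition, ValidationError

__all__ = [
    "MissingPureValueError",
    "MixturePrediction",
    "additive_prediction",
    "replacement_prediction",
    "deviation_report",
]


class MissingPureValueError(KeyError):
    """A composition species has no pure-component value."""


@dataclass(frozen=True)
class MixturePrediction:
    """Predicted vs observed per-lipid property for one mixture."""

    composition: Composition
    property_name: str  # "area_A2" or "mu_mD"
    scheme: str  # "additive" | "replacement"
    predicted: float
    observed: float | None = None

    def __post_init__(self) -> None:
        if self.scheme not in ("additive", "replacement"):
            raise ValidationError(f"unknown scheme {self.scheme!r}")

    @property
    def deviation_abs(self) -> float | None:
        if self.observed is None:
            return None
        return self.observed - self.predicted

    @property
    def deviation_rel(self) -> float | None:
        if self.observed is None:
            return None
        return (self.observed - self.predicted) / self.predicted


def additive_prediction(
    composition: Composition, pure_values: Mapping[str, float]
) -> float:
    """Mole-fraction linear combination Σ xᵢ·vᵢ of pure-component values.

    Falls back to the species' registry reference value (``ref_area_A2``
    / ``ref_dipole_mD``) only if it is supplied in ``pure_values``; every
    species in the composition must be covered.
    """
    total = 0.0
    for sp, x in composition.components:
        if sp.name not in pure_values:
            raise MissingPureValueError(
                f"no pure value for species {sp.name!r}"
            )
        total += x * pure_values[sp.name]
    return total


def replacement_prediction(
    base_pair_value: float,
    base_pair_fraction: float,
    substitutions: Mapping[str, tuple[float, float]],
) -> float:
    """Replacement-scheme prediction.

    ``base_pair_value`` is the measured per-lipid value of the reference
    binary (counting all its molecules); ``base_pair_fraction`` the mole
    fraction of the film it still occupies; ``substitutions`` maps each
    substituent to its (mole fraction, pure value).  Fractions must sum
    to 1.
    """
    frac_sum = base_pair_fraction + sum(f for f, _ in substitutions.values())
    if abs(frac_sum - 1.0) > 1e-9:
        raise ValidationError(
            f"base + substitution fractions must sum to 1 (got {frac_sum!r})"
        )
    return base_pair_fraction * base_pair_value + sum(
        f * v for f, v in substitutions.values()
    )


def deviation_report(predictions: list[MixturePrediction]) -> pd.DataFrame:
    """Tabulate predictions with observed values and signed deviations.

    One row per prediction: (system, property, scheme, predicted,
    observed, deviation_abs, deviation_rel, sign).  sign < 0 means the
    observed value lies below the ideal-mixing identity line
    (condensation, for areas); sign > 0 means expansion.
    """
    rows = []
    for p in predictions:
        if p.observed is None:
            raise ValidationError(
                f"{p.composition.label()}: observed value required for report"
            )
        dev = p.deviation_abs
        rows.append(
            {
                "system": p.composition.label(),
                "property": p.property_name,
                "scheme": p.scheme,
                "predicted": p.predicted,
                "observed": p.observed,
                "deviation_abs": dev,
                "deviation_rel": p.deviation_rel,
                "sign": 0 if dev == 0 else (1 if dev > 0 else -1),
            }
        )
    return pd.DataFrame(rows)
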