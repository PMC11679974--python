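"""Leaflet asymmetry and cross-system statistics.

An asymmetric bilayer is modelled as two independent monolayers (inner
and outer leaflet).  Because the dipole potential of each leaflet points
from the aqueous phase into the membrane, a composition difference
between leaflets leaves a net transbilayer dipole potential
Δψ = ψ(inner) − ψ(outer), the sign convention chosen so that the
plasma-membrane model (PS-containing inner leaflet, SpM-rich outer
leaflet) is positive.

Also here: ordinary least-squares helpers relating the dipole potential
at saturation to its value extrapolated to 30 mN/m, comparing computed
dipole moments with literature reference values, and fitting the linear
relation between membrane partition free energies and the dipole
potential.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ValidationError
from .electrostatics import MonolayerRecord, round_half_away

__all__ = [
    "BilayerModel",
    "LinearFit",
    "transbilayer_potential",
    "transbilayer_with_surface",
    "percent_change",
    "pressure_correlation",
    "compare_reference_dipoles",
    "partition_energy_fit",
    "bilayer_summary",
]

#: literature transverse dipole moments (mD) for pure films, used by
#: :func:`compare_reference_dipoles` by default.
REFERENCE_DIPOLES_MD: Mapping[str, float] = {
    "POPC": 468.0,
    "POPE": 467.0,
    "POPS": 459.0,
}


@dataclass(frozen=True)
class BilayerModel:
    """Two analyzed leaflets under the same ΔV0 convention."""

    inner: MonolayerRecord
    outer: MonolayerRecord

    def __post_init__(self) -> None:
        if self.inner.delta_V0_mV != self.outer.delta_V0_mV:
            raise ValidationError("leaflets analyzed under different dV0")


@dataclass(frozen=True)
class LinearFit:
    """Simple OLS fit y = slope·x + intercept."""

    slope: float
    intercept: float
    r: float
    n: int

    @property
    def r_squared(self) -> float:
        return self.r * self.r

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


_MODE_FIELD = {
    "sat": "psi_dipole_sat_mV",
    "30mNm_eq1": "psi30_eq1_mV",
    "30mNm_eq2": "psi30_eq2_mV",
}


def transbilayer_potential(bilayer: BilayerModel, pressure_mode: str = "sat") -> float:
    """Transbilayer dipole potential Δψ = ψ(inner) − ψ(outer), in mV.

    ``pressure_mode`` selects the dipole potential used for each
    leaflet: at saturation (``"sat"``) or extrapolated to 30 mN/m with
    either capacitor variant (``"30mNm_eq1"`` / ``"30mNm_eq2"``).
    """
    try:
        field = _MODE_FIELD[pressure_mode]
    except KeyError:
        raise ValidationError(
            f"unknown pressure_mode {pressure_mode!r}; one of {sorted(_MODE_FIELD)}"
        ) from None
    inner = getattr(bilayer.inner, field)
    outer = getattr(bilayer.outer, field)
    if inner is None or outer is None:
        raise ValidationError(
            f"missing {field} on a leaflet for mode {pressure_mode!r}"
        )
    return inner - outer


def transbilayer_with_surface(bilayer: BilayerModel) -> float:
    """Δ(ψd + ψ0) at saturation: the leaflet difference including each
    side's diffuse-layer surface potential.

    Reported alongside :func:`transbilayer_potential` because for charged
    inner leaflets the two differ and which one a given experiment probes
    depends on where the potential reference sits.
    """
    inner = bilayer.inner.psi_dipole_sat_mV + bilayer.inner.psi0_mV
    outer = bilayer.outer.psi_dipole_sat_mV + bilayer.outer.psi0_mV
    return inner - outer


def percent_change(value_from: float, value_to: float) -> int:
    """Relative change in percent, rounded half away from zero."""
    if value_from == 0:
        raise ZeroDivisionError("percent change from zero is undefined")
    return round_half_away(100.0 * (value_to - value_from) / value_from)


def _ols(x: np.ndarray, y: np.ndarray) -> LinearFit:
    res = stats.linregress(x, y)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        n=len(x),
    )


def pressure_correlation(
    records: Iterable[MonolayerRecord], eq_variant: int = 1
) -> LinearFit:
    """OLS of ψd30* on ψd_sat across films (how well the saturation
    potential predicts the 30 mN/m value)."""
    if eq_variant not in (1, 2):
        raise ValidationError("eq_variant must be 1 or 2")
    field = f"psi30_eq{eq_variant}_mV"
    pairs = [
        (r.psi_dipole_sat_mV, getattr(r, field))
        for r in records
        if getattr(r, field) is not None
    ]
    if len(pairs) < 3:
        raise ValidationError("need >= 3 records with both potentials")
    xy = np.asarray(pairs, dtype=float)
    return _ols(xy[:, 0], xy[:, 1])


def compare_reference_dipoles(
    records: Iterable[MonolayerRecord],
    reference: Mapping[str, float] = REFERENCE_DIPOLES_MD,
) -> pd.DataFrame:
    """Relative differences between computed μ⊥ and literature values.

    Returns one row per (lipid, capacitor variant) with
    rel_diff = (μ_calc − μ_ref)/μ_ref; only pure films whose species
    appears in ``reference`` are compared.
    """
    rows = []
    for rec in records:
        if len(rec.composition.components) != 1:
            continue
        name = rec.composition.species[0].name
        if name not in reference:
            continue
        for variant in (1, 2):
            mu = getattr(rec, f"mu_eq{variant}_mD")
            if mu is None:
                continue
            ref = reference[name]
            rows.append(
                {
                    "lipid": name,
                    "eq_variant": variant,
                    "mu_calc_mD": mu,
                    "mu_ref_mD": ref,
                    "rel_diff": (mu - ref) / ref,
                }
            )
    if not rows:
        raise ValidationError("no pure-film record matches the reference map")
    return pd.DataFrame(rows)


def partition_energy_fit(
    pairs: Sequence[tuple[float, float]],
    holdout: Sequence[tuple[float, float]] = (),
) -> tuple[LinearFit, np.ndarray]:
    """Fit ΔΔG°P (kJ/mol) vs dipole potential (mV) by OLS.

    ``pairs`` are the calibration points; ``holdout`` points (e.g.
    complex mixtures not used in the fit) are evaluated against the
    fitted line and their residuals returned.
    """
    if len(pairs) < 3:
        raise ValidationError("need >= 3 (psi_d, ddG) pairs")
    xy = np.asarray(pairs, dtype=float)
    fit = _ols(xy[:, 0], xy[:, 1])
    if holdout:
        ho = np.asarray(holdout, dtype=float)
        residuals = ho[:, 1] - fit.predict(ho[:, 0])
    else:
        residuals = np.empty(0)
    return fit, residuals


def bilayer_summary(
    records: Sequence[MonolayerRecord],
    bilayer: BilayerModel | None = None,
) -> dict:
    """Cross-system summary: correlations, reference comparison and (if a
    bilayer model is given) transbilayer potentials by every convention."""
    out: dict = {
        "pressure_correlation_eq1": pressure_correlation(records, 1),
        "pressure_correlation_eq2": pressure_correlation(records, 2),
        "reference_dipoles": compare_reference_dipoles(records),
    }
    if bilayer is not None:
        out["transbilayer_sat_mV"] = transbilayer_potential(bilayer, "sat")
        out["transbilayer_30mNm_eq1_mV"] = transbilayer_potential(
            bilayer, "30mNm_eq1"
        )
        out["transbilayer_30mNm_eq2_mV"] = transbilayer_potential(
            bilayer, "30mNm_eq2"
        )
        out["transbilayer_sat_with_surface_mV"] = transbilayer_with_surface(bilayer)
    return out
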