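"""Dipole-layer and diffuse-double-layer electrostatics of lipid monolayers.

Two models are combined here.

**Helmholtz parallel-plate capacitor.**  A monolayer is treated as a sheet
of aligned molecular dipoles; the potential drop across it is

    ΔV = 12π·μ⊥/A  (+ ΔV0)

with ΔV in mV, the transverse dipole moment μ⊥ in millidebye and the mean
area per lipid A in Å².  The optional area-independent intercept ΔV0
(~100 mV for zwitterionic phospholipids) captures the empirical finite
intercept of ΔV-vs-1/A plots.

**Gouy–Chapman diffuse layer.**  For films containing charged lipids the
measured interfacial potential also contains the surface-charge potential
ψ0, related to the surface charge density σ by the Grahame equation

    σ² = 2000·ε0·εr·R·T · Σᵢ Cᵢ·(exp(−zᵢ·F·ψ0/(R·T)) − 1)

(Cᵢ in mol/L).  The dipole potential is then ψ_dipole = ψ_measured − ψ0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

from .constants import E_CHARGE, EPS0, F, K_HELMHOLTZ, R
from .core import Composition, Subphase, ValidationError

__all__ = [
    "BracketError",
    "HelmholtzResult",
    "SurfacePotentialResult",
    "MonolayerRecord",
    "helmholtz_potential",
    "helmholtz_dipole",
    "surface_charge_density",
    "grahame_sigma",
    "grahame_psi0",
    "correct_measured_potential",
    "analyze_monolayer",
    "round_half_away",
]


class BracketError(RuntimeError):
    """Grahame root finding could not bracket a sign change."""


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (report convention).

    The value is first snapped to 9 decimals so that exact halves that
    float arithmetic has perturbed by ~1e-10 (e.g. 370.5 computed as a
    product/quotient chain) still tie-break away from zero.
    """
    x = round(x, 9)
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


# ---------------------------------------------------------------------------
# Helmholtz dipole layer
# ---------------------------------------------------------------------------

def helmholtz_potential(
    mu_perp_mD: float, area_A2: float, delta_V0_mV: float = 0.0
) -> float:
    """Dipole potential ΔV (mV) of a film of dipoles μ⊥ (mD) at area A (Å²).

    ΔV = 12π·μ⊥/A + ΔV0.
    """
    if not area_A2 > 0:
        raise ValidationError(f"area must be > 0 (got {area_A2})")
    return K_HELMHOLTZ * mu_perp_mD / area_A2 + delta_V0_mV


def helmholtz_dipole(
    delta_V_mV: float, area_A2: float, delta_V0_mV: float = 0.0
) -> float:
    """Invert the capacitor relation: μ⊥ = (ΔV − ΔV0)·A/(12π), in mD."""
    if not area_A2 > 0:
        raise ValidationError(f"area must be > 0 (got {area_A2})")
    return (delta_V_mV - delta_V0_mV) * area_A2 / K_HELMHOLTZ


@dataclass(frozen=True)
class HelmholtzResult:
    """A consistent (μ⊥, A, ΔV0, ΔV) quadruple."""

    mu_perp_mD: float
    area_A2: float
    delta_V0_mV: float
    delta_V_mV: float

    @classmethod
    def from_dipole(
        cls, mu_perp_mD: float, area_A2: float, delta_V0_mV: float = 0.0
    ) -> "HelmholtzResult":
        return cls(
            mu_perp_mD,
            area_A2,
            delta_V0_mV,
            helmholtz_potential(mu_perp_mD, area_A2, delta_V0_mV),
        )

    @classmethod
    def from_potential(
        cls, delta_V_mV: float, area_A2: float, delta_V0_mV: float = 0.0
    ) -> "HelmholtzResult":
        return cls(
            helmholtz_dipole(delta_V_mV, area_A2, delta_V0_mV),
            area_A2,
            delta_V0_mV,
            delta_V_mV,
        )


# ---------------------------------------------------------------------------
# Gouy–Chapman / Grahame
# ---------------------------------------------------------------------------

def surface_charge_density(area_A2: float, composition: Composition) -> float:
    """Surface charge density σ in C/m² from the mean charge per lipid.

    σ = (Σ xᵢ·zᵢ)·e / (A·10⁻²⁰ m²), counting all lipids in the mean area.
    """
    if not area_A2 > 0:
        raise ValidationError(f"area must be > 0 (got {area_A2})")
    return composition.mean_charge * E_CHARGE / (area_A2 * 1e-20)


def grahame_sigma(psi0_mV: float, subphase: Subphase) -> float:
    """Forward Grahame relation: σ (C/m²) carried by a diffuse layer at ψ0.

    σ shares the sign of ψ0; the sum runs over all electrolyte species.
    """
    rt = R * subphase.temperature_K
    psi_V = psi0_mV * 1e-3
    s = sum(
        sp.conc_M * math.expm1(-sp.z * F * psi_V / rt) for sp in subphase.species
    )
    # s >= 0 always (expm1 is convex; electroneutral sum has positive curvature)
    return math.copysign(
        math.sqrt(max(s, 0.0) * 2000.0 * EPS0 * subphase.rel_permittivity * rt),
        psi_V,
    )


_BRACKET_MV = 500.0


def grahame_psi0(sigma_C_m2: float, subphase: Subphase) -> float:
    """Solve the Grahame equation for the surface potential ψ0 (mV).

    Bracketed root finding of σ(ψ) = σ_target on ψ ∈ [−500, 500] mV,
    widened once to ±1000 mV; the residual |σ(ψ0) − σ| is below
    1e-10 C/m².  sign(ψ0) = sign(σ); σ = 0 returns exactly 0.
    """
    if sigma_C_m2 == 0.0:
        return 0.0
    if not any(sp.conc_M > 0 and sp.z != 0 for sp in subphase.species):
        raise ValidationError("charged surface requires an ionic subphase")

    def f(psi_mV: float) -> float:
        return grahame_sigma(psi_mV, subphase) - sigma_C_m2

    for half_width in (_BRACKET_MV, 2 * _BRACKET_MV):
        lo, hi = (0.0, half_width) if sigma_C_m2 > 0 else (-half_width, 0.0)
        if f(lo) * f(hi) <= 0:
            psi = brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16, maxiter=200)
            if abs(f(psi)) > 1e-10:  # tighten by bisection if brentq's xtol left slack
                psi = brentq(f, lo, hi, xtol=1e-15, rtol=8.9e-16, maxiter=500)
            return psi
    raise BracketError(
        f"no ψ0 in ±{2 * _BRACKET_MV:g} mV carries σ = {sigma_C_m2:g} C/m²"
    )


def correct_measured_potential(psi_measured_mV: float, psi0_mV: float) -> float:
    """Remove the diffuse-layer term: ψ_dipole = ψ_measured − ψ0 (mV).

    For anionic films ψ0 < 0, so the dipole potential exceeds the
    measured potential.
    """
    return psi_measured_mV - psi0_mV


@dataclass(frozen=True)
class SurfacePotentialResult:
    """Surface-charge bookkeeping for one film."""

    sigma_C_m2: float
    psi0_mV: float
    psi_measured_mV: float

    @property
    def psi_dipole_mV(self) -> float:
        return self.psi_measured_mV - self.psi0_mV


# ---------------------------------------------------------------------------
# Whole-monolayer analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MonolayerRecord:
    """All measured and derived electrostatic quantities of one film.

    ``mu_eq1``/``psi30_eq1`` use the plain capacitor relation (ΔV0 = 0);
    ``mu_eq2``/``psi30_eq2`` include the area-independent offset ΔV0.
    ``area_sat_A2`` may be None when only literature μ⊥ values are
    available for the film (the derived fields are then supplied
    directly rather than computed).
    """

    composition: Composition
    psi_measured_mV: float
    psi0_mV: float
    psi_dipole_sat_mV: float
    area_sat_A2: float | None
    area30_A2: float | None
    mu_eq1_mD: float | None = None
    mu_eq2_mD: float | None = None
    psi30_eq1_mV: float | None = None
    psi30_eq2_mV: float | None = None
    delta_V0_mV: float = 100.0
    name: str | None = None

    @property
    def label(self) -> str:
        return self.name or self.composition.label()


def analyze_monolayer(
    composition: Composition,
    psi_measured_mV: float,
    area_sat_A2: float,
    area30_A2: float,
    subphase: Subphase,
    delta_V0_mV: float = 100.0,
    name: str | None = None,
) -> MonolayerRecord:
    """Full electrostatic analysis of one monolayer.

    Pipeline: σ at the saturation area → ψ0 (Grahame) → ψd_sat =
    ψ_measured − ψ0 → μ⊥ by both capacitor variants at (ψd_sat, A_sat) →
    dipole potential at 30 mN/m from μ⊥ and A30.
    """
    sigma = surface_charge_density(area_sat_A2, composition)
    psi0 = grahame_psi0(sigma, subphase)
    psi_d_sat = correct_measured_potential(psi_measured_mV, psi0)
    mu1 = helmholtz_dipole(psi_d_sat, area_sat_A2)
    mu2 = helmholtz_dipole(psi_d_sat, area_sat_A2, delta_V0_mV)
    return MonolayerRecord(
        composition=composition,
        psi_measured_mV=psi_measured_mV,
        psi0_mV=psi0,
        psi_dipole_sat_mV=psi_d_sat,
        area_sat_A2=area_sat_A2,
        area30_A2=area30_A2,
        mu_eq1_mD=mu1,
        mu_eq2_mD=mu2,
        psi30_eq1_mV=helmholtz_potential(mu1, area30_A2),
        psi30_eq2_mV=helmholtz_potential(mu2, area30_A2, delta_V0_mV),
        delta_V0_mV=delta_V0_mV,
        name=name,
    )
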