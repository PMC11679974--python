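"""Synthetic monolayer data with known ground truth.

Raw trough traces for the study systems are not publicly deposited, so
every stage of the analysis pipeline is exercised against generated data
whose true parameters are recorded.  The generator emulates:

* π(n) curves of the constant-area method — a steep compression region
  that meets a hard saturation plateau at π_sat (the knee sits exactly
  at the true saturation amount, so the two-line extraction has a
  well-defined truth);
* π(A) isotherms described by a low-order polynomial on the compressed
  branch (< 100 Å²);
* interfacial potential measurements composed of a Helmholtz dipole
  term, an optional ΔV0 offset, a Gouy–Chapman surface term for charged
  films, and Gaussian noise.

Default noise levels follow the scatter of the study's measurements:
0.3 mN/m on surface pressure and 5 mV on potentials.  All randomness
flows through explicit seeds; the same seed and parameters reproduce a
dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .constants import N_A
from .core import Composition, Subphase, ValidationError
from .electrostatics import grahame_psi0, helmholtz_potential, surface_charge_density
from .isotherm import AreaIsotherm, PressureAmountIsotherm, amount_to_area

__all__ = [
    "SyntheticTruth",
    "popc_like_truth",
    "simulate_pressure_amount",
    "simulate_area_isotherm",
    "simulate_potential_measurement",
]


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth parameters behind a generated dataset.

    ``poly_coeffs`` define the underlying π(A) in ascending powers;
    the saturation knee sits at (A_sat, π_sat) with poly(A_sat) = π_sat.
    """

    A_sat_A2: float
    pi_sat_mNm: float
    poly_coeffs: tuple[float, ...]
    mu_mD: float = 546.0
    delta_V0_mV: float = 0.0
    noise_sd_pi_mNm: float = 0.3
    noise_sd_psi_mV: float = 5.0
    seed: int = 0
    valid_area_A2: tuple[float, float] = (0.0, float("inf"))

    def pi_of_area(self, area_A2):
        return np.polynomial.polynomial.polyval(area_A2, self.poly_coeffs)

    def with_seed(self, seed: int) -> "SyntheticTruth":
        return replace(self, seed=seed)


def popc_like_truth(
    seed: int = 0,
    A_sat_A2: float = 49.4,
    pi_sat_mNm: float = 50.0,
    area30_A2: float = 64.5,
    noise_sd_pi_mNm: float = 0.3,
    noise_sd_psi_mV: float = 5.0,
    mu_mD: float = 546.0,
    degree: int = 5,
) -> SyntheticTruth:
    """Truth emulating a POPC film: polynomial π(A) through (A_sat,
    π_sat) and (A30, 30 mN/m), decaying toward low pressure near 100 Å².

    The polynomial approximates π = α + β/A — the form that makes a
    constant-area π(n) trace rise linearly in n below saturation, as
    observed traces do — with the two anchor points matched exactly by
    heavy weighting.  The default degree 5 keeps the approximation
    error below ~0.02 mN/m so the two-line saturation geometry has a
    sharp, unbiased knee; pass ``degree=3`` for a truth matching the
    default analysis polynomial exactly.
    """
    valid_hi = 105.0
    alpha_beta = np.linalg.solve(
        np.array([[1.0, 1.0 / A_sat_A2], [1.0, 1.0 / area30_A2]]),
        np.array([pi_sat_mNm, 30.0]),
    )
    grid = np.linspace(A_sat_A2, valid_hi, 120)
    target = alpha_beta[0] + alpha_beta[1] / grid
    weights = np.ones_like(grid)
    grid = np.concatenate([grid, [A_sat_A2, area30_A2]])
    target = np.concatenate([target, [pi_sat_mNm, 30.0]])
    weights = np.concatenate([weights, [1e6, 1e6]])  # pin the anchors
    coeffs = np.polynomial.polynomial.polyfit(grid, target, degree, w=weights)
    deriv = np.polynomial.polynomial.polyder(coeffs)
    check = np.linspace(A_sat_A2, valid_hi, 200)
    if np.any(np.polynomial.polynomial.polyval(check, deriv) >= 0):
        raise ValidationError("constructed pi(A) is not monotone decreasing")
    return SyntheticTruth(
        A_sat_A2=A_sat_A2,
        pi_sat_mNm=pi_sat_mNm,
        poly_coeffs=tuple(float(c) for c in coeffs),
        mu_mD=mu_mD,
        noise_sd_pi_mNm=noise_sd_pi_mNm,
        noise_sd_psi_mV=noise_sd_psi_mV,
        seed=seed,
        valid_area_A2=(A_sat_A2, valid_hi),
    )


def simulate_pressure_amount(
    truth: SyntheticTruth,
    trough_area_cm2: float = 100.0,
    n_points: int = 40,
    n_max_nmol: float | None = None,
) -> PressureAmountIsotherm:
    """Generate a constant-area π(n) trace.

    Amounts are an even grid up to ``n_max_nmol`` (default: 1.35× the
    true saturation amount, so roughly a quarter of the points lie on
    the plateau), starting where the sampled area enters the truth
    polynomial's validity range; π(n) = min(poly(A(n)), π_sat) + noise,
    clipped at 0.
    """
    if n_points < 10:
        raise ValidationError("n_points must be >= 10")
    n_sat = trough_area_cm2 * 1e16 / (truth.A_sat_A2 * 1e-9 * N_A)
    if n_max_nmol is None:
        n_max_nmol = 1.35 * n_sat
    if n_max_nmol <= n_sat:
        raise ValidationError("n_max_nmol must exceed the saturation amount")
    hi = truth.valid_area_A2[1]
    n_min = n_sat * truth.A_sat_A2 / hi if np.isfinite(hi) else 0.4 * n_sat
    n_grid = np.linspace(n_min, n_max_nmol, n_points)
    area = amount_to_area(n_grid, trough_area_cm2)
    pi_clean = np.minimum(truth.pi_of_area(area), truth.pi_sat_mNm)
    rng = np.random.default_rng(truth.seed)
    pi = np.clip(pi_clean + rng.normal(0.0, truth.noise_sd_pi_mNm, n_points), 0, None)
    return PressureAmountIsotherm(
        n_nmol=tuple(n_grid),
        pi_mNm=tuple(pi),
        trough_area_cm2=trough_area_cm2,
    )


def simulate_area_isotherm(truth: SyntheticTruth, area_grid) -> AreaIsotherm:
    """π(A) samples on an explicit area grid (Å²) with pressure noise."""
    area = np.asarray(area_grid, dtype=float)
    if area.size == 0:
        raise ValidationError("area grid must be non-empty")
    if np.any(area <= 0):
        raise ValidationError("areas must be > 0")
    lo, hi = truth.valid_area_A2
    if np.any(area < lo) or np.any(area > hi):
        raise ValidationError(
            f"area grid must lie inside the validity range [{lo:g}, {hi:g}]"
        )
    rng = np.random.default_rng(truth.seed)
    pi = truth.pi_of_area(area) + rng.normal(0.0, truth.noise_sd_pi_mNm, area.size)
    return AreaIsotherm(tuple(area), tuple(np.clip(pi, 0, None)))


def simulate_potential_measurement(
    truth: SyntheticTruth,
    composition: Composition,
    area_A2: float,
    subphase: Subphase,
    seed: int | None = None,
) -> float:
    """One noisy interfacial-potential reading (mV) at the given area.

    ψ_measured = 12π·μ/A + ΔV0 + ψ0(σ(composition, A)) + noise.
    """
    if not area_A2 > 0:
        raise ValidationError("area must be > 0")
    psi0 = grahame_psi0(surface_charge_density(area_A2, composition), subphase)
    clean = helmholtz_potential(truth.mu_mD, area_A2, truth.delta_V0_mV) + psi0
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    return float(clean + rng.normal(0.0, truth.noise_sd_psi_mV))
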