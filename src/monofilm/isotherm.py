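"""Surface-pressure isotherm analysis.

The constant-area (saturation) method spreads successive aliquots of lipid
on a trough of fixed area and records the surface pressure π after each
addition.  π rises steeply while the film compresses and flattens into a
plateau once the interface saturates and excess lipid aggregates in the
subphase.  The saturation point is located as the intersection of two
least-squares lines — one through the steepest-rise region, one through
the plateau — and converts to a mean area per lipid A_sat = trough area /
(N_A · n_sat).

π(A) isotherms are summarised by a low-order polynomial fitted below
100 Å² (liquid expanded/condensed regime), from which the area at an
arbitrary lateral pressure (conventionally 30 mN/m, the bilayer-equivalent
pressure) is read off by root finding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import N_A
from .core import ValidationError

__all__ = [
    "NoPlateauError",
    "DegenerateLinesError",
    "InsufficientPointsError",
    "NoRootInRangeError",
    "PressureAmountIsotherm",
    "AreaIsotherm",
    "SaturationPoint",
    "IsothermPolynomial",
    "detect_saturation",
    "to_area_isotherm",
    "amount_to_area",
    "fit_isotherm_polynomial",
    "area_at_pressure",
]


class NoPlateauError(RuntimeError):
    """The isotherm shows no saturation plateau (slope-ratio test failed)."""


class DegenerateLinesError(RuntimeError):
    """Steep and plateau lines are near-parallel; no stable intersection."""


class InsufficientPointsError(ValueError):
    """Too few points for the requested fit."""


class NoRootInRangeError(RuntimeError):
    """No area in the fitted range carries the requested pressure."""


def amount_to_area(n_nmol, trough_area_cm2: float):
    """Mean area per lipid (Å²) from the spread amount (nmol) at fixed
    trough area (cm²): A = trough·10¹⁶ Å²/cm² / (n·10⁻⁹·N_A)."""
    n = np.asarray(n_nmol, dtype=float)
    return trough_area_cm2 * 1e16 / (n * 1e-9 * N_A)


@dataclass(frozen=True)
class PressureAmountIsotherm:
    """Raw π(n) record: surface pressure vs total lipid spread at fixed
    trough area."""

    n_nmol: tuple[float, ...]
    pi_mNm: tuple[float, ...]
    trough_area_cm2: float
    temperature_K: float = 298.15

    def __post_init__(self) -> None:
        if len(self.n_nmol) != len(self.pi_mNm):
            raise ValidationError("n and pi must have equal length")
        if len(self.n_nmol) < 6:
            raise ValidationError("need at least 6 isotherm points")
        n = np.asarray(self.n_nmol)
        if not np.all(np.diff(n) > 0):
            raise ValidationError("n_nmol must be strictly increasing")
        if np.any(np.asarray(self.pi_mNm) < 0):
            raise ValidationError("surface pressure must be >= 0")
        if not self.trough_area_cm2 > 0:
            raise ValidationError("trough_area_cm2 must be > 0")

    def __len__(self) -> int:
        return len(self.n_nmol)


@dataclass(frozen=True)
class AreaIsotherm:
    """π(A) record: surface pressure vs mean area per lipid (Å²),
    stored with area decreasing as π increases."""

    area_A2: tuple[float, ...]
    pi_mNm: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.area_A2) != len(self.pi_mNm):
            raise ValidationError("area and pi must have equal length")
        if np.any(np.asarray(self.area_A2) <= 0):
            raise ValidationError("areas must be > 0")

    def __len__(self) -> int:
        return len(self.area_A2)

    def sorted_by_area(self) -> "AreaIsotherm":
        order = np.argsort(self.area_A2)
        return AreaIsotherm(
            tuple(np.asarray(self.area_A2)[order]),
            tuple(np.asarray(self.pi_mNm)[order]),
        )


@dataclass(frozen=True)
class SaturationPoint:
    """Two-line intersection result of the constant-area method."""

    n_sat_nmol: float
    pi_sat_mNm: float
    A_sat_A2: float


@dataclass(frozen=True)
class IsothermPolynomial:
    """Polynomial π(A) fitted to the compressed branch of a π–A isotherm.

    ``coeffs`` are in ascending-power order (numpy.polynomial convention).
    """

    coeffs: tuple[float, ...]
    fitted_area_range: tuple[float, float]
    degree: int
    residual_rms: float

    def __call__(self, area_A2):
        return np.polynomial.polynomial.polyval(area_A2, self.coeffs)


def _window_slope(n: np.ndarray, pi: np.ndarray) -> float:
    """OLS slope of pi on n (centered; stable for narrow windows)."""
    nc = n - n.mean()
    denom = float(nc @ nc)
    if denom == 0.0:
        return 0.0
    return float(nc @ (pi - pi.mean())) / denom


def detect_saturation(
    iso: PressureAmountIsotherm,
    plateau_tol_mNm: float = 0.5,
    steep_window: int = 5,
) -> SaturationPoint:
    """Locate the saturation point of a π(n) isotherm by two-line
    intersection.

    The steep line is the least-squares fit through the contiguous window
    (default width 5 points) of maximal slope, ties broken toward larger
    n; the plateau line is the fit through all points with
    π ≥ π_max − plateau_tol (at least 3; the last three points are used
    if fewer qualify).  Requires the steepest slope to exceed 5× the
    final-window slope, otherwise :class:`NoPlateauError` is raised.
    """
    n = np.asarray(iso.n_nmol, dtype=float)
    pi = np.asarray(iso.pi_mNm, dtype=float)
    w = max(2, int(steep_window))
    if len(n) < w + 3:
        raise InsufficientPointsError(
            f"need at least steep_window + 3 = {w + 3} points"
        )

    slopes = np.array(
        [_window_slope(n[i : i + w], pi[i : i + w]) for i in range(len(n) - w + 1)]
    )
    final_slope = slopes[-1]
    max_slope = float(slopes.max())
    if final_slope > 0 and max_slope < 5.0 * final_slope:
        raise NoPlateauError(
            f"max window slope {max_slope:.3g} < 5x final slope {final_slope:.3g}"
        )

    # ties toward larger n: last argmax
    i_steep = int(len(slopes) - 1 - np.argmax(slopes[::-1]))
    steep_n = n[i_steep : i_steep + w]
    steep_pi = pi[i_steep : i_steep + w]
    a1 = _window_slope(steep_n, steep_pi)
    b1 = float(steep_pi.mean() - a1 * steep_n.mean())

    plateau_mask = pi >= pi.max() - plateau_tol_mNm
    if plateau_mask.sum() < 3:
        plateau_mask = np.zeros_like(plateau_mask)
        plateau_mask[-3:] = True
    a2 = _window_slope(n[plateau_mask], pi[plateau_mask])
    b2 = float(pi[plateau_mask].mean() - a2 * n[plateau_mask].mean())

    angle_deg = abs(math.degrees(math.atan(a1) - math.atan(a2)))
    if angle_deg < 1.0:
        raise DegenerateLinesError(
            f"lines nearly parallel (angle {angle_deg:.3g} deg)"
        )

    n_sat = (b2 - b1) / (a1 - a2)
    pi_sat = a1 * n_sat + b1
    return SaturationPoint(
        n_sat_nmol=n_sat,
        pi_sat_mNm=pi_sat,
        A_sat_A2=float(amount_to_area(n_sat, iso.trough_area_cm2)),
    )


def to_area_isotherm(iso: PressureAmountIsotherm) -> AreaIsotherm:
    """Convert π(n) at fixed trough area to π(A) per molecule.

    Point order is reversed so that area decreases as π increases.
    """
    n = np.asarray(iso.n_nmol, dtype=float)
    if np.any(n <= 0):
        raise ValidationError("all n_nmol must be > 0 for area conversion")
    area = amount_to_area(n, iso.trough_area_cm2)
    return AreaIsotherm(tuple(area), tuple(iso.pi_mNm))


def fit_isotherm_polynomial(
    aiso: AreaIsotherm, max_area_A2: float = 100.0, degree: int = 3
) -> IsothermPolynomial:
    """Least-squares polynomial π(A) restricted to A ≤ max_area_A2.

    The restriction to small areas targets the liquid expanded/condensed
    regime where a low-order polynomial describes the compression branch
    well.  Needs at least ``degree + 2`` qualifying points.
    """
    area = np.asarray(aiso.area_A2, dtype=float)
    pi = np.asarray(aiso.pi_mNm, dtype=float)
    mask = area <= max_area_A2
    if mask.sum() < degree + 2:
        raise InsufficientPointsError(
            f"polynomial of degree {degree} needs >= {degree + 2} points "
            f"with area <= {max_area_A2} (got {int(mask.sum())})"
        )
    a_sel, pi_sel = area[mask], pi[mask]
    series = np.polynomial.Polynomial.fit(a_sel, pi_sel, deg=degree)
    coeffs = series.convert().coef
    resid = pi_sel - np.polynomial.polynomial.polyval(a_sel, coeffs)
    return IsothermPolynomial(
        coeffs=tuple(coeffs),
        fitted_area_range=(float(a_sel.min()), float(a_sel.max())),
        degree=degree,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def area_at_pressure(model: IsothermPolynomial, pi_mNm: float = 30.0) -> float:
    """Area per lipid (Å²) at the given lateral pressure.

    Solves π(A) = π for real roots inside the fitted range lying on a
    branch where π decreases with A (compression behaviour); with several
    such roots the largest area is returned.
    """
    lo, hi = model.fitted_area_range
    pi_range = np.polynomial.polynomial.polyval(np.array([lo, hi]), model.coeffs)
    if not (min(pi_range) - 1e-9 <= pi_mNm <= max(pi_range) + 1e-9):
        raise NoRootInRangeError(
            f"pi = {pi_mNm} outside fitted pressure range "
            f"[{min(pi_range):.3g}, {max(pi_range):.3g}]"
        )
    shifted = np.array(model.coeffs, dtype=float)
    shifted[0] -= pi_mNm
    roots = np.polynomial.polynomial.polyroots(shifted)
    deriv = np.polynomial.polynomial.polyder(np.array(model.coeffs, dtype=float))
    candidates = [
        float(r.real)
        for r in roots
        if abs(r.imag) < 1e-9
        and lo - 1e-9 <= r.real <= hi + 1e-9
        and np.polynomial.polynomial.polyval(r.real, deriv) < 0
    ]
    if not candidates:
        raise NoRootInRangeError(
            f"no decreasing-branch root of pi(A) = {pi_mNm} in [{lo:.3g}, {hi:.3g}]"
        )
    return max(candidates)
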