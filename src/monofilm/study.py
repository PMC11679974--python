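"""The study dataset: measured inputs for the eleven monolayer systems.

These are the measured (or literature-sourced) inputs of the monolayer
campaign this package analyses: for each lipid composition, the mean area
per lipid at 30 mN/m and at the saturation pressure, the saturation
pressure where determined, and the dipole potential at saturation.  For
charged films the tabulated potential is the *dipole* potential, i.e.
already corrected for the diffuse-layer surface term; ψ_measured is
back-computed here from the Grahame solver so that :func:`study_records`
exercises the full forward analysis.

The SpM:Chol 6:4 film has no saturation area determination; its dipole
moment and 30 mN/m potential are carried as reported values (the pair is
not exactly Helmholtz-consistent with its tabulated 39 Å² area — an
inconsistency of the source data that is preserved, not repaired).
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import Composition, Registry, Subphase, make_study_registry
from .electrostatics import (
    MonolayerRecord,
    analyze_monolayer,
    grahame_psi0,
    surface_charge_density,
)

__all__ = ["StudyRow", "STUDY_TABLE", "study_records", "study_bilayer_pair"]


@dataclass(frozen=True)
class StudyRow:
    """Measured inputs for one film (areas in Å², potentials in mV)."""

    name: str
    lipids: tuple[str, ...]
    ratio: tuple[float, ...]
    area30_A2: float
    area_sat_A2: float | None
    pi_sat_mNm: float | None
    psi_dipole_sat_mV: float
    # reported-value fallbacks for films without a saturation area
    mu_eq1_mD: float | None = None
    psi30_eq1_mV: float | None = None
    mu_eq2_mD: float | None = None
    psi30_eq2_mV: float | None = None


#: Measured inputs for the eleven study systems.
STUDY_TABLE: tuple[StudyRow, ...] = (
    StudyRow("POPC", ("POPC",), (1,), 64.5, 49.4, 50.0, 417.0),
    StudyRow("POPS", ("POPS",), (1,), 55.0, 44.0, None, 465.0),
    StudyRow("POPE", ("POPE",), (1,), 56.0, 42.0, None, 494.0),
    StudyRow("SpM", ("SpM",), (1,), 48.0, 42.0, None, 341.0),
    StudyRow("POPC:POPS (9:1)", ("POPC", "POPS"), (9, 1), 69.8, 51.0, 51.0, 441.0),
    StudyRow("POPC:POPE (8:2)", ("POPC", "POPE"), (8, 2), 59.6, 45.4, 47.0, 424.0),
    StudyRow("POPC:CHOL (7:3)", ("POPC", "cholesterol"), (7, 3), 48.0, 45.0, None, 463.0),
    StudyRow("POPC:CHOL (5:5)", ("POPC", "cholesterol"), (5, 5), 44.0, 43.0, None, 490.0),
    StudyRow(
        "POPC:CHOL:POPE (5:3:2)",
        ("POPC", "cholesterol", "POPE"),
        (5, 3, 2),
        56.0,
        46.4,
        46.0,
        481.0,
    ),
    StudyRow(
        "POPC:CHOL:POPE:POPS (4:3:2:1) inner",
        ("POPC", "cholesterol", "POPE", "POPS"),
        (4, 3, 2, 1),
        61.5,
        49.7,
        49.0,
        474.0,
    ),
    StudyRow(
        "SpM:CHOL (6:4) outer",
        ("SpM", "cholesterol"),
        (6, 4),
        39.0,
        None,
        None,
        408.0,
        mu_eq1_mD=379.0,
        psi30_eq1_mV=357.0,
        mu_eq2_mD=286.0,
        psi30_eq2_mV=370.0,
    ),
)


def _composition(row: StudyRow, registry: Registry) -> Composition:
    return Composition.from_ratio([registry[n] for n in row.lipids], row.ratio)


def study_records(
    registry: Registry | None = None,
    subphase: Subphase | None = None,
    delta_V0_mV: float = 100.0,
) -> list[MonolayerRecord]:
    """Analyze all study films through the forward pipeline.

    For films with a saturation area the record is computed end to end
    (σ → ψ0 → ψd_sat → μ⊥ → ψd30*); films without one carry their
    reported dipole moments and 30 mN/m potentials directly.
    """
    if registry is None or subphase is None:
        default_registry, default_sub = make_study_registry()
        registry = registry or default_registry
        subphase = subphase or default_sub

    records: list[MonolayerRecord] = []
    for row in STUDY_TABLE:
        comp = _composition(row, registry)
        if row.area_sat_A2 is not None:
            # back out psi_measured so analyze_monolayer runs forward
            sigma = surface_charge_density(row.area_sat_A2, comp)
            psi0 = grahame_psi0(sigma, subphase)
            rec = analyze_monolayer(
                comp,
                psi_measured_mV=row.psi_dipole_sat_mV + psi0,
                area_sat_A2=row.area_sat_A2,
                area30_A2=row.area30_A2,
                subphase=subphase,
                delta_V0_mV=delta_V0_mV,
                name=row.name,
            )
        else:
            rec = MonolayerRecord(
                composition=comp,
                psi_measured_mV=row.psi_dipole_sat_mV,
                psi0_mV=0.0,
                psi_dipole_sat_mV=row.psi_dipole_sat_mV,
                area_sat_A2=None,
                area30_A2=row.area30_A2,
                mu_eq1_mD=row.mu_eq1_mD,
                mu_eq2_mD=row.mu_eq2_mD,
                psi30_eq1_mV=row.psi30_eq1_mV,
                psi30_eq2_mV=row.psi30_eq2_mV,
                delta_V0_mV=delta_V0_mV,
                name=row.name,
            )
        records.append(rec)
    return records


def study_bilayer_pair(
    records: list[MonolayerRecord] | None = None,
) -> tuple[MonolayerRecord, MonolayerRecord]:
    """(inner, outer) leaflet records of the plasma-membrane model:
    PC:Chol:PE:PS 4:3:2:1 inner, SpM:Chol 6:4 outer."""
    records = records if records is not None else study_records()
    by_name = {r.label: r for r in records}
    return (
        by_name["POPC:CHOL:POPE:POPS (4:3:2:1) inner"],
        by_name["SpM:CHOL (6:4) outer"],
    )
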