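"""Readers, writers, configuration and the end-to-end pipeline.

Tables are plain delimited text (comma or tab, auto-detected) with
unit-bearing column names (``area_A2``, ``pi_mN_per_m``, ``psi_mV``…) so
a file can never be mis-read in the wrong unit system.  Metadata such as
the trough area rides in ``# key = value`` comment lines.  All rounding
happens at serialization; in-memory values keep full precision.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .bilayer import BilayerModel, bilayer_summary
from .core import (
    Composition,
    Registry,
    Subphase,
    ValidationError,
    make_study_registry,
)
from .electrostatics import MonolayerRecord, analyze_monolayer, round_half_away
from .isotherm import AreaIsotherm, PressureAmountIsotherm
from .synthetic import SyntheticTruth

__all__ = [
    "SchemaError",
    "read_isotherm_table",
    "write_isotherm_table",
    "records_to_frame",
    "write_records",
    "read_records",
    "report_table",
    "parse_composition",
    "write_truth_sidecar",
    "read_truth_sidecar",
    "StudyConfig",
    "load_config",
    "MeasurementInput",
    "PipelineReport",
    "run_pipeline",
]


class SchemaError(ValueError):
    """A table is missing a required, unit-annotated column."""


_AMOUNT_COLS = {"n_nmol", "pi_mN_per_m"}
_AREA_COLS = {"area_A2", "pi_mN_per_m"}


def _read_metadata(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                key, _, value = line.lstrip("# ").partition("=")
                meta[key.strip()] = value.strip()
    return meta


def read_isotherm_table(
    path, trough_area_cm2: float | None = None, temperature_K: float | None = None
) -> PressureAmountIsotherm | AreaIsotherm:
    """Read a π(n) or π(A) table; the header decides the variant.

    π(n) tables need a trough area, either as an argument or as a
    ``# trough_area_cm2 = …`` comment line in the file.
    """
    path = Path(path)
    meta = _read_metadata(path)
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    cols = set(df.columns)
    if "pi_mN_per_m" not in cols:
        raise SchemaError("missing required column 'pi_mN_per_m'")
    if (df["pi_mN_per_m"] < 0).any():
        raise ValidationError("negative surface pressure in table")
    if "n_nmol" in cols:
        trough = trough_area_cm2 or float(meta.get("trough_area_cm2", 0) or 0)
        if not trough:
            raise SchemaError(
                "pi(n) table needs trough_area_cm2 (argument or '# trough_area_cm2 = ...')"
            )
        temp = temperature_K or float(meta.get("temperature_K", 298.15))
        return PressureAmountIsotherm(
            n_nmol=tuple(df["n_nmol"].astype(float)),
            pi_mNm=tuple(df["pi_mN_per_m"].astype(float)),
            trough_area_cm2=trough,
            temperature_K=temp,
        )
    if "area_A2" in cols:
        return AreaIsotherm(
            area_A2=tuple(df["area_A2"].astype(float)),
            pi_mNm=tuple(df["pi_mN_per_m"].astype(float)),
        )
    raise SchemaError(
        f"table must contain 'n_nmol' or 'area_A2' (found {sorted(cols)})"
    )


def write_isotherm_table(
    iso: PressureAmountIsotherm | AreaIsotherm, path, sep: str = ","
) -> None:
    """Write an isotherm in the same schema :func:`read_isotherm_table`
    consumes, at 12 significant digits."""
    path = Path(path)
    with open(path, "w") as fh:
        if isinstance(iso, PressureAmountIsotherm):
            fh.write(f"# trough_area_cm2 = {iso.trough_area_cm2!r}\n")
            fh.write(f"# temperature_K = {iso.temperature_K!r}\n")
            df = pd.DataFrame({"n_nmol": iso.n_nmol, "pi_mN_per_m": iso.pi_mNm})
        else:
            df = pd.DataFrame({"area_A2": iso.area_A2, "pi_mN_per_m": iso.pi_mNm})
        df.to_csv(fh, sep=sep, index=False, float_format="%.12g")


_RECORD_COLUMNS = [
    "composition",
    "psi_measured_mV",
    "A_sat_A2",
    "A30_A2",
    "psi0_mV",
    "psi_dipole_sat_mV",
    "mu_eq1_mD",
    "psi30_eq1_mV",
    "mu_eq2_mD",
    "psi30_eq2_mV",
]


def records_to_frame(records: Iterable[MonolayerRecord]) -> pd.DataFrame:
    """Flat table of analyzed films (machine twin of the report tables)."""
    rows = []
    for r in records:
        rows.append(
            {
                "composition": r.label,
                "psi_measured_mV": r.psi_measured_mV,
                "A_sat_A2": r.area_sat_A2,
                "A30_A2": r.area30_A2,
                "psi0_mV": r.psi0_mV,
                "psi_dipole_sat_mV": r.psi_dipole_sat_mV,
                "mu_eq1_mD": r.mu_eq1_mD,
                "psi30_eq1_mV": r.psi30_eq1_mV,
                "mu_eq2_mD": r.mu_eq2_mD,
                "psi30_eq2_mV": r.psi30_eq2_mV,
            }
        )
    return pd.DataFrame(rows, columns=_RECORD_COLUMNS)


def write_records(records: Iterable[MonolayerRecord], path, sep: str = ",") -> None:
    records_to_frame(records).to_csv(
        path, sep=sep, index=False, float_format="%.12g"
    )


def read_records(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    missing = set(_RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"record table missing columns {sorted(missing)}")
    return df


def report_table(records: Iterable[MonolayerRecord]) -> pd.DataFrame:
    """Reporting view with μ⊥ and potentials rounded to integers
    (halves away from zero), the field's tabulation convention."""
    df = records_to_frame(records)
    out = df[["composition", "A30_A2", "A_sat_A2"]].copy()
    for col in (
        "psi_dipole_sat_mV",
        "mu_eq1_mD",
        "psi30_eq1_mV",
        "mu_eq2_mD",
        "psi30_eq2_mV",
    ):
        out[col] = [
            round_half_away(v) if pd.notna(v) else pd.NA for v in df[col]
        ]
    return out


def parse_composition(spec: str, registry: Registry) -> Composition:
    """Parse ``"POPC:CHOL (7:3)"``, ``"POPC:CHOL 7:3"`` or
    ``"POPC=0.7,CHOL=0.3"`` into a :class:`Composition`."""
    spec = spec.strip()
    if "=" in spec:
        parts = [p for p in spec.replace(";", ",").split(",") if p.strip()]
        species, fracs = [], []
        for part in parts:
            name, _, value = part.partition("=")
            species.append(registry[name.strip()])
            fracs.append(float(value))
        return Composition.from_ratio(species, fracs)
    if "(" in spec:
        names_part, _, ratio_part = spec.partition("(")
        ratio_part = ratio_part.rstrip(") ")
    else:
        pieces = spec.rsplit(None, 1)
        if len(pieces) == 2 and any(c.isdigit() for c in pieces[1]):
            names_part, ratio_part = pieces
        else:
            names_part, ratio_part = spec, ""
    names = [n for n in names_part.strip().split(":") if n]
    species = [registry[n] for n in names]
    if not ratio_part:
        if len(species) != 1:
            raise ValidationError(f"composition {spec!r} needs a ratio")
        return Composition.pure(species[0])
    ratios = [float(r) for r in ratio_part.split(":")]
    return Composition.from_ratio(species, ratios)


def write_truth_sidecar(truth: SyntheticTruth, path) -> None:
    """Flat key = value sidecar recording a generator's ground truth."""
    with open(path, "w") as fh:
        fh.write(f"A_sat_A2 = {truth.A_sat_A2!r}\n")
        fh.write(f"pi_sat_mNm = {truth.pi_sat_mNm!r}\n")
        fh.write(f"mu_mD = {truth.mu_mD!r}\n")
        fh.write(f"delta_V0_mV = {truth.delta_V0_mV!r}\n")
        fh.write(f"noise_sd_pi_mNm = {truth.noise_sd_pi_mNm!r}\n")
        fh.write(f"noise_sd_psi_mV = {truth.noise_sd_psi_mV!r}\n")
        fh.write(f"seed = {truth.seed!r}\n")
        fh.write(
            "poly_coeffs = "
            + ",".join(repr(float(c)) for c in truth.poly_coeffs)
            + "\n"
        )


def read_truth_sidecar(path) -> SyntheticTruth:
    fields: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            key, _, value = line.partition("=")
            fields[key.strip()] = value.strip()
    return SyntheticTruth(
        A_sat_A2=float(fields["A_sat_A2"]),
        pi_sat_mNm=float(fields["pi_sat_mNm"]),
        poly_coeffs=tuple(float(c) for c in fields["poly_coeffs"].split(",")),
        mu_mD=float(fields["mu_mD"]),
        delta_V0_mV=float(fields["delta_V0_mV"]),
        noise_sd_pi_mNm=float(fields["noise_sd_pi_mNm"]),
        noise_sd_psi_mV=float(fields["noise_sd_psi_mV"]),
        seed=int(fields["seed"]),
    )


# ---------------------------------------------------------------------------
# Configuration and pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeasurementInput:
    """Per-film measured inputs handed to :func:`run_pipeline`."""

    name: str
    composition: str
    psi_measured_mV: float
    area_sat_A2: float
    area30_A2: float


@dataclass
class StudyConfig:
    """Analysis configuration (YAML-serializable).

    ``lipids`` may extend or override the built-in registry;
    ``measurements`` lists the films to analyze; ``options`` collects
    the numerical knobs (ΔV0, εr, polynomial degree, plateau tolerance).
    """

    lipids: list[dict] = field(default_factory=list)
    measurements: list[MeasurementInput] = field(default_factory=list)
    delta_V0_mV: float = 100.0
    rel_permittivity: float = 78.5
    temperature_K: float = 298.15
    extended_buffer: bool = False
    polynomial_degree: int = 3
    plateau_tol_mNm: float = 0.5


def load_config(path) -> StudyConfig:
    """Load a :class:`StudyConfig` from YAML."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    opts = raw.get("options", {})
    measurements = [
        MeasurementInput(
            name=m.get("name", m["composition"]),
            composition=m["composition"],
            psi_measured_mV=float(m["psi_measured_mV"]),
            area_sat_A2=float(m["area_sat_A2"]),
            area30_A2=float(m["area30_A2"]),
        )
        for m in raw.get("measurements", [])
    ]
    return StudyConfig(
        lipids=raw.get("lipids", []),
        measurements=measurements,
        delta_V0_mV=float(opts.get("delta_V0_mV", 100.0)),
        rel_permittivity=float(opts.get("rel_permittivity", 78.5)),
        temperature_K=float(opts.get("temperature_K", 298.15)),
        extended_buffer=bool(opts.get("extended_buffer", False)),
        polynomial_degree=int(opts.get("polynomial_degree", 3)),
        plateau_tol_mNm=float(opts.get("plateau_tol_mNm", 0.5)),
    )


@dataclass
class PipelineReport:
    """Bundle emitted by :func:`run_pipeline`."""

    records: list[MonolayerRecord]
    measured_table: pd.DataFrame  # areas and dipole potentials at saturation
    derived_table: pd.DataFrame  # mu and 30 mN/m potentials, both variants
    errors: list[tuple[str, str]]
    summary: dict | None = None


def run_pipeline(
    config: StudyConfig,
    registry: Registry | None = None,
    subphase: Subphase | None = None,
    bilayer_pair: tuple[str, str] | None = None,
) -> PipelineReport:
    """Analyze every configured film and assemble the report tables.

    A film that fails validation or root finding is recorded in
    ``errors`` and skipped; the rest of the run proceeds.
    """
    from .core import LipidSpecies, default_subphase

    if registry is None:
        registry, _ = make_study_registry()
        for entry in config.lipids:
            registry.add(
                LipidSpecies(
                    entry["name"],
                    int(entry.get("formal_charge", 0)),
                    entry.get("ref_area_A2"),
                    entry.get("ref_dipole_mD"),
                )
            )
    if subphase is None:
        subphase = default_subphase(
            temperature_K=config.temperature_K,
            rel_permittivity=config.rel_permittivity,
            extended_buffer=config.extended_buffer,
        )

    records: list[MonolayerRecord] = []
    errors: list[tuple[str, str]] = []
    for m in config.measurements:
        try:
            comp = parse_composition(m.composition, registry)
            records.append(
                analyze_monolayer(
                    comp,
                    m.psi_measured_mV,
                    m.area_sat_A2,
                    m.area30_A2,
                    subphase,
                    delta_V0_mV=config.delta_V0_mV,
                    name=m.name,
                )
            )
        except Exception as exc:  # per-film isolation
            errors.append((m.name, f"{type(exc).__name__}: {exc}"))

    frame = records_to_frame(records)
    measured = frame[
        ["composition", "A30_A2", "A_sat_A2", "psi0_mV", "psi_dipole_sat_mV"]
    ].copy()
    derived = report_table(records)

    summary = None
    if bilayer_pair is not None and len(records) >= 3:
        by_name = {r.label: r for r in records}
        try:
            model = BilayerModel(
                inner=by_name[bilayer_pair[0]], outer=by_name[bilayer_pair[1]]
            )
            summary = bilayer_summary(records, model)
        except KeyError as exc:
            errors.append(("bilayer", f"missing leaflet record {exc}"))
    return PipelineReport(
        records=records,
        measured_table=measured,
        derived_table=derived,
        errors=errors,
        summary=summary,
    )
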