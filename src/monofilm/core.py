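"""Domain types shared across the package.

A :class:`LipidSpecies` is a lipid identified by name, carrying its formal
charge and, optionally, reference values (area per molecule, transverse
dipole moment) used by the mixture-additivity predictions.  A
:class:`Composition` is a mole-fraction mixture of species — one monolayer
leaflet.  A :class:`Subphase` describes the aqueous electrolyte underneath
the film, which the Gouy–Chapman/Grahame solver needs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid species.

    Parameters
    ----------
    name:
        Non-empty identifier, e.g. ``"POPC"``.
    formal_charge:
        Elementary charges per molecule (−1 for fully ionized POPS,
        0 for zwitterionic or neutral lipids).
    ref_area_A2:
        Optional reference area per molecule in Å², used by additivity
        predictions when the species was not measured as a pure film
        (e.g. 30 Å² for cholesterol).
    ref_dipole_mD:
        Optional reference transverse dipole moment in millidebye
        (e.g. 373 mD for cholesterol).
    """

    name: str
    formal_charge: int = 0
    ref_area_A2: float | None = None
    ref_dipole_mD: float | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("lipid name must be non-empty")
        if self.ref_area_A2 is not None and not self.ref_area_A2 > 0:
            raise ValidationError(f"{self.name}: ref_area_A2 must be > 0")
        if self.ref_dipole_mD is not None and not math.isfinite(self.ref_dipole_mD):
            raise ValidationError(f"{self.name}: ref_dipole_mD must be finite")


#: sum-to-one tolerance for mole fractions
_FRACTION_TOL = 1e-9


@dataclass(frozen=True)
class Composition:
    """Mole-fraction mixture of lipid species (one leaflet).

    Fractions must be non-negative and sum to 1 within 1e-9; species may
    not repeat.  Use :meth:`from_ratio` for the conventional ratio
    notation (``7:3``) used for monolayer mixtures.
    """

    components: tuple[tuple[LipidSpecies, float], ...]

    def __post_init__(self) -> None:
        names = [sp.name for sp, _ in self.components]
        if len(set(names)) != len(names):
            raise ValidationError(f"repeated species in composition: {names}")
        fractions = [x for _, x in self.components]
        if any(x < 0 for x in fractions):
            raise ValidationError("mole fractions must be >= 0")
        total = sum(fractions)
        if abs(total - 1.0) > _FRACTION_TOL:
            raise ValidationError(
                f"mole fractions must sum to 1 (got {total!r}); "
                "normalize ratios with Composition.from_ratio"
            )

    @classmethod
    def from_ratio(
        cls, species: Sequence[LipidSpecies], ratios: Sequence[float]
    ) -> "Composition":
        """Build a composition from mole *ratios* (e.g. ``[7, 3]``)."""
        if len(species) != len(ratios):
            raise ValidationError("species and ratios must have equal length")
        total = float(sum(ratios))
        if not total > 0:
            raise ValidationError("ratios must have a positive sum")
        return cls(tuple((sp, r / total) for sp, r in zip(species, ratios)))

    @classmethod
    def pure(cls, species: LipidSpecies) -> "Composition":
        return cls(((species, 1.0),))

    @property
    def species(self) -> tuple[LipidSpecies, ...]:
        return tuple(sp for sp, _ in self.components)

    @property
    def fractions(self) -> tuple[float, ...]:
        return tuple(x for _, x in self.components)

    def fraction_of(self, name: str) -> float:
        for sp, x in self.components:
            if sp.name == name:
                return x
        return 0.0

    @property
    def mean_charge(self) -> float:
        """Mole-fraction-weighted formal charge, Σ xᵢ·zᵢ (elementary charges)."""
        return sum(x * sp.formal_charge for sp, x in self.components)

    def label(self) -> str:
        if len(self.components) == 1:
            return self.components[0][0].name
        names = ":".join(sp.name for sp, _ in self.components)
        fracs = ":".join(f"{x:g}" for _, x in self.components)
        return f"{names} ({fracs})"


@dataclass(frozen=True)
class ElectrolyteSpecies:
    """One ionic species of the subphase: valence ``z`` and bulk
    concentration in mol/L."""

    name: str
    z: int
    conc_M: float

    def __post_init__(self) -> None:
        if self.conc_M < 0:
            raise ValidationError(f"{self.name}: concentration must be >= 0")
        if self.z != 0 and not math.isfinite(self.conc_M):
            raise ValidationError(f"{self.name}: charged species needs finite conc")


@dataclass(frozen=True)
class Subphase:
    """Aqueous electrolyte under the monolayer.

    Electroneutrality (Σ zᵢCᵢ = 0) is enforced at construction; pass
    ``auto_balance=True`` to :meth:`balanced` to add a monovalent
    counter-ion instead of raising.
    """

    species: tuple[ElectrolyteSpecies, ...]
    temperature_K: float = 298.15
    rel_permittivity: float = 78.5

    def __post_init__(self) -> None:
        if not self.temperature_K > 0:
            raise ValidationError("temperature_K must be > 0")
        if not self.rel_permittivity > 1:
            raise ValidationError("rel_permittivity must be > 1")
        imbalance = sum(s.z * s.conc_M for s in self.species)
        if abs(imbalance) > _FRACTION_TOL:
            raise ValidationError(
                f"subphase not electroneutral (sum z*C = {imbalance:g} M); "
                "use Subphase.balanced to auto-add a counter-ion"
            )

    @classmethod
    def balanced(
        cls,
        species: Iterable[ElectrolyteSpecies],
        temperature_K: float = 298.15,
        rel_permittivity: float = 78.5,
    ) -> "Subphase":
        """Construct a subphase, adding a monovalent counter-ion if needed."""
        species = tuple(species)
        imbalance = sum(s.z * s.conc_M for s in species)
        if imbalance > _FRACTION_TOL:
            species += (ElectrolyteSpecies("counter-", -1, imbalance),)
        elif imbalance < -_FRACTION_TOL:
            species += (ElectrolyteSpecies("counter+", +1, -imbalance),)
        return cls(species, temperature_K, rel_permittivity)

    @property
    def ionic_strength_M(self) -> float:
        return 0.5 * sum(s.conc_M * s.z**2 for s in self.species)


class Registry:
    """Name-keyed lipid registry with the aliases common in the field
    (``CHOL``/``Chol`` for cholesterol, ``SPM`` for sphingomyelin)."""

    _ALIASES = {
        "chol": "cholesterol",
        "c": "cholesterol",
        "spm": "SpM",
        "sphingomyelin": "SpM",
    }

    def __init__(self, species: Iterable[LipidSpecies] = ()) -> None:
        self._by_name: dict[str, LipidSpecies] = {}
        for sp in species:
            self.add(sp)

    def _canonical(self, name: str) -> str:
        key = self._ALIASES.get(name.lower(), name)
        for existing in self._by_name:
            if existing.lower() == key.lower():
                return existing
        return key

    def add(self, species: LipidSpecies) -> None:
        key = self._canonical(species.name)
        if key in self._by_name:
            raise ValidationError(f"species {species.name!r} already registered")
        self._by_name[species.name] = species

    def __getitem__(self, name: str) -> LipidSpecies:
        key = self._canonical(name)
        try:
            return self._by_name[key]
        except KeyError:
            raise KeyError(
                f"unknown lipid {name!r}; known: {sorted(self._by_name)}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return self._canonical(name) in self._by_name

    def __iter__(self):
        return iter(self._by_name.values())

    def names(self) -> list[str]:
        return sorted(self._by_name)


def default_subphase(
    temperature_K: float = 298.15,
    rel_permittivity: float = 78.5,
    extended_buffer: bool = False,
) -> Subphase:
    """The study subphase: 150 mM NaCl as a 1:1 electrolyte at 25 °C.

    With ``extended_buffer=True`` an approximate speciation of the full
    buffer (HEPES 10 mM, EDTA 1 mM at pH 7.4, Na⁺-balanced) is added.
    HEPES (pKa₂ ≈ 7.5) is ≈ 44 % anionic at pH 7.4; EDTA is dominantly
    HEDTA³⁻.  The extra ions shift |ψ0| by only a few mV at physiological
    charge densities, which is why the plain 1:1 salt is the default.
    """
    species = [
        ElectrolyteSpecies("Na+", +1, 0.150),
        ElectrolyteSpecies("Cl-", -1, 0.150),
    ]
    if extended_buffer:
        hepes_anion = 0.010 / (1.0 + 10 ** (7.5 - 7.4))  # one-site H-H
        species += [
            ElectrolyteSpecies("HEPES-", -1, hepes_anion),
            ElectrolyteSpecies("HEDTA3-", -3, 0.001),
        ]
        return Subphase.balanced(species, temperature_K, rel_permittivity)
    return Subphase(tuple(species), temperature_K, rel_permittivity)


def make_study_registry(
    extended_buffer: bool = False,
) -> tuple[Registry, Subphase]:
    """Lipids of the study plus its default subphase.

    POPC, POPE and SpM are zwitterionic (z = 0); POPS is treated as fully
    ionized (z = −1); cholesterol is neutral and carries the literature
    reference values used by the additivity analysis (30 Å², 373 mD).
    """
    registry = Registry(
        [
            LipidSpecies("POPC", 0),
            LipidSpecies("POPE", 0),
            LipidSpecies("POPS", -1),
            LipidSpecies("SpM", 0),
            LipidSpecies("cholesterol", 0, ref_area_A2=30.0, ref_dipole_mD=373.0),
        ]
    )
    return registry, default_subphase(extended_buffer=extended_buffer)


__all__ = [
    "ValidationError",
    "LipidSpecies",
    "Composition",
    "ElectrolyteSpecies",
    "Subphase",
    "Registry",
    "default_subphase",
    "make_study_registry",
]
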