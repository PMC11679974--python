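import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from monofilm import (
    Composition,
    ElectrolyteSpecies,
    Subphase,
    ValidationError,
    analyze_monolayer,
    correct_measured_potential,
    grahame_psi0,
    grahame_sigma,
    helmholtz_dipole,
    helmholtz_potential,
    round_half_away,
    surface_charge_density,
)
from monofilm.constants import EPS0, F, R


def closed_form_psi0_1to1(sigma, conc_M, temperature_K=298.15, eps_r=78.5):
    """Independent analytic solution for a single 1:1 electrolyte."""
    rt = R * temperature_K
    return (
        2e3
        * rt
        / F
        * math.asinh(sigma / math.sqrt(8000.0 * EPS0 * eps_r * rt * conc_M))
    )


class TestHelmholtz:
    @pytest.mark.parametrize(
        "mu, area, v0, expected_mV",
        [
            (546.43, 64.5, 0.0, 319),  # POPC at 30 mN/m
            (415.39, 64.5, 100.0, 343),  # POPC with offset
        ],
    )
    def test_forward_matches_tabulated_integers(self, mu, area, v0, expected_mV):
        assert round_half_away(helmholtz_potential(mu, area, v0)) == expected_mV

    def test_zero_dipole_returns_offset(self):
        assert helmholtz_potential(0.0, 57.3, 100.0) == 100.0

    @pytest.mark.parametrize(
        "psi, area, v0, expected_mD",
        [
            (417.0, 49.4, 0.0, 546),  # POPC at saturation
            (494.0, 42.0, 100.0, 439),  # POPE with offset
        ],
    )
    def test_inverse_matches_tabulated_integers(self, psi, area, v0, expected_mD):
        assert round_half_away(helmholtz_dipole(psi, area, v0)) == expected_mD

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValidationError):
            helmholtz_potential(500.0, 0.0)
        with pytest.raises(ValidationError):
            helmholtz_dipole(400.0, -3.0)

    @given(
        mu=st.floats(min_value=-2000, max_value=2000),
        area=st.floats(min_value=1.0, max_value=500.0),
        v0=st.floats(min_value=-200, max_value=200),
    )
    @settings(max_examples=200, deadline=None)
    def test_round_trip_exact(self, mu, area, v0):
        back = helmholtz_dipole(helmholtz_potential(mu, area, v0), area, v0)
        assert back == pytest.approx(mu, rel=1e-12, abs=1e-9)


class TestSurfaceCharge:
    def test_pure_anionic_film(self, registry):
        comp = Composition.pure(registry["POPS"])
        sigma = surface_charge_density(49.4, comp)
        assert sigma == pytest.approx(-0.32433, abs=1e-4)

    def test_neutral_film_is_uncharged(self, registry):
        assert surface_charge_density(64.5, Composition.pure(registry["POPC"])) == 0.0

    def test_dilute_anionic_mixture(self, registry):
        comp = Composition.from_ratio([registry["POPC"], registry["POPS"]], [9, 1])
        assert surface_charge_density(49.7, comp) == pytest.approx(
            -0.03224, abs=2e-5
        )


class TestGrahame:
    def test_uncharged_surface(self, subphase):
        assert grahame_psi0(0.0, subphase) == 0.0

    def test_pops_surface_potential(self, subphase):
        psi0 = grahame_psi0(-0.32433, subphase)
        assert psi0 == pytest.approx(-136.8, abs=0.1)

    @pytest.mark.parametrize("sigma", [-0.5, -0.1, -0.01, 0.01, 0.1, 0.5])
    @pytest.mark.parametrize("conc", [0.001, 0.010, 0.150, 0.500])
    def test_agrees_with_closed_form_1to1(self, sigma, conc):
        sub = Subphase(
            (
                ElectrolyteSpecies("M+", 1, conc),
                ElectrolyteSpecies("X-", -1, conc),
            )
        )
        assert grahame_psi0(sigma, sub) == pytest.approx(
            closed_form_psi0_1to1(sigma, conc), abs=1e-6
        )

    def test_odd_symmetry_for_symmetric_electrolyte(self, subphase):
        psi = grahame_psi0(0.3243, subphase)
        assert psi == pytest.approx(-grahame_psi0(-0.3243, subphase), abs=1e-9)
        assert psi > 0

    def test_screening_increases_with_salt(self):
        psis = []
        for conc in (0.01, 0.05, 0.150, 0.500):
            sub = Subphase(
                (
                    ElectrolyteSpecies("M+", 1, conc),
                    ElectrolyteSpecies("X-", -1, conc),
                )
            )
            psis.append(abs(grahame_psi0(-0.3243, sub)))
        assert all(a > b for a, b in zip(psis, psis[1:]))

    def test_psi0_vanishes_with_charge(self, subphase):
        assert abs(grahame_psi0(-1e-9, subphase)) < 1e-3

    def test_asymmetric_multivalent_residual(self):
        sub = Subphase.balanced(
            [
                ElectrolyteSpecies("Ca2+", 2, 0.005),
                ElectrolyteSpecies("Na+", 1, 0.140),
                ElectrolyteSpecies("SO4 2-", -2, 0.010),
            ]
        )
        sigma = -0.2
        psi0 = grahame_psi0(sigma, sub)
        assert abs(grahame_sigma(psi0, sub) - sigma) < 1e-10

    def test_requires_ions_for_charged_surface(self):
        pure_water = Subphase(())
        with pytest.raises(ValidationError):
            grahame_psi0(-0.1, pure_water)


class TestMeasuredPotentialCorrection:
    def test_anionic_film_correction(self):
        # a film measured at 330 mV over a -135 mV double layer
        assert correct_measured_potential(330.0, -135.0) == 465.0

    def test_neutral_film_unchanged(self):
        assert correct_measured_potential(417.0, 0.0) == 417.0

    def test_dipole_potential_grows_as_psi0_drops(self):
        values = [correct_measured_potential(400.0, p) for p in (0.0, -50.0, -135.0)]
        assert values == sorted(values)


class TestAnalyzeMonolayer:
    def test_neutral_popc_film(self, registry, subphase):
        rec = analyze_monolayer(
            Composition.pure(registry["POPC"]), 417.0, 49.4, 64.5, subphase
        )
        assert rec.psi0_mV == 0.0
        assert round_half_away(rec.mu_eq1_mD) == 546
        assert round_half_away(rec.psi30_eq1_mV) == 319

    def test_charged_quaternary_film(self, registry, subphase):
        comp = Composition.from_ratio(
            [registry[n] for n in ("POPC", "cholesterol", "POPE", "POPS")],
            [4, 3, 2, 1],
        )
        # measured potential back-computed so psi_d_sat = 474 mV
        psi0 = grahame_psi0(surface_charge_density(49.7, comp), subphase)
        rec = analyze_monolayer(comp, 474.0 + psi0, 49.7, 61.5, subphase)
        assert rec.psi0_mV < 0
        assert rec.psi_dipole_sat_mV == pytest.approx(474.0)
        assert round_half_away(rec.mu_eq1_mD) == 625
        assert round_half_away(rec.psi30_eq1_mV) == 383

    def test_zero_dipole_degenerate_input(self, registry, subphase):
        rec = analyze_monolayer(
            Composition.pure(registry["POPC"]), 100.0, 50.0, 60.0, subphase,
            delta_V0_mV=100.0,
        )
        assert rec.mu_eq2_mD == pytest.approx(0.0)
        assert rec.psi30_eq2_mV == pytest.approx(100.0)

    def test_record_is_helmholtz_consistent(self, records):
        for rec in records:
            if rec.area_sat_A2 is None:
                continue
            assert rec.psi30_eq1_mV == pytest.approx(
                helmholtz_potential(rec.mu_eq1_mD, rec.area30_A2), rel=1e-9
            )
            assert rec.psi30_eq2_mV == pytest.approx(
                helmholtz_potential(rec.mu_eq2_mD, rec.area30_A2, rec.delta_V0_mV),
                rel=1e-9,
            )
            assert rec.psi_dipole_sat_mV == pytest.approx(
                rec.psi_measured_mV - rec.psi0_mV, rel=1e-9
            )
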