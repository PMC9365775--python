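"""Tests of Bethe stopping power, effective charge and CSDA ranges."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

import gcrdose as g
from gcrdose.stopping_power import (
    ICRU_TISSUE,
    ALUMINUM,
    Material,
    RangeEnergyTable,
    TARGET_ELEMENTS,
    mass_stopping_power,
)


class TestKinematics:
    def test_beta_closed_form_at_one_amu(self):
        # gamma = 2 at E = one nucleon rest mass -> beta = sqrt(3)/2
        assert g.beta_from_energy(931.49410) == pytest.approx(
            math.sqrt(3) / 2, rel=1e-9
        )

    def test_beta_monotone_and_bounded(self):
        E = np.geomspace(0.01, 1e6, 300)
        b = g.beta_from_energy(E)
        assert np.all(np.diff(b) > 0)
        assert np.all((b > 0) & (b < 1))

    def test_beta_rejects_nonpositive_energy(self):
        with pytest.raises(ValueError):
            g.beta_from_energy(0.0)


class TestEffectiveCharge:
    def test_relativistic_limit_recovers_full_charge(self):
        # the residual 1 - Z*/Z at beta -> 1 is exp(-125 Z^(-2/3)), which is
        # below 1e-10 for light ions and still below 1e-6 up to iron
        for Z in range(1, 13):
            assert abs(g.effective_charge(Z, 1 - 1e-12) / Z - 1) < 1e-10
        for Z in range(13, 27):
            assert abs(g.effective_charge(Z, 1 - 1e-12) / Z - 1) < 1e-6

    def test_proton_at_half_light_speed_is_fully_stripped(self):
        assert g.effective_charge(1, 0.5) == pytest.approx(1.0, abs=1e-20)

    def test_slow_iron_against_direct_arithmetic(self):
        # independent scalar evaluation of the Barkas form
        expected = 26.0 * (1.0 - math.exp(-125.0 * 0.05 * 26.0 ** (-2.0 / 3.0)))
        assert g.effective_charge(26, 0.05) == pytest.approx(expected, rel=1e-14)
        assert expected < 26.0

    @settings(deadline=None, max_examples=50)
    @given(Z=st.integers(1, 26), beta=st.floats(1e-3, 0.999))
    def test_bounded_by_full_charge(self, Z, beta):
        zs = g.effective_charge(Z, beta)
        assert 0 < zs <= Z

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            g.effective_charge(0, 0.5)
        with pytest.raises(ValueError):
            g.effective_charge(2, 1.0)


class TestLET:
    def test_minimum_ionizing_proton_benchmark(self):
        # published proton stopping-power tables put the minimum-ionizing
        # LET in unit-density tissue near 0.2 keV/um
        let = g.let_keV_um(1, 1000.0, ICRU_TISSUE)
        assert 0.18 <= let <= 0.28

    @pytest.mark.parametrize(
        "Z,expected", [(2, 0.9), (26, 150.0)], ids=["He", "Fe"]
    )
    def test_minimum_ionizing_let_scale(self, Z, expected):
        E = np.geomspace(100.0, 1e5, 400)
        lmin = g.let_keV_um(Z, E, ICRU_TISSUE).min()
        assert lmin == pytest.approx(expected, rel=0.15)

    @pytest.mark.parametrize("Z", [1, 2, 6, 8, 14, 26])
    def test_let_has_one_minimum_between_half_and_five_gev(self, Z):
        E = np.geomspace(1.0, 1e5, 2000)
        L = g.let_keV_um(Z, E, ICRU_TISSUE)
        falls = np.diff(L) < 0
        # exactly one sign change: monotone fall then monotone rise
        assert np.sum(np.diff(falls.astype(int)) != 0) == 1
        e_min = E[np.argmin(L)]
        assert 500.0 <= e_min <= 5000.0

    def test_equal_beta_let_ratio_is_effective_charge_squared(self):
        E = 2500.0
        r = g.let_keV_um(26, E, ICRU_TISSUE) / g.let_keV_um(2, E, ICRU_TISSUE)
        zr = (g.effective_charge(26, g.beta_from_energy(E))
              / g.effective_charge(2, g.beta_from_energy(E))) ** 2
        assert r == pytest.approx(zr, rel=1e-12)

    def test_bragg_additivity_over_constituents(self):
        E = np.geomspace(1.0, 1e4, 50)
        total = mass_stopping_power(8, E, ICRU_TISSUE)
        summed = sum(
            w * mass_stopping_power(8, E, Material(s, {s: 1.0}, density=1.0))
            for s, w in ICRU_TISSUE.mass_fractions.items()
        )
        np.testing.assert_allclose(total, summed, rtol=1e-12)

    def test_rejects_energy_below_validity_floor(self):
        with pytest.raises(ValueError, match="validity floor"):
            g.let_keV_um(1, 0.05, ICRU_TISSUE)


class TestRange:
    def test_monotone_in_energy(self):
        E = np.geomspace(1.0, 1e5, 200)
        R = g.csda_range(26, 56, ICRU_TISSUE, E)
        assert np.all(np.diff(R) > 0)

    def test_low_energy_protons_cannot_cross_the_thinnest_shield(self):
        # 10 MeV/n protons stop within a fraction of a g/cm^2 of aluminum
        assert g.csda_range(1, 1, ALUMINUM, 10.0) < 0.5

    def test_range_additivity_against_quadrature(self):
        # R(E2) - R(E1) must equal the independent quadrature of dE/S
        Z, A = 6, 12
        E1, E2 = 50.0, 800.0
        table = RangeEnergyTable(Z, A, ICRU_TISSUE)
        diff = table.range_of_energy(E2) - table.range_of_energy(E1)
        oracle, err = quad(
            lambda e: A / mass_stopping_power(Z, e, ICRU_TISSUE), E1, E2,
            limit=200,
        )
        assert diff == pytest.approx(oracle, rel=1e-3)

    def test_energy_of_range_inverts_range_of_energy(self):
        table = RangeEnergyTable(2, 4, ALUMINUM)
        E = np.geomspace(1.0, 1e4, 50)
        back = table.energy_of_range(table.range_of_energy(E))
        np.testing.assert_allclose(back, E, rtol=1e-6)


class TestMaterial:
    def test_fraction_sum_enforced(self):
        with pytest.raises(ValueError, match="sum"):
            Material("bad", {"H": 0.5, "O": 0.4}, density=1.0)

    def test_positive_density_enforced(self):
        with pytest.raises(ValueError, match="density"):
            Material("bad", {"H": 1.0}, density=0.0)

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError, match="unknown target element"):
            Material("bad", {"Xx": 1.0}, density=1.0)

    def test_polyethylene_formula_fractions(self):
        pe = g.POLYETHYLENE
        wc = 2 * TARGET_ELEMENTS["C"][1]
        wh = 4 * TARGET_ELEMENTS["H"][1]
        assert pe.mass_fractions["C"] == pytest.approx(wc / (wc + wh), rel=1e-12)
        assert sum(pe.mass_fractions.values()) == pytest.approx(1.0, abs=1e-12)

    def test_tissue_i_value_from_bragg_additivity(self):
        # log-average of the elemental I-values, weighted by electron share
        assert 65.0 < ICRU_TISSUE.i_value_eV < 80.0
        override = Material("t", {"H": 1.0}, density=1.0, mean_excitation_energy=75.0)
        assert override.i_value_eV == 75.0
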