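"""Tests of absorbed dose, dose-weighted means and effective dose equivalents."""

import numpy as np
import pytest

import gcrdose as g
from gcrdose.bio_weighting import qf_icrp
from gcrdose.dosimetry import (
    DoseLETDistribution,
    SlabPhantom,
    ThinTarget,
    absorbed_dose_element,
    dose_breakdown,
    effective_dose_equivalent,
    mean_weight,
    shielding_report,
)
from gcrdose.spectra import default_let_edges
from gcrdose.transport_1d import ShieldConfig


def narrow_proton_beam(E0=1000.0, half_width=1.0, height=4.0):
    grid = np.array([E0 - half_width, E0 - half_width / 2, E0,
                     E0 + half_width / 2, E0 + half_width])
    flux = np.array([0.0, height, height, height, 0.0])
    return g.DifferentialSpectrum(g.element(1), grid, flux)


class TestAbsorbedDose:
    def test_thin_mode_unit_conversion(self):
        # D = 1.602e-9 Gy per unit fluence per keV/um at unit density
        spec = narrow_proton_beam()
        ed = absorbed_dose_element(spec, phantom=ThinTarget())
        L = g.let_keV_um(1, spec.energy, g.ICRU_TISSUE)
        expected = 1.602e-6 * np.trapezoid(spec.flux * L, spec.energy)
        assert ed.dose_mGy_yr == pytest.approx(expected, rel=1e-6)

    def test_dose_is_linear_in_fluence(self):
        spec = narrow_proton_beam(height=4.0)
        twice = narrow_proton_beam(height=8.0)
        d1 = absorbed_dose_element(spec, phantom=ThinTarget()).dose_mGy_yr
        d2 = absorbed_dose_element(twice, phantom=ThinTarget()).dose_mGy_yr
        assert d2 == pytest.approx(2 * d1, rel=1e-12)

    def test_stopping_beam_in_a_short_slab_exceeds_thin_dose(self):
        # a 100 MeV proton ranges out inside 5 g/cm^2 of tissue; its average
        # LET over the track exceeds the entrance LET, so the slab-averaged
        # dose beats the thin-target dose
        beam = narrow_proton_beam(E0=100.0, half_width=0.5)
        thin = absorbed_dose_element(beam, phantom=ThinTarget()).dose_mGy_yr
        slab = absorbed_dose_element(
            beam, phantom=SlabPhantom(depth=5.0, sublayer=0.1)
        ).dose_mGy_yr
        assert slab > thin

    def test_slab_energy_bookkeeping_for_a_fully_stopped_beam(self):
        # every particle deposits its full kinetic energy inside the slab
        beam = narrow_proton_beam(E0=100.0, half_width=0.5)
        slab = absorbed_dose_element(
            beam, phantom=SlabPhantom(depth=30.0, sublayer=0.25)
        ).dose_mGy_yr
        fluence = np.trapezoid(beam.flux, beam.energy)
        expected = 1.602e-7 * fluence * 100.0 / 30.0  # MeV/g -> mGy
        assert slab == pytest.approx(expected, rel=2e-2)

    def test_phantom_validation(self):
        with pytest.raises(ValueError):
            SlabPhantom(depth=-1.0)
        with pytest.raises(ValueError):
            SlabPhantom(depth=10.0, sublayer=20.0)


class TestMeanWeight:
    def test_low_let_dose_gives_unit_quality_factor(self):
        edges = default_let_edges()
        dose = np.where(np.sqrt(edges[:-1] * edges[1:]) < 5.0, 1.0, 0.0)
        dist = DoseLETDistribution(edges, dose)
        assert mean_weight(dist, qf_icrp) == pytest.approx(1.0, abs=1e-12)

    def test_equal_dose_bins_average_their_weights(self):
        edges = np.array([1.0, 2.0, 4.0, 8.0])
        dist = DoseLETDistribution(edges, np.array([1.0, 0.0, 1.0]))
        weights = {dist.let[0]: 1.0, dist.let[2]: 3.0}
        w = mean_weight(dist, lambda L: np.array([weights.get(x, 0.0) for x in L]))
        assert w == pytest.approx(2.0, rel=1e-12)

    def test_zero_dose_rejected(self):
        dist = DoseLETDistribution(np.array([1.0, 2.0]), np.array([0.0]))
        with pytest.raises(ValueError, match="zero"):
            mean_weight(dist, qf_icrp)

    def test_bounded_by_weight_extremes(self, free_space):
        dist = free_space.dose_vs_let
        w = mean_weight(dist, qf_icrp)
        support = dist.let[dist.dose > 0]
        assert qf_icrp(support).min() <= w <= qf_icrp(support).max()


class TestBreakdown:
    def test_carbon_mean_weights_near_the_reference_values(self, free_space):
        # reference free-space means for carbon are 3.36 (QF) and 2.26
        # (RBE); the LET-only slab estimator carries no in-body secondary
        # dilution, so agreement is looser than for the totals
        row = free_space.per_element.set_index("Z").loc[6]
        assert row["mean_QF"] == pytest.approx(3.36, rel=0.25)
        assert row["mean_RBE"] == pytest.approx(2.26, rel=0.25)

    def test_effective_dose_equals_sum_of_products(self, free_space):
        df = free_space.per_element
        assert effective_dose_equivalent(free_space, "qf") == pytest.approx(
            float((df["D_mGy_yr"] * df["mean_QF"]).sum()), rel=1e-14
        )

    def test_single_element_h_is_d_times_w(self, rbe_params):
        spec = g.build_solar_min_spectrum(g.element(26))
        bd = dose_breakdown([spec], rbe_params=rbe_params)
        row = bd.per_element.iloc[0]
        assert bd.he_icrp_mSv_yr == pytest.approx(
            row["D_mGy_yr"] * row["mean_QF"], rel=1e-14
        )

    def test_unit_weight_reduces_h_to_total_dose(self):
        # dose deposited entirely below 10 keV/um: QF = 1 so H_E = D
        beam = narrow_proton_beam()
        bd = dose_breakdown([beam], phantom=ThinTarget())
        assert bd.he_icrp_mSv_yr == pytest.approx(bd.total_dose_mGy_yr, rel=1e-12)
        assert bd.mean_qf == pytest.approx(1.0, abs=1e-12)

    def test_ddref_divides_only_the_rbe_column(self, source, rbe_params):
        plain = dose_breakdown(source[:3], rbe_params=rbe_params)
        halved = dose_breakdown(source[:3], rbe_params=rbe_params, ddref=2.0)
        assert halved.he_rbe == pytest.approx(plain.he_rbe / 2.0, rel=1e-12)
        assert halved.he_icrp_mSv_yr == pytest.approx(
            plain.he_icrp_mSv_yr, rel=1e-12
        )

    def test_rbe_weighted_h_requires_parameters(self, source):
        bd = dose_breakdown(source[:2])
        with pytest.raises(ValueError, match="without RBE parameters"):
            effective_dose_equivalent(bd, "rbe")


class TestShieldingReport:
    @pytest.fixture()
    def report(self, source, rbe_params):
        shields = [ShieldConfig(g.POLYETHYLENE, t) for t in (0.0, 10.0, 20.0)]
        return shielding_report(source, shields, rbe_params=rbe_params)

    def test_reference_row_ratios_are_one(self, report):
        ref = report[report["thickness_gcm2"] == 0].iloc[0]
        assert ref["rel_dose"] == pytest.approx(1.0, rel=1e-12)
        assert ref["rel_HE_ICRP"] == pytest.approx(1.0, rel=1e-12)
        assert ref["rel_HE_RBE"] == pytest.approx(1.0, rel=1e-12)

    def test_mean_qf_and_relative_he_decrease_with_thickness(self, report):
        ordered = report.sort_values("thickness_gcm2")
        assert np.all(np.diff(ordered["mean_QF"]) < 0)
        assert np.all(np.diff(ordered["rel_HE_ICRP"]) < 0)
        assert np.all(np.diff(ordered["rel_dose"]) < 0)

    def test_missing_reference_rejected(self, source):
        with pytest.raises(ValueError, match="reference"):
            shielding_report(source, [ShieldConfig(g.ALUMINUM, 5.0)])
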