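"""Dose engine: kernel math, linearity, conservation, oracle equivalence."""

import math

import numpy as np
import pytest

import protonpb as pb
from protonpb.engine import SIGMA_FLOOR_MM
from tests.conftest import surface_beam_geometry


class TestCentralSigma:
    def test_plain_sum(self, lib_small):
        layer = lib_small.layers[0]
        zw = 10.0
        z = 1500.0
        expected = float(layer.sigma_air_at(z)) + float(layer.sigma_mcs_at(zw))
        assert pb.central_sigma(layer, z, zw) == pytest.approx(expected)

    def test_zero_mcs_at_reference_depth(self, lib_small):
        layer = lib_small.layers[0]
        zw_ref = 0.7 * layer.r80_mm
        assert float(layer.sigma_mcs_at(zw_ref)) == pytest.approx(0.0, abs=2e-3)
        assert pb.central_sigma(layer, 1635.0, zw_ref) == pytest.approx(
            float(layer.sigma_air_at(1635.0)), abs=2e-3
        )

    def test_clamped_at_floor(self, lib_small):
        layer = lib_small.layers[0]
        bad = pb.EnergyLayerModel(
            energy_mev=1.0, idd_zw_mm=layer.idd_zw_mm, idd=layer.idd,
            sigma_mcs_zw_mm=layer.sigma_mcs_zw_mm,
            sigma_mcs=np.full_like(layer.sigma_mcs, -10.0),
            sigma_air_coeffs=(2.0, 0.0, 0.0), r80_mm=layer.r80_mm,
        )
        assert pb.central_sigma(bad, 1000.0, 5.0) == SIGMA_FLOOR_MM


class TestKernelTotal:
    def test_axis_value_single_gaussian(self):
        p = pb.KernelParams(sigma_c=4.0, sigma_air=4.0, sigma_mcs=0.0, u_n=0.0, sigma_n=8.0)
        assert pb.kernel_total(p, 0.0) == pytest.approx(1.0 / (2 * math.pi * 16.0))
        assert pb.kernel_total(p, 4.0) == pytest.approx(math.exp(-0.5) / (2 * math.pi * 16.0))

    @pytest.mark.parametrize("sigma_c,sigma_n,u_n", [
        (3.0, 8.0, 0.0), (3.0, 8.0, 0.3), (5.0, 12.0, 0.1), (0.5, 2.0, 0.3),
    ])
    def test_plane_integral_is_one(self, sigma_c, sigma_n, u_n):
        """Quadrature oracle: the 2D integral over r <= 6 max(sigma) is ~1."""
        p = pb.KernelParams(sigma_c=sigma_c, sigma_air=sigma_c, sigma_mcs=0.0, u_n=u_n, sigma_n=sigma_n)
        rmax = 6.0 * max(sigma_c, sigma_n)
        h = min(sigma_c, sigma_n) / 8.0
        ax = np.arange(-rmax, rmax + h, h)
        xx, yy = np.meshgrid(ax, ax, indexing="ij")
        integral = float(np.sum(pb.kernel_total(p, np.sqrt(xx**2 + yy**2))) * h * h)
        assert integral == pytest.approx(1.0, abs=1e-3)


class TestBeamDose:
    def test_no_spots_gives_zero(self, lib_small):
        sr = pb.hu_to_sr(pb.make_water_phantom((10, 10, 10), 1.0))
        beam = pb.Beam(geometry=surface_beam_geometry(), spots=[])
        dose = pb.beam_dose(sr, beam, lib_small)
        assert np.all(dose.values == 0.0)

    def test_linear_in_mu_and_additive_over_spots(self, lib_small):
        sr = pb.hu_to_sr(pb.make_water_phantom((24, 24, 48), 1.0))
        geom = surface_beam_geometry()
        d1 = pb.beam_dose(sr, pb.Beam(geom, [pb.Spot(0.0, 0.0, 1.0, 70.2)]), lib_small)
        d2 = pb.beam_dose(sr, pb.Beam(geom, [pb.Spot(0.0, 0.0, 2.0, 70.2)]), lib_small)
        assert np.array_equal(d2.values, 2.0 * d1.values)
        d3 = pb.beam_dose(
            sr, pb.Beam(geom, [pb.Spot(0.0, 0.0, 1.0, 70.2), pb.Spot(5.0, -3.0, 0.5, 90.0)]), lib_small
        )
        d4 = pb.beam_dose(sr, pb.Beam(geom, [pb.Spot(5.0, -3.0, 0.5, 90.0)]), lib_small)
        assert np.allclose(d3.values, d1.values + d4.values, rtol=0, atol=1e-12 * d3.values.max())

    def test_plane_integral_recovers_idd(self, water_dose_70):
        """The kernel-normalization consistency of the dose model: in water the
        plane-integrated dose equals MU * IDD at every contained depth."""
        dose, geom, layer = water_dose_70
        s = dose.spacing_mm
        for k in range(0, int(layer.r80_mm)):
            zw = k + 0.5
            idd = float(layer.idd_at(zw))
            plane = dose.values[:, :, k].sum() * s * s
            assert plane == pytest.approx(1.0 * idd, rel=0.01)

    def test_unknown_energy_label_named(self, lib_small):
        sr = pb.hu_to_sr(pb.make_water_phantom((6, 6, 6), 1.0))
        beam = pb.Beam(surface_beam_geometry(), [pb.Spot(0.0, 0.0, 1.0, 199.9)])
        with pytest.raises(KeyError, match="199.9"):
            pb.beam_dose(sr, beam, lib_small)

    def test_deterministic_bitwise(self, lib_small):
        sr = pb.hu_to_sr(pb.make_water_phantom((16, 16, 30), 1.0))
        beam = pb.Beam(surface_beam_geometry(), [pb.Spot(1.0, 2.0, 0.7, 70.2)])
        a = pb.beam_dose(sr, beam, lib_small)
        b = pb.beam_dose(sr, beam, lib_small)
        assert np.array_equal(a.values, b.values)

    def test_single_voxel_hand_computation(self, lib_small):
        layer = lib_small.layer_for(70.2)
        sr = pb.ImageGrid(np.ones((1, 1, 1)), 1.0, [0.0, 0.0, 0.0], "Sr")
        geom = surface_beam_geometry()
        dose = pb.beam_dose(sr, pb.Beam(geom, [pb.Spot(0.0, 0.0, 2.0, 70.2)]), lib_small)
        # hand computation: zw = 0.5 (sub-voxel disc leaves smoothing inert),
        # z = SAD + 0.5, spot axis through (0,0,-0.5) gives r ~ 0 at the voxel
        zw = 0.5
        z = 1635.0 + 0.5
        sc = float(layer.sigma_air_at(z)) + float(layer.sigma_mcs_at(zw))
        halo = pb.HaloModel()
        un = float(halo.u_n(layer.r80_mm, zw))
        sn = float(halo.sigma_n(layer.r80_mm, zw))
        k0 = (1 - un) / (2 * math.pi * sc**2) + un / (2 * math.pi * sn**2)
        expected = 2.0 * float(layer.idd_at(zw)) * k0
        assert dose.values[0, 0, 0] == pytest.approx(expected, rel=1e-6)

    def test_zero_mu_spots_give_zero(self, lib_small):
        sr = pb.hu_to_sr(pb.make_water_phantom((8, 8, 8), 1.0))
        beam = pb.Beam(surface_beam_geometry(), [pb.Spot(0.0, 0.0, 0.0, 70.2)])
        assert np.all(pb.beam_dose(sr, beam, lib_small).values == 0.0)
        assert np.all(pb.brute_force_beam_dose(sr, beam, lib_small).values == 0.0)


class TestPlanDose:
    def test_two_identical_beams_double(self, lib_small):
        hu = pb.make_water_phantom((16, 16, 30), 1.0)
        beam = pb.Beam(surface_beam_geometry(), [pb.Spot(0.0, 0.0, 1.0, 70.2)])
        single = pb.plan_dose(hu, pb.Plan(beams=[beam]), lib_small)
        double = pb.plan_dose(hu, pb.Plan(beams=[beam, beam]), lib_small)
        assert np.allclose(double.values, 2.0 * single.values, rtol=0, atol=1e-14 * double.values.max())

    def test_empty_plan_zero(self, lib_small):
        hu = pb.make_water_phantom((6, 6, 6), 1.0)
        assert np.all(pb.plan_dose(hu, pb.Plan(beams=[]), lib_small).values == 0.0)

    def test_rbe_report_is_1p1_times_physical(self, lib_small):
        hu = pb.make_water_phantom((16, 16, 30), 1.0)
        beam = pb.Beam(surface_beam_geometry(), [pb.Spot(0.0, 0.0, 1.0, 70.2)])
        plan = pb.Plan(beams=[beam], rbe=1.1)
        phys = pb.plan_dose(hu, plan, lib_small, report="physical")
        rbe = pb.plan_dose(hu, plan, lib_small, report="rbe")
        m = phys.values > 0
        assert np.allclose(rbe.values[m] / phys.values[m], 1.1)
        assert rbe.role.value == "DOSE_RBE"


class TestOracleEquivalence:
    def test_matches_brute_force(self, lib_small):
        """Engine vs the independent triple-loop oracle on a small grid."""
        rng = np.random.default_rng(21)
        sr = pb.hu_to_sr(pb.make_water_phantom((24, 24, 24), 1.0))
        geom = surface_beam_geometry()
        spots = [
            pb.Spot(float(rng.uniform(-6, 6)), float(rng.uniform(-6, 6)),
                    float(rng.uniform(0.2, 1.0)), [70.2, 90.0][i % 2])
            for i in range(4)
        ]
        beam = pb.Beam(geom, spots)
        fast = pb.beam_dose(sr, beam, lib_small)
        slow = pb.brute_force_beam_dose(sr, beam, lib_small)
        assert np.abs(fast.values - slow.values).max() <= 1e-6 * fast.values.max()
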