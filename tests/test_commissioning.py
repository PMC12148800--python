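"""Commissioning fits: IDD extraction, R80, lateral sigmas, quadratic sigma_air,
sigma_mcs table, and the end-to-end parameter-recovery round trip."""

import numpy as np
import pytest

import protonpb as pb
from protonpb.commissioning import DepthTable
from protonpb.grids import GridRole


def _flat_dose_grid(value=2.0, shape=(20, 20, 10), spacing=1.0):
    g = pb.ImageGrid(np.full(shape, value), spacing,
                     [-(shape[0] - 1) / 2, -(shape[1] - 1) / 2, 0.5 * spacing],
                     GridRole.DOSE_PHYSICAL)
    return g


class TestExtractIdd:
    def test_synthetic_noiseless_matches_truth(self):
        spec = pb.SyntheticBeamSpec(energy_mev=70.2, noise_sd_rel=0.0)
        g = pb.generate_pristine_grid(spec, 1635.0, 1.0, (60, 60, 46))
        idd = pb.extract_idd(g, spec.mu_per_spot)
        truth = np.asarray(spec.depth_dose(idd.zw_mm))
        sel = (idd.zw_mm <= spec.r80_true_mm) & (truth > 0)
        assert np.all(np.abs(idd.values[sel] / truth[sel] - 1.0) < 5e-3)

    def test_mu_normalization(self):
        g = _flat_dose_grid(value=1.0)
        a = pb.extract_idd(g, 0.2)
        b = pb.extract_idd(g, 0.4)
        assert np.allclose(a.values, 2.0 * b.values)

    def test_all_zero_grid(self):
        g = _flat_dose_grid(value=0.0)
        assert np.all(pb.extract_idd(g, 0.2).values == 0.0)

    def test_truncation_warning(self):
        g = _flat_dose_grid(value=1.0)  # uniform plane: edge dose = plane max
        with pytest.warns(UserWarning, match="truncated"):
            pb.extract_idd(g, 0.2)


class TestAverageIdds:
    def test_pointwise_mean_and_identity(self):
        z = np.arange(5.0)
        a = DepthTable(z, np.array([1.0, 2, 3, 4, 5]))
        b = DepthTable(z, np.array([3.0, 4, 5, 6, 7]))
        avg = pb.average_idds([a, b])
        assert np.array_equal(avg.values, [2.0, 3, 4, 5, 6])
        assert np.array_equal(pb.average_idds([a]).values, a.values)
        assert np.array_equal(pb.average_idds([a, a]).values, a.values)

    def test_mismatched_grids_refused(self):
        a = DepthTable(np.arange(5.0), np.ones(5))
        b = DepthTable(np.arange(5.0) + 0.5, np.ones(5))
        with pytest.raises(ValueError, match="mismatch"):
            pb.average_idds([a, b])


class TestComputeR80:
    def test_triangle_closed_form(self):
        """Peak 1.0 at 100 mm, linear falloff to 0 at 110 mm: crossing at 102."""
        z = np.arange(0.0, 121.0)
        v = np.where(z <= 100, z / 100.0, np.maximum(0.0, (110.0 - z) / 10.0))
        assert pb.compute_r80(DepthTable(z, v)) == pytest.approx(102.0)

    def test_synthetic_truth(self):
        spec = pb.SyntheticBeamSpec(energy_mev=150.0, r80_true_mm=150.0, noise_sd_rel=0.0)
        zw = np.arange(170.0) + 0.5
        idd = DepthTable(zw, np.asarray(spec.depth_dose(zw)))
        assert pb.compute_r80(idd) == pytest.approx(150.0, abs=0.2)

    def test_monotone_curve_fails(self):
        z = np.arange(0.0, 50.0)
        with pytest.raises(ValueError, match="crossing"):
            pb.compute_r80(DepthTable(z, z**1.5))


class TestFitLateralSigma:
    @staticmethod
    def _gaussian_plane(sx, sy, n=61, spacing=1.0, amp=10.0):
        x = (np.arange(n) - (n - 1) / 2) * spacing
        return amp * np.exp(-x[:, None] ** 2 / (2 * sx**2) - x[None, :] ** 2 / (2 * sy**2))

    def test_exact_isotropic(self):
        assert pb.fit_lateral_sigma(self._gaussian_plane(5.0, 5.0)) == pytest.approx(5.0, abs=0.02)

    def test_anisotropic_returns_xy_mean(self):
        assert pb.fit_lateral_sigma(self._gaussian_plane(4.0, 6.0)) == pytest.approx(5.0, abs=0.05)

    def test_noisy_fit_distribution(self):
        rng = np.random.default_rng(8)
        vals = []
        for _ in range(20):
            plane = self._gaussian_plane(5.0, 5.0)
            plane *= 1.0 + 0.005 * rng.standard_normal(plane.shape)
            vals.append(pb.fit_lateral_sigma(plane))
        assert np.mean(vals) == pytest.approx(5.0, abs=0.1)
        assert np.std(vals) < 0.1

    def test_empty_plane_fails(self):
        with pytest.raises(ValueError):
            pb.fit_lateral_sigma(np.zeros((21, 21)))


class TestFitSigmaAir:
    def test_exact_quadratic_recovered(self):
        c = (2.0, 1e-3, 1e-7)
        zs = [1385.0 + 0.7 * 90, 1435.0 + 0.7 * 90, 1535.0 + 0.7 * 90, 1635.0 + 0.7 * 90]
        pts = [(z, c[0] + c[1] * z + c[2] * z**2) for z in zs]
        (c0, c1, c2), resid = pb.fit_sigma_air(pts)
        assert c0 == pytest.approx(c[0], rel=0.01)
        assert c1 == pytest.approx(c[1], rel=0.01)
        assert c2 == pytest.approx(c[2], rel=0.01)
        assert np.abs(resid).max() < 1e-9

    def test_constant_sigma(self):
        pts = [(1400.0, 3.3), (1500.0, 3.3), (1600.0, 3.3), (1700.0, 3.3)]
        (c0, c1, c2), _ = pb.fit_sigma_air(pts)
        assert c0 == pytest.approx(3.3, abs=1e-9)
        assert abs(c1) < 1e-9 and abs(c2) < 1e-9

    def test_two_points_fail(self):
        with pytest.raises(ValueError):
            pb.fit_sigma_air([(1400.0, 3.0), (1500.0, 3.1)])


class TestBuildSigmaMcs:
    def test_zero_at_reference_depth(self):
        zw = np.arange(100.0) + 0.5
        prof = DepthTable(zw, 3.0 + 0.02 * zw)
        cfg = pb.FitConfig(ssd_list_mm=[1635.0, 1535.0, 1435.0])
        out = pb.build_sigma_mcs([prof, prof, prof], cfg, r80_mm=90.0)
        assert out.at(0.7 * 90.0) == pytest.approx(0.0, abs=1e-12)

    def test_single_profile_minus_reference(self):
        zw = np.arange(100.0) + 0.5
        prof = DepthTable(zw, 3.0 + 0.02 * zw)
        cfg = pb.FitConfig(ssd_list_mm=[1635.0, 1535.0, 1435.0])
        out = pb.build_sigma_mcs([prof], cfg, r80_mm=90.0)
        assert np.allclose(out.values, prof.values - prof.at(63.0))

    def test_reference_outside_profiles_fails(self):
        zw = np.arange(10.0) + 0.5
        prof = DepthTable(zw, np.ones(10))
        cfg = pb.FitConfig(ssd_list_mm=[1635.0, 1535.0, 1435.0])
        with pytest.raises(ValueError, match="outside"):
            pb.build_sigma_mcs([prof], cfg, r80_mm=90.0)


class TestBuildEnergyModel:
    def test_round_trip_parameter_recovery(self, commissioning_run):
        """Noisy 4-SSD commissioning recovers the generator ground truth."""
        spec, grids, cfg, layer = commissioning_run
        r80 = spec.r80_true_mm
        assert layer.r80_mm == pytest.approx(r80, abs=0.2)
        exp = spec.expected_sigma_air_coeffs(cfg.zw_ref_fraction)
        for z in cfg.ssd_list_mm:
            got = layer.sigma_air_at(z)
            want = exp[0] + exp[1] * z + exp[2] * z**2
            assert got == pytest.approx(want, abs=0.1)
        zws = np.linspace(0.2 * r80, 0.9 * r80, 25)
        err = np.asarray(layer.sigma_mcs_at(zws)) - np.asarray(
            spec.expected_sigma_mcs(zws, cfg.zw_ref_fraction)
        )
        assert np.abs(err).max() < 0.1
        assert float(layer.sigma_mcs_at(cfg.zw_ref_fraction * layer.r80_mm)) == pytest.approx(0.0, abs=1e-6)

    def test_sigma_c_profile_recovers_truth(self, commissioning_run):
        spec, grids, cfg, layer = commissioning_run
        prof = pb.sigma_c_profile(grids[0], halo=spec.halo_spec, r80_mm=layer.r80_mm)
        sel = prof.zw_mm <= 0.9 * spec.r80_true_mm
        truth = spec.sigma_central(1635.0 + prof.zw_mm[sel], prof.zw_mm[sel])
        assert np.abs(prof.values[sel] - truth).max() < 0.05
        # broadening grows with depth when mcs_scale > 0
        assert prof.values[sel][-1] > prof.values[sel][0]

    def test_minimum_three_ssds_succeed(self):
        spec = pb.SyntheticBeamSpec(energy_mev=70.2, noise_sd_rel=0.005, seed=5)
        ssds = [1635.0, 1535.0, 1435.0]
        grids = pb.generate_commissioning_set(spec, ssds, 1.0, (60, 60, 46))
        cfg = pb.FitConfig(ssd_list_mm=ssds, mu_per_spot=spec.mu_per_spot)
        layer = pb.build_energy_model(grids, cfg, halo=spec.halo_spec)
        assert layer.r80_mm == pytest.approx(spec.r80_true_mm, abs=0.2)

    def test_r80_stable_across_seeds(self):
        """Noise propagation: R80 spread over repeated noisy runs stays small."""
        ssds = [1635.0, 1535.0, 1435.0, 1385.0]
        r80s = []
        for seed in range(5):
            spec = pb.SyntheticBeamSpec(energy_mev=70.2, noise_sd_rel=0.005, seed=seed)
            grids = pb.generate_commissioning_set(spec, ssds, 1.0, (60, 60, 46))
            idd = pb.average_idds([pb.extract_idd(g, spec.mu_per_spot) for g in grids])
            r80s.append(pb.compute_r80(idd))
        assert np.std(r80s) <= 0.2

    def test_failing_stage_is_named(self, commissioning_run):
        spec, grids, cfg, _ = commissioning_run
        truncated = [g.copy(values=g.values[:, :, :20]) for g in grids]
        for g in truncated:
            g.origin_mm = grids[0].origin_mm.copy()
        with pytest.raises(RuntimeError, match="stage R80"):
            pb.build_energy_model(truncated, cfg, halo=spec.halo_spec)
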