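"""Synthetic pristine-Bragg-peak dose grids with known ground truth.

Stands in for treatment-planning-system Monte Carlo exports: 3D single-spot
dose grids in a digital water tank on a 1 mm isotropic grid, 0.2 MU per
spot, with 0.5 % multiplicative Gaussian noise emulating MC statistical
uncertainty, at several effective source-to-surface distances (SSDs).  The
depth-dose is the Bortfeld analytic Bragg curve calibrated so its distal
80 % crossing lands exactly on the requested R80; the lateral profile at
every depth is the double Gaussian of the dose model with a known in-air
quadratic sigma_air(z), a known in-medium broadening term, and a known
nuclear-halo parameterization.  Every generated grid carries its generating
spec in metadata, so commissioning fits can be scored as parameter recovery.

Grid convention: the tank surface is the outer face of the first depth
slice, so the voxel at depth index k is centred at depth (k + 1/2) * spacing
and the grid's z coordinate equals depth below the surface.  Distance from
the effective source is then z = SSD + depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq
from scipy.special import pbdv

from .beam_model import BeamModelLibrary, EnergyLayerModel
from .grids import GridRole, ImageGrid
from .halo import HaloModel

# Bortfeld analytic Bragg-curve constants (depth and range in cm):
# range-energy exponent p, fluence-reduction slope beta, low-energy
# contamination fraction epsilon, straggling width sigma = 0.012 * R0^0.935.
_P = 1.77
_BETA = 0.012
_EPS = 0.1
_ZETA_JUNCTION = 17.0  # switch to the non-straggled plateau form (mismatch ~1e-4)


def _bortfeld_cm(z_cm: np.ndarray, r0_cm: float) -> np.ndarray:
    """Bortfeld depth-dose at depths z_cm for nominal range r0_cm (arbitrary units)."""
    z = np.atleast_1d(np.asarray(z_cm, dtype=np.float64))
    sigma = 0.012 * r0_cm**0.935
    zeta = (r0_cm - z) / sigma
    out = np.zeros_like(z)
    plateau = zeta > _ZETA_JUNCTION
    if np.any(plateau):
        uu = r0_cm - z[plateau]
        out[plateau] = (
            17.93 * uu ** (-0.435) + (0.444 + 31.7 * _EPS / r0_cm) * uu**0.565
        ) / (1.0 + _BETA * r0_cm)
    mid = (zeta <= _ZETA_JUNCTION) & (zeta > -5.0)
    if np.any(mid):
        zt = zeta[mid]
        out[mid] = (
            np.exp(-(zt**2) / 4.0)
            * sigma**0.565
            / (1.0 + _BETA * r0_cm)
            * (11.26 / sigma * pbdv(-0.565, -zt)[0] + (0.157 + 11.26 * _EPS / r0_cm) * pbdv(-1.565, -zt)[0])
        )
    return np.maximum(out, 0.0)


def _distal_80_cm(r0_cm: float) -> float:
    zg = np.linspace(max(r0_cm - 2.0, 0.0), r0_cm * 1.04, 2000)
    d = _bortfeld_cm(zg, r0_cm)
    imax = int(np.argmax(d))
    dmax = d[imax]
    return brentq(lambda z: float(_bortfeld_cm(np.array([z]), r0_cm)[0]) - 0.8 * dmax,
                  zg[imax], r0_cm * 1.04, xtol=1e-7)


@lru_cache(maxsize=256)
def _calibrated_r0_cm(r80_mm: float) -> float:
    """Nominal range r0 such that the distal 80 % crossing sits at r80_mm."""
    r0 = r80_mm / 10.0
    for _ in range(4):
        r0 -= _distal_80_cm(r0) - r80_mm / 10.0
    return r0


def energy_to_r80_mm(energy_mev: float) -> float:
    """Bragg-Kleeman range-energy relation for water (R = 0.022 E^1.77 mm)."""
    return 0.022 * float(energy_mev) ** _P


@dataclass
class SyntheticBeamSpec:
    """Ground truth for one synthetic pristine Bragg peak.

    The lateral central sigma painted at depth d (water, so z_w = d) for a
    grid at source distance z = SSD + d is
    ``sigma_air_true(z) + mcs_broadening(z_w)`` with the broadening
    ``mcs_scale * r80 * (z_w / r80) ** 1.7`` (zero at the surface).
    """

    energy_mev: float
    r80_true_mm: float | None = None  # default: Bragg-Kleeman from energy
    sigma_air_true: tuple[float, float, float] = (2.0, 1.0e-3, 1.0e-7)
    mcs_scale: float = 0.025
    mcs_exp: float = 1.7
    halo_spec: HaloModel = field(default_factory=HaloModel)
    mu_per_spot: float = 0.2
    idd_peak: float = 25.0  # peak IDD, cGy mm^2 / MU
    noise_sd_rel: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r80_true_mm is None:
            self.r80_true_mm = energy_to_r80_mm(self.energy_mev)
        self.r80_true_mm = float(self.r80_true_mm)
        if not self.r80_true_mm > 0:
            raise ValueError("r80_true_mm must be > 0")
        if not self.mu_per_spot > 0:
            raise ValueError("mu_per_spot must be > 0")
        if self.noise_sd_rel < 0:
            raise ValueError("noise_sd_rel must be >= 0")

    # ------------------------------------------------------- ground truth
    def depth_dose(self, zw_mm: np.ndarray | float) -> np.ndarray | float:
        """Analytic IDD (cGy mm^2 / MU) at water depth zw; 0 beyond 1.05 R80."""
        zw = np.atleast_1d(np.asarray(zw_mm, dtype=np.float64))
        if np.any(zw < 0):
            raise ValueError("zw must be >= 0")
        r0 = _calibrated_r0_cm(self.r80_true_mm)
        out = _bortfeld_cm(zw / 10.0, r0) * self._idd_scale()
        out[zw > 1.05 * self.r80_true_mm] = 0.0
        return float(out[0]) if np.isscalar(zw_mm) else out

    def _idd_scale(self) -> float:
        cached = self.__dict__.get("_idd_scale_cache")
        if cached is None:
            r0 = _calibrated_r0_cm(self.r80_true_mm)
            zg = np.linspace(0.0, self.r80_true_mm * 1.05, 4000)
            cached = self.idd_peak / float(_bortfeld_cm(zg / 10.0, r0).max())
            self.__dict__["_idd_scale_cache"] = cached
        return cached

    def sigma_air_at(self, z_mm: np.ndarray | float) -> np.ndarray | float:
        c0, c1, c2 = self.sigma_air_true
        z = np.asarray(z_mm, dtype=np.float64)
        return c0 + c1 * z + c2 * z**2

    def mcs_broadening(self, zw_mm: np.ndarray | float) -> np.ndarray | float:
        """In-medium lateral broadening, mm; zero at the surface, flat past R80."""
        t = np.clip(np.asarray(zw_mm, dtype=np.float64) / self.r80_true_mm, 0.0, 1.0)
        return self.mcs_scale * self.r80_true_mm * t**self.mcs_exp

    def sigma_central(self, z_mm, zw_mm):
        return self.sigma_air_at(z_mm) + self.mcs_broadening(zw_mm)

    # ---------------------------------------- truth in the fitted basis
    # The commissioning fit is only identifiable up to the reference depth:
    # sigma_mcs is referenced to z_w,ref and sigma_air absorbs the in-medium
    # broadening already present there.
    def expected_sigma_mcs(self, zw_mm, zw_ref_fraction: float = 0.7):
        ref = float(self.mcs_broadening(zw_ref_fraction * self.r80_true_mm))
        return self.mcs_broadening(zw_mm) - ref

    def expected_sigma_air_coeffs(self, zw_ref_fraction: float = 0.7) -> tuple[float, float, float]:
        c0, c1, c2 = self.sigma_air_true
        ref = float(self.mcs_broadening(zw_ref_fraction * self.r80_true_mm))
        return (c0 + ref, c1, c2)

    def to_meta(self) -> dict:
        """JSON-serialisable ground-truth ledger carried in grid metadata."""
        d = asdict(self)
        d["sigma_air_true"] = list(d["sigma_air_true"])
        d["halo_spec"] = {k: v for k, v in asdict(self.halo_spec).items() if not callable(v) and v is not None}
        return d


def analytic_depth_dose(spec: SyntheticBeamSpec, zw_mm: np.ndarray | float):
    """Module-level alias for the spec's analytic IDD."""
    return spec.depth_dose(zw_mm)


# ----------------------------------------------------------- generation


def _required_lateral_half_mm(spec: SyntheticBeamSpec, ssd_mm: float) -> float:
    z_max = ssd_mm + 1.05 * spec.r80_true_mm
    sc_max = float(spec.sigma_air_at(z_max)) + float(spec.mcs_broadening(spec.r80_true_mm))
    return 4.0 * sc_max


def generate_pristine_grid(
    spec: SyntheticBeamSpec,
    ssd_mm: float,
    spacing_mm: float = 1.0,
    grid_shape: tuple[int, int, int] = (80, 80, 350),
    rng: np.random.Generator | None = None,
) -> ImageGrid:
    """Single-spot 3D dose grid (cGy) in a water tank at the given SSD.

    The lateral plane integral at every depth equals
    ``mu_per_spot * analytic IDD`` up to the finite lateral extent; seeded
    multiplicative Gaussian noise emulates MC statistical uncertainty.
    """
    nx, ny, nz = grid_shape
    spacing_mm = float(spacing_mm)
    half_x = (nx - 1) / 2.0 * spacing_mm
    half_y = (ny - 1) / 2.0 * spacing_mm
    need_half = _required_lateral_half_mm(spec, ssd_mm)
    need_depth = 1.05 * spec.r80_true_mm
    depth_extent = nz * spacing_mm
    if min(half_x, half_y) < need_half or depth_extent < need_depth:
        need_n_lat = int(np.ceil(2 * need_half / spacing_mm)) + 1
        need_n_z = int(np.ceil(need_depth / spacing_mm))
        raise ValueError(
            f"grid {grid_shape} too small for this beam: need >= "
            f"({need_n_lat}, {need_n_lat}, {need_n_z}) voxels at {spacing_mm} mm "
            "(4 sigma laterally, full range in depth)"
        )
    rng = rng if rng is not None else np.random.default_rng(spec.seed)

    x = (np.arange(nx) - (nx - 1) / 2.0) * spacing_mm
    y = (np.arange(ny) - (ny - 1) / 2.0) * spacing_mm
    r2 = x[:, None] ** 2 + y[None, :] ** 2
    depths = (np.arange(nz) + 0.5) * spacing_mm
    idd = np.asarray(spec.depth_dose(depths))
    values = np.zeros((nx, ny, nz), dtype=np.float64)
    r80 = spec.r80_true_mm
    for k, d in enumerate(depths):
        if idd[k] <= 0.0:
            continue
        sc = float(spec.sigma_central(ssd_mm + d, d))
        un = float(spec.halo_spec.u_n(r80, d))
        sn = float(spec.halo_spec.sigma_n(r80, d))
        kern = (1.0 - un) / (2.0 * np.pi * sc**2) * np.exp(-r2 / (2.0 * sc**2))
        if un > 0:
            kern += un / (2.0 * np.pi * sn**2) * np.exp(-r2 / (2.0 * sn**2))
        values[:, :, k] = spec.mu_per_spot * idd[k] * kern
    if spec.noise_sd_rel > 0:
        values *= 1.0 + spec.noise_sd_rel * rng.standard_normal(values.shape)
        np.maximum(values, 0.0, out=values)

    origin = np.array([x[0], y[0], 0.5 * spacing_mm])
    return ImageGrid(
        values=values,
        spacing_mm=spacing_mm,
        origin_mm=origin,
        role=GridRole.DOSE_PHYSICAL,
        meta={"ssd_mm": float(ssd_mm), "mu": spec.mu_per_spot, "energy_mev": spec.energy_mev,
              "spec": spec.to_meta()},
    )


def generate_commissioning_set(
    spec: SyntheticBeamSpec,
    ssds_mm: list[float],
    spacing_mm: float = 1.0,
    grid_shape: tuple[int, int, int] = (80, 80, 350),
) -> list[ImageGrid]:
    """One pristine-peak grid per SSD with per-SSD derived seeds."""
    if len(set(ssds_mm)) < 3:
        raise ValueError("commissioning needs >= 3 distinct SSDs (quadratic sigma_air fit)")
    children = np.random.SeedSequence(spec.seed).spawn(len(ssds_mm))
    return [
        generate_pristine_grid(spec, ssd, spacing_mm, grid_shape, rng=np.random.default_rng(child))
        for ssd, child in zip(ssds_mm, children)
    ]


# ------------------------------------------------- truth-derived models


def build_true_layer(
    spec: SyntheticBeamSpec,
    zw_ref_fraction: float = 0.7,
    depth_step_mm: float = 1.0,
) -> EnergyLayerModel:
    """Beam-model layer taken directly from the generator ground truth.

    Tables use the same half-voxel depth nodes as the generated grids; the
    sigma_air / sigma_mcs split is expressed in the commissioning basis
    (sigma_mcs zero at z_w,ref).
    """
    n = int(np.ceil(1.05 * spec.r80_true_mm / depth_step_mm)) + 1
    zw = (np.arange(n) + 0.5) * depth_step_mm
    return EnergyLayerModel(
        energy_mev=spec.energy_mev,
        idd_zw_mm=zw,
        idd=np.asarray(spec.depth_dose(zw)),
        sigma_mcs_zw_mm=zw.copy(),
        sigma_mcs=np.asarray(spec.expected_sigma_mcs(zw, zw_ref_fraction)),
        sigma_air_coeffs=spec.expected_sigma_air_coeffs(zw_ref_fraction),
        r80_mm=spec.r80_true_mm,
    )


def make_synthetic_library(
    energies_mev: list[float],
    sad_mm: float = 1635.0,
    zw_ref_fraction: float = 0.7,
    **spec_kwargs,
) -> BeamModelLibrary:
    """Library of ground-truth layers for a list of nominal energies."""
    layers = [
        build_true_layer(SyntheticBeamSpec(energy_mev=e, **spec_kwargs), zw_ref_fraction)
        for e in energies_mev
    ]
    return BeamModelLibrary.from_layers(layers, sad_mm=sad_mm)
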