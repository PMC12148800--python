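"""Double-Gaussian pencil-beam dose engine.

Dose to a point from one mono-energetic spot is

    D(x) = MU * IDD(E, z_w) * K_t(E, x, z_w)

with IDD the integrated depth-dose (cGy mm^2 / MU) looked up at the voxel's
water-equivalent depth z_w, and K_t the total lateral kernel (1/mm^2):

    K_t = (1 - u_n) * G(r; sigma_c) + u_n * G(r; sigma_n)

where G is the rotationally symmetric normalized 2D Gaussian, r the distance
from the voxel to the spot's central axis, sigma_c = sigma_air(z) +
sigma_mcs(z_w) the central width (clamped below at a configurable floor,
since the additive decomposition can turn negative for pathological fits),
and (u_n, sigma_n) the nuclear-halo fraction and width.  Spot axes diverge
from the single effective source through each spot's isocenter-plane
position, consistent with the sigma_air(z) divergence model.

Raytracing runs once per beam; spots then accumulate additively, so the
result is independent of accumulation order up to float round-off and linear
in every spot's MU.
"""

from __future__ import annotations

import dataclasses
import math
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

from .beam_model import BeamModelLibrary, EnergyLayerModel, canon_energy
from .grids import GridRole, HuToSrTable, ImageGrid, hu_to_sr
from .halo import HaloModel
from .raytrace import BeamGeometry, beam_axis, bev_axes, compute_wepl, smooth_wepl, source_position

SIGMA_FLOOR_MM = 0.5


# ------------------------------------------------------------------ types


@dataclass
class Spot:
    x_mm: float
    y_mm: float
    mu: float
    energy_label: float

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError(f"spot MU must be >= 0, got {self.mu}")


@dataclass
class Beam:
    geometry: BeamGeometry
    spots: list[Spot] = field(default_factory=list)


@dataclass
class Plan:
    beams: list[Beam] = field(default_factory=list)
    rbe: float = 1.1
    fractions: int = 1

    def __post_init__(self) -> None:
        if not self.rbe > 0:
            raise ValueError("rbe must be > 0")
        if self.fractions < 1:
            raise ValueError("fractions must be >= 1")


@dataclass
class KernelParams:
    """Resolved per-point kernel parameters (all sigmas in mm)."""

    sigma_c: float
    sigma_air: float
    sigma_mcs: float
    u_n: float
    sigma_n: float


# ------------------------------------------------------------- kernel math


def central_sigma(
    layer: EnergyLayerModel, z: float, zw: float, sigma_floor: float = SIGMA_FLOOR_MM
) -> float:
    """sigma_air(z) + sigma_mcs(z_w), clamped below at the sigma floor."""
    return max(float(layer.sigma_air_at(z)) + float(layer.sigma_mcs_at(zw)), sigma_floor)


def kernel_total(params: KernelParams, r: np.ndarray | float) -> np.ndarray | float:
    """Total double-Gaussian lateral kernel (1/mm^2); integrates to 1 over the plane."""
    r2 = np.asarray(r, dtype=np.float64) ** 2
    sc2 = params.sigma_c**2
    sn2 = params.sigma_n**2
    out = (1.0 - params.u_n) / (2.0 * np.pi * sc2) * np.exp(-r2 / (2.0 * sc2))
    if params.u_n > 0:
        out = out + params.u_n / (2.0 * np.pi * sn2) * np.exp(-r2 / (2.0 * sn2))
    return float(out) if np.isscalar(r) else out


# ----------------------------------------------------------- dose engine


def _resolve_geometry(geom: BeamGeometry, lib: BeamModelLibrary) -> BeamGeometry:
    if geom.sad_mm is None:
        return dataclasses.replace(geom, sad_mm=lib.sad_mm)
    return geom


def _check_spots_resolvable(beam: Beam, lib: BeamModelLibrary) -> None:
    for spot in beam.spots:
        if canon_energy(spot.energy_label) not in lib.energy_index:
            raise KeyError(
                f"energy label {spot.energy_label} not found in beam-model library "
                "(no nearest-energy fallback is applied)"
            )


def beam_dose(
    sr: ImageGrid,
    beam: Beam,
    lib: BeamModelLibrary,
    halo: HaloModel | None = None,
    sigma_floor: float = SIGMA_FLOOR_MM,
    cutoff_sigmas: float = 5.0,
    wepl: ImageGrid | None = None,
) -> ImageGrid:
    """Physical dose (cGy) for one beam on the Sr grid.

    Raytracing (WEPL + lateral smoothing) runs once for the beam; every spot
    then adds MU * IDD(z_w) * K_t(r) per voxel.  Kernel contributions beyond
    ``cutoff_sigmas`` times the wider Gaussian sigma are skipped (< 4e-6 of
    the kernel mass at the default 5).  A precomputed smoothed WEPL grid may
    be passed to share raytracing across calls with identical geometry.
    """
    if sr.role is not GridRole.SR:
        raise ValueError(f"beam_dose expects an Sr grid, got role {sr.role.value}")
    halo = halo if halo is not None else HaloModel()
    _check_spots_resolvable(beam, lib)
    dose = np.zeros(sr.shape, dtype=np.float64)
    out = sr.copy(values=dose, role=GridRole.DOSE_PHYSICAL)
    if not beam.spots:
        return out

    geom = _resolve_geometry(beam.geometry, lib)
    if wepl is None:
        wepl = smooth_wepl(compute_wepl(sr, geom), geom)
    elif not wepl.same_geometry(sr):
        raise ValueError("precomputed WEPL grid does not match the Sr grid geometry")

    src = source_position(geom)
    axis = beam_axis(geom)
    u, v = bev_axes(geom)
    nx, ny, nz = sr.shape
    s = sr.spacing_mm
    cx = (sr.origin_mm[0] + s * np.arange(nx) - src[0])[:, None, None]
    cy = (sr.origin_mm[1] + s * np.arange(ny) - src[1])[None, :, None]
    cz = (sr.origin_mm[2] + s * np.arange(nz) - src[2])[None, None, :]
    vec_x = np.broadcast_to(cx, sr.shape).ravel()
    vec_y = np.broadcast_to(cy, sr.shape).ravel()
    vec_z = np.broadcast_to(cz, sr.shape).ravel()
    v2 = vec_x**2 + vec_y**2 + vec_z**2
    z_from_source = vec_x * axis[0] + vec_y * axis[1] + vec_z * axis[2]
    zw = wepl.values.ravel()

    dose_flat = dose.reshape(-1)
    spots_by_layer: dict[float, list[Spot]] = {}
    for spot in beam.spots:
        spots_by_layer.setdefault(canon_energy(spot.energy_label), []).append(spot)

    for label, spots in spots_by_layer.items():
        layer = lib.layer_for(label)
        idd_v = np.interp(zw, layer.idd_zw_mm, layer.idd)
        idd_v[zw > layer.idd_zw_mm[-1]] = 0.0
        c0, c1, c2 = layer.sigma_air_coeffs
        sigma_air = c0 + c1 * z_from_source + c2 * z_from_source**2
        sigma_mcs = np.interp(zw, layer.sigma_mcs_zw_mm, layer.sigma_mcs)
        sc = np.maximum(sigma_air + sigma_mcs, sigma_floor)
        un = np.clip(np.asarray(halo.u_n(layer.r80_mm, zw), dtype=np.float64), 0.0, 1.0 - 1e-12)
        sn = np.maximum(np.asarray(halo.sigma_n(layer.r80_mm, zw), dtype=np.float64), sigma_floor)
        amp_c = (1.0 - un) / (2.0 * np.pi * sc**2)
        amp_n = un / (2.0 * np.pi * sn**2)
        inv2_c = 1.0 / (2.0 * sc**2)
        inv2_n = 1.0 / (2.0 * sn**2)
        r2_cut = (cutoff_sigmas * np.maximum(sc, sn)) ** 2
        live = idd_v > 0.0
        for spot in spots:
            p = geom.isocenter_mm + spot.x_mm * u + spot.y_mm * v
            a = p - src
            a /= np.linalg.norm(a)
            t = vec_x * a[0] + vec_y * a[1] + vec_z * a[2]
            r2 = v2 - t**2
            sel = live & (r2 <= r2_cut)
            if not np.any(sel):
                continue
            r2s = r2[sel]
            k = amp_c[sel] * np.exp(-r2s * inv2_c[sel]) + amp_n[sel] * np.exp(-r2s * inv2_n[sel])
            dose_flat[sel] += spot.mu * idd_v[sel] * k
    return out


def plan_dose(
    hu: ImageGrid,
    plan: Plan,
    lib: BeamModelLibrary,
    table: HuToSrTable | None = None,
    halo: HaloModel | None = None,
    report: str = "physical",
    total: bool = False,
) -> ImageGrid:
    """Sum per-beam doses on an HU grid; ``report='rbe'`` applies the uniform RBE.

    Returns per-fraction dose unless ``total`` is set, in which case the dose
    is multiplied by the plan's fraction count.
    """
    if report not in ("physical", "rbe"):
        raise ValueError(f"report must be 'physical' or 'rbe', got {report!r}")
    sr = hu_to_sr(hu, table)
    acc = np.zeros(hu.shape, dtype=np.float64)
    for beam in plan.beams:
        acc += beam_dose(sr, beam, lib, halo).values
    if total:
        acc *= plan.fractions
    if report == "rbe":
        acc *= plan.rbe
        role = GridRole.DOSE_RBE
    else:
        role = GridRole.DOSE_PHYSICAL
    return hu.copy(values=acc, role=role)


# ------------------------------------------------------------ test oracle


def _interp_table(x: float, xs: np.ndarray, ys: np.ndarray, beyond_zero: bool) -> float:
    """Scalar linear interpolation with explicit end handling (oracle path)."""
    if x <= xs[0]:
        return float(ys[0])
    if x >= xs[-1]:
        return 0.0 if beyond_zero else float(ys[-1])
    i = bisect_right(xs.tolist(), x)
    x0, x1 = xs[i - 1], xs[i]
    y0, y1 = ys[i - 1], ys[i]
    return float(y0 + (y1 - y0) * (x - x0) / (x1 - x0))


def brute_force_beam_dose(
    sr: ImageGrid,
    beam: Beam,
    lib: BeamModelLibrary,
    halo: HaloModel | None = None,
    sigma_floor: float = SIGMA_FLOOR_MM,
    cutoff_sigmas: float = 5.0,
    wepl: ImageGrid | None = None,
) -> ImageGrid:
    """Unoptimized per-voxel/per-spot reference implementation of beam_dose.

    Shares only the raytraced WEPL field (validated separately against its
    own slow oracle); kernel evaluation, spot-axis geometry, table lookups
    and accumulation are written independently as explicit scalar loops.
    """
    if sr.role is not GridRole.SR:
        raise ValueError(f"brute_force_beam_dose expects an Sr grid, got role {sr.role.value}")
    halo = halo if halo is not None else HaloModel()
    _check_spots_resolvable(beam, lib)
    dose = np.zeros(sr.shape, dtype=np.float64)
    out = sr.copy(values=dose, role=GridRole.DOSE_PHYSICAL)
    if not beam.spots:
        return out
    geom = _resolve_geometry(beam.geometry, lib)
    if wepl is None:
        wepl = smooth_wepl(compute_wepl(sr, geom), geom)

    src = source_position(geom)
    axis = beam_axis(geom)
    u, v = bev_axes(geom)
    spot_axes = []
    for spot in beam.spots:
        px = geom.isocenter_mm[0] + spot.x_mm * u[0] + spot.y_mm * v[0]
        py = geom.isocenter_mm[1] + spot.x_mm * u[1] + spot.y_mm * v[1]
        pz = geom.isocenter_mm[2] + spot.x_mm * u[2] + spot.y_mm * v[2]
        ax, ay, az = px - src[0], py - src[1], pz - src[2]
        norm = math.sqrt(ax * ax + ay * ay + az * az)
        spot_axes.append((ax / norm, ay / norm, az / norm))

    s = sr.spacing_mm
    nx, ny, nz = sr.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                wx = sr.origin_mm[0] + s * i - src[0]
                wy = sr.origin_mm[1] + s * j - src[1]
                wz = sr.origin_mm[2] + s * k - src[2]
                zsrc = wx * axis[0] + wy * axis[1] + wz * axis[2]
                zw_v = wepl.values[i, j, k]
                total = 0.0
                for spot, (ax, ay, az) in zip(beam.spots, spot_axes):
                    layer = lib.layer_for(spot.energy_label)
                    idd = _interp_table(zw_v, layer.idd_zw_mm, layer.idd, beyond_zero=True)
                    if idd <= 0.0:
                        continue
                    smcs = _interp_table(zw_v, layer.sigma_mcs_zw_mm, layer.sigma_mcs, beyond_zero=False)
                    c0, c1, c2 = layer.sigma_air_coeffs
                    sc = c0 + c1 * zsrc + c2 * zsrc * zsrc + smcs
                    if sc < sigma_floor:
                        sc = sigma_floor
                    un = float(halo.u_n(layer.r80_mm, zw_v))
                    sn = max(float(halo.sigma_n(layer.r80_mm, zw_v)), sigma_floor)
                    # perpendicular distance to the diverging spot axis
                    tproj = wx * ax + wy * ay + wz * az
                    ex, ey, ez = wx - tproj * ax, wy - tproj * ay, wz - tproj * az
                    r2 = ex * ex + ey * ey + ez * ez
                    if r2 > (cutoff_sigmas * max(sc, sn)) ** 2:
                        continue
                    kval = (1.0 - un) / (2.0 * math.pi * sc * sc) * math.exp(-r2 / (2.0 * sc * sc))
                    kval += un / (2.0 * math.pi * sn * sn) * math.exp(-r2 / (2.0 * sn * sn))
                    total += spot.mu * idd * kval
                dose[i, j, k] = total
    return out
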