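"""Automated beam-model commissioning from pristine-Bragg-peak dose grids.

From single-spot 3D dose grids exported at several effective SSDs, one
energy layer is built in five stages:

1. IDD extraction: at each depth the lateral plane sum times the voxel area,
   normalized by the delivered MU (cGy mm^2 / MU); averaged across SSDs.
2. R80: distal 80 %-of-maximum crossing of the averaged IDD by linear
   interpolation.
3. Lateral sigma: a 2D Gaussian least-squares fit per 1 mm depth slice gives
   sigma_c versus z_w for each SSD.  When the (a-priori fixed) nuclear-halo
   parameterization is supplied, its contribution is included in the fit
   model with frozen parameters so the central sigma is not inflated by the
   halo tail; otherwise a plain single Gaussian is fitted.
4. sigma_air: quadratic least squares of sigma_c(z_w,ref) against distance
   from the effective source across SSDs, with z_w,ref = 0.7 R80.
5. sigma_mcs: the average of sigma_c(z_w) - sigma_c(z_w,ref) across SSDs
   (zero at the reference depth by construction, negative above it).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

from .beam_model import EnergyLayerModel
from .grids import DOSE_ROLES, ImageGrid
from .halo import HaloModel


@dataclass
class DepthTable:
    """A quantity tabulated against depth (or water-equivalent depth), mm."""

    zw_mm: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.zw_mm = np.asarray(self.zw_mm, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.zw_mm.shape != self.values.shape or self.zw_mm.ndim != 1:
            raise ValueError("DepthTable needs matching 1D arrays")

    def at(self, zw: float) -> float:
        return float(np.interp(zw, self.zw_mm, self.values))


@dataclass
class FitConfig:
    ssd_list_mm: list[float]
    zw_ref_fraction: float = 0.7
    depth_step_mm: float = 1.0
    mu_per_spot: float = 0.2
    # Commissioning grids are water-tank exports, so depth advances z and z_w
    # together: the raw sigma_c(z_w) - sigma_c(z_w,ref) difference contains
    # the in-air divergence growth over the depth interval, which the engine
    # would apply a second time through sigma_air(z).  When enabled, the
    # fitted quadratic's own growth is subtracted from each profile before
    # differencing, making the sigma_air/sigma_mcs decomposition
    # self-consistent under the engine's independent (z, z_w) evaluation.
    correct_air_growth: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.zw_ref_fraction < 1:
            raise ValueError("zw_ref_fraction must be in (0, 1)")
        if len(set(self.ssd_list_mm)) < 3:
            raise ValueError("need >= 3 distinct SSDs for the quadratic sigma_air fit")


# ------------------------------------------------------------------- IDD


def extract_idd(grid: ImageGrid, mu: float, depth_step_mm: float = 1.0) -> DepthTable:
    """Plane-integrated depth dose normalized by MU (cGy mm^2 / MU).

    Depth nodes are the grid's native z coordinates (depth below the tank
    surface), resampled to ``depth_step_mm`` if the grid spacing differs.
    Warns if the beam appears laterally truncated.
    """
    if grid.role not in DOSE_ROLES:
        raise ValueError(f"extract_idd expects a dose grid, got role {grid.role.value}")
    if not mu > 0:
        raise ValueError("mu must be > 0")
    vals = grid.values
    plane_max = vals.max(axis=(0, 1))
    edge = np.concatenate([vals[0, :, :], vals[-1, :, :], vals[:, 0, :], vals[:, -1, :]], axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        bad = np.any(edge.max(axis=0) > 1.0e-3 * np.where(plane_max > 0, plane_max, np.inf))
    if bad:
        warnings.warn("beam laterally truncated: edge dose exceeds 0.1% of plane maximum")
    idd = vals.sum(axis=(0, 1)) * grid.spacing_mm**2 / mu
    zw = grid.axis_coords(2)
    if abs(depth_step_mm - grid.spacing_mm) > 1e-9:
        zw_new = np.arange(zw[0], zw[-1] + 1e-9, depth_step_mm)
        idd = np.interp(zw_new, zw, idd)
        zw = zw_new
    return DepthTable(zw_mm=zw, values=idd)


def average_idds(idds: list[DepthTable]) -> DepthTable:
    if not idds:
        raise ValueError("no IDD tables to average")
    zw = idds[0].zw_mm
    for t in idds[1:]:
        if t.zw_mm.shape != zw.shape or not np.allclose(t.zw_mm, zw):
            raise ValueError("IDD tables have mismatched depth grids")
    return DepthTable(zw_mm=zw.copy(), values=np.mean([t.values for t in idds], axis=0))


def compute_r80(idd: DepthTable) -> float:
    """Depth where the distal falloff reaches 80 % of the Bragg-peak dose.

    The Bragg peak is the distal-most local maximum of significant height
    (>= half the global maximum) — for axial single-spot curves at high
    energy the entrance dose can exceed the Bragg peak because the entrance
    kernel is much narrower, so the global maximum is not the peak.  The
    crossing of 0.8 times the peak value beyond the peak is located by
    linear interpolation.
    """
    v = idd.values
    n = v.size
    gmax = float(v.max())
    step = float(np.median(np.diff(idd.zw_mm))) if n > 1 else 1.0
    w = max(1, int(round(5.0 / step)))  # 5 mm prominence window
    interior = np.nonzero((v[1:-1] >= v[:-2]) & (v[1:-1] >= v[2:]) & (v[1:-1] >= 0.25 * gmax))[0] + 1
    candidates = [i for i in interior if v[i] >= v[max(0, i - w): i + w + 1].max()]
    imax = int(candidates[-1]) if candidates else int(np.argmax(v))
    level = 0.8 * v[imax]
    below = np.nonzero(v[imax:] < level)[0]
    if below.size == 0:
        raise ValueError("no distal 80% crossing: curve does not fall below 0.8 of its peak")
    j = imax + below[0]
    z0, z1 = idd.zw_mm[j - 1], idd.zw_mm[j]
    v0, v1 = v[j - 1], v[j]
    return float(z0 + (v0 - level) / (v0 - v1) * (z1 - z0))


# -------------------------------------------------------- lateral sigmas


def _gauss2d(xy, amp, x0, y0, sx, sy):
    x, y = xy
    return amp * np.exp(-((x - x0) ** 2) / (2 * sx**2) - ((y - y0) ** 2) / (2 * sy**2))


def _moments(plane: np.ndarray, x: np.ndarray, y: np.ndarray):
    total = plane.sum()
    x0 = float((plane.sum(axis=1) * x).sum() / total)
    y0 = float((plane.sum(axis=0) * y).sum() / total)
    vx = float((plane.sum(axis=1) * (x - x0) ** 2).sum() / total)
    vy = float((plane.sum(axis=0) * (y - y0) ** 2).sum() / total)
    return x0, y0, np.sqrt(max(vx, 1e-12)), np.sqrt(max(vy, 1e-12))


def fit_lateral_sigma(
    plane: np.ndarray,
    spacing_mm: float = 1.0,
    x_mm: np.ndarray | None = None,
    y_mm: np.ndarray | None = None,
    window_sigmas: float = 3.0,
    fixed_halo: tuple[float, float] | None = None,
    full: bool = False,
):
    """Least-squares 2D Gaussian fit of one lateral dose slice.

    Fits independent sigma_x / sigma_y with free centre and amplitude over
    the central window ``r <= window_sigmas * moment-sigma`` and returns the
    x/y mean sigma (mm).  With ``fixed_halo = (u_n, sigma_n)`` the fit model
    is the double Gaussian with halo fraction and width frozen, isolating the
    central component.
    """
    plane = np.asarray(plane, dtype=np.float64)
    if x_mm is None:
        x_mm = (np.arange(plane.shape[0]) - (plane.shape[0] - 1) / 2.0) * spacing_mm
    if y_mm is None:
        y_mm = (np.arange(plane.shape[1]) - (plane.shape[1] - 1) / 2.0) * spacing_mm
    if plane.max() <= 0:
        raise ValueError("plane has no positive dose to fit")
    x0, y0, mx, my = _moments(plane, x_mm, y_mm)
    m_sig = 0.5 * (mx + my)
    xx, yy = np.meshgrid(x_mm, y_mm, indexing="ij")
    sel = (xx - x0) ** 2 + (yy - y0) ** 2 <= (window_sigmas * m_sig) ** 2
    if sel.sum() < 8:
        raise ValueError("fit window contains too few voxels (spot under-sampled)")
    xs, ys, vs = xx[sel], yy[sel], plane[sel]

    if fixed_halo is None:
        model = _gauss2d
    else:
        u_n, sigma_n = fixed_halo

        def model(xy, amp, cx, cy, sx, sy):
            x, y = xy
            r2 = (x - cx) ** 2 + (y - cy) ** 2
            central = (1.0 - u_n) / (2 * np.pi * sx * sy) * np.exp(
                -((x - cx) ** 2) / (2 * sx**2) - ((y - cy) ** 2) / (2 * sy**2)
            )
            haloterm = u_n / (2 * np.pi * sigma_n**2) * np.exp(-r2 / (2 * sigma_n**2))
            return amp * (central + haloterm)

    amp0 = vs.max() if fixed_halo is None else float(plane.sum() * (x_mm[1] - x_mm[0]) ** 2)
    p0 = [amp0, x0, y0, m_sig, m_sig]
    try:
        with warnings.catch_warnings():
            # parameter covariance is unused; noiseless slices make it singular
            warnings.simplefilter("ignore", category=OptimizeWarning)
            popt, _ = curve_fit(model, (xs, ys), vs, p0=p0, maxfev=10000)
    except RuntimeError as exc:
        raise ValueError(f"lateral sigma fit did not converge: {exc}") from exc
    sx, sy = abs(popt[3]), abs(popt[4])
    if full:
        return 0.5 * (sx + sy), popt
    return 0.5 * (sx + sy)


def sigma_c_profile(
    grid: ImageGrid,
    halo: HaloModel | None = None,
    r80_mm: float | None = None,
    min_rel_signal: float = 1.0e-3,
) -> DepthTable:
    """sigma_c versus z_w from per-depth-slice Gaussian fits.

    Slices whose maximum is below ``min_rel_signal`` of the grid maximum
    (beyond the range) are skipped.  When ``halo`` and ``r80_mm`` are given
    the per-slice fixed-halo fit is used.
    """
    if grid.role not in DOSE_ROLES:
        raise ValueError(f"sigma_c_profile expects a dose grid, got role {grid.role.value}")
    if (halo is None) != (r80_mm is None):
        raise ValueError("halo and r80_mm must be supplied together")
    x = grid.axis_coords(0)
    y = grid.axis_coords(1)
    zw = grid.axis_coords(2)
    gmax = grid.values.max()
    depths, sigmas = [], []
    for k in range(grid.shape[2]):
        plane = grid.values[:, :, k]
        if plane.max() < min_rel_signal * gmax:
            continue
        fixed = None
        if halo is not None:
            fixed = (float(halo.u_n(r80_mm, zw[k])), float(halo.sigma_n(r80_mm, zw[k])))
        sigmas.append(fit_lateral_sigma(plane, grid.spacing_mm, x, y, fixed_halo=fixed))
        depths.append(zw[k])
    return DepthTable(zw_mm=np.array(depths), values=np.array(sigmas))


def fit_sigma_air(points: list[tuple[float, float]]) -> tuple[tuple[float, float, float], np.ndarray]:
    """Quadratic least squares of sigma versus source distance z.

    Returns ((c0, c1, c2), residuals) with sigma_air(z) = c0 + c1 z + c2 z^2.
    """
    if len(points) < 3:
        raise ValueError("quadratic sigma_air fit needs >= 3 points")
    z = np.array([p[0] for p in points], dtype=np.float64)
    sig = np.array([p[1] for p in points], dtype=np.float64)
    if np.unique(z).size < 3:
        raise ValueError("sigma_air fit needs >= 3 distinct source distances")
    # centred/scaled design for conditioning, mapped back to raw coefficients
    z0 = z.mean()
    zs = z - z0
    a, b, c = np.polynomial.polynomial.polyfit(zs, sig, 2)
    c0 = a - b * z0 + c * z0**2
    c1 = b - 2 * c * z0
    c2 = c
    fitted = c0 + c1 * z + c2 * z**2
    return (float(c0), float(c1), float(c2)), sig - fitted


def build_sigma_mcs(
    profiles_by_ssd: list[DepthTable], config: FitConfig, r80_mm: float
) -> DepthTable:
    """Average of sigma_c(z_w) - sigma_c(z_w,ref) across SSDs."""
    zw_ref = config.zw_ref_fraction * r80_mm
    zw = profiles_by_ssd[0].zw_mm
    for p in profiles_by_ssd[1:]:
        if p.zw_mm.shape != zw.shape or not np.allclose(p.zw_mm, zw):
            raise ValueError("sigma_c profiles have mismatched depth grids")
    if not (zw[0] <= zw_ref <= zw[-1]):
        raise ValueError(f"z_w,ref = {zw_ref:.1f} mm outside the profiled depth range")
    diffs = [p.values - p.at(zw_ref) for p in profiles_by_ssd]
    return DepthTable(zw_mm=zw.copy(), values=np.mean(diffs, axis=0))


# ------------------------------------------------------------ end to end


def build_energy_model(
    grids_by_ssd: list[ImageGrid],
    config: FitConfig,
    halo: HaloModel | None = None,
    energy_mev: float | None = None,
) -> EnergyLayerModel:
    """Compose the full commissioning pipeline into one energy layer.

    ``halo`` should be the same parameterization the dose engine will use;
    it is frozen inside the lateral fits, not fitted.
    """
    if len(grids_by_ssd) != len(config.ssd_list_mm):
        raise ValueError("one grid per SSD in config.ssd_list_mm is required")
    if energy_mev is None:
        energy_mev = float(grids_by_ssd[0].meta.get("energy_mev", 0.0))

    try:
        idds = [extract_idd(g, config.mu_per_spot, config.depth_step_mm) for g in grids_by_ssd]
        idd = average_idds(idds)
    except Exception as exc:
        raise RuntimeError(f"commissioning failed at stage IDD extraction: {exc}") from exc
    try:
        r80 = compute_r80(idd)
    except Exception as exc:
        raise RuntimeError(f"commissioning failed at stage R80: {exc}") from exc
    try:
        profiles = [
            sigma_c_profile(g, halo=halo, r80_mm=(r80 if halo is not None else None))
            for g in grids_by_ssd
        ]
    except Exception as exc:
        raise RuntimeError(f"commissioning failed at stage lateral sigma fits: {exc}") from exc
    zw_ref = config.zw_ref_fraction * r80
    try:
        pts = [
            (float(ssd) + zw_ref, prof.at(zw_ref))
            for ssd, prof in zip(config.ssd_list_mm, profiles)
        ]
        coeffs, _ = fit_sigma_air(pts)
    except Exception as exc:
        raise RuntimeError(f"commissioning failed at stage sigma_air fit: {exc}") from exc
    try:
        # trim sigma_c profiles to a common depth grid before differencing
        n_common = min(p.zw_mm.size for p in profiles)
        trimmed = [DepthTable(p.zw_mm[:n_common], p.values[:n_common]) for p in profiles]
        if config.correct_air_growth:
            c0f, c1f, c2f = coeffs

            def _q(z):
                return c0f + c1f * z + c2f * z**2

            trimmed = [
                DepthTable(p.zw_mm, p.values - (_q(ssd + p.zw_mm) - _q(ssd + zw_ref)))
                for ssd, p in zip(config.ssd_list_mm, trimmed)
            ]
        mcs = build_sigma_mcs(trimmed, config, r80)
    except Exception as exc:
        raise RuntimeError(f"commissioning failed at stage sigma_mcs table: {exc}") from exc

    return EnergyLayerModel(
        energy_mev=energy_mev,
        idd_zw_mm=idd.zw_mm,
        idd=np.maximum(idd.values, 0.0),
        sigma_mcs_zw_mm=mcs.zw_mm,
        sigma_mcs=mcs.values,
        sigma_air_coeffs=coeffs,
        r80_mm=r80,
    )
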