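"""Dose-distribution comparison toolkit: 3D gamma, DVH metrics, depth-dose.

Gamma analysis uses the generalized-distance formulation with global dose
normalization: a reference voxel above the analysis threshold gets

    gamma = min over offsets o of sqrt( dd(o)^2 + |o|^2 / dta^2 )

with dd(o) the dose difference between the evaluated grid interpolated at
the offset position and the reference voxel, as a fraction of the dose
criterion times the global reference maximum.  The search ball has radius
2 * dta with 0.25 * dta interpolation steps, which makes pass/fail (gamma
<= 1) decisions exact near the criterion while bounding cost.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .commissioning import DepthTable, compute_r80  # noqa: F401  (re-exported analytics)
from .grids import DOSE_ROLES, ImageGrid
from .raytrace import BeamGeometry, beam_axis, source_position


@dataclass
class GammaCriteria:
    dose_pct: float
    dta_mm: float
    threshold_pct: float = 10.0

    def __post_init__(self) -> None:
        if not (self.dose_pct > 0 and self.dta_mm > 0 and self.threshold_pct > 0):
            raise ValueError("gamma criteria must all be > 0")


@dataclass
class GammaResult:
    pass_rate: float          # % of analyzed voxels with gamma <= 1, 0.1% resolution
    gamma_map: np.ndarray     # per-voxel gamma; NaN outside the analyzed set
    n_analyzed: int


def _search_offsets(dta_mm: float, radius_factor: float, step_factor: float) -> np.ndarray:
    step = step_factor * dta_mm
    radius = radius_factor * dta_mm
    m = int(np.floor(radius / step + 1e-9))
    axis = np.arange(-m, m + 1) * step
    ox, oy, oz = np.meshgrid(axis, axis, axis, indexing="ij")
    offs = np.stack([ox.ravel(), oy.ravel(), oz.ravel()], axis=1)
    d2 = (offs**2).sum(axis=1)
    offs = offs[d2 <= radius**2 + 1e-9]
    return offs[np.argsort((offs**2).sum(axis=1), kind="stable")]


def gamma_3d(
    reference: ImageGrid,
    evaluated: ImageGrid,
    criteria: GammaCriteria,
    search_radius_factor: float = 2.0,
    search_step_factor: float = 0.25,
) -> GammaResult:
    """3D gamma of ``evaluated`` against ``reference`` on a shared geometry."""
    if reference.role not in DOSE_ROLES or evaluated.role not in DOSE_ROLES:
        raise ValueError("gamma_3d expects dose grids")
    if not reference.same_geometry(evaluated):
        raise ValueError("grids have mismatched geometry; resample first")
    ref = reference.values
    dmax = float(ref.max())
    if dmax <= 0:
        raise ValueError("reference grid has no positive dose")
    analyzed = ref > criteria.threshold_pct / 100.0 * dmax
    idx = np.argwhere(analyzed).T.astype(np.float64)  # (3, N) index coords
    ref_vals = ref[analyzed]
    dose_norm = criteria.dose_pct / 100.0 * dmax

    offsets = _search_offsets(criteria.dta_mm, search_radius_factor, search_step_factor)
    gamma2 = np.full(ref_vals.shape, np.inf)
    spacing = reference.spacing_mm
    for off in offsets:
        spatial2 = float(off @ off) / criteria.dta_mm**2
        if spatial2 >= gamma2.max():
            break  # offsets sorted by distance: no voxel can improve further
        coords = idx + (off / spacing)[:, None]
        ev_vals = ndimage.map_coordinates(evaluated.values, coords, order=1, mode="nearest")
        dd2 = ((ev_vals - ref_vals) / dose_norm) ** 2
        np.minimum(gamma2, dd2 + spatial2, out=gamma2)

    gamma = np.sqrt(gamma2)
    gmap = np.full(ref.shape, np.nan)
    gmap[analyzed] = gamma
    n = int(ref_vals.size)
    rate = 100.0 * float(np.count_nonzero(gamma <= 1.0 + 1e-9)) / n
    return GammaResult(pass_rate=round(rate, 1), gamma_map=gmap, n_analyzed=n)


# ------------------------------------------------------------------- DVH

_METRIC_RE = re.compile(
    r"^(?:(?P<dmean>D_?mean)|D_?(?P<dpct>[\d.]+)\s*%|D_?(?P<dcc>[\d.]+)\s*cc|V_?(?P<vdose>[\d.]+)\s*(?:cGy)?)$",
    re.IGNORECASE,
)


@dataclass
class DvhResult:
    metrics: dict[str, float]  # metric spec string -> value (cGy for D, % for V)

    def __getitem__(self, key: str) -> float:
        return self.metrics[key]


def dvh_metrics(dose: ImageGrid, mask: np.ndarray, metrics: list[str]) -> DvhResult:
    """Dose-volume metrics over a structure mask.

    Supported metric strings: ``Dmean``, ``D<x>%`` (dose exceeded by x % of
    the structure volume), ``D<x>cc`` (dose to the hottest x cm^3) and
    ``V<x>cGy`` (% of the structure receiving at least x cGy).
    """
    if dose.role not in DOSE_ROLES:
        raise ValueError("dvh_metrics expects a dose grid")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dose.shape:
        raise ValueError("mask geometry does not match the dose grid")
    vox = dose.values[mask]
    if vox.size == 0:
        raise ValueError("empty structure mask")
    sorted_desc = np.sort(vox)[::-1]
    n = vox.size
    # cumulative volume fraction receiving >= sorted_desc[i]
    frac = (np.arange(n) + 0.5) / n
    voxel_cc = dose.voxel_volume_mm3() / 1000.0

    out: dict[str, float] = {}
    for spec in metrics:
        m = _METRIC_RE.match(spec.strip())
        if not m:
            raise ValueError(f"unrecognized DVH metric {spec!r}")
        if m.group("dmean"):
            out[spec] = float(vox.mean())
        elif m.group("dpct") is not None:
            x = float(m.group("dpct")) / 100.0
            out[spec] = float(np.interp(x, frac, sorted_desc))
        elif m.group("dcc") is not None:
            x = float(m.group("dcc")) / (n * voxel_cc)
            out[spec] = float(np.interp(x, frac, sorted_desc))
        else:
            level = float(m.group("vdose"))
            out[spec] = 100.0 * float(np.count_nonzero(vox >= level)) / n
    return DvhResult(metrics=out)


# ----------------------------------------------------------- depth dose


def axial_depth_dose(dose: ImageGrid, geom: BeamGeometry, step_mm: float = 1.0) -> DepthTable:
    """Dose sampled along the beam's central axis at fixed depth steps.

    Depth 0 is where the axis enters the grid's outer bounding box (the
    physical phantom surface for grids whose first slice face is the
    surface); samples use trilinear interpolation, clamped at the box.
    """
    if dose.role not in DOSE_ROLES:
        raise ValueError("axial_depth_dose expects a dose grid")
    src = source_position(geom)
    d = beam_axis(geom)
    half = 0.5 * dose.spacing_mm
    lo = dose.origin_mm - half
    hi = dose.origin_mm + (np.array(dose.shape) - 1) * dose.spacing_mm + half
    t0, t1 = -np.inf, np.inf
    for ax in range(3):
        if abs(d[ax]) < 1e-12:
            if not (lo[ax] <= src[ax] <= hi[ax]):
                raise ValueError("beam central axis does not intersect the dose grid")
            continue
        ta = (lo[ax] - src[ax]) / d[ax]
        tb = (hi[ax] - src[ax]) / d[ax]
        t0 = max(t0, min(ta, tb))
        t1 = min(t1, max(ta, tb))
    if not t0 < t1:
        raise ValueError("beam central axis does not intersect the dose grid")
    depths = np.arange(0.0, t1 - t0 + 1e-9, step_mm)
    pts = src[None, :] + (t0 + depths)[:, None] * d[None, :]
    coords = (pts - dose.origin_mm[None, :]).T / dose.spacing_mm
    vals = ndimage.map_coordinates(dose.values, coords, order=1, mode="nearest")
    return DepthTable(zw_mm=depths, values=vals)
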