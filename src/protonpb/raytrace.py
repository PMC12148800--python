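"""Water-equivalent path length (WEPL) raytracing toward the effective source.

For every voxel the water-equivalent depth z_w is the line integral of the
relative stopping power Sr from the voxel back toward the effective proton
source (back-projection), terminated where the ray leaves the image.  For
grids padded with air (Sr ~ 0) outside the patient this is equivalent to
integrating from the patient surface.  Integration uses midpoint sampling at
a fixed step of half a voxel with trilinear Sr interpolation (zero outside
the grid).

Geometry follows IEC 61217: in the fixed coordinate system X points to the
patient's left, Y to the head, Z up (anterior).  At gantry 0 the source lies
on the +Z axis; the gantry rotates the source about Y, and a couch rotation
turns the patient about Z (implemented by counter-rotating the source and
beam's-eye axes).

A lateral smoothing step mitigates z_w sampling artifacts and approximates
tortuous proton paths: each voxel's z_w is replaced by the unweighted mean of
z_w over a disc perpendicular to the beam axis, of radius 5 mm where
z_w > 5 mm and radius z_w where z_w <= 5 mm; discs smaller than one voxel
leave the value unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit, prange

from .grids import GridRole, ImageGrid


@dataclass
class BeamGeometry:
    """Beam orientation and effective-source distance (IEC 61217 angles)."""

    gantry_deg: float
    couch_deg: float
    isocenter_mm: np.ndarray
    sad_mm: float | None = None  # resolved from the beam-model library if None

    def __post_init__(self) -> None:
        self.isocenter_mm = np.asarray(self.isocenter_mm, dtype=np.float64).reshape(3)
        if self.sad_mm is not None and not self.sad_mm > 0:
            raise ValueError("sad_mm must be > 0")

    def _require_sad(self) -> float:
        if self.sad_mm is None:
            raise ValueError("BeamGeometry.sad_mm is unset; resolve it from the library first")
        return float(self.sad_mm)


def _rot(geom: BeamGeometry) -> np.ndarray:
    """Fixed-system rotation taking gantry-0/couch-0 directions to this beam."""
    g = np.deg2rad(geom.gantry_deg)
    c = np.deg2rad(geom.couch_deg)
    ry = np.array([[np.cos(g), 0.0, np.sin(g)], [0.0, 1.0, 0.0], [-np.sin(g), 0.0, np.cos(g)]])
    rz = np.array([[np.cos(c), np.sin(c), 0.0], [-np.sin(c), np.cos(c), 0.0], [0.0, 0.0, 1.0]])
    return rz @ ry


def source_position(geom: BeamGeometry) -> np.ndarray:
    """Effective proton source position in patient coordinates (mm)."""
    return geom.isocenter_mm + geom._require_sad() * (_rot(geom) @ np.array([0.0, 0.0, 1.0]))


def beam_axis(geom: BeamGeometry) -> np.ndarray:
    """Unit vector pointing downstream (from source toward isocenter)."""
    return _rot(geom) @ np.array([0.0, 0.0, -1.0])


def bev_axes(geom: BeamGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Beam's-eye-view in-plane unit vectors (u, v) for spot (x, y) positions."""
    r = _rot(geom)
    return r @ np.array([1.0, 0.0, 0.0]), r @ np.array([0.0, 1.0, 0.0])


# ------------------------------------------------------------ numba kernels


@njit(cache=False)
def _trilinear(vals, xi, yi, zi):
    """Trilinear interpolation in index coordinates, zero outside the grid."""
    nx, ny, nz = vals.shape
    if xi <= -1.0 or yi <= -1.0 or zi <= -1.0 or xi >= nx or yi >= ny or zi >= nz:
        return 0.0
    x0 = int(np.floor(xi)); y0 = int(np.floor(yi)); z0 = int(np.floor(zi))
    fx = xi - x0; fy = yi - y0; fz = zi - z0
    acc = 0.0
    for dx in range(2):
        wx = fx if dx == 1 else 1.0 - fx
        ix = x0 + dx
        if ix < 0 or ix >= nx:
            continue
        for dy in range(2):
            wy = fy if dy == 1 else 1.0 - fy
            iy = y0 + dy
            if iy < 0 or iy >= ny:
                continue
            for dz in range(2):
                wz = fz if dz == 1 else 1.0 - fz
                iz = z0 + dz
                if iz < 0 or iz >= nz:
                    continue
                acc += wx * wy * wz * vals[ix, iy, iz]
    return acc


@njit(parallel=True, cache=False)
def _wepl_kernel(sr, spacing, origin, source, step_mm):
    nx, ny, nz = sr.shape
    out = np.empty((nx, ny, nz), dtype=np.float64)
    for flat in prange(nx * ny * nz):
        i = flat // (ny * nz)
        j = (flat // nz) % ny
        k = flat % nz
        px = origin[0] + spacing * i
        py = origin[1] + spacing * j
        pz = origin[2] + spacing * k
        dx = source[0] - px
        dy = source[1] - py
        dz = source[2] - pz
        dist = np.sqrt(dx * dx + dy * dy + dz * dz)
        ux = dx / dist
        uy = dy / dist
        uz = dz / dist
        acc = 0.0
        t = 0.5 * step_mm
        while t < dist:
            xi = (px + t * ux - origin[0]) / spacing
            yi = (py + t * uy - origin[1]) / spacing
            zi = (pz + t * uz - origin[2]) / spacing
            if xi <= -1.0 or yi <= -1.0 or zi <= -1.0 or xi >= nx or yi >= ny or zi >= nz:
                break  # left the image (box is convex: never re-enters)
            acc += _trilinear(sr, xi, yi, zi) * step_mm
            t += step_mm
        out[i, j, k] = acc
    return out


@njit(parallel=True, cache=False)
def _smooth_kernel(wepl, spacing, origin, uvec, vvec, radius_mm):
    nx, ny, nz = wepl.shape
    out = np.empty((nx, ny, nz), dtype=np.float64)
    for flat in prange(nx * ny * nz):
        i = flat // (ny * nz)
        j = (flat // nz) % ny
        k = flat % nz
        zw = wepl[i, j, k]
        r = radius_mm if zw > radius_mm else zw
        if r < spacing:
            out[i, j, k] = zw
            continue
        m = int(r / spacing)
        px = origin[0] + spacing * i
        py = origin[1] + spacing * j
        pz = origin[2] + spacing * k
        acc = 0.0
        cnt = 0
        for a in range(-m, m + 1):
            for b in range(-m, m + 1):
                if (a * a + b * b) * spacing * spacing > r * r:
                    continue
                qx = px + spacing * (a * uvec[0] + b * vvec[0])
                qy = py + spacing * (a * uvec[1] + b * vvec[1])
                qz = pz + spacing * (a * uvec[2] + b * vvec[2])
                xi = (qx - origin[0]) / spacing
                yi = (qy - origin[1]) / spacing
                zi = (qz - origin[2]) / spacing
                if xi < 0.0 or yi < 0.0 or zi < 0.0 or xi > nx - 1.0 or yi > ny - 1.0 or zi > nz - 1.0:
                    continue  # disc sample outside the grid: excluded from the mean
                acc += _trilinear(wepl, xi, yi, zi)
                cnt += 1
        out[i, j, k] = acc / cnt if cnt > 0 else zw
    return out


# ------------------------------------------------------------- public API


def compute_wepl(sr: ImageGrid, geom: BeamGeometry, step_fraction: float = 0.5) -> ImageGrid:
    """Per-voxel water-equivalent path length by back-projection raytracing."""
    if sr.role is not GridRole.SR:
        raise ValueError(f"compute_wepl expects an Sr grid, got role {sr.role.value}")
    src = source_position(geom)
    step = step_fraction * sr.spacing_mm
    values = _wepl_kernel(sr.values, sr.spacing_mm, sr.origin_mm, src, step)
    np.maximum(values, 0.0, out=values)
    return sr.copy(values=values, role=GridRole.WEPL)


def smooth_wepl(wepl: ImageGrid, geom: BeamGeometry, radius_mm: float = 5.0) -> ImageGrid:
    """Disc-average z_w in the beam-perpendicular plane.

    Radius is ``radius_mm`` for voxels with z_w > radius_mm, else z_w itself;
    voxels whose disc is smaller than one voxel are unchanged.  Disc samples
    are taken on a voxel-pitch Cartesian pattern spanned by the beam's-eye
    axes, so for axis-aligned beams the samples coincide with voxel centres.
    """
    if wepl.role is not GridRole.WEPL:
        raise ValueError(f"smooth_wepl expects a WEPL grid, got role {wepl.role.value}")
    u, v = bev_axes(geom)
    values = _smooth_kernel(wepl.values, wepl.spacing_mm, wepl.origin_mm, u, v, float(radius_mm))
    return wepl.copy(values=values, role=GridRole.WEPL)
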