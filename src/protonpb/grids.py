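"""Isotropic 3D image grids, HU-to-stopping-power conversion, and digital phantoms.

The engine operates exclusively on isotropic voxel grids in a right-handed
patient coordinate system: grid index ``(i, j, k)`` maps to physical position
``origin_mm + spacing_mm * (i, j, k)`` in mm, with ``origin_mm`` the centre of
voxel ``(0, 0, 0)``.  A single grid container is role-specialised as an HU
image, a relative-stopping-power (Sr) map, a water-equivalent-path-length
(WEPL) map, or a dose distribution.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage


class GridRole(str, enum.Enum):
    HU = "HU"
    SR = "Sr"
    WEPL = "WEPL"
    DOSE_PHYSICAL = "DOSE_PHYSICAL"
    DOSE_RBE = "DOSE_RBE"


DOSE_ROLES = (GridRole.DOSE_PHYSICAL, GridRole.DOSE_RBE)


@dataclass
class ImageGrid:
    """One 3D scalar field on an isotropic grid.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel values; float64.
    spacing_mm : float
        Isotropic voxel size in mm (one value for all three axes).
    origin_mm : ndarray, shape (3,)
        Physical position (mm) of the centre of voxel (0, 0, 0).
    role : GridRole
        What the scalar field represents.
    meta : dict
        Free-form JSON-serialisable metadata (e.g. SSD of a commissioning
        export, the MU it was generated with).
    """

    values: np.ndarray
    spacing_mm: float
    origin_mm: np.ndarray
    role: GridRole
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3D, got shape {self.values.shape}")
        self.spacing_mm = float(self.spacing_mm)
        if not self.spacing_mm > 0:
            raise ValueError(f"spacing_mm must be > 0, got {self.spacing_mm}")
        self.origin_mm = np.asarray(self.origin_mm, dtype=np.float64).reshape(3)
        self.role = GridRole(self.role)
        if self.role in (GridRole.SR, GridRole.WEPL) + DOSE_ROLES:
            if not np.all(np.isfinite(self.values)):
                raise ValueError(f"{self.role.value} grid contains non-finite values")
            if np.any(self.values < 0):
                raise ValueError(f"{self.role.value} grid contains negative values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centres along one axis."""
        n = self.shape[axis]
        return self.origin_mm[axis] + self.spacing_mm * np.arange(n)

    def voxel_volume_mm3(self) -> float:
        return self.spacing_mm**3

    def copy(self, values: np.ndarray | None = None, role: GridRole | None = None) -> "ImageGrid":
        return ImageGrid(
            values=self.values.copy() if values is None else values,
            spacing_mm=self.spacing_mm,
            origin_mm=self.origin_mm.copy(),
            role=self.role if role is None else role,
            meta=dict(self.meta),
        )

    def same_geometry(self, other: "ImageGrid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and abs(self.spacing_mm - other.spacing_mm) <= tol
            and bool(np.all(np.abs(self.origin_mm - other.origin_mm) <= tol))
        )

    # ---------------------------------------------------------------- I/O
    def save(self, path: str | Path) -> None:
        """Write the grid as a MetaImage (.mha) file.

        Role and metadata are stored in the MetaImage header so the grid
        round-trips through :meth:`load`.
        """
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(self.values.T))
        img.SetSpacing((self.spacing_mm,) * 3)
        img.SetOrigin(tuple(float(v) for v in self.origin_mm))
        img.SetMetaData("protonpb_role", self.role.value)
        img.SetMetaData("protonpb_meta", json.dumps(self.meta, sort_keys=True))
        sitk.WriteImage(img, str(path))

    @classmethod
    def load(cls, path: str | Path) -> "ImageGrid":
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        spacing = img.GetSpacing()
        if max(spacing) - min(spacing) > 1e-6 * max(spacing):
            raise ValueError(f"non-isotropic image {path}: spacing {spacing}")
        role = GridRole(img.GetMetaData("protonpb_role")) if img.HasMetaDataKey("protonpb_role") else GridRole.HU
        meta = json.loads(img.GetMetaData("protonpb_meta")) if img.HasMetaDataKey("protonpb_meta") else {}
        values = sitk.GetArrayFromImage(img).T.astype(np.float64)
        return cls(values=values, spacing_mm=spacing[0], origin_mm=np.array(img.GetOrigin()), role=role, meta=meta)


# -------------------------------------------------------------- HU -> Sr


# Water-anchored piecewise-linear calibration covering air through dense bone.
# Placeholder stoichiometric-style curve, user-replaceable via CSV; any
# monotone, water-anchored table exercises the same code paths.
_DEFAULT_HU_SR = [
    (-1000.0, 0.001),
    (-800.0, 0.190),
    (-700.0, 0.290),
    (-500.0, 0.500),
    (-100.0, 0.950),
    (0.0, 1.000),
    (100.0, 1.070),
    (500.0, 1.290),
    (1000.0, 1.560),
    (1500.0, 1.800),
]


@dataclass
class HuToSrTable:
    """Piecewise-linear HU -> relative stopping power calibration."""

    hu: np.ndarray
    sr: np.ndarray

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu, dtype=np.float64)
        self.sr = np.asarray(self.sr, dtype=np.float64)
        if self.hu.ndim != 1 or self.hu.shape != self.sr.shape or self.hu.size < 2:
            raise ValueError("table needs matching 1D hu/sr arrays with >= 2 breakpoints")
        if np.any(np.diff(self.hu) <= 0):
            raise ValueError("HU breakpoints must be strictly increasing")
        if np.any(self.sr < 0):
            raise ValueError("Sr values must be >= 0")
        if abs(float(np.interp(0.0, self.hu, self.sr)) - 1.0) > 1e-9:
            raise ValueError("table must satisfy the water anchor Sr(HU=0) = 1.0")

    @classmethod
    def default(cls) -> "HuToSrTable":
        hu, sr = zip(*_DEFAULT_HU_SR)
        return cls(hu=np.array(hu), sr=np.array(sr))

    def __call__(self, hu: np.ndarray | float) -> np.ndarray:
        """Scalar/array lookup, clamped to end values outside the table."""
        return np.interp(hu, self.hu, self.sr)

    @classmethod
    def from_csv(cls, path: str | Path) -> "HuToSrTable":
        df = pd.read_csv(path)
        return cls(hu=df["hu"].to_numpy(), sr=df["sr"].to_numpy())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"hu": self.hu, "sr": self.sr}).to_csv(path, index=False)


def hu_to_sr(hu: ImageGrid, table: HuToSrTable | None = None) -> ImageGrid:
    """Convert an HU grid to a relative-stopping-power grid voxelwise."""
    if hu.role is not GridRole.HU:
        raise ValueError(f"hu_to_sr expects an HU grid, got role {hu.role.value}")
    table = table if table is not None else HuToSrTable.default()
    return hu.copy(values=table(hu.values), role=GridRole.SR)


# ---------------------------------------------------------- resampling


def resample_isotropic(grid: ImageGrid, new_spacing_mm: float) -> ImageGrid:
    """Trilinearly resample onto an isotropic grid covering the same extent.

    The new grid keeps the old origin; new voxel centres never extend past
    the old voxel-centre extent, so no extrapolation is required.
    """
    new_spacing_mm = float(new_spacing_mm)
    if not new_spacing_mm > 0:
        raise ValueError(f"new_spacing_mm must be > 0, got {new_spacing_mm}")
    old = grid.spacing_mm
    new_shape = tuple(int(np.floor((n - 1) * old / new_spacing_mm + 1e-9)) + 1 for n in grid.shape)
    idx = [np.arange(n) * new_spacing_mm / old for n in new_shape]
    coords = np.meshgrid(*idx, indexing="ij")
    values = ndimage.map_coordinates(grid.values, coords, order=1, mode="nearest")
    return ImageGrid(
        values=values,
        spacing_mm=new_spacing_mm,
        origin_mm=grid.origin_mm.copy(),
        role=grid.role,
        meta=dict(grid.meta),
    )


# ------------------------------------------------------------ phantoms
#
# Phantoms are built for irradiation along the +z grid axis: the beam enters
# the k = 0 face and "depth" below means physical distance from that face.


def _centered_origin(shape: tuple[int, int, int], spacing_mm: float) -> np.ndarray:
    """Origin putting (x, y) = (0, 0) at the lateral centre and z = 0 at the entry face."""
    nx, ny, _ = shape
    return np.array([-(nx - 1) / 2.0 * spacing_mm, -(ny - 1) / 2.0 * spacing_mm, 0.0])


def make_water_phantom(shape: tuple[int, int, int], spacing_mm: float) -> ImageGrid:
    """Homogeneous digital water phantom (HU = 0 everywhere)."""
    return ImageGrid(
        values=np.zeros(shape, dtype=np.float64),
        spacing_mm=spacing_mm,
        origin_mm=_centered_origin(tuple(shape), float(spacing_mm)),
        role=GridRole.HU,
    )


def make_het_phantom(
    shape: tuple[int, int, int],
    spacing_mm: float,
    insert_depth_mm: float = 70.0,
    insert_thickness_mm: float = 50.0,
    lung_hu: float = -700.0,
    bone_hu: float = 500.0,
) -> ImageGrid:
    """Water phantom with side-by-side lung and bone slab inserts.

    The inserts start at ``insert_depth_mm`` below the entry face (k = 0) and
    are ``insert_thickness_mm`` thick along the beam direction; the lung slab
    occupies the x < 0 half, the bone slab the x > 0 half, with the tissue
    interface parallel to the beam axis.
    """
    grid = make_water_phantom(shape, spacing_mm)
    z = grid.axis_coords(2)
    x = grid.axis_coords(0)
    k_in = (z >= insert_depth_mm) & (z < insert_depth_mm + insert_thickness_mm)
    if insert_depth_mm < 0 or insert_depth_mm + insert_thickness_mm > z[-1]:
        raise ValueError(
            f"inserts [{insert_depth_mm}, {insert_depth_mm + insert_thickness_mm}] mm "
            f"do not fit in the grid depth extent [0, {z[-1]}] mm"
        )
    lung_cols = x < 0
    bone_cols = x > 0
    vals = grid.values
    vals[np.ix_(lung_cols, np.ones(shape[1], bool), k_in)] = lung_hu
    vals[np.ix_(bone_cols, np.ones(shape[1], bool), k_in)] = bone_hu
    return grid
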