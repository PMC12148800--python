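"""Per-energy beam-model tables: IDD, in-medium sigma, in-air sigma, R80.

Each nominal beam energy is described by three components: a lookup table of
the integrated depth-dose IDD versus water-equivalent depth z_w
(cGy mm^2 / MU, 1 mm resolution), a lookup table of the multiple-Coulomb-
scattering spot sigma sigma_mcs versus z_w (mm), and the coefficients of a
quadratic in distance-from-effective-source z giving the in-air spot sigma
sigma_air (mm).  The library is persisted as diff-friendly CSV files, one per
energy, plus a master list mapping plan energy labels to file indices.

Conventions:

* IDD queried below the first table node returns the first value (entrance
  plateau); beyond the last node it returns 0 (the proton has stopped).
* sigma_mcs is clamped to the nearest end value outside the table.  It is
  zero at the reference depth z_w,ref by construction of the commissioning
  fit and may be negative at shallower depths; positivity is enforced only
  on the final central sigma in the dose engine.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


def canon_energy(label: float) -> float:
    """Canonical float key for a nominal-energy label (0.001 MeV resolution)."""
    return round(float(label), 3)


@dataclass
class EnergyLayerModel:
    """Beam-model content for one nominal energy."""

    energy_mev: float
    idd_zw_mm: np.ndarray      # depth nodes, mm (1 mm resolution, increasing)
    idd: np.ndarray            # cGy mm^2 / MU at each node
    sigma_mcs_zw_mm: np.ndarray
    sigma_mcs: np.ndarray      # mm; 0 at z_w,ref by fit construction
    sigma_air_coeffs: tuple[float, float, float]  # (c0, c1, c2): sigma_air(z) = c0 + c1 z + c2 z^2
    r80_mm: float

    def __post_init__(self) -> None:
        self.energy_mev = float(self.energy_mev)
        self.idd_zw_mm = np.asarray(self.idd_zw_mm, dtype=np.float64)
        self.idd = np.asarray(self.idd, dtype=np.float64)
        self.sigma_mcs_zw_mm = np.asarray(self.sigma_mcs_zw_mm, dtype=np.float64)
        self.sigma_mcs = np.asarray(self.sigma_mcs, dtype=np.float64)
        self.sigma_air_coeffs = tuple(float(c) for c in self.sigma_air_coeffs)  # type: ignore[assignment]
        self.r80_mm = float(self.r80_mm)
        self.validate()

    def validate(self) -> None:
        if self.idd_zw_mm.shape != self.idd.shape or self.idd_zw_mm.ndim != 1:
            raise ValueError("IDD table arrays must be matching 1D arrays")
        if np.any(np.diff(self.idd_zw_mm) <= 0):
            raise ValueError("IDD depth column must be strictly increasing")
        if np.any(np.diff(self.sigma_mcs_zw_mm) <= 0):
            raise ValueError("sigma_mcs depth column must be strictly increasing")
        if not np.all(np.isfinite(self.idd)) or np.any(self.idd < 0):
            raise ValueError("IDD values must be finite and >= 0")
        if not np.all(np.isfinite(self.sigma_mcs)):
            raise ValueError("sigma_mcs values must be finite")
        if not (0 < self.r80_mm <= self.idd_zw_mm[-1]):
            raise ValueError(
                f"r80_mm = {self.r80_mm} must lie within the IDD depth domain "
                f"(0, {self.idd_zw_mm[-1]}]"
            )

    # ------------------------------------------------------------ queries
    def idd_at(self, zw: np.ndarray | float) -> np.ndarray | float:
        """IDD at water-equivalent depth zw (mm); 0 beyond the table."""
        zw_arr = np.asarray(zw, dtype=np.float64)
        if np.any(zw_arr < 0):
            raise ValueError("zw must be >= 0")
        out = np.interp(zw_arr, self.idd_zw_mm, self.idd)
        out = np.where(zw_arr > self.idd_zw_mm[-1], 0.0, out)
        return float(out) if np.isscalar(zw) else out

    def sigma_mcs_at(self, zw: np.ndarray | float) -> np.ndarray | float:
        """In-medium sigma at zw (mm); clamped to end values outside the table."""
        zw_arr = np.asarray(zw, dtype=np.float64)
        if np.any(zw_arr < 0):
            raise ValueError("zw must be >= 0")
        out = np.interp(zw_arr, self.sigma_mcs_zw_mm, self.sigma_mcs)
        return float(out) if np.isscalar(zw) else out

    def sigma_air_at(self, z: np.ndarray | float) -> np.ndarray | float:
        """In-air sigma at distance z (mm) from the effective source."""
        z_arr = np.asarray(z, dtype=np.float64)
        if np.any(z_arr <= 0):
            raise ValueError("z must be > 0")
        c0, c1, c2 = self.sigma_air_coeffs
        out = c0 + c1 * z_arr + c2 * z_arr**2
        return float(out) if np.isscalar(z) else out


@dataclass
class BeamModelLibrary:
    """Ordered collection of per-energy layers plus the plan-label index."""

    layers: list[EnergyLayerModel]
    energy_index: dict[float, int]  # canonical energy label -> index into layers
    sad_mm: float

    def __post_init__(self) -> None:
        self.sad_mm = float(self.sad_mm)
        self.validate()

    def validate(self) -> None:
        if not self.sad_mm > 0:
            raise ValueError("sad_mm must be > 0")
        labels = [canon_energy(lay.energy_mev) for lay in self.layers]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate energy labels in library")
        for label, idx in self.energy_index.items():
            if not 0 <= idx < len(self.layers):
                raise ValueError(f"energy label {label} maps to missing layer index {idx}")

    def layer_for(self, energy_label: float) -> EnergyLayerModel:
        key = canon_energy(energy_label)
        if key not in self.energy_index:
            raise KeyError(f"energy label {energy_label} not in beam-model library")
        return self.layers[self.energy_index[key]]

    @classmethod
    def from_layers(cls, layers: list[EnergyLayerModel], sad_mm: float) -> "BeamModelLibrary":
        index = {canon_energy(lay.energy_mev): i for i, lay in enumerate(layers)}
        return cls(layers=list(layers), energy_index=index, sad_mm=sad_mm)


# ----------------------------------------------------------------- I/O

_MASTER_NAME = "beam_model_index.csv"


def _fmt(x: float) -> str:
    return repr(float(x))


def save_library(lib: BeamModelLibrary, path: str | Path) -> None:
    """Write one CSV per energy plus the master-list CSV.

    File content is deterministic for identical input, so two saves of the
    same library are byte-identical.
    """
    lib.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = sorted(lib.energy_index.items())
    master = io.StringIO()
    master.write(f"# sad_mm={_fmt(lib.sad_mm)}\n")
    master.write("energy_label_mev,file_index\n")
    for label, idx in rows:
        master.write(f"{_fmt(label)},{idx}\n")
    (path / _MASTER_NAME).write_text(master.getvalue())

    for idx, layer in enumerate(lib.layers):
        buf = io.StringIO()
        c0, c1, c2 = layer.sigma_air_coeffs
        buf.write(f"# energy_mev={_fmt(layer.energy_mev)}\n")
        buf.write(f"# r80_mm={_fmt(layer.r80_mm)}\n")
        buf.write(f"# sigma_air_c0={_fmt(c0)}\n")
        buf.write(f"# sigma_air_c1={_fmt(c1)}\n")
        buf.write(f"# sigma_air_c2={_fmt(c2)}\n")
        buf.write("zw_mm,idd_cgy_mm2_per_mu,sigma_mcs_mm\n")
        # IDD and sigma_mcs share the 1 mm depth grid in commissioned models;
        # if they differ, sigma_mcs is stored resampled onto the IDD grid.
        if layer.sigma_mcs_zw_mm.shape == layer.idd_zw_mm.shape and np.allclose(
            layer.sigma_mcs_zw_mm, layer.idd_zw_mm
        ):
            smcs = layer.sigma_mcs
        else:
            smcs = np.interp(layer.idd_zw_mm, layer.sigma_mcs_zw_mm, layer.sigma_mcs)
        for zw, idd, sm in zip(layer.idd_zw_mm, layer.idd, smcs):
            buf.write(f"{_fmt(zw)},{_fmt(idd)},{_fmt(sm)}\n")
        (path / f"energy_{idx:03d}.csv").write_text(buf.getvalue())


def _parse_header(lines: list[str]) -> dict[str, float]:
    out: dict[str, float] = {}
    for line in lines:
        if not line.startswith("#"):
            break
        key, _, val = line[1:].strip().partition("=")
        out[key.strip()] = float(val)
    return out


def load_library(path: str | Path) -> BeamModelLibrary:
    """Load a library saved by :func:`save_library` (exact round trip)."""
    path = Path(path)
    master_path = path / _MASTER_NAME
    if not master_path.is_file():
        raise FileNotFoundError(f"missing master list {master_path}")
    text = master_path.read_text().splitlines()
    header = _parse_header(text)
    if "sad_mm" not in header:
        raise ValueError(f"master list {master_path} lacks a sad_mm header line")
    body = "\n".join(line for line in text if not line.startswith("#"))
    master = pd.read_csv(io.StringIO(body), float_precision="round_trip")

    energy_index: dict[float, int] = {}
    n_layers = int(master["file_index"].max()) + 1 if len(master) else 0
    layers: list[EnergyLayerModel | None] = [None] * n_layers
    for _, row in master.iterrows():
        label = canon_energy(row["energy_label_mev"])
        idx = int(row["file_index"])
        fname = path / f"energy_{idx:03d}.csv"
        if not fname.is_file():
            raise FileNotFoundError(f"master list references index {idx} but {fname} is absent")
        if layers[idx] is None:
            ltext = fname.read_text().splitlines()
            lhead = _parse_header(ltext)
            lbody = "\n".join(line for line in ltext if not line.startswith("#"))
            df = pd.read_csv(io.StringIO(lbody), float_precision="round_trip")
            zw = df["zw_mm"].to_numpy()
            if np.any(np.diff(zw) <= 0):
                raise ValueError(f"{fname}: non-monotone depth column")
            layers[idx] = EnergyLayerModel(
                energy_mev=lhead["energy_mev"],
                idd_zw_mm=zw,
                idd=df["idd_cgy_mm2_per_mu"].to_numpy(),
                sigma_mcs_zw_mm=zw.copy(),
                sigma_mcs=df["sigma_mcs_mm"].to_numpy(),
                sigma_air_coeffs=(lhead["sigma_air_c0"], lhead["sigma_air_c1"], lhead["sigma_air_c2"]),
                r80_mm=lhead["r80_mm"],
            )
        energy_index[label] = idx
    if any(lay is None for lay in layers):
        missing = [i for i, lay in enumerate(layers) if lay is None]
        raise ValueError(f"layer indices {missing} not referenced by the master list")
    return BeamModelLibrary(layers=layers, energy_index=energy_index, sad_mm=header["sad_mm"])  # type: ignore[arg-type]
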