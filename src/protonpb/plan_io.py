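"""Plan and dose I/O: internal JSON plans, DICOM RT Ion Plan, DICOM RT Dose.

The internal JSON plan format is the canonical test-facing format:

    {
      "rbe": 1.1,
      "fractions": 1,
      "beams": [
        {"gantry_deg": 0.0, "couch_deg": 0.0, "isocenter_mm": [0, 0, 0],
         "spots": [{"x_mm": 0.0, "y_mm": 0.0, "mu": 1.0, "energy_mev": 150.0}]}
      ]
    }

Readers validate strictly and reject rather than guess: unknown fields,
missing attributes and negative MUs are errors naming the offending path.
DICOM RT Ion Plan reading resolves spot MUs by proportional scaling of the
scan-spot meterset weights with the beam meterset over the final cumulative
meterset weight.  Dose grids are written as DICOM RT Dose in Gy (internal
cGy converted) with 32-bit scaled integer pixels.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .engine import Beam, Plan, Spot
from .grids import DOSE_ROLES, GridRole, ImageGrid
from .raytrace import BeamGeometry

_RT_DOSE_CLASS = "1.2.840.10008.5.1.4.1.1.481.2"
_RT_ION_PLAN_CLASS = "1.2.840.10008.5.1.4.1.1.481.8"


# ------------------------------------------------------------------ JSON

_BEAM_KEYS = {"gantry_deg", "couch_deg", "isocenter_mm", "spots"}
_SPOT_KEYS = {"x_mm", "y_mm", "mu", "energy_mev"}
_PLAN_KEYS = {"rbe", "fractions", "beams"}


def read_plan_json(path: str | Path) -> Plan:
    """Read and validate a plan from the internal JSON format."""
    with open(path) as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: plan document must be a JSON object")
    unknown = set(doc) - _PLAN_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown top-level fields {sorted(unknown)}")
    beams = []
    for bi, b in enumerate(doc.get("beams", [])):
        loc = f"{path}: beams[{bi}]"
        unknown = set(b) - _BEAM_KEYS
        if unknown:
            raise ValueError(f"{loc}: unknown fields {sorted(unknown)}")
        missing = _BEAM_KEYS - set(b)
        if missing:
            raise ValueError(f"{loc}: missing fields {sorted(missing)}")
        spots = []
        for si, s in enumerate(b["spots"]):
            sloc = f"{loc}.spots[{si}]"
            unknown = set(s) - _SPOT_KEYS
            if unknown:
                raise ValueError(f"{sloc}: unknown fields {sorted(unknown)}")
            missing = _SPOT_KEYS - set(s)
            if missing:
                raise ValueError(f"{sloc}: missing fields {sorted(missing)}")
            if s["mu"] < 0:
                raise ValueError(f"{sloc}: negative MU {s['mu']}")
            spots.append(Spot(x_mm=float(s["x_mm"]), y_mm=float(s["y_mm"]),
                              mu=float(s["mu"]), energy_label=float(s["energy_mev"])))
        geom = BeamGeometry(
            gantry_deg=float(b["gantry_deg"]),
            couch_deg=float(b["couch_deg"]),
            isocenter_mm=np.asarray(b["isocenter_mm"], dtype=float),
        )
        beams.append(Beam(geometry=geom, spots=spots))
    return Plan(beams=beams, rbe=float(doc.get("rbe", 1.1)), fractions=int(doc.get("fractions", 1)))


def write_plan_json(plan: Plan, path: str | Path) -> None:
    doc = {
        "rbe": plan.rbe,
        "fractions": plan.fractions,
        "beams": [
            {
                "gantry_deg": b.geometry.gantry_deg,
                "couch_deg": b.geometry.couch_deg,
                "isocenter_mm": [float(v) for v in b.geometry.isocenter_mm],
                "spots": [
                    {"x_mm": s.x_mm, "y_mm": s.y_mm, "mu": s.mu, "energy_mev": s.energy_label}
                    for s in b.spots
                ],
            }
            for b in plan.beams
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


# ----------------------------------------------------------- DICOM plans


def read_ion_plan_dicom(path: str | Path) -> Plan:
    """Read a spot-scanning DICOM RT Ion Plan.

    Spot MU = meterset weight * beam meterset / final cumulative meterset
    weight; gantry/couch angles and isocenter are taken from the first
    control point of each beam.
    """
    ds = pydicom.dcmread(str(path))
    if getattr(ds, "SOPClassUID", "") != _RT_ION_PLAN_CLASS and getattr(ds, "Modality", "") != "RTIONPLAN":
        raise ValueError(f"{path}: not an RT Ion Plan")
    if "IonBeamSequence" not in ds:
        raise ValueError(f"{path}: missing IonBeamSequence")
    metersets: dict[int, float] = {}
    for fg in getattr(ds, "FractionGroupSequence", []):
        for rb in getattr(fg, "ReferencedBeamSequence", []):
            metersets[int(rb.ReferencedBeamNumber)] = float(rb.BeamMeterset)
    n_fractions = 1
    if "FractionGroupSequence" in ds and len(ds.FractionGroupSequence):
        n_fractions = int(getattr(ds.FractionGroupSequence[0], "NumberOfFractionsPlanned", 1))

    beams = []
    for ib in ds.IonBeamSequence:
        scan_mode = getattr(ib, "ScanMode", "")
        if scan_mode != "MODULATED":
            raise ValueError(
                f"{path}: beam {getattr(ib, 'BeamNumber', '?')} has unsupported scan mode "
                f"{scan_mode!r} (only MODULATED spot scanning is supported)"
            )
        if "IonControlPointSequence" not in ib:
            raise ValueError(f"{path}: beam {ib.BeamNumber} missing IonControlPointSequence")
        cp0 = ib.IonControlPointSequence[0]
        for attr in ("GantryAngle", "PatientSupportAngle", "IsocenterPosition"):
            if attr not in cp0:
                raise ValueError(f"{path}: beam {ib.BeamNumber} first control point missing {attr}")
        final_cum = float(ib.FinalCumulativeMetersetWeight)
        if not final_cum > 0:
            raise ValueError(f"{path}: beam {ib.BeamNumber} has non-positive FinalCumulativeMetersetWeight")
        beam_meterset = metersets.get(int(ib.BeamNumber))
        if beam_meterset is None:
            raise ValueError(f"{path}: no ReferencedBeamSequence meterset for beam {ib.BeamNumber}")
        scale = beam_meterset / final_cum

        spots: list[Spot] = []
        energy = None
        for cp in ib.IonControlPointSequence:
            if "NominalBeamEnergy" in cp:
                energy = float(cp.NominalBeamEnergy)
            if energy is None:
                raise ValueError(f"{path}: beam {ib.BeamNumber} control point lacks NominalBeamEnergy")
            positions = np.asarray(getattr(cp, "ScanSpotPositionMap", []), dtype=float).reshape(-1, 2)
            weights = np.atleast_1d(np.asarray(getattr(cp, "ScanSpotMetersetWeights", []), dtype=float))
            if positions.shape[0] != weights.size:
                raise ValueError(
                    f"{path}: beam {ib.BeamNumber}: ScanSpotPositionMap/ScanSpotMetersetWeights "
                    "length mismatch"
                )
            for (x, y), w in zip(positions, weights):
                if w > 0:
                    spots.append(Spot(x_mm=x, y_mm=y, mu=w * scale, energy_label=energy))
        geom = BeamGeometry(
            gantry_deg=float(cp0.GantryAngle),
            couch_deg=float(cp0.PatientSupportAngle),
            isocenter_mm=np.asarray(cp0.IsocenterPosition, dtype=float),
        )
        beams.append(Beam(geometry=geom, spots=spots))
    return Plan(beams=beams, rbe=1.1, fractions=n_fractions)


def write_ion_plan_dicom(plan: Plan, path: str | Path) -> None:
    """Write a minimal spot-scanning RT Ion Plan (fixture writer).

    Spots are grouped into energy layers per beam, each layer emitted as the
    standard pair of control points (the first carrying the scan-spot
    weights).  Meterset weights are the spot MUs, so the beam meterset
    equals the final cumulative meterset weight.
    """
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = _RT_ION_PLAN_CLASS
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = _RT_ION_PLAN_CLASS
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTIONPLAN"
    ds.RTPlanLabel = "protonpb"

    fg = Dataset()
    fg.NumberOfFractionsPlanned = plan.fractions
    fg.ReferencedBeamSequence = []
    ds.FractionGroupSequence = [fg]
    ds.IonBeamSequence = []

    for bi, beam in enumerate(plan.beams, start=1):
        layers: dict[float, list[Spot]] = {}
        for s in beam.spots:
            layers.setdefault(round(s.energy_label, 3), []).append(s)
        total_mu = sum(s.mu for s in beam.spots)

        ib = Dataset()
        ib.BeamNumber = bi
        ib.BeamName = f"beam{bi}"
        ib.RadiationType = "PROTON"
        ib.ScanMode = "MODULATED"
        ib.BeamType = "STATIC"
        ib.TreatmentDeliveryType = "TREATMENT"
        ib.FinalCumulativeMetersetWeight = total_mu
        ib.NumberOfControlPoints = 2 * len(layers)
        ib.IonControlPointSequence = []
        cum = 0.0
        cp_index = 0
        for energy in sorted(layers):
            spots = layers[energy]
            pos = []
            wts = []
            for s in spots:
                pos.extend([s.x_mm, s.y_mm])
                wts.append(s.mu)
            for half in range(2):
                cp = Dataset()
                cp.ControlPointIndex = cp_index
                cp.NominalBeamEnergy = energy
                cp.CumulativeMetersetWeight = cum if half == 0 else cum + sum(wts)
                cp.NumberOfScanSpotPositions = len(spots)
                cp.ScanSpotPositionMap = [float(v) for v in pos]
                cp.ScanSpotMetersetWeights = [float(w) for w in wts] if half == 0 else [0.0] * len(wts)
                if cp_index == 0:
                    cp.GantryAngle = beam.geometry.gantry_deg
                    cp.PatientSupportAngle = beam.geometry.couch_deg
                    cp.IsocenterPosition = [float(v) for v in beam.geometry.isocenter_mm]
                ib.IonControlPointSequence.append(cp)
                cp_index += 1
            cum += sum(wts)

        ds.IonBeamSequence.append(ib)
        rb = Dataset()
        rb.ReferencedBeamNumber = bi
        rb.BeamMeterset = total_mu
        fg.ReferencedBeamSequence.append(rb)

    ds.save_as(str(path), enforce_file_format=True)


# ------------------------------------------------------------ RT Dose


def write_rt_dose(dose: ImageGrid, path: str | Path) -> None:
    """Write a dose grid as DICOM RT Dose (Gy, 32-bit scaled integers)."""
    if dose.role not in DOSE_ROLES:
        raise ValueError("write_rt_dose expects a dose grid")
    dmax_cgy = float(dose.values.max())
    if dmax_cgy <= 0:
        raise ValueError("refusing to write an all-zero dose grid")
    gy = dose.values / 100.0
    scaling = gy.max() / (2**32 - 1)
    pixels = np.round(gy / scaling).astype(np.uint32)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = _RT_DOSE_CLASS
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = _RT_DOSE_CLASS
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    ds.DoseUnits = "GY"
    ds.DoseType = "EFFECTIVE" if dose.role is GridRole.DOSE_RBE else "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    nx, ny, nz = dose.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.NumberOfFrames = nz
    ds.Rows = ny
    ds.Columns = nx
    ds.PixelSpacing = [dose.spacing_mm, dose.spacing_mm]  # row (y), column (x)
    ds.SliceThickness = dose.spacing_mm
    ds.ImagePositionPatient = [float(v) for v in dose.origin_mm]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.GridFrameOffsetVector = [float(k * dose.spacing_mm) for k in range(nz)]
    ds.DoseGridScaling = scaling
    ds.FrameIncrementPointer = pydicom.tag.Tag(0x3004, 0x000C)
    # DICOM frame layout is (frame=z, row=y, col=x)
    ds.PixelData = np.ascontiguousarray(pixels.transpose(2, 1, 0)).tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def read_rt_dose(path: str | Path) -> ImageGrid:
    """Read a DICOM RT Dose written by :func:`write_rt_dose` back to cGy."""
    ds = pydicom.dcmread(str(path))
    if getattr(ds, "Modality", "") != "RTDOSE":
        raise ValueError(f"{path}: not an RT Dose file")
    spacing = [float(v) for v in ds.PixelSpacing]
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
    dz = float(np.diff(offsets).mean()) if offsets.size > 1 else spacing[0]
    if abs(spacing[0] - spacing[1]) > 1e-6 or abs(spacing[0] - dz) > 1e-6:
        raise ValueError(f"{path}: non-isotropic dose grid is unsupported")
    arr = ds.pixel_array.astype(np.float64)  # (z, y, x)
    gy = arr * float(ds.DoseGridScaling)
    role = GridRole.DOSE_RBE if getattr(ds, "DoseType", "PHYSICAL") == "EFFECTIVE" else GridRole.DOSE_PHYSICAL
    return ImageGrid(
        values=gy.transpose(2, 1, 0) * 100.0,
        spacing_mm=spacing[0],
        origin_mm=np.asarray([float(v) for v in ds.ImagePositionPatient]),
        role=role,
    )
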