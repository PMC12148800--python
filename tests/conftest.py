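"""Shared fixtures: small synthetic beam-model libraries and water-phantom doses.

Everything is generated programmatically; expensive single-spot dose grids
are session-scoped so several tests can share one engine run.
"""

from __future__ import annotations

import numpy as np
import pytest

import protonpb as pb


def surface_beam_geometry(sad_mm: float = 1635.0) -> pb.BeamGeometry:
    """Beam along +z entering the phantom's k = 0 face, isocenter on the surface.

    Phantoms put the voxel-(.,.,0) centre at z = 0, so the physical entry
    face (outer voxel face) is at z = -spacing/2; with 1 mm grids that is
    z = -0.5 and SSD = SAD.
    """
    return pb.BeamGeometry(gantry_deg=180.0, couch_deg=0.0, isocenter_mm=[0.0, 0.0, -0.5], sad_mm=sad_mm)


@pytest.fixture(scope="session")
def lib150() -> pb.BeamModelLibrary:
    """Ground-truth single-energy library (150 MeV, R80 ~ 156 mm)."""
    return pb.make_synthetic_library([150.0], sad_mm=1635.0)


@pytest.fixture(scope="session")
def lib_small() -> pb.BeamModelLibrary:
    """Two low energies for fast engine tests (R80 ~ 41 and 61 mm)."""
    return pb.make_synthetic_library([70.2, 90.0], sad_mm=1635.0)


@pytest.fixture(scope="session")
def water_dose_70(lib_small):
    """Single 70.2 MeV spot, 1 MU, in a 1 mm water phantom; returns
    (dose grid, geometry, layer)."""
    layer = lib_small.layer_for(70.2)
    nz = int(np.ceil(1.05 * layer.r80_mm)) + 3
    hu = pb.make_water_phantom((60, 60, nz), 1.0)
    sr = pb.hu_to_sr(hu)
    geom = surface_beam_geometry(lib_small.sad_mm)
    beam = pb.Beam(geometry=geom, spots=[pb.Spot(0.0, 0.0, 1.0, 70.2)])
    return pb.beam_dose(sr, beam, lib_small), geom, layer


@pytest.fixture(scope="session")
def commissioning_run():
    """A 4-SSD noisy commissioning set plus the fitted layer (R80 ~ 90 mm)."""
    spec = pb.SyntheticBeamSpec(energy_mev=110.0, noise_sd_rel=0.005, seed=11)
    ssds = [1635.0, 1535.0, 1435.0, 1385.0]
    nz = int(np.ceil(1.05 * spec.r80_true_mm)) + 2
    grids = pb.generate_commissioning_set(spec, ssds, 1.0, (70, 70, nz))
    cfg = pb.FitConfig(ssd_list_mm=ssds, mu_per_spot=spec.mu_per_spot)
    layer = pb.build_energy_model(grids, cfg, halo=spec.halo_spec)
    return spec, grids, cfg, layer
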