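# Methods

This note documents the physics model, the commissioning procedure, the
synthetic-data generator used in place of treatment-planning-system (TPS)
exports, the numerical choices, and the known limitations of `protonpb`.

## Dose model

A spot-scanning plan is a set of beams, each a list of spots
(x, y, MU, nominal energy). Dose to a voxel from one spot is

    D = MU · IDD(E, z_w) · K_t(E, r, z, z_w)

with

* **IDD(E, z_w)** — the integrated depth-dose of the energy's pristine Bragg
  peak in water, tabulated at 1 mm steps in water-equivalent depth z_w, in
  cGy·mm²/MU. Because the lateral kernel is normalized, the IDD carries the
  beam's absolute dose calibration. Queries below the first node return the
  first value (entrance plateau); queries beyond the last node return 0 (the
  proton has stopped).
* **K_t** — a double Gaussian in the distance r from the spot's central
  axis: a central component of width σ_c carrying fraction (1 − u_n) of the
  dose and a nuclear-halo component of width σ_n carrying fraction u_n. Both
  components are normalized 2D Gaussians, so K_t integrates to one over any
  beam-perpendicular plane.
* **σ_c = σ_air(z) + σ_mcs(z_w)** — in-air divergence evaluated at the
  distance z from the effective source (a per-energy quadratic, coefficients
  from commissioning) plus in-medium multiple-Coulomb-scattering broadening
  (a per-energy z_w table). σ_mcs is zero at the commissioning reference
  depth by construction and negative above it, so σ_c is clamped below at a
  configurable floor (default 0.5 mm) to prevent singular kernels if a
  pathological fit drives the sum negative.
* **Spot axes** diverge from a single effective source (taken mid-way
  between the scanning magnets, at distance `sad_mm` from the isocenter)
  through the spot's (x, y) position in the isocenter plane. This keeps the
  geometric divergence consistent with the σ_air(z) model.

Assumptions inherited from this model class: no spot decomposition into
computational beamlets, no explicit simulation of particle transport, a
single effective source for both scanning directions, and lateral scatter in
heterogeneous media represented only through z_w and the σ terms.

### Raytracing

z_w is computed per voxel by back-projection: the line integral of relative
stopping power S_r from the voxel toward the effective source, terminated at
the image boundary (equivalent to integrating from the patient surface when
the grid is padded with air). Integration uses midpoint sampling at half a
voxel step with trilinear interpolation; S_r tapers linearly to zero across
the half-voxel shell beyond the outermost voxel centres, i.e. the medium
ends at the outer voxel face. Each voxel's ray is independent, so redundant
work between voxels on one ray is accepted in exchange for a trivially
parallel kernel (numba).

To damp depth-sampling artifacts and mimic the lateral wander of proton
paths, z_w is then averaged over a disc perpendicular to the beam axis:
radius 5 mm where z_w > 5 mm, radius z_w otherwise, and no change where the
disc is smaller than one voxel. The disc is sampled on a voxel-pitch lattice
spanned by the beam's-eye axes, which coincides with voxel centres for
axis-aligned beams. The plane (disc) interpretation, rather than a sphere,
follows from the smoothing's lateral purpose.

### Nuclear halo

The halo fraction u_n(R80, z_w) and width σ_n(R80, z_w) follow the packaged
default parameterization

    u_n = 0.29 · (1 − exp(−R80/350 mm)) · (z_w/R80)^0.6,   capped at z_w = R80
    σ_n = 2.0 mm + 0.045 · R80 · (z_w/R80)^0.8

chosen to reproduce the qualitative behaviour reported for scanned proton
beams: a halo that grows with beam range, builds up with depth to roughly
10–20 % of the local dose near the Bragg peak of high energies, and widens
to a few percent of the range. The parameterization is deliberately
pluggable (`HaloModel(u_n_fn=..., sigma_n_fn=...)`): any callables
satisfying 0 ≤ u_n < 1 and σ_n > 0 may be substituted, and the engine,
generator and commissioning all accept the same object. The halo is never
fitted from data.

## HU → stopping power

CT numbers are converted voxelwise through a monotone piecewise-linear
table anchored at water (S_r(0 HU) = 1). The packaged default spans air
(−1000 HU → 0.001) through dense bone (+1500 HU → 1.80) with lung at
−700 HU → 0.29 and bone at +500 HU → 1.29. It is a placeholder with the
shape of a stoichiometric calibration, not a scanner-specific clinical
curve, and is user-replaceable via CSV. Grids must be isotropic; a trilinear
resampler produces the isotropic grid that then defines the dose grid.

## Beam-model commissioning

One energy layer is fitted from single-spot 3D dose grids in a water tank at
three or more effective SSDs (default four: 1635, 1535, 1435, 1385 mm):

1. **IDD**: lateral plane sum × voxel area at each depth, divided by the
   delivered MU; averaged across SSDs (the IDD has almost no SSD
   dependence). A diagnostic warns if edge dose exceeds 0.1 % of the plane
   maximum (laterally truncated export).
2. **R80**: the depth where the distal falloff crosses 80 % of the Bragg
   peak, located by linear interpolation. The peak is the distal-most
   5-mm-prominent local maximum above 25 % of the curve maximum — not the
   global maximum, because the entrance of an *axial* single-spot curve can
   exceed the Bragg peak at high energies where the entrance kernel is much
   narrower.
3. **σ_c(z_w) per SSD**: a least-squares 2D Gaussian (independent σ_x, σ_y,
   free centre and amplitude, initialized from second moments, window
   r ≤ 3 moment-σ) fitted to each 1 mm depth slice; the x/y mean is
   reported. When the a-priori halo model is supplied (the default in
   `build_energy_model`), its term is frozen inside the fit model so the
   halo pedestal cannot inflate the central sigma — without this the
   recovery error is several times the noise floor. The plain single
   Gaussian remains available (`fit_lateral_sigma`) and is what the
   evaluation toolkit uses.
4. **σ_air**: quadratic least squares of σ_c(z_w,ref) against the distance
   from the effective source (SSD + z_w,ref) across SSDs, with
   z_w,ref = 0.7·R80, a stable fitting point that favours accuracy near the
   Bragg peak. The fit is performed on a centred abscissa and mapped back to
   raw coefficients for conditioning.
5. **σ_mcs**: the average of σ_c(z_w) − σ_c(z_w,ref) across SSDs. Because
   tank data advance z and z_w together, this raw difference also contains
   the in-air divergence growth over the depth interval, which the engine
   would then apply a second time through σ_air(z); `build_energy_model`
   therefore subtracts the fitted quadratic's own growth from each profile
   before differencing (`FitConfig.correct_air_growth`, default on). This
   makes the σ_air/σ_mcs decomposition self-consistent under the engine's
   independent (z, z_w) evaluation; without it the engine-vs-generator
   closure error is ~4 % of the peak dose, with it ~0.1 %.

The fitted decomposition is only identifiable up to the reference depth:
σ_air absorbs whatever in-medium broadening exists at z_w,ref. The synthetic
generator therefore exposes its truth re-expressed in this basis
(`expected_sigma_air_coeffs`, `expected_sigma_mcs`) for recovery scoring.

Libraries persist as one CSV per energy (z_w, IDD, σ_mcs columns; energy,
R80 and σ_air coefficients in header comments) plus a master-list CSV
mapping plan energy labels to file indices, with `repr`-exact floats so
save → load is an identity and saves are byte-stable.

## Synthetic beam generator

The generator emulates TPS Monte Carlo exports of pristine Bragg peaks in a
digital water tank: 1 mm isotropic grids, 0.2 MU per spot, four SSDs, and
0.5 % multiplicative Gaussian voxel noise (seeded; per-SSD substreams are
spawned deterministically from the set seed). Its components:

* **Depth-dose**: the Bortfeld analytic Bragg curve (power-law range-energy
  relation p = 1.77, range straggling σ = 0.012·R0^0.935 cm, parabolic
  cylinder functions), switched to the non-straggled plateau closed form for
  ζ = (R0 − z)/σ > 17 where the straggled form would overflow (branch
  mismatch ~1e−4). R0 is calibrated by fixed-point iteration so the distal
  80 % crossing equals the requested R80 to better than 0.01 mm; the curve
  is clamped to zero beyond 1.05·R80. Nominal energies map to ranges by
  Bragg-Kleeman, R80 = 0.022·E^1.77 mm (70.2 MeV → 41 mm,
  228.7 MeV → 330 mm). The peak IDD is scaled to 25 cGy·mm²/MU by default.
* **Lateral profile**: at depth d (z_w = d in water) the plane is painted
  with the model's own double Gaussian: central width
  σ_air,true(SSD + d) + mcs(d) with σ_air,true a quadratic (default
  (2.0, 1e−3, 1e−7) — about 3.9 mm at the isocenter SSD) and
  mcs(z_w) = 0.025·R80·(z_w/R80)^1.7 (zero at the surface, ~2.5 % of range
  at the peak); halo per the same `HaloModel` the engine uses. Planes are
  scaled so the lateral integral equals MU × IDD.
* **Grid convention**: the tank surface is the outer face of the first
  slice, so slice k is centred at depth (k + ½)·spacing and the grid's z
  coordinate equals depth. Generation refuses grids smaller than 4 central
  sigmas laterally or shorter than the full range in depth, naming the
  required minimum dimensions.

What the generator does *not* emulate: Monte Carlo lateral-scatter physics
in heterogeneous media (all exports are water-tank peaks), Poisson counting
noise (multiplicative Gaussian is used at the stated 0.5 % level), range
shifters, and detector effects. Consequently, passing tests demonstrate that
the engine and fitter are mutually consistent and numerically correct under
the model's own assumptions — they do not certify accuracy against real
measurements or MC in heterogeneous anatomy, where pencil-beam models are
known to degrade.

## Evaluation toolkit

* **3D gamma**: generalized-distance formulation, global normalization to
  the reference maximum, analysis threshold 10 % of that maximum by default.
  The minimum is searched over a ball of radius 2·DTA sampled at 0.25·DTA
  steps with trilinear interpolation of the evaluated grid; offsets are
  visited in increasing distance with early termination once the spatial
  term alone exceeds the worst remaining candidate. Pass rates are reported
  at 0.1 % resolution. These search parameters make pass/fail decisions
  exact near the criterion while bounding cost.
* **DVH metrics**: `Dmean`, `Dx%` (dose exceeded by x % of the structure,
  interpolated on the sorted voxel-dose curve with mid-voxel plotting
  positions), `Dxcc` (hottest x cm³), `Vx cGy` (direct voxel counting, so
  DVH-curve and counting definitions agree by construction).
* **Depth-dose extraction**: trilinear sampling along the beam's central
  axis at 1 mm steps, depth zero at the grid's outer bounding box.

## Numerical choices and degenerate inputs

* Ray step 0.5·voxel (midpoint rule): sub-voxel depth accuracy at bounded
  cost; validated against a dense-sampling oracle to the larger of 1 % and
  half a voxel.
* Kernel lateral cutoff 5·max(σ_c, σ_n): discards < 4e−6 of kernel mass.
* σ floor 0.5 mm on σ_c and σ_n.
* Energy labels resolve through the master list exactly (0.001 MeV
  canonicalization); there is no nearest-energy fallback — silent energy
  substitution is a safety hazard, so unknown labels raise.
* Accumulation is plain additive float64: order-independent up to round-off,
  linear in MU, and bitwise deterministic for identical inputs.
* Readers (JSON plan, DICOM RT Ion Plan, RT Dose, beam-model CSVs) validate
  strictly and reject rather than guess, naming the offending field or file.
  Spot MU from DICOM is meterset weight × beam meterset / final cumulative
  meterset weight.
* Coordinates: right-handed patient system, IEC 61217 angles (gantry about
  the longitudinal axis, couch about the vertical axis, source on +Z at
  gantry 0), voxel centres, lengths in mm, isotropic grids only.

## Problem sizes

The shipped validation uses single-spot fields on grids up to 80×80×350
voxels at 1 mm (criterion-scale water phantoms), 4-SSD commissioning sets at
R80 ≈ 90–120 mm, and a 90×60×205 heterogeneous slab phantom — sizes chosen
so the full suite and the acceptance script each complete in minutes on one
CPU while still exercising every code path at clinically representative
ranges.

## Known limitations

* Pencil-beam physics: no lateral-scatter disequilibrium distal to
  heterogeneities; the engine reproduces the expected range shifts behind
  lung/bone slabs but, like all σ(z_w) models, produces an unrealistically
  sharp penumbra beyond a lateral tissue interface.
* The nozzle-mounted range shifter is not modeled.
* The halo default is an empirical stand-in with the correct invariants and
  magnitudes, not a fit to nuclear-interaction data; swap in a
  measurement-derived parameterization for quantitative halo work.
* The HU→S_r default table is not a clinical calibration.
* Double-Gaussian (not triple-Gaussian) halo; anisotropic voxels are
  unsupported by design.
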