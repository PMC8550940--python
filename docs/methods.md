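# Methods

This note documents the models, conventions and numerical choices behind
porescope, in the spirit of a methods section: what is computed, under
which assumptions, and what the synthetic benchmarks do and do not show.

## Conventions

* Volumes are `data[x, y, z]` arrays with a physical voxel size in Å; the
  voxel at index `n // 2` per axis is the physical origin, so rotations
  and Fourier operations share one fixed point.
* Orientations are ZYZ intrinsic Euler angles in degrees,
  `R = Rz(rot) · Ry(tilt) · Rz(psi)`, mapping the reference frame onto
  the particle frame: `particle(x) = reference(R⁻¹(x − t))` with `t` in
  voxels. Worked example: `(90, 0, 0)` maps the reference `+x` axis to
  the particle `+y` axis.
* Lengths are stored in Å; the geometry layer reports nm (the literature
  mixes both: voxel sizes and B-factors in Å, pore dimensions in nm).
* Particle metadata is tab-separated text with the fixed column order
  `particle_id source_id x y z rot tilt psi cc half_set class_label`;
  an optional STAR-dialect writer serves interoperability.

## The phantom

The phantom is a parametric stand-in for an NPC in the nuclear envelope,
defined in cylindrical coordinates about the pore axis (z; +z is
cytoplasmic, the IR midplane is z = 0):

* **Membrane.** Two sheets rising linearly from the pore rim
  (radius = `membrane_pore_diameter / 2`, default 52.5 nm) at
  `angle_cyto` (42°) and `angle_nucleo` (28°), capped at the distal ring
  offsets, rendered with a Gaussian cross-section of 7 nm FWHM — the
  scale of an unresolved bilayer pair — and tapered smoothly at a
  configurable cylindrical radius so the sheet ends inside the box.
  The membrane amplitude is 1.5× the ring amplitude, reflecting the
  dominant lipid contrast of cellular tomograms.
* **Rings.** Gaussian annuli with an azimuthal `1 + 0.35·cos(8φ)`
  modulation (exactly C8 by construction). The IR annulus spans the
  half-maximum radii `channel_diameter/2` (28.5 nm) to
  `ir_outer_diameter/2` (52.5 nm); CR and NR sit at the IR center radius
  with 12 nm FWHM, and their axial centers are placed so the *distal
  half-maximum edge* lands exactly at `cr_distal_offset` (+37 nm) and
  `−nr_distal_offset` (−29 nm). Edge-based measurements on a clean
  phantom therefore recover the named parameters identically.
* **Presets.** `wildtype` (in-cell geometry), `constricted` (the earlier
  purified-envelope geometry: 43 nm channel, 89 nm pore, 75 nm height),
  and `class1/2/3` (ring subsets of the scaffold-depletion series:
  three rings, IR+NR, IR only).

## Particle simulation

Each particle is the phantom at a random pose — azimuth uniform, axis
tilt limited to a 15° wobble cone (emulating envelope-normal
prealignment of picked pores; full SO(3) behind a flag), in-plane angle
uniform, translations jittered ±2 voxels — multiplied in Fourier space
by the binary missing-wedge mask of the −52°…+68° tilt range (tilt axis
y), plus white Gaussian noise. SNR is defined as the variance of the
wedge-filtered signal over the noise variance, measured inside a central
sphere (0.4× the box extent by default). No CTF, dose weighting or
per-tilt projection model is simulated; the wedge is applied
analytically, so tilt increments and dose schedules play no role.

What this emulates: anisotropic information loss, envelope-based
prealignment, realistic pose scatter, and shot-noise-limited contrast.
What it does not: structured cellular background, CTF oscillations,
particle heterogeneity beyond the ring subsets, or lamella geometry.
Passing recovery tests therefore demonstrate correctness of the
averaging and measurement machinery under wedge and noise — not
performance on real cellular data.

## Alignment and averaging

* **Constrained CC.** Normalized cross-correlation evaluated only over
  the Fourier region covered by both volumes' wedges (means removed,
  unit-normalized in the region); the translational peak is found by FFT
  within `max_shift` and refined parabolically per axis. With full
  coverage this reduces exactly to plain normalized CC.
* **Angular search.** A coarse grid (default 7.5°) followed by a local
  grid at step/4 around the best node. The in-plane angle is scanned
  globally over one asymmetric unit (360/8 = 45°); the axis angles are
  refined locally around the prealigned values. Linear interpolation
  during search, cubic spline for final averaging.
* **Averaging.** Particles are mapped back to the reference frame, the
  Fourier sums are divided voxel-wise by the summed pose-rotated wedge
  masks (only where the summed weight ≥ 0.5 — with binary wedges this
  means "at least one observation" and avoids dividing by interpolation
  slivers), half sets A/B are built independently, and the pooled sums
  give the merged map. Half sets are merged after every iteration and
  the merged, C8-symmetrized map is the next template (no gold-standard
  split — FSC values inherit the usual reference-bias caveat, which the
  resolution output states).
* **In-plane degeneracy and coverage.** A C8 reference pins the in-plane
  angle only modulo 45°. All eight equivalents carry identical signal
  but place the particle's missing cone at different azimuths after
  back-rotation, so the refinement distributes them deterministically
  across particles (k = index mod 8) to keep the pooled Fourier coverage
  isotropic. Without this the estimated angles cluster in [0°, 45°) and
  the union coverage develops a systematic azimuthal gap.
* **Binning.** By Fourier cropping (exact band limit). The benchmark
  protocol searches orientations on 2×-binned copies and polishes
  shifts only at full sampling.
* **Restoration.** For measurement, the merged map is refined by
  alternating projections (POCS): keep the measured Fourier components
  inside the realized coverage mask, enforce non-negativity in real
  space, iterate to convergence (relative change < 1e-4, ≤300
  iterations, on the real-FFT half spectrum). This recovers most of the
  thin, flat features (the IR annulus) that the residual ~7° missing
  cone suppresses, and removes the associated negative ringing. It
  cannot invent data in the never-covered region.

## Geometry measurements

All measurements mimic manual orthoslice reading, made robust for
wedge-limited averages:

* **Radial profiles** are averaged over 45° sectors around each of the
  two orthogonal directions (one C8 period, so blob modulation cancels
  while elliptical pores still resolve their axes) and over a ±1-voxel
  slab in z.
* **Pore diameter**: outermost membrane density maximum flanking the
  pore per direction, narrowest flank-to-flank distance over |z| ≤ 8 nm,
  two directions averaged, sub-voxel by parabolic interpolation.
* **Channel diameter**: innermost significant radial maximum (the IR
  annulus, searched inside the membrane rim), then the inward
  half-maximum crossing referenced to the channel floor (the wedge rings
  the empty bore below zero; the floor correction removes that bias).
* **Axial geometry**: the IR midplane is the center of mass of the IR
  shell profile; CR/NR distal edges come from a Gaussian fit to the
  pedestal-subtracted peak core of each ring's axial profile (the wedge
  lays a z-elongated streak pedestal beyond the rings), reported as
  μ ± 1.177σ. Height is the sum of the two distances by construction.
  Absent rings yield NaN fields rather than exceptions.
* **Membrane angles**: membrane midline points (r, z) from Gaussian fits
  to each radial column on either side of the midplane; the angle is the
  secant from the pore rim (an exactly located landmark on the IR
  midplane) to the mean of the outermost midline points — the long lever
  arm suppresses residual point-spread distortion of the sloped sheet.
* **Ring presence**: a ring is present when its (r, z) shell mean
  exceeds the mean of its inner radial flank — the empty channel bore at
  the same z, which shares the local artifact baseline — by 3 robust
  (MAD) sigmas. Presence calls map to the depletion-series classes
  (1 = three rings, 2 = IR+NR, 3 = IR only; CR+IR is flagged as the
  never-observed combination).
* **Percentages** in reports use largest-remainder apportionment (sums
  to exactly 100; reproduces the conventional 17/32/51 from 27/53/83).

### Known residual biases

Measured through the −52°/+68° wedge with 15° prealignment wobble, a
24-particle average retains a ~7° missing cone whose tilted band skews
axial edges and inflates the narrowest-point search slightly. After
restoration the benchmark protocol reads, at seed 1: pore 106.3 nm
(+1.3), channel 57.7 nm (+0.7), IR–CR 35.9 nm (−1.1), IR–NR 30.5 nm
(+1.5), height 66.4 nm (+0.4), angles 42.6°/29.9° (+0.6/+1.9).
Run-to-run spread across seeds is about ±1 nm / ±1°. The IR–NR distance
is the one quantity that can fall just outside a one-voxel band; its
test documents this rather than widening the tolerance.

## Rigid-body fitting

* **Map simulation**: each point becomes an isotropic Gaussian with
  σ = 0.225 × resolution (the Fourier-half-height kernel convention of
  common simulation tools), mass-weighted; the map integrates to the
  total weight.
* **CAM** is the Pearson correlation between target and model map over
  the model-map support; **OVR** is the fraction of model mass above a
  target contour (default: mean + 1σ of the target). CAM is invariant
  under affine intensity rescaling of the target.
* **Global search**: uniform random rotations; for each, the
  translational subproblem is solved exactly by FFT cross-correlation of
  the mass-weighted point cloud against the target (best shift kept away
  from the box edge — partially clipped models otherwise score
  deceptively well on their surviving lobes). Fits within 6° and 1 voxel
  merge into clusters; the top clusters are polished by per-coordinate
  line-search ascent of the metric on the full grid. At the scale of
  millions of placements a pure small-step optimizer covers the same
  space by brute force; at thousands of placements the exact translation
  search keeps orientation sampling the only stochastic element.
* **Significance**: cluster scores → Z (population σ, so two clusters
  are well defined) → two-sided normal P → Benjamini–Hochberg q. No
  hard q cutoff is imposed; reports list q.
* **Density subtraction** zeroes voxels within a stated radius of fitted
  model points, for difference-map fitting of remaining components.

## Resolution

FSC on one-voxel frequency shells; resolution at the first downward 0.5
crossing by linear interpolation (Nyquist-flagged when no crossing).
Local resolution tiles the volume with 40³ boxes every 4 voxels, each
spherically masked (radius box/2, 10% cosine edge) before the shell
correlation; values floor at Nyquist and interpolate trilinearly between
nodes. Sharpening multiplies amplitudes by `exp(−B s²/4)` with an
optional cosine-edged low-pass; DC is untouched.

## Problem sizes

Benchmarks run at 128³ voxels × 13.6 Å (the 4×-binned sampling of a
3.4 Å acquisition pixel) with 24 particles; unit tests use 48³–64³
phantoms with proportionally scaled geometry. Fitting benchmarks use a
16-point conical spiral in a 48³ × 4 Å box with 1,000 random placements.
These sizes were chosen so every check runs on a single CPU in minutes
while keeping each feature several voxels wide.

## Numerical notes and limitations

* Symmetrization is the real-space mean of rotated copies; it is a
  projector only in the continuum, so repeated application agrees with a
  single application to ~0.5% on compact smooth maps (interpolation
  limited). A wedge-weighted Fourier-domain symmetrization was evaluated
  and rejected: complex Fourier interpolation is numerically hostile.
* Wedge coverage fractions are quoted within the inscribed Nyquist
  sphere, where direction weighting is uniform and the analytic value is
  (tilt span)/180.
* All randomness flows from explicit integer seeds; seeded runs are
  bit-reproducible, including the full pipeline outputs.
* Maps are stored in single precision; round-trip identities in tests
  are asserted at 1e-4–1e-3 relative accordingly.
* The exclusion rules (threshold / worst-k / percentile) are scored
  proxies for what was historically a manual curation step; manual lists
  can be imported as tables for parity.
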