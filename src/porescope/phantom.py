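"""Parametric NPC phantoms and simulated subtomogram particles.

The phantom emulates the architecture seen in situ: a fused double nuclear
envelope (NE) whose two sheets rise from the pore rim at different slopes on
the cytoplasmic and nucleoplasmic sides, plus up to three Cn-symmetric
rings (cytoplasmic ring CR, inner ring IR, nucleoplasmic ring NR) rendered
as azimuthally modulated Gaussian annuli.

Geometry conventions (all :class:`PhantomParams` lengths in nm):

* z is the pore axis, +z cytoplasmic; the IR midplane is z = 0.
* ``membrane_pore_diameter`` is the NE-to-NE distance at the narrowest
  point, i.e. twice the rim radius.
* ``cr_distal_offset`` / ``nr_distal_offset`` are distances from the IR
  midplane to the *distal half-max edge* of the CR / NR axial profile, so a
  half-max edge measurement on the rendered density recovers them directly.
* Membranes are drawn with a Gaussian cross-section (default 7 nm FWHM, a
  typical unresolved-bilayer-pair scale at this resolution) and a 1.5x
  higher amplitude than the rings, reflecting the dominant lipid contrast
  in cellular tomograms.

Simulated particles are the phantom at a random pose, multiplied in Fourier
space by the binary missing-wedge mask of the stated tilt range, plus white
Gaussian noise scaled to a stated SNR (signal variance measured inside a
central sphere).  Particle axes wobble within a small cone by default,
emulating envelope-based prealignment of picked pores.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy.spatial import cKDTree

from ._transforms import euler_to_matrix, grid_center, transform_volume
from .errors import ParameterError
from .tables import new_table
from .volumes import DensityVolume

__all__ = ["PhantomParams", "SimParams", "PointModel", "RINGS",
           "build_phantom", "phantom_point_model", "simulate_particles",
           "prealign_poses", "get_preset", "PRESETS"]

RINGS = ("CR", "IR", "NR")

_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))   # FWHM = _FWHM * sigma
_HM = np.sqrt(2.0 * np.log(2.0))           # half-max offset = _HM * sigma


@dataclass
class PhantomParams:
    """Full parametric description of the phantom geometry (lengths in nm)."""

    membrane_pore_diameter: float = 105.0
    channel_diameter: float = 57.0
    ir_outer_diameter: float = 105.0
    cr_distal_offset: float = 37.0
    nr_distal_offset: float = 29.0
    angle_cyto: float = 42.0
    angle_nucleo: float = 28.0
    membrane_thickness: float = 7.0     # FWHM of the membrane cross-section
    ring_thickness: float = 12.0        # axial FWHM of each ring
    n_subunits: int = 8
    present_rings: tuple = ("CR", "IR", "NR")
    density_scale: float = 1.0
    membrane_amplitude: float = 1.5     # relative to ring amplitude 1.0
    ring_azimuthal_contrast: float = 0.35
    membrane_radial_extent: float | None = None  # nm; None -> fill the grid

    def __post_init__(self):
        self.present_rings = tuple(self.present_rings)
        self.validate()

    def validate(self) -> None:
        if not self.channel_diameter < self.membrane_pore_diameter:
            raise ParameterError("channel_diameter must be < membrane_pore_diameter")
        for a in (self.angle_cyto, self.angle_nucleo):
            if not 0.0 < a < 90.0:
                raise ParameterError(f"membrane angles must lie in (0, 90), got {a}")
        if self.n_subunits < 1:
            raise ParameterError("n_subunits must be >= 1")
        if not set(self.present_rings) <= set(RINGS):
            raise ParameterError(f"present_rings must be a subset of {RINGS}")
        if not 0.0 <= self.ring_azimuthal_contrast < 1.0:
            raise ParameterError("ring_azimuthal_contrast must be in [0, 1)")

    @property
    def height(self) -> float:
        """Total height across the NE (nm), CR edge to NR edge."""
        return self.cr_distal_offset + self.nr_distal_offset

    def ring_layout(self) -> dict:
        """Per-ring Gaussian parameters in nm: radius, sigma_r, z_center, sigma_z.

        The IR annulus is sized so that its inner/outer half-max radii are
        ``channel_diameter/2`` and ``ir_outer_diameter/2``; CR/NR axial
        centers are placed so their distal half-max edges land exactly at
        the distal offsets.
        """
        s_z = self.ring_thickness / _FWHM
        r_in = self.channel_diameter / 2.0
        r_out = self.ir_outer_diameter / 2.0
        ir_r = (r_in + r_out) / 2.0
        layout = {
            "IR": dict(radius=ir_r, sigma_r=(r_out - ir_r) / _HM,
                       z_center=0.0, sigma_z=s_z),
            "CR": dict(radius=ir_r, sigma_r=s_z,
                       z_center=self.cr_distal_offset - _HM * s_z, sigma_z=s_z),
            "NR": dict(radius=ir_r, sigma_r=s_z,
                       z_center=-(self.nr_distal_offset - _HM * s_z), sigma_z=s_z),
        }
        return layout


def _membrane_midline(params: PhantomParams, r_max: float, step: float) -> np.ndarray:
    """Sampled (r, z) polyline points of both NE sheets, in nm."""
    r_rim = params.membrane_pore_diameter / 2.0
    rs = np.arange(r_rim, r_max + step, step)
    branches = []
    for angle, cap, sign in ((params.angle_cyto, params.cr_distal_offset, 1.0),
                             (params.angle_nucleo, params.nr_distal_offset, -1.0)):
        z = sign * np.minimum((rs - r_rim) * np.tan(np.radians(angle)), cap)
        branches.append(np.column_stack([rs, z]))
    return np.vstack(branches)


def build_phantom(params: PhantomParams, shape, voxel_size: float) -> DensityVolume:
    """Render the phantom on a grid (``voxel_size`` in A).

    The result is non-negative and exactly Cn-symmetric about z up to grid
    sampling: membranes are rotation-invariant by construction, rings are
    analytic in cos(n * phi).
    """
    params.validate()
    shape = tuple(int(n) for n in shape)
    vox_nm = voxel_size / 10.0
    c = grid_center(shape)
    half_xy = min(c[0], c[1], shape[0] - 1 - c[0], shape[1] - 1 - c[1]) * vox_nm
    half_z = min(c[2], shape[2] - 1 - c[2]) * vox_nm

    r_max = params.membrane_radial_extent or half_xy - 3.0 * vox_nm
    taper_w = 3.0 * vox_nm
    r_rim = params.membrane_pore_diameter / 2.0
    if r_rim + 2.0 * vox_nm > r_max:
        raise ParameterError("membrane pore does not fit in the grid with a 2-voxel margin")
    layout = params.ring_layout()
    for name in params.present_rings:
        ring = layout[name]
        if abs(ring["z_center"]) + 2.0 * ring["sigma_z"] + 2.0 * vox_nm > half_z:
            raise ParameterError(f"ring {name} exceeds the grid axially")
        if ring["radius"] + 2.0 * vox_nm > half_xy:
            raise ParameterError(f"ring {name} exceeds the grid radially")

    # --- membrane: 2D (r, z) field via distance to the midline polyline ---
    sigma_m = params.membrane_thickness / _FWHM
    pts = _membrane_midline(params, r_max + 4.0 * sigma_m, vox_nm / 4.0)
    tree = cKDTree(pts)
    r_axis = np.arange(0.0, half_xy * np.sqrt(2.0) + 2.0 * vox_nm, vox_nm / 2.0)
    z_axis = (np.arange(shape[2]) - c[2]) * vox_nm
    rr, zz = np.meshgrid(r_axis, z_axis, indexing="ij")
    d, _ = tree.query(np.column_stack([rr.ravel(), zz.ravel()]), workers=-1)
    mem2d = np.exp(-0.5 * (d / sigma_m) ** 2).reshape(rr.shape)
    # radial cosine taper so the sheet ends smoothly inside the box
    taper = np.clip((r_axis - (r_max - taper_w)) / taper_w, 0.0, 1.0)
    mem2d *= (0.5 * (1.0 + np.cos(np.pi * taper)))[:, None]

    # --- map to 3D ---
    gx = (np.arange(shape[0]) - c[0]) * vox_nm
    gy = (np.arange(shape[1]) - c[1]) * vox_nm
    r_xy = np.sqrt(gx[:, None] ** 2 + gy[None, :] ** 2)
    phi = np.arctan2(gy[None, :], gx[:, None])
    idx = np.clip(r_xy / (vox_nm / 2.0), 0, len(r_axis) - 2)
    i0 = idx.astype(int)
    frac = (idx - i0)[..., None]
    density = params.membrane_amplitude * (
        (1.0 - frac) * mem2d[i0, :] + frac * mem2d[i0 + 1, :])

    gz = z_axis[None, None, :]
    n = params.n_subunits
    contrast = params.ring_azimuthal_contrast
    azi = 1.0 + contrast * np.cos(n * phi)[..., None]
    for name in params.present_rings:
        ring = layout[name]
        radial = np.exp(-0.5 * ((r_xy - ring["radius"]) / ring["sigma_r"]) ** 2)
        axial = np.exp(-0.5 * ((gz - ring["z_center"]) / ring["sigma_z"]) ** 2)
        density += radial[..., None] * axial * azi

    return DensityVolume(density.astype(np.float32) * params.density_scale, voxel_size)


@dataclass
class PointModel:
    """Labeled 3D point cloud (coordinates in A) with unitless mass weights."""

    points: np.ndarray
    chains: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.chains = np.asarray(self.chains)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.points.shape[0] < 1 or self.points.shape[1] != 3:
            raise ParameterError("point model needs an N x 3 coordinate array, N >= 1")
        if not (self.weights > 0).all():
            raise ParameterError("point weights must be > 0")

    def __len__(self) -> int:
        return self.points.shape[0]

    def transformed(self, matrix: np.ndarray, translation=(0.0, 0.0, 0.0),
                    pivot=None) -> "PointModel":
        """Rotate about ``pivot`` (default: centroid) then translate, in A."""
        p = self.points.mean(axis=0) if pivot is None else np.asarray(pivot, float)
        pts = (self.points - p) @ np.asarray(matrix).T + p + np.asarray(translation, float)
        return PointModel(pts, self.chains.copy(), self.weights.copy())


def phantom_point_model(params: PhantomParams, points_per_subunit: int) -> PointModel:
    """Deterministic point cloud at the ring-blob centers of the phantom (A).

    ``points_per_subunit`` points are fanned azimuthally (8 deg apart) around
    each subunit center of every present ring.
    """
    if points_per_subunit < 1:
        raise ParameterError("points_per_subunit must be >= 1")
    if not params.present_rings:
        raise ParameterError("cannot build a point model with no rings present")
    layout = params.ring_layout()
    pts, chains = [], []
    m = points_per_subunit
    for name in sorted(params.present_rings):
        ring = layout[name]
        for k in range(params.n_subunits):
            phi_k = 360.0 * k / params.n_subunits
            for j in range(m):
                phi = np.radians(phi_k + (j - (m - 1) / 2.0) * 8.0)
                pts.append([ring["radius"] * 10.0 * np.cos(phi),
                            ring["radius"] * 10.0 * np.sin(phi),
                            ring["z_center"] * 10.0])
                chains.append(f"{name}{k}")
    return PointModel(np.asarray(pts), np.asarray(chains), np.ones(len(pts)))


@dataclass
class SimParams:
    """Particle-simulation conditions.

    ``snr`` is the variance of the wedge-filtered signal over the variance of
    the added white noise, measured inside a central sphere
    (``snr_radius_A``; default 0.4x the box extent).  ``wobble`` limits the
    tilt of the particle axis from z, emulating NE-based prealignment;
    ``full_sphere`` lifts that limit to uniform SO(3) poses.
    """

    n_particles: int = 16
    tilt_min: float = -52.0
    tilt_max: float = 68.0
    snr: float = 0.5
    pose_jitter: float = 2.0        # max |translation| per axis, voxels
    seed: int = 0
    wobble: float = 15.0            # max axis tilt, degrees
    randomize_inplane: bool = True
    full_sphere: bool = False
    snr_radius_A: float | None = None

    def validate(self) -> None:
        if self.n_particles < 1:
            raise ParameterError("n_particles must be >= 1")
        if not -90.0 < self.tilt_min < self.tilt_max < 90.0:
            raise ParameterError("require -90 < tilt_min < tilt_max < 90")
        if not self.snr > 0:
            raise ParameterError("snr must be > 0")
        if self.pose_jitter < 0 or self.wobble < 0:
            raise ParameterError("pose_jitter and wobble must be >= 0")


def simulate_particles(phantom: DensityVolume, sim: SimParams
                       ) -> tuple[list[DensityVolume], "pd.DataFrame"]:
    """Simulate subtomogram particles from a phantom.

    Each particle is the phantom at a random pose, wedge-filtered in Fourier
    space for the stated tilt range, with white Gaussian noise added at the
    stated SNR.  True poses (reference -> particle) and shifts (voxels) are
    recorded in the returned table; half sets alternate A, B by index.
    Fully reproducible from ``sim.seed``.
    """
    from .align import wedge_mask  # local import: align must not depend on phantom

    sim.validate()
    rng = np.random.default_rng(sim.seed)
    shape = phantom.shape
    wedge = wedge_mask(sim.tilt_min, sim.tilt_max, shape, soft_edge=0.0)
    w_fft = wedge.fft_order()

    # noise scale from the wedge-filtered, unrotated phantom
    filtered0 = np.fft.ifftn(np.fft.fftn(phantom.data) * w_fft).real
    from ._transforms import radius_grid
    r_lim = sim.snr_radius_A or 0.4 * min(shape) * phantom.voxel_size
    sphere = radius_grid(shape, phantom.voxel_size) <= r_lim
    sigma_noise = float(np.sqrt(filtered0[sphere].var() / sim.snr))

    table = new_table(sim.n_particles, source_id=f"sim_seed{sim.seed}")
    particles = []
    for i in range(sim.n_particles):
        if sim.full_sphere:
            rot = rng.uniform(0.0, 360.0)
            tilt = np.degrees(np.arccos(rng.uniform(-1.0, 1.0)))
        else:
            rot = rng.uniform(0.0, 360.0)
            tilt = rng.uniform(0.0, sim.wobble)
            if sim.wobble == 0.0:
                rot = 0.0  # no wobble: the axis azimuth is meaningless
        psi = rng.uniform(0.0, 360.0) if sim.randomize_inplane else 0.0
        shift = rng.uniform(-sim.pose_jitter, sim.pose_jitter, size=3)
        moved = transform_volume(phantom.data, euler_to_matrix(rot, tilt, psi),
                                 shift, order=3)
        filtered = np.fft.ifftn(np.fft.fftn(moved) * w_fft).real
        noisy = filtered + rng.normal(0.0, sigma_noise, size=shape)
        particles.append(DensityVolume(noisy.astype(np.float32), phantom.voxel_size))
        table.loc[i, ["x", "y", "z", "rot", "tilt", "psi"]] = [*shift, rot, tilt, psi]
    return particles, table


def prealign_poses(table, keep_axis: bool = True):
    """Degrade simulated truth to envelope-style prealignment.

    Keeps the particle axis orientation (rot, tilt) — which envelope-normal
    prealignment provides — but zeroes the unknowable in-plane angle psi and
    the shifts.  Returns a copy; with ``keep_axis=False`` all angles are
    zeroed.
    """
    out = table.copy()
    out[["psi", "x", "y", "z"]] = 0.0
    if not keep_axis:
        out[["rot", "tilt"]] = 0.0
    return out


PRESETS: dict[str, PhantomParams] = {
    # native (wild-type) in-cell geometry
    "wildtype": PhantomParams(),
    # earlier constricted models from purified nuclear envelopes:
    # 43 nm channel, 89 nm membrane-to-membrane, 75 nm total height
    "constricted": PhantomParams(membrane_pore_diameter=89.0, channel_diameter=43.0,
                                 ir_outer_diameter=89.0, cr_distal_offset=42.0,
                                 nr_distal_offset=33.0, angle_cyto=35.0,
                                 angle_nucleo=35.0),
    # scaffold-depletion classes: ring subsets on the wild-type geometry
    "class1": PhantomParams(present_rings=("CR", "IR", "NR")),
    "class2": PhantomParams(present_rings=("IR", "NR")),
    "class3": PhantomParams(present_rings=("IR",)),
}


def get_preset(name: str) -> PhantomParams:
    if name not in PRESETS:
        raise ParameterError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return replace(PRESETS[name])


def params_to_dict(params: PhantomParams) -> dict:
    return asdict(params)
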