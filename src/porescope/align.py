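"""Missing-wedge-weighted subtomogram alignment and averaging.

The missing wedge is the unsampled region of Fourier space caused by the
limited tilt range of the tomographic acquisition (tilt axis = y, beam
along z at zero tilt).  Alignment scores are normalized cross-correlations
computed only over the Fourier region covered by both volumes' wedges;
averages divide the summed Fourier terms by the summed (pose-rotated)
wedge masks, the classic wedge compensation.

Iteration scheme: half-set averages are merged after every iteration and
the merged, symmetrized map is the template for the next iteration — i.e.
no gold-standard independent half sets; the reference-bias caveat applies
to resolution estimates downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._transforms import (bin_volume, euler_to_matrix, grid_center,
                          rotate_about_z, transform_volume, untransform_volume)
from .errors import DegenerateOverlapError, ParameterError, PartitionError
from .tables import validate_table
from .volumes import DensityVolume

__all__ = ["WedgeMask", "AlignConfig", "AverageResult", "wedge_mask",
           "constrained_cc", "align_particle", "average_particles",
           "apply_symmetry", "iterative_align"]


@dataclass
class WedgeMask:
    """Scalar Fourier-domain wedge mask in [0, 1], stored fftshift-centered.

    A frequency is covered (value 1) when some tilt in ``[tilt_min,
    tilt_max]`` sampled it, i.e. when ``-atan2(kz, kx)`` folded into
    (-90, 90] lies inside the tilt range; ``ky`` (the tilt axis) is free.
    The mask is symmetric under Friedel inversion by construction.
    """

    tilt_min: float
    tilt_max: float
    shape: tuple
    soft_edge: float
    data: np.ndarray

    def fft_order(self) -> np.ndarray:
        """Mask in standard (unshifted) FFT index order."""
        return np.fft.ifftshift(self.data)

    def coverage_fraction(self) -> float:
        """Covered fraction of directions within the inscribed Nyquist sphere.

        Restricting to the band-limit sphere weights directions uniformly,
        so a hard mask gives (tilt_max - tilt_min) / 180 analytically.
        """
        c = grid_center(self.shape)
        ax = [np.arange(n) - ci for n, ci in zip(self.shape, c)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        r = np.sqrt(gx * gx + gy * gy + gz * gz)
        inside = r <= min(self.shape) / 2.0
        return float(self.data[inside].mean())

    def binned(self, factor: int) -> "WedgeMask":
        if factor == 1:
            return self
        new_shape = tuple(n // factor for n in self.shape)
        return wedge_mask(self.tilt_min, self.tilt_max, new_shape, self.soft_edge)


def wedge_mask(tilt_min: float, tilt_max: float, shape,
               soft_edge: float = 0.0) -> WedgeMask:
    """Binary (or cosine-softened) missing-wedge mask for a tilt range in degrees."""
    if not -90.0 < tilt_min < tilt_max < 90.0:
        raise ParameterError("require -90 < tilt_min < tilt_max < 90")
    shape = tuple(int(n) for n in shape)
    c = grid_center(shape)
    kx = (np.arange(shape[0]) - c[0])[:, None, None]
    kz = (np.arange(shape[2]) - c[2])[None, None, :]
    t = np.degrees(np.arctan2(-kz, kx))
    t = (t + 90.0) % 180.0 - 90.0  # fold to [-90, 90)
    covered = (t >= tilt_min) & (t <= tilt_max)
    covered[kx.squeeze() == 0, :, kz.squeeze() == 0] = True  # ky axis: always sampled
    mask2d = covered.astype(np.float32)
    if soft_edge > 0:
        from scipy import ndimage
        d = ndimage.distance_transform_edt(mask2d[:, 0, :])
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.clip(d / soft_edge, 0.0, 1.0)))
        mask2d = ramp.astype(np.float32)[:, None, :]
    data = np.broadcast_to(mask2d, shape).copy()
    return WedgeMask(tilt_min, tilt_max, shape, soft_edge, data)


def _as_data(v) -> np.ndarray:
    return v.data if isinstance(v, DensityVolume) else np.asarray(v)


class _CCEngine:
    """Constrained-CC scorer with the particle-side FFT precomputed."""

    def __init__(self, particle, wedge_particle: WedgeMask | None,
                 wedge_reference: WedgeMask | None = None,
                 max_shift: float | None = None):
        b = _as_data(particle)
        self.shape = b.shape
        region = np.ones(self.shape, dtype=bool)
        if wedge_particle is not None:
            region &= wedge_particle.fft_order() >= 0.5
        if wedge_reference is not None:
            region &= wedge_reference.fft_order() >= 0.5
        if not region.any():
            raise DegenerateOverlapError("wedge overlap region is empty")
        self.region = region
        B = np.fft.fftn(b) * region
        B[0, 0, 0] = 0.0
        self.B = B
        self.nb = np.sqrt((np.abs(B) ** 2).sum())
        if self.nb == 0:
            raise DegenerateOverlapError("particle volume is zero in the overlap region")
        self.max_shift = max_shift
        self.n = b.size

    def score(self, a) -> tuple[float, np.ndarray]:
        a = _as_data(a)
        A = np.fft.fftn(a) * self.region
        A[0, 0, 0] = 0.0
        na = np.sqrt((np.abs(A) ** 2).sum())
        if na == 0:
            raise DegenerateOverlapError("reference volume is zero in the overlap region")
        cc = np.fft.fftshift(np.fft.ifftn(np.conj(A) * self.B).real) * self.n / (na * self.nb)
        c = grid_center(self.shape).astype(int)
        if self.max_shift is not None:
            w = int(np.ceil(self.max_shift))
            sl = tuple(slice(ci - w, ci + w + 1) for ci in c)
            win = cc[sl]
            off = np.array([ci - w for ci in c])
        else:
            win, off = cc, np.zeros(3, dtype=int)
        peak = np.unravel_index(np.argmax(win), win.shape)
        score = float(win[peak])
        shift = np.array(peak, dtype=float) + off - c
        # parabolic sub-voxel refinement per axis
        for ax in range(3):
            i = peak[ax]
            if 0 < i < win.shape[ax] - 1:
                idx = list(peak)
                idx[ax] = i - 1
                y0 = win[tuple(idx)]
                idx[ax] = i + 1
                y2 = win[tuple(idx)]
                denom = y0 - 2.0 * score + y2
                if denom < 0:
                    shift[ax] += 0.5 * (y0 - y2) / denom
        return score, shift


def constrained_cc(a, b, wedge_a: WedgeMask | None, wedge_b: WedgeMask | None,
                   max_shift: float | None = None) -> tuple[float, np.ndarray]:
    """Wedge-constrained normalized cross-correlation of two volumes.

    The correlation is computed only over the Fourier region where both
    wedge masks are >= 0.5 (``None`` counts as a full wedge), with means
    removed and unit normalization inside that region.  Returns the peak
    value in [-1, 1] and the sub-voxel shift of ``b`` relative to ``a``.
    """
    if _as_data(a).shape != _as_data(b).shape:
        raise ParameterError("volumes must share a shape")
    engine = _CCEngine(b, wedge_b, wedge_a, max_shift=max_shift)
    return engine.score(a)


@dataclass
class AlignConfig:
    """Alignment search configuration.

    ``binnings`` are *extra* binning factors relative to the input sampling
    (decreasing, e.g. ``(2, 1)``), with ``n_iterations`` per stage.  The
    angular search is a coarse grid at ``angular_step`` followed by a local
    grid at ``angular_step / refinement_factor`` around the best node.
    ``psi_range=None`` scans psi globally over one asymmetric unit
    [0, 360/symmetry); finite ranges search +/- range around the current
    pose (a range of 0 freezes that angle).
    """

    angular_step: float = 7.5
    refinement_factor: int = 4
    max_shift: float = 4.0
    binnings: tuple = (2, 1)
    n_iterations: tuple = (2, 1)
    symmetry: int = 8
    reference_init: str = "average_prealigned"
    rot_range: float = 0.0
    tilt_range: float = 8.0
    psi_range: float | None = None
    interp_search: int = 1
    interp_avg: int = 3
    min_weight: float = 0.5
    divergence_drop: float = 0.05

    def validate(self) -> None:
        if self.angular_step <= 0:
            raise ParameterError("angular_step must be > 0")
        if len(self.binnings) != len(self.n_iterations):
            raise ParameterError("binnings and n_iterations must have equal length")
        if list(self.binnings) != sorted(self.binnings, reverse=True):
            raise ParameterError("binnings must be decreasing")
        if self.symmetry < 1:
            raise ParameterError("symmetry order must be >= 1")


def _axis_values(center: float, half_range: float | None, step: float,
                 global_span: float | None = None) -> np.ndarray:
    if half_range is None:
        return np.arange(0.0, global_span, step)
    if half_range == 0:
        return np.array([center])
    deltas = np.arange(-half_range, half_range + 1e-9, step)
    return center + deltas


def _candidate_grid(cfg: AlignConfig, pose) -> list[tuple[float, float, float]]:
    rot_c, tilt_c, psi_c = pose
    rots = _axis_values(rot_c, cfg.rot_range, cfg.angular_step)
    tilts = np.clip(_axis_values(tilt_c, cfg.tilt_range, cfg.angular_step), 0.0, 180.0)
    psis = _axis_values(psi_c, cfg.psi_range, cfg.angular_step,
                        global_span=360.0 / cfg.symmetry)
    return [(r, t, p) for r in rots for t in np.unique(tilts) for p in psis]


def _refine_grid(cfg: AlignConfig, best, active) -> list[tuple[float, float, float]]:
    step = cfg.angular_step / cfg.refinement_factor
    offs = np.arange(-2, 3) * step
    axes = []
    for i, on in enumerate(active):
        axes.append(best[i] + offs if on else np.array([best[i]]))
    return [(r, max(t, 0.0), p) for r in axes[0] for t in axes[1] for p in axes[2]]


def align_particle(particle, reference, wedge: WedgeMask | None,
                   cfg: AlignConfig, pose=(0.0, 0.0, 0.0)
                   ) -> tuple[tuple[float, float, float], np.ndarray, float]:
    """Find the pose of ``reference`` that best matches ``particle``.

    Scans the configured angular grid (coarse, then refined at
    ``angular_step / refinement_factor`` around the best node), scoring each
    candidate with the wedge-constrained CC and its best shift.  Returns
    ``(euler, shift_voxels, cc_score)``; deterministic given its inputs.
    """
    cfg.validate()
    ref = _as_data(reference)
    if ref.shape != _as_data(particle).shape:
        raise ParameterError("reference and particle must share a shape")
    candidates = _candidate_grid(cfg, pose)
    if not candidates:
        raise ParameterError("empty angular search grid")
    engine = _CCEngine(particle, wedge, None, max_shift=cfg.max_shift)

    def evaluate(eulers):
        best = (-np.inf, None, None)
        for e in eulers:
            rotated = transform_volume(ref, euler_to_matrix(*e),
                                       order=cfg.interp_search)
            s, shift = engine.score(rotated)
            if s > best[0]:
                best = (s, e, shift)
        return best

    score, best_e, shift = evaluate(candidates)
    active = [cfg.rot_range != 0,
              cfg.tilt_range is None or cfg.tilt_range != 0,
              cfg.psi_range is None or cfg.psi_range != 0]
    if any(active) and len(candidates) > 1:
        score2, e2, shift2 = evaluate(_refine_grid(cfg, best_e, active))
        if score2 > score:
            score, best_e, shift = score2, e2, shift2
    return tuple(best_e), shift, score


@dataclass
class AverageResult:
    """Merged and half-set averages plus the refined particle table.

    ``coverage`` is the pooled Fourier-coverage mask (standard FFT order):
    True where the summed rotated wedge weights reached the compensation
    floor, i.e. where the merged map carries measured data.
    """

    merged: DensityVolume
    half_a: DensityVolume
    half_b: DensityVolume
    table: pd.DataFrame
    log: list = field(default_factory=list)
    early_stop: bool = False
    coverage: np.ndarray | None = None


def _compensated(fsum: np.ndarray, wsum: np.ndarray, min_weight: float) -> np.ndarray:
    ok = wsum >= min_weight
    out = np.zeros_like(fsum)
    out[ok] = fsum[ok] / wsum[ok]
    return np.fft.ifftn(out).real.astype(np.float32)


def average_particles(particles, table: pd.DataFrame, wedge: WedgeMask | None,
                      order: int = 3, min_weight: float = 0.5) -> AverageResult:
    """Wedge-compensated average of posed particles.

    Every particle is mapped back to the reference frame with its pose, the
    Fourier sums are divided voxel-wise by the summed rotated wedge masks
    (only where the summed weight reaches ``min_weight``; elsewhere zero),
    and half-set A/B averages are built independently before pooling into
    the merged map.

    With ``symmetry`` > 1 the Fourier numerator and weight sums are summed
    over the Cn orbit *before* compensation — the wedge-weighted form of
    symmetrization.  (Averaging already-compensated maps in real space
    instead would attenuate every frequency by the fraction of its
    symmetry partners that happened to be covered.)
    """
    validate_table(table, aligned=True)
    if len(particles) != len(table):
        raise ParameterError("particle stack and table lengths differ")
    shape = _as_data(particles[0]).shape
    wedge_c = wedge.data if wedge is not None else np.ones(shape, dtype=np.float32)
    sums = {"A": np.zeros(shape, dtype=complex), "B": np.zeros(shape, dtype=complex)}
    wsums = {"A": np.zeros(shape), "B": np.zeros(shape)}
    for vol, row in zip(particles, table.itertuples(index=False)):
        r = euler_to_matrix(row.rot, row.tilt, row.psi)
        back = untransform_volume(_as_data(vol), r, (row.x, row.y, row.z), order=order)
        w_rot = transform_volume(wedge_c, r.T, order=1)  # W_ref(k) = W(R k)
        sums[row.half_set] += np.fft.fftn(back)
        wsums[row.half_set] += np.fft.ifftshift(w_rot)
    for h in "AB":
        if not (table["half_set"] == h).any():
            raise PartitionError(f"half set {h} is empty")
    voxel = particles[0].voxel_size if isinstance(particles[0], DensityVolume) else 1.0
    half_a = _compensated(sums["A"], wsums["A"], min_weight)
    half_b = _compensated(sums["B"], wsums["B"], min_weight)
    merged = _compensated(sums["A"] + sums["B"], wsums["A"] + wsums["B"], min_weight)
    coverage = (wsums["A"] + wsums["B"]) >= min_weight
    return AverageResult(DensityVolume(merged, voxel), DensityVolume(half_a, voxel),
                         DensityVolume(half_b, voxel), table.copy(),
                         coverage=coverage)


def apply_symmetry(v, order: int, interp_order: int = 3):
    """Cn-symmetrize about z: mean of the ``order`` rotated copies."""
    if order < 1:
        raise ParameterError("symmetry order must be >= 1")
    data = _as_data(v).astype(np.float64)
    if order == 1:
        out = data
    else:
        acc = data.copy()
        for k in range(1, order):
            acc += transform_volume(data, euler_to_matrix(360.0 * k / order, 0, 0),
                                    order=interp_order)
        out = acc / order
    out = out.astype(np.float32)
    return v.copy_with(out) if isinstance(v, DensityVolume) else out


def restore_missing_wedge(v: DensityVolume, coverage: np.ndarray,
                          n_iter: int = 300) -> DensityVolume:
    """Constrained (POCS-style) missing-wedge restoration.

    Alternates between enforcing the measured Fourier components inside the
    ``coverage`` mask and non-negativity in real space.  For high-SNR
    averaged maps this recovers much of the density that the residual
    missing cone suppresses (flat, thin features perpendicular to the beam)
    and removes the associated negative ringing; it cannot invent
    information, so features entirely inside the never-covered region stay
    band-limited.
    """
    if coverage.shape != v.shape:
        raise ParameterError("coverage mask must match the volume shape")
    shape = v.shape
    # Friedel symmetry lets the iteration run on the real-FFT half spectrum
    cov_half = coverage[..., : shape[2] // 2 + 1]
    f_meas = np.fft.rfftn(v.data.astype(np.float64))
    x = v.data.astype(np.float64).copy()
    scale = float(np.abs(x).max()) or 1.0
    for _ in range(int(n_iter)):
        x_new = np.clip(x, 0.0, None)
        f = np.fft.rfftn(x_new)
        f[cov_half] = f_meas[cov_half]
        x_new = np.fft.irfftn(f, s=shape, axes=(0, 1, 2))
        delta = float(np.abs(x_new - x).max()) / scale
        x = x_new
        if delta < 1e-4:
            break
    return v.copy_with(np.clip(x, 0.0, None).astype(np.float32))


def iterative_align(particles, table: pd.DataFrame, wedge: WedgeMask,
                    cfg: AlignConfig, reference: DensityVolume | None = None
                    ) -> AverageResult:
    """Iterative wedge-weighted alignment and averaging with symmetrization.

    The initial template is the wedge-compensated, symmetrized average over
    the input (prealigned) poses unless an external ``reference`` is given.
    Each iteration aligns every particle to the current template at the
    stage's binning, re-averages, applies the point-group symmetry and
    records the mean CC.  A mean-CC drop beyond ``cfg.divergence_drop``
    triggers a warning and an early stop.
    """
    cfg.validate()
    validate_table(table, aligned=True)
    table = table.copy()
    log: list[dict] = []

    def averaged(parts, wdg, tbl):
        res = average_particles(parts, tbl, wdg, order=cfg.interp_avg,
                                min_weight=cfg.min_weight)
        res.merged = apply_symmetry(res.merged, cfg.symmetry, cfg.interp_avg)
        return res

    total_iters = sum(cfg.n_iterations)
    early_stop = False
    if total_iters > 0:
        prev_cc = -np.inf
        first_stage = True
        for b, iters in zip(cfg.binnings, cfg.n_iterations):
            if iters == 0 or early_stop:
                continue
            parts_b = [bin_volume(_as_data(p), b) for p in particles]
            wedge_b = wedge.binned(b)
            cfg_b = replace(cfg, max_shift=max(1.0, cfg.max_shift / b))
            if first_stage and reference is not None:
                ref_b = bin_volume(_as_data(reference), b)
            else:
                # template from the current poses at this stage's binning
                ref_b = averaged(parts_b, wedge_b, table).merged
            first_stage = False
            for it in range(iters):
                scores = []
                for i, row in enumerate(table.itertuples(index=False)):
                    euler, shift, score = align_particle(
                        parts_b[i], ref_b, wedge_b, cfg_b,
                        pose=(row.rot, row.tilt, row.psi))
                    # a Cn reference pins psi only modulo 360/n; all n
                    # equivalents carry identical signal but place the
                    # particle's missing cone at different azimuths after
                    # back-rotation, so distribute them deterministically
                    # to keep the pooled Fourier coverage isotropic
                    if cfg.psi_range is None and cfg.symmetry > 1:
                        euler = (euler[0], euler[1],
                                 euler[2] + 360.0 / cfg.symmetry
                                 * (i % cfg.symmetry))
                    table.iloc[i, table.columns.get_indexer(
                        ["rot", "tilt", "psi"])] = euler
                    table.iloc[i, table.columns.get_indexer(
                        ["x", "y", "z"])] = shift * b
                    table.iloc[i, table.columns.get_loc("cc")] = score
                    scores.append(score)
                mean_cc = float(np.mean(scores))
                log.append({"binning": b, "iteration": it, "mean_cc": mean_cc})
                ref_b = averaged(parts_b, wedge_b, table).merged
                if mean_cc < prev_cc - cfg.divergence_drop:
                    warnings.warn(f"mean CC dropped {prev_cc:.3f} -> {mean_cc:.3f}; "
                                  "stopping early")
                    early_stop = True
                    break
                prev_cc = mean_cc

    final = averaged(particles, wedge, table)
    final.half_a = apply_symmetry(final.half_a, cfg.symmetry, cfg.interp_avg)
    final.half_b = apply_symmetry(final.half_b, cfg.symmetry, cfg.interp_avg)
    final.log = log
    final.early_stop = early_stop
    return final
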