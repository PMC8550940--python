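"""Fourier shell correlation, local resolution and B-factor sharpening.

FSC here is the shell-resolved normalized correlation between two half-set
maps; resolution is read at a threshold crossing (0.5 by default, matching
the half-sets-merged-each-iteration refinement scheme, which is *not*
gold-standard — treat reported values with the usual reference-bias
caveat).  Local resolution tiles the map with small boxes, computes a
spherically masked FSC per tile, and interpolates between tile centers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from ._transforms import grid_center
from .errors import DegenerateOverlapError, ParameterError
from .volumes import DensityVolume, MaskSpec, make_mask

__all__ = ["FSCCurve", "LocalResolutionField", "ResolutionEstimate",
           "fsc", "resolution_at", "local_resolution", "sharpen"]


@dataclass
class FSCCurve:
    """Shell-resolved correlation between two maps.

    ``shell_centers`` are spatial frequencies in 1/A (strictly increasing up
    to Nyquist), ``values`` the per-shell correlations, ``n_voxels`` the
    Fourier-voxel count per shell.
    """

    shell_centers: np.ndarray
    values: np.ndarray
    n_voxels: np.ndarray
    voxel_size: float

    def to_tsv(self, path) -> None:
        import pandas as pd
        res = np.divide(1.0, self.shell_centers,
                        out=np.full_like(self.shell_centers, np.inf),
                        where=self.shell_centers > 0)
        pd.DataFrame({"frequency_invA": self.shell_centers,
                      "resolution_A": res,
                      "fsc": self.values,
                      "n_voxels": self.n_voxels}).to_csv(path, sep="\t", index=False)


def _shell_index(shape) -> tuple[np.ndarray, int]:
    ax = [np.fft.fftfreq(n) * n for n in shape]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    r = np.sqrt(gx * gx + gy * gy + gz * gz)
    shells = np.floor(r + 0.5).astype(int)
    n_shells = min(shape) // 2 + 1
    shells[shells >= n_shells] = n_shells  # overflow bin (discarded)
    return shells, n_shells


def _shell_correlation(fa: np.ndarray, fb: np.ndarray, shells: np.ndarray,
                       n_shells: int) -> tuple[np.ndarray, np.ndarray]:
    flat = shells.ravel()
    num = np.bincount(flat, weights=(fa * np.conj(fb)).real.ravel(),
                      minlength=n_shells + 1)[:n_shells]
    pa = np.bincount(flat, weights=(np.abs(fa) ** 2).ravel(),
                     minlength=n_shells + 1)[:n_shells]
    pb = np.bincount(flat, weights=(np.abs(fb) ** 2).ravel(),
                     minlength=n_shells + 1)[:n_shells]
    denom = np.sqrt(pa * pb)
    values = np.divide(num, denom, out=np.zeros_like(num), where=denom > 0)
    counts = np.bincount(flat, minlength=n_shells + 1)[:n_shells]
    return values, counts


def fsc(a: DensityVolume, b: DensityVolume,
        mask: MaskSpec | DensityVolume | None = None) -> FSCCurve:
    """Fourier shell correlation on one-voxel-wide spherical shells.

    An optional real-space mask (spec or volume) is applied to both maps
    before transforming.  Raises on all-zero masked input.
    """
    if a.shape != b.shape:
        raise ParameterError("maps must share a shape")
    if abs(a.voxel_size - b.voxel_size) > 1e-6:
        raise ParameterError("maps must share a voxel size")
    da, db = a.data.astype(np.float64), b.data.astype(np.float64)
    if mask is not None:
        m = make_mask(mask, a.shape, a.voxel_size).data if isinstance(mask, MaskSpec) \
            else _coerce_mask(mask, a.shape)
        da, db = da * m, db * m
    if not da.any() or not db.any():
        raise DegenerateOverlapError("masked volume is identically zero")
    shells, n_shells = _shell_index(a.shape)
    values, counts = _shell_correlation(np.fft.fftn(da), np.fft.fftn(db),
                                        shells, n_shells)
    freq = np.arange(n_shells) / (min(a.shape) * a.voxel_size)
    return FSCCurve(freq, values, counts, a.voxel_size)


def _coerce_mask(mask, shape) -> np.ndarray:
    m = mask.data if isinstance(mask, DensityVolume) else np.asarray(mask)
    if m.shape != tuple(shape):
        raise ParameterError("mask shape does not match the maps")
    return m.astype(np.float64)


class ResolutionEstimate(NamedTuple):
    resolution_A: float
    at_nyquist: bool
    warning: str | None


def resolution_at(curve: FSCCurve, threshold: float = 0.5) -> ResolutionEstimate:
    """Resolution (A) at the first downward threshold crossing of an FSC curve.

    The crossing is located by linear interpolation between adjacent shells.
    If the curve never drops below the threshold the Nyquist limit
    (2 x voxel size) is returned with ``at_nyquist=True``; if it starts
    below threshold the lowest-resolution shell is returned with a warning.
    """
    if not -1.0 < threshold < 1.0:
        raise ParameterError("threshold must lie in (-1, 1)")
    v = np.asarray(curve.values)
    s = np.asarray(curve.shell_centers)
    if len(v) < 2:
        raise ParameterError("FSC curve is empty")
    if v[1] < threshold:  # shell 0 is DC
        warnings.warn("FSC starts below threshold; no resolvable signal")
        return ResolutionEstimate(float(1.0 / s[1]), False, "below-threshold-at-start")
    for i in range(2, len(v)):
        if v[i] < threshold <= v[i - 1]:
            frac = (v[i - 1] - threshold) / (v[i - 1] - v[i])
            s_cross = s[i - 1] + frac * (s[i] - s[i - 1])
            return ResolutionEstimate(float(1.0 / s_cross), False, None)
    return ResolutionEstimate(2.0 * curve.voxel_size, True, "at-nyquist")


@dataclass
class LocalResolutionField:
    """Resolution (A) sampled on a regular grid of windowed-FSC boxes.

    ``values[i, j, k]`` is the resolution for the box whose low corner is at
    voxel ``starts_x[i], starts_y[j], starts_z[k]``; values between nodes are
    obtained by trilinear interpolation.  All values are floored at the
    Nyquist limit of the map.
    """

    values: np.ndarray
    box: int
    spacing: int
    voxel_size: float
    starts: tuple

    def interpolate(self, points_voxels: np.ndarray) -> np.ndarray:
        """Trilinear interpolation at voxel coordinates of the parent map."""
        from scipy.interpolate import RegularGridInterpolator
        centers = [s + self.box / 2.0 for s in self.starts]
        itp = RegularGridInterpolator(centers, self.values, bounds_error=False,
                                      fill_value=None)
        return itp(np.atleast_2d(points_voxels))


def local_resolution(a: DensityVolume, b: DensityVolume, box: int = 40,
                     spacing: int = 4, threshold: float = 0.5,
                     mask_edge_fraction: float = 0.1) -> LocalResolutionField:
    """Windowed local resolution between two half maps.

    The volume is tiled with ``box``-sized cubes spaced ``spacing`` voxels
    apart; each pair of subvolumes is multiplied by a spherical mask
    (radius box/2 with a 10% cosine edge) before the shell correlation, and
    the threshold crossing gives that node's resolution.
    """
    if spacing <= 0:
        raise ParameterError("spacing must be > 0")
    if a.shape != b.shape:
        raise ParameterError("maps must share a shape")
    if box > min(a.shape):
        raise ParameterError("box exceeds the smallest map dimension")
    edge = max(1.0, mask_edge_fraction * box / 2.0)
    sphere = make_mask(MaskSpec("sphere",
                                {"radius": (box / 2.0 - edge) * a.voxel_size},
                                soft_edge=edge),
                       (box, box, box), a.voxel_size).data.astype(np.float64)
    shells, n_shells = _shell_index((box, box, box))
    freq = np.arange(n_shells) / (box * a.voxel_size)
    nyq = 2.0 * a.voxel_size
    starts = tuple(np.arange(0, n - box + 1, spacing) for n in a.shape)
    values = np.zeros(tuple(len(s) for s in starts))
    da, db = a.data.astype(np.float64), b.data.astype(np.float64)
    for i, x0 in enumerate(starts[0]):
        for j, y0 in enumerate(starts[1]):
            for k, z0 in enumerate(starts[2]):
                sa = da[x0:x0 + box, y0:y0 + box, z0:z0 + box] * sphere
                sb = db[x0:x0 + box, y0:y0 + box, z0:z0 + box] * sphere
                if not sa.any() or not sb.any():
                    values[i, j, k] = np.inf
                    continue
                vals, counts = _shell_correlation(np.fft.fftn(sa), np.fft.fftn(sb),
                                                  shells, n_shells)
                est = resolution_at(FSCCurve(freq, vals, counts, a.voxel_size),
                                    threshold)
                values[i, j, k] = max(est.resolution_A, nyq)
    return LocalResolutionField(values, box, spacing, a.voxel_size, starts)


def sharpen(v: DensityVolume, b_factor: float,
            lowpass: float | None = None) -> DensityVolume:
    """B-factor amplitude scaling ``exp(-B s^2 / 4)`` with optional low-pass.

    ``b_factor`` in A^2 (negative sharpens); ``lowpass`` is a resolution in
    A at which a cosine edge (10% fractional width) cuts the spectrum.  The
    DC term is unchanged.
    """
    v.validate()
    ax = [np.fft.fftfreq(n, d=v.voxel_size) for n in v.shape]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    s2 = gx * gx + gy * gy + gz * gz
    filt = np.exp(-b_factor * s2 / 4.0)
    if lowpass is not None:
        if lowpass <= 0:
            raise ParameterError("lowpass resolution must be > 0")
        s = np.sqrt(s2)
        s_c = 1.0 / lowpass
        x = np.clip((s - 0.9 * s_c) / (0.1 * s_c), 0.0, 1.0)
        filt *= 0.5 * (1.0 + np.cos(np.pi * x))
    out = np.fft.ifftn(np.fft.fftn(v.data.astype(np.float64)) * filt).real
    return v.copy_with(out.astype(np.float32))
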