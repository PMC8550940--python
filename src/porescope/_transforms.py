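"""Rotation conventions and grid resampling shared by every module.

Conventions (package-wide):

* Volumes are numpy arrays indexed ``data[x, y, z]``.
* The grid origin is the voxel ``shape // 2`` per axis ("grid-center origin"):
  that voxel sits at physical coordinate (0, 0, 0), so Fourier operations and
  real-space rotations share one fixed point.
* Euler angles are ZYZ **intrinsic**, in degrees: ``R = Rz(rot) @ Ry(tilt) @
  Rz(psi)``.  The rotation maps the *reference* frame onto the *particle*
  frame: a particle with pose ``(R, t)`` satisfies
  ``particle(x) = reference(R^-1 (x - t))`` (translations in voxels).

Worked example: the reference-frame unit vector ``+x`` under
``(rot, tilt, psi) = (90, 0, 0)`` maps to ``+y`` in the particle frame —
``euler_to_matrix(90, 0, 0) @ [1, 0, 0] == [0, 1, 0]``.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

__all__ = [
    "euler_to_matrix",
    "matrix_to_euler",
    "normalize_euler",
    "compose_euler",
    "rotation_angle_between",
    "grid_center",
    "transform_volume",
    "untransform_volume",
    "rotate_about_z",
    "bin_volume",
    "radius_grid",
    "frequency_grids",
]


def euler_to_matrix(rot: float, tilt: float, psi: float) -> np.ndarray:
    """ZYZ intrinsic Euler angles (degrees) -> 3x3 rotation matrix.

    Hand-rolled Rz(rot) @ Ry(tilt) @ Rz(psi) — equivalent to scipy's
    ``from_euler("ZYZ", ...)`` but without per-call object overhead (this
    sits in the innermost alignment/fitting loops).
    """
    a, b, g = np.radians([rot, tilt, psi])
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cg, sg = np.cos(g), np.sin(g)
    return np.array([
        [ca * cb * cg - sa * sg, -ca * cb * sg - sa * cg, ca * sb],
        [sa * cb * cg + ca * sg, -sa * cb * sg + ca * cg, sa * sb],
        [-sb * cg, sb * sg, cb],
    ])


def matrix_to_euler(matrix: np.ndarray) -> tuple[float, float, float]:
    """3x3 rotation matrix -> normalized ZYZ intrinsic Euler angles (degrees)."""
    rot, tilt, psi = Rotation.from_matrix(matrix).as_euler("ZYZ", degrees=True)
    return normalize_euler(rot, tilt, psi)


def normalize_euler(rot: float, tilt: float, psi: float) -> tuple[float, float, float]:
    """Map angles to the canonical ranges rot, psi in [-180, 180), tilt in [0, 180]."""
    tilt = tilt % 360.0
    if tilt > 180.0:
        tilt -= 360.0
    if tilt < 0:
        # (rot, -tilt, psi) == (rot + 180, tilt, psi + 180) in ZYZ
        rot, tilt, psi = rot + 180.0, -tilt, psi + 180.0
    rot = (rot + 180.0) % 360.0 - 180.0
    psi = (psi + 180.0) % 360.0 - 180.0
    return float(rot), float(tilt), float(psi)


def compose_euler(first: tuple[float, float, float],
                  second: tuple[float, float, float]) -> tuple[float, float, float]:
    """Euler angles of ``R(first) @ R(second)`` (apply *second* in the frame of *first*)."""
    return matrix_to_euler(euler_to_matrix(*first) @ euler_to_matrix(*second))


def rotation_angle_between(r1: np.ndarray, r2: np.ndarray) -> float:
    """Geodesic angle in degrees between two rotation matrices."""
    cos = (np.trace(r1.T @ r2) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


def grid_center(shape) -> np.ndarray:
    """Physical-origin voxel index per axis (``n // 2``)."""
    return np.array([n // 2 for n in shape], dtype=float)


def transform_volume(data: np.ndarray, matrix: np.ndarray,
                     translation=(0.0, 0.0, 0.0), order: int = 1) -> np.ndarray:
    """Apply a pose: return ``v`` with ``v(x) = data(R^-1 (x - c - t) + c)``.

    This produces the volume as it would appear in the *particle* frame given
    reference-frame ``data``; ``translation`` is in voxels.
    """
    c = grid_center(data.shape)
    t = np.asarray(translation, dtype=float)
    m = np.asarray(matrix, dtype=float).T  # R^-1
    offset = c - m @ (c + t)
    return ndimage.affine_transform(data, m, offset=offset, order=order,
                                    mode="constant", cval=0.0, prefilter=order > 1)


def untransform_volume(data: np.ndarray, matrix: np.ndarray,
                       translation=(0.0, 0.0, 0.0), order: int = 1) -> np.ndarray:
    """Invert a pose: return ``v`` with ``v(x) = data(R (x - c) + c + t)``.

    Maps a particle-frame volume back into the reference frame.
    """
    c = grid_center(data.shape)
    t = np.asarray(translation, dtype=float)
    m = np.asarray(matrix, dtype=float)
    offset = c + t - m @ c
    return ndimage.affine_transform(data, m, offset=offset, order=order,
                                    mode="constant", cval=0.0, prefilter=order > 1)


def rotate_about_z(data: np.ndarray, angle_deg: float, order: int = 1) -> np.ndarray:
    """Rotate a volume by ``angle_deg`` about the z axis through the grid center."""
    return transform_volume(data, euler_to_matrix(angle_deg, 0.0, 0.0), order=order)


def bin_volume(data: np.ndarray, factor: int) -> np.ndarray:
    """Bin by Fourier cropping (exact band limit); the mean is preserved.

    ``factor`` must divide every dimension.
    """
    if factor == 1:
        return data.astype(np.float32, copy=False)
    shape = data.shape
    if any(n % factor for n in shape):
        raise ValueError(f"factor {factor} does not divide shape {shape}")
    new = tuple(n // factor for n in shape)
    f = np.fft.fftshift(np.fft.fftn(data))
    c = [n // 2 for n in shape]
    sl = tuple(slice(ci - ni // 2, ci - ni // 2 + ni) for ci, ni in zip(c, new))
    cropped = np.fft.ifftshift(f[sl])
    out = np.fft.ifftn(cropped).real * (np.prod(new) / np.prod(shape))
    return out.astype(np.float32)


def radius_grid(shape, voxel_size: float = 1.0, center=None) -> np.ndarray:
    """Physical distance of every voxel from the grid center (same units as voxel_size)."""
    c = grid_center(shape) if center is None else np.asarray(center, dtype=float)
    axes = [(np.arange(n) - ci) * voxel_size for n, ci in zip(shape, c)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    return np.sqrt(gx * gx + gy * gy + gz * gz)


def frequency_grids(shape, voxel_size: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Spatial-frequency coordinate grids (1/A) in standard (unshifted) FFT order."""
    fx, fy, fz = (np.fft.fftfreq(n, d=voxel_size) for n in shape)
    return np.meshgrid(fx, fy, fz, indexing="ij")
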