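"""Density volumes, MRC I/O and mask construction.

A :class:`DensityVolume` is the package's universal currency: a 3D scalar
grid with a physical voxel size in Angstrom.  Files are MRC2014 mode-2
(32-bit float) maps, read and written through :mod:`gemmi`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np

from ._transforms import grid_center, radius_grid
from .errors import ParameterError, VolumeFormatError

__all__ = ["DensityVolume", "MaskSpec", "read_volume", "write_volume", "make_mask"]


@dataclass
class DensityVolume:
    """3D scalar density grid with physical voxel size.

    Parameters
    ----------
    data
        Array indexed ``[x, y, z]``; finite values only.
    voxel_size
        Edge length of one voxel in Angstrom (> 0).
    origin
        Physical coordinate of the grid-center voxel, default (0, 0, 0).
    """

    data: np.ndarray
    voxel_size: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        self.validate()

    def validate(self) -> None:
        if self.data.ndim != 3:
            raise VolumeFormatError(f"volume must be 3D, got {self.data.ndim}D")
        if any(n < 2 for n in self.data.shape):
            raise VolumeFormatError(f"each dimension must be >= 2, got {self.data.shape}")
        if not np.isfinite(self.data).all():
            raise VolumeFormatError("volume contains non-finite values")
        if not (self.voxel_size > 0):
            raise ParameterError(f"voxel_size must be > 0, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def center(self) -> np.ndarray:
        return grid_center(self.data.shape)

    def copy_with(self, data: np.ndarray) -> "DensityVolume":
        return DensityVolume(data, self.voxel_size, self.origin)


def read_volume(path) -> DensityVolume:
    """Read an MRC/CCP4 map.

    Falls back to a voxel size of 1.0 A (with a warning) when the header cell
    is zero; raises :class:`VolumeFormatError` on corrupt or non-3D input.
    """
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise VolumeFormatError(f"cannot read MRC map {path!r}: {exc}") from exc
    data = np.array(m.grid, copy=True)
    if data.ndim != 3:
        raise VolumeFormatError(f"{path!r} is not a 3D map")
    spacings = np.array(m.grid.spacing)
    if np.any(spacings <= 0):
        warnings.warn(f"{path}: header voxel size is zero; assuming 1.0 A")
        voxel = 1.0
    else:
        voxel = float(spacings.mean())
    return DensityVolume(data, voxel)


def write_volume(v: DensityVolume, path) -> None:
    """Write an MRC2014 mode-2 map with the voxel size encoded in the header."""
    v.validate()
    nx, ny, nz = v.data.shape
    grid = gemmi.FloatGrid(nx, ny, nz)
    np.asarray(grid)[...] = v.data
    grid.unit_cell = gemmi.UnitCell(nx * v.voxel_size, ny * v.voxel_size,
                                    nz * v.voxel_size, 90.0, 90.0, 90.0)
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    try:
        m.write_ccp4_map(str(path))
    except (RuntimeError, OSError) as exc:
        raise OSError(f"cannot write map to {path!r}: {exc}") from exc


@dataclass
class MaskSpec:
    """Geometric mask specification.

    ``kind`` is one of ``sphere``, ``soft_sphere``, ``cylinder``,
    ``ring_shell``.  Geometric parameters are in Angstrom, measured from the
    grid center; ``soft_edge`` is a cosine-ramp width in voxels.

    Parameters by kind::

        sphere / soft_sphere : radius
        cylinder             : radius, height (full axial extent along z)
        ring_shell           : r_inner, r_outer, z_min, z_max
    """

    kind: str
    params: dict = field(default_factory=dict)
    soft_edge: float = 0.0

    KINDS = ("sphere", "soft_sphere", "cylinder", "ring_shell")

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise ParameterError(f"unknown mask kind {self.kind!r}")
        if self.kind == "soft_sphere" and self.soft_edge == 0.0:
            self.soft_edge = 3.0
        if self.soft_edge < 0:
            raise ParameterError("soft_edge must be >= 0")

    def to_json(self) -> str:
        return json.dumps({"kind": self.kind, "params": self.params,
                           "soft_edge": self.soft_edge})

    @classmethod
    def from_json(cls, text: str) -> "MaskSpec":
        d = json.loads(text)
        return cls(d["kind"], d.get("params", {}), d.get("soft_edge", 0.0))


def _soft_ramp(distance_out: np.ndarray, width: float) -> np.ndarray:
    """1 inside (distance <= 0), cosine ramp to 0 over ``width``, 0 beyond."""
    if width <= 0:
        return (distance_out <= 0).astype(np.float32)
    x = np.clip(distance_out / width, 0.0, 1.0)
    return (0.5 * (1.0 + np.cos(np.pi * x))).astype(np.float32)


def make_mask(spec: MaskSpec, shape, voxel_size: float) -> DensityVolume:
    """Build a [0, 1] mask volume from a :class:`MaskSpec`.

    The hard region is exactly 1; outside it a cosine ramp of ``soft_edge``
    voxels falls monotonically to 0.
    """
    p = spec.params
    w = spec.soft_edge * voxel_size  # ramp width in A
    c = grid_center(shape)
    if spec.kind in ("sphere", "soft_sphere"):
        radius = float(p["radius"])
        if radius <= 0:
            raise ParameterError("sphere radius must be > 0")
        r = radius_grid(shape, voxel_size)
        mask = _soft_ramp(r - radius, w)
    elif spec.kind == "cylinder":
        radius, height = float(p["radius"]), float(p["height"])
        if radius <= 0 or height <= 0:
            raise ParameterError("cylinder radius and height must be > 0")
        ax = [(np.arange(n) - ci) * voxel_size for n, ci in zip(shape, c)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        d_r = np.sqrt(gx * gx + gy * gy) - radius
        d_z = np.abs(gz) - height / 2.0
        mask = _soft_ramp(np.maximum(d_r, d_z), w)
    elif spec.kind == "ring_shell":
        r_in, r_out = float(p["r_inner"]), float(p["r_outer"])
        z_min, z_max = float(p.get("z_min", -np.inf)), float(p.get("z_max", np.inf))
        if r_in < 0 or r_out < r_in:
            raise ParameterError("require 0 <= r_inner <= r_outer")
        if r_in == r_out:
            warnings.warn("ring_shell with r_inner == r_outer is empty")
        ax = [(np.arange(n) - ci) * voxel_size for n, ci in zip(shape, c)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        r = np.sqrt(gx * gx + gy * gy)
        d_r = np.maximum(r_in - r, r - r_out)
        d_z = np.maximum(z_min - gz, gz - z_max)
        mask = _soft_ramp(np.maximum(d_r, d_z), w)
        if r_in == r_out:
            mask = np.zeros(shape, dtype=np.float32)
    else:  # pragma: no cover - guarded in MaskSpec
        raise ParameterError(f"unknown mask kind {spec.kind!r}")
    return DensityVolume(mask, voxel_size)
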