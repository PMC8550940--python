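"""Protomer (asymmetric-unit) expansion, refinement, exclusion and recomposition.

An aligned Cn-symmetric particle is expanded into its n protomers: each
record inherits the parent pose composed with the k-th symmetry rotation,
and its center is displaced radially along the asymmetric unit's azimuth.
Protomer quality control is score-driven (threshold / worst-k / percentile)
with a deterministic tie-break, implemented as a soft delete so particle
accounting stays auditable; the original study's visual inspection can be
reproduced by importing a manual exclusion list as a table.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd

from ._transforms import compose_euler, euler_to_matrix, matrix_to_euler
from .align import AlignConfig, WedgeMask, align_particle, apply_symmetry
from .errors import ParameterError, PartitionError
from .tables import validate_table
from .volumes import DensityVolume, MaskSpec, make_mask

__all__ = ["PROTOMER_COLUMNS", "expand_protomers", "extract_subvolume",
           "masked_refine", "exclude_protomers", "split_classes",
           "compose_full_map"]

PROTOMER_COLUMNS = ["parent_particle_id", "asu_index", "x", "y", "z",
                    "rot", "tilt", "psi", "cc", "included"]


def expand_protomers(table: pd.DataFrame, order: int,
                     radial_offset: float, voxel_size: float = 1.0) -> pd.DataFrame:
    """Expand each aligned particle into ``order`` protomer records.

    The k-th protomer pose is the parent pose composed with a rotation of
    ``360 k / order`` about z; its center is the parent center displaced by
    ``radial_offset`` (A) along the asymmetric unit's azimuth, expressed in
    the particle frame.  Positions are in voxels of the parent frame.
    """
    validate_table(table)
    if order < 1:
        raise ParameterError("symmetry order must be >= 1")
    if table[["rot", "tilt", "psi"]].isna().any().any():
        raise ParameterError("all particles need refined poses before expansion")
    rows = []
    r_vox = radial_offset / voxel_size
    for row in table.itertuples(index=False):
        parent_euler = (row.rot, row.tilt, row.psi)
        r_parent = euler_to_matrix(*parent_euler)
        for k in range(order):
            theta = 360.0 * k / order
            euler_k = compose_euler(parent_euler, (theta, 0.0, 0.0))
            direction = r_parent @ euler_to_matrix(theta, 0, 0) @ np.array([r_vox, 0.0, 0.0])
            rows.append({
                "parent_particle_id": row.particle_id, "asu_index": k,
                "x": row.x + direction[0], "y": row.y + direction[1],
                "z": row.z + direction[2],
                "rot": euler_k[0], "tilt": euler_k[1], "psi": euler_k[2],
                "cc": row.cc, "included": True,
            })
    out = pd.DataFrame(rows, columns=PROTOMER_COLUMNS)
    assert len(out) == order * len(table)
    return out


def extract_subvolume(v: DensityVolume, center_voxels, box: int) -> DensityVolume:
    """Crop a ``box``-sized cube around a (voxel) center, zero-padding at edges."""
    c = np.round(np.asarray(v.center) + np.asarray(center_voxels)).astype(int)
    out = np.zeros((box, box, box), dtype=np.float32)
    lo = c - box // 2
    src_lo = np.maximum(lo, 0)
    src_hi = np.minimum(lo + box, v.shape)
    dst_lo = src_lo - lo
    dst_hi = dst_lo + (src_hi - src_lo)
    if np.all(src_hi > src_lo):
        out[dst_lo[0]:dst_hi[0], dst_lo[1]:dst_hi[1], dst_lo[2]:dst_hi[2]] = \
            v.data[src_lo[0]:src_hi[0], src_lo[1]:src_hi[1], src_lo[2]:src_hi[2]]
    return DensityVolume(out, v.voxel_size)


def masked_refine(protomer_vols, records: pd.DataFrame, reference: DensityVolume,
                  ring_mask: MaskSpec | DensityVolume, wedge: WedgeMask | None,
                  cfg: AlignConfig | None = None) -> pd.DataFrame:
    """Local pose refinement of protomers against a ring-masked reference.

    The mask (e.g. a CR/IR/NR ring shell) is applied to the reference and
    each protomer before the wedge-constrained CC search; the search is
    restricted to a small range (default +/-10 degrees, +/-5 voxels).
    Returns an updated copy of ``records``.
    """
    if cfg is None:
        cfg = AlignConfig(angular_step=2.5, rot_range=0.0, tilt_range=10.0,
                          psi_range=10.0, max_shift=5.0, symmetry=1)
    mask = ring_mask if isinstance(ring_mask, DensityVolume) else \
        make_mask(ring_mask, reference.shape, reference.voxel_size)
    if mask.data.max() <= 0:
        raise ParameterError("ring mask is empty")
    ref_masked = reference.data * mask.data
    out = records.copy()
    for i, (vol, row) in enumerate(zip(protomer_vols, out.itertuples(index=False))):
        data = vol.data if isinstance(vol, DensityVolume) else np.asarray(vol)
        euler, shift, score = align_particle(
            data * mask.data, ref_masked, wedge, cfg,
            pose=(row.rot, row.tilt, row.psi))
        out.iloc[i, out.columns.get_indexer(["rot", "tilt", "psi"])] = euler
        out.iloc[i, out.columns.get_indexer(["x", "y", "z"])] = shift
        out.iloc[i, out.columns.get_loc("cc")] = score
    return out


def exclude_protomers(records: pd.DataFrame, cc_threshold: float | None = None,
                      worst_k: int | None = None,
                      percentile: float | None = None) -> pd.DataFrame:
    """Flag low-quality protomers as excluded (soft delete, count preserved).

    Exactly one rule must be given: ``cc_threshold`` (exclude cc below it),
    ``worst_k`` (exclude the k worst) or ``percentile`` (exclude the lowest
    percent).  Ties break deterministically by ascending
    (cc, parent_particle_id, asu_index).
    """
    rules = [r is not None for r in (cc_threshold, worst_k, percentile)]
    if sum(rules) != 1:
        raise ParameterError("give exactly one of cc_threshold, worst_k, percentile")
    if records["cc"].isna().any():
        raise ParameterError("cc scores must be populated before exclusion")
    out = records.copy()
    order = out.sort_values(["cc", "parent_particle_id", "asu_index"],
                            kind="mergesort").index
    if cc_threshold is not None:
        drop = out.index[out["cc"] < cc_threshold]
    elif worst_k is not None:
        if worst_k < 0:
            raise ParameterError("worst_k must be >= 0")
        drop = order[:worst_k]
    else:
        if not 0.0 <= percentile <= 100.0:
            raise ParameterError("percentile must be in [0, 100]")
        k = int(np.floor(len(out) * percentile / 100.0))
        drop = order[:k]
    out["included"] = True
    out.loc[drop, "included"] = False
    if not out["included"].any():
        raise PartitionError("exclusion rule removed every protomer")
    return out


def split_classes(table: pd.DataFrame, ring_presence_by_particle: dict
                  ) -> pd.DataFrame:
    """Assign depletion-series class labels from per-particle ring presence.

    Class 1 = CR+IR+NR, class 2 = IR+NR, class 3 = IR only; a CR+IR call —
    an assembly the depletion series never produced — gets class 0 with a
    warning.  Raises when a particle has no presence call.
    """
    from .geometry import classify_ring_presence

    validate_table(table)
    out = table.copy()
    labels = []
    for pid in out["particle_id"]:
        if pid not in ring_presence_by_particle:
            raise ParameterError(f"no ring-presence call for particle {pid}")
        labels.append(classify_ring_presence(ring_presence_by_particle[pid]))
    out["class_label"] = labels
    return out


def compose_full_map(subprotomer: DensityVolume, order: int,
                     placement, canvas_shape, mode: str = "max",
                     interp_order: int = 1) -> DensityVolume:
    """Compose a full Cn map from one subprotomer average.

    ``placement`` is a ``(euler, translation_voxels)`` pair mapping the
    subprotomer frame into the canvas frame; the ``order`` symmetry copies
    are blended voxel-wise by max (default) or mean.  The result is
    Cn-symmetric up to interpolation.
    """
    from scipy import ndimage

    if order < 1:
        raise ParameterError("symmetry order must be >= 1")
    if mode not in ("max", "mean"):
        raise ParameterError("mode must be 'max' or 'mean'")
    euler, t = placement
    t = np.asarray(t, dtype=float)
    canvas_shape = tuple(int(n) for n in canvas_shape)
    c_canvas = np.array([n // 2 for n in canvas_shape], dtype=float)
    c_src = np.asarray(subprotomer.center, dtype=float)
    if np.any(np.abs(t) > np.asarray(canvas_shape) / 2.0):
        raise ParameterError("placement translation lies outside the canvas")
    r_place = euler_to_matrix(*euler)
    acc = None
    for k in range(order):
        rz = euler_to_matrix(360.0 * k / order, 0.0, 0.0)
        m = r_place.T @ rz.T  # x_src = Rp^-1 (Rz^-1 (x - c)) - t ... + c_src
        offset = c_src - r_place.T @ t - m @ c_canvas
        copy = ndimage.affine_transform(subprotomer.data.astype(float), m,
                                        offset=offset, output_shape=canvas_shape,
                                        order=interp_order, mode="constant", cval=0.0,
                                        prefilter=interp_order > 1)
        if acc is None:
            acc = copy if mode == "max" else copy.copy()
        elif mode == "max":
            np.maximum(acc, copy, out=acc)
        else:
            acc += copy
    if mode == "mean":
        acc /= order
    return DensityVolume(acc.astype(np.float32), subprotomer.voxel_size)
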