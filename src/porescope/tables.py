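"""Particle metadata tables.

One row per particle: position (voxels of the source frame), ZYZ intrinsic
Euler angles in degrees (mapping the reference frame onto the particle
frame), a correlation score, a half-set label and an optional class label.
Serialized as tab-separated text with a fixed column order; an optional
STAR-dialect writer is provided for ecosystem compatibility.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._transforms import normalize_euler
from .errors import ParameterError, PartitionError

COLUMNS = ["particle_id", "source_id", "x", "y", "z",
           "rot", "tilt", "psi", "cc", "half_set", "class_label"]

__all__ = ["COLUMNS", "new_table", "validate_table", "normalize_table_eulers",
           "read_table", "write_table", "write_star"]


def new_table(n: int, source_id: str = "sim") -> pd.DataFrame:
    """Empty table for ``n`` particles with identity poses and alternating half sets."""
    if n < 1:
        raise ParameterError("need at least one particle")
    return pd.DataFrame({
        "particle_id": np.arange(n, dtype=int),
        "source_id": source_id,
        "x": 0.0, "y": 0.0, "z": 0.0,
        "rot": 0.0, "tilt": 0.0, "psi": 0.0,
        "cc": np.nan,
        "half_set": np.where(np.arange(n) % 2 == 0, "A", "B"),
        "class_label": -1,
    })


def validate_table(df: pd.DataFrame, aligned: bool = False) -> None:
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ParameterError(f"particle table is missing columns {missing}")
    if df["particle_id"].duplicated().any():
        raise ParameterError("particle_id values must be unique")
    if aligned and not df["half_set"].isin(["A", "B"]).all():
        raise PartitionError("every aligned particle needs a half_set in {A, B}")


def normalize_table_eulers(df: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with rot, psi in [-180, 180) and tilt in [0, 180]."""
    out = df.copy()
    trip = [normalize_euler(r, t, p)
            for r, t, p in zip(df["rot"], df["tilt"], df["psi"])]
    out[["rot", "tilt", "psi"]] = np.asarray(trip, dtype=float)
    return out


def write_table(df: pd.DataFrame, path) -> None:
    validate_table(df)
    df.to_csv(path, sep="\t", index=False, columns=COLUMNS, float_format="%.6g")


def read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    validate_table(df)
    return df


def write_star(df: pd.DataFrame, path, block: str = "particles") -> None:
    """Minimal STAR-dialect writer (one loop_ block, RELION-style tag names)."""
    validate_table(df)
    tags = ["rlnImageName", "rlnMicrographName",
            "rlnCoordinateX", "rlnCoordinateY", "rlnCoordinateZ",
            "rlnAngleRot", "rlnAngleTilt", "rlnAnglePsi",
            "rlnAutopickFigureOfMerit", "rlnRandomSubset", "rlnClassNumber"]
    half_num = df["half_set"].map({"A": 1, "B": 2}).fillna(0).astype(int)
    with open(path, "w") as fh:
        fh.write(f"\ndata_{block}\n\nloop_\n")
        for i, tag in enumerate(tags, start=1):
            fh.write(f"_{tag} #{i}\n")
        for row, half in zip(df.itertuples(index=False), half_num):
            fh.write(f"{row.particle_id} {row.source_id} "
                     f"{row.x:.6g} {row.y:.6g} {row.z:.6g} "
                     f"{row.rot:.6g} {row.tilt:.6g} {row.psi:.6g} "
                     f"{0.0 if pd.isna(row.cc) else row.cc:.6g} "
                     f"{half} {row.class_label}\n")
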