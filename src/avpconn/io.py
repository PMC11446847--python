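"""Readers and writers for synapse tables, annotations, weight matrices,
region hulls and eye maps.

Dialect: comma-separated UTF-8 with '.' decimal, one record per line,
header required.  All positions are carried in nm end-to-end; the single
voxel-to-nm conversion point is the ``scale`` argument of
:func:`read_synapse_table`.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .types import ANNOTATION_COLUMNS, SYNAPSE_COLUMNS, EyeMap, RegionHull

logger = logging.getLogger(__name__)

# cell-class families accepted without a warning
_KNOWN_CLASS_PREFIXES = (
    "MeTu", "TuBu", "ER", "ExR", "TuTu", "AOTU046", "Mi", "Dm", "Sm", "L",
    "T", "R7", "R8", "EPG", "MeMeDRA", "other",
)


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")


def read_synapse_table(path, scale: tuple = (1.0, 1.0, 1.0)) -> pd.DataFrame:
    """Read a synapse table CSV into a DataFrame with nm positions.

    Columns: pre_id, post_id, x_nm, y_nm, z_nm, cleft_score.  ``scale``
    converts voxel input coordinates to nm (applied once, here).  Row order
    is preserved; background contacts (partner id "0") are kept so raw
    counts stay auditable.
    """
    df = pd.read_csv(path, dtype={"pre_id": str, "post_id": str})
    _require_columns(df, SYNAPSE_COLUMNS, path)
    df = df[SYNAPSE_COLUMNS].copy()
    for col in ("x_nm", "y_nm", "z_nm"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[vals.isna() & df[col].notna()]
        if len(bad):
            raise FormatError(f"{path}: non-numeric {col} at row {bad[0]}")
        if vals.isna().any():
            raise FormatError(f"{path}: missing {col} at row {int(vals.index[vals.isna()][0])}")
        df[col] = vals.astype(float)
    if not np.isfinite(df[["x_nm", "y_nm", "z_nm"]].to_numpy()).all():
        raise ValidationError(f"{path}: non-finite synapse position")
    cleft = pd.to_numeric(df["cleft_score"], errors="coerce")
    if cleft.isna().any():
        raise FormatError(f"{path}: non-numeric cleft_score at row {int(cleft.index[cleft.isna()][0])}")
    if (cleft < 0).any():
        row = int(cleft.index[cleft < 0][0])
        raise ValidationError(f"{path}: negative cleft_score at row {row}")
    df["cleft_score"] = cleft.astype(int)
    sx, sy, sz = scale
    if (sx, sy, sz) != (1.0, 1.0, 1.0):
        df["x_nm"] *= sx
        df["y_nm"] *= sy
        df["z_nm"] *= sz
    return df


def write_synapse_table(df: pd.DataFrame, path) -> None:
    df[SYNAPSE_COLUMNS].to_csv(path, index=False)


def read_annotations(path) -> pd.DataFrame:
    """Read a neuron annotation CSV (neuron_id, cell_class, hemisphere, subtype).

    Duplicate neuron ids are rejected; unknown cell classes are kept
    verbatim with a logged warning.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ANNOTATION_COLUMNS[:3], path)
    if "subtype" not in df.columns:
        df["subtype"] = ""
    df = df[ANNOTATION_COLUMNS].copy()
    dup = df["neuron_id"][df["neuron_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"{path}: duplicate neuron_id(s): {sorted(set(dup))}")
    bad_hemi = df["hemisphere"][~df["hemisphere"].isin(["L", "R"])]
    if len(bad_hemi):
        raise ValidationError(f"{path}: hemisphere must be L or R, got {bad_hemi.iloc[0]!r}")
    for cls in df["cell_class"].unique():
        if not any(cls.startswith(p) for p in _KNOWN_CLASS_PREFIXES):
            logger.warning("unknown cell_class %r kept verbatim", cls)
    return df


def write_annotations(df: pd.DataFrame, path) -> None:
    df[ANNOTATION_COLUMNS].to_csv(path, index=False)


def write_matrix(matrix, path) -> None:
    """Write a WeightMatrix as a rectangular CSV (pre ids x post ids).

    Values survive a round trip to 12 decimal digits; NaN entries are
    refused.
    """
    vals = np.asarray(matrix.values, dtype=float)
    if np.isnan(vals).any():
        raise ValidationError("weight matrix contains NaN; refusing to write")
    frame = pd.DataFrame(vals, index=list(matrix.pre_ids), columns=list(matrix.post_ids))
    frame.index.name = "pre_id"
    frame.to_csv(path, float_format="%.17g")


def read_matrix(path, region: str = "", level: str = "individual"):
    """Read a weight-matrix CSV back into a WeightMatrix (no denominators)."""
    from .connectivity import WeightMatrix

    frame = pd.read_csv(path, index_col=0)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    return WeightMatrix(
        region=region,
        pre_ids=list(frame.index),
        post_ids=list(frame.columns),
        values=frame.to_numpy(dtype=float),
        counts=None,
        denominators=None,
        level=level,
    )


def write_region_hulls(hulls: Iterable[RegionHull], path) -> None:
    payload = [
        {"name": h.name, "vertices": np.asarray(h.vertices).tolist(), "subtract": h.subtract}
        for h in hulls
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_region_hulls(path) -> dict:
    payload = json.loads(Path(path).read_text())
    hulls = {}
    for item in payload:
        hulls[item["name"]] = RegionHull(
            name=item["name"],
            vertices=np.asarray(item["vertices"], dtype=float),
            subtract=item.get("subtract"),
        )
    return hulls


def write_eye_map(eye_map: EyeMap, columns, path) -> None:
    """Write an eye map CSV: column_id,q,r,azimuth_deg,elevation_deg,is_equator."""
    rows = []
    by_id = {c.column_id: c for c in columns}
    for cid, (az, el) in sorted(eye_map.directions.items()):
        col = by_id.get(cid)
        rows.append({
            "column_id": cid,
            "q": col.q if col else "",
            "r": col.r if col else "",
            "azimuth_deg": az,
            "elevation_deg": el,
            "is_equator": int(cid in eye_map.equator),
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_eye_map(path) -> EyeMap:
    df = pd.read_csv(path, dtype={"column_id": str})
    directions = {r.column_id: (float(r.azimuth_deg), float(r.elevation_deg)) for r in df.itertuples()}
    equator = {r.column_id for r in df.itertuples() if int(r.is_equator)}
    return EyeMap(directions=directions, equator=equator, unmatched=[])
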