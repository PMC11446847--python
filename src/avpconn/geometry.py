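"""Neuropil region membership, medulla column/layer coordinates, and
hexagonal-lattice alignment of columns to ommatidial viewing directions.

Region membership uses a Delaunay tessellation of the hull vertex set, so a
point is inside exactly when it lies in the convex hull (brute-force
half-space test gives identical answers).  Column axes come from a PCA of
the anchor neuron's synapse cloud, oriented toward a caller-supplied
proximal reference; depth bounds are 3rd/97th linear-interpolation
percentiles of the axial projections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.spatial import Delaunay, QhullError

from .errors import GeometryError
from .types import EyeMap, MedullaColumn, RegionHull

# ---------------------------------------------------------------------------
# region membership


def _tessellation(hull: RegionHull) -> Delaunay:
    try:
        return Delaunay(hull.vertices)
    except QhullError as exc:  # degenerate (coplanar) vertex set
        raise GeometryError(f"hull {hull.name!r} is degenerate: {exc}") from exc


def point_in_region(points, hull: RegionHull, subtract_hull: Optional[RegionHull] = None):
    """True where a point lies inside the hull (minus the subtracted hull).

    Accepts a single 3-vector or an (n, 3) array; returns a bool or a bool
    array accordingly.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    tess = _tessellation(hull)
    inside = tess.find_simplex(pts) >= 0
    if hull.subtract is not None and subtract_hull is None:
        raise GeometryError(
            f"hull {hull.name!r} subtracts {hull.subtract!r} but no subtract hull was supplied"
        )
    if subtract_hull is not None:
        inside &= _tessellation(subtract_hull).find_simplex(pts) < 0
    if np.asarray(points).ndim == 1:
        return bool(inside[0])
    return inside


def points_in_hull_halfspace(points, hull: RegionHull, tol: float = 1e-9):
    """Brute-force half-space membership over the hull facets (oracle)."""
    from scipy.spatial import ConvexHull

    pts = np.atleast_2d(np.asarray(points, dtype=float))
    ch = ConvexHull(hull.vertices)
    # facet inequalities A x + b <= 0
    a, b = ch.equations[:, :3], ch.equations[:, 3]
    scale = max(1.0, np.abs(hull.vertices).max())
    return np.all(pts @ a.T + b <= tol * scale, axis=1)


# ---------------------------------------------------------------------------
# column axes and layers


def fit_column_axis(
    positions,
    proximal_reference,
    column_id: str = "",
    q: int = 0,
    r: int = 0,
    min_points: int = 10,
    isotropy_warning_ratio: float = 1.2,
) -> MedullaColumn:
    """Fit the distal->proximal axis of one column from its anchor neuron.

    The axis is the first principal direction of the synapse cloud,
    oriented so that increasing depth points toward ``proximal_reference``.
    Depth bounds are the 3rd/97th percentile of the axial projections.
    """
    pts = np.asarray(positions, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < min_points:
        raise GeometryError(f"column {column_id!r}: need >= {min_points} 3-D points")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    cov = centred.T @ centred / pts.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    scale = max(1.0, float(np.abs(pts).max()) ** 2)
    if evals[0] <= 1e-12 * scale:
        raise GeometryError(f"column {column_id!r}: coincident point cloud, no axis")
    if evals[1] <= 1e-12 * scale:
        raise GeometryError(f"column {column_id!r}: collinear point cloud (rank deficient)")
    axis = evecs[:, 0]
    if evals[0] / evals[1] < isotropy_warning_ratio:
        warnings.warn(
            f"column {column_id!r}: leading eigenvalue ratio "
            f"{evals[0] / evals[1]:.3f} < {isotropy_warning_ratio}; axis ill-defined",
            stacklevel=2,
        )
    ref = np.asarray(proximal_reference, dtype=float)
    if np.dot(axis, ref - centroid) < 0:
        axis = -axis
    proj = centred @ axis
    lo, hi = np.percentile(proj, [3.0, 97.0])
    if not lo < hi:
        raise GeometryError(f"column {column_id!r}: degenerate depth extent")
    return MedullaColumn(
        column_id=column_id, q=q, r=r, axis=axis, anchor=centroid,
        depth_lo=float(lo), depth_hi=float(hi),
    )


#: default medulla layer boundaries (percent along the distal-proximal axis)
DEFAULT_LAYER_BOUNDS = (-3.9, 5.5, 17.1, 30.8, 34.0, 43.2, 50.1, 63.1, 75.4, 92.4, 102.2)
DEFAULT_LAYER_NAMES = tuple(f"M{i}" for i in range(1, 11))


@dataclass(frozen=True)
class LayerTable:
    """Ten contiguous half-open depth intervals M1..M10 (terminal edge closed)."""

    bounds: tuple = DEFAULT_LAYER_BOUNDS
    names: tuple = DEFAULT_LAYER_NAMES

    def __post_init__(self) -> None:
        b = np.asarray(self.bounds, dtype=float)
        if len(b) != len(self.names) + 1 or np.any(np.diff(b) <= 0):
            raise GeometryError("layer bounds must be strictly increasing and match names")


def layer_of(depth_percent: float, layers: LayerTable = LayerTable()) -> str:
    """Layer label whose half-open interval contains the depth (percent).

    Intervals are [lo, hi); the terminal upper edge belongs to the last
    layer.  Out-of-range depths raise.
    """
    b = np.asarray(layers.bounds, dtype=float)
    if depth_percent < b[0] or depth_percent > b[-1]:
        raise GeometryError(
            f"depth {depth_percent} outside layer cover [{b[0]}, {b[-1]}]"
        )
    if depth_percent == b[-1]:
        return layers.names[-1]
    idx = int(np.searchsorted(b, depth_percent, side="right") - 1)
    return layers.names[idx]


# ---------------------------------------------------------------------------
# equator detection and hex grid alignment


def detect_equator(photoreceptor_counts: Mapping[str, int]) -> Set[str]:
    """Columns with 7 or 8 photoreceptors are equatorial (6 elsewhere)."""
    equator = set()
    for cid, count in photoreceptor_counts.items():
        if count < 0:
            raise GeometryError(f"column {cid}: negative photoreceptor count")
        if count == 0:
            warnings.warn(f"column {cid}: photoreceptor count 0, flagged non-equatorial", stacklevel=2)
        if count in (7, 8):
            equator.add(cid)
    return equator


def _mirror_axial(q: int, r: int) -> Tuple[int, int]:
    # reflection that maps rows of constant r onto themselves (left-right flip)
    return (-q - r, r)


def align_hex_grids(
    columns: Mapping[str, Tuple[int, int]],
    column_equator: Set[str],
    ommatidia: Mapping[Tuple[int, int], Tuple[float, float]],
    ommatidia_equator_rows: Set[int],
    search_margin: int = 3,
) -> EyeMap:
    """Align the medulla column lattice to the ommatidial lattice.

    Searches integer axial offsets (dq, dr), constrained so that column
    equator rows land on ommatidial equator rows, in both mirror
    orientations, and returns the assignment minimizing the total count of
    unmatched points on either side.  Ties prefer the unmirrored
    orientation (a mirror is unidentifiable on a mirror-symmetric field),
    then the smallest offset magnitude, then lexicographic (dq, dr).
    Matched columns receive the azimuth/elevation of their ommatidium.
    """
    if not columns or not ommatidia:
        raise GeometryError("empty lattice")
    col_eq_rows = {columns[cid][1] for cid in column_equator if cid in columns}
    if not col_eq_rows or not ommatidia_equator_rows:
        raise GeometryError("both lattices need at least one equator row")

    omm_set = set(ommatidia.keys())
    col_items = list(columns.items())
    qs = [qr[0] for qr in ommatidia] + [qr[0] for qr in columns.values()]
    q_lo, q_hi = min(qs), max(qs)

    candidates = []
    for mirrored in (False, True):
        coords = {
            cid: (_mirror_axial(*qr) if mirrored else tuple(qr)) for cid, qr in col_items
        }
        dr_options = sorted({ro - rc for rc in col_eq_rows for ro in ommatidia_equator_rows})
        for dr in dr_options:
            for dq in range(q_lo - q_hi - search_margin, q_hi - q_lo + search_margin + 1):
                shifted = {cid: (qr[0] + dq, qr[1] + dr) for cid, qr in coords.items()}
                matched = {cid: qr for cid, qr in shifted.items() if qr in omm_set}
                unmatched = (len(shifted) - len(matched)) + (len(omm_set) - len(matched))
                candidates.append((unmatched, dq * dq + dr * dr, mirrored, dq, dr, matched))
    # ties: identity orientation first, then smallest offset magnitude,
    # then lexicographic offset
    candidates.sort(key=lambda c: (c[0], c[2], c[1], c[3], c[4]))
    unmatched_n, _, mirrored, dq, dr, matched = candidates[0]

    directions = {cid: ommatidia[qr] for cid, qr in matched.items()}
    unmatched_cols = sorted(set(columns) - set(matched))
    return EyeMap(
        directions=directions,
        equator=set(column_equator) & set(matched),
        unmatched=unmatched_cols,
        offset=(dq, dr),
        mirrored=mirrored,
    )


# ---------------------------------------------------------------------------
# hex lattice helpers (axial coordinates, pointy-top rows of constant r)

SQRT3 = float(np.sqrt(3.0))


def hex_lattice(side: int) -> List[Tuple[int, int]]:
    """Axial coordinates of a hexagon-shaped lattice of the given side."""
    n = side - 1
    cells = []
    for q in range(-n, n + 1):
        for r in range(max(-n, -q - n), min(n, -q + n) + 1):
            cells.append((q, r))
    return cells


def axial_to_xy(q, r, pitch: float) -> Tuple[float, float]:
    """Centre of an axial cell; x = anterior-posterior, y = dorsal-ventral."""
    return (pitch * (q + r / 2.0), pitch * (SQRT3 / 2.0) * r)


def nearest_column_ids(points, columns: Sequence[MedullaColumn]) -> List[str]:
    """Assign each 3-D point to the column with nearest axis (perpendicular
    distance); ties go to the lexicographically smaller column_id."""
    if not columns:
        raise GeometryError("no columns defined")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    cols = sorted(columns, key=lambda c: c.column_id)
    anchors = np.stack([c.anchor for c in cols])          # (m, 3)
    axes = np.stack([c.axis for c in cols])               # (m, 3)
    diff = pts[:, None, :] - anchors[None, :, :]          # (n, m, 3)
    along = np.einsum("nmk,mk->nm", diff, axes)
    perp = diff - along[..., None] * axes[None, :, :]
    dist = np.linalg.norm(perp, axis=2)
    idx = np.argmin(dist, axis=1)  # first occurrence = smallest id (sorted)
    return [cols[i].column_id for i in idx]
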