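"""Receptive-field prediction by synaptic back-tracing, and analysis of
stimulus-response grids from calcium imaging.

The predicted visual field of a ring (ER) neuron assigns each medulla
column c a direct-pathway value

    D(c) = sum_b sum_m w(b->ER) * w(m->b) * occ(m, c)

over TuBu neurons b and MeTu neurons m, where occ(m, c) is the fraction of
m's qualifying medulla sites nearest column c; the indirect pathway
interposes the bilateral TuTu neurons, I(c) = sum_{b,t,m}
w(b->ER) * w(t->b) * w(m->t) * occ(m, c).  Because occupancies sum to one
per neuron, sum_c D(c) = sum_b w(b->ER) * sum_m w(m->b).  Direct and
indirect values are reported separately (putatively excitatory vs
inhibitory) and never summed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import wilcoxon

from .errors import AvpError, GeometryError, ValidationError
from .geometry import nearest_column_ids
from .types import ColumnWeightField, EllipseFit, EyeMap, MedullaColumn, Occupancy

#: key under which weights of columns absent from the eye map are reported
UNMAPPED = None


def column_occupancy(
    sites,
    columns: Sequence[MedullaColumn],
    metu_id: str = "",
) -> Occupancy:
    """Fraction of a MeTu neuron's medulla sites nearest each column.

    ``sites`` are the presynaptic site positions by default (a caller may
    pass dendritic postsynaptic sites instead; see the pipeline switch).
    An empty site set yields an empty mapping with a warning.
    """
    if not columns:
        raise GeometryError("no columns defined")
    pts = np.asarray(sites, dtype=float)
    if pts.size == 0:
        warnings.warn(f"neuron {metu_id!r} has no qualifying sites; empty occupancy", stacklevel=2)
        return Occupancy(metu_id=metu_id, fractions={})
    assigned = nearest_column_ids(pts, columns)
    fractions: Dict[str, float] = {}
    for cid in assigned:
        fractions[cid] = fractions.get(cid, 0.0) + 1.0
    total = float(len(assigned))
    return Occupancy(metu_id=metu_id, fractions={c: n / total for c, n in fractions.items()})


def backtrace_field(
    er_id: str,
    tubu_er,          # WeightMatrix: pre=TuBu, post=ER (bulb)
    metu_tubu,        # WeightMatrix: pre=MeTu, post=TuBu (AOTUsu)
    occupancies: Mapping[str, Occupancy],
    pathway: str = "both",
    metu_tutu=None,   # WeightMatrix: pre=MeTu, post=TuTu
    tutu_tubu=None,   # WeightMatrix: pre=TuTu, post=TuBu
) -> ColumnWeightField:
    """Back-trace one ER neuron to per-column pathway weights.

    The AOTU046-mediated interhemispheric path is not traced.  ER neurons
    without TuBu input yield an empty field with a warning.
    """
    if pathway not in ("direct", "indirect", "both"):
        raise ValidationError(f"unknown pathway {pathway!r}")
    if er_id not in tubu_er.post_ids:
        warnings.warn(f"{er_id!r} has no TuBu input; empty field", stacklevel=2)
        return ColumnWeightField(er_id=er_id)

    er_col = tubu_er.column(er_id)
    direct: Dict[str, float] = {}
    indirect: Dict[str, float] = {}

    def accumulate(target: Dict[str, float], metu_ids, metu_weights: np.ndarray) -> None:
        for m_idx, metu in enumerate(metu_ids):
            wm = metu_weights[m_idx]
            if wm == 0.0:
                continue
            occ = occupancies.get(metu)
            if occ is None:
                continue
            for cid, frac in occ.fractions.items():
                target[cid] = target.get(cid, 0.0) + wm * frac

    if pathway in ("direct", "both"):
        for b_idx, tubu in enumerate(tubu_er.pre_ids):
            w_b = float(er_col[b_idx])
            if w_b == 0.0 or tubu not in metu_tubu.post_ids:
                continue
            metu_w = w_b * metu_tubu.column(tubu)
            accumulate(direct, metu_tubu.pre_ids, metu_w)

    if pathway in ("indirect", "both") and metu_tutu is not None and tutu_tubu is not None:
        for b_idx, tubu in enumerate(tubu_er.pre_ids):
            w_b = float(er_col[b_idx])
            if w_b == 0.0 or tubu not in tutu_tubu.post_ids:
                continue
            tutu_col = tutu_tubu.column(tubu)
            for t_idx, tutu in enumerate(tutu_tubu.pre_ids):
                w_t = float(tutu_col[t_idx])
                if w_t == 0.0 or tutu not in metu_tutu.post_ids:
                    continue
                metu_w = w_b * w_t * metu_tutu.column(tutu)
                accumulate(indirect, metu_tutu.pre_ids, metu_w)

    covered = sum(1 for v in direct.values() if v > 0)
    return ColumnWeightField(er_id=er_id, direct=direct, indirect=indirect, covered_columns=covered)


def _hex_polygon(center: Tuple[float, float], circumradius: float):
    from shapely.geometry import Polygon

    cx, cy = center
    # pointy-top hexagon matching rows of constant elevation
    angles = np.radians(np.arange(6) * 60.0 + 30.0)
    return Polygon([(cx + circumradius * np.cos(a), cy + circumradius * np.sin(a)) for a in angles])


def _hex_size(eye_map: EyeMap) -> float:
    pts = np.array(list(eye_map.directions.values()), dtype=float)
    if len(pts) < 2:
        return 1.0
    from scipy.spatial import cKDTree

    d, _ = cKDTree(pts).query(pts, k=2)
    spacing = float(np.median(d[:, 1]))
    return spacing / np.sqrt(3.0)


def visual_area(
    fld: ColumnWeightField,
    eye_map: Optional[EyeMap] = None,
    eps: float = 0.0,
) -> Tuple[int, list]:
    """Covered-column count and eye-coordinate outline of a field.

    A column is covered when its direct value exceeds ``eps`` (default:
    any positive weight).  The outline is the boundary of the union of
    hexagonal cells of covered, eye-mapped columns; hexagon size derives
    from nearest-neighbour ommatidial spacing.
    """
    covered = [c for c, v in fld.direct.items() if v > eps]
    count = len(covered)
    if eye_map is None or not covered:
        return count, []
    from shapely.ops import unary_union

    size = _hex_size(eye_map)
    cells = [
        _hex_polygon(eye_map.directions[c], size)
        for c in covered
        if c in eye_map.directions
    ]
    if not cells:
        return count, []
    union = unary_union(cells)
    geoms = getattr(union, "geoms", [union])
    outline = [list(g.exterior.coords) for g in geoms]
    return count, outline


def population_outline(fields: Iterable[ColumnWeightField], eye_map: EyeMap, eps: float = 0.0) -> list:
    """Outline of the union of the visual areas of a set of ER neurons."""
    from shapely.ops import unary_union

    size = _hex_size(eye_map)
    cells = []
    for fld in fields:
        for c, v in fld.direct.items():
            if v > eps and c in eye_map.directions:
                cells.append(_hex_polygon(eye_map.directions[c], size))
    if not cells:
        return []
    union = unary_union(cells)
    geoms = getattr(union, "geoms", [union])
    return [list(g.exterior.coords) for g in geoms]


# ---------------------------------------------------------------------------
# stimulus-response analysis

#: canonical layout of the 38 pre-indexed 18 x 18 degree stimulus squares:
#: staggered rows of 8/7/8/7/8 centres, non-overlapping tiling.
def dot_layout_38() -> np.ndarray:
    rows = []
    for elevation, n in zip((-36.0, -18.0, 0.0, 18.0, 36.0), (8, 7, 8, 7, 8)):
        start = -18.0 * (n - 1) / 2.0
        for i in range(n):
            rows.append((start + 18.0 * i, elevation))
    return np.array(rows)


def _signed_rank_p(diffs: np.ndarray) -> float:
    """Two-sided signed-rank p-value: exact for small untied samples,
    normal approximation otherwise (a tied permutation test is far more
    expensive and changes nothing at these sample sizes)."""
    diffs = np.asarray(diffs, dtype=float)
    nonzero = diffs[diffs != 0.0]
    if nonzero.size == 0:
        return 1.0
    method = "exact" if nonzero.size <= 25 else "approx"
    try:
        _, p = wilcoxon(diffs, method=method)
    except ValueError:
        return 1.0
    return float(p)


@dataclass
class ResponseGrid:
    """Per-trial and mean responses over the 38 stimulus positions."""

    positions: np.ndarray          # (38, 2) azimuth, elevation (deg)
    trials: np.ndarray             # (38, n_trials) response per trial
    extent_deg: float = 18.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.trials = np.asarray(self.trials, dtype=float)
        if self.trials.ndim != 2 or self.trials.shape[0] != self.positions.shape[0]:
            raise ValidationError("trials must be (n_positions, n_trials)")
        if self.trials.shape[1] < 1:
            raise ValidationError("need >= 1 trial per position")

    @property
    def mean(self) -> np.ndarray:
        return self.trials.mean(axis=1)

    def responsive(self, alpha: float = 0.05, empty_control: float = 0.0) -> np.ndarray:
        flags = np.zeros(self.positions.shape[0], dtype=bool)
        for i in range(self.positions.shape[0]):
            diffs = self.trials[i]
            if np.allclose(diffs, 0.0):
                continue
            p = _signed_rank_p(diffs)
            flags[i] = (p <= alpha) and (diffs.mean() > empty_control)
        return flags


def stimulus_response(
    trials: np.ndarray,
    stim_window: Tuple[int, int],
    baseline_window: Tuple[int, int],
    empty_control: float = 0.0,
    alpha: float = 0.05,
) -> Tuple[np.ndarray, float, bool]:
    """Stimulus-minus-baseline response per trial, its mean, and a
    responsiveness flag.

    ``trials`` is (n_trials, n_frames) of dF/F.  Per-trial response = mean
    dF/F over the stimulation window minus mean dF/F over the pre-stimulus
    baseline window.  The flag is False when a paired signed-rank test over
    trials gives p > alpha (exact small-sample test when n is small) or
    when the mean response does not exceed the empty-control response.
    """
    arr = np.asarray(trials, dtype=float)
    if arr.ndim != 2 or arr.shape[0] == 0:
        raise ValidationError("need a (n_trials, n_frames) array with >= 1 trial")
    n_frames = arr.shape[1]
    for lo, hi in (stim_window, baseline_window):
        if not (0 <= lo < hi <= n_frames):
            raise ValidationError(f"window ({lo}, {hi}) outside trace of length {n_frames}")
    stim = arr[:, stim_window[0]:stim_window[1]].mean(axis=1)
    base = arr[:, baseline_window[0]:baseline_window[1]].mean(axis=1)
    responses = stim - base
    mean_resp = float(responses.mean())
    if np.allclose(responses, 0.0):
        return responses, mean_resp, False
    p = _signed_rank_p(responses)
    flag = (p <= alpha) and (mean_resp > empty_control)
    return responses, mean_resp, bool(flag)


def dff_from_raw(raw: np.ndarray, empty_control: np.ndarray) -> np.ndarray:
    """dF/F from raw fluorescence with per-frame empty-ROI subtraction.

    F0 is the mean of the lowest decile of the control-subtracted series;
    F0 <= 0 means the signal is not normalizable and raises.
    """
    raw = np.asarray(raw, dtype=float)
    ctrl = np.asarray(empty_control, dtype=float)
    if raw.size == 0:
        raise ValidationError("empty fluorescence series")
    if ctrl.shape != raw.shape:
        ctrl = np.broadcast_to(ctrl, raw.shape)
    sub = raw - ctrl
    k = max(1, int(np.ceil(sub.size * 0.1)))
    f0 = float(np.sort(sub)[:k].mean())
    if f0 <= 0:
        raise ValidationError(f"baseline F0 = {f0} <= 0; signal not normalizable")
    return (sub - f0) / f0


def rf_ellipse(
    grid: ResponseGrid,
    level: float = 0.2,
    raster_step: float = 1.0,
    empty_control: float = 0.0,
) -> Tuple[EllipseFit, list]:
    """Fit an ellipse to the iso-contour of a response grid.

    Mean responses are interpolated onto a fine azimuth-elevation raster
    (smooth thin-plate-spline surface through the staggered stimulus grid,
    clipped at zero), the iso-contour at ``level`` x max is extracted, and
    the largest closed contour's enclosed region is summarized by its
    second moments (the regionprops convention: a filled ellipse of
    semi-axes a, b has moment eigenvalues a^2/4, b^2/4).  Returns the
    ellipse (axes in degrees, angle from vertical) and the contour
    polygons.  Features narrower than about half the stimulus spacing are
    broadened by the reconstruction and cannot be recovered faithfully.
    """
    from scipy.interpolate import RBFInterpolator
    from skimage import measure

    flags = grid.responsive(empty_control=empty_control)
    if not flags.any():
        raise ValidationError("no responsive stimulus position")
    mean = np.where(flags, grid.mean, 0.0)
    if mean.max() <= 0:
        raise ValidationError("no positive mean response")

    az_min, el_min = grid.positions.min(axis=0) - grid.extent_deg / 2
    az_max, el_max = grid.positions.max(axis=0) + grid.extent_deg / 2
    az = np.arange(az_min, az_max + raster_step, raster_step)
    el = np.arange(el_min, el_max + raster_step, raster_step)
    az_g, el_g = np.meshgrid(az, el)
    surface = RBFInterpolator(grid.positions, mean, kernel="thin_plate_spline")
    raster = surface(np.stack([az_g.ravel(), el_g.ravel()], axis=1)).reshape(az_g.shape)
    raster = np.clip(raster, 0.0, None)

    threshold = level * float(raster.max())
    contours = measure.find_contours(raster, threshold)
    closed = [c for c in contours if np.allclose(c[0], c[-1])]
    if not closed:
        raise ValidationError(
            f"no closed contour at level {level}; try a lower contour level"
        )

    def enclosed_area(c: np.ndarray) -> float:
        x, y = c[:, 1], c[:, 0]
        return 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))

    largest = max(closed, key=enclosed_area)
    mask = measure.grid_points_in_poly(raster.shape, largest)
    rows, cols = np.nonzero(mask)
    if rows.size < 3:
        raise ValidationError("contour encloses too few raster cells to fit an ellipse")
    # raster indices -> degrees
    xs = az[cols]
    ys = el[rows]
    pts = np.stack([xs, ys], axis=1)
    mean_xy = pts.mean(axis=0)
    centred = pts - mean_xy
    cov = centred.T @ centred / pts.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    a = 2.0 * float(np.sqrt(max(evals[0], 1e-12)))
    b = 2.0 * float(np.sqrt(max(evals[1], 1e-12)))
    major = evecs[:, 0]
    angle = float(np.degrees(np.arctan2(major[0], major[1])) % 180.0)
    fit = EllipseFit(centroid=(float(mean_xy[0]), float(mean_xy[1])), semi_major=a, semi_minor=max(b, 1e-9), angle_deg=angle)
    polygons = [
        np.stack([az_min + c[:, 1] * raster_step, el_min + c[:, 0] * raster_step], axis=1).tolist()
        for c in closed
    ]
    return fit, polygons
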