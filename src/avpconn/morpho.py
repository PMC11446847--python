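"""Dendritic-span morphometrics and retinotopy statistics.

The span of an arbor is summarized by a maximum-likelihood 2-D Gaussian fit
in the medulla tangent plane; the reported ellipse is the k-sigma contour
(k = 1 by default).  Angles are measured from the dorsal-ventral (second)
axis of the projection plane and live in [0, 180), so orientation
statistics use axial circular statistics (doubled angles).
"""

from __future__ import annotations

from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import spearmanr

from .errors import GeometryError, ValidationError
from .geometry import nearest_column_ids
from .types import AxialStats, EllipseFit, MedullaColumn


def fit_span_ellipse(
    points,
    weights=None,
    k_sigma: float = 1.0,
    min_points: int = 10,
) -> EllipseFit:
    """Maximum-likelihood 2-D Gaussian fit of a planar synapse cloud.

    Returns the k-sigma contour ellipse: centroid = mean, semi-axes =
    k * sqrt(covariance eigenvalues), angle from the dorsal-ventral
    (second) plane axis in [0, 180).  ``weights`` fits a weighted Gaussian
    instead (weighted mean and covariance).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise GeometryError("expected an (n, 2) array of plane coordinates")
    if weights is None:
        w = np.ones(pts.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValidationError("weights must be non-negative with positive sum")
    support = int(np.count_nonzero(w))
    if support < min_points:
        raise GeometryError(f"need >= {min_points} (weighted) points, got {support}")
    w = w / w.sum()
    mean = w @ pts
    centred = pts - mean
    cov = (centred * w[:, None]).T @ centred
    evals, evecs = np.linalg.eigh(cov)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    scale = max(1.0, float(np.abs(pts).max()) ** 2)
    if evals[1] <= 1e-12 * scale:
        raise GeometryError("rank-deficient (collinear) point cloud")
    a = k_sigma * float(np.sqrt(evals[0]))
    b = k_sigma * float(np.sqrt(evals[1]))
    major = evecs[:, 0]
    angle = float(np.degrees(np.arctan2(major[0], major[1])) % 180.0)
    return EllipseFit(centroid=(float(mean[0]), float(mean[1])), semi_major=a, semi_minor=b, angle_deg=angle)


def rayleigh_axial(angles_deg) -> AxialStats:
    """Rayleigh test of uniformity for axial (orientation) data.

    Angles in [0, 180) are doubled before computing the resultant length
    R-bar; z = n * R-bar^2 and the first-order corrected p-value
    p = exp(-z) * (1 + (2z - z^2) / (4n)) is clamped to (0, 1].  The mean
    angle is half the circular mean of the doubled angles.
    """
    angles = np.asarray(angles_deg, dtype=float)
    n = angles.size
    if n < 5:
        raise ValidationError(f"need n >= 5 angles, got {n}")
    doubled = np.radians(2.0 * angles)
    c, s = np.cos(doubled).sum(), np.sin(doubled).sum()
    rbar = float(np.hypot(c, s) / n)
    z = n * rbar ** 2
    p = float(np.exp(-z) * (1.0 + (2.0 * z - z ** 2) / (4.0 * n)))
    p = float(np.clip(p, np.finfo(float).tiny, 1.0))
    mean_angle = float((np.degrees(np.arctan2(s, c)) / 2.0) % 180.0)
    return AxialStats(n=n, mean_angle_deg=mean_angle, resultant_length=min(rbar, 1.0), z=float(z), p_value=p)


def annulus_density(
    points_nm,
    center=None,
    annulus_area_um2: float = 314.15,
) -> np.ndarray:
    """Synapse density in concentric equal-area annuli around a centre.

    Outer radii are r_k = sqrt(k * A / pi) (A in um^2, converted to nm
    internally); density_k = count_k / A, in synapses per um^2.  Annuli are
    enumerated until all synapses are covered.  Zero synapses give an empty
    profile.
    """
    pts = np.asarray(points_nm, dtype=float)
    if pts.size == 0:
        return np.array([])
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise GeometryError("expected an (n, 2) array of plane coordinates (nm)")
    if center is None:
        center = pts.mean(axis=0)
    radii = np.linalg.norm(pts - np.asarray(center, dtype=float), axis=1)
    area_nm2 = annulus_area_um2 * 1e6  # 1 um^2 = 1e6 nm^2
    # annulus index of each point: outer radius r_k = sqrt(k * A / pi)
    k_of = np.ceil(np.pi * radii ** 2 / area_nm2).astype(int)
    k_of = np.maximum(k_of, 1)
    n_annuli = int(k_of.max())
    counts = np.bincount(k_of, minlength=n_annuli + 1)[1:]
    return counts / annulus_area_um2


def retinotopy(
    medulla_positions: Mapping[str, float],
    target_positions: Mapping[str, float],
) -> Tuple[List[Tuple[str, float, float]], float, float]:
    """Pair per-neuron sensory and target axis positions; Spearman rho.

    ``medulla_positions``: centroid of each neuron's dendritic synapses on
    the anterior-posterior medulla axis; ``target_positions``: centroid of
    its axonal synapses on the target region's dorsal-ventral axis.
    """
    shared = sorted(set(medulla_positions) & set(target_positions))
    if len(shared) < 3:
        raise ValidationError(f"need >= 3 paired neurons, got {len(shared)}")
    med = np.array([medulla_positions[n] for n in shared])
    tgt = np.array([target_positions[n] for n in shared])
    if np.allclose(med, med[0]) or np.allclose(tgt, tgt[0]):
        raise ValidationError("zero variance in positions; correlation undefined")
    rho, p = spearmanr(med, tgt)
    pairs = [(n, float(m), float(t)) for n, m, t in zip(shared, med, tgt)]
    return pairs, float(rho), float(p)


def columns_spanned(
    synapses_by_neuron: Mapping[str, np.ndarray],
    columns: Sequence[MedullaColumn],
) -> Tuple[Dict[str, int], Dict[str, int]]:
    """Distinct columns innervated per neuron, and neurons per column.

    Each dendritic synapse is assigned to the column whose axis is nearest
    (perpendicular distance; ties to the lexicographically smaller
    column_id).
    """
    if not columns:
        raise GeometryError("no columns defined")
    span: Dict[str, int] = {}
    per_column: Dict[str, int] = {c.column_id: 0 for c in columns}
    for neuron, pts in synapses_by_neuron.items():
        pts = np.asarray(pts, dtype=float)
        if pts.size == 0:
            span[neuron] = 0
            continue
        assigned = set(nearest_column_ids(pts, columns))
        span[neuron] = len(assigned)
        for cid in assigned:
            per_column[cid] += 1
    return span, per_column
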