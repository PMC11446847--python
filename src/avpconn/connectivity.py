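"""Synapse filtering, regional weight matrices, upstream traversal,
neurotransmitter averaging and projected synapse-density maps.

A regional weight is the synapse count from one presynaptic neuron onto one
postsynaptic neuron, divided by the postsynaptic neuron's total synapse
count inside the region; postsynaptic neurons with fewer than five total
regional connections are dropped.  Type-level weights aggregate all neurons
of each type before normalizing by the postsynaptic type's regional total.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .config import PipelineConfig
from .errors import AvpError, ValidationError
from .geometry import point_in_region
from .types import BACKGROUND_ID, NTProfile, RegionHull

logger = logging.getLogger(__name__)


@dataclass
class WeightMatrix:
    """Region-restricted normalized connectivity at neuron or type level."""

    region: str
    pre_ids: List[str]
    post_ids: List[str]
    values: np.ndarray                       # (n_pre, n_post) in [0, 1]
    counts: Optional[np.ndarray] = None      # raw synapse counts, same shape
    denominators: Optional[np.ndarray] = None  # per-post regional totals
    level: str = "individual"

    def weight(self, pre: str, post: str) -> float:
        return float(self.values[self.pre_ids.index(pre), self.post_ids.index(post)])

    def column(self, post: str) -> np.ndarray:
        return self.values[:, self.post_ids.index(post)]


def filter_synapses(synapses: pd.DataFrame, config: PipelineConfig = PipelineConfig()) -> pd.DataFrame:
    """Remove low-confidence contacts, autapses and background contacts.

    Keeps rows with cleft_score >= threshold, pre != post, and neither
    partner equal to the background sentinel; surviving row order is
    preserved.  Idempotent.
    """
    keep = (
        (synapses["cleft_score"] >= config.cleft_threshold)
        & (synapses["pre_id"] != synapses["post_id"])
        & (synapses["pre_id"] != BACKGROUND_ID)
        & (synapses["post_id"] != BACKGROUND_ID)
    )
    return synapses.loc[keep]


def _restrict_to_region(synapses: pd.DataFrame, hull: Optional[RegionHull],
                        subtract_hull: Optional[RegionHull] = None) -> pd.DataFrame:
    if hull is None:
        return synapses
    pts = synapses[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
    if len(pts) == 0:
        return synapses
    inside = point_in_region(pts, hull, subtract_hull)
    return synapses.loc[inside]


def _regional_totals(regional: pd.DataFrame, posts: Sequence[str], side: str) -> np.ndarray:
    as_post = regional.groupby("post_id").size()
    totals = np.array([as_post.get(p, 0) for p in posts], dtype=float)
    if side == "both":
        as_pre = regional.groupby("pre_id").size()
        totals = totals + np.array([as_pre.get(p, 0) for p in posts], dtype=float)
    return totals


def neuron_weight_matrix(
    synapses: pd.DataFrame,
    pre_ids: Sequence[str],
    post_ids: Sequence[str],
    hull: Optional[RegionHull] = None,
    config: PipelineConfig = PipelineConfig(),
    subtract_hull: Optional[RegionHull] = None,
    exclude: Iterable[str] = (),
) -> WeightMatrix:
    """Individual-neuron weight matrix over filtered synapses.

    Denominator is each postsynaptic neuron's total regional synapse count
    (input side by default; input+output with
    ``config.denominator_side='both'``).  Posts below
    ``min_regional_connections`` are dropped; ``exclude`` removes listed
    outlier neurons from both margins.
    """
    regional = _restrict_to_region(synapses, hull, subtract_hull)
    exclude = set(exclude)
    pres = [p for p in pre_ids if p not in exclude]
    posts = [p for p in post_ids if p not in exclude]

    totals = _regional_totals(regional, posts, config.denominator_side)
    keep = totals >= config.min_regional_connections
    posts = [p for p, k in zip(posts, keep) if k]
    totals = totals[keep]
    if not posts:
        warnings.warn("no postsynaptic neuron meets the regional-connection minimum", stacklevel=2)

    pre_index = {p: i for i, p in enumerate(pres)}
    post_index = {p: j for j, p in enumerate(posts)}
    counts = np.zeros((len(pres), len(posts)))
    pair_counts = regional.groupby(["pre_id", "post_id"]).size()
    for (pre, post), n in pair_counts.items():
        i, j = pre_index.get(pre), post_index.get(post)
        if i is not None and j is not None:
            counts[i, j] = n
    values = np.divide(counts, totals[None, :], out=np.zeros_like(counts), where=totals[None, :] > 0)
    return WeightMatrix(
        region=hull.name if hull is not None else "",
        pre_ids=pres, post_ids=posts, values=values, counts=counts,
        denominators=totals, level="individual",
    )


def type_weight_matrix(
    synapses: pd.DataFrame,
    type_map: Mapping[str, str],
    hull: Optional[RegionHull] = None,
    config: PipelineConfig = PipelineConfig(),
    subtract_hull: Optional[RegionHull] = None,
    pre_types: Optional[Sequence[str]] = None,
    post_types: Optional[Sequence[str]] = None,
) -> WeightMatrix:
    """Type-level weight matrix: total synapses from all pre-type neurons to
    all post-type neurons, over the post type's total regional synapses."""
    regional = _restrict_to_region(synapses, hull, subtract_hull)
    missing = set(regional["pre_id"]) | set(regional["post_id"])
    missing -= set(type_map)
    if missing:
        raise ValidationError(f"untyped neurons in synapse table: {sorted(missing)[:5]}")

    regional = regional.assign(
        pre_type=regional["pre_id"].map(type_map),
        post_type=regional["post_id"].map(type_map),
    )
    pre_list = list(pre_types) if pre_types is not None else sorted(regional["pre_type"].unique())
    post_list = list(post_types) if post_types is not None else sorted(regional["post_type"].unique())

    totals = regional.groupby("post_type").size()
    denom = np.array([totals.get(t, 0) for t in post_list], dtype=float)
    for t, d in zip(post_list, denom):
        if d == 0:
            warnings.warn(f"type {t!r} has zero regional synapses; weights reported as 0", stacklevel=2)

    counts = np.zeros((len(pre_list), len(post_list)))
    pair = regional.groupby(["pre_type", "post_type"]).size()
    pre_index = {t: i for i, t in enumerate(pre_list)}
    post_index = {t: j for j, t in enumerate(post_list)}
    for (tp, tq), n in pair.items():
        i, j = pre_index.get(tp), post_index.get(tq)
        if i is not None and j is not None:
            counts[i, j] = n
    values = np.divide(counts, denom[None, :], out=np.zeros_like(counts), where=denom[None, :] > 0)
    return WeightMatrix(
        region=hull.name if hull is not None else "",
        pre_ids=pre_list, post_ids=post_list, values=values, counts=counts,
        denominators=denom, level="type",
    )


def order_matrix_rows(matrix: WeightMatrix, tubu_dv_positions: Mapping[str, float]) -> WeightMatrix:
    """Reorder the rows of a (neuron x TuBu) matrix retinotopically.

    Rows group by each neuron's strongest TuBu partner, groups ordered by
    that TuBu's dorsal-ventral position; within a group, descending synapse
    count with that TuBu, ties broken by neuron id.  Neurons without any
    TuBu partner trail in a final group.
    """
    counts = matrix.counts if matrix.counts is not None else matrix.values
    tubu_cols = [j for j, p in enumerate(matrix.post_ids) if p in tubu_dv_positions]
    if not tubu_cols:
        raise ValidationError("matrix has no TuBu columns present in the position table")
    keys = []
    for i, pre in enumerate(matrix.pre_ids):
        row = counts[i, tubu_cols]
        if row.max() <= 0:
            warnings.warn(f"neuron {pre!r} has no TuBu partner; placed in trailing group", stacklevel=2)
            keys.append((np.inf, "", 0.0, pre))
            continue
        best = tubu_cols[int(np.argmax(row))]
        tubu = matrix.post_ids[best]
        keys.append((tubu_dv_positions[tubu], tubu, -float(counts[i, best]), pre))
    order = sorted(range(len(keys)), key=lambda i: keys[i])
    return WeightMatrix(
        region=matrix.region,
        pre_ids=[matrix.pre_ids[i] for i in order],
        post_ids=list(matrix.post_ids),
        values=matrix.values[order],
        counts=None if matrix.counts is None else matrix.counts[order],
        denominators=matrix.denominators,
        level=matrix.level,
    )


def upstream_traversal(
    seed_ids: Sequence[str],
    synapses: pd.DataFrame,
    optic_lobe_ids: Set[str],
    central_complex_ids: Set[str] = frozenset(),
    max_hops: int = 2,
    min_syn: int = 5,
    render_fraction: float = 0.01,
) -> pd.DataFrame:
    """Breadth-first upstream expansion from seed neurons.

    An edge exists when the partner supplies at least ``min_syn`` synapses
    to its downstream neuron.  Central-complex-intrinsic neurons are not
    expanded.  For each visited neuron the summed relative weight of
    optic-lobe-resident inputs is reported, and partners supplying at least
    ``render_fraction`` of their downstream neuron's total non-central-
    complex synaptic weight carry a render flag.
    """
    known = set(synapses["pre_id"]) | set(synapses["post_id"])
    for s in seed_ids:
        if s not in known:
            raise ValidationError(f"unknown seed id {s!r}")

    pair_counts = synapses.groupby(["pre_id", "post_id"]).size()
    graph = nx.DiGraph()
    for (pre, post), n in pair_counts.items():
        if n >= min_syn:
            graph.add_edge(pre, post, count=int(n))

    in_counts = synapses.groupby("post_id").size().to_dict()
    non_cc_in = (
        synapses[~synapses["pre_id"].isin(central_complex_ids)].groupby("post_id").size().to_dict()
    )
    ol_in = (
        synapses[synapses["pre_id"].isin(optic_lobe_ids)].groupby("post_id").size().to_dict()
    )

    hop_of = {s: 0 for s in seed_ids}
    frontier = list(seed_ids)
    for hop in range(1, max_hops + 1):
        nxt = []
        for node in frontier:
            if node not in graph:
                continue
            for pred in graph.predecessors(node):
                if pred in hop_of:
                    continue
                hop_of[pred] = hop
                # CC-intrinsic partners are recorded but never expanded
                if pred not in central_complex_ids:
                    nxt.append(pred)
        frontier = nxt

    rows = []
    for node, hop in sorted(hop_of.items(), key=lambda kv: (kv[1], kv[0])):
        total = in_counts.get(node, 0)
        ol_weight = (ol_in.get(node, 0) / total) if total else 0.0
        render = False
        for succ in graph.successors(node) if node in graph else ():
            if succ in hop_of and hop_of[succ] == hop - 1:
                denom = non_cc_in.get(succ, 0)
                if denom and graph[node][succ]["count"] / denom >= render_fraction:
                    render = True
                    break
        rows.append({
            "neuron_id": node, "hop": hop,
            "optic_lobe_weight": ol_weight,
            "is_optic_lobe": node in optic_lobe_ids,
            "render": render,
        })
    return pd.DataFrame(rows)


def mean_nt_profile(neuron_id: str, site_probabilities, classes: tuple = ()) -> NTProfile:
    """Arithmetic mean of per-presynaptic-site transmitter probabilities.

    Renormalizes when the inputs deviate from the simplex by more than 1e-6.
    """
    probs = np.asarray(site_probabilities, dtype=float)
    if probs.ndim != 2 or probs.shape[0] == 0:
        raise ValidationError(f"neuron {neuron_id!r}: no presynaptic sites with probabilities")
    mean = probs.mean(axis=0)
    total = mean.sum()
    # renormalize; also washes out rounding so the simplex invariant holds
    mean = mean / total
    return NTProfile(neuron_id=neuron_id, probabilities=mean, classes=classes)


# ---------------------------------------------------------------------------
# density maps

#: orthonormal projection frames (u, v, view axis); x is anterior-posterior.
#: each named view is rotated 30 degrees about the anterior-posterior axis.
def _rot_x(deg: float) -> np.ndarray:
    a = np.radians(deg)
    return np.array([
        [1, 0, 0],
        [0, np.cos(a), -np.sin(a)],
        [0, np.sin(a), np.cos(a)],
    ])


DENSITY_VIEW_PRESETS = {
    "dorsal": _rot_x(30.0) @ np.array([[1.0, 0, 0], [0, 0, 1.0], [0, -1.0, 0]]).T,
    "anterior": _rot_x(30.0) @ np.array([[0, 1.0, 0], [0, 0, 1.0], [1.0, 0, 0]]).T,
    "lateral": _rot_x(30.0) @ np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]]).T,
}


def synapse_density_map(
    synapses: pd.DataFrame,
    view: str | np.ndarray = "anterior",
    hull: Optional[RegionHull] = None,
    config: PipelineConfig = PipelineConfig(),
    sigma_bins: Optional[float] = None,
):
    """Project synapses onto a view plane and return a smoothed density grid.

    Counts are binned on a ``density_bin_nm`` square grid over the plane,
    then Gaussian-smoothed (sigma ``density_sigma_bins`` bins, truncated at
    4 sigma with a renormalized kernel; the grid is padded by 4 sigma bins
    so smoothing conserves total mass within 0.1 %).  Returns
    (grid, (u_edges, v_edges)).
    """
    frame = DENSITY_VIEW_PRESETS[view] if isinstance(view, str) else np.asarray(view, dtype=float)
    regional = _restrict_to_region(synapses, hull)
    sigma = config.density_sigma_bins if sigma_bins is None else sigma_bins
    pad = int(np.ceil(4 * sigma)) + 1
    bin_nm = config.density_bin_nm

    if len(regional) == 0:
        warnings.warn("empty synapse set; returning all-zero density grid", stacklevel=2)
        grid = np.zeros((2 * pad, 2 * pad))
        edges = (np.arange(2 * pad + 1) * bin_nm, np.arange(2 * pad + 1) * bin_nm)
        return grid, edges

    pts = regional[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
    uv = pts @ frame[:, :2]  # columns u, v of the frame
    u_edges = np.arange(np.floor(uv[:, 0].min() / bin_nm) - pad,
                        np.ceil(uv[:, 0].max() / bin_nm) + pad + 1) * bin_nm
    v_edges = np.arange(np.floor(uv[:, 1].min() / bin_nm) - pad,
                        np.ceil(uv[:, 1].max() / bin_nm) + pad + 1) * bin_nm
    grid, _, _ = np.histogram2d(uv[:, 0], uv[:, 1], bins=(u_edges, v_edges))
    smoothed = gaussian_filter(grid, sigma=sigma, mode="constant", truncate=4.0)
    return smoothed, (u_edges, v_edges)
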