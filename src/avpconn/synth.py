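"""Synthetic anterior-visual-pathway connectome with planted ground truth.

The generator emulates the structure the downstream analyses rely on,
without anatomical claims: a hexagonal lattice of medulla columns with one
columnar anchor neuron per column; ten MeTu-like subtypes whose dendritic
synapse clouds follow planted 2-D Gaussian spans and whose input partners
are drawn from subtype-specific Dirichlet type fingerprints; retinotopic
MeTu->TuBu convergence (anterior-posterior medulla position mapping
monotonically to dorsal-ventral tubercle position); TuBu->ER divergence;
two bilateral TuTu neurons; and configurable noise (positional jitter,
low-cleft contacts, background contacts and autapses).

Two channel geometries matter downstream: the MeTu1-like channel has
vertically elongated spans and azimuth-only retinotopy, so its ER fields
are vertical stripes; the MeTu3c-like channel tiles the field in two
dimensions, so its ER fields are compact patches.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import SynthConfig
from .errors import ConfigError
from .fields import ResponseGrid, dot_layout_38
from .geometry import SQRT3, axial_to_xy, hex_lattice
from .types import BACKGROUND_ID, EllipseFit, RegionHull

#: medulla input neuron types used for subtype fingerprints
INPUT_TYPES = (
    "Dm2", "Sm16", "Sm15", "Sm07", "Mi15", "DmDRA1", "R7", "Sm17",
    "Sm23", "MeMeDRA", "Sm12", "Dm8", "Mi4", "L3", "Sm01", "Mi9",
)

#: (subtype, TuBu type, ER type, geometry kind, lobula synapses?)
CHANNELS = (
    ("MeTu1", "TuBu08", "ER4d", "vertical", False),
    ("MeTu2a", "TuBu01", "ER4m", "generic", False),
    ("MeTu2b", "TuBu06", "ER5", "generic", False),
    ("MeTu3a", "TuBu07", "ER3w_ab", "generic", False),
    ("MeTu3b", "TuBu07b", "ER3w_ab", "generic", False),
    ("MeTu3c", "TuBu09", "ER2_ad", "tiling", False),
    ("MeTu4a", "TuBu03", "ER3a_ad", "generic", True),
    ("MeTu4b", "TuBu02", "ER3m", "generic", True),
    ("MeTu4c", "TuBu05", "ER3d_a", "generic", True),
    ("MeTu4d", "TuBu05b", "ER3d_b", "generic", False),
)

#: region box origins (nm); regions are disjoint axis-aligned boxes
AOTU_OFFSET = np.array([300000.0, 0.0, 0.0])
BU_OFFSET = np.array([600000.0, 0.0, 0.0])
LO_OFFSET = np.array([-300000.0, 0.0, 0.0])


@dataclass
class GroundTruth:
    """Planted parameters of a generated connectome."""

    subtypes: Dict[str, str]                  # neuron_id -> planted subtype
    span_ellipses: Dict[str, EllipseFit]      # MeTu id -> planted 1-sigma span
    retinotopy_slope: float
    retinotopy_intercept: float
    retinotopy_pairs: Dict[str, Tuple[float, float]]  # MeTu id -> (ap, dv)
    er_columns: Dict[str, List[str]]          # ER id -> planted column set
    er_channel: Dict[str, str]                # ER id -> geometry kind
    photoreceptor_counts: Dict[str, int]      # column_id -> count (7/8 on equator)
    column_coords: Dict[str, Tuple[int, int]]  # column_id -> (q, r)
    metu_tubu: Dict[str, str]                 # MeTu id -> wired TuBu id
    seed: int = 0

    def to_json(self, path) -> None:
        payload = {
            "subtypes": self.subtypes,
            "span_ellipses": {
                k: {"centroid": list(v.centroid), "semi_major": v.semi_major,
                    "semi_minor": v.semi_minor, "angle_deg": v.angle_deg}
                for k, v in self.span_ellipses.items()
            },
            "retinotopy_slope": self.retinotopy_slope,
            "retinotopy_intercept": self.retinotopy_intercept,
            "retinotopy_pairs": {k: list(v) for k, v in self.retinotopy_pairs.items()},
            "er_columns": self.er_columns,
            "er_channel": self.er_channel,
            "photoreceptor_counts": self.photoreceptor_counts,
            "column_coords": {k: list(v) for k, v in self.column_coords.items()},
            "metu_tubu": self.metu_tubu,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload))


def _box_hull(name: str, lo: np.ndarray, hi: np.ndarray, subtract: Optional[str] = None) -> RegionHull:
    corners = np.array([[x, y, z] for x in (lo[0], hi[0]) for y in (lo[1], hi[1]) for z in (lo[2], hi[2])])
    return RegionHull(name=name, vertices=corners, subtract=subtract)


def _fingerprints(rng: np.random.Generator, concentration: float) -> Dict[str, np.ndarray]:
    """Dirichlet type-weight fingerprint per subtype, with the structural
    constraints the threshold rules rely on (Mi15 absent for MeTu3a,
    prominent for MeTu3b/c; Dm2 dominant for MeTu1)."""
    mi15 = INPUT_TYPES.index("Mi15")
    dm2 = INPUT_TYPES.index("Dm2")
    fps = {}
    for subtype, *_ in CHANNELS:
        w = rng.dirichlet(np.full(len(INPUT_TYPES), concentration))
        if subtype == "MeTu1":
            w[dm2] = max(w[dm2], 0.45)
        if subtype == "MeTu3a":
            w[mi15] = 0.0
        if subtype in ("MeTu3b", "MeTu3c"):
            w[mi15] = max(w[mi15], 0.25)
        fps[subtype] = w / w.sum()
    return fps


def _span_cov(sigma: float, ratio: float, angle_deg: float) -> np.ndarray:
    """Covariance of a planted span: minor sigma = ``sigma``, major sigma =
    ratio * sigma, major axis at ``angle_deg`` from the vertical (y) axis."""
    a = np.radians(angle_deg)
    major = np.array([np.sin(a), np.cos(a)])
    minor = np.array([np.cos(a), -np.sin(a)])
    return (ratio * sigma) ** 2 * np.outer(major, major) + sigma ** 2 * np.outer(minor, minor)


def expected_contact_count(cfg: SynthConfig) -> int:
    """Total contacts the generator plants: per-neuron configured counts
    plus injected background contacts and autapses (the conservation
    bookkeeping checked by the tests)."""
    n_cols = len(hex_lattice(cfg.columns_per_side))
    n = cfg.neurons_per_subtype
    total = n_cols * cfg.anchor_synapses
    per_metu = cfg.dendritic_synapses + cfg.presynaptic_sites + cfg.axonal_synapses + cfg.tutu_synapses
    total += 10 * n * per_metu
    lobula_channels = sum(1 for *_x, lob in CHANNELS if lob)
    total += lobula_channels * n * cfg.lobula_synapses
    n_tubu_total = 0
    for _subtype, *_rest in CHANNELS:
        n_tubu_total += max(1, n // cfg.convergence)
    total += n_tubu_total * cfg.divergence * cfg.tubu_er_synapses  # TuBu -> ER
    total += 2 * n_tubu_total * cfg.tutu_synapses                  # TuTu -> TuBu
    total += cfg.n_background_contacts + cfg.n_autapses
    return total


def generate_connectome(cfg: SynthConfig = SynthConfig()):
    """Generate (synapse table, annotations, region hulls, GroundTruth).

    Identical configs (including seed) give identical outputs.
    """
    rng = np.random.default_rng(cfg.seed)
    pitch = cfg.lattice_pitch_nm
    depth = cfg.column_depth_nm
    cells = hex_lattice(cfg.columns_per_side)
    col_ids = [f"c{q:+03d}{r:+03d}" for q, r in cells]
    centers = {cid: np.array(axial_to_xy(q, r, pitch)) for cid, (q, r) in zip(col_ids, cells)}
    centers_arr = np.stack([centers[c] for c in col_ids])

    rows: List[tuple] = []  # (pre, post, x, y, z, cleft placeholder)
    ann: List[tuple] = []   # (neuron_id, cell_class, hemisphere)

    def add_contacts(pre: str, post: str, positions: np.ndarray) -> None:
        for p in positions:
            rows.append((pre, post, float(p[0]), float(p[1]), float(p[2])))

    def nearest_cells(xy: np.ndarray) -> List[str]:
        d = np.linalg.norm(xy[:, None, :] - centers_arr[None, :, :], axis=2)
        return [col_ids[i] for i in np.argmin(d, axis=1)]

    # --- columnar anchors (Mi1-like), one per column, with L1-like inputs
    photoreceptors: Dict[str, int] = {}
    for cid, (q, r) in zip(col_ids, cells):
        anchor = f"Mi1_{cid}"
        partner = f"L1_{cid}"
        ann.append((anchor, "Mi1", "R"))
        ann.append((partner, "L1", "R"))
        z = rng.uniform(0.0, depth, cfg.anchor_synapses)
        xy = centers[cid] + rng.normal(0.0, cfg.positional_noise_nm, (cfg.anchor_synapses, 2))
        add_contacts(partner, anchor, np.column_stack([xy, z]))
        photoreceptors[cid] = int(rng.integers(7, 9)) if r == 0 else 6

    # --- medulla input neurons per type
    input_neurons = {t: [f"{t}_{i:02d}" for i in range(10)] for t in INPUT_TYPES}
    for t, ids in input_neurons.items():
        for nid in ids:
            ann.append((nid, t, "R"))

    fingerprints = _fingerprints(rng, cfg.fingerprint_concentration)
    x_extent = pitch * (cfg.columns_per_side - 1) * 1.5

    # planted retinotopic map: medulla anterior-posterior (x) -> AOTU
    # dorsal-ventral (y), strictly monotone increasing
    slope, intercept = 0.15, 0.0

    subtypes: Dict[str, str] = {}
    span_ellipses: Dict[str, EllipseFit] = {}
    retinotopy_pairs: Dict[str, Tuple[float, float]] = {}
    metu_tubu_map: Dict[str, str] = {}
    er_columns: Dict[str, List[str]] = {}
    er_channel: Dict[str, str] = {}
    metu_pre_cols: Dict[str, List[str]] = {}  # MeTu -> columns of its pre sites

    n = cfg.neurons_per_subtype
    for subtype, tubu_type, er_type, kind, has_lobula in CHANNELS:
        metu_ids = [f"{subtype}_R_{i:03d}" for i in range(n)]
        for mid in metu_ids:
            ann.append((mid, "MeTu", "R"))
            subtypes[mid] = subtype

        # dendritic centres over the lattice (MeTu4d-like stays ventral);
        # distinct home columns keep the channel's coverage even
        centre_cells = rng.choice(len(cells), size=n, replace=n > len(cells))
        centres_xy = centers_arr[centre_cells].copy()
        if subtype == "MeTu4d":
            centres_xy[:, 1] = -np.abs(centres_xy[:, 1])

        if kind == "vertical":
            ratios = np.full(n, cfg.span_ratio_vertical)
            angles = rng.normal(0.0, 5.0, n) % 180.0
        elif kind == "tiling":
            ratios = np.full(n, cfg.span_ratio_tiling)
            angles = rng.uniform(0.0, 180.0, n)
        else:
            ratios = np.full(n, 1.5)
            angles = rng.uniform(0.0, 180.0, n)

        fp = fingerprints[subtype]

        # TuBu layout for this channel
        n_tubu = max(1, n // cfg.convergence)
        tubu_ids = [f"{tubu_type}_R_{k:02d}" for k in range(n_tubu)]
        # a trailing 'b' marks a second TuBu population of the same named type
        tubu_class = tubu_type[:-1] if len(tubu_type) == 7 and tubu_type.endswith("b") else tubu_type
        for tid in tubu_ids:
            ann.append((tid, tubu_class, "R"))

        aps = centres_xy[:, 0]
        x_lo, x_hi = centers_arr[:, 0].min(), centers_arr[:, 0].max()
        if kind == "tiling":
            # compact 2-D patches: k-means on the dendritic centres, so each
            # TuBu integrates a near-isotropic neighbourhood of the field
            from sklearn.cluster import KMeans

            km = KMeans(n_clusters=n_tubu, random_state=cfg.seed, n_init=10)
            assignment = km.fit_predict(centres_xy)
        else:
            # azimuth-only bins of equal spatial width
            assignment = np.clip(((aps - x_lo) / (x_hi - x_lo) * n_tubu).astype(int), 0, n_tubu - 1)

        for i, mid in enumerate(metu_ids):
            cov = _span_cov(cfg.span_sigma_nm, ratios[i], angles[i])
            span_ellipses[mid] = EllipseFit(
                centroid=(float(centres_xy[i, 0]), float(centres_xy[i, 1])),
                semi_major=ratios[i] * cfg.span_sigma_nm,
                semi_minor=cfg.span_sigma_nm,
                angle_deg=float(angles[i]),
            )
            # dendritic (postsynaptic) sites: input type drawn per fingerprint
            nd = cfg.dendritic_synapses
            xy = rng.multivariate_normal(centres_xy[i], cov, nd)
            z = depth * 0.55 + rng.normal(0.0, depth * 0.03, nd)
            type_draw = rng.choice(len(INPUT_TYPES), size=nd, p=fp)
            for k in range(nd):
                t = INPUT_TYPES[type_draw[k]]
                pre = input_neurons[t][rng.integers(0, len(input_neurons[t]))]
                rows.append((pre, mid, float(xy[k, 0]), float(xy[k, 1]), float(z[k])))

            # presynaptic medulla sites onto the nearest column anchors
            npre = cfg.presynaptic_sites
            xy_pre = rng.multivariate_normal(centres_xy[i], cov, npre)
            z_pre = depth * 0.55 + rng.normal(0.0, depth * 0.03, npre)
            near = nearest_cells(xy_pre)
            metu_pre_cols[mid] = near
            for k in range(npre):
                rows.append((mid, f"Mi1_{near[k]}", float(xy_pre[k, 0]), float(xy_pre[k, 1]), float(z_pre[k])))

            # axonal synapses in the tubercle onto the wired TuBu
            ap = float(np.mean(xy[:, 0]))
            dv = slope * ap + intercept + rng.normal(0.0, 200.0)
            retinotopy_pairs[mid] = (ap, dv)
            tid = tubu_ids[assignment[i]]
            metu_tubu_map[mid] = tid
            pos = AOTU_OFFSET + np.column_stack([
                rng.normal(0.0, 1000.0, cfg.axonal_synapses),
                dv + rng.normal(0.0, 300.0, cfg.axonal_synapses),
                rng.normal(0.0, 1000.0, cfg.axonal_synapses),
            ])
            add_contacts(mid, tid, pos)

            # bilateral TuTu input from every MeTu
            tutu = "TuTuB_a_R" if i % 2 == 0 else "TuTuB_b_R"
            pos_t = AOTU_OFFSET + rng.normal(0.0, 2000.0, (cfg.tutu_synapses, 3))
            add_contacts(mid, tutu, pos_t)

            if has_lobula:
                pos_l = LO_OFFSET + rng.normal(0.0, 3000.0, (cfg.lobula_synapses, 3))
                add_contacts(mid, "LT_generic_R", pos_l)

        # TuBu -> ER divergence
        for k, tid in enumerate(tubu_ids):
            members = [metu_ids[i] for i in range(n) if assignment[i] == k]
            planted = sorted({c for m in members for c in metu_pre_cols[m]})
            for d in range(cfg.divergence):
                eid = f"{er_type}_R_{k * cfg.divergence + d:02d}"
                if eid not in er_channel:
                    ann.append((eid, er_type, "R"))
                    er_channel[eid] = kind
                    er_columns[eid] = planted
                pos = BU_OFFSET + rng.normal(0.0, 2000.0, (cfg.tubu_er_synapses, 3))
                add_contacts(tid, eid, pos)

    # TuTu -> TuBu feedback
    all_tubu = sorted({t for t in metu_tubu_map.values()})
    for tutu in ("TuTuB_a_R", "TuTuB_b_R"):
        ann.append((tutu, "TuTuB_a" if tutu.endswith("a_R") else "TuTuB_b", "R"))
        for tid in all_tubu:
            pos = AOTU_OFFSET + rng.normal(0.0, 2000.0, (cfg.tutu_synapses, 3))
            add_contacts(tutu, tid, pos)
    ann.append(("LT_generic_R", "other", "R"))

    # --- assemble table, assign cleft scores, inject noise contacts
    df = pd.DataFrame(rows, columns=["pre_id", "post_id", "x_nm", "y_nm", "z_nm"])
    n_contacts = len(df)
    cleft = rng.integers(cfg.cleft_low, cfg.cleft_high + 1, n_contacts)
    n_low = int(round(cfg.low_cleft_fraction * n_contacts))
    if n_low:
        low_idx = rng.choice(n_contacts, size=n_low, replace=False)
        cleft[low_idx] = rng.integers(0, 50, n_low)
    df["cleft_score"] = cleft

    metu_all = sorted(subtypes)
    noise_rows = []
    for _ in range(cfg.n_background_contacts):
        nid = metu_all[rng.integers(0, len(metu_all))]
        pos = rng.uniform(-x_extent, x_extent, 3)
        noise_rows.append((nid, BACKGROUND_ID, pos[0], pos[1], pos[2], int(rng.integers(50, 200))))
    for _ in range(cfg.n_autapses):
        nid = metu_all[rng.integers(0, len(metu_all))]
        pos = rng.uniform(-x_extent, x_extent, 3)
        noise_rows.append((nid, nid, pos[0], pos[1], pos[2], int(rng.integers(50, 200))))
    if noise_rows:
        df = pd.concat(
            [df, pd.DataFrame(noise_rows, columns=list(df.columns))], ignore_index=True
        )

    annotations = pd.DataFrame(ann, columns=["neuron_id", "cell_class", "hemisphere"])
    annotations["subtype"] = ""
    annotations = annotations.drop_duplicates(subset="neuron_id", keep="first").reset_index(drop=True)

    # prune planted ER column sets to contacts that survive the cleft filter
    surviving = df[(df["cleft_score"] >= 50) & (df["pre_id"] != df["post_id"])]
    pre_site_cols: Dict[str, set] = {}
    med_pre = surviving[surviving["post_id"].str.startswith("Mi1_") & surviving["pre_id"].isin(subtypes)]
    for pre, post in zip(med_pre["pre_id"], med_pre["post_id"]):
        pre_site_cols.setdefault(pre, set()).add(post.removeprefix("Mi1_"))
    tubu_members: Dict[str, List[str]] = {}
    for mid, tid in metu_tubu_map.items():
        tubu_members.setdefault(tid, []).append(mid)
    # recompute ER planted sets from surviving pre sites
    tubu_er_pairs = surviving[surviving["post_id"].isin(er_columns)]
    for eid in er_columns:
        tubus = set(tubu_er_pairs.loc[tubu_er_pairs["post_id"] == eid, "pre_id"])
        cols = set()
        for tid in tubus:
            for m in tubu_members.get(tid, ()):  # every wired MeTu contributes
                cols |= pre_site_cols.get(m, set())
        er_columns[eid] = sorted(cols)

    # --- region hulls (disjoint boxes)
    margin = 6.0 * cfg.span_sigma_nm
    me_lo = centers_arr.min(axis=0) - margin
    me_hi = centers_arr.max(axis=0) + margin
    hulls = {
        "ME_R": _box_hull("ME_R", np.array([me_lo[0], me_lo[1], -0.2 * depth]),
                          np.array([me_hi[0], me_hi[1], 1.2 * depth])),
        "AOTU_R": _box_hull("AOTU_R", AOTU_OFFSET - 60000.0, AOTU_OFFSET + 60000.0),
        "BU_R": _box_hull("BU_R", BU_OFFSET - 30000.0, BU_OFFSET + 30000.0),
        "LO_R": _box_hull("LO_R", LO_OFFSET - 30000.0, LO_OFFSET + 30000.0),
    }

    gt = GroundTruth(
        subtypes=subtypes,
        span_ellipses=span_ellipses,
        retinotopy_slope=slope,
        retinotopy_intercept=intercept,
        retinotopy_pairs=retinotopy_pairs,
        er_columns=er_columns,
        er_channel=er_channel,
        photoreceptor_counts=photoreceptors,
        column_coords=dict(zip(col_ids, cells)),
        metu_tubu=metu_tubu_map,
        seed=cfg.seed,
    )
    return df, annotations, hulls, gt


def generate_response_grid(
    planted: EllipseFit,
    n_trials: int,
    noise_sd: float,
    seed: int,
    positions: Optional[np.ndarray] = None,
) -> ResponseGrid:
    """Per-trial responses over the 38 stimulus positions for a planted
    Gaussian receptive-field profile (amplitude 1 at the centre)."""
    if n_trials < 1:
        raise ConfigError("n_trials must be >= 1")
    if noise_sd < 0:
        raise ConfigError("noise sd must be >= 0")
    pos = dot_layout_38() if positions is None else np.asarray(positions, dtype=float)
    a = np.radians(planted.angle_deg)
    major = np.array([np.sin(a), np.cos(a)])
    minor = np.array([np.cos(a), -np.sin(a)])
    cov = (planted.semi_major ** 2 * np.outer(major, major)
           + planted.semi_minor ** 2 * np.outer(minor, minor))
    inv = np.linalg.inv(cov)
    d = pos - np.asarray(planted.centroid, dtype=float)
    profile = np.exp(-0.5 * np.einsum("ni,ij,nj->n", d, inv, d))
    rng = np.random.default_rng(seed)
    trials = profile[:, None] + rng.normal(0.0, noise_sd, (pos.shape[0], n_trials)) if noise_sd > 0 \
        else np.tile(profile[:, None], (1, n_trials))
    return ResponseGrid(positions=pos, trials=trials)
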