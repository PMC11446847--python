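"""End-to-end assembly of the standard analysis on a connectome.

Wires the individual stages together for the common case: filter synapses,
fit medulla columns from the columnar anchor neurons, compute MeTu column
occupancies, build the regional weight matrices, classify MeTu subtypes
from connectivity fingerprints, and back-trace ER receptive fields.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .classify import build_feature_vectors, cluster_subtypes
from .config import PipelineConfig
from .connectivity import WeightMatrix, filter_synapses, neuron_weight_matrix
from .fields import backtrace_field, column_occupancy
from .geometry import fit_column_axis
from .morpho import fit_span_ellipse, retinotopy
from .types import ColumnWeightField, EllipseFit, MedullaColumn, Occupancy, RegionHull


@dataclass
class AnalysisResult:
    columns: List[MedullaColumn]
    occupancies: Dict[str, Occupancy]
    metu_tubu: WeightMatrix        # MeTu -> TuBu weights in the tubercle
    tubu_er: WeightMatrix          # TuBu -> ER weights in the bulb
    metu_input: WeightMatrix       # medulla inputs -> MeTu weights
    features: pd.DataFrame
    labels: pd.Series
    fields: Dict[str, ColumnWeightField]
    field_ellipses: Dict[str, EllipseFit]
    retinotopy_rho: float
    synapses: pd.DataFrame         # filtered table


def fit_columns_from_anchors(
    synapses: pd.DataFrame,
    anchor_prefix: str = "Mi1_",
    proximal_reference=None,
) -> List[MedullaColumn]:
    """One column per anchor neuron, fitted from its synapse cloud."""
    onto_anchor = synapses[synapses["post_id"].str.startswith(anchor_prefix)]
    pts_all = onto_anchor[["x_nm", "y_nm", "z_nm"]]
    if proximal_reference is None:
        # proximal = deep end of the shared distal-proximal axis
        proximal_reference = np.array([
            pts_all["x_nm"].mean(), pts_all["y_nm"].mean(), pts_all["z_nm"].max() * 10,
        ])
    columns = []
    for aid, g in onto_anchor.groupby("post_id"):
        cid = aid[len(anchor_prefix):]
        columns.append(
            fit_column_axis(g[["x_nm", "y_nm", "z_nm"]].to_numpy(), proximal_reference, column_id=cid)
        )
    return columns


def analyze(
    synapses: pd.DataFrame,
    annotations: pd.DataFrame,
    hulls: Mapping[str, RegionHull],
    config: PipelineConfig = PipelineConfig(),
    n_subtypes: int = 10,
    metu_prefix: str = "MeTu",
    tubu_prefix: str = "TuBu",
    er_prefix: str = "ER",
    tutu_prefix: str = "TuTu",
    anchor_class: str = "Mi1",
    anchor_input_class: str = "L1",
) -> AnalysisResult:
    """Run the standard pipeline on a (synthetic or real) connectome."""
    fs = filter_synapses(synapses, config)
    type_map = dict(zip(annotations["neuron_id"], annotations["cell_class"]))

    metu_ids = sorted(annotations.loc[annotations["cell_class"].str.startswith(metu_prefix), "neuron_id"])
    tubu_ids = sorted(annotations.loc[annotations["cell_class"].str.startswith(tubu_prefix), "neuron_id"])
    er_ids = sorted(annotations.loc[annotations["cell_class"].str.startswith(er_prefix), "neuron_id"])
    tutu_ids = sorted(annotations.loc[annotations["cell_class"].str.startswith(tutu_prefix), "neuron_id"])
    anchor_ids = set(annotations.loc[annotations["cell_class"] == anchor_class, "neuron_id"])
    helper_ids = set(annotations.loc[annotations["cell_class"] == anchor_input_class, "neuron_id"])
    input_ids = sorted(
        set(annotations["neuron_id"])
        - set(metu_ids) - set(tubu_ids) - set(er_ids) - set(tutu_ids)
        - anchor_ids - helper_ids
        - set(annotations.loc[annotations["cell_class"] == "other", "neuron_id"])
    )

    # medulla columns from the anchor neurons' own (helper-supplied) inputs
    anchor_syn = fs[fs["pre_id"].isin(helper_ids)]
    columns = fit_columns_from_anchors(anchor_syn)

    # MeTu occupancy from presynaptic medulla sites
    med_pre = fs[fs["pre_id"].isin(metu_ids) & fs["post_id"].isin(anchor_ids)]
    occupancies: Dict[str, Occupancy] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for mid, g in med_pre.groupby("pre_id"):
            occupancies[mid] = column_occupancy(
                g[["x_nm", "y_nm", "z_nm"]].to_numpy(), columns, metu_id=mid
            )

    metu_tubu = neuron_weight_matrix(fs, metu_ids, tubu_ids, hulls["AOTU_R"], config)
    tubu_er = neuron_weight_matrix(fs, tubu_ids, er_ids, hulls["BU_R"], config)
    metu_input = neuron_weight_matrix(fs, input_ids, metu_ids, hulls["ME_R"], config)
    metu_out = neuron_weight_matrix(
        fs, metu_ids, tubu_ids + tutu_ids, hulls["AOTU_R"], config
    )

    # coarse grouping by dominant tubercle partner type selects the top
    # input types per group before the final clustering
    groups = {}
    for i, m in enumerate(metu_out.pre_ids):
        j = int(np.argmax(metu_out.counts[i]))
        groups[m] = type_map.get(metu_out.post_ids[j], "unknown")
    features = build_feature_vectors(metu_input, metu_out, type_map, metu_ids, groups=groups)
    labels, _ = cluster_subtypes(features, mode="dendrogram", n_clusters=n_subtypes)

    # ER receptive fields (direct pathway) and their weighted span ellipses
    col_xy = {c.column_id: (float(c.anchor[0]), float(c.anchor[1])) for c in columns}
    fields: Dict[str, ColumnWeightField] = {}
    field_ellipses: Dict[str, EllipseFit] = {}
    for eid in er_ids:
        fld = backtrace_field(eid, tubu_er, metu_tubu, occupancies, pathway="direct")
        fields[eid] = fld
        if len(fld.direct) >= 10:
            pts = np.array([col_xy[c] for c in fld.direct])
            w = np.array(list(fld.direct.values()))
            field_ellipses[eid] = fit_span_ellipse(pts, weights=w)

    # anterior-posterior medulla position vs dorsal-ventral tubercle position
    dend = fs[fs["post_id"].isin(metu_ids)].groupby("post_id")["x_nm"].mean().to_dict()
    axon = (
        fs[fs["pre_id"].isin(metu_ids) & fs["post_id"].isin(tubu_ids)]
        .groupby("pre_id")["y_nm"].mean().to_dict()
    )
    _, rho, _ = retinotopy(dend, axon)

    return AnalysisResult(
        columns=columns,
        occupancies=occupancies,
        metu_tubu=metu_tubu,
        tubu_er=tubu_er,
        metu_input=metu_input,
        features=features,
        labels=labels,
        fields=fields,
        field_ellipses=field_ellipses,
        retinotopy_rho=rho,
        synapses=fs,
    )
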