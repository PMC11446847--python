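"""Connectivity feature vectors and MeTu subtype assignment.

Three complementary routes are provided: feature vectors from regional
weight matrices (summed input weight per medulla type, output weight per
tubercle partner type), unsupervised grouping (seeded 2-D embedding with
density-based clusters, or an agglomerative dendrogram on correlation
distance), and the explicit count-threshold rules that define the named
subtypes (Mi15 synapses <= 13 for MeTu3a, < 15 lobula synapses for MeTu4d,
dominant TuBu partner for the rest).
"""

from __future__ import annotations

import warnings
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .connectivity import WeightMatrix
from .errors import ValidationError

#: AOTUsu subregion -> MeTu class implied by the location of axonal boutons
SUBREGION_CLASS = {
    "AOTUsu_PL": "MeTu1",
    "AOTUsu_PC": "MeTu2",
    "AOTUsu_A": "MeTu3",
    "AOTUsu_M": "MeTu4",
}

MI15_MAX_FOR_3A = 13     # MeTu3 with <= 13 Mi15 synapses is MeTu3a
LOBULA_MAX_FOR_4D = 15   # MeTu4 with < 15 lobula pre+post synapses is MeTu4d


def build_feature_vectors(
    input_matrix: WeightMatrix,
    output_matrix: WeightMatrix,
    type_map: Mapping[str, str],
    neurons: Sequence[str],
    groups: Optional[Mapping[str, str]] = None,
    top_k: int = 5,
    output_types: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-neuron connectivity fingerprint from two regional weight matrices.

    Upstream block: the neuron's summed input weight from each medulla
    input type, with the type list formed by ranking input types by mean
    weight within each group (``groups``; one group if omitted), keeping the
    top ``top_k``, and taking the union across groups.  Downstream block:
    the neuron's summed output weight to each tubercle partner type.
    Missing partners contribute 0.
    """
    for n in neurons:
        if n not in input_matrix.post_ids and n not in output_matrix.pre_ids:
            raise ValidationError(f"neuron {n!r} absent from both weight matrices")

    pre_types = np.array([type_map.get(p, "other") for p in input_matrix.pre_ids])
    all_in_types = sorted(set(pre_types))

    # input weight of each neuron from each type
    in_block = pd.DataFrame(0.0, index=list(neurons), columns=all_in_types)
    post_index = {p: j for j, p in enumerate(input_matrix.post_ids)}
    for t in all_in_types:
        rows = pre_types == t
        for n in neurons:
            j = post_index.get(n)
            if j is not None:
                in_block.loc[n, t] = input_matrix.values[rows, j].sum()

    # top-k input types per group, union across groups
    grp = {n: (groups.get(n, "all") if groups else "all") for n in neurons}
    selected: set = set()
    for g in sorted(set(grp.values())):
        members = [n for n in neurons if grp[n] == g]
        mean_w = in_block.loc[members].mean(axis=0)
        selected |= set(mean_w.sort_values(ascending=False).index[:top_k])
    in_cols = sorted(selected)

    # output weight of each neuron to each partner type
    post_types = np.array([type_map.get(p, "other") for p in output_matrix.post_ids])
    out_cols = sorted(set(post_types)) if output_types is None else list(output_types)
    out_block = pd.DataFrame(0.0, index=list(neurons), columns=out_cols)
    pre_index = {p: i for i, p in enumerate(output_matrix.pre_ids)}
    for t in out_cols:
        cols = post_types == t
        for n in neurons:
            i = pre_index.get(n)
            if i is not None:
                out_block.loc[n, t] = output_matrix.values[i, cols].sum()

    feats = pd.concat(
        [in_block[in_cols].add_prefix("in:"), out_block.add_prefix("out:")], axis=1
    )
    return feats.clip(lower=0.0, upper=1.0)


def cluster_subtypes(
    features: pd.DataFrame,
    mode: str = "dendrogram",
    seed: int = 0,
    n_clusters: Optional[int] = None,
    height: Optional[float] = None,
    linkage_method: str = "average",
    metric: str = "correlation",
    embedding_eps: float = 0.8,
):
    """Group neurons by connectivity fingerprint.

    ``dendrogram`` mode builds an agglomerative tree (average linkage on
    correlation distance by default) cut at ``n_clusters`` or ``height``;
    ``embedding`` mode returns a seeded 2-D nonlinear embedding plus
    density-based labels.  Returns (labels: pd.Series, embedding or None).
    Identical seeds give identical output.
    """
    X = features.to_numpy(dtype=float)
    if X.shape[0] == 1:
        return pd.Series([0], index=features.index), None
    if np.allclose(X, X[0]):
        warnings.warn("constant feature matrix; returning a single cluster", stacklevel=2)
        return pd.Series(np.zeros(X.shape[0], dtype=int), index=features.index), None

    if mode == "dendrogram":
        dists = pdist(X, metric=metric)
        # rows with zero variance yield undefined correlations; treat them
        # as maximally distant from everything rather than propagating NaN
        dists = np.nan_to_num(dists, nan=2.0)
        tree = linkage(dists, method=linkage_method)
        if n_clusters is not None:
            labels = fcluster(tree, t=n_clusters, criterion="maxclust")
        else:
            cut = height if height is not None else 0.7 * tree[:, 2].max()
            labels = fcluster(tree, t=cut, criterion="distance")
        return pd.Series(labels - 1, index=features.index), None

    if mode == "embedding":
        import umap
        from sklearn.cluster import DBSCAN

        n_neighbors = min(15, X.shape[0] - 1)
        reducer = umap.UMAP(
            n_components=2, n_neighbors=n_neighbors, min_dist=0.1, random_state=seed
        )
        emb = reducer.fit_transform(X)
        labels = DBSCAN(eps=embedding_eps, min_samples=3).fit_predict(emb)
        emb_df = pd.DataFrame(emb, index=features.index, columns=["umap1", "umap2"])
        return pd.Series(labels, index=features.index), emb_df

    raise ValidationError(f"unknown clustering mode {mode!r}")


def rule_subtype(
    neuron_id: str,
    subregion_synapses: Mapping[str, int],
    mi15_synapses: int = 0,
    lobula_synapses: int = 0,
    tubu_counts: Optional[Mapping[str, int]] = None,
) -> str:
    """Assign a MeTu subtype with the explicit count-threshold rules.

    The class comes from the AOTUsu subregion holding the neuron's axonal
    synapses; subtype rules: MeTu3a iff MeTu3 with <= 13 Mi15 synapses;
    MeTu4d iff MeTu4 with < 15 total lobula pre+post synapses; MeTu4a/b/c
    by dominant TuBu partner (TuBu03/04 -> 4a, TuBu02 -> 4b, TuBu05 -> 4c);
    MeTu2a vs 2b by TuBu01 vs TuBu06 preference; MeTu3b vs 3c by TuBu07 vs
    TuBu09/10 preference.  No axonal synapses -> "incomplete".
    """
    tubu_counts = dict(tubu_counts or {})

    counts = {k: subregion_synapses.get(k, 0) for k in SUBREGION_CLASS}
    if sum(counts.values()) == 0:
        return "incomplete"
    subregion = max(sorted(counts), key=lambda k: counts[k])
    metu_class = SUBREGION_CLASS[subregion]

    def tubu(*names: str) -> int:
        return sum(tubu_counts.get(n, 0) for n in names)

    if metu_class == "MeTu1":
        return "MeTu1"
    if metu_class == "MeTu2":
        return "MeTu2a" if tubu("TuBu01") > tubu("TuBu06") else "MeTu2b"
    if metu_class == "MeTu3":
        if mi15_synapses <= MI15_MAX_FOR_3A:
            return "MeTu3a"
        return "MeTu3b" if tubu("TuBu07") >= tubu("TuBu09", "TuBu10") else "MeTu3c"
    # MeTu4
    if lobula_synapses < LOBULA_MAX_FOR_4D:
        return "MeTu4d"
    best = max(
        ("MeTu4a", tubu("TuBu03", "TuBu04")),
        ("MeTu4b", tubu("TuBu02")),
        ("MeTu4c", tubu("TuBu05")),
        key=lambda kv: (kv[1], kv[0]),
    )
    return best[0]
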