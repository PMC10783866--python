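"""Discover metabolic subtypes by structural deep clustering.

Standardizes the retained prognostic-pathway activities, builds a
10-nearest-neighbor patient graph, trains the autoencoder +
graph-convolution clustering network for k = 2..10 and keeps the k with
the highest average silhouette width; cluster 1 is relabeled to the
poor-prognosis group.  Writes results/subtype_assignment.tsv and
results/per_k_silhouette.tsv.
"""

import pandas as pd
from dataclasses import replace

from mutstrat import (
    build_knn_graph,
    io,
    orient_cluster_labels,
    select_n_clusters,
    standardize_features,
)
from mutstrat.pipeline import COMPACT_SDCN

activity = io.read_matrix("results/pathway_activity.tsv")
clinical = io.read_clinical("results/demo_data/clinical.tsv")
prognostic = pd.read_csv("results/prognostic_pathways.tsv", sep="\t", index_col=0)

feats = standardize_features(activity[list(prognostic.index)])
cfg = replace(COMPACT_SDCN, seed=1)
graph = build_knn_graph(feats, cfg.k_neighbors)
best_k, assignment, per_k = select_n_clusters(feats, graph, cfg, (2, 10))
assignment = orient_cluster_labels(assignment, clinical)

pd.DataFrame(
    {"cluster": assignment.labels, "silhouette": assignment.silhouette}
).to_csv("results/subtype_assignment.tsv", sep="\t", index_label="sample_id")
pd.Series(per_k, name="average_silhouette").rename_axis("k").to_csv(
    "results/per_k_silhouette.tsv", sep="\t"
)

print("average silhouette by k:", {k: round(v, 3) for k, v in per_k.items()})
print(f"selected k = {best_k}; cluster sizes: {assignment.labels.value_counts().to_dict()}")
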