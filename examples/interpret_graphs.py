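"""Neighbor graphs and a lead-optimization pathway.

Compares the chemical-space KNN graph against the TR graph (edges to the
anchors with the largest predicted weights) on a cliff landscape.  The
mean within-cluster standard deviation of activity measures how
homogeneous the graph clusters are: TR finds neighbors in the response
space, so its clusters should be markedly more homogeneous when activity
cliffs are present.  Finally, the maximum-similarity spanning tree of
the most active cluster yields the path between its activity extremes —
a lead-optimization pathway a chemist can walk.
"""

import numpy as np

import topreg as tg

ds, _ = tg.simulate_landscape(tg.LandscapeSpec(seed=11))
sim = tg.pairwise_similarity_matrix(ds).values
dist = tg.design_distances(1.0 - sim, 2)
y = ds.activities()

model = tg.fit_tr(dist, y, seed=0)
tr_neigh = tg.tr_weight_neighbors(
    model, dist[:, model.anchor_indices], query_ids=np.arange(len(ds)), k=5
)
knn_neigh = tg.chemical_knn_neighbors(sim, k=5)

g_tr = tg.build_knn_graph(sim, tr_neigh, k=5, activities=y)
g_knn = tg.build_knn_graph(sim, knn_neigh, k=5, activities=y)
s_tr = tg.within_cluster_std(g_tr, y)
s_knn = tg.within_cluster_std(g_knn, y)
print(f"mean within-cluster activity std: KNN graph {s_knn.mean_std:.3f}, "
      f"TR graph {s_tr.mean_std:.3f}")

best = max((c for c in s_tr.clusters if len(c) >= 3), key=lambda c: y[list(c)].mean())
path = tg.lead_path(g_tr.subgraph(best).copy(), y)
print("lead path (most -> least active) through the top cluster:")
for i in path:
    print(f"  {ds.ids[i]:>8s}  activity {y[i]:.2f}")
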