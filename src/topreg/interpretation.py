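"""Neighbor graphs, cluster activity statistics and lead pathways.

Network-like similarity graphs: every molecule is a node; an edge (i, j)
exists when j is among i's k predicted nearest neighbors AND the
Tanimoto similarity passes a cutoff (default: the mean off-diagonal
similarity of the dataset).  "Nearest neighbors" are either chemical
(top-k Tanimoto similarity) or TR-derived (anchors with the k largest
predicted weights), so the same graph machinery compares a plain KNN
view of the landscape against the response-space view TR learns.
Connected components act as clusters; the mean within-cluster standard
deviation of activity quantifies landscape homogeneity (low = activity
cliffs smoothed out).  Inside a cluster, the maximum-similarity spanning
tree's unique path between the most and least active molecules traces a
lead-optimization pathway.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .univariate import UnivariateTRModel, predicted_log_weights


@dataclass
class ClusterStats:
    clusters: list[list[int]]
    stds: np.ndarray
    mean_std: float


def mean_offdiagonal_similarity(sim: np.ndarray) -> float:
    """Mean similarity of the dataset, self-similarities excluded."""
    sim = np.asarray(sim, dtype=float)
    mask = ~np.eye(len(sim), dtype=bool)
    return float(sim[mask].mean())


def chemical_knn_neighbors(sim: np.ndarray, k: int = 5) -> list[list[int]]:
    """Top-k most Tanimoto-similar other molecules per molecule."""
    sim = np.asarray(sim, dtype=float)
    n = len(sim)
    out = []
    for i in range(n):
        order = np.argsort(-sim[i])
        out.append([int(j) for j in order if j != i][:k])
    return out


def tr_weight_neighbors(
    model: UnivariateTRModel,
    d_query_rows: np.ndarray,
    query_ids: np.ndarray | None = None,
    k: int = 5,
) -> list[list[int]]:
    """Anchors with the k largest predicted TR weights per query.

    Rankings use the fitted mean structure (exact: the corrected weight is
    strictly monotone in μ̂ in both modes).  Anchor indices are returned
    in the model's global indexing; a query that is itself an anchor never
    lists itself.
    """
    lw = predicted_log_weights(model, d_query_rows)
    anchors = model.anchor_indices
    out = []
    for qi, row in enumerate(lw):
        order = np.argsort(-row)
        self_id = None if query_ids is None else int(query_ids[qi])
        picks = [int(anchors[a]) for a in order if int(anchors[a]) != self_id]
        out.append(picks[:k])
    return out


def build_knn_graph(
    sim: np.ndarray,
    neighbor_lists: list[list[int]],
    k: int = 5,
    cutoff: float | None = None,
    activities: np.ndarray | None = None,
) -> nx.Graph:
    """Undirected neighbor graph with a similarity cutoff.

    Edge (i, j) is included iff j is in i's top-k neighbor list and
    sim(i, j) ≥ cutoff; reciprocal duplicates collapse.  Every molecule
    appears as a node even when isolated.
    """
    sim = np.asarray(sim, dtype=float)
    if cutoff is None:
        cutoff = mean_offdiagonal_similarity(sim)
    g = nx.Graph(cutoff=float(cutoff), k=int(k))
    n = len(sim)
    for i in range(n):
        attrs = {"activity": float(activities[i])} if activities is not None else {}
        g.add_node(i, **attrs)
    for i, neigh in enumerate(neighbor_lists):
        for j in neigh[:k]:
            if i != j and sim[i, j] >= cutoff:
                g.add_edge(i, int(j), similarity=float(sim[i, j]))
    return g


def within_cluster_std(graph: nx.Graph, activities: np.ndarray) -> ClusterStats:
    """Population std of activity per connected component; singletons
    contribute 0; the mean over components summarizes homogeneity."""
    activities = np.asarray(activities, dtype=float)
    clusters = [sorted(c) for c in nx.connected_components(graph)]
    clusters.sort()
    stds = np.array([float(np.std(activities[list(c)])) for c in clusters])
    return ClusterStats(clusters=clusters, stds=stds, mean_std=float(stds.mean()))


def _kruskal_mst(nodes, edges) -> nx.Graph:
    """Deterministic Kruskal: edges sorted by (1−sim, min id, max id)."""
    parent = {v: v for v in nodes}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    tree = nx.Graph()
    tree.add_nodes_from(nodes)
    for dist, u, v, sim in sorted(edges):
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            tree.add_edge(u, v, similarity=sim, distance=dist)
    return tree


def maximum_similarity_spanning_tree(graph: nx.Graph) -> nx.Graph:
    """MST on edge weight 1−similarity (ties broken lexicographically)."""
    edges = [
        (1.0 - d["similarity"], min(u, v), max(u, v), d["similarity"])
        for u, v, d in graph.edges(data=True)
    ]
    return _kruskal_mst(list(graph.nodes), edges)


def lead_path(graph: nx.Graph, activities: np.ndarray) -> list[int]:
    """Lead-optimization pathway within one connected component.

    Builds the maximum-similarity spanning tree and returns the unique
    tree path from the most active to the least active molecule (ties in
    the extremes resolved toward the lowest node id).
    """
    if graph.number_of_nodes() < 2:
        raise ValueError("need a component with at least 2 nodes")
    if not nx.is_connected(graph):
        raise ValueError("lead_path requires a connected component")
    activities = np.asarray(activities, dtype=float)
    nodes = sorted(graph.nodes)
    act = {v: activities[v] for v in nodes}
    top = max(nodes, key=lambda v: (act[v], -v))
    bottom = min(nodes, key=lambda v: (act[v], v))
    tree = maximum_similarity_spanning_tree(graph)
    return [int(v) for v in nx.shortest_path(tree, source=top, target=bottom)]


def mds_coordinates(dist: np.ndarray, dims: int = 2, seed: int = 0) -> np.ndarray:
    """Classical stress-minimizing MDS embedding of a distance matrix.

    Plot-only helper (never used for prediction); deterministic under a
    fixed seed.
    """
    import warnings

    from sklearn.manifold import MDS

    dist = np.asarray(dist, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        mds = MDS(
            n_components=dims,
            dissimilarity="precomputed",
            random_state=seed,
            n_init=4,
            init="random",
            normalized_stress="auto",
        )
        return mds.fit_transform(dist)


def export_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def export_edge_list(graph: nx.Graph, path) -> None:
    rows = [
        {"source": u, "target": v, "similarity": d.get("similarity", np.nan)}
        for u, v, d in graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "similarity"]).to_csv(path, index=False)
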