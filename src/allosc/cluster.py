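"""Shared-nearest-neighbor graph construction and Louvain clustering.

Cells are embedded by PCA, connected to their k nearest Euclidean neighbors,
edges reweighted by the Jaccard overlap of the two cells' neighbor sets, and
partitioned by modularity optimization with a resolution parameter (default
0.4). Cluster labels are canonicalized to 0..K-1 by decreasing cluster size,
so label 0 is always the largest cluster.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import igraph as ig
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .containers import NormalizedMatrix, PCAEmbedding
from .errors import ConfigurationError, EmptyResultError


@dataclass
class NeighborGraph:
    """Weighted undirected SNN graph over cells.

    Edges carry Jaccard weights in (0, 1]; zero-overlap candidate edges are
    dropped and there are no self-loops.
    """

    nodes: List[str]
    edges: np.ndarray  # (n_edges, 2) int node indices, i < j
    weights: np.ndarray
    k: int

    def modularity(self, membership: Sequence[int], resolution: float = 1.0) -> float:
        g = _to_igraph(self, list(range(len(self.nodes))))
        return g.modularity(list(membership), weights="weight", resolution=resolution)


def build_knn_graph(emb: PCAEmbedding, k: int = 20) -> NeighborGraph:
    """kNN in embedding space with shared-nearest-neighbor Jaccard weights."""
    coords = emb.coordinates.values
    n = coords.shape[0]
    if k >= n:
        raise ConfigurationError(f"k={k} must be smaller than the number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    # drop self from each neighbor list (may not be first among exact duplicates)
    neigh = np.empty((n, k), dtype=int)
    for i in range(n):
        row = [j for j in idx[i] if j != i]
        neigh[i] = row[:k] if len(row) >= k else (row + [idx[i][-1]])[:k]
    indptr = np.arange(0, n * k + 1, k)
    adj = sp.csr_matrix(
        (np.ones(n * k, dtype=np.int32), neigh.ravel(), indptr), shape=(n, n)
    )
    inter = (adj @ adj.T).tocoo()  # |N(i) & N(j)| on candidate pairs
    cand = (adj + adj.T).tocoo()  # i-j connected if either lists the other
    cand_pairs = {(i, j) for i, j in zip(cand.row, cand.col) if i < j}
    inter_map = {(i, j): v for i, j, v in zip(inter.row, inter.col, inter.data) if i < j}
    edges, weights = [], []
    for (i, j) in sorted(cand_pairs):
        shared = inter_map.get((i, j), 0)
        w = shared / (2 * k - shared)
        if w > 0:
            edges.append((i, j))
            weights.append(w)
    return NeighborGraph(
        nodes=list(emb.barcodes),
        edges=np.array(edges, dtype=int).reshape(-1, 2),
        weights=np.array(weights, dtype=float),
        k=k,
    )


def _to_igraph(g: NeighborGraph, order: List[int]) -> ig.Graph:
    """Build an igraph graph with vertices in the given node order."""
    pos = {node: p for p, node in enumerate(order)}
    graph = ig.Graph(n=len(g.nodes))
    if len(g.edges):
        graph.add_edges([(pos[i], pos[j]) for i, j in g.edges])
        graph.es["weight"] = list(g.weights)
    else:
        graph.es["weight"] = []
    return graph


def louvain_cluster(g: NeighborGraph, resolution: float = 0.4, seed: int = 0) -> pd.Series:
    """Louvain modularity clustering; returns barcode -> label Series.

    Node order fed to the optimizer is the barcode sort order shuffled by
    ``seed``, so results do not depend on input cell order and are
    reproducible for a fixed seed. Labels are consecutive integers ordered by
    decreasing cluster size (ties broken by smallest member barcode).
    """
    if not g.nodes:
        raise EmptyResultError("cannot cluster an empty graph")
    rng = np.random.RandomState(seed)
    order = np.array(sorted(range(len(g.nodes)), key=lambda i: g.nodes[i]))
    rng.shuffle(order)
    order = list(order)
    graph = _to_igraph(g, order)
    pyrandom = _random.Random(seed)
    ig.set_random_number_generator(pyrandom)
    try:
        part = graph.community_multilevel(weights="weight", resolution=resolution)
    finally:
        ig.set_random_number_generator(_random)
    raw = {g.nodes[node]: part.membership[p] for p, node in enumerate(order)}
    return _canonicalize_labels(pd.Series(raw).loc[g.nodes])


def _canonicalize_labels(labels: pd.Series) -> pd.Series:
    groups = labels.groupby(labels)
    stats = sorted(
        ((-len(members), min(members.index), lab) for lab, members in groups),
    )
    remap = {lab: new for new, (_, _, lab) in enumerate(stats)}
    return labels.map(remap).astype(int)


def label_clusters(
    assign: pd.Series,
    nm: NormalizedMatrix,
    marker_map: Dict[str, List[str]],
    contaminant_markers: Optional[List[str]] = None,
    contaminant_alpha: float = 0.01,
    contaminant_log2fc: float = 1.0,
) -> pd.DataFrame:
    """Annotate clusters by marker expression and flag contaminant clusters.

    Each cluster gets the annotation whose marker genes have the highest mean
    in-cluster minus out-of-cluster expression margin. A cluster is flagged
    for exclusion when a contaminant marker gene (e.g. the monocyte marker
    CD14, B-cell CD19 or NK NCAM1) is significantly upregulated one-vs-rest
    (adjusted p < ``contaminant_alpha`` and log2FC > ``contaminant_log2fc``).
    Marker genes absent from the matrix produce a warning-level annotation of
    None rather than an error.
    """
    from .de import de_test  # local import; de does not depend on cluster

    symbols = nm.genes["symbol"].astype(str)
    sym_to_row = {s: i for i, s in enumerate(symbols)}
    rows = []
    for cluster_id in sorted(assign.unique()):
        in_cells = assign.index[assign == cluster_id]
        out_cells = assign.index[assign != cluster_id]
        in_idx = nm.cell_meta.index.get_indexer(in_cells)
        out_idx = nm.cell_meta.index.get_indexer(out_cells)
        best, best_margin = None, -np.inf
        for annotation, markers in marker_map.items():
            present = [sym_to_row[m] for m in markers if m in sym_to_row]
            if not present:
                continue
            margin = (
                nm.values[np.ix_(present, in_idx)].mean()
                - (nm.values[np.ix_(present, out_idx)].mean() if len(out_idx) else 0.0)
            )
            if margin > best_margin:
                best, best_margin = annotation, margin
        excluded = False
        reason = ""
        if contaminant_markers and len(in_cells) >= 3 and len(out_cells) >= 3:
            de = de_test(nm, set(in_cells), set(out_cells), min_pct=0.0)
            contaminant_ids = {
                nm.genes.index[sym_to_row[m]]
                for m in contaminant_markers
                if m in sym_to_row
            }
            hits = de[
                de["gene_id"].isin(contaminant_ids)
                & (de["p_adjusted"] < contaminant_alpha)
                & (de["avg_log2FC"] > contaminant_log2fc)
            ]
            if len(hits):
                excluded = True
                reason = ",".join(
                    symbols.loc[hits["gene_id"]].tolist()
                )
        rows.append(
            {
                "cluster": cluster_id,
                "n_cells": len(in_cells),
                "annotation": best if marker_map else None,
                "excluded": excluded,
                "contaminant_markers": reason,
            }
        )
    return pd.DataFrame(rows).set_index("cluster")
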