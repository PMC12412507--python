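"""Sample-similarity graphs and homophily-based edge re-weighting.

Three undirected weighted graphs are built from the autoencoder latent
space: one within the reference samples, one within the target samples
and one over both jointly. Each node is connected to its k most
cosine-similar neighbours (union symmetrization), with the similarity as
the edge weight. When a composition is known (ground truth on the
reference, model predictions on the target), the cosine similarity of
the two endpoints' proportion vectors decides whether an edge is scaled
up (x1.5 for homophilous edges, label similarity > 0.5) or damped
(x0.8 otherwise); the topology is never changed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse as sp

from .io_data import ProportionMatrix

DEFAULT_K_NEIGHBORS = 10
HOMOPHILY_THRESHOLD = 0.5
UPWEIGHT = 1.5
DOWNWEIGHT = 0.8

GRAPH_KINDS = ("reference", "target", "joint")


@dataclass
class SimilarityGraph:
    """Weighted undirected graph over samples; edges stored once (i < j)."""

    node_ids: list[str]
    node_domains: list[str]
    edges: list[tuple[int, int, float]]
    kind: str
    k_neighbors: int

    def __post_init__(self):
        if self.kind not in GRAPH_KINDS:
            raise ValueError(f"kind must be one of {GRAPH_KINDS}")
        n = len(self.node_ids)
        if len(self.node_domains) != n:
            raise ValueError("one domain tag per node required")
        seen = set()
        degree = np.zeros(n, dtype=int)
        canon = []
        for i, j, w in self.edges:
            if i == j:
                raise ValueError(f"self-loop on node {i}; handled by the GNN update")
            if not np.isfinite(w):
                raise ValueError(f"non-finite weight on edge ({i},{j})")
            if i > j:
                i, j = j, i
            if (i, j) in seen:
                raise ValueError(f"duplicate edge ({i},{j})")
            seen.add((i, j))
            degree[i] += 1
            degree[j] += 1
            canon.append((int(i), int(j), float(w)))
        if n > 1 and (degree == 0).any():
            isolated = int(np.flatnonzero(degree == 0)[0])
            raise ValueError(f"isolated node {self.node_ids[isolated]}")
        self.edges = canon

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def adjacency(self) -> sp.csr_matrix:
        """Symmetric weighted adjacency (no self-loops)."""
        n = self.n_nodes
        if not self.edges:
            return sp.csr_matrix((n, n))
        i, j, w = zip(*self.edges)
        a = sp.coo_matrix((w, (i, j)), shape=(n, n))
        return (a + a.T).tocsr()

    def edge_weight_map(self) -> dict[tuple[int, int], float]:
        return {(i, j): w for i, j, w in self.edges}


def cosine_similarity(u, v) -> float:
    """u.v / (||u|| ||v||); raises on zero-norm input."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity undefined for zero-norm vector")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def _cosine_matrix(Z: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(Z, axis=1)
    if (norms == 0).any():
        bad = int(np.flatnonzero(norms == 0)[0])
        raise ValueError(
            f"zero-norm latent vector at row {bad}: degenerate embedding")
    zn = Z / norms[:, None]
    return np.clip(zn @ zn.T, -1.0, 1.0)


def pairwise_cosine(Z: np.ndarray) -> np.ndarray:
    """Full pairwise cosine-similarity matrix of the rows of Z."""
    return _cosine_matrix(np.asarray(Z, dtype=float))


def build_knn_graph(Z, k: int = DEFAULT_K_NEIGHBORS, kind: str = "reference",
                    node_ids=None, node_domains=None) -> SimilarityGraph:
    """Connect each sample to its k most cosine-similar other samples.

    Ties in the top-k ranking are broken toward the smaller node index;
    the final edge set is the union over both endpoints' selections.
    """
    from .embed_ae import LatentRepresentation

    if isinstance(Z, LatentRepresentation):
        domains = list(Z.domains)
        Z = Z.Z
    else:
        Z = np.asarray(Z, dtype=float)
        domains = None
    n = Z.shape[0]
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the node count {n}")
    sim = _cosine_matrix(Z)
    idx = np.arange(n)
    weights: dict[tuple[int, int], float] = {}
    for i in range(n):
        # rank by (-similarity, index): deterministic tie-break to smaller index
        order = np.lexsort((idx, -sim[i]))
        picked = 0
        for j in order:
            if j == i:
                continue
            a, b = (i, j) if i < j else (j, i)
            weights[(a, b)] = sim[a, b]
            picked += 1
            if picked == k:
                break
    node_ids = list(node_ids) if node_ids is not None else [str(i) for i in range(n)]
    if node_domains is None:
        node_domains = domains if domains is not None else ["reference"] * n
    edges = [(i, j, w) for (i, j), w in sorted(weights.items())]
    return SimilarityGraph(node_ids, list(node_domains), edges, kind, k)


def build_joint_graph(Z_ref, Z_tgt, k: int = DEFAULT_K_NEIGHBORS,
                      ref_ids=None, tgt_ids=None) -> SimilarityGraph:
    """kNN graph over the stacked reference+target latent rows."""
    from .embed_ae import LatentRepresentation

    if isinstance(Z_ref, LatentRepresentation):
        Z_ref = Z_ref.Z
    if isinstance(Z_tgt, LatentRepresentation):
        Z_tgt = Z_tgt.Z
    Z_ref = np.asarray(Z_ref, dtype=float)
    Z_tgt = np.asarray(Z_tgt, dtype=float)
    n_ref, n_tgt = Z_ref.shape[0], Z_tgt.shape[0]
    ids = (list(ref_ids) if ref_ids is not None
           else [f"ref_{i}" for i in range(n_ref)])
    ids += (list(tgt_ids) if tgt_ids is not None
            else [f"tgt_{i}" for i in range(n_tgt)])
    domains = ["reference"] * n_ref + ["target"] * n_tgt
    return build_knn_graph(np.vstack([Z_ref, Z_tgt]), k, kind="joint",
                           node_ids=ids, node_domains=domains)


def label_homophily_weight(z_i_label, z_j_label) -> float:
    """Cosine similarity between two proportion vectors (edge homophily)."""
    return cosine_similarity(z_i_label, z_j_label)


def reweight_edges(g: SimilarityGraph, labels: ProportionMatrix,
                   threshold: float = HOMOPHILY_THRESHOLD,
                   up: float = UPWEIGHT,
                   down: float = DOWNWEIGHT) -> SimilarityGraph:
    """Scale each edge weight by 1.5 (homophily > 0.5, strict) or 0.8.

    `labels` may be ground-truth compositions (reference graph) or model
    predictions (target graph); rows are matched to nodes by position and
    checked against node ids when they coincide.
    """
    if labels.n_samples != g.n_nodes:
        raise ValueError(
            f"labels cover {labels.n_samples} samples but graph has "
            f"{g.n_nodes} nodes")
    L = labels.values
    norms = np.linalg.norm(L, axis=1)
    if (norms == 0).any():
        raise ValueError("zero proportion row; homophily undefined")
    Ln = L / norms[:, None]
    new_edges = []
    for i, j, w in g.edges:
        homophily = float(np.clip(Ln[i] @ Ln[j], -1.0, 1.0))
        factor = up if homophily > threshold else down
        new_edges.append((i, j, factor * w))
    return SimilarityGraph(list(g.node_ids), list(g.node_domains), new_edges,
                           g.kind, g.k_neighbors)


def reweight_target_graph(g_t: SimilarityGraph,
                          predicted: ProportionMatrix) -> SimilarityGraph:
    """Re-weight the target graph using predicted compositions as labels."""
    return reweight_edges(g_t, predicted)


def export_edges_tsv(g: SimilarityGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write("i\tj\tweight\n")
        for i, j, w in g.edges:
            fh.write(f"{g.node_ids[i]}\t{g.node_ids[j]}\t{w:.10g}\n")
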