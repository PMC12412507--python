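"""Multi-channel GraphSAGE encoder, deconvolution head, domain discriminator.

Each channel is an independently initialized two-layer GraphSAGE: a node
is updated by concatenating its own representation with the (weighted)
mean of its neighbours' and applying a learned linear map + ReLU. The two
layer outputs are fused by softmax-normalized per-layer scalars
(initialized at 0.7/0.3) and the C channel outputs are concatenated into
the final node embedding Z_GNN. A two-layer MLP + softmax maps Z_GNN to
cell-type proportions; a two-layer MLP + sigmoid discriminates
reference vs target for adversarial batch-effect removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse as sp

from ._autodiff import Tensor, concat, grad_reverse, softmax, spmm
from .graphs import SimilarityGraph

DEFAULT_HIDDEN_DIM = 256
DEFAULT_N_CHANNELS = 3
DEFAULT_N_LAYERS = 2
DEFAULT_HEAD_HIDDEN = 128
DEFAULT_DISC_HIDDEN = 64
FUSION_INIT = (0.7, 0.3)


def _glorot(rng, d_out: int, d_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / (d_in + d_out))
    return rng.uniform(-bound, bound, size=(d_out, d_in))


@dataclass
class ChannelParams:
    """One GraphSAGE channel: layer weights + fusion logits."""

    W: list[Tensor]            # W[k]: (hidden, 2*prev_dim)
    fusion_logits: Tensor      # (L,), softmax -> layer fusion weights

    def fusion_weights(self) -> np.ndarray:
        e = np.exp(self.fusion_logits.data - self.fusion_logits.data.max())
        return e / e.sum()


@dataclass
class GnnModelState:
    """All trainable parameters of the deconvolution network."""

    channels: list[ChannelParams]
    head_W1: Tensor
    head_b1: Tensor
    head_W2: Tensor
    head_b2: Tensor
    disc_W1: Tensor
    disc_b1: Tensor
    disc_W2: Tensor
    disc_b2: Tensor
    input_dim: int
    n_types: int
    hidden_dim: int = DEFAULT_HIDDEN_DIM
    n_layers: int = DEFAULT_N_LAYERS
    fixed_fusion: bool = False
    use_graph: bool = True           # False = no-GNN ablation (MLP path)
    weighted_aggregation: bool = True

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def embedding_dim(self) -> int:
        return self.n_channels * self.hidden_dim

    def parameters(self, include_discriminator: bool = True) -> list[Tensor]:
        params: list[Tensor] = []
        for ch in self.channels:
            params.extend(ch.W)
            if not self.fixed_fusion:
                params.append(ch.fusion_logits)
        params += [self.head_W1, self.head_b1, self.head_W2, self.head_b2]
        if include_discriminator:
            params += [self.disc_W1, self.disc_b1, self.disc_W2, self.disc_b2]
        return params

    def copy_values(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_values(self, values: list[np.ndarray]) -> None:
        for p, v in zip(self.parameters(), values):
            p.data = v.copy()


@dataclass
class NodeEmbeddingSet:
    """Per-layer, fused, and concatenated multi-channel node embeddings."""

    per_layer: list[list[np.ndarray]]   # [channel][layer] -> (N, hidden)
    fused: list[np.ndarray]             # [channel] -> (N, hidden)
    Z_GNN: np.ndarray                   # (N, C*hidden)

    def __post_init__(self):
        if not np.isfinite(self.Z_GNN).all():
            raise ValueError("non-finite node embeddings")


def init_gnn(input_dim: int, n_types: int,
             hidden_dim: int = DEFAULT_HIDDEN_DIM,
             n_channels: int = DEFAULT_N_CHANNELS,
             n_layers: int = DEFAULT_N_LAYERS,
             head_hidden: int = DEFAULT_HEAD_HIDDEN,
             disc_hidden: int = DEFAULT_DISC_HIDDEN,
             seed: int = 0, fixed_fusion: bool = False,
             use_graph: bool = True,
             weighted_aggregation: bool = True,
             dtype=np.float64) -> GnnModelState:
    """Independently initialize C channels plus both MLP heads."""
    rng = np.random.default_rng(seed)
    fusion_init = np.log(np.array(FUSION_INIT[:n_layers], dtype=dtype))
    if n_layers != len(FUSION_INIT):
        fusion_init = np.zeros(n_layers, dtype=dtype)
    channels = []
    # graph channels consume concat(self, aggregate); the no-GNN ablation
    # is a plain MLP of matched width on the raw features
    in_mult = 2 if use_graph else 1
    for _ in range(n_channels):
        W = []
        prev = input_dim
        for _layer in range(n_layers):
            W.append(Tensor(_glorot(rng, hidden_dim, in_mult * prev).astype(dtype),
                            requires_grad=True))
            prev = hidden_dim
        channels.append(ChannelParams(
            W=W, fusion_logits=Tensor(fusion_init.copy(), requires_grad=True)))
    emb = n_channels * hidden_dim
    return GnnModelState(
        channels=channels,
        head_W1=Tensor(_glorot(rng, head_hidden, emb).astype(dtype),
                       requires_grad=True),
        head_b1=Tensor(np.zeros(head_hidden, dtype=dtype), requires_grad=True),
        # final layers start at zero: the head opens at the uniform
        # composition and the discriminator at chance, which keeps the
        # softmax/sigmoid out of saturation on unnormalized abundances
        head_W2=Tensor(np.zeros((n_types, head_hidden), dtype=dtype),
                       requires_grad=True),
        head_b2=Tensor(np.zeros(n_types, dtype=dtype), requires_grad=True),
        disc_W1=Tensor(_glorot(rng, disc_hidden, emb).astype(dtype),
                       requires_grad=True),
        disc_b1=Tensor(np.zeros(disc_hidden, dtype=dtype), requires_grad=True),
        disc_W2=Tensor(np.zeros((1, disc_hidden), dtype=dtype),
                       requires_grad=True),
        disc_b2=Tensor(np.zeros(1, dtype=dtype), requires_grad=True),
        input_dim=input_dim, n_types=n_types, hidden_dim=hidden_dim,
        n_layers=n_layers, fixed_fusion=fixed_fusion, use_graph=use_graph,
        weighted_aggregation=weighted_aggregation,
    )


# ---------------------------------------------------------------------------
# per-node reference operations (used directly and as oracles' subjects)


def sage_aggregate(node: int, graph: SimilarityGraph, H_prev: np.ndarray,
                   weighted: bool = True) -> np.ndarray:
    """Mean (optionally edge-weight weighted) of the neighbours' embeddings."""
    nbrs = []
    weights = []
    for i, j, w in graph.edges:
        if i == node:
            nbrs.append(j)
            weights.append(w)
        elif j == node:
            nbrs.append(i)
            weights.append(w)
    if not nbrs:
        raise ValueError(f"node {node} has no neighbours")
    H_prev = np.asarray(H_prev, dtype=float)
    if not weighted:
        return H_prev[nbrs].mean(axis=0)
    w = np.asarray(weights, dtype=float)
    total = w.sum()
    if abs(total) < 1e-12:
        return H_prev[nbrs].mean(axis=0)
    return (w[:, None] * H_prev[nbrs]).sum(axis=0) / total


def sage_update(h_self: np.ndarray, h_agg: np.ndarray,
                W_k: np.ndarray) -> np.ndarray:
    """ReLU(W_k . concat(h_self, h_agg))."""
    W_k = W_k.data if isinstance(W_k, Tensor) else np.asarray(W_k)
    return np.maximum(W_k @ np.concatenate([h_self, h_agg]), 0.0)


def fuse_layers(per_layer: list[np.ndarray], fusion: np.ndarray) -> np.ndarray:
    """Layer-wise weighted sum M_v = sum_l s_l h_v^l; weights on the simplex."""
    fusion = np.asarray(fusion, dtype=float)
    if len(per_layer) != fusion.shape[0]:
        raise ValueError("one fusion weight per layer required")
    if (fusion < -1e-9).any() or abs(fusion.sum() - 1.0) > 1e-6:
        raise ValueError("fusion weights must be non-negative and sum to 1")
    out = np.zeros_like(np.asarray(per_layer[0], dtype=float))
    for s_l, h_l in zip(fusion, per_layer):
        out = out + s_l * np.asarray(h_l, dtype=float)
    return out


# ---------------------------------------------------------------------------
# vectorized forward passes (autodiff Tensors)


def normalized_adjacency(graph: SimilarityGraph,
                         weighted: bool = True,
                         use_graph: bool = True,
                         dtype=None) -> sp.csr_matrix:
    """Cached row-normalized aggregation operator (see _normalized_adjacency)."""
    key = (weighted, use_graph, np.dtype(dtype).name if dtype else "f8",
           len(graph.edges))
    cache = getattr(graph, "_norm_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(graph, "_norm_cache", cache)
    if key not in cache:
        a = _normalized_adjacency(graph, weighted, use_graph)
        cache[key] = a.astype(dtype) if dtype is not None else a
    return cache[key]


def _normalized_adjacency(graph: SimilarityGraph,
                          weighted: bool = True,
                          use_graph: bool = True) -> sp.csr_matrix:
    """Row-normalized aggregation operator for Eq.-style mean aggregation.

    With ``use_graph=False`` (no-GNN ablation) returns the identity, so the
    "aggregate" is the node itself and the network degenerates to an MLP of
    matched width on the raw features.
    """
    n = graph.n_nodes
    if not use_graph:
        return sp.identity(n, format="csr")
    a = graph.adjacency()
    if not weighted:
        a = (a != 0).astype(float)
    rows = np.asarray(a.sum(axis=1)).ravel()
    # rows with vanishing total weight fall back to an unweighted mean
    degenerate = np.abs(rows) < 1e-12
    if degenerate.any():
        counts = np.asarray((a != 0).sum(axis=1)).ravel()
        binary = (a != 0).astype(float)
        d = sp.diags(np.where(degenerate, 1.0 / np.maximum(counts, 1), 0.0))
        a_fallback = d @ binary
        rows = np.where(degenerate, 1.0, rows)
        return (sp.diags(np.where(degenerate, 0.0, 1.0 / rows)) @ a
                + a_fallback).tocsr()
    return (sp.diags(1.0 / rows) @ a).tocsr()


def channel_forward(X: Tensor, A_norm: sp.csr_matrix | None,
                    ch: ChannelParams) -> tuple[list[Tensor], Tensor]:
    """Run one GraphSAGE channel; returns per-layer states and fused M_v.

    ``A_norm=None`` selects the MLP path (no-GNN ablation): no
    aggregation, plain per-layer linear + ReLU on the node's own state.
    """
    per_layer: list[Tensor] = []
    h = X
    for W in ch.W:
        if A_norm is None:
            h = (h @ W.T).relu()
        else:
            agg = spmm(A_norm, h)
            h = (concat([h, agg], axis=1) @ W.T).relu()
        per_layer.append(h)
    s = softmax(ch.fusion_logits, axis=0)
    fused = per_layer[0] * s.gather_rows([0])
    for l in range(1, len(per_layer)):
        fused = fused + per_layer[l] * s.gather_rows([l])
    return per_layer, fused


def gnn_forward(X: Tensor, graph: SimilarityGraph,
                state: GnnModelState) -> Tensor:
    """Concatenate all channel outputs: Z_GNN = [M^1_v, ..., M^C_v]."""
    if X.shape[0] != graph.n_nodes:
        raise ValueError(
            f"feature rows ({X.shape[0]}) must match graph nodes "
            f"({graph.n_nodes})")
    A = (normalized_adjacency(graph, state.weighted_aggregation,
                              dtype=X.data.dtype)
         if state.use_graph else None)
    fused = [channel_forward(X, A, ch)[1] for ch in state.channels]
    return concat(fused, axis=1) if len(fused) > 1 else fused[0]


def multi_channel_forward(X, graph: SimilarityGraph,
                          state: GnnModelState) -> NodeEmbeddingSet:
    """Inference-mode forward returning all intermediate embeddings."""
    values = X.values if hasattr(X, "values") and not isinstance(X, np.ndarray) else X
    Xt = Tensor(np.asarray(values, dtype=float))
    if Xt.shape[0] != graph.n_nodes:
        raise ValueError("feature rows must match graph nodes")
    A = (normalized_adjacency(graph, state.weighted_aggregation)
         if state.use_graph else None)
    per_layer, fused = [], []
    for ch in state.channels:
        layers, M = channel_forward(Xt, A, ch)
        per_layer.append([l.data.copy() for l in layers])
        fused.append(M.data.copy())
    return NodeEmbeddingSet(per_layer=per_layer, fused=fused,
                            Z_GNN=np.concatenate(fused, axis=1))


def deconv_head(state: GnnModelState, Z) -> Tensor:
    """softmax(MLP(z)): rows are valid cell-type proportion vectors."""
    Zt = Z if isinstance(Z, Tensor) else Tensor(np.atleast_2d(np.asarray(Z, dtype=float)))
    h = (Zt @ state.head_W1.T + state.head_b1).relu()
    logits = h @ state.head_W2.T + state.head_b2
    return softmax(logits, axis=1)


def deconv_head_numpy(state: GnnModelState, Z: np.ndarray) -> np.ndarray:
    """Gradient-free head forward (validation monitoring)."""
    h = np.maximum(Z @ state.head_W1.data.T + state.head_b1.data, 0.0)
    logits = h @ state.head_W2.data.T + state.head_b2.data
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def domain_logits(state: GnnModelState, Z,
                  reverse_gradient: bool = False,
                  grl_lambda: float = 1.0) -> Tensor:
    """Pre-sigmoid output of the domain discriminator MLP."""
    Zt = Z if isinstance(Z, Tensor) else Tensor(np.atleast_2d(np.asarray(Z, dtype=float)))
    if reverse_gradient:
        Zt = grad_reverse(Zt, grl_lambda)
    h = (Zt @ state.disc_W1.T + state.disc_b1).relu()
    return h @ state.disc_W2.T + state.disc_b2


def domain_discriminator(state: GnnModelState, Z,
                         reverse_gradient: bool = False,
                         grl_lambda: float = 1.0) -> Tensor:
    """P(domain = reference) via a two-layer perceptron with sigmoid output."""
    return domain_logits(state, Z, reverse_gradient, grl_lambda).sigmoid()
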