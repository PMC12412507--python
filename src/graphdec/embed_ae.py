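"""Autoencoder feature projection for graph construction.

A small fully connected autoencoder (default architecture
[input, 16, input], ReLU at every layer) is trained on the concatenated
reference and target samples restricted to their shared proteins. Its
16-dimensional latent space is used only to measure cosine similarity
between samples when building the k-nearest-neighbour graphs; the
autoencoder is trained first and then frozen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Adam, Tensor
from .io_data import ProteinMatrix

DEFAULT_LATENT_DIM = 16
DEFAULT_EPOCHS = 200
DEFAULT_LR = 1e-3


@dataclass
class AutoencoderState:
    """Weights and biases of the encoder/decoder stacks."""

    encoder_weights: list[np.ndarray]
    encoder_biases: list[np.ndarray]
    decoder_weights: list[np.ndarray]
    decoder_biases: list[np.ndarray]
    latent_dim: int = DEFAULT_LATENT_DIM
    loss_history: list[float] = field(default_factory=list)

    def __post_init__(self):
        dims = [w.shape[1] for w in self.encoder_weights]
        outs = [w.shape[0] for w in self.encoder_weights]
        for w_in, h_out in zip(dims[1:], outs[:-1]):
            if w_in != h_out:
                raise ValueError("encoder layer dimensions do not chain")
        if outs[-1] != self.latent_dim:
            raise ValueError("final encoder layer must produce latent_dim")

    @property
    def input_dim(self) -> int:
        return self.encoder_weights[0].shape[1]


@dataclass
class LatentRepresentation:
    """Per-sample latent coordinates with their domain tags."""

    Z: np.ndarray
    domains: list[str]

    def __post_init__(self):
        self.Z = np.asarray(self.Z, dtype=float)
        if not np.isfinite(self.Z).all():
            raise ValueError("latent representation contains non-finite values")
        if self.Z.shape[0] != len(self.domains):
            raise ValueError("one domain tag per latent row required")


def init_autoencoder(input_dim: int, latent_dim: int = DEFAULT_LATENT_DIM,
                     hidden_dims: tuple[int, ...] = (),
                     seed: int = 0,
                     output_bias: np.ndarray | None = None) -> AutoencoderState:
    """Glorot-uniform weights; `hidden_dims` inserts extra layers.

    Biases start slightly positive and, when `output_bias` is given
    (train_autoencoder passes the feature means), the final decoder bias
    starts there — with ReLU at every layer and non-negative abundances
    this keeps all units initially active instead of permanently dead.
    """
    rng = np.random.default_rng(seed)
    enc_dims = [input_dim, *hidden_dims, latent_dim]
    dec_dims = list(reversed(enc_dims))

    def _stack(dims):
        ws, bs = [], []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            bound = np.sqrt(6.0 / (d_in + d_out))
            ws.append(rng.uniform(-bound, bound, size=(d_out, d_in)))
            bs.append(np.full(d_out, 0.01))
        return ws, bs

    ew, eb = _stack(enc_dims)
    dw, db = _stack(dec_dims)
    if output_bias is not None:
        db[-1] = np.asarray(output_bias, dtype=float).copy()
    return AutoencoderState(ew, eb, dw, db, latent_dim=latent_dim)


def _forward_stack(x: np.ndarray, weights, biases) -> np.ndarray:
    h = x
    for w, b in zip(weights, biases):
        h = np.maximum(h @ w.T + b, 0.0)
    return h


def encode(X: ProteinMatrix | np.ndarray, state: AutoencoderState,
           domain: str | None = None) -> LatentRepresentation:
    """Project samples into the latent space: H^(l) = ReLU(W_e H + b_e)."""
    if isinstance(X, ProteinMatrix):
        values, domains = X.values, [X.domain] * X.n_samples
    else:
        values = np.asarray(X, dtype=float)
        domains = [domain or "reference"] * values.shape[0]
    if values.shape[1] != state.input_dim:
        raise ValueError(
            f"feature count {values.shape[1]} != encoder input {state.input_dim}")
    return LatentRepresentation(_forward_stack(values, state.encoder_weights,
                                               state.encoder_biases), domains)


def decode(Z: LatentRepresentation | np.ndarray,
           state: AutoencoderState) -> np.ndarray:
    """Reconstruct inputs from latent coordinates (mirror of encode)."""
    z = Z.Z if isinstance(Z, LatentRepresentation) else np.asarray(Z, dtype=float)
    if z.shape[1] != state.latent_dim:
        raise ValueError("latent width mismatch")
    return _forward_stack(z, state.decoder_weights, state.decoder_biases)


def reconstruction_loss(X: np.ndarray, X_rec: np.ndarray) -> float:
    """Squared error summed over features, averaged over samples."""
    X = np.asarray(X, dtype=float)
    X_rec = np.asarray(X_rec, dtype=float)
    if X.shape != X_rec.shape:
        raise ValueError(f"shape mismatch {X.shape} vs {X_rec.shape}")
    return float(((X - X_rec) ** 2).sum(axis=1).mean())


def train_autoencoder(ref: ProteinMatrix, tgt: ProteinMatrix,
                      latent_dim: int = DEFAULT_LATENT_DIM,
                      hidden_dims: tuple[int, ...] = (),
                      epochs: int = DEFAULT_EPOCHS, lr: float = DEFAULT_LR,
                      seed: int = 0, max_retries: int = 4) -> AutoencoderState:
    """Train on the concatenated reference+target matrix, full batch Adam.

    Both domains share one state so batch mixing happens in the latent
    space. Raises if the loss becomes non-finite; records the loss
    trajectory on the returned state.

    Because the bottleneck is ReLU, a rare initialization can leave some
    sample with an all-zero latent (undefined cosine similarity
    downstream). Training is then retried with a deterministic offset
    init seed, up to ``max_retries`` times.
    """
    import logging

    for attempt in range(max_retries + 1):
        state = _train_once(ref, tgt, latent_dim, hidden_dims, epochs, lr,
                            seed + 1000 * attempt)
        if epochs <= 0:
            return state
        Z = np.vstack([encode(ref, state).Z, encode(tgt, state).Z])
        dead = int((np.linalg.norm(Z, axis=1) == 0).sum())
        if dead == 0:
            return state
        logging.getLogger(__name__).warning(
            "autoencoder left %d sample(s) with zero-norm latents "
            "(attempt %d); retrying with offset init seed", dead, attempt)
    return state


def _train_once(ref: ProteinMatrix, tgt: ProteinMatrix,
                latent_dim: int, hidden_dims: tuple[int, ...],
                epochs: int, lr: float, seed: int) -> AutoencoderState:
    if ref.feature_ids != tgt.feature_ids:
        raise ValueError("reference and target must be feature-aligned")
    X = np.vstack([ref.values, tgt.values])
    state = init_autoencoder(ref.n_features, latent_dim, hidden_dims, seed,
                             output_bias=X.mean(axis=0))
    if epochs <= 0:
        state.loss_history.append(reconstruction_loss(
            X, _forward_stack(_forward_stack(X, state.encoder_weights,
                                             state.encoder_biases),
                              state.decoder_weights, state.decoder_biases)))
        return state

    params = []
    for arrs in (state.encoder_weights, state.encoder_biases,
                 state.decoder_weights, state.decoder_biases):
        for i, a in enumerate(arrs):
            t = Tensor(a.copy(), requires_grad=True)
            arrs[i] = t  # temporarily hold Tensors
            params.append(t)
    opt = Adam(params, lr=lr)
    Xt = Tensor(X)
    inv_n = 1.0 / X.shape[0]
    best_loss = np.inf
    best_params = None

    for _ in range(epochs + 1):  # final pass evaluates the last update
        h = Xt
        for w, b in zip(state.encoder_weights, state.encoder_biases):
            h = (h @ w.T + b).relu()
        for w, b in zip(state.decoder_weights, state.decoder_biases):
            h = (h @ w.T + b).relu()
        diff = h - Xt
        loss = (diff * diff).sum() * inv_n
        value = float(loss.data)
        if not np.isfinite(value):
            raise FloatingPointError(
                f"autoencoder loss diverged at epoch {len(state.loss_history)}: "
                f"{value}")
        state.loss_history.append(value)
        if value < best_loss:
            best_loss = value
            best_params = [p.data.copy() for p in params]
        if len(state.loss_history) > epochs:
            break
        opt.zero_grad()
        loss.backward()
        opt.step()

    # keep the best checkpoint seen, so the returned state never does
    # worse than the initialization
    for p, best in zip(params, best_params):
        p.data = best
    for arrs in (state.encoder_weights, state.encoder_biases,
                 state.decoder_weights, state.decoder_biases):
        for i, t in enumerate(arrs):
            arrs[i] = np.asarray(t.data)
    return state
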