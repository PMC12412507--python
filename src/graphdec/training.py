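"""Losses and the four-stage training/prediction protocol.

Training minimizes  L = L_dec + alpha * L_tri + beta * L_dom  where
L_dec is the mean squared error between predicted and true compositions
on the labeled reference, L_tri a cosine triplet margin loss whose
positives/negatives are mined once from the frozen autoencoder latents,
and L_dom a domain-adversarial binary cross-entropy realized with a
gradient-reversal layer so a single Adam step trains the discriminator
while un-training the encoder's domain information.

Each iteration has two steps: (1) the reference and target graphs are
forwarded separately and all three losses apply; (2) the joint graph is
forwarded and only the prediction and triplet losses apply. Early
stopping watches the validation CCC on a held-out slice of the
reference, never firing before ``min_iterations``. Prediction runs the
target graph once, re-weights its edges by the homophily of the initial
predicted compositions, and runs the adjusted graph again for the final
estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from ._autodiff import Adam, Tensor, clip_grad_norm
from .gnn_core import (GnnModelState, deconv_head, deconv_head_numpy,
                       domain_discriminator, domain_logits, gnn_forward,
                       init_gnn)
from .graphs import SimilarityGraph, reweight_target_graph
from .io_data import ProportionMatrix, ProteinMatrix
from .metrics import UndefinedMetricError, ccc
from .pseudobulk import PseudoBulkSet

logger = logging.getLogger(__name__)

EPS_PROB = 1e-7

ABLATION_COMPONENTS = ("gnn", "triplet", "reweight")


@dataclass
class TrainConfig:
    """Hyperparameters of the training protocol."""

    lr: float = 0.001
    iterations: int = 3000
    min_iterations: int = 1500
    patience: int = 100
    val_fraction: float = 0.10
    m: float = 0.3           # triplet margin
    alpha: float = 0.01      # triplet loss weight
    beta: float = 1.0        # domain loss weight
    seed: int = 0
    device: str = "cpu"
    clip_grad_norm: float = 0.0  # global grad-norm ceiling; 0 disables
    disc_lr_scale: float = 1.0   # <1 slows the discriminator (two-time-scale)
    disc_label_smoothing: float = 0.0  # >0 keeps the adversarial gradient alive
    grl_lambda: float = 1.0
    grl_schedule: str = "ramp"  # "ramp": 2/(1+exp(-10 p)) - 1, or "constant"
    alternating_updates: bool = False  # alternative to gradient reversal

    def __post_init__(self):
        for name in ("lr", "iterations", "min_iterations", "patience"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must lie in (0, 1)")
        if self.m < 0 or self.alpha < 0 or self.beta < 0:
            raise ValueError("m, alpha, beta must be non-negative")


@dataclass
class TripletSet:
    """(anchor, positive, negative) index triples and their source matrix."""

    triplets: list[tuple[int, int, int]]
    similarity: np.ndarray
    _selectors: tuple | None = None

    def __post_init__(self):
        for a, p, ng in self.triplets:
            if a == p or a == ng or p == ng:
                raise ValueError(f"degenerate triplet ({a},{p},{ng})")

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        t = np.asarray(self.triplets, dtype=int)
        return t[:, 0], t[:, 1], t[:, 2]

    def selectors(self, n_rows: int, dtype=np.float64):
        """Sparse row-selection matrices (anchor/pos/neg), built once."""
        from scipy import sparse as sp

        if (self._selectors is None
                or self._selectors[0].shape[1] != n_rows
                or self._selectors[0].dtype != dtype):
            a, p, ng = self.arrays()
            m = a.size
            ones = np.ones(m, dtype=dtype)
            rows = np.arange(m)
            self._selectors = tuple(
                sp.csr_matrix((ones, (rows, idx)), shape=(m, n_rows))
                for idx in (a, p, ng))
        return self._selectors


# ---------------------------------------------------------------------------
# losses


def loss_dec(pred, truth):
    """Mean over samples of the squared L2 distance between compositions."""
    if isinstance(pred, Tensor):
        diff = pred - (truth if isinstance(truth, Tensor)
                       else Tensor(np.asarray(truth)))
        return (diff * diff).sum(axis=1).mean()
    pred = np.atleast_2d(np.asarray(pred, dtype=float))
    truth = np.atleast_2d(np.asarray(truth, dtype=float))
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    return float(((pred - truth) ** 2).sum(axis=1).mean())


def mine_triplets(S: np.ndarray) -> TripletSet:
    """One triplet per anchor: argmax-similarity positive, argmin negative.

    Ties resolve to the lowest index; the diagonal (self) is excluded.
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    if S.shape != (n, n):
        raise ValueError("similarity matrix must be square")
    if n < 3:
        raise ValueError("triplet mining needs at least 3 samples")
    masked = S.copy()
    np.fill_diagonal(masked, -np.inf)
    pos = masked.argmax(axis=1)  # argmax/argmin both break ties low
    masked = S.copy()
    np.fill_diagonal(masked, np.inf)
    neg = masked.argmin(axis=1)
    triplets = []
    for a in range(n):
        p, ng = int(pos[a]), int(neg[a])
        if p == ng:  # all off-diagonal similarities equal; tie-rule, logged
            logger.debug("anchor %d has constant similarities; skipped", a)
            ng = next(j for j in range(n) if j not in (a, p))
        triplets.append((a, p, ng))
    return TripletSet(triplets, S)


def loss_triplet(embeddings, triplets: TripletSet, m: float = 0.3):
    """Mean over anchors of max(cos(a, neg) - cos(a, pos) + m, 0)."""
    a, p, ng = triplets.arrays()
    if isinstance(embeddings, Tensor):
        from ._autodiff import spmm

        z = embeddings
        norms = ((z * z).sum(axis=1, keepdims=True) + 1e-12).sqrt()
        zn = z / norms
        P_a, P_p, P_n = triplets.selectors(z.shape[0], z.data.dtype)
        za = spmm(P_a, zn)
        cos_neg = (za * spmm(P_n, zn)).sum(axis=1)
        cos_pos = (za * spmm(P_p, zn)).sum(axis=1)
        return (cos_neg - cos_pos + m).relu().mean()
    z = np.asarray(embeddings, dtype=float)
    zn = z / (np.linalg.norm(z, axis=1, keepdims=True) + 1e-12)
    cos_neg = (zn[a] * zn[ng]).sum(axis=1)
    cos_pos = (zn[a] * zn[p]).sum(axis=1)
    return float(np.maximum(cos_neg - cos_pos + m, 0.0).mean())


def loss_domain(d_ref, d_tgt):
    """Discriminator log-likelihood: mean log d_r + mean log(1 - d_t).

    This is the quantity the discriminator maximizes (0 at perfect
    discrimination, 2 log 0.5 at chance); training minimizes its
    negation (the binary cross-entropy) with the encoder on the reversed
    gradient. Probabilities are clipped to [eps, 1-eps].
    """
    if isinstance(d_ref, Tensor) or isinstance(d_tgt, Tensor):
        dr = d_ref if isinstance(d_ref, Tensor) else Tensor(np.asarray(d_ref, dtype=float))
        dt = d_tgt if isinstance(d_tgt, Tensor) else Tensor(np.asarray(d_tgt, dtype=float))
        return (dr.clip(EPS_PROB, 1 - EPS_PROB).log().mean()
                + (1.0 - dt).clip(EPS_PROB, 1 - EPS_PROB).log().mean())
    dr = np.clip(np.asarray(d_ref, dtype=float), EPS_PROB, 1 - EPS_PROB)
    dt = np.clip(np.asarray(d_tgt, dtype=float), EPS_PROB, 1 - EPS_PROB)
    return float(np.log(dr).mean() + np.log(1.0 - dt).mean())


def total_loss(L_dec, L_tri, L_dom, alpha: float = 0.01, beta: float = 1.0):
    """L = L_dec + alpha * L_tri + beta * L_dom."""
    return L_dec + alpha * L_tri + beta * L_dom


# ---------------------------------------------------------------------------
# the trained model wrapper


@dataclass
class TrainedModel:
    """A fitted network plus everything prediction needs."""

    state: GnnModelState
    type_universe: list[str]
    config: TrainConfig
    reweight_enabled: bool = True
    history: list[dict] = field(default_factory=list)
    best_iteration: int = -1
    best_val_ccc: float = np.nan
    stopped_at: int = -1


def _val_ccc(pred: np.ndarray, truth: np.ndarray) -> float:
    scores = []
    for i in range(pred.shape[0]):
        try:
            scores.append(ccc(truth[i], pred[i]))
        except UndefinedMetricError:
            continue
    return float(np.mean(scores)) if scores else -np.inf


def stratified_validation_split(props: np.ndarray, val_fraction: float,
                                rng: np.random.Generator):
    """Hold out ``val_fraction`` of rows, stratified on the dominant type."""
    n = props.shape[0]
    dominant = props.argmax(axis=1)
    val_idx = []
    for k in np.unique(dominant):
        members = np.flatnonzero(dominant == k)
        n_val = max(1, int(round(val_fraction * members.size))) if members.size > 1 else 0
        val_idx.extend(rng.permutation(members)[:n_val])
    val_idx = np.sort(np.asarray(val_idx, dtype=int))
    train_idx = np.setdiff1d(np.arange(n), val_idx)
    if train_idx.size == 0 or val_idx.size == 0:
        raise ValueError("validation split left one side empty")
    return train_idx, val_idx


def grl_lambda_at(config: TrainConfig, iteration: int) -> float:
    """Gradient-reversal strength for the given iteration.

    The default ramp 2/(1+exp(-10p)) - 1 (p = training progress) eases the
    adversarial pressure in while the deconvolution head finds its feet,
    the standard schedule for reversal-based domain-adversarial training.
    """
    if config.grl_schedule == "constant":
        return float(config.grl_lambda)
    p = iteration / max(config.iterations - 1, 1)
    # plain float: a NumPy scalar would upcast float32 gradients
    return float(config.grl_lambda * (2.0 / (1.0 + np.exp(-10.0 * p)) - 1.0))


def train_epoch(state: GnnModelState, opt: Adam, data: dict,
                config: TrainConfig, grl_lam: float | None = None) -> dict:
    """One iteration = the two-step protocol; returns the loss record.

    data keys: X_ref, X_tgt, X_joint (ndarrays), g_ref, g_tgt, g_joint,
    Y_train (training-row labels), train_idx, triplets_ref, triplets_tgt,
    triplets_joint.
    """
    record: dict[str, float] = {}

    # -- step 1: per-domain graphs; prediction + triplet + domain losses
    z_ref = gnn_forward(Tensor(data["X_ref"]), data["g_ref"], state)
    z_tgt = gnn_forward(Tensor(data["X_tgt"]), data["g_tgt"], state)
    pred_train = deconv_head(state, z_ref.gather_rows(data["train_idx"]))
    l_dec = loss_dec(pred_train, data["Y_train"])
    if "val_idx" in data:
        # monitor with the parameters in force at this iteration's start
        record["val_pred"] = deconv_head_numpy(
            state, z_ref.data[data["val_idx"]])

    if config.alpha > 0:
        from ._autodiff import concat

        z_all = concat([z_ref, z_tgt], axis=0)
        l_tri = loss_triplet(z_all, data["triplets_step1"], config.m)
    else:
        l_tri = Tensor(0.0)

    if config.beta > 0 and config.alternating_updates:
        # explicit two-player alternation: first the discriminator fits
        # the current (detached) embeddings, then the encoder un-fits it
        disc_opt = data["disc_opt"]
        logit_ref_d = domain_logits(state, z_ref.data)
        logit_tgt_d = domain_logits(state, z_tgt.data)
        disc_loss = ((-logit_ref_d).softplus().mean()
                     + logit_tgt_d.softplus().mean())
        disc_opt.zero_grad()
        disc_loss.backward()
        if config.clip_grad_norm > 0:
            clip_grad_norm(disc_opt.params, config.clip_grad_norm)
        disc_opt.step()
        # encoder maximizes the (fresh) discriminator's BCE
        lam = config.grl_lambda if grl_lam is None else grl_lam
        logit_ref = domain_logits(state, z_ref, reverse_gradient=True,
                                  grl_lambda=lam)
        logit_tgt = domain_logits(state, z_tgt, reverse_gradient=True,
                                  grl_lambda=lam)
        l_dom_bce = (-logit_ref).softplus().mean() + logit_tgt.softplus().mean()
        l_dom_ll = -float(l_dom_bce.data)
        record["disc_balanced_acc"] = 0.5 * (
            float((logit_ref.data >= 0.0).mean())
            + float((logit_tgt.data < 0.0).mean()))
    elif config.beta > 0:
        # BCE from logits (stable softplus form): the discriminator
        # minimizes it while the encoder, behind the gradient-reversal
        # layer, maximizes it
        lam = config.grl_lambda if grl_lam is None else grl_lam
        logit_ref = domain_logits(state, z_ref, reverse_gradient=True,
                                  grl_lambda=lam)
        logit_tgt = domain_logits(state, z_tgt, reverse_gradient=True,
                                  grl_lambda=lam)
        eps = config.disc_label_smoothing
        l_dom_bce = (
            (1 - eps) * (-logit_ref).softplus().mean()
            + eps * logit_ref.softplus().mean()
            + (1 - eps) * logit_tgt.softplus().mean()
            + eps * (-logit_tgt).softplus().mean())
        # report the unsmoothed log-likelihood for interpretability
        l_dom_ll = -float(((-logit_ref).softplus().mean()
                           + logit_tgt.softplus().mean()).data)
        record["disc_balanced_acc"] = 0.5 * (
            float((logit_ref.data >= 0.0).mean())
            + float((logit_tgt.data < 0.0).mean()))
    else:
        l_dom_bce = Tensor(0.0)
        l_dom_ll = 0.0

    step1 = total_loss(l_dec, l_tri, l_dom_bce, config.alpha, config.beta)
    _check_finite(step1, "step 1")
    opt.zero_grad()
    step1.backward()
    if config.clip_grad_norm > 0:
        clip_grad_norm(opt.params, config.clip_grad_norm)
    opt.step()
    record.update(L_dec=float(l_dec.data), L_tri=float(l_tri.data),
                  L_dom=float(l_dom_ll), step1=float(step1.data))

    # -- step 2: joint graph; only prediction + triplet losses
    z_joint = gnn_forward(Tensor(data["X_joint"]), data["g_joint"], state)
    pred_train2 = deconv_head(state, z_joint.gather_rows(data["train_idx"]))
    l_dec2 = loss_dec(pred_train2, data["Y_train"])
    if config.alpha > 0:
        l_tri2 = loss_triplet(z_joint, data["triplets_joint"], config.m)
    else:
        l_tri2 = Tensor(0.0)
    step2 = l_dec2 + config.alpha * l_tri2
    _check_finite(step2, "step 2")
    opt.zero_grad()
    step2.backward()
    if config.clip_grad_norm > 0:
        clip_grad_norm(opt.params, config.clip_grad_norm)
    opt.step()
    record.update(L_dec_joint=float(l_dec2.data), L_tri_joint=float(l_tri2.data),
                  step2=float(step2.data))
    return record


def merge_domain_triplets(trip_ref: TripletSet, trip_tgt: TripletSet,
                          n_ref: int) -> TripletSet:
    """Per-domain triplets re-indexed onto the stacked ref+tgt rows."""
    shifted = [(a + n_ref, p + n_ref, ng + n_ref)
               for a, p, ng in trip_tgt.triplets]
    return TripletSet(trip_ref.triplets + shifted, trip_ref.similarity)


def _check_finite(loss: Tensor, where: str) -> None:
    if not np.isfinite(float(loss.data)):
        raise FloatingPointError(f"non-finite loss in {where}")


def prepare_training_data(ref: PseudoBulkSet, tgt: ProteinMatrix,
                          g_ref: SimilarityGraph, g_tgt: SimilarityGraph,
                          g_joint: SimilarityGraph,
                          S_ref: np.ndarray, S_tgt: np.ndarray,
                          S_joint: np.ndarray,
                          config: TrainConfig,
                          dtype=np.float64) -> dict:
    """Assemble the static per-run tensors, split, and mined triplets."""
    rng = np.random.default_rng(config.seed)
    train_idx, val_idx = stratified_validation_split(
        ref.props.values, config.val_fraction, rng)
    X_ref = ref.expr.values.astype(dtype)
    X_tgt = tgt.values.astype(dtype)
    trip_ref = mine_triplets(S_ref)
    trip_tgt = mine_triplets(S_tgt)
    return {
        "X_ref": X_ref, "X_tgt": X_tgt,
        "X_joint": np.vstack([X_ref, X_tgt]),
        "g_ref": g_ref, "g_tgt": g_tgt, "g_joint": g_joint,
        "train_idx": train_idx, "val_idx": val_idx,
        "Y_train": ref.props.values[train_idx].astype(dtype),
        "Y_val": ref.props.values[val_idx],
        "triplets_ref": trip_ref,
        "triplets_tgt": trip_tgt,
        "triplets_step1": merge_domain_triplets(trip_ref, trip_tgt,
                                                X_ref.shape[0]),
        "triplets_joint": mine_triplets(S_joint),
    }


def fit(ref: PseudoBulkSet, tgt: ProteinMatrix, graphs: dict,
        config: TrainConfig | None = None,
        state: GnnModelState | None = None,
        similarity: dict | None = None,
        reweight_enabled: bool = True,
        gnn_kwargs: dict | None = None,
        dtype=np.float64) -> TrainedModel:
    """Train the network with early stopping on validation CCC.

    `graphs` maps {"reference", "target", "joint"} to SimilarityGraphs
    (the reference graph already homophily-re-weighted unless ablated);
    `similarity` maps the same keys to the dense cosine matrices the
    triplet miner uses. Early stopping fires when the validation CCC has
    not improved for `patience` consecutive iterations AND the iteration
    count has reached `min_iterations`; the best-validation checkpoint is
    restored.
    """
    config = config or TrainConfig()
    if similarity is None:
        raise ValueError("similarity matrices are required for triplet mining")
    if state is None:
        state = init_gnn(ref.expr.n_features, len(ref.props.type_universe),
                         seed=config.seed, dtype=dtype, **(gnn_kwargs or {}))
    data = prepare_training_data(ref, tgt, graphs["reference"],
                                 graphs["target"], graphs["joint"],
                                 similarity["reference"], similarity["target"],
                                 similarity["joint"], config, dtype=dtype)
    disc_ids = {id(t) for t in (state.disc_W1, state.disc_b1,
                                state.disc_W2, state.disc_b2)}
    if config.alternating_updates:
        opt = Adam(state.parameters(include_discriminator=False),
                   lr=config.lr)
        disc_params = [state.disc_W1, state.disc_b1, state.disc_W2,
                       state.disc_b2]
        data["disc_opt"] = Adam(disc_params, lr=config.lr * config.disc_lr_scale)
    else:
        params = state.parameters()
        scales = [config.disc_lr_scale if id(p) in disc_ids else 1.0
                  for p in params]
        opt = Adam(params, lr=config.lr, lr_scales=scales)

    model = TrainedModel(state=state, type_universe=list(ref.props.type_universe),
                         config=config, reweight_enabled=reweight_enabled)
    best_val = -np.inf
    best_params = state.copy_values()
    since_improve = 0

    for it in range(config.iterations):
        # validation is measured with the parameters in force when the
        # iteration starts, so the snapshot matching the score is cheap
        snapshot = state.copy_values()
        record = train_epoch(state, opt, data, config,
                             grl_lam=grl_lambda_at(config, it))
        val = _val_ccc(record.pop("val_pred"), data["Y_val"])
        record["val_ccc"] = val
        record["iteration"] = it
        model.history.append(record)
        if val > best_val:
            best_val = val
            best_params = snapshot
            model.best_iteration = it
            since_improve = 0
        else:
            since_improve += 1
        if since_improve >= config.patience and it + 1 >= config.min_iterations:
            model.stopped_at = it
            logger.info("early stop at iteration %d (best val CCC %.4f at %d)",
                        it, best_val, model.best_iteration)
            break

    state.load_values(best_params)
    model.best_val_ccc = best_val
    if model.stopped_at < 0:
        model.stopped_at = config.iterations - 1
    return model


def predict(model: TrainedModel, tgt: ProteinMatrix,
            g_t: SimilarityGraph) -> ProportionMatrix:
    """Two-pass prediction: initial estimate, edge re-weighting, final pass."""
    state = model.state
    X = tgt.values.astype(state.head_W1.data.dtype)
    z = gnn_forward(Tensor(X), g_t, state)
    initial = deconv_head(state, z).data.astype(float)
    props0 = ProportionMatrix(initial / initial.sum(axis=1, keepdims=True),
                              list(tgt.sample_ids), list(model.type_universe))
    if not model.reweight_enabled:
        return props0
    g_adj = reweight_target_graph(g_t, props0)
    z2 = gnn_forward(Tensor(X), g_adj, state)
    final = deconv_head(state, z2).data.astype(float)
    return ProportionMatrix(final / final.sum(axis=1, keepdims=True),
                            list(tgt.sample_ids), list(model.type_universe))


def ablate(config: TrainConfig, component: str,
           gnn_kwargs: dict | None = None) -> tuple[TrainConfig, dict, bool]:
    """Return (config, gnn_kwargs, reweight_enabled) for an ablation.

    gnn: GraphSAGE channels degrade to an MLP of matched width on the raw
    features; triplet: alpha = 0; reweight: homophily re-weighting skipped
    everywhere (reference graph and prediction stage alike).
    """
    gnn_kwargs = dict(gnn_kwargs or {})
    if component == "gnn":
        gnn_kwargs["use_graph"] = False
        return config, gnn_kwargs, True
    if component == "triplet":
        return replace(config, alpha=0.0), gnn_kwargs, True
    if component == "reweight":
        return config, gnn_kwargs, False
    raise ValueError(f"unknown ablation {component!r}; "
                     f"choose from {ABLATION_COMPONENTS}")
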