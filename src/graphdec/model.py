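"""Top-level modelling interface: GraphDECModel / GraphDECResults.

Follows the model/results convention of statistical modelling packages:
the model object is built from data, ``fit()`` runs the full pipeline
(autoencoder projection, similarity-graph construction with homophily
re-weighting, adversarially regularized multi-channel GraphSAGE
training, and the two-pass re-weighted prediction) and returns a results
object carrying the predicted compositions, the training trajectory and
diagnostics, with ``summary()`` and ``evaluate()`` on top.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import embed_ae, graphs as graphmod, training
from .io_data import (ProportionMatrix, ProteinMatrix,
                      align_shared_features, minmax_scale_features,
                      select_top_variance_features, write_proportions)
from .metrics import MetricReport, evaluate
from .pseudobulk import PseudoBulkSet
from .synthetic import SyntheticSpec, make_benchmark_pair
from .training import TrainConfig, TrainedModel

logger = logging.getLogger(__name__)


@dataclass
class GraphDECModel:
    """Cell-type deconvolution model for a labeled reference and a target.

    Parameters
    ----------
    reference
        Labeled pseudo-bulk reference (expression + true compositions).
    target
        Target expression matrix to deconvolve (samples x proteins).
    k_neighbors
        Neighbours per node in the similarity graphs.
    latent_dim
        Autoencoder bottleneck width used only for graph construction.
    hidden_dim, n_channels
        GraphSAGE channel width and number of independent channels.
    top_k_features
        If set, keep only the k highest-variance shared features
        (variance measured on the reference).
    minmax_scale
        Optional per-feature min-max scaling; the raw pathway is default.
    ablation
        Subset of {"gnn", "triplet", "reweight"} to disable.
    """

    reference: PseudoBulkSet
    target: ProteinMatrix
    k_neighbors: int = graphmod.DEFAULT_K_NEIGHBORS
    latent_dim: int = embed_ae.DEFAULT_LATENT_DIM
    ae_epochs: int = embed_ae.DEFAULT_EPOCHS
    hidden_dim: int = 256
    n_channels: int = 3
    fixed_fusion: bool = False
    weighted_aggregation: bool = True
    top_k_features: int | None = None
    minmax_scale: bool = False
    ablation: tuple[str, ...] = ()

    def __post_init__(self):
        for comp in self.ablation:
            if comp not in training.ABLATION_COMPONENTS:
                raise ValueError(f"unknown ablation component {comp!r}")

    # -- constructors --------------------------------------------------
    @classmethod
    def from_single_cells(cls, sc: ProteinMatrix, annotation, target,
                          n_samples: int = 2000, cells_per_sample: int = 50,
                          seed: int = 0, **kwargs) -> "GraphDECModel":
        """Build the reference by pseudo-bulk mixup from labeled cells."""
        from .pseudobulk import generate_pseudobulk

        ref = generate_pseudobulk(sc, annotation, n_samples,
                                  cells_per_sample, seed=seed)
        return cls(reference=ref, target=target, **kwargs)

    @classmethod
    def from_synthetic(cls, spec: SyntheticSpec | None = None,
                       n_ref_samples: int = 2000, n_tgt_samples: int = 500,
                       cells_per_sample: int = 50,
                       **kwargs) -> tuple["GraphDECModel", ProportionMatrix]:
        """Standard synthetic benchmark; returns (model, held-out truth)."""
        spec = spec or SyntheticSpec()
        ref, tgt = make_benchmark_pair(spec, n_ref_samples, n_tgt_samples,
                                       cells_per_sample)
        return cls(reference=ref, target=tgt.expr, **kwargs), tgt.props

    # -- fitting ---------------------------------------------------------
    def fit(self, config: TrainConfig | None = None,
            seed: int | None = None, **config_overrides) -> "GraphDECResults":
        """Run the full pipeline and return a results object."""
        if config is None:
            config = TrainConfig(**config_overrides)
        elif config_overrides:
            from dataclasses import replace

            config = replace(config, **config_overrides)
        if seed is not None:
            from dataclasses import replace

            config = replace(config, seed=seed)

        ref_expr, tgt_expr = align_shared_features(self.reference.expr,
                                                   self.target)
        if self.top_k_features is not None:
            ref_expr, tgt_expr = select_top_variance_features(
                ref_expr, tgt_expr, self.top_k_features)
        if self.minmax_scale:
            ref_expr, tgt_expr = minmax_scale_features(ref_expr, tgt_expr)
        ref = PseudoBulkSet(ref_expr, self.reference.props,
                            self.reference.cells_per_sample,
                            self.reference.seed)

        # Stage 1b: frozen autoencoder -> latents -> similarity graphs
        ae = embed_ae.train_autoencoder(ref_expr, tgt_expr,
                                        latent_dim=self.latent_dim,
                                        epochs=self.ae_epochs,
                                        seed=config.seed)
        z_ref = embed_ae.encode(ref_expr, ae)
        z_tgt = embed_ae.encode(tgt_expr, ae)
        similarity = {
            "reference": graphmod.pairwise_cosine(z_ref.Z),
            "target": graphmod.pairwise_cosine(z_tgt.Z),
            "joint": graphmod.pairwise_cosine(np.vstack([z_ref.Z, z_tgt.Z])),
        }
        g_ref = graphmod.build_knn_graph(z_ref, self.k_neighbors, "reference",
                                         node_ids=ref_expr.sample_ids)
        g_tgt = graphmod.build_knn_graph(z_tgt, self.k_neighbors, "target",
                                         node_ids=tgt_expr.sample_ids)
        g_joint = graphmod.build_joint_graph(z_ref, z_tgt, self.k_neighbors,
                                             ref_ids=ref_expr.sample_ids,
                                             tgt_ids=tgt_expr.sample_ids)

        reweight_enabled = "reweight" not in self.ablation
        if reweight_enabled:
            g_ref_final = graphmod.reweight_edges(g_ref, ref.props)
        else:
            g_ref_final = g_ref

        gnn_kwargs = dict(hidden_dim=self.hidden_dim,
                          n_channels=self.n_channels,
                          fixed_fusion=self.fixed_fusion,
                          weighted_aggregation=self.weighted_aggregation,
                          use_graph="gnn" not in self.ablation)
        if "triplet" in self.ablation:
            from dataclasses import replace

            config = replace(config, alpha=0.0)

        trained = training.fit(
            ref, tgt_expr,
            graphs={"reference": g_ref_final, "target": g_tgt, "joint": g_joint},
            config=config, similarity=similarity,
            reweight_enabled=reweight_enabled, gnn_kwargs=gnn_kwargs,
            dtype=np.float32)  # single precision: training is CPU-bound

        proportions = training.predict(trained, tgt_expr, g_tgt)
        return GraphDECResults(
            model=self, trained=trained, proportions=proportions,
            autoencoder=ae, graphs={"reference": g_ref_final, "target": g_tgt,
                                    "joint": g_joint},
            latent_reference=z_ref.Z, latent_target=z_tgt.Z,
            config=config)


@dataclass
class GraphDECResults:
    """Fitted pipeline: predictions, diagnostics, training history."""

    model: GraphDECModel
    trained: TrainedModel
    proportions: ProportionMatrix
    autoencoder: embed_ae.AutoencoderState
    graphs: dict
    latent_reference: np.ndarray
    latent_target: np.ndarray
    config: TrainConfig
    _embeddings_cache: dict = field(default_factory=dict, repr=False)

    @property
    def history(self) -> pd.DataFrame:
        return pd.DataFrame(self.trained.history)

    def target_embeddings(self) -> np.ndarray:
        """Z_GNN of the target samples under the fitted parameters."""
        return self._domain_embeddings("target")

    def reference_embeddings(self) -> np.ndarray:
        return self._domain_embeddings("reference")

    def _domain_embeddings(self, which: str) -> np.ndarray:
        if which not in self._embeddings_cache:
            from ._autodiff import Tensor
            from .gnn_core import gnn_forward

            X = (self.model.target.values if which == "target"
                 else self.model.reference.expr.values)
            # features may have been subset during fit; recompute alignment
            n_feat = self.trained.state.input_dim
            if X.shape[1] != n_feat:
                ref_expr, tgt_expr = align_shared_features(
                    self.model.reference.expr, self.model.target)
                if self.model.top_k_features is not None:
                    ref_expr, tgt_expr = select_top_variance_features(
                        ref_expr, tgt_expr, self.model.top_k_features)
                X = tgt_expr.values if which == "target" else ref_expr.values
            X = X.astype(self.trained.state.head_W1.data.dtype)
            z = gnn_forward(Tensor(X), self.graphs[which], self.trained.state)
            self._embeddings_cache[which] = z.data
        return self._embeddings_cache[which]

    def discriminator_balanced_accuracy(self) -> float:
        """Chance level (~0.5) indicates the embedding carries no batch signal."""
        from .gnn_core import domain_discriminator

        d_ref = domain_discriminator(self.trained.state,
                                     self.reference_embeddings()).data.ravel()
        d_tgt = domain_discriminator(self.trained.state,
                                     self.target_embeddings()).data.ravel()
        return 0.5 * (float((d_ref >= 0.5).mean()) + float((d_tgt < 0.5).mean()))

    def evaluate(self, truth: ProportionMatrix) -> MetricReport:
        """Score predictions against held-out target compositions."""
        return evaluate(self.proportions, truth)

    def save_proportions(self, path) -> None:
        write_proportions(self.proportions, path)

    def summary(self, truth: ProportionMatrix | None = None) -> str:
        """Human-readable fit summary table."""
        hist = self.history
        lines = [
            "GraphDEC deconvolution results",
            "=" * 46,
            f"{'reference samples':<30}{self.model.reference.expr.n_samples:>16}",
            f"{'target samples':<30}{self.proportions.n_samples:>16}",
            f"{'shared features used':<30}{self.trained.state.input_dim:>16}",
            f"{'cell types':<30}{len(self.proportions.type_universe):>16}",
            f"{'channels x hidden dim':<30}"
            f"{f'{self.trained.state.n_channels} x {self.trained.state.hidden_dim}':>16}",
            f"{'k neighbours':<30}{self.model.k_neighbors:>16}",
            f"{'iterations run':<30}{len(hist):>16}",
            f"{'best iteration':<30}{self.trained.best_iteration:>16}",
            f"{'best validation CCC':<30}{self.trained.best_val_ccc:>16.4f}",
            f"{'final L_dec':<30}{hist['L_dec'].iloc[-1]:>16.4f}",
            f"{'final L_tri':<30}{hist['L_tri'].iloc[-1]:>16.4f}",
            f"{'final L_dom':<30}{hist['L_dom'].iloc[-1]:>16.4f}",
            f"{'ablation':<30}{','.join(self.model.ablation) or 'none':>16}",
        ]
        if truth is not None:
            report = self.evaluate(truth)
            lines += [
                "-" * 46,
                f"{'target sample CCC (mean)':<30}"
                f"{report.aggregate['sample_ccc']:>16.4f}",
                f"{'target sample RMSE (mean)':<30}"
                f"{report.aggregate['sample_rmse']:>16.4f}",
                f"{'target sample PCC (mean)':<30}"
                f"{report.aggregate['sample_pcc']:>16.4f}",
            ]
        lines.append("=" * 46)
        return "\n".join(lines)

    def plot_loss(self, ax=None):
        """Training losses and validation CCC over iterations."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        hist = self.history
        for col in ("L_dec", "L_tri", "val_ccc"):
            if col in hist:
                ax.plot(hist["iteration"], hist[col], label=col)
        ax.set_xlabel("iteration")
        ax.legend()
        return ax

    def save(self, out_dir) -> None:
        """Checkpoint: one npz archive of arrays + JSON hyperparameter sidecar."""
        from pathlib import Path

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        arrays = {}
        st = self.trained.state
        for c, ch in enumerate(st.channels):
            for l, W in enumerate(ch.W):
                arrays[f"ch{c}_W{l}"] = W.data
            arrays[f"ch{c}_fusion"] = ch.fusion_logits.data
        for name in ("head_W1", "head_b1", "head_W2", "head_b2",
                     "disc_W1", "disc_b1", "disc_W2", "disc_b2"):
            arrays[name] = getattr(st, name).data
        for i, (w, b) in enumerate(zip(self.autoencoder.encoder_weights,
                                       self.autoencoder.encoder_biases)):
            arrays[f"ae_enc_W{i}"], arrays[f"ae_enc_b{i}"] = w, b
        for i, (w, b) in enumerate(zip(self.autoencoder.decoder_weights,
                                       self.autoencoder.decoder_biases)):
            arrays[f"ae_dec_W{i}"], arrays[f"ae_dec_b{i}"] = w, b
        np.savez(out_dir / "checkpoint.npz", **arrays)
        import json

        ref_expr, tgt_expr = align_shared_features(self.model.reference.expr,
                                                   self.model.target)
        if self.model.top_k_features is not None:
            ref_expr, tgt_expr = select_top_variance_features(
                ref_expr, tgt_expr, self.model.top_k_features)
        meta = {
            "feature_ids": ref_expr.feature_ids,
            "type_universe": self.trained.type_universe,
            "k_neighbors": self.model.k_neighbors,
            "latent_dim": self.model.latent_dim,
            "hidden_dim": self.trained.state.hidden_dim,
            "n_channels": self.trained.state.n_channels,
            "n_layers": self.trained.state.n_layers,
            "n_ae_enc_layers": len(self.autoencoder.encoder_weights),
            "fixed_fusion": self.trained.state.fixed_fusion,
            "use_graph": self.trained.state.use_graph,
            "weighted_aggregation": self.trained.state.weighted_aggregation,
            "reweight_enabled": self.trained.reweight_enabled,
        }
        (out_dir / "hyperparameters.json").write_text(json.dumps(meta, indent=2))

    def plot_concordance(self, truth: ProportionMatrix, ax=None):
        """Predicted vs true proportions scatter, one point per entry."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(truth.values.ravel(), self.proportions.values.ravel(),
                   s=4, alpha=0.4)
        ax.plot([0, 1], [0, 1], "k--", lw=1)
        ax.set_xlabel("true proportion")
        ax.set_ylabel("predicted proportion")
        return ax


@dataclass
class LoadedPipeline:
    """A checkpointed pipeline restored for prediction on new targets."""

    state: "object"
    autoencoder: embed_ae.AutoencoderState
    feature_ids: list[str]
    type_universe: list[str]
    k_neighbors: int
    reweight_enabled: bool

    def predict(self, target: ProteinMatrix) -> ProportionMatrix:
        missing = set(self.feature_ids) - set(target.feature_ids)
        if missing:
            raise ValueError(
                f"target lacks {len(missing)} features the model was "
                f"trained on, e.g. {sorted(missing)[:3]}")
        tgt = target.subset_features(self.feature_ids)
        z = embed_ae.encode(tgt, self.autoencoder)
        g_t = graphmod.build_knn_graph(z, self.k_neighbors, "target",
                                       node_ids=tgt.sample_ids)
        trained = TrainedModel(state=self.state,
                               type_universe=list(self.type_universe),
                               config=TrainConfig(),
                               reweight_enabled=self.reweight_enabled)
        return training.predict(trained, tgt, g_t)


def load_pipeline(checkpoint_dir) -> LoadedPipeline:
    """Restore a pipeline saved with :meth:`GraphDECResults.save`."""
    import json
    from pathlib import Path

    from ._autodiff import Tensor
    from .gnn_core import ChannelParams, GnnModelState

    checkpoint_dir = Path(checkpoint_dir)
    meta = json.loads((checkpoint_dir / "hyperparameters.json").read_text())
    arrays = np.load(checkpoint_dir / "checkpoint.npz")

    channels = []
    for c in range(meta["n_channels"]):
        W = [Tensor(arrays[f"ch{c}_W{l}"], requires_grad=True)
             for l in range(meta["n_layers"])]
        channels.append(ChannelParams(
            W=W, fusion_logits=Tensor(arrays[f"ch{c}_fusion"],
                                      requires_grad=True)))
    state = GnnModelState(
        channels=channels,
        head_W1=Tensor(arrays["head_W1"], requires_grad=True),
        head_b1=Tensor(arrays["head_b1"], requires_grad=True),
        head_W2=Tensor(arrays["head_W2"], requires_grad=True),
        head_b2=Tensor(arrays["head_b2"], requires_grad=True),
        disc_W1=Tensor(arrays["disc_W1"], requires_grad=True),
        disc_b1=Tensor(arrays["disc_b1"], requires_grad=True),
        disc_W2=Tensor(arrays["disc_W2"], requires_grad=True),
        disc_b2=Tensor(arrays["disc_b2"], requires_grad=True),
        input_dim=len(meta["feature_ids"]),
        n_types=len(meta["type_universe"]),
        hidden_dim=meta["hidden_dim"], n_layers=meta["n_layers"],
        fixed_fusion=meta["fixed_fusion"], use_graph=meta["use_graph"],
        weighted_aggregation=meta["weighted_aggregation"])
    n_enc = meta["n_ae_enc_layers"]
    ae = embed_ae.AutoencoderState(
        encoder_weights=[arrays[f"ae_enc_W{i}"] for i in range(n_enc)],
        encoder_biases=[arrays[f"ae_enc_b{i}"] for i in range(n_enc)],
        decoder_weights=[arrays[f"ae_dec_W{i}"] for i in range(n_enc)],
        decoder_biases=[arrays[f"ae_dec_b{i}"] for i in range(n_enc)],
        latent_dim=meta["latent_dim"])
    return LoadedPipeline(state=state, autoencoder=ae,
                          feature_ids=meta["feature_ids"],
                          type_universe=meta["type_universe"],
                          k_neighbors=meta["k_neighbors"],
                          reweight_enabled=meta["reweight_enabled"])
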