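"""Synthetic single-cell proteomics pools with controlled batch effects.

Protein abundances are modelled as log-normal: each cell type k has an
archetype log-mean vector drawn once per seed, and a cell from batch b
measures  scale_b * exp(log mu_k + shift_b + eps)  with per-protein
additive log-shift and multiplicative scale shared within a batch, i.i.d.
Gaussian cell noise, and Bernoulli dropout to zero. Two batches with
different shifts emulate the run/technology batch effect between a
labeled reference and an unlabeled target; pseudo-bulk sets built from
each batch give a benchmark whose target truth is known but used only
for evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_data import CellTypeAnnotation, ProteinMatrix, REFERENCE, TARGET
from .pseudobulk import PseudoBulkSet, generate_pseudobulk

#: desk-scale defaults: 4 cell types, 200 proteins, 2000 reference and
#: 500 target pseudo-samples of 50 cells each (the large-scale protocol
#: uses 20000/4000; this preserves its structure at tractable size)
DEFAULT_BENCHMARK = dict(n_ref_samples=2000, n_tgt_samples=500,
                         cells_per_sample=50)


@dataclass
class SyntheticSpec:
    """Knobs of the generator; defaults define the standard benchmark."""

    n_types: int = 4
    n_proteins: int = 200
    cells_per_type_per_batch: int = 400
    archetype_scale: float = 1.0   # sd of archetype log-means (separation)
    noise_sd: float = 0.35         # per-cell log-normal noise
    batch_shift_sd: float = 0.4    # per-protein additive log-shift per batch
    batch_scale_range: tuple[float, float] = (0.8, 1.25)
    dropout_rate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if min(self.n_types, self.n_proteins, self.cells_per_type_per_batch) <= 0:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.archetype_scale <= 0 or self.noise_sd < 0 or self.batch_shift_sd < 0:
            raise ValueError("scales must be non-negative (archetype_scale > 0)")
        lo, hi = self.batch_scale_range
        if not 0 < lo <= hi:
            raise ValueError("batch_scale_range must be a positive interval")


def _archetypes(spec: SyntheticSpec) -> np.ndarray:
    """Per-type log-mean vectors, drawn once per seed."""
    rng = np.random.default_rng([spec.seed, 7919])
    return rng.normal(0.0, spec.archetype_scale,
                      size=(spec.n_types, spec.n_proteins))


def simulate_cells(spec: SyntheticSpec,
                   batch_id: int = 0) -> tuple[ProteinMatrix, CellTypeAnnotation]:
    """Simulate one batch of labeled single cells, deterministic per (seed, batch)."""
    log_mu = _archetypes(spec)
    batch_rng = np.random.default_rng([spec.seed, 104729, batch_id])
    shift = batch_rng.normal(0.0, spec.batch_shift_sd, size=spec.n_proteins)
    scale = batch_rng.uniform(*spec.batch_scale_range, size=spec.n_proteins)

    n_cells = spec.n_types * spec.cells_per_type_per_batch
    cell_rng = np.random.default_rng([spec.seed, 1299709, batch_id])
    labels = np.repeat(np.arange(spec.n_types), spec.cells_per_type_per_batch)
    eps = cell_rng.normal(0.0, spec.noise_sd, size=(n_cells, spec.n_proteins))
    values = scale * np.exp(log_mu[labels] + shift + eps)
    if spec.dropout_rate > 0:
        keep = cell_rng.random(values.shape) >= spec.dropout_rate
        values = values * keep

    type_names = [f"type_{k}" for k in range(spec.n_types)]
    cell_ids = [f"b{batch_id}_c{i}" for i in range(n_cells)]
    expr = ProteinMatrix(values, cell_ids,
                         [f"prot_{j}" for j in range(spec.n_proteins)],
                         REFERENCE if batch_id == 0 else TARGET)
    ann = CellTypeAnnotation(cell_ids, [type_names[k] for k in labels],
                             type_names)
    return expr, ann


def make_benchmark_pair(spec: SyntheticSpec,
                        n_ref_samples: int = DEFAULT_BENCHMARK["n_ref_samples"],
                        n_tgt_samples: int = DEFAULT_BENCHMARK["n_tgt_samples"],
                        cells_per_sample: int = DEFAULT_BENCHMARK["cells_per_sample"],
                        ) -> tuple[PseudoBulkSet, PseudoBulkSet]:
    """Reference (batch 0) and target (batch 1) pseudo-bulk benchmark sets.

    The target's ground-truth compositions are retained on the returned
    set for evaluation only; the pipeline never reads them.
    """
    ref_cells, ref_ann = simulate_cells(spec, batch_id=0)
    tgt_cells, tgt_ann = simulate_cells(spec, batch_id=1)
    ref = generate_pseudobulk(ref_cells, ref_ann, n_ref_samples,
                              cells_per_sample, seed=spec.seed * 2 + 1,
                              domain=REFERENCE)
    tgt = generate_pseudobulk(tgt_cells, tgt_ann, n_tgt_samples,
                              cells_per_sample, seed=spec.seed * 2 + 2,
                              domain=TARGET)
    return ref, tgt
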