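"""Pseudo-bulk mixup: build bulk-like samples from labeled single cells.

Each pseudo-sample is the arithmetic mean of a random combination of
single cells; its ground-truth composition is the realized count of each
cell type divided by the total number of cells in the combination. The
composition of each draw comes from a flat Dirichlet over the cell types
followed by a multinomial allocation, so compositions cover the simplex
uniformly on average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_data import (CellTypeAnnotation, ProportionMatrix, ProteinMatrix,
                      REFERENCE)

#: pseudo-sample sizes used by the standard mixup protocols
PROTOCOL_CELL_COUNTS = (15, 50, 200)
DEFAULT_CELLS_PER_SAMPLE = 50


@dataclass
class PseudoBulkSet:
    """Paired expression and ground-truth proportions for pseudo-samples."""

    expr: ProteinMatrix
    props: ProportionMatrix
    cells_per_sample: int
    seed: int
    cell_indices: list[np.ndarray] | None = None  # constituents per sample

    def __post_init__(self):
        if self.expr.sample_ids != self.props.sample_ids:
            raise ValueError("expr and props must share sample ids and order")


def make_pseudo_sample(cells: ProteinMatrix, labels: CellTypeAnnotation,
                       chosen_indices) -> tuple[np.ndarray, np.ndarray]:
    """Average the chosen cells and count their type composition.

    Returns the mean expression vector and the proportion vector
    (count of each type / number of chosen cells).
    """
    idx = np.asarray(chosen_indices, dtype=int)
    if idx.size == 0:
        raise ValueError("chosen_indices must be non-empty")
    if idx.min() < 0 or idx.max() >= cells.n_samples:
        raise IndexError("chosen_indices out of range")
    expression = cells.values[idx].mean(axis=0)
    type_idx = labels.label_indices()[idx]
    counts = np.bincount(type_idx, minlength=labels.n_types).astype(float)
    return expression, counts / idx.size


def generate_pseudobulk(sc: ProteinMatrix, ann: CellTypeAnnotation,
                        n_samples: int,
                        cells_per_sample: int = DEFAULT_CELLS_PER_SAMPLE,
                        seed: int = 0,
                        alpha: float = 1.0,
                        domain: str = REFERENCE,
                        keep_indices: bool = False) -> PseudoBulkSet:
    """Generate a reproducible set of pseudo-bulk samples.

    Composition sampling: a proportion vector is drawn from a symmetric
    Dirichlet(alpha) over the annotated cell types, cells_per_sample cells
    are allocated to types by a multinomial on that vector, and cells are
    drawn uniformly within each type (without replacement when the type
    pool is large enough, with replacement otherwise). The recorded
    proportions are the realized cell-count ratios, not the Dirichlet draw.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if cells_per_sample <= 0:
        raise ValueError("cells_per_sample must be positive")
    if sc.n_samples < cells_per_sample:
        raise ValueError(
            f"need at least {cells_per_sample} cells, got {sc.n_samples}")
    if len(ann.cell_ids) != sc.n_samples:
        raise ValueError("annotation must cover every cell")

    rng = np.random.default_rng(seed)
    type_idx = ann.label_indices()
    pools = [np.flatnonzero(type_idx == k) for k in range(ann.n_types)]
    present = [k for k, p in enumerate(pools) if p.size > 0]
    if not present:
        raise ValueError("no annotated cells")

    expr = np.empty((n_samples, sc.n_features))
    props = np.empty((n_samples, ann.n_types))
    all_indices: list[np.ndarray] = []
    for i in range(n_samples):
        frac = np.zeros(ann.n_types)
        frac[present] = rng.dirichlet(np.full(len(present), alpha))
        counts = rng.multinomial(cells_per_sample, frac)
        chosen = []
        for k in np.flatnonzero(counts):
            pool = pools[k]
            replace = pool.size < counts[k]
            chosen.append(rng.choice(pool, size=counts[k], replace=replace))
        idx = np.concatenate(chosen)
        all_indices.append(idx)
        expr[i], props[i] = make_pseudo_sample(sc, ann, idx)

    ids = [f"pseudo_{seed}_{i}" for i in range(n_samples)]
    return PseudoBulkSet(
        expr=ProteinMatrix(expr, ids, list(sc.feature_ids), domain),
        props=ProportionMatrix(props, ids, list(ann.type_universe)),
        cells_per_sample=cells_per_sample,
        seed=seed,
        cell_indices=all_indices if keep_indices else None,
    )
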