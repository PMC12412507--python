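"""Expression-matrix containers and I/O.

The pipeline moves three kinds of tables around: protein-abundance
matrices (samples x proteins) tagged with their domain of origin
(reference or target), per-cell type annotations, and cell-type
proportion matrices whose rows are compositions (non-negative, summing
to one). Loading supports delimited text, AnnData (h5ad) and MatrixMarket
with sidecar id files; missing entries are imputed to zero and counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REFERENCE = "reference"
TARGET = "target"
_DOMAINS = (REFERENCE, TARGET)

PROPORTION_TOL = 1e-6


class ValidationError(ValueError):
    """Raised when a container violates its invariants."""


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dupes[:5]}")
    return ids


@dataclass
class ProteinMatrix:
    """Samples x proteins abundance matrix with a domain tag."""

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    domain: str
    imputed_count: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.domain not in _DOMAINS:
            raise ValidationError(f"domain must be one of {_DOMAINS}")
        self.sample_ids = _check_unique(self.sample_ids, "sample_ids")
        self.feature_ids = _check_unique(self.feature_ids, "feature_ids")
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if not np.isfinite(self.values).all():
            raise ValidationError("values must be finite (impute at load time)")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def subset_features(self, feature_ids: Sequence[str]) -> "ProteinMatrix":
        pos = {f: j for j, f in enumerate(self.feature_ids)}
        idx = [pos[f] for f in feature_ids]
        return ProteinMatrix(
            self.values[:, idx], list(self.sample_ids), list(feature_ids),
            self.domain, self.imputed_count,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.feature_ids)


@dataclass
class CellTypeAnnotation:
    """Per-cell type labels over an ordered universe of type names."""

    cell_ids: list[str]
    labels: list[str]
    type_universe: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.cell_ids = _check_unique(self.cell_ids, "cell_ids")
        self.labels = [str(l) for l in self.labels]
        if len(self.labels) != len(self.cell_ids):
            raise ValidationError("labels and cell_ids must have equal length")
        if self.type_universe is None:
            self.type_universe = sorted(set(self.labels))
        self.type_universe = _check_unique(self.type_universe, "type_universe")
        unknown = set(self.labels) - set(self.type_universe)
        if unknown:
            raise ValidationError(f"labels outside type_universe: {sorted(unknown)}")

    @property
    def n_types(self) -> int:
        return len(self.type_universe)

    def label_indices(self) -> np.ndarray:
        pos = {t: k for k, t in enumerate(self.type_universe)}
        return np.array([pos[l] for l in self.labels], dtype=int)


@dataclass
class ProportionMatrix:
    """Samples x cell-types composition matrix; rows sum to one."""

    values: np.ndarray
    sample_ids: list[str]
    type_universe: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = _check_unique(self.sample_ids, "sample_ids")
        self.type_universe = _check_unique(self.type_universe, "type_universe")
        if self.values.shape != (len(self.sample_ids), len(self.type_universe)):
            raise ValidationError("proportion matrix shape inconsistent with ids")
        if (self.values < -PROPORTION_TOL).any():
            raise ValidationError("proportions must be non-negative")
        sums = self.values.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=PROPORTION_TOL):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValidationError(
                f"row {self.sample_ids[bad]} sums to {sums[bad]:.6g}, expected 1"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.type_universe)


# ---------------------------------------------------------------------------
# loading / writing


def _from_frame(df: pd.DataFrame, domain: str) -> ProteinMatrix:
    values = df.to_numpy(dtype=float)
    n_missing = int(np.count_nonzero(~np.isfinite(values)))
    if n_missing:
        logger.info("imputed %d missing entries to 0", n_missing)
        values = np.nan_to_num(values, nan=0.0, posinf=0.0, neginf=0.0)
    return ProteinMatrix(values, [str(i) for i in df.index],
                         [str(c) for c in df.columns], domain,
                         imputed_count=n_missing)


def load_expression(path, format: str | None = None,
                    domain: str = REFERENCE) -> ProteinMatrix:
    """Load an expression matrix from csv/tsv/h5ad/mtx.

    Missing values (empty cells, NaN) are imputed to 0; the count is
    recorded on the returned matrix and logged.
    """
    path = Path(path)
    if format is None:
        format = {".csv": "csv", ".tsv": "tsv", ".h5ad": "h5ad",
                  ".mtx": "mtx"}.get(path.suffix.lower())
        if format is None:
            raise ValueError(f"cannot infer format from suffix {path.suffix!r}")
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:  # noqa: BLE001 - re-raise with context
            raise ValueError(f"cannot parse {path} as {format}: {exc}") from exc
        return _from_frame(df, domain)
    if format == "h5ad":
        import anndata as ad

        adata = ad.read_h5ad(path)
        x = adata.X
        if not isinstance(x, np.ndarray):
            x = x.toarray()
        df = pd.DataFrame(x, index=adata.obs_names, columns=adata.var_names)
        return _from_frame(df, domain)
    if format == "mtx":
        from scipy.io import mmread

        values = np.asarray(mmread(path).todense(), dtype=float)
        rows = _read_id_sidecar(path.with_suffix(".rows.txt"))
        cols = _read_id_sidecar(path.with_suffix(".cols.txt"))
        return _from_frame(pd.DataFrame(values, index=rows, columns=cols), domain)
    raise ValueError(f"unsupported format {format!r}")


def _read_id_sidecar(path: Path) -> list[str]:
    if not path.exists():
        raise FileNotFoundError(f"MTX sidecar id file missing: {path}")
    return [line.strip() for line in path.read_text().splitlines() if line.strip()]


def write_expression(pm: ProteinMatrix, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".h5ad":
        import anndata as ad

        adata = ad.AnnData(X=pm.values.copy())
        adata.obs_names = pm.sample_ids
        adata.var_names = pm.feature_ids
        adata.write_h5ad(path)
    else:
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        pm.to_frame().to_csv(path, sep=sep)


def load_annotation(path) -> CellTypeAnnotation:
    """Read a two-column TSV (cell_id, cell_type), no header required."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("annotation file needs two columns: cell_id, cell_type")
    if list(df.iloc[0]) == ["cell_id", "cell_type"]:
        df = df.iloc[1:]
    return CellTypeAnnotation(df.iloc[:, 0].tolist(), df.iloc[:, 1].tolist())


def write_annotation(ann: CellTypeAnnotation, path) -> None:
    pd.DataFrame({"cell_id": ann.cell_ids, "cell_type": ann.labels}).to_csv(
        path, sep="\t", header=False, index=False)


def write_proportions(props: ProportionMatrix, path) -> None:
    """Write a proportion matrix as a delimited table (header + index)."""
    # re-validate: refuses rows that do not sum to one
    ProportionMatrix(props.values, props.sample_ids, props.type_universe)
    sep = "\t" if Path(path).suffix.lower() == ".tsv" else ","
    props.to_frame().to_csv(path, sep=sep)


def load_proportions(path) -> ProportionMatrix:
    sep = "\t" if Path(path).suffix.lower() == ".tsv" else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return ProportionMatrix(df.to_numpy(dtype=float),
                            [str(i) for i in df.index],
                            [str(c) for c in df.columns])


# ---------------------------------------------------------------------------
# feature alignment


def align_shared_features(ref: ProteinMatrix,
                          tgt: ProteinMatrix) -> tuple[ProteinMatrix, ProteinMatrix]:
    """Restrict both matrices to their shared features, in canonical order.

    The shared feature set is sorted lexicographically so the operation is
    deterministic and idempotent.
    """
    shared = sorted(set(ref.feature_ids) & set(tgt.feature_ids))
    if not shared:
        raise ValidationError(
            f"no shared features between reference ({ref.n_features}) "
            f"and target ({tgt.n_features})"
        )
    return ref.subset_features(shared), tgt.subset_features(shared)


def select_top_variance_features(ref: ProteinMatrix, tgt: ProteinMatrix,
                                 k: int) -> tuple[ProteinMatrix, ProteinMatrix]:
    """Keep the k features with the highest variance on the reference.

    Ties are broken by lexicographic feature id; both matrices are subset
    identically, preserving the variance ranking order.
    """
    if k <= 0:
        raise ValidationError("k must be a positive integer")
    if set(ref.feature_ids) != set(tgt.feature_ids):
        ref, tgt = align_shared_features(ref, tgt)
    if k > ref.n_features:
        raise ValidationError(f"k={k} exceeds {ref.n_features} shared features")
    variances = ref.values.var(axis=0)
    order = sorted(range(ref.n_features),
                   key=lambda j: (-variances[j], ref.feature_ids[j]))
    keep = [ref.feature_ids[j] for j in order[:k]]
    return ref.subset_features(keep), tgt.subset_features(keep)


def minmax_scale_features(ref: ProteinMatrix,
                          tgt: ProteinMatrix) -> tuple[ProteinMatrix, ProteinMatrix]:
    """Optional per-feature min-max scaling fitted on the concatenated data.

    Off by default throughout the pipeline: raw abundances are the default
    pathway and no log transform is applied.
    """
    stacked = np.vstack([ref.values, tgt.values])
    lo = stacked.min(axis=0)
    span = stacked.max(axis=0) - lo
    span[span == 0] = 1.0

    def _scale(pm: ProteinMatrix) -> ProteinMatrix:
        return ProteinMatrix((pm.values - lo) / span, list(pm.sample_ids),
                             list(pm.feature_ids), pm.domain, pm.imputed_count)

    return _scale(ref), _scale(tgt)
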