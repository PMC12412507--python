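"""Deconvolution accuracy metrics: CCC, RMSE, PCC.

Lin's concordance correlation coefficient (CCC) is the headline metric:
it rewards both correlation and agreement in location/scale,

    CCC = 2 rho sigma_y sigma_yhat / (sigma_y^2 + sigma_yhat^2 + (mu_y - mu_yhat)^2),

computed with population (divide-by-N) variances by default. Reports are
produced both per sample (across the cell types of one composition) and
per cell type (across samples), plus unweighted aggregate means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_data import ProportionMatrix


class UndefinedMetricError(ValueError):
    """Raised when a correlation metric is undefined (constant input)."""


def _validate_pair(y, y_hat, min_len: int = 2):
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.shape != y_hat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {y_hat.shape}")
    if y.size < min_len:
        raise ValueError(f"need at least {min_len} values, got {y.size}")
    return y, y_hat


def pcc(y, y_hat) -> float:
    """Pearson correlation; errors out if either vector is constant."""
    y, y_hat = _validate_pair(y, y_hat)
    sy = y.std()
    sy_hat = y_hat.std()
    if sy == 0.0 or sy_hat == 0.0:
        raise UndefinedMetricError("PCC undefined for constant input")
    cov = ((y - y.mean()) * (y_hat - y_hat.mean())).mean()
    return float(np.clip(cov / (sy * sy_hat), -1.0, 1.0))


def ccc(y, y_hat, sample_variance: bool = False) -> float:
    """Lin's concordance correlation coefficient.

    Population standard deviations by default; set ``sample_variance`` for
    the divide-by-(N-1) convention.
    """
    y, y_hat = _validate_pair(y, y_hat)
    ddof = 1 if sample_variance else 0
    vy = y.var(ddof=ddof)
    vy_hat = y_hat.var(ddof=ddof)
    if vy == 0.0 and vy_hat == 0.0:
        raise UndefinedMetricError("CCC undefined when both vectors are constant")
    cov = ((y - y.mean()) * (y_hat - y_hat.mean())).sum() / (y.size - ddof)
    denom = vy + vy_hat + (y.mean() - y_hat.mean()) ** 2
    return float(np.clip(2.0 * cov / denom, -1.0, 1.0))


def rmse(y, y_hat) -> float:
    """Root mean squared error."""
    y, y_hat = _validate_pair(y, y_hat, min_len=1)
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


@dataclass
class MetricReport:
    """Per-sample, per-cell-type and aggregate CCC/RMSE/PCC tables."""

    per_sample: pd.DataFrame
    per_celltype: pd.DataFrame | None
    aggregate: dict[str, float]

    def to_json_dict(self) -> dict:
        return {
            "aggregate": self.aggregate,
            "per_sample": self.per_sample.to_dict(orient="index"),
            "per_celltype": (self.per_celltype.to_dict(orient="index")
                             if self.per_celltype is not None else None),
        }


def _metric_row(y, y_hat) -> dict[str, float]:
    row = {"rmse": rmse(y, y_hat)}
    try:
        row["ccc"] = ccc(y, y_hat)
    except UndefinedMetricError:
        row["ccc"] = np.nan
    try:
        row["pcc"] = pcc(y, y_hat)
    except UndefinedMetricError:
        row["pcc"] = np.nan
    return row


def evaluate(pred: ProportionMatrix, truth: ProportionMatrix) -> MetricReport:
    """Score predictions against ground truth in both orientations.

    Per-sample metrics run across the cell-type entries of each row;
    per-cell-type metrics run across samples for each column (requires at
    least two samples, otherwise that table is omitted with an error when
    explicitly requested). Aggregates are unweighted means ignoring
    undefined (NaN) correlation entries.
    """
    if pred.sample_ids != truth.sample_ids:
        raise ValueError("prediction and truth sample_ids differ")
    if pred.type_universe != truth.type_universe:
        raise ValueError("prediction and truth cell-type universes differ")

    per_sample = pd.DataFrame(
        [_metric_row(truth.values[i], pred.values[i])
         for i in range(pred.n_samples)],
        index=pred.sample_ids)

    per_celltype = None
    if pred.n_samples >= 2:
        per_celltype = pd.DataFrame(
            [_metric_row(truth.values[:, k], pred.values[:, k])
             for k in range(len(pred.type_universe))],
            index=pred.type_universe)

    aggregate = {f"sample_{m}": float(per_sample[m].mean(skipna=True))
                 for m in ("ccc", "rmse", "pcc")}
    if per_celltype is not None:
        aggregate.update({f"celltype_{m}": float(per_celltype[m].mean(skipna=True))
                          for m in ("ccc", "rmse", "pcc")})
    return MetricReport(per_sample=per_sample, per_celltype=per_celltype,
                        aggregate=aggregate)


def per_celltype_or_error(pred: ProportionMatrix,
                          truth: ProportionMatrix) -> pd.DataFrame:
    """Per-cell-type table, erroring clearly on single-sample input."""
    if pred.n_samples < 2:
        raise ValueError(
            "per-cell-type metrics need at least 2 samples "
            f"(got {pred.n_samples}); only the per-sample view is defined")
    return evaluate(pred, truth).per_celltype
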