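"""Expression filtering, normalization and site (batch) correction.

The processing chain is strict and stage-tagged:

``counts -> cpm -> log2 -> adjusted``

* counts-per-million: cpm(g, s) = counts(g, s) / total_s * 1e6;
* gene filter: keep a gene iff cpm > 1 in at least 50% of subjects, the gene
  is mapped to a chromosome, and the chromosome is not Y;
* log2 transform with a pseudo-count offset (default 1, recorded);
* site correction with a parametric empirical-Bayes location/scale model
  (the ComBat algorithm): per-gene standardization, shrinkage of per-batch
  means and variances across genes toward common priors, removal of the
  shrunken batch effects, and restoration of the grand mean and pooled
  scale. A non-EB per-batch standardization is available as a fallback.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneAnnotation",
    "StageError",
    "DataError",
    "to_cpm",
    "filter_genes",
    "log2_transform",
    "batch_adjust",
    "CPM_THRESHOLD",
    "CPM_FRACTION",
]

logger = logging.getLogger(__name__)

CPM_THRESHOLD = 1.0
CPM_FRACTION = 0.5  # "50% or more" of subjects

_STAGES = ("counts", "cpm", "log2", "adjusted")


class StageError(ValueError):
    """Operation applied at the wrong processing stage."""


class DataError(ValueError):
    """Malformed or inconsistent expression/metadata input."""


@dataclass
class ExpressionMatrix:
    """Gene x subject expression values with a processing-stage flag.

    ``data`` is a DataFrame with gene ids as the index and subject ids as
    columns. ``provenance`` accumulates a record of the transforms applied.
    """

    data: pd.DataFrame
    stage: str = "counts"
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.stage not in _STAGES:
            raise StageError(f"unknown stage {self.stage!r}; expected one of {_STAGES}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][:5].tolist()
            raise DataError(f"duplicate gene ids: {dup}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][:5].tolist()
            raise DataError(f"duplicate subject ids: {dup}")
        if self.stage == "counts" and (self.data.to_numpy() < 0).any():
            raise DataError("counts must be non-negative")

    @property
    def gene_ids(self):
        return self.data.index

    @property
    def subject_ids(self):
        return self.data.columns

    def _require_stage(self, *stages: str) -> None:
        if self.stage not in stages:
            raise StageError(
                f"operation requires stage in {stages}, matrix is at {self.stage!r}"
            )


@dataclass
class GeneAnnotation:
    """gene_id -> chromosome mapping; genes absent from it count as unmapped."""

    table: pd.DataFrame  # columns: gene_id, chromosome

    def __post_init__(self) -> None:
        missing = {"gene_id", "chromosome"} - set(self.table.columns)
        if missing:
            raise DataError(f"annotation missing columns: {sorted(missing)}")
        if self.table["gene_id"].duplicated().any():
            raise DataError("duplicate gene ids in annotation")

    def chromosome_of(self) -> pd.Series:
        return self.table.set_index("gene_id")["chromosome"]


def to_cpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Counts-per-million normalization; column sums become 1e6."""
    matrix._require_stage("counts")
    totals = matrix.data.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise DataError(f"subjects with zero total counts: {zero.index.tolist()}")
    cpm = matrix.data / totals * 1e6
    return ExpressionMatrix(cpm, "cpm", matrix.provenance + ["cpm"])


def filter_genes(
    matrix: ExpressionMatrix, annotation: GeneAnnotation
) -> list[str]:
    """Gene ids passing the detection/annotation filter, in matrix order.

    Keep a gene iff cpm > 1 in >= 50% of subjects, the gene is mapped (has
    an annotation row with a non-null chromosome), and chromosome != Y.
    """
    matrix._require_stage("cpm")
    frac = (matrix.data > CPM_THRESHOLD).mean(axis=1)
    chrom = annotation.chromosome_of().reindex(matrix.gene_ids)
    unmapped = chrom.isna()
    if unmapped.any():
        logger.info("dropping %d unmapped genes", int(unmapped.sum()))
    keep = (frac >= CPM_FRACTION) & ~unmapped & (chrom.astype("string") != "Y")
    return matrix.gene_ids[keep.to_numpy()].tolist()


def log2_transform(matrix: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """log2(cpm + offset); the offset is recorded in provenance."""
    matrix._require_stage("cpm")
    if (matrix.data.to_numpy() < 0).any():
        raise DataError("negative cpm values")
    out = np.log2(matrix.data + offset)
    return ExpressionMatrix(out, "log2", matrix.provenance + [f"log2(cpm+{offset:g})"])


def batch_adjust(
    matrix: ExpressionMatrix,
    batches: Sequence[str],
    empirical_bayes: bool = True,
) -> ExpressionMatrix:
    """Remove additive/multiplicative batch (site) effects.

    With ``empirical_bayes`` (default) this is the parametric ComBat model:
    batch means and variances of the standardized data are shrunk across
    genes toward normal / inverse-gamma priors before removal. With
    ``empirical_bayes=False``, each batch is simply standardized to the
    pooled location/scale per gene (no shrinkage).

    A single batch is a no-op (copy). Every batch needs >= 2 subjects.
    """
    matrix._require_stage("log2", "adjusted")
    batches = pd.Series(list(batches), index=matrix.subject_ids, dtype="string")
    if batches.isna().any():
        raise DataError("every subject needs a batch label")
    levels = batches.unique().tolist()
    sizes = batches.value_counts()
    small = sizes[sizes < 2]
    if len(small):
        raise DataError(f"batches with < 2 subjects: {small.index.tolist()}")
    if len(levels) == 1:
        return ExpressionMatrix(
            matrix.data.copy(), "adjusted", matrix.provenance + ["batch:noop"]
        )

    X = matrix.data.to_numpy(dtype=float)
    G, N = X.shape
    masks = [(batches == b).to_numpy() for b in levels]
    n_b = np.array([m.sum() for m in masks])

    batch_means = np.stack([X[:, m].mean(axis=1) for m in masks])  # (B, G)
    grand = (n_b / N) @ batch_means  # per-gene weighted grand mean
    resid = X.copy()
    for i, m in enumerate(masks):
        resid[:, m] -= batch_means[i][:, None]
    var_pooled = (resid**2).mean(axis=1)  # 1/N, as in the reference algorithm
    var_pooled = np.where(var_pooled <= 0, 1e-12, var_pooled)
    sd = np.sqrt(var_pooled)

    s_data = (X - grand[:, None]) / sd[:, None]

    adj = np.empty_like(s_data)
    method = "combat-eb" if empirical_bayes else "batch-standardize"
    for i, m in enumerate(masks):
        sb = s_data[:, m]
        gamma_hat = sb.mean(axis=1)
        delta_hat = sb.var(axis=1, ddof=1)
        if empirical_bayes:
            gamma_star, delta_star = _eb_shrink(sb, gamma_hat, delta_hat)
        else:
            gamma_star, delta_star = gamma_hat, delta_hat
        adj[:, m] = (sb - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]

    out = adj * sd[:, None] + grand[:, None]
    df = pd.DataFrame(out, index=matrix.gene_ids, columns=matrix.subject_ids)
    return ExpressionMatrix(df, "adjusted", matrix.provenance + [f"batch:{method}"])


def _eb_shrink(
    sb: np.ndarray, gamma_hat: np.ndarray, delta_hat: np.ndarray, conv: float = 1e-4
) -> tuple[np.ndarray, np.ndarray]:
    """Parametric EB posterior means for one batch (normal / inverse-gamma).

    Iterates the standard coupled update: the batch mean shrinks toward the
    across-gene mean with weight n*tau2 / (n*tau2 + delta*), and the batch
    variance toward the inverse-gamma prior fit by moment matching.
    """
    n = sb.shape[1]
    gamma_bar = gamma_hat.mean()
    tau2 = gamma_hat.var(ddof=1)
    m = delta_hat.mean()
    s2 = delta_hat.var(ddof=1)
    if s2 <= 0 or tau2 <= 0:
        return gamma_hat, delta_hat
    a_prior = (2 * s2 + m**2) / s2
    b_prior = (m * s2 + m**3) / s2

    g_old = gamma_hat.copy()
    d_old = delta_hat.copy()
    for _ in range(200):
        g_new = (tau2 * n * gamma_hat + d_old * gamma_bar) / (tau2 * n + d_old)
        sum2 = ((sb - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sum2 + b_prior) / (n / 2.0 + a_prior - 1.0)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old
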