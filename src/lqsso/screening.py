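"""Two-stage gene screening: variance filter, then marginal-correlation top-k.

This is the preprocessing used to shrink an expression matrix (samples x
genes) to a design of tractable width before penalized regression: keep the
k1 genes with the largest expression variance, then keep the k2 of those
with the largest absolute Pearson correlation with a target transcript.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike, NDArray

__all__ = ["ExpressionMatrix", "variance_screen", "correlation_screen"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExpressionMatrix:
    """An n-samples x G-genes expression table with unique labels."""

    values: NDArray[np.float64]
    gene_ids: tuple
    sample_ids: tuple

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be 2-dimensional (samples x genes)")
        if np.any(~np.isfinite(v)):
            raise ValueError("expression values must be finite (no missing)")
        genes = tuple(self.gene_ids)
        samples = tuple(self.sample_ids)
        if len(genes) != v.shape[1]:
            raise ValueError("gene_ids length does not match columns")
        if len(samples) != v.shape[0]:
            raise ValueError("sample_ids length does not match rows")
        if len(set(genes)) != len(genes) or len(set(samples)) != len(samples):
            raise ValueError("gene and sample labels must be unique")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "gene_ids", genes)
        object.__setattr__(self, "sample_ids", samples)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), tuple(df.columns),
                   tuple(df.index))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.sample_ids),
                            columns=list(self.gene_ids))

    def subset(self, keep: NDArray[np.int64]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[:, keep],
                                tuple(self.gene_ids[j] for j in keep),
                                self.sample_ids)


def _topk_stable(scores: NDArray[np.float64], k: int) -> NDArray[np.int64]:
    """Indices of the k largest scores; ties keep the original gene order."""
    # stable sort on (-score) preserves original order within ties
    order = np.argsort(-scores, kind="stable")
    return np.sort(order[:k])


def variance_screen(expr: ExpressionMatrix, k: int) -> ExpressionMatrix:
    """Keep the k genes with the largest sample variance (n-1 denominator)."""
    if not 1 <= k <= expr.n_genes:
        raise ValueError(f"k must lie in [1, {expr.n_genes}], got {k}")
    variances = expr.values.var(axis=0, ddof=1)
    return expr.subset(_topk_stable(variances, k))


def correlation_screen(expr: ExpressionMatrix, target: ArrayLike,
                       k: int) -> ExpressionMatrix:
    """Keep the k genes with the largest |Pearson correlation| with target.

    Zero-variance genes get correlation 0 (logged); the target must vary.
    """
    if not 1 <= k <= expr.n_genes:
        raise ValueError(f"k must lie in [1, {expr.n_genes}], got {k}")
    t = np.asarray(target, dtype=float).ravel()
    if t.shape[0] != expr.n_samples:
        raise ValueError("target length does not match number of samples")
    t_sd = t.std()
    if t_sd == 0:
        raise ValueError("target has zero variance")
    tc = (t - t.mean()) / t_sd
    V = expr.values
    Vc = V - V.mean(axis=0)
    sd = V.std(axis=0)
    flat = sd == 0
    if np.any(flat):
        logger.warning("%d zero-variance gene(s) assigned correlation 0",
                       int(flat.sum()))
        sd = np.where(flat, 1.0, sd)
    corr = (Vc / sd).T @ tc / expr.n_samples
    corr[flat] = 0.0
    return expr.subset(_topk_stable(np.abs(corr), k))
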