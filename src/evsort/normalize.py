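"""Library-size normalization, variant-gene selection, and sample PCA.

Size factors follow the median-of-ratios convention: each sample's factor
is the median, over genes with a positive geometric mean, of the ratio of
its count to that gene's across-sample geometric mean, rescaled so the
factors themselves have geometric mean 1.  Normalized values are simple
shifted logs, ``log2(count/factor + pseudocount)``; the downstream
statistics are correlation- and rank-based and tolerate the absence of
variance-stabilizing shrinkage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["NormalizedMatrix", "PCAResult", "size_factors", "log_normalize",
           "top_variant_genes", "pca"]


@dataclass
class NormalizedMatrix:
    """Log2-scale normalized expression (genes x samples)."""

    values: pd.DataFrame
    size_factors: pd.Series
    pseudocount: float = 1.0


@dataclass
class PCAResult:
    scores: pd.DataFrame          # samples x components
    loadings: pd.DataFrame        # selected genes x components
    variance_explained: np.ndarray  # percent, non-increasing
    selected_genes: list


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample, geometric mean 1.

    Falls back to total-count scaling (with a warning) when no gene has a
    positive geometric mean across all samples.
    """
    x = counts.to_numpy(float)
    with np.errstate(divide="ignore"):
        log_gm = np.log(x).mean(axis=1)
    ok = np.isfinite(log_gm)
    if not ok.any():
        log.warning("no gene expressed in all samples; "
                    "falling back to total-count size factors")
        totals = x.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("sample with zero total counts")
        factors = totals
    else:
        ratios = x[ok] / np.exp(log_gm[ok])[:, None]
        factors = np.median(ratios, axis=0)
    if (factors <= 0).any():
        raise ValueError("non-positive size factor; check input counts")
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def log_normalize(counts: pd.DataFrame, factors: pd.Series,
                  pseudocount: float = 1.0) -> NormalizedMatrix:
    """``log2(count/factor + pseudocount)`` per gene and sample."""
    factors = factors.reindex(counts.columns)
    if factors.isna().any() or (factors <= 0).any():
        raise ValueError("size factors must be positive and cover all samples")
    values = np.log2(counts.to_numpy(float) / factors.to_numpy()[None, :]
                     + pseudocount)
    return NormalizedMatrix(
        values=pd.DataFrame(values, index=counts.index, columns=counts.columns),
        size_factors=factors, pseudocount=pseudocount,
    )


def top_variant_genes(norm: NormalizedMatrix, n: int = 500) -> list:
    """Genes ordered by decreasing sample variance; ties broken by gene id."""
    if n > norm.values.shape[0]:
        raise ValueError(f"n={n} exceeds number of genes {norm.values.shape[0]}")
    var = norm.values.var(axis=1, ddof=1)
    order = sorted(var.index, key=lambda g: (-var[g], g))
    return order[:n]


def pca(norm: NormalizedMatrix, genes: list | None = None,
        n_components: int | None = None) -> PCAResult:
    """Sample-space PCA of the centered selected-genes submatrix.

    Each gene is centered across samples; the SVD of the samples x genes
    centered matrix gives scores (samples x components) and loadings.
    Component signs are fixed so the largest-magnitude loading of each
    component is positive.  Degenerate all-equal input yields zero scores
    and 0% variance explained.
    """
    values = norm.values if genes is None else norm.values.loc[list(genes)]
    if values.shape[1] < 2:
        raise ValueError("PCA requires at least 2 samples")
    x = values.to_numpy(float).T                 # samples x genes
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(len(s), n_components) if n_components else len(s)
    u, s, vt = u[:, :k], s[:k], vt[:k]
    # sign convention: largest-|loading| entry positive
    for j in range(k):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    total = float(np.sum(s ** 2))
    var_exp = (100.0 * s ** 2 / total) if total > 0 else np.zeros(k)
    comp = [f"PC{j + 1}" for j in range(k)]
    return PCAResult(
        scores=pd.DataFrame(u * s, index=values.columns, columns=comp),
        loadings=pd.DataFrame(vt.T, index=values.index, columns=comp),
        variance_explained=var_exp,
        selected_genes=list(values.index),
    )
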