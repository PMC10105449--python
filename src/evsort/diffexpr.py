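"""Two-group negative-binomial Wald differential expression.

A deliberately simple, calibration-oriented test: per gene, group means of
size-factor-normalized counts, a pooled method-of-moments dispersion
``alpha = (var - mean)/mean^2`` (floored at 0, the Poisson limit, and
capped at 10), and a Wald statistic on the log2 fold change with a
delta-method standard error.  This is a stand-in for a full factorial
GLM fit; its claims are type-I-error calibration and planted-effect
recovery, not equivalence to any particular GLM implementation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = ["bh_adjust", "nb_wald_test"]

DISPERSION_CAP = 10.0
MEAN_FLOOR = 0.5  # pseudo normalized counts added to group means


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving.

    NaN inputs are excluded from the ranking and propagated as NaN.
    """
    p = np.asarray(p_values, float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not ok.any():
        return out
    if ok.size != ok.sum():
        log.warning("bh_adjust: %d NaN p-values excluded", ok.size - ok.sum())
    q = p[ok]
    m = q.size
    order = np.argsort(q, kind="stable")
    ranked = q[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


def nb_wald_test(counts: pd.DataFrame, factors: pd.Series,
                 group_labels: pd.Series) -> pd.DataFrame:
    """Per-gene Wald test between the two levels of ``group_labels``.

    Returns a DataFrame indexed by gene with columns ``log2FC`` (level1 -
    level2, levels in sorted order so the contrast is deterministic),
    ``SE``, ``stat``, ``pvalue``, ``padj``, ``baseMean``, and an
    ``all_zero`` flag.  Genes with zero counts everywhere get p = 1.
    """
    group_labels = pd.Series(group_labels)
    if isinstance(group_labels.index, pd.RangeIndex):
        group_labels.index = counts.columns
    levels = sorted(pd.unique(group_labels.dropna()))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 group levels, got {levels}")
    norm = counts.to_numpy(float) / factors.reindex(counts.columns).to_numpy()[None, :]
    labels = group_labels.reindex(counts.columns).to_numpy()
    masks = [labels == lv for lv in levels]
    if any(m.sum() < 2 for m in masks):
        raise ValueError("each group needs at least 2 samples")
    if any(norm[:, m].sum() == 0 for m in masks):
        raise ValueError("group with all-zero library")

    means, variances, ns = [], [], []
    for m in masks:
        sub = norm[:, m]
        means.append(sub.mean(axis=1))
        variances.append(sub.var(axis=1, ddof=1))
        ns.append(int(m.sum()))
    m1, m2 = means
    v1, v2 = variances
    n1, n2 = ns

    # pooled method-of-moments dispersion, clipped to [0, 10]
    with np.errstate(divide="ignore", invalid="ignore"):
        a1 = (v1 - m1) / m1 ** 2
        a2 = (v2 - m2) / m2 ** 2
    stacked = np.stack([a1, a2])
    valid = np.isfinite(stacked)
    alpha = (np.where(valid, stacked, 0.0).sum(axis=0)
             / np.maximum(valid.sum(axis=0), 1))
    alpha = np.clip(np.nan_to_num(alpha), 0.0, DISPERSION_CAP)

    m1f = m1 + MEAN_FLOOR
    m2f = m2 + MEAN_FLOOR
    lfc = np.log2(m1f) - np.log2(m2f)
    ln2sq = np.log(2.0) ** 2
    var_lfc = ((m1f + alpha * m1f ** 2) / (n1 * m1f ** 2 * ln2sq)
               + (m2f + alpha * m2f ** 2) / (n2 * m2f ** 2 * ln2sq))
    se = np.sqrt(var_lfc)
    stat = np.where(se > 0, lfc / se, 0.0)
    pvalue = 2.0 * stats.norm.sf(np.abs(stat))

    all_zero = norm.sum(axis=1) == 0
    pvalue = np.where(all_zero, 1.0, pvalue)
    stat = np.where(all_zero, 0.0, stat)
    lfc = np.where(all_zero, 0.0, lfc)

    return pd.DataFrame({
        "log2FC": lfc, "SE": se, "stat": stat, "pvalue": pvalue,
        "padj": bh_adjust(pvalue), "baseMean": norm.mean(axis=1),
        "all_zero": all_zero,
    }, index=counts.index)
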