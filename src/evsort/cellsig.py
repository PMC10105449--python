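"""Composite gene-signature scoring of single cells.

Each cell is scored by the sum (or mean) of its log-normalized values
over a signature gene set; cells with a composite score strictly above a
threshold (default log2(4)) are called "expressing", and per-cluster
expressing fractions summarize where in a tissue the signature's
cells-of-origin reside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["CellScores", "normalize_cells", "composite_score",
           "call_expressing", "DEFAULT_THRESHOLD"]

DEFAULT_THRESHOLD = float(np.log2(4.0))  # the "> log2 4" cutoff


@dataclass
class CellScores:
    scores: pd.Series               # per cell, log2 scale
    expressing: pd.Series | None = None
    clusters: pd.Series | None = None

    def cluster_fractions(self) -> pd.DataFrame:
        if self.expressing is None or self.clusters is None:
            raise ValueError("call_expressing with cluster labels first")
        df = pd.DataFrame({"cluster": self.clusters,
                           "expressing": self.expressing})
        out = df.groupby("cluster")["expressing"].agg(["sum", "count", "mean"])
        out.columns = ["n_expressing", "n_cells", "fraction"]
        return out


def normalize_cells(counts: pd.DataFrame, scale: float = 10_000.0) -> pd.DataFrame:
    """Depth-normalized log values: ``log2(1 + scale * count/total)``.

    Zero-total cells are dropped with a warning.
    """
    totals = counts.sum(axis=0)
    zero = totals == 0
    if zero.any():
        log.warning("dropping %d zero-total cells", int(zero.sum()))
        counts = counts.loc[:, ~zero]
        totals = totals[~zero]
    values = np.log2(1.0 + scale * counts.to_numpy(float)
                     / totals.to_numpy()[None, :])
    return pd.DataFrame(values, index=counts.index, columns=counts.columns)


def composite_score(normalized: pd.DataFrame, gene_set,
                    agg: str = "sum") -> CellScores:
    """Per-cell composite score over ``gene_set`` (sum or mean)."""
    gene_set = list(dict.fromkeys(gene_set))
    present = [g for g in gene_set if g in normalized.index]
    missing = len(gene_set) - len(present)
    if not present:
        raise ValueError("no signature gene found in the matrix")
    if missing:
        log.warning("%d signature genes absent from the matrix", missing)
    sub = normalized.loc[present]
    if agg == "sum":
        scores = sub.sum(axis=0)
    elif agg == "mean":
        scores = sub.mean(axis=0)
    else:
        raise ValueError("agg must be 'sum' or 'mean'")
    return CellScores(scores=scores.rename("composite_score"))


def call_expressing(scores: CellScores, clusters: pd.Series | None = None,
                    threshold: float = DEFAULT_THRESHOLD) -> CellScores:
    """Flag cells with score strictly above ``threshold``.

    Returns a new CellScores with the flag and, when cluster labels are
    supplied, enables per-cluster fraction tables.
    """
    expressing = scores.scores > threshold
    clusters = clusters if clusters is not None else scores.clusters
    if clusters is not None:
        clusters = clusters.reindex(scores.scores.index)
    return CellScores(scores=scores.scores,
                      expressing=expressing.rename("expressing"),
                      clusters=clusters)
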