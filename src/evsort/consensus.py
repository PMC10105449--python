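"""Two-set consensus co-expression network analysis.

A consensus module is a gene cluster that is highly interconnected in
both data sets (here: EV samples and cell samples).  The consensus TOM
is the element-wise minimum after quantile scaling of the second set's
TOM onto the first's; module correspondence between two assignments is
cross-tabulated with Fisher's exact test; and the per-set module-trait
tables are combined with the min-abs/NA rule: when both sets agree in
sign the weaker correlation is kept, when they disagree the relationship
is declared undetermined (NA).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["consensus_tom", "module_overlap_fisher",
           "combined_trait_relationship", "summarize_combined",
           "CorrespondenceTable", "CombinedTraitTable"]


@dataclass
class CorrespondenceTable:
    counts: pd.DataFrame      # A modules x B modules overlap gene counts
    fisher_p: pd.DataFrame    # same shape, two-sided Fisher exact p
    sizes_a: pd.Series
    sizes_b: pd.Series

    @property
    def neg_log10_p(self) -> pd.DataFrame:
        return -np.log10(self.fisher_p.clip(lower=1e-300))


@dataclass
class CombinedTraitTable:
    values: pd.DataFrame        # module x trait, NaN encodes 'NA'
    significant_a: pd.DataFrame  # bool flags, set A (e.g. EV)
    significant_b: pd.DataFrame  # bool flags, set B (e.g. Cell)


def consensus_tom(tom_a: pd.DataFrame, tom_b: pd.DataFrame,
                  scale_quantile: float = 0.95) -> pd.DataFrame:
    """Element-wise minimum of quantile-scaled TOMs.

    ``tom_b`` is power-transformed so that its ``scale_quantile``
    off-diagonal quantile matches ``tom_a``'s, then the element-wise
    minimum is taken; the diagonal is reset to 1.
    """
    if list(tom_a.index) != list(tom_b.index):
        diff = set(tom_a.index) ^ set(tom_b.index)
        raise ValueError(f"gene universes differ (or are ordered "
                         f"differently): {sorted(diff)[:10]}")
    a = tom_a.to_numpy(float)
    b = tom_b.to_numpy(float)
    off = ~np.eye(len(a), dtype=bool)
    qa = np.quantile(a[off], scale_quantile)
    qb = np.quantile(b[off], scale_quantile)
    if 0 < qb < 1 and 0 < qa < 1:
        b = b ** (np.log(qa) / np.log(qb))
    cons = np.minimum(a, b)
    np.fill_diagonal(cons, 1.0)
    return pd.DataFrame(cons, index=tom_a.index, columns=tom_a.columns)


def module_overlap_fisher(assign_a: pd.Series,
                          assign_b: pd.Series) -> CorrespondenceTable:
    """Cross-tabulate two module assignments with Fisher exact tests.

    For each module pair the 2x2 table (in both, A only, B only,
    neither) over the shared gene universe yields a two-sided Fisher
    exact p (sum of all hypergeometric outcomes no more probable than
    the observed one).
    """
    assign_a = pd.Series(assign_a)
    assign_b = pd.Series(assign_b).reindex(assign_a.index)
    if assign_b.isna().any() or len(assign_a) == 0:
        raise ValueError("assignments must share a non-empty gene universe")
    n = len(assign_a)
    mods_a = sorted(assign_a.unique())
    mods_b = sorted(assign_b.unique())
    counts = pd.DataFrame(0, index=mods_a, columns=mods_b, dtype=int)
    for (ma, mb), sub in pd.DataFrame(
            {"a": assign_a, "b": assign_b}).groupby(["a", "b"]):
        counts.loc[ma, mb] = len(sub)
    sizes_a = counts.sum(axis=1)
    sizes_b = counts.sum(axis=0)
    pvals = counts.astype(float).copy()
    for ma in mods_a:
        for mb in mods_b:
            k = int(counts.loc[ma, mb])
            table = [[k, sizes_a[ma] - k],
                     [sizes_b[mb] - k, n - sizes_a[ma] - sizes_b[mb] + k]]
            pvals.loc[ma, mb] = stats.fisher_exact(table)[1]
    return CorrespondenceTable(counts, pvals, sizes_a, sizes_b)


def combined_trait_relationship(
    r_a: pd.DataFrame, p_a: pd.DataFrame,
    r_b: pd.DataFrame, p_b: pd.DataFrame,
    alpha: float = 0.05,
) -> CombinedTraitTable:
    """Min-abs/NA combination of two module-trait tables.

    Same sign in both sets -> shared sign times min(|r_a|, |r_b|);
    opposite signs, or either r exactly 0 while the other is not, ->
    NA (encoded NaN).  Per-set significance flags are carried so NA
    cells significant in one set can still be marked.
    """
    if list(r_a.index) != list(r_b.index) or list(r_a.columns) != list(r_b.columns):
        raise ValueError("module/trait sets differ between the two tables")
    a = r_a.to_numpy(float)
    b = r_b.to_numpy(float)
    same_sign = np.sign(a) * np.sign(b) > 0
    combined = np.where(same_sign,
                        np.sign(a) * np.minimum(np.abs(a), np.abs(b)),
                        np.nan)
    values = pd.DataFrame(combined, index=r_a.index, columns=r_a.columns)
    return CombinedTraitTable(
        values=values,
        significant_a=p_a < alpha,
        significant_b=p_b < alpha,
    )


def summarize_combined(table: CombinedTraitTable, trait: str) -> dict:
    """Counts of NA / NA-but-significant-in-one-set / same-sign modules."""
    col = table.values[trait]
    na = col.isna()
    sig_one = na & (table.significant_a[trait] | table.significant_b[trait])
    n = len(col)
    return {
        "trait": trait,
        "n_modules": n,
        "n_na": int(na.sum()),
        "n_na_significant_one_set": int(sig_one.sum()),
        "n_same_sign": int((~na).sum()),
        "frac_na": float(na.mean()) if n else float("nan"),
        "frac_same_sign": float((~na).mean()) if n else float("nan"),
    }
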