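"""Paired effect-size statistics for EV/cell cargo-sorting analysis.

Three-criteria gene selection for ethanol-vs-control comparisons: a
paired-samples t-test (p < 0.05), a Hedges' g effect size (|g| > 0.4),
and a 95% confidence interval for g that excludes zero.  Comparisons are
run within a compartment (EV or Cell) or on the per-pair EV:cell ratio
— the difference of log2-normalized values, whose paired dose contrast
cancels any shift shared by both compartments and thereby isolates
genuine sorting of transcripts into vesicles.

Pairing units are (pregnancy, sex) cells of the design: with three
pregnancies and two sexes each dose contrast rests on n = 6 pairs.

Hedges' g uses the difference-score standardizer: g = (mean(d)/sd(d)) * J
with the small-sample correction J = 1 - 3/(4(n-1) - 1), and a
normal-theory CI g +/- t_{0.975, n-1} * sqrt(1/n + g^2/(2n)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["hedges_g_paired", "paired_t_test", "ethanol_shift",
           "ev_cell_ratio_shift", "overlap_chi_square", "ShiftTable"]


def _as_frame(norm):
    """Accept a NormalizedMatrix-like object or a plain DataFrame."""
    if isinstance(norm, pd.DataFrame):
        return norm
    values = getattr(norm, "values", None)
    if isinstance(values, pd.DataFrame):
        return values
    raise TypeError("expected a DataFrame or an object with a .values frame")

P_THRESHOLD = 0.05
G_THRESHOLD = 0.4


@dataclass
class ShiftTable:
    """Per-gene paired-comparison records for one dose contrast."""

    records: pd.DataFrame   # gene-indexed: mean_shift, t, p, g, ci_low, ci_high, selected, direction
    comparison: str

    def summary(self) -> dict:
        sel = self.records[self.records["selected"]]
        n_up = int((sel["direction"] == "up").sum())
        n_down = int((sel["direction"] == "down").sum())
        total = int(len(sel))
        return {
            "comparison": self.comparison,
            "n_genes": int(len(self.records)),
            "n_selected": total,
            "n_increased": n_up,
            "n_decreased": n_down,
            "frac_increased": n_up / total if total else float("nan"),
            "frac_decreased": n_down / total if total else float("nan"),
        }


def hedges_g_paired(x, y, confidence: float = 0.95):
    """Hedges' g for paired samples with its normal-theory CI.

    Returns ``(g, ci_low, ci_high)``.  Degenerate input (zero variance of
    the differences) yields g = 0 with a zero-width CI; such genes carry
    a flag downstream and are never selected.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-d arrays, n >= 2")
    d = x - y
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        return 0.0, 0.0, 0.0
    j = 1.0 - 3.0 / (4.0 * (n - 1) - 1.0)
    g = float(d.mean() / sd * j)
    se = np.sqrt(1.0 / n + g ** 2 / (2.0 * n))
    tcrit = stats.t.ppf(0.5 + confidence / 2.0, n - 1)
    return g, float(g - tcrit * se), float(g + tcrit * se)


def paired_t_test(x, y):
    """Paired-samples t-test; returns ``(t, df, p)``.

    Zero variance of the differences yields t = 0, p = 1 (flagged
    degenerate by the callers).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-d arrays, n >= 2")
    d = x - y
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        return 0.0, n - 1, 1.0
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t), n - 1))
    return t, n - 1, p


def _paired_matrices(values: pd.DataFrame, meta: pd.DataFrame,
                     mask_treat, mask_ctrl, unit_cols=("pregnancy", "sex")):
    """Align treatment and control sample columns by pairing unit.

    Raises if any pairing unit lacks a sample on either side.
    """
    meta = meta.set_index("sample") if "sample" in meta.columns else meta

    def unit_map(mask):
        sub = meta[mask]
        units = list(zip(*(sub[c] for c in unit_cols)))
        if len(set(units)) != len(units):
            raise ValueError("duplicate samples per pairing unit")
        return dict(zip(units, sub.index))

    treat = unit_map(mask_treat)
    ctrl = unit_map(mask_ctrl)
    missing = set(treat) ^ set(ctrl)
    if missing:
        raise ValueError(f"incomplete pairing units: {sorted(missing)}")
    units = sorted(treat)
    xt = values[[treat[u] for u in units]].to_numpy(float)
    xc = values[[ctrl[u] for u in units]].to_numpy(float)
    return xt, xc, units


def _shift_records(xt: np.ndarray, xc: np.ndarray, index,
                   p_thr: float = P_THRESHOLD,
                   g_thr: float = G_THRESHOLD) -> pd.DataFrame:
    """Vectorized paired t / Hedges' g / CI over the rows of xt - xc."""
    d = xt - xc
    n = d.shape[1]
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    degenerate = sd == 0
    sd_safe = np.where(degenerate, 1.0, sd)

    t = mean / (sd_safe / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), n - 1)
    j = 1.0 - 3.0 / (4.0 * (n - 1) - 1.0)
    g = mean / sd_safe * j
    se = np.sqrt(1.0 / n + g ** 2 / (2.0 * n))
    tcrit = stats.t.ppf(0.975, n - 1)
    ci_low = g - tcrit * se
    ci_high = g + tcrit * se

    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    g = np.where(degenerate, 0.0, g)
    ci_low = np.where(degenerate, 0.0, ci_low)
    ci_high = np.where(degenerate, 0.0, ci_high)

    selected = ((p < p_thr) & (np.abs(g) > g_thr)
                & ((ci_low > 0) | (ci_high < 0)) & ~degenerate)
    return pd.DataFrame({
        "mean_shift": mean, "t": t, "p": p, "g": g,
        "ci_low": ci_low, "ci_high": ci_high, "n_pairs": n,
        "degenerate": degenerate, "selected": selected,
        "direction": np.where(mean >= 0, "up", "down"),
    }, index=index)


def ethanol_shift(norm, meta: pd.DataFrame, location: str, dose,
                  p_thr: float = P_THRESHOLD,
                  g_thr: float = G_THRESHOLD) -> ShiftTable:
    """Paired dose-vs-control comparison within one compartment.

    ``norm`` is a :class:`evsort.normalize.NormalizedMatrix` (or a plain
    log2-scale DataFrame).  Samples are paired across doses by their
    (pregnancy, sex) design cell.
    """
    values = _as_frame(norm)
    meta = meta.set_index("sample") if "sample" in meta.columns else meta
    if location not in ("EV", "Cell"):
        raise ValueError("location must be 'EV' or 'Cell'")
    loc = meta["location"] == location
    xt, xc, _ = _paired_matrices(values, meta,
                                 loc & (meta["dose"] == dose),
                                 loc & (meta["dose"] == 0))
    records = _shift_records(xt, xc, values.index, p_thr, g_thr)
    return ShiftTable(records, f"{location} dose {dose} vs 0")


def ev_cell_ratio_shift(norm, meta: pd.DataFrame, dose,
                        p_thr: float = P_THRESHOLD,
                        g_thr: float = G_THRESHOLD) -> ShiftTable:
    """Paired dose-vs-control comparison of the log EV:cell ratio.

    The ratio R = value(EV) - value(Cell) is formed per pair_id on the
    log2 scale; its dose contrast cancels any expression shift shared by
    both compartments, so selection here indicates sorting between
    compartments rather than overall up/down regulation.
    """
    values = _as_frame(norm)
    meta = meta.set_index("sample") if "sample" in meta.columns else meta
    pairs = {}
    for pair_id, sub in meta.groupby("pair_id"):
        by_loc = sub.groupby("location").groups
        if set(by_loc) != {"EV", "Cell"} or any(len(v) != 1 for v in by_loc.values()):
            raise ValueError(f"pair {pair_id!r} lacks exactly one EV and one Cell sample")
        pairs[pair_id] = (by_loc["EV"][0], by_loc["Cell"][0])
    ratio = pd.DataFrame(
        {pid: values[ev].to_numpy() - values[cell].to_numpy()
         for pid, (ev, cell) in pairs.items()},
        index=values.index,
    )
    pair_meta = (meta.drop_duplicates("pair_id").set_index("pair_id")
                 [["sex", "dose", "pregnancy"]])
    pair_meta.index.name = None
    pair_meta = pair_meta.loc[ratio.columns]
    pair_meta["sample"] = pair_meta.index
    xt, xc, _ = _paired_matrices(ratio, pair_meta,
                                 pair_meta["dose"] == dose,
                                 pair_meta["dose"] == 0)
    records = _shift_records(xt, xc, ratio.index, p_thr, g_thr)
    return ShiftTable(records, f"EV:cell ratio dose {dose} vs 0")


def overlap_chi_square(table):
    """Pearson chi-square (no continuity correction) on an RxC table.

    Returns ``(chi2, df, p)``; raises on zero margins.
    """
    tab = np.asarray(table, float)
    if tab.ndim != 2 or (tab < 0).any():
        raise ValueError("table must be a 2-d non-negative array")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined with a zero margin")
    chi2, p, df, _ = stats.chi2_contingency(tab, correction=False)
    return float(chi2), int(df), float(p)
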