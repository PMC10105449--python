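"""Signed weighted gene co-expression network analysis (WGCNA) core.

From correlation to modules: signed soft-threshold adjacency
``a_ij = ((1 + cor)/2)^beta``, topological overlap (TOM), average-linkage
hierarchical clustering of 1 - TOM with a static branch cut, eigengene
computation, iterative eigengene merging, module membership (kME),
gene/module significance against sample traits, and hub-gene calls.

Conventions (stated because implementations differ): the adjacency
diagonal is 0 when computing connectivity, the TOM diagonal is 1, and
the unsigned TOM formula is applied to the signed adjacency.  Module
labels come from a fixed color palette in decreasing size order, with
"grey" reserved for unassigned genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

log = logging.getLogger(__name__)

__all__ = [
    "NetworkConfig", "ModuleAssignment", "EigengeneMatrix",
    "adjacency_signed", "pick_soft_power", "tom_similarity",
    "detect_modules", "module_eigengenes", "correlation_with_p",
    "module_trait_relationships", "gene_and_module_significance",
    "hub_genes", "MODULE_COLORS", "encode_traits",
]


def _as_frame(norm):
    """Accept a NormalizedMatrix-like object or a plain DataFrame."""
    if isinstance(norm, pd.DataFrame):
        return norm
    values = getattr(norm, "values", None)
    if isinstance(values, pd.DataFrame):
        return values
    raise TypeError("expected a DataFrame or an object with a .values frame")

#: standard module color sequence, assigned in decreasing size order
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black",
    "pink", "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown",
    "steelblue", "paleturquoise", "violet", "darkolivegreen",
    "darkmagenta", "sienna", "yellowgreen", "skyblue2", "plum",
    "orangered", "mediumpurple", "lightsteelblue", "lightcoral",
    "ivory", "honeydew", "floralwhite", "brown2", "coral", "salmon4",
    "thistle", "navajowhite",
]
UNASSIGNED = "grey"


@dataclass(frozen=True)
class NetworkConfig:
    """Network construction parameters.

    ``soft_power`` defaults match a 36-sample joint analysis (14);
    single-compartment analyses conventionally use 9 and two-set
    consensus 6.  ``static_cut_height`` of None means 0.95 x the
    dendrogram's maximum merge height; cutting just below the top
    merges keeps weakly attached background genes out of the module
    branches.
    """

    soft_power: int = 14
    min_module_size: int = 30
    merge_cut_height: float = 0.20
    static_cut_height: float | None = None

    def __post_init__(self):
        if self.soft_power < 1:
            raise ValueError("soft_power must be >= 1")
        if not 0 < self.merge_cut_height < 1:
            raise ValueError("merge_cut_height must lie in (0, 1)")


@dataclass
class ModuleAssignment:
    labels: pd.Series            # gene -> color label
    dendrogram: np.ndarray       # scipy linkage matrix
    module_sizes: pd.Series = field(default=None)

    def __post_init__(self):
        if self.module_sizes is None:
            self.module_sizes = self.labels.value_counts()

    def modules(self) -> list:
        return [m for m in self.module_sizes.index if m != UNASSIGNED]

    def members(self, module: str) -> list:
        return list(self.labels.index[self.labels == module])


@dataclass
class EigengeneMatrix:
    eigengenes: pd.DataFrame     # samples x modules (column "ME<color>")
    kme: pd.DataFrame            # genes x modules

    def module_names(self) -> list:
        return [c[2:] for c in self.eigengenes.columns]


def _drop_zero_variance(values: pd.DataFrame) -> pd.DataFrame:
    var = values.to_numpy(float).var(axis=1)
    if (var == 0).any():
        dropped = values.index[var == 0]
        log.warning("dropping %d zero-variance genes from network", len(dropped))
        values = values.loc[var > 0]
    return values


def adjacency_signed(norm, beta: int) -> pd.DataFrame:
    """Signed adjacency ``((1 + cor)/2)^beta`` with zero diagonal."""
    values = _drop_zero_variance(_as_frame(norm))
    if values.shape[1] < 3:
        raise ValueError("adjacency requires at least 3 samples")
    cor = np.corrcoef(values.to_numpy(float))
    adj = ((1.0 + cor) / 2.0) ** beta
    np.fill_diagonal(adj, 0.0)
    return pd.DataFrame(adj, index=values.index, columns=values.index)


def pick_soft_power(norm, candidate_powers=(1, 2, 3, 4, 5, 6, 7, 8, 9, 10,
                                            12, 14, 16, 18, 20),
                    r2_target: float = 0.8, n_bins: int = 10):
    """Scale-free-topology power selection.

    For each candidate power the signed R^2 of log10 p(k) on log10 k over
    binned connectivities is computed; the smallest power reaching
    ``r2_target`` is chosen, or the argmax if none does.  Returns
    ``(power, fit_table)``.
    """
    candidate_powers = list(candidate_powers)
    if not candidate_powers:
        raise ValueError("candidate power list is empty")
    rows = []
    for beta in candidate_powers:
        adj = adjacency_signed(norm, beta).to_numpy()
        k = adj.sum(axis=1)
        rows.append({"power": beta, "signed_r2": _scale_free_fit(k, n_bins),
                     "mean_k": float(k.mean()), "max_k": float(k.max())})
    fit = pd.DataFrame(rows).set_index("power")
    ok = fit[fit["signed_r2"] >= r2_target]
    power = int(ok.index[0]) if len(ok) else int(fit["signed_r2"].idxmax())
    return power, fit


def _scale_free_fit(k: np.ndarray, n_bins: int) -> float:
    """Signed R^2 of the log-log frequency regression (NaN if degenerate)."""
    k = k[k > 0]
    if k.size < n_bins or np.allclose(k, k[0]):
        return float("nan")
    edges = np.linspace(k.min(), k.max() + 1e-9, n_bins + 1)
    which = np.digitize(k, edges) - 1
    xs, ys = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() > 0:
            xs.append(np.log10(k[sel].mean()))
            ys.append(np.log10(sel.mean()))
    if len(xs) < 3:
        return float("nan")
    slope, _, r, _, _ = stats.linregress(xs, ys)
    return float(-np.sign(slope) * r ** 2)


def tom_similarity(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap: shared-neighbor-weighted similarity in [0, 1].

    ``TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)``
    for i != j, with unit diagonal.
    """
    a = adjacency.to_numpy(float)
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    k = a.sum(axis=1)
    num = a @ a + a
    den = np.minimum.outer(k, k) + 1.0 - a
    tom = num / den
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def detect_modules(dissimilarity: pd.DataFrame, norm,
                   config: NetworkConfig) -> ModuleAssignment:
    """Average-linkage clustering of 1 - TOM with static cut and merging.

    Branches cut at ``static_cut_height`` become provisional modules;
    branches below ``min_module_size`` go to grey.  Provisional modules
    whose eigengenes are closer than ``merge_cut_height`` (dissimilarity
    1 - cor) are merged iteratively.  Labels are colors in decreasing
    size order.
    """
    d = dissimilarity.to_numpy(float).copy()
    np.fill_diagonal(d, 0.0)
    genes = dissimilarity.index
    z = linkage(squareform(d, checks=False), method="average")
    cut = (config.static_cut_height if config.static_cut_height is not None
           else 0.95 * z[:, 2].max())
    raw = fcluster(z, t=cut, criterion="distance")

    labels = pd.Series(UNASSIGNED, index=genes, dtype=object)
    sizes = pd.Series(raw).value_counts()
    keep = [c for c in sizes.index if sizes[c] >= config.min_module_size]
    for c in keep:
        labels[raw == c] = f"tmp{c}"
    if not keep:
        log.warning("no branch reached min_module_size; all genes grey")
        return ModuleAssignment(labels, z)

    values = _as_frame(norm).loc[genes]
    labels = _merge_by_eigengene(values, labels, config.merge_cut_height)
    labels = _relabel_colors(labels)
    return ModuleAssignment(labels, z)


def _merge_by_eigengene(values: pd.DataFrame, labels: pd.Series,
                        merge_cut_height: float) -> pd.Series:
    """Iteratively merge the closest eigengene pair while below the cut."""
    labels = labels.copy()
    while True:
        modules = sorted(set(labels) - {UNASSIGNED})
        if len(modules) < 2:
            return labels
        me = _eigengene_frame(values, labels, modules)
        cor = np.corrcoef(me.to_numpy().T)
        diss = 1.0 - cor
        np.fill_diagonal(diss, np.inf)
        i, j = np.unravel_index(np.argmin(diss), diss.shape)
        if diss[i, j] >= merge_cut_height:
            return labels
        labels[labels == modules[j]] = modules[i]


def _eigengene_frame(values: pd.DataFrame, labels: pd.Series,
                     modules: list) -> pd.DataFrame:
    cols = {}
    for m in modules:
        cols[m] = _first_pc(values.loc[labels.index[labels == m]])
    return pd.DataFrame(cols, index=values.columns)


def _first_pc(values: pd.DataFrame) -> np.ndarray:
    """Unit-variance first PC of standardized module expression,
    sign-aligned with the module's mean expression profile."""
    x = values.to_numpy(float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    xs = (x - mean) / sd
    if xs.shape[0] == 1:
        pc = xs[0]
    else:
        _, _, vt = np.linalg.svd(xs, full_matrices=False)
        pc = vt[0]
    ref = xs.mean(axis=0)
    if np.dot(pc, ref) < 0:
        pc = -pc
    sd_pc = pc.std(ddof=1)
    return pc / sd_pc if sd_pc > 0 else pc


def _relabel_colors(labels: pd.Series) -> pd.Series:
    sizes = labels[labels != UNASSIGNED].value_counts()
    mapping = {}
    for rank, (old, _) in enumerate(sizes.items()):
        mapping[old] = (MODULE_COLORS[rank] if rank < len(MODULE_COLORS)
                        else f"module{rank + 1}")
    return labels.map(lambda v: mapping.get(v, UNASSIGNED))


def module_eigengenes(norm, assignment: ModuleAssignment) -> EigengeneMatrix:
    """Per-module eigengenes (unit variance, sign-aligned) and kME.

    kME is the Pearson correlation of each gene's expression with each
    module eigengene (including non-member genes).
    """
    values = _as_frame(norm).loc[assignment.labels.index]
    modules = assignment.modules()
    if not modules:
        raise ValueError("no modules to compute eigengenes for")
    me = _eigengene_frame(values, assignment.labels, modules)
    me.columns = [f"ME{m}" for m in modules]

    x = values.to_numpy(float)
    xc = x - x.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(xc, axis=1)
    xn[xn == 0] = 1.0
    e = me.to_numpy()
    ec = e - e.mean(axis=0, keepdims=True)
    en = np.linalg.norm(ec, axis=0)
    kme = (xc @ ec) / np.outer(xn, en)
    return EigengeneMatrix(
        eigengenes=me,
        kme=pd.DataFrame(kme, index=values.index, columns=modules),
    )


def correlation_with_p(x, y, n: int | None = None):
    """Pearson r with the Student asymptotic two-sided p-value.

    ``t = r sqrt(n-2) / sqrt(1-r^2)``, df = n - 2.  |r| = 1 gives p = 0.
    ``x`` may be a plain correlation coefficient when ``n`` is given.
    """
    if y is None:
        if n is None:
            raise ValueError("pass two vectors, or (r, None, n)")
        r = float(x)
    else:
        xv = np.asarray(x, float)
        yv = np.asarray(y, float)
        n = xv.size
        if n < 3:
            raise ValueError("need n >= 3")
        if xv.std() == 0 or yv.std() == 0:
            return float("nan"), float("nan")
        r = float(np.corrcoef(xv, yv)[0, 1])
    if n is None or n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1.0:
        return float(np.sign(r)), 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r ** 2)
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return r, p


def encode_traits(meta: pd.DataFrame,
                  traits=("location", "sex", "pregnancy", "dose")) -> pd.DataFrame:
    """Numeric trait encodings: EV=1/Cell=0; F=1/M=0; pregnancy set
    number; alcohol dose in mg/dL.  Positive correlation then reads
    "higher in EV" / "higher in female"."""
    meta = meta.set_index("sample") if "sample" in meta.columns else meta
    cols = {}
    for t in traits:
        if t == "location" and "location" in meta:
            cols["Location"] = (meta["location"] == "EV").astype(float)
        elif t == "sex" and "sex" in meta:
            cols["Sex"] = (meta["sex"] == "F").astype(float)
        elif t == "pregnancy" and "pregnancy" in meta:
            cols["Pregnancy"] = meta["pregnancy"].astype(float)
        elif t == "dose" and "dose" in meta:
            cols["Alcohol"] = meta["dose"].astype(float)
    return pd.DataFrame(cols, index=meta.index)


def module_trait_relationships(eigengenes: EigengeneMatrix,
                               traits: pd.DataFrame):
    """(r, p) of every module eigengene against every numeric trait.

    Returns two DataFrames (r and p), modules x traits.  Constant traits
    give NaN columns.
    """
    me = eigengenes.eigengenes
    traits = traits.loc[me.index]
    r = pd.DataFrame(index=eigengenes.module_names(), columns=traits.columns,
                     dtype=float)
    p = r.copy()
    for mcol, mname in zip(me.columns, eigengenes.module_names()):
        for tcol in traits.columns:
            tv = traits[tcol].to_numpy(float)
            if np.std(tv) == 0:
                log.warning("trait %s is constant; correlations set NaN", tcol)
                r.loc[mname, tcol] = np.nan
                p.loc[mname, tcol] = np.nan
                continue
            rv, pv = correlation_with_p(me[mcol].to_numpy(), tv)
            r.loc[mname, tcol] = rv
            p.loc[mname, tcol] = pv
    return r, p


def gene_and_module_significance(norm, trait, assignment: ModuleAssignment):
    """GS = |cor(gene, trait)| per gene; MS = mean GS per module.

    Returns ``(gs_frame, ms_series)``; the grey module's MS is computed
    but conventionally non-interpretable.
    """
    values = _as_frame(norm).loc[assignment.labels.index]
    tv = np.asarray(trait, float)
    if np.std(tv) == 0:
        raise ValueError("trait is constant; gene significance undefined")
    x = values.to_numpy(float)
    xc = x - x.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(xc, axis=1)
    tc = tv - tv.mean()
    tn = np.linalg.norm(tc)
    with np.errstate(invalid="ignore"):
        r = (xc @ tc) / (xn * tn)
    n = x.shape[1]
    gs = np.abs(r)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = gs * np.sqrt(n - 2) / np.sqrt(1.0 - gs ** 2)
    pvals = 2.0 * stats.t.sf(t, n - 2)
    gs_frame = pd.DataFrame({"GS": gs, "p": pvals,
                             "module": assignment.labels.to_numpy()},
                            index=values.index)
    ms = gs_frame.groupby("module")["GS"].mean()
    return gs_frame, ms


def hub_genes(eigengenes: EigengeneMatrix,
              assignment: ModuleAssignment) -> pd.Series:
    """Per module, the member gene with maximal kME (ties by gene id)."""
    hubs = {}
    for module in assignment.modules():
        members = assignment.members(module)
        if not members:
            continue
        kme = eigengenes.kme.loc[members, module]
        best = kme.max()
        hubs[module] = sorted(kme.index[kme == best])[0]
    return pd.Series(hubs, name="hub_gene")
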