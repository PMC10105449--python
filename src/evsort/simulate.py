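"""Synthetic paired EV/cell count data with planted ground truth.

The generator emulates a 2 (Location: EV vs Cell) x 2 (Sex) x 3 (ethanol
dose: 0/120/320 mg/dL) x 3 (pregnancy) factorial design, 36 samples in
total, with every EV sample paired to the cell-of-origin sample of the
same (sex, dose, pregnancy) cell.  Counts are negative binomial with
variance mu + alpha*mu^2.  Planted structure — location and sex
differential expression, dose-monotone EV/cell "sorting" shifts, latent
co-expression modules with optional trait links, and a per-pregnancy
random intercept — is recorded in a :class:`GroundTruth` object so that
downstream stages can be scored for recovery.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SingleCellTruth",
    "simulate_paired_counts",
    "simulate_single_cell",
    "make_geneset_collection",
]

LOCATIONS = ("EV", "Cell")
SEXES = ("F", "M")

#: default per-dose sorting shift (log2), non-decreasing with dose
DEFAULT_SORT_DELTA = {0: 0.0, 120: 0.75, 320: 1.5}

#: default module -> (trait, direction) links; remaining modules are pure
#: latent factors with no trait association
DEFAULT_MODULE_TRAITS = {"M1": ("location", 1.0), "M2": ("sex", 1.0)}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the paired-count simulation.

    Fractions refer to disjoint gene subsets; their sum (plus the module
    genes) must fit inside ``n_genes``.
    """

    n_genes: int = 3000
    n_pregnancies: int = 3
    doses: tuple = (0, 120, 320)
    baseline_log_mean_range: tuple = (3.0, 9.0)
    nb_dispersion: float = 0.05
    lib_size_range: tuple | None = None
    frac_location_de: float = 0.10
    location_lfc: float = 2.0
    frac_sex_de_ev: float = 0.05
    frac_sex_de_cell: float = 0.03
    sex_lfc: float = 1.5
    frac_sorted: float = 0.05
    sort_delta: Mapping[int, float] | None = None
    n_modules: int = 5
    module_size: int = 50
    module_factor_sd: float = 1.0
    module_trait_rho: float = 0.85
    module_trait_links: Mapping[str, tuple] | None = None
    pregnancy_effect_sd: float = 0.3
    seed: int = 0

    def resolved_sort_delta(self) -> dict:
        delta = dict(self.sort_delta) if self.sort_delta is not None else {
            d: DEFAULT_SORT_DELTA.get(d, 0.0) for d in self.doses
        }
        return {d: float(delta.get(d, 0.0)) for d in self.doses}

    def validate(self) -> None:
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        fracs = (self.frac_location_de, self.frac_sex_de_ev,
                 self.frac_sex_de_cell, self.frac_sorted)
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError("effect fractions must lie in [0, 1]")
        if sum(fracs) > 1:
            raise ValueError("planted-gene fractions overlap: sum > 1")
        n_effect = sum(int(round(f * self.n_genes)) for f in fracs)
        n_module = self.n_modules * self.module_size
        if n_effect + n_module > self.n_genes:
            raise ValueError(
                f"planted genes ({n_effect} effect + {n_module} module) "
                f"exceed n_genes={self.n_genes}"
            )
        delta = self.resolved_sort_delta()
        ordered = [delta[d] for d in sorted(self.doses)]
        if delta.get(min(self.doses), 0.0) != 0.0:
            raise ValueError("sort_delta at the control dose must be 0")
        if any(b < a for a, b in zip(ordered, ordered[1:])):
            raise ValueError("sort_delta must be non-decreasing in dose")
        if self.lib_size_range is not None:
            lo, hi = self.lib_size_range
            if lo <= 0 or hi < lo:
                raise ValueError("lib_size_range must be a positive interval")


@dataclass
class GroundTruth:
    """Record of every planted effect, keyed by gene id."""

    location_de_genes: dict = field(default_factory=dict)   # gene -> signed lfc
    sex_de_genes: dict = field(default_factory=dict)        # location -> {gene: lfc}
    sorted_genes: dict = field(default_factory=dict)        # gene -> {dose: delta}
    module_of_gene: dict = field(default_factory=dict)      # gene -> module | "unassigned"
    module_trait_links: dict = field(default_factory=dict)  # module -> (trait, direction)
    hub_gene_of_module: dict = field(default_factory=dict)  # module -> gene

    @property
    def genes(self) -> list:
        return list(self.module_of_gene)

    def module_members(self, module: str) -> list:
        return [g for g, m in self.module_of_gene.items() if m == module]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["module_trait_links"] = {
            k: tuple(v) for k, v in d["module_trait_links"].items()
        }
        return cls(**d)


def _sample_table(config: SimConfig) -> pd.DataFrame:
    rows = []
    for preg in range(1, config.n_pregnancies + 1):
        for sex in SEXES:
            for dose in config.doses:
                pair = f"{sex}_d{dose}_p{preg}"
                for loc in LOCATIONS:
                    rows.append({
                        "sample": f"{loc}_{pair}",
                        "location": loc,
                        "sex": sex,
                        "dose": dose,
                        "pregnancy": preg,
                        "pair_id": pair,
                    })
    return pd.DataFrame(rows).set_index("sample")


def _trait_vector(meta: pd.DataFrame, trait: str) -> np.ndarray:
    """Numeric trait encoding: EV=1/Cell=0, F=1/M=0, dose value, set number."""
    if trait == "location":
        return (meta["location"] == "EV").to_numpy(float)
    if trait == "sex":
        return (meta["sex"] == "F").to_numpy(float)
    if trait == "dose":
        return meta["dose"].to_numpy(float)
    if trait == "pregnancy":
        return meta["pregnancy"].to_numpy(float)
    raise ValueError(f"unknown trait {trait!r}")


def simulate_paired_counts(config: SimConfig):
    """Draw a paired EV/cell count matrix under ``config``.

    Returns ``(counts, metadata, truth)`` where ``counts`` is a genes x
    samples integer DataFrame, ``metadata`` a per-sample factor table
    indexed by sample id, and ``truth`` the planted-effect record.
    Identical config (including seed) reproduces identical output.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    meta = _sample_table(config)
    n_samples = len(meta)
    width = max(4, len(str(config.n_genes - 1)))
    genes = [f"g{i:0{width}d}" for i in range(config.n_genes)]

    # disjoint planted blocks laid out from the front of the gene list
    counts_of = [int(round(f * config.n_genes)) for f in (
        config.frac_location_de, config.frac_sex_de_ev,
        config.frac_sex_de_cell, config.frac_sorted)]
    edges = np.cumsum([0] + counts_of)
    loc_idx = np.arange(edges[0], edges[1])
    sex_ev_idx = np.arange(edges[1], edges[2])
    sex_cell_idx = np.arange(edges[2], edges[3])
    sort_idx = np.arange(edges[3], edges[4])
    module_idx = {}
    pos = edges[4]
    for m in range(config.n_modules):
        module_idx[f"M{m + 1}"] = np.arange(pos, pos + config.module_size)
        pos += config.module_size

    lo, hi = config.baseline_log_mean_range
    log_mu = np.tile(rng.uniform(lo, hi, config.n_genes)[:, None], (1, n_samples))

    is_ev = (meta["location"] == "EV").to_numpy()
    is_f = (meta["sex"] == "F").to_numpy()
    dose = meta["dose"].to_numpy()
    preg = meta["pregnancy"].to_numpy()

    truth = GroundTruth(sex_de_genes={"EV": {}, "Cell": {}})
    truth.module_of_gene = {g: "unassigned" for g in genes}

    # location effect: signed log2 fold change applied to EV samples
    loc_sign = rng.choice([-1.0, 1.0], loc_idx.size)
    log_mu[np.ix_(loc_idx, np.flatnonzero(is_ev))] += (
        loc_sign[:, None] * config.location_lfc)
    truth.location_de_genes = {
        genes[i]: float(s * config.location_lfc)
        for i, s in zip(loc_idx, loc_sign)
    }

    # sex effect within one compartment (F relative to M)
    for block, loc_mask, key in (
        (sex_ev_idx, is_ev, "EV"), (sex_cell_idx, ~is_ev, "Cell")
    ):
        sign = rng.choice([-1.0, 1.0], block.size)
        cols = np.flatnonzero(loc_mask & is_f)
        log_mu[np.ix_(block, cols)] += sign[:, None] * config.sex_lfc
        truth.sex_de_genes[key] = {
            genes[i]: float(s * config.sex_lfc) for i, s in zip(block, sign)
        }

    # dose-monotone sorting: +delta in EV, -delta in Cell
    delta = config.resolved_sort_delta()
    dose_delta = np.array([delta[d] for d in dose])
    sign_loc = np.where(is_ev, 1.0, -1.0)
    log_mu[sort_idx] += (sign_loc * dose_delta)[None, :]
    truth.sorted_genes = {genes[i]: dict(delta) for i in sort_idx}

    # module latent factors; first member carries a double loading (hub)
    links = (dict(config.module_trait_links)
             if config.module_trait_links is not None
             else {k: v for k, v in DEFAULT_MODULE_TRAITS.items()
                   if k in module_idx})
    rho = config.module_trait_rho
    for module, idx in module_idx.items():
        if module in links:
            trait, direction = links[module]
            z = _trait_vector(meta, trait)
            z = (z - z.mean()) / z.std()
            factor = (rho * direction * z
                      + np.sqrt(1 - rho ** 2) * rng.standard_normal(n_samples))
            truth.module_trait_links[module] = (trait, float(np.sign(direction)))
        else:
            factor = rng.standard_normal(n_samples)
        loading = np.full(idx.size, config.module_factor_sd)
        # hub gene: double loading and the block's highest baseline, so its
        # signal is not drowned by low-count measurement noise
        loading[0] *= 2.0
        log_mu[idx[0]] += log_mu[idx].mean(axis=1).max() - log_mu[idx[0]].mean()
        log_mu[idx] += loading[:, None] * factor[None, :]
        for i in idx:
            truth.module_of_gene[genes[i]] = module
        truth.hub_gene_of_module[module] = genes[idx[0]]

    # pregnancy random intercept, shared by all samples of a pregnancy
    b = rng.normal(0.0, config.pregnancy_effect_sd,
                   (config.n_genes, config.n_pregnancies))
    log_mu += b[:, preg - 1]

    # library size factors
    if config.lib_size_range is None:
        log_sf = rng.uniform(-1.0, 1.0, n_samples)
    else:
        target = rng.uniform(*config.lib_size_range, n_samples)
        base_total = float(np.sum(2.0 ** log_mu.mean(axis=1)))
        log_sf = np.log2(target / base_total)
    log_mu += log_sf[None, :]

    mu = 2.0 ** log_mu
    r = 1.0 / config.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    counts = pd.DataFrame(counts, index=genes, columns=meta.index)
    return counts, meta.reset_index(), truth


@dataclass
class SingleCellTruth:
    """Planted design of the single-cell simulation."""

    signature_genes: list
    expressing_clusters: list
    fold_change: float


def simulate_single_cell(
    n_cells: int,
    n_clusters: int,
    signature_genes: Sequence[str],
    expressing_clusters: Sequence[int],
    seed: int,
    n_background_genes: int = 1000,
    background_mean: float = 0.5,
    signature_mean: float = 0.02,
    fold_change: float = 8.0,
):
    """Sparse clustered single-cell counts with a planted signature.

    The background transcriptome (``n_background_genes`` genes at mean
    ``background_mean`` counts per cell, lognormal scatter) sets each
    cell's sequencing depth; signature genes are rare (``signature_mean``)
    and have ``fold_change``-times elevated Poisson means in
    ``expressing_clusters`` only.  Returns ``(counts, labels, truth)``
    with counts genes x cells and ``labels`` a per-cell cluster Series.
    """
    signature_genes = list(dict.fromkeys(signature_genes))
    if not signature_genes:
        raise ValueError("signature gene set must be non-empty")
    expressing_clusters = sorted(set(int(c) for c in expressing_clusters))
    if any(c < 0 or c >= n_clusters for c in expressing_clusters):
        raise ValueError("expressing_clusters must be a subset of clusters")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    genes = signature_genes + [f"bg{i:04d}" for i in range(n_background_genes)]
    labels = rng.integers(0, n_clusters, n_cells)
    base = np.concatenate([
        signature_mean * rng.lognormal(0.0, 0.5, len(signature_genes)),
        background_mean * rng.lognormal(0.0, 0.5, n_background_genes),
    ])
    lam = np.tile(base[:, None], (1, n_cells))
    if expressing_clusters:
        cols = np.flatnonzero(np.isin(labels, expressing_clusters))
        lam[np.ix_(np.arange(len(signature_genes)), cols)] *= fold_change
    counts = pd.DataFrame(
        rng.poisson(lam), index=genes,
        columns=[f"cell{i:05d}" for i in range(n_cells)],
    )
    label_series = pd.Series(labels, index=counts.columns, name="cluster")
    truth = SingleCellTruth(signature_genes, expressing_clusters, fold_change)
    return counts, label_series, truth


def make_geneset_collection(
    truth: GroundTruth,
    n_decoy_sets: int,
    set_size_range: tuple,
    seed: int,
):
    """Gene-set collection with one set per planted group plus decoys.

    Decoy sets are drawn uniformly from the simulated gene universe; set
    sizes are drawn from ``set_size_range`` (inclusive).  Returns a
    :class:`evsort.ora.GeneSetCollection`.
    """
    from .ora import GeneSetCollection

    universe = truth.genes
    sets: dict[str, set] = {}
    if truth.location_de_genes:
        sets["planted_location_de"] = set(truth.location_de_genes)
    for loc, members in truth.sex_de_genes.items():
        if members:
            sets[f"planted_sex_de_{loc}"] = set(members)
    if truth.sorted_genes:
        sets["planted_sorted"] = set(truth.sorted_genes)
    for module in truth.module_trait_links.keys() | {
        m for m in truth.module_of_gene.values() if m != "unassigned"
    }:
        sets[f"planted_module_{module}"] = set(truth.module_members(module))

    lo, hi = int(set_size_range[0]), int(set_size_range[1])
    if hi > len(universe):
        raise ValueError("decoy set size exceeds gene universe")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    for i in range(n_decoy_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(universe), size, replace=False)
        sets[f"decoy_{i:03d}"] = {universe[j] for j in members}
    return GeneSetCollection(sets=sets, universe=set(universe))
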