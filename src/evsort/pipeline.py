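"""End-to-end pipeline orchestration and the reproducibility harness.

Stages run in a fixed order (simulate -> normalize -> pca -> de -> shift
-> wgcna -> consensus -> ora -> cellsig); each stage's randomness, where
any exists, flows from the single global seed through a named substream,
so disabling one stage never perturbs another's draws.  A RunManifest
(config snapshot, input hashes, output file list) is written at the end
and suffices for an exact rerun.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, consensus, effects, network, normalize, ora
from .diffexpr import nb_wald_test
from .io import read_counts, read_metadata, write_counts, write_table
from .simulate import SimConfig, make_geneset_collection, simulate_paired_counts

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "stage_seed"]

STAGES = ("simulate", "pca", "de", "shift", "wgcna", "consensus", "ora")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed derived from the global one."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class PipelineConfig:
    out_dir: str = "evsort_run"
    counts_path: str | None = None      # None -> simulate
    metadata_path: str | None = None
    gmt_path: str | None = None
    stages: tuple = STAGES
    seed: int = 0
    n_top_genes: int = 500
    p_threshold: float = 0.05
    g_threshold: float = 0.4
    soft_power: int = 14
    soft_power_consensus: int = 6
    min_module_size: int = 30
    merge_cut_height: float = 0.20
    merge_cut_height_consensus: float = 0.25
    sim: SimConfig = field(default_factory=SimConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        cfg = cls(**raw, sim=sim)
        if isinstance(cfg.stages, list):
            cfg.stages = tuple(cfg.stages)
        return cfg


@dataclass
class RunManifest:
    config: dict
    input_hashes: dict
    outputs: dict               # stage -> list of files
    package_version: str = __version__

    def write(self, path) -> None:
        tmp = Path(str(path) + ".tmp")
        tmp.write_text(json.dumps(dataclasses.asdict(self), indent=1))
        tmp.replace(path)


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, list] = {}
    input_hashes: dict[str, str] = {}

    def record(stage, *paths):
        outputs.setdefault(stage, []).extend(str(p) for p in paths)

    # --- inputs ---------------------------------------------------------
    if config.counts_path:
        counts = read_counts(config.counts_path)
        meta = read_metadata(config.metadata_path)
        input_hashes["counts"] = _sha256(config.counts_path)
        input_hashes["metadata"] = _sha256(config.metadata_path)
        truth = None
    else:
        sim = dataclasses.replace(
            config.sim, seed=stage_seed(config.seed, "simulate"))
        counts, meta, truth = simulate_paired_counts(sim)
        if "simulate" in config.stages:
            cpath, mpath, tpath = (out / "counts.tsv", out / "metadata.tsv",
                                   out / "ground_truth.json")
            write_counts(counts, cpath)
            meta.to_csv(mpath, sep="\t", index=False)
            truth.to_json(tpath)
            record("simulate", cpath, mpath, tpath)
    meta_idx = meta.set_index("sample")
    log.info("input: %d genes x %d samples", *counts.shape)

    # --- normalization (always needed downstream) -----------------------
    factors = normalize.size_factors(counts)
    norm = normalize.log_normalize(counts, factors)

    if "pca" in config.stages:
        top = normalize.top_variant_genes(norm, min(config.n_top_genes,
                                                    counts.shape[0]))
        res = normalize.pca(norm, top)
        scores = res.scores.copy()
        scores.columns = [
            f"{c} ({v:.2f}%)" for c, v in
            zip(scores.columns, res.variance_explained)]
        p = out / "pca_scores.tsv"
        write_table(scores, p, index_label="sample")
        record("pca", p)
        log.info("pca: PC1 %.2f%% of variance", res.variance_explained[0])

    if "de" in config.stages:
        de = nb_wald_test(counts, factors, meta_idx["location"])
        p = out / "de_location.tsv"
        write_table(de, p, index_label="gene")
        record("de", p)
        for loc in ("EV", "Cell"):
            cols = meta_idx.index[meta_idx["location"] == loc]
            de_sex = nb_wald_test(counts[cols], factors[cols],
                                  meta_idx.loc[cols, "sex"])
            ps = out / f"de_sex_{loc}.tsv"
            write_table(de_sex, ps, index_label="gene")
            record("de", ps)

    if "shift" in config.stages:
        doses = sorted(d for d in meta_idx["dose"].unique() if d != 0)
        summaries = []
        for dose in doses:
            for mode in ("EV", "Cell", "ratio"):
                if mode == "ratio":
                    tab = effects.ev_cell_ratio_shift(
                        norm, meta, dose, config.p_threshold, config.g_threshold)
                else:
                    tab = effects.ethanol_shift(
                        norm, meta, mode, dose,
                        config.p_threshold, config.g_threshold)
                p = out / f"shift_{mode}_{dose}.tsv"
                write_table(tab.records, p, index_label="gene")
                record("shift", p)
                summaries.append(tab.summary())
        p = out / "shift_summary.json"
        p.write_text(json.dumps(summaries, indent=1))
        record("shift", p)

    assignment = eigen = None
    if "wgcna" in config.stages:
        net_cfg = network.NetworkConfig(
            soft_power=config.soft_power,
            min_module_size=config.min_module_size,
            merge_cut_height=config.merge_cut_height)
        adj = network.adjacency_signed(norm, net_cfg.soft_power)
        tom = network.tom_similarity(adj)
        assignment = network.detect_modules(1.0 - tom, norm, net_cfg)
        eigen = network.module_eigengenes(norm, assignment)
        traits = network.encode_traits(meta)
        r, pv = network.module_trait_relationships(eigen, traits)
        hubs = network.hub_genes(eigen, assignment)
        files = [out / "modules.tsv", out / "eigengenes.tsv",
                 out / "module_trait_r.tsv", out / "module_trait_p.tsv",
                 out / "hub_genes.tsv"]
        write_table(assignment.labels.rename("module").to_frame(),
                    files[0], index_label="gene")
        write_table(eigen.eigengenes, files[1], index_label="sample")
        write_table(r, files[2], index_label="module")
        write_table(pv, files[3], index_label="module")
        write_table(hubs.to_frame(), files[4], index_label="module")
        record("wgcna", *files)
        log.info("wgcna: %d modules", len(assignment.modules()))

    if "consensus" in config.stages:
        cons_cfg = network.NetworkConfig(
            soft_power=config.soft_power_consensus,
            min_module_size=config.min_module_size,
            merge_cut_height=config.merge_cut_height_consensus)
        sets = {}
        for loc in ("EV", "Cell"):
            cols = meta_idx.index[meta_idx["location"] == loc]
            sets[loc] = norm.values[list(cols)]
        toms = {loc: network.tom_similarity(
                    network.adjacency_signed(v, cons_cfg.soft_power))
                for loc, v in sets.items()}
        shared = toms["EV"].index.intersection(toms["Cell"].index)
        cons_tom = consensus.consensus_tom(
            toms["EV"].loc[shared, shared], toms["Cell"].loc[shared, shared])
        joint = pd.concat([sets["EV"].loc[shared], sets["Cell"].loc[shared]],
                          axis=1)
        cons_assign = network.detect_modules(1.0 - cons_tom, joint, cons_cfg)
        files = [out / "consensus_modules.tsv"]
        write_table(cons_assign.labels.rename("module").to_frame(),
                    files[0], index_label="gene")
        if assignment is not None:
            corr = consensus.module_overlap_fisher(
                assignment.labels.loc[shared], cons_assign.labels)
            f1, f2 = out / "correspondence_counts.tsv", out / "correspondence_logp.tsv"
            write_table(corr.counts, f1, index_label="module")
            write_table(corr.neg_log10_p, f2, index_label="module")
            files += [f1, f2]
        rtabs, ptabs = {}, {}
        for loc in ("EV", "Cell"):
            me = network.module_eigengenes(sets[loc].loc[shared], cons_assign)
            tr = network.encode_traits(
                meta[meta["location"] == loc], ("sex", "pregnancy"))
            rtabs[loc], ptabs[loc] = network.module_trait_relationships(me, tr)
        combined = consensus.combined_trait_relationship(
            rtabs["EV"], ptabs["EV"], rtabs["Cell"], ptabs["Cell"])
        f3 = out / "consensus_combined_trait.tsv"
        write_table(combined.values, f3, index_label="module")
        files.append(f3)
        record("consensus", *files)

    if "ora" in config.stages:
        if config.gmt_path:
            collection = ora.read_gmt(config.gmt_path)
            input_hashes["gmt"] = _sha256(config.gmt_path)
        elif truth is not None:
            collection = make_geneset_collection(
                truth, n_decoy_sets=20, set_size_range=(20, 60),
                seed=stage_seed(config.seed, "ora"))
        else:
            collection = None
            log.warning("ora stage skipped: no GMT and no simulation truth")
        if collection is not None:
            de = nb_wald_test(counts, factors, meta_idx["location"])
            query = de.index[(de["padj"] < 0.05)
                             & (de["log2FC"] > 0)].tolist()
            if query:
                res = ora.ora_test(query, collection,
                                   universe=set(counts.index))
                p = out / "ora_location_up.tsv"
                write_table(res, p)
                record("ora", p)

    manifest = RunManifest(
        config={**dataclasses.asdict(config),
                "stages": list(config.stages)},
        input_hashes=input_hashes, outputs=outputs)
    manifest.write(out / "manifest.json")
    return manifest
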