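"""WGCNA core: adjacency, TOM, modules, eigengenes, traits, hubs."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from evsort import network
from evsort.network import (NetworkConfig, adjacency_signed,
                            correlation_with_p, detect_modules,
                            gene_and_module_significance, hub_genes,
                            module_eigengenes, module_trait_relationships,
                            pick_soft_power, tom_similarity)
from evsort.normalize import log_normalize, size_factors
from evsort.simulate import SimConfig, simulate_paired_counts


def tom_oracle(a):
    """Naive triple-loop topological overlap."""
    n = a.shape[0]
    k = a.sum(axis=1)
    t = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n))
            t[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return t


def random_adjacency(rng, n):
    a = rng.uniform(0, 1, (n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    return a


class TestAdjacency:
    def test_endpoint_and_arithmetic_cases(self):
        s = np.linspace(0, 2 * np.pi, 9)[:-1]
        up = np.sin(s)
        values = pd.DataFrame([up, up * 2 + 1, -up], index=list("abc"))
        adj = adjacency_signed(values, 1)
        assert adj.loc["a", "b"] == pytest.approx(1.0)   # cor +1
        assert adj.loc["a", "c"] == pytest.approx(0.0)   # cor -1
        assert adj.loc["a", "a"] == 0.0

    def test_beta_monotonicity(self, small_norm):
        sub = small_norm.values.iloc[:30]
        a1 = adjacency_signed(sub, 2).to_numpy()
        a2 = adjacency_signed(sub, 6).to_numpy()
        off = ~np.eye(30, dtype=bool)
        imperfect = a1[off] < 1.0
        assert (a2[off][imperfect] < a1[off][imperfect]).all()

    def test_zero_variance_gene_dropped(self, caplog):
        values = pd.DataFrame([[1.0, 1.0, 1.0, 1.0],
                               [0.0, 1.0, 3.0, 2.0],
                               [4.0, 2.0, 1.0, 0.0]], index=list("abc"))
        with caplog.at_level("WARNING"):
            adj = adjacency_signed(values, 2)
        assert list(adj.index) == ["b", "c"]


class TestTOM:
    def test_two_gene_algebra(self):
        a = np.array([[0.0, 0.37], [0.37, 0.0]])
        tom = tom_similarity(pd.DataFrame(a, index=list("ab"),
                                          columns=list("ab")))
        assert tom.loc["a", "b"] == pytest.approx(0.37, abs=1e-12)

    def test_three_gene_complete_graph(self):
        w = 0.6
        a = np.full((3, 3), w)
        np.fill_diagonal(a, 0.0)
        tom = tom_similarity(pd.DataFrame(a, index=list("abc"),
                                          columns=list("abc"))).to_numpy()
        off = ~np.eye(3, dtype=bool)
        # (w^2 + w) / (2w + 1 - w) = w
        assert np.allclose(tom[off], w, atol=1e-12)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = random_adjacency(rng, 15)
            tom = tom_similarity(pd.DataFrame(a)).to_numpy()
            assert np.abs(tom - tom_oracle(a)).max() < 1e-12

    def test_range_symmetry_diagonal(self, small_norm):
        adj = adjacency_signed(small_norm.values.iloc[:50], 6)
        tom = tom_similarity(adj).to_numpy()
        assert np.allclose(tom, tom.T)
        assert (tom >= 0).all() and (tom <= 1 + 1e-12).all()
        assert np.allclose(np.diag(tom), 1.0)


class TestSoftPower:
    def test_modular_data_reaches_scale_free_fit(self):
        # heterogeneous module sizes with graded memberships give the
        # heavy-tailed connectivity a soft power can make scale-free
        rng = np.random.default_rng(1)
        ns = 36
        blocks = []
        for size in (100, 70, 50, 35, 25):
            f = rng.standard_normal(ns)
            load = rng.uniform(0.3, 1.2, size)
            blocks.append(load[:, None] * f[None, :]
                          + 0.6 * rng.standard_normal((size, ns)))
        blocks.append(0.7 * rng.standard_normal((300, ns)))
        values = pd.DataFrame(np.vstack(blocks),
                              index=[f"g{i}" for i in range(580)])
        power, fit = pick_soft_power(values)
        assert fit["signed_r2"].max() >= 0.8
        assert power <= 20

    def test_fixed_power_candidate_returned_untouched(self, module_sim):
        power, _ = pick_soft_power(module_sim[3], candidate_powers=(14,))
        assert power == 14

    def test_mean_connectivity_decreases_with_power(self, module_sim):
        _, _, _, norm = module_sim
        _, fit = pick_soft_power(norm, candidate_powers=(2, 6, 10, 14))
        assert (np.diff(fit["mean_k"]) < 0).all()

    def test_empty_candidates_rejected(self, module_sim):
        with pytest.raises(ValueError):
            pick_soft_power(module_sim[3], candidate_powers=())


class TestModuleDetection:
    def test_planted_modules_recovered(self, module_sim):
        counts, meta, truth, norm = module_sim
        tom = tom_similarity(adjacency_signed(norm, 14))
        a = detect_modules(1.0 - tom, norm, NetworkConfig(soft_power=14))
        planted = [truth.module_of_gene[g] for g in a.labels.index]
        assert adjusted_rand_score(planted, list(a.labels)) >= 0.8
        assert all(a.module_sizes[m] >= 30 for m in a.modules())

    def test_pure_noise_goes_grey(self):
        cfg = SimConfig(n_genes=400, frac_location_de=0, frac_sex_de_ev=0,
                        frac_sex_de_cell=0, frac_sorted=0, n_modules=0,
                        pregnancy_effect_sd=0.0, seed=77)
        counts, _, _ = simulate_paired_counts(cfg)
        norm = log_normalize(counts, size_factors(counts))
        tom = tom_similarity(adjacency_signed(norm, 14))
        a = detect_modules(1.0 - tom, norm, NetworkConfig(soft_power=14))
        assert (a.labels == "grey").mean() >= 0.9

    def test_correlated_factor_modules_merge(self):
        # two blocks from factors correlated at ~0.9 -> eigengene
        # dissimilarity below 0.20 -> single module after merging
        rng = np.random.default_rng(3)
        ns = 24
        f1 = rng.standard_normal(ns)
        f2 = 0.9 * f1 + np.sqrt(1 - 0.81) * rng.standard_normal(ns)
        blocks = [np.tile(f, (40, 1)) + 0.3 * rng.standard_normal((40, ns))
                  for f in (f1, f2)]
        noise = rng.standard_normal((200, ns))
        values = pd.DataFrame(np.vstack(blocks + [noise]),
                              index=[f"g{i}" for i in range(280)])
        tom = tom_similarity(adjacency_signed(values, 6))
        a = detect_modules(1.0 - tom, values,
                           NetworkConfig(soft_power=6, merge_cut_height=0.20))
        labels = a.labels.iloc[:80]
        assert (labels != "grey").all()
        assert labels.nunique() == 1

    def test_merge_is_idempotent(self, module_sim):
        counts, meta, truth, norm = module_sim
        tom = tom_similarity(adjacency_signed(norm, 14))
        cfg = NetworkConfig(soft_power=14)
        a = detect_modules(1.0 - tom, norm, cfg)
        from evsort.network import _merge_by_eigengene
        again = _merge_by_eigengene(norm.values.loc[a.labels.index],
                                    a.labels, cfg.merge_cut_height)
        assert again.equals(a.labels)


@pytest.fixture(scope="module")
def detected(module_sim):
    counts, meta, truth, norm = module_sim
    tom = tom_similarity(adjacency_signed(norm, 14))
    a = detect_modules(1.0 - tom, norm, NetworkConfig(soft_power=14))
    eig = module_eigengenes(norm, a)
    return a, eig


class TestEigengenes:
    def test_unit_variance_and_sign_alignment(self, module_sim, detected):
        _, _, _, norm = module_sim
        a, eig = detected
        for col, mod in zip(eig.eigengenes.columns, eig.module_names()):
            me = eig.eigengenes[col]
            assert me.var(ddof=1) == pytest.approx(1.0)
            members = norm.values.loc[a.members(mod)]
            mean_profile = ((members.T - members.mean(axis=1))
                            / members.std(axis=1, ddof=1)).mean(axis=1)
            assert np.corrcoef(me, mean_profile)[0, 1] >= 0

    def test_identical_genes_module(self):
        base = np.sin(np.linspace(0, 7, 12))
        values = pd.DataFrame([base, 2 * base + 3, base - 1],
                              index=list("abc"))
        from evsort.network import ModuleAssignment
        a = ModuleAssignment(pd.Series("turquoise", index=list("abc")),
                             np.empty((0, 4)))
        eig = module_eigengenes(values, a)
        assert np.allclose(eig.kme["turquoise"], 1.0, atol=1e-10)

    def test_first_pc_optimality_against_svd(self, module_sim, detected):
        _, _, _, norm = module_sim
        a, eig = detected
        mod = a.modules()[0]
        x = norm.values.loc[a.members(mod)].to_numpy()
        xs = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1,
                                                         keepdims=True)
        _, s, vt = np.linalg.svd(xs, full_matrices=False)
        var_me = np.mean((xs @ eig.eigengenes[f"ME{mod}"].to_numpy()
                          / np.linalg.norm(eig.eigengenes[f"ME{mod}"])) ** 2)
        var_other = np.mean((xs @ vt[1]) ** 2)
        assert var_me >= var_other - 1e-9


class TestCorrelationP:
    @pytest.mark.parametrize("r, n, expected, tol_oom", [
        (-0.98, 36, 1e-24, 1.0),
        (0.77, 36, 4e-08, 1.0),
        (-0.66, 18, 0.003, None),
    ])
    def test_reproduces_reported_values(self, r, n, expected, tol_oom):
        rv, p = correlation_with_p(r, None, n)
        assert rv == r
        if tol_oom is not None:
            assert abs(np.log10(p) - np.log10(expected)) <= tol_oom
        else:
            assert round(p, 3) == expected

    def test_zero_and_perfect_correlation(self):
        assert correlation_with_p(0.0, None, 20)[1] == 1.0
        assert correlation_with_p(1.0, None, 20)[1] == 0.0

    def test_vector_interface_matches_scipy(self):
        from scipy import stats
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=15), rng.normal(size=15)
        r, p = correlation_with_p(x, y)
        ref = stats.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_constant_input_flagged(self):
        r, p = correlation_with_p(np.ones(5), np.arange(5.0))
        assert np.isnan(r) and np.isnan(p)


class TestTraitsAndHubs:
    def test_planted_trait_link_has_top_correlation(self, module_sim, detected):
        counts, meta, truth, norm = module_sim
        a, eig = detected
        r, p = module_trait_relationships(eig, network.encode_traits(meta))
        det = a.labels.loc[truth.module_members("M1")].mode()[0]
        assert det != "grey"
        assert r["Location"].abs().idxmax() == det

    def test_sex_encoding_flip_negates_column(self, module_sim, detected):
        counts, meta, truth, norm = module_sim
        a, eig = detected
        traits = network.encode_traits(meta)
        r1, _ = module_trait_relationships(eig, traits)
        flipped = traits.copy()
        flipped["Sex"] = 1.0 - flipped["Sex"]
        r2, _ = module_trait_relationships(eig, flipped)
        assert np.allclose(r1["Sex"].astype(float),
                           -r2["Sex"].astype(float), atol=1e-12)

    def test_module_significance_definition(self, module_sim, detected):
        counts, meta, truth, norm = module_sim
        a, _ = detected
        trait = network.encode_traits(meta)["Location"]
        gs, ms = gene_and_module_significance(norm, trait, a)
        assert ((gs["GS"] >= 0) & (gs["GS"] <= 1)).all()
        mod = a.modules()[0]
        assert ms[mod] == pytest.approx(
            gs.loc[gs["module"] == mod, "GS"].mean())
        assert "grey" in ms.index  # computed, though not interpretable

    def test_trait_linked_module_ranks_first_by_ms(self, module_sim, detected):
        counts, meta, truth, norm = module_sim
        a, _ = detected
        trait = network.encode_traits(meta)["Location"]
        _, ms = gene_and_module_significance(norm, trait, a)
        det = a.labels.loc[truth.module_members("M1")].mode()[0]
        assert ms.drop(index="grey").idxmax() == det

    def test_hub_has_maximal_kme(self, detected):
        a, eig = detected
        hubs = hub_genes(eig, a)
        for mod, gene in hubs.items():
            members = a.members(mod)
            assert eig.kme.loc[gene, mod] >= eig.kme.loc[members, mod].max() - 1e-12

    def test_planted_hub_recovered_across_seeds(self):
        ok = tot = 0
        for seed in range(10):
            cfg = SimConfig(n_genes=600, frac_location_de=0,
                            frac_sex_de_ev=0, frac_sex_de_cell=0,
                            frac_sorted=0, n_modules=5, module_size=50,
                            seed=seed)
            counts, meta, truth = simulate_paired_counts(cfg)
            norm = log_normalize(counts, size_factors(counts))
            tom = tom_similarity(adjacency_signed(norm, 14))
            a = detect_modules(1.0 - tom, norm, NetworkConfig(soft_power=14))
            eig = module_eigengenes(norm, a)
            hubs = hub_genes(eig, a)
            for mod in ("M3", "M4", "M5"):
                det = a.labels.loc[truth.module_members(mod)].mode()[0]
                tot += 1
                ok += int(det != "grey"
                          and hubs.get(det) == truth.hub_gene_of_module[mod])
        assert ok / tot >= 0.9
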