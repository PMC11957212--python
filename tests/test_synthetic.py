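"""Generator properties: determinism, limits, moments, and oracles."""

import filecmp
from pathlib import Path

import numpy as np
import pytest
import yaml

from admixtwas.exceptions import ConfigError
from admixtwas.synthetic import (SimConfig, compute_reference_covariance,
                                 export_fixture, individual_oracle_twas,
                                 simulate_expression_and_weights,
                                 simulate_panel, simulate_trait_gwas,
                                 snp_set_jaccard, sparse_overlap_config)


def small_cfg(**kw):
    base = dict(n_genes=20, snps_per_gene=10, n_gwas=800, n_train=300, seed=5)
    base.update(kw)
    return SimConfig(**base)


class TestConfigValidation:
    def test_contradictory_null_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(h2_trait=0.0, prop_causal_genes=0.5)

    @pytest.mark.parametrize("kw", [
        dict(fst=0.0), dict(fst=1.0), dict(ld_rho=(1.0, 0.3)),
        dict(maf_range=(0.0, 0.5)), dict(h2_expr=1.0),
        dict(n_causal_eqtl_per_gene=50), dict(gwas_population="C"),
    ])
    def test_out_of_range_fields_rejected(self, kw):
        with pytest.raises(ConfigError):
            small_cfg(**kw)

    def test_yaml_round_trip(self):
        cfg = small_cfg(ld_rho=(0.6, 0.2))
        assert SimConfig.from_dict(cfg.to_dict()) == cfg


class TestPanel:
    def test_same_seed_identical_matrices(self):
        a = simulate_panel(small_cfg())
        b = simulate_panel(small_cfg())
        for cohort in a.cohorts:
            np.testing.assert_array_equal(a.cohorts[cohort], b.cohorts[cohort])

    def test_different_seeds_differ(self):
        a = simulate_panel(small_cfg(seed=1))
        b = simulate_panel(small_cfg(seed=2))
        assert not np.array_equal(a.cohorts["gwas"], b.cohorts["gwas"])

    def test_fst_limit_recovers_ancestral_frequencies(self):
        cfg = small_cfg(fst=1e-4, n_genes=40, snps_per_gene=20)
        panel = simulate_panel(cfg)
        for pop in ("A", "B"):
            assert np.mean(np.abs(panel.pop_freq[pop] - panel.ancestral_freq)) < 0.01

    def test_zero_ld_rho_gives_uncorrelated_dosages(self):
        cfg = SimConfig(n_genes=10, snps_per_gene=10, ld_rho=(0.0, 0.0),
                        n_gwas=5_000, n_train=50, gwas_population="A", seed=3)
        panel = simulate_panel(cfg)
        offdiag = []
        for gid in panel.gene_ids:
            G = panel.cohorts["gwas"][:, panel.gene_slices[gid]].astype(float)
            corr = np.corrcoef(G, rowvar=False)
            offdiag.append(corr[np.triu_indices_from(corr, k=1)])
        offdiag = np.concatenate(offdiag)
        offdiag = offdiag[np.isfinite(offdiag)]  # cohort-monomorphic SNPs
        assert np.mean(np.abs(offdiag)) < 3.0 / np.sqrt(5_000)

    def test_positive_ld_rho_gives_adjacent_correlation(self):
        cfg = SimConfig(n_genes=10, snps_per_gene=10, ld_rho=(0.8, 0.8),
                        n_gwas=5_000, n_train=50, gwas_population="A", seed=3)
        panel = simulate_panel(cfg)
        adj = []
        for gid in panel.gene_ids:
            G = panel.cohorts["gwas"][:, panel.gene_slices[gid]].astype(float)
            corr = np.corrcoef(G, rowvar=False)
            adj.extend(np.diag(corr, k=1))
        adj = np.asarray(adj)
        adj = adj[np.isfinite(adj)]
        # dosage correlation is attenuated relative to the latent rho=0.8
        # (dichotomized Gaussians, differing frequencies), but stays large
        assert np.mean(adj) > 0.3


class TestExpressionAndWeights:
    def test_null_heritability_gives_null_cv_r2(self):
        cfg = SimConfig(n_genes=200, snps_per_gene=10, h2_expr=0.0,
                        n_gwas=100, n_train=300, seed=5)
        panel = simulate_panel(cfg)
        _, _, truth = simulate_expression_and_weights(panel, cfg)
        med = np.median(list(truth.cv_r2["A"].values()))
        assert med == pytest.approx(0.0, abs=0.05)

    def test_identical_populations_give_concordant_weights(self):
        cfg = SimConfig(n_genes=40, snps_per_gene=30, fst=1e-3,
                        ld_rho=(0.2, 0.2), topk=(28, 28), n_train=1_500,
                        h2_expr=0.4, n_gwas=100, seed=3)
        panel = simulate_panel(cfg)
        ma, mb, _ = simulate_expression_and_weights(panel, cfg)
        wa, wb = [], []
        for gid in sorted(set(ma.genes) & set(mb.genes)):
            da = {f.snp_id: f.weight for f in ma.genes[gid].features}
            db = {f.snp_id: f.weight for f in mb.genes[gid].features}
            for s in set(da) | set(db):
                wa.append(da.get(s, 0.0))
                wb.append(db.get(s, 0.0))
        assert np.corrcoef(wa, wb)[0, 1] > 0.9

    def test_divergent_eligibility_yields_mostly_disjoint_features(self):
        cfg = sparse_overlap_config(seed=1)
        panel = simulate_panel(cfg)
        ma, mb, _ = simulate_expression_and_weights(panel, cfg)
        union = set(ma.genes) | set(mb.genes)
        co = set(ma.genes) & set(mb.genes)
        zero_shared = sum(
            1 for g in union
            if g not in co or not (set(ma.genes[g].snp_ids)
                                   & set(mb.genes[g].snp_ids)))
        assert zero_shared / len(union) > 0.3

    def test_lasso_weight_training_gives_sparse_models(self):
        cfg = SimConfig(n_genes=8, snps_per_gene=30, weight_method="coordinate_lasso",
                        n_train=250, n_gwas=100, seed=2)
        panel = simulate_panel(cfg)
        ma, mb, truth = simulate_expression_and_weights(panel, cfg)
        assert ma.n_genes > 0
        # L1 selection should leave some candidate SNPs out
        assert any(g.n_features < cfg.snps_per_gene for g in ma.genes.values())
        for g in ma.genes.values():
            assert all(w != 0 for w in g.weights)

    def test_single_model_genes_arise_by_construction(self):
        cfg = sparse_overlap_config(seed=1)
        panel = simulate_panel(cfg)
        ma, mb, _ = simulate_expression_and_weights(panel, cfg)
        only_a = set(ma.genes) - set(mb.genes)
        only_b = set(mb.genes) - set(ma.genes)
        assert only_a and only_b


class TestTraitGwas:
    def test_null_alpha_gives_nominal_rejection_rate(self):
        cfg = SimConfig(n_genes=60, snps_per_gene=20, prop_causal_genes=0.0,
                        h2_trait=0.0, n_gwas=2_000, n_train=50,
                        gwas_population="A", seed=13)
        panel = simulate_panel(cfg)
        _, _, truth = simulate_expression_and_weights(panel, cfg)
        gwas, _ = simulate_trait_gwas(panel, truth, cfg)
        rate = float((np.abs(gwas.table["zscore"]) > 1.96).mean())
        se = np.sqrt(0.05 * 0.95 / gwas.n_snps)
        # SNPs within a gene are correlated, so allow a generous band
        assert abs(rate - 0.05) < 6 * se

    def test_single_causal_snp_matches_ncp_closed_form(self):
        cfg = SimConfig(n_genes=1, snps_per_gene=1, n_causal_eqtl_per_gene=1,
                        prop_causal_genes=1.0, h2_trait=0.2, n_gwas=50_000,
                        n_train=100, topk=(1, 1), gwas_population="A", seed=21)
        panel = simulate_panel(cfg)
        _, _, truth = simulate_expression_and_weights(panel, cfg)
        gwas, _ = simulate_trait_gwas(panel, truth, cfg)
        z2 = float(gwas.table["zscore"].iloc[0]) ** 2
        expected = cfg.n_gwas * cfg.h2_trait / (1 - cfg.h2_trait)
        # chi-square with this noncentrality has sd ~ 2 sqrt(2 ncp)
        assert abs(z2 - expected) < 4 * np.sqrt(2 * expected)

    def test_same_seed_identical_summary_stats(self):
        cfg = small_cfg()
        pa = simulate_panel(cfg)
        _, _, ta = simulate_expression_and_weights(pa, cfg)
        ga, _ = simulate_trait_gwas(pa, ta, cfg)
        pb = simulate_panel(cfg)
        _, _, tb = simulate_expression_and_weights(pb, cfg)
        gb, _ = simulate_trait_gwas(pb, tb, cfg)
        np.testing.assert_array_equal(ga.table["zscore"].to_numpy(),
                                      gb.table["zscore"].to_numpy())


class TestReferenceCovariance:
    def test_diagonal_equals_dosage_variances(self, sim_bundle):
        panel, model = sim_bundle["panel"], sim_bundle["model_a"]
        cov = compute_reference_covariance(panel, model, cohort="train_A")
        gid = sorted(model.genes)[0]
        snps, mat = cov.entries[gid]
        G = panel.dosages("train_A", snps)
        np.testing.assert_allclose(np.diag(mat), G.var(axis=0, ddof=1),
                                   rtol=1e-12)

    def test_matches_two_pass_bruteforce(self):
        rng = np.random.default_rng(8)
        G = rng.integers(0, 3, size=(10, 5)).astype(float)
        mu = G.mean(axis=0)
        brute = np.zeros((5, 5))
        for i in range(5):
            for j in range(5):
                brute[i, j] = np.sum((G[:, i] - mu[i]) * (G[:, j] - mu[j])) / 9
        np.testing.assert_allclose(np.cov(G, rowvar=False, ddof=1), brute,
                                   atol=1e-12)

    def test_single_individual_cohort_rejected(self, sim_bundle):
        panel, model = sim_bundle["panel"], sim_bundle["model_a"]
        clipped = {k: v[:1] for k, v in panel.cohorts.items()}
        import dataclasses
        tiny = dataclasses.replace(panel, cohorts=clipped)
        with pytest.raises(Exception):
            compute_reference_covariance(tiny, model, cohort="train_A")


class TestIndividualOracle:
    def test_single_snp_gene_equals_oriented_gwas_z(self):
        cfg = SimConfig(n_genes=5, snps_per_gene=1, n_causal_eqtl_per_gene=1,
                        topk=(1, 1), n_train=200, n_gwas=500,
                        gwas_population="A", seed=9)
        panel = simulate_panel(cfg)
        ma, _, truth = simulate_expression_and_weights(panel, cfg)
        gwas, y = simulate_trait_gwas(panel, truth, cfg)
        oracle = individual_oracle_twas(panel, ma, y)
        for _, row in oracle.iterrows():
            feat = ma.genes[row["gene"]].features[0]
            z_snp = float(gwas.table.loc[feat.snp_id, "zscore"])
            assert row["oracle_z"] == pytest.approx(np.sign(feat.weight) * z_snp,
                                                    abs=1e-10)


class TestExportFixture:
    def test_manifest_records_seed(self, tmp_path):
        manifest = export_fixture(small_cfg(seed=77), tmp_path / "fx")
        assert manifest["seed"] == 77
        stored = yaml.safe_load((tmp_path / "fx" / "manifest.yaml").read_text())
        assert stored["seed"] == 77

    def test_reexport_byte_identical(self, tmp_path):
        cfg = small_cfg()
        export_fixture(cfg, tmp_path / "a")
        export_fixture(cfg, tmp_path / "b")
        files = sorted(p.name for p in (tmp_path / "a").iterdir())
        assert files
        for name in files:
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes(), name
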