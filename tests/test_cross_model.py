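"""Sharing/significance classification and stratified correlations."""

import numpy as np
import pandas as pd
import pytest

from admixtwas._stats import pearson_with_ci
from admixtwas.cross_model import (ComparisonReport, build_report,
                                   combine_results_any, correlate_effects,
                                   correlate_pvalues,
                                   correlate_shared_snp_weights,
                                   gwas_restricted_features, model_specificity,
                                   sharing_class, significance_class,
                                   threshold_sweep)
from admixtwas.exceptions import AdmixTwasError, InsufficientDataSignal
from admixtwas.model_io import GeneModel, PredictionModel
from admixtwas.twas_engine import TwasResultSet, bh_fdr, zscore_pvalue

from conftest import make_feature, make_gwas


def result_set(zscores: dict, model_id="MA", trait_id="T"):
    genes = sorted(zscores)
    z = np.array([zscores[g] for g in genes], dtype=float)
    p = zscore_pvalue(z)
    table = pd.DataFrame({
        "gene": genes, "gene_name": genes, "zscore": z, "effect_size": z,
        "pvalue": p, "fdr_p": bh_fdr(p), "n_snps_used": 1,
        "n_snps_in_model": 1, "model_id": model_id, "trait_id": trait_id})
    return TwasResultSet(model_id=model_id, trait_id=trait_id, table=table)


class TestClassifiers:
    @pytest.mark.parametrize("sa,sb,expected", [
        ({"a", "b"}, {"c"}, "shared_distinct"),
        ({"a", "b"}, {"b", "c"}, "shared_overlapping"),
        ({"a"}, set(), "A_only"),
        (set(), {"a"}, "B_only"),
    ])
    def test_sharing_class(self, sa, sb, expected):
        assert sharing_class(sa, sb) == expected

    def test_sharing_class_undefined_for_empty_pair(self):
        with pytest.raises(AdmixTwasError):
            sharing_class(set(), set())

    @pytest.mark.parametrize("fa,fb,expected", [
        (0.01, 0.2, "A_only"),
        (0.01, 0.01, "both"),
        (0.9, None, "none"),
        (None, 0.04, "B_only"),
        (0.05, 0.05, "none"),  # strict inequality at the threshold
    ])
    def test_significance_class(self, fa, fb, expected):
        assert significance_class(fa, fb, 0.05) == expected

    def test_model_specificity_partition(self):
        spec = model_specificity({"g1", "g2"}, {"g2", "g3"})
        assert spec == {"g1": "A_only_tested", "g2": "co_tested",
                        "g3": "B_only_tested"}


class TestGwasRestrictedFeatures:
    def test_intersection_per_gene(self, tiny_model, tiny_gwas):
        feats = gwas_restricted_features(tiny_model, tiny_gwas)
        assert feats["GA"] == {"rs1", "rs2", "rs3"}
        assert feats["GB"] == {"rs4"}

    def test_empty_gwas_gives_empty_sets(self, tiny_model):
        gwas = make_gwas([("rsZZ", "A", "G", 0.0)])
        feats = gwas_restricted_features(tiny_model, gwas)
        assert all(s == set() for s in feats.values())


class TestCorrelations:
    def test_identical_zscores_give_unit_r(self):
        ra = result_set({"g1": 1.0, "g2": -2.0, "g3": 0.5})
        rb = result_set({"g1": 1.0, "g2": -2.0, "g3": 0.5}, model_id="MB")
        assert correlate_effects(ra, rb).r == pytest.approx(1.0)

    def test_negated_zscores_give_minus_one(self):
        ra = result_set({"g1": 1.0, "g2": -2.0, "g3": 0.5})
        rb = result_set({"g1": -1.0, "g2": 2.0, "g3": -0.5}, model_id="MB")
        assert correlate_effects(ra, rb).r == pytest.approx(-1.0)

    def test_symmetry_exact(self):
        ra = result_set({"g1": 1.0, "g2": -2.0, "g3": 0.5, "g4": 3.0})
        rb = result_set({"g1": 0.6, "g2": -1.0, "g3": 1.5, "g4": 2.0},
                        model_id="MB")
        assert correlate_effects(ra, rb).r == correlate_effects(rb, ra).r

    def test_hand_computed_pearson(self):
        # definitional oracle on x=(1,2,3,4), y=(2,4,6,9)
        x, y = [1, 2, 3, 4], [2, 4, 6, 9]
        mx, my = sum(x) / 4, sum(y) / 4
        sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
        sxx = sum((a - mx) ** 2 for a in x)
        syy = sum((b - my) ** 2 for b in y)
        expected = sxy / (sxx * syy) ** 0.5
        ci = pearson_with_ci(x, y)
        assert ci.r == pytest.approx(expected, abs=1e-12)
        assert ci.ci_low <= ci.r <= ci.ci_high

    def test_ci_width_shrinks_with_n(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        y = x + rng.normal(size=200) * 0.5
        narrow = pearson_with_ci(x, y)
        wide = pearson_with_ci(x[:20], y[:20])
        assert (narrow.ci_high - narrow.ci_low) < (wide.ci_high - wide.ci_low)

    def test_insufficient_pairs_signalled(self):
        ra = result_set({"g1": 1.0, "g2": 2.0})
        rb = result_set({"g1": 1.0, "g2": 2.0}, model_id="MB")
        with pytest.raises(InsufficientDataSignal):
            correlate_effects(ra, rb)

    def test_pvalue_transforms_both_defined(self):
        ra = result_set({"g1": 0.2, "g2": 2.0, "g3": -3.0, "g4": 1.1})
        rb = result_set({"g1": 0.3, "g2": 1.8, "g3": -2.5, "g4": 0.9},
                        model_id="MB")
        raw = correlate_pvalues(ra, rb, transform="raw")
        log = correlate_pvalues(ra, rb, transform="neglog10")
        assert -1 <= raw.r <= 1 and -1 <= log.r <= 1
        assert raw.r != log.r  # transforms genuinely differ


class TestSharedSnpWeights:
    def model(self, spec, model_id):
        genes = {}
        for gid, feats in spec.items():
            features = [make_feature(s, eff, ref, w) for s, eff, ref, w in feats]
            genes[gid] = GeneModel(gene_id=gid, gene_name=gid, cv_r2=0.2,
                                   features=features)
        return PredictionModel(model_id=model_id, genes=genes)

    def gwas_for(self, *models):
        snps = sorted({f.snp_id for m in models for g in m.genes.values()
                       for f in g.features})
        return make_gwas([(s, "A", "G", 1.0) for s in snps])

    def test_identical_tables_full_sharing(self):
        spec = {"g1": [("rs1", "A", "G", 0.5), ("rs2", "A", "G", -0.2)],
                "g2": [("rs3", "A", "G", 0.9)]}
        ma = self.model(spec, "MA")
        mb = self.model(spec, "MB")
        ws = correlate_shared_snp_weights(ma, mb, self.gwas_for(ma))
        assert ws.fraction_shared == 1.0
        assert ws.r == pytest.approx(1.0)

    def test_disjoint_pairs_no_r(self):
        ma = self.model({"g1": [("rs1", "A", "G", 0.5)]}, "MA")
        mb = self.model({"g1": [("rs2", "A", "G", 0.5)]}, "MB")
        ws = correlate_shared_snp_weights(ma, mb, self.gwas_for(ma, mb))
        assert ws.fraction_shared == 0.0
        assert ws.r is None

    def test_opposite_encoding_aligned_by_negation(self):
        ma = self.model({"g1": [("rs1", "A", "G", 0.5), ("rs2", "A", "G", 0.3),
                                ("rs3", "A", "G", -0.7)]}, "MA")
        # same SNPs with swapped effect/ref and negated weights: identical
        # content under the alignment convention
        mb = self.model({"g1": [("rs1", "G", "A", -0.5), ("rs2", "G", "A", -0.3),
                                ("rs3", "G", "A", 0.7)]}, "MB")
        ws = correlate_shared_snp_weights(ma, mb, self.gwas_for(ma))
        assert ws.n_pairs == 3
        assert ws.r == pytest.approx(1.0)


class TestThresholdSweep:
    def test_unfiltered_point_equals_marginal(self):
        ra = result_set({"g1": 0.5, "g2": 2.0, "g3": -3.0, "g4": 1.0})
        rb = result_set({"g1": 0.4, "g2": 1.5, "g3": -2.0, "g4": 0.8},
                        model_id="MB")
        sweep = threshold_sweep(ra, rb, [1.0, 0.05])
        marginal = correlate_effects(ra, rb)
        row = sweep[sweep["threshold"] == 1.0].iloc[0]
        assert row["r"] == pytest.approx(marginal.r)
        assert row["n"] == marginal.n

    def test_threshold_below_min_p_is_absent(self):
        ra = result_set({"g1": 0.5, "g2": 1.0, "g3": 0.2, "g4": 0.9})
        rb = result_set({"g1": 0.4, "g2": 1.5, "g3": 0.1, "g4": 0.8},
                        model_id="MB")
        sweep = threshold_sweep(ra, rb, [1e-10])
        assert np.isnan(sweep["r"].iloc[0])

    def test_nested_thresholds_monotone_n(self):
        rng = np.random.default_rng(1)
        za = {f"g{i}": float(z) for i, z in enumerate(rng.normal(0, 2, 50))}
        zb = {g: z + rng.normal() for g, z in za.items()}
        ra, rb = result_set(za), result_set(zb, model_id="MB")
        sweep = threshold_sweep(ra, rb, [1.0, 0.5, 0.1, 0.05, 0.01])
        assert (np.diff(sweep["n"]) <= 0).all()


class TestBuildReport:
    def engineered_inputs(self):
        rng = np.random.default_rng(3)
        spec_a, spec_b, za, zb = {}, {}, {}, {}
        # 4 significance patterns x 2 sharing patterns, 3 genes each
        patterns = [(sa, sb, share) for sa in (True, False) for sb in (True, False)
                    for share in (True, False)]
        i = 0
        for sig_a, sig_b, share in patterns:
            for _ in range(3):
                gid = f"g{i:02d}"
                s1, s2, s3 = f"rs{i}_1", f"rs{i}_2", f"rs{i}_3"
                spec_a[gid] = [(s1, "A", "G", 0.5), (s2, "A", "G", 0.3)]
                spec_b[gid] = [(s2, "A", "G", 0.4)] if share else \
                    [(s3, "A", "G", 0.4)]
                za[gid] = 8.0 + rng.normal() if sig_a else rng.normal() * 0.5
                zb[gid] = 8.0 + rng.normal() if sig_b else rng.normal() * 0.5
                i += 1
        ma = TestSharedSnpWeights().model(spec_a, "MA")
        mb = TestSharedSnpWeights().model(spec_b, "MB")
        gwas = TestSharedSnpWeights().gwas_for(ma, mb)
        return (result_set(za, "MA"), result_set(zb, "MB"), ma, mb, gwas)

    def test_stratum_counts_match_hand_counts(self):
        ra, rb, ma, mb, gwas = self.engineered_inputs()
        report = build_report("T", ra, rb, ma, mb, gwas)
        gc = report.gene_classes
        assert len(gc) == 24
        # each (sig, share) cell holds exactly 3 genes by construction
        counts = gc.groupby(["significance_class", "sharing_class"]).size()
        assert set(counts) == {3}
        assert counts.sum() == 24

    def test_partition_sums(self):
        ra, rb, ma, mb, gwas = self.engineered_inputs()
        report = build_report("T", ra, rb, ma, mb, gwas)
        gc = report.gene_classes
        assert gc["significance_class"].value_counts().sum() == len(gc)
        assert gc["sharing_class"].value_counts().sum() == len(gc)

    def test_identical_result_sets_give_unit_effect_correlations(self):
        ra, rb, ma, mb, gwas = self.engineered_inputs()
        rb_same = TwasResultSet(model_id="MB", trait_id="T",
                                table=ra.table.assign(model_id="MB"))
        report = build_report("T", ra, rb_same, ma, mb, gwas)
        eff = report.correlations.query("statistic == 'effect' and stratum == 'all'")
        assert eff["r"].iloc[0] == pytest.approx(1.0)

    def test_report_serializes_and_reparses(self, tmp_path):
        ra, rb, ma, mb, gwas = self.engineered_inputs()
        report = build_report("T", ra, rb, ma, mb, gwas)
        report.to_dir(tmp_path)
        back = pd.read_csv(tmp_path / "correlations.csv")
        pd.testing.assert_frame_equal(
            back, report.correlations, check_exact=False, atol=1e-12)
        assert (tmp_path / "sharing.csv").exists()
        assert (tmp_path / "sweep.csv").exists()


class TestCombineResultsAny:
    def test_gene_significant_if_any_member_significant(self):
        ra = result_set({"g1": 8.0, "g2": 0.1}, model_id="M1")
        rb = result_set({"g1": 0.2, "g2": 7.5}, model_id="M2")
        combined = combine_results_any([ra, rb], "AGG")
        fdr = combined.fdr()
        assert fdr["g1"] < 0.05 and fdr["g2"] < 0.05

    def test_mixed_traits_rejected(self):
        ra = result_set({"g1": 1.0, "g2": 1.0, "g3": 1.0}, trait_id="T1")
        rb = result_set({"g1": 1.0, "g2": 1.0, "g3": 1.0}, trait_id="T2")
        with pytest.raises(AdmixTwasError):
            combine_results_any([ra, rb], "AGG")
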