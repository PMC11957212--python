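"""Shared fixtures: tiny hand-built objects plus one small simulated bundle."""

import numpy as np
import pandas as pd
import pytest

from admixtwas.gwas_io import GwasSumStats
from admixtwas.model_io import GeneModel, PredictionModel, SnpFeature
from admixtwas.synthetic import (SimConfig, compute_reference_covariance,
                                 simulate_expression_and_weights, simulate_panel,
                                 simulate_trait_gwas)


def make_feature(snp_id, eff="A", ref="G", weight=0.5, chrom="1", pos=1000):
    return SnpFeature(snp_id=snp_id, ref_allele=ref, eff_allele=eff,
                      weight=weight, chrom=chrom, pos=pos)


def make_gwas(records, trait_id="TRAIT"):
    """records: list of (snp_id, a1, a2, z) or (snp_id, a1, a2, z, chrom, pos)."""
    rows = []
    for rec in records:
        snp, a1, a2, z = rec[:4]
        chrom = rec[4] if len(rec) > 4 else "1"
        pos = rec[5] if len(rec) > 5 else 1
        rows.append({"snp_id": snp, "chrom": chrom, "pos": pos, "a1": a1,
                     "a2": a2, "zscore": z, "beta": np.nan, "se": np.nan,
                     "n": pd.NA})
    table = pd.DataFrame(rows).set_index("snp_id")
    table["pos"] = table["pos"].astype("Int64")
    table["n"] = table["n"].astype("Int64")
    return GwasSumStats(trait_id=trait_id, table=table)


@pytest.fixture
def tiny_model():
    ga = GeneModel(
        gene_id="GA", gene_name="GENEA", cv_r2=0.30,
        features=[make_feature("rs1", "A", "G", 0.5, "1", 1000),
                  make_feature("rs2", "T", "C", -0.3, "1", 2000),
                  make_feature("rs3", "A", "C", 0.2, "1", 3000)])
    gb = GeneModel(gene_id="GB", gene_name="GENEB", cv_r2=0.20,
                   features=[make_feature("rs4", "C", "T", 0.8, "2", 500)])
    return PredictionModel(model_id="TINY", genes={"GA": ga, "GB": gb},
                           ancestry_label="test")


@pytest.fixture
def tiny_gwas():
    return make_gwas([
        ("rs1", "A", "G", 2.0),       # matches GA/rs1 orientation
        ("rs2", "C", "T", 1.5),       # swapped relative to GA/rs2 -> negate
        ("rs3", "A", "T", 0.7),       # allele-incompatible with GA/rs3
        ("rs4", "C", "T", -1.5),      # matches GB/rs4
        ("rs9", "A", "G", 0.1),       # not in any model
    ])


@pytest.fixture(scope="session")
def sim_bundle():
    """One small end-to-end simulation reused by several test modules."""
    cfg = SimConfig(n_genes=30, snps_per_gene=20, n_gwas=1500, n_train=400,
                    seed=7)
    panel = simulate_panel(cfg)
    model_a, model_b, truth = simulate_expression_and_weights(panel, cfg)
    gwas, phenotypes = simulate_trait_gwas(panel, truth, cfg)
    cov_a = compute_reference_covariance(panel, model_a, cohort="train_A")
    cov_b = compute_reference_covariance(panel, model_b, cohort="train_B")
    return {"cfg": cfg, "panel": panel, "model_a": model_a, "model_b": model_b,
            "truth": truth, "gwas": gwas, "phenotypes": phenotypes,
            "cov_a": cov_a, "cov_b": cov_b}
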