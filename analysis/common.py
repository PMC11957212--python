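"""Shared study conditions and paths for the numbered analysis scripts."""

from pathlib import Path

from admixtwas.synthetic import SimConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
FIXTURE_DIR = RESULTS / "fixture"

#: the workshop-scale conditions used across scripts 01-05: two populations
#: at Fst 0.15 with strong vs moderate cis LD, wide cis candidate pools, and
#: sparse per-population models (28 vs 8 SNPs, the realized medians of the
#: real admixed and European whole-blood models)
STUDY = SimConfig(n_genes=100, snps_per_gene=100, fst=0.15, ld_rho=(0.8, 0.3),
                  maf_range=(0.01, 0.4), model_maf_min=0.05, h2_expr=0.15,
                  min_cv_r2=0.03, n_train=500, n_gwas=5_000,
                  h2_trait=0.3, prop_causal_genes=0.25, seed=42)

TRAITS = ["MDD_like", "SCZ_like", "BD_like", "ADHD_like", "PTSD_like",
          "AUD_like"]
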