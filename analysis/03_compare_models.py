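"""Cross-model concordance: do divergent SNP features yield convergent
gene-level effects?

Classifies genes by SNP-feature sharing and significance pattern, computes
stratified correlations of effects and p-values, the shared-SNP weight
correlation, and the discovery-threshold sweep. Writes the report tables
under results/comparison/.
"""

from common import FIXTURE_DIR, RESULTS

from admixtwas.cross_model import build_report
from admixtwas.gwas_io import read_gwas
from admixtwas.model_io import read_model
from admixtwas.twas_engine import TwasResultSet


def main():
    res_a = TwasResultSet.from_csv(RESULTS / "twas_SYN_A.csv")
    res_b = TwasResultSet.from_csv(RESULTS / "twas_SYN_B.csv")
    model_a = read_model(FIXTURE_DIR / "model_A.tsv", model_id="SYN_A")
    model_b = read_model(FIXTURE_DIR / "model_B.tsv", model_id="SYN_B")
    gwas = read_gwas(FIXTURE_DIR / "gwas_SYN_TRAIT.tsv", trait_id="SYN_TRAIT")

    report = build_report("SYN_TRAIT", res_a, res_b, model_a, model_b, gwas)
    out = RESULTS / "comparison"
    report.to_dir(out)

    corr = report.correlations.set_index(["statistic", "stratum"])
    eff_all = corr.loc[("effect", "all")]
    eff_sig = corr.loc[("effect", "sig_any")]
    p_all = corr.loc[("pvalue_raw", "all")]
    p_sig = corr.loc[("pvalue_raw", "sig_any")]
    print(f"effect-size correlation, all co-tested genes:       "
          f"r={eff_all['r']:.3f} (n={eff_all['n']:.0f})")
    print(f"effect-size correlation, significant in >=1 model:  "
          f"r={eff_sig['r']:.3f} (n={eff_sig['n']:.0f})")
    print(f"p-value correlation, all co-tested genes:           "
          f"r={p_all['r']:.3f}")
    print(f"p-value correlation, significant in >=1 model:      "
          f"r={p_sig['r']:.3f}")
    ws = report.weight_sharing
    print(f"(gene,SNP) feature pairs shared by both models:     "
          f"{100 * ws.fraction_shared:.1f}%"
          + (f"; weight r={ws.r:.2f} over {ws.n_pairs} pairs"
             if ws.r is not None else ""))
    ss = report.sharing_summary
    print(f"genes with zero shared SNPs (co-carried):           "
          f"{100 * ss['fraction_genes_zero_shared_snps']:.1f}%; "
          f"median SNPs/gene {ss['median_snps_per_gene_a']:.0f} vs "
          f"{ss['median_snps_per_gene_b']:.0f}")
    print(f"report tables -> {out}")


if __name__ == "__main__":
    main()
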