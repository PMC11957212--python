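"""Generate the synthetic two-population study bundle.

Writes prediction models for populations A and B, per-model LD reference
covariances, GReX-mediated GWAS summary statistics, the ground-truth table,
and a synthetic gene->NIDP repository under results/fixture/.
"""

import json

from common import FIXTURE_DIR, STUDY

from admixtwas.synthetic import export_fixture


def main():
    manifest = export_fixture(STUDY, FIXTURE_DIR)
    print(f"fixture written to {FIXTURE_DIR}")
    print(json.dumps(manifest["realized"], indent=2))
    med_a = manifest["realized"]["median_snps_per_gene_A"]
    med_b = manifest["realized"]["median_snps_per_gene_B"]
    print(f"\nPopulation A models use a median of {med_a:.0f} SNPs per gene, "
          f"population B {med_b:.0f} — sparse models trained on the same "
          f"causal architecture select very different SNP sets "
          f"(median Jaccard "
          f"{manifest['realized']['median_snp_set_jaccard']:.3f}).")


if __name__ == "__main__":
    main()
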