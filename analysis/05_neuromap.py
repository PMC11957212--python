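"""Map trait-associated genes onto neuroimaging-derived phenotypes.

Takes the significant genes from the two TWAS runs (script 02), queries the
synthetic gene->NIDP repository from the fixture bundle with
within-query FDR adjustment, summarizes mean effects per brain region, and
quantifies what fraction of implicated NIDPs is driven solely by genes that
only the population-A model found significant.
"""

import pandas as pd

from common import FIXTURE_DIR, RESULTS

from admixtwas.neuromap import (load_repository, model_specific_fraction,
                                query_trait_nidps, region_mean_effects)
from admixtwas.twas_engine import TwasResultSet, significant_set


def main():
    res_a = TwasResultSet.from_csv(RESULTS / "twas_SYN_A.csv")
    res_b = TwasResultSet.from_csv(RESULTS / "twas_SYN_B.csv")
    sig_a, sig_b = significant_set(res_a), significant_set(res_b)
    sig = sig_a | sig_b
    a_specific = sig_a - sig_b
    print(f"{len(sig)} significant genes ({len(a_specific)} found only by "
          f"the population-A model)")

    repo = load_repository(FIXTURE_DIR / "nidp_repository.tsv")
    pairs = query_trait_nidps(sig, repo, fdr_threshold=0.05)
    out = RESULTS / "neuromap"
    out.mkdir(parents=True, exist_ok=True)
    pairs.to_csv(out / "pairs.csv", index=False)
    regions = region_mean_effects(pairs)
    regions.to_csv(out / "regions.csv", index=False)
    print(f"{len(pairs)} surviving gene-NIDP associations over "
          f"{pairs['nidp_id'].nunique()} NIDPs and {len(regions)} regions")

    if not pairs.empty:
        spec = model_specific_fraction(pairs, a_specific)
        spec.to_csv(out / "specificity.csv", index=False)
        overall = spec[spec["measure"] == "overall"].iloc[0]
        print(f"{100 * overall['fraction']:.0f}% of implicated NIDPs are "
              f"driven solely by model-A-specific genes")
    print(f"tables -> {out}")


if __name__ == "__main__":
    main()
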