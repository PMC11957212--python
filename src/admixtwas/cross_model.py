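"""Cross-model comparison: SNP-feature sharing, significance strata, and
stratified correlations of gene-level effects, p-values, and SNP weights.

The comparison asks whether two expression models trained in different
ancestries — which typically select largely different SNP features for the
same gene — nevertheless converge on concordant gene-level disease effects.
Genes are classified along two axes:

* sharing: after restricting each model to SNPs present in the GWAS, a gene
  is ``A_only``/``B_only`` if only one model carries features for it,
  ``shared_overlapping`` if both do and at least one SNP is shared, and
  ``shared_distinct`` if both do with fully disjoint SNP sets;
* significance: whether the gene's association passes FDR < threshold in
  neither, one, or both models.

Pearson correlations of z-scores (and of p-values, raw and -log10) are then
reported per stratum with Fisher-z 95% intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._stats import PearsonCI, pearson_with_ci
from .exceptions import AdmixTwasError, InsufficientDataSignal
from .gwas_io import GwasSumStats
from .model_io import PredictionModel
from .twas_engine import TwasResultSet

logger = logging.getLogger(__name__)

SHARING_CLASSES = ("A_only", "B_only", "shared_distinct", "shared_overlapping")
SIGNIFICANCE_CLASSES = ("none", "A_only", "B_only", "both")
MODEL_SPECIFICITY = ("A_only_tested", "B_only_tested", "co_tested")


def gwas_restricted_features(model: PredictionModel, gwas: GwasSumStats
                             ) -> dict[str, set[str]]:
    """Per gene, the model SNPs that the GWAS interrogates (possibly empty)."""
    gwas_snps = gwas.snp_ids()
    return {gid: {f.snp_id for f in gm.features if f.snp_id in gwas_snps}
            for gid, gm in model.genes.items()}


def sharing_class(set_a: set[str], set_b: set[str]) -> str:
    """Classify a gene by SNP-feature sharing between two models."""
    if not set_a and not set_b:
        raise AdmixTwasError("sharing class undefined: both SNP sets empty")
    if not set_b:
        return "A_only"
    if not set_a:
        return "B_only"
    return "shared_overlapping" if set_a & set_b else "shared_distinct"


def significance_class(fdr_a: float | None, fdr_b: float | None,
                       threshold: float = 0.05) -> str:
    """Classify by strict FDR significance in each model; absent = not sig."""
    if fdr_a is None and fdr_b is None:
        raise AdmixTwasError("significance class undefined: both values absent")
    sig_a = fdr_a is not None and fdr_a < threshold
    sig_b = fdr_b is not None and fdr_b < threshold
    if sig_a and sig_b:
        return "both"
    if sig_a:
        return "A_only"
    if sig_b:
        return "B_only"
    return "none"


def model_specificity(tested_a: set[str], tested_b: set[str]) -> dict[str, str]:
    """Annotate every tested gene as A_only_tested / B_only_tested / co_tested."""
    out = {}
    for g in tested_a | tested_b:
        if g in tested_a and g in tested_b:
            out[g] = "co_tested"
        elif g in tested_a:
            out[g] = "A_only_tested"
        else:
            out[g] = "B_only_tested"
    return out


@dataclass(frozen=True)
class StratifiedCorrelation:
    """A Pearson correlation over the genes of one stratum."""

    stratum: str
    n: int
    r: float
    ci_low: float
    ci_high: float

    @classmethod
    def from_ci(cls, stratum: str, ci: PearsonCI) -> "StratifiedCorrelation":
        return cls(stratum=stratum, n=ci.n, r=ci.r, ci_low=ci.ci_low, ci_high=ci.ci_high)


def _paired(res_a: TwasResultSet, res_b: TwasResultSet, column: str,
            genes: Iterable[str] | None = None) -> tuple[np.ndarray, np.ndarray, list[str]]:
    a = res_a.table.set_index("gene")[column]
    b = res_b.table.set_index("gene")[column]
    common = a.index.intersection(b.index)
    if genes is not None:
        common = common.intersection(pd.Index(list(genes)))
    common = common.sort_values()
    return a.loc[common].to_numpy(), b.loc[common].to_numpy(), list(common)


def correlate_effects(res_a: TwasResultSet, res_b: TwasResultSet,
                      genes: Iterable[str] | None = None,
                      stratum: str = "all") -> StratifiedCorrelation:
    """Pearson r of gene z-scores over co-tested genes (optionally a stratum)."""
    xa, xb, _ = _paired(res_a, res_b, "zscore", genes)
    return StratifiedCorrelation.from_ci(stratum, pearson_with_ci(xa, xb))


def correlate_pvalues(res_a: TwasResultSet, res_b: TwasResultSet,
                      genes: Iterable[str] | None = None,
                      transform: str = "raw",
                      stratum: str = "all") -> StratifiedCorrelation:
    """Pearson r of p-values, raw or on the -log10 scale."""
    pa, pb, _ = _paired(res_a, res_b, "pvalue", genes)
    if transform == "neglog10":
        pa, pb = -np.log10(pa), -np.log10(pb)
    elif transform != "raw":
        raise ValueError(f"unknown p-value transform {transform!r}")
    return StratifiedCorrelation.from_ci(stratum, pearson_with_ci(pa, pb))


@dataclass(frozen=True)
class WeightSharing:
    """Shared-SNP-feature weight concordance between two models."""

    r: float | None
    n_pairs: int
    fraction_shared: float
    n_union_pairs: int
    n_allele_incompatible: int = 0


def correlate_shared_snp_weights(model_a: PredictionModel, model_b: PredictionModel,
                                 gwas: GwasSumStats) -> WeightSharing:
    """Correlate weights of (gene, SNP) features present in both models.

    Both models are first restricted to GWAS-interrogated SNPs. Weights are
    sign-aligned to a common effect allele: when the two models encode
    opposite effect alleles for the same SNP, one weight is negated; pairs
    whose allele pairs are entirely incompatible are dropped and counted.
    ``fraction_shared`` is shared pairs over the union of (gene, SNP) pairs.
    """
    gwas_snps = gwas.snp_ids()

    def pair_map(model: PredictionModel) -> dict[tuple[str, str], tuple[str, str, float]]:
        return {(gid, f.snp_id): (f.eff_allele, f.ref_allele, f.weight)
                for gid, gm in model.genes.items()
                for f in gm.features if f.snp_id in gwas_snps}

    pa, pb = pair_map(model_a), pair_map(model_b)
    union = set(pa) | set(pb)
    shared = sorted(set(pa) & set(pb))
    wa, wb = [], []
    n_incompatible = 0
    for key in shared:
        ea, ra, weight_a = pa[key]
        eb, rb, weight_b = pb[key]
        if (eb, rb) == (ea, ra):
            aligned_b = weight_b
        elif (eb, rb) == (ra, ea):
            aligned_b = -weight_b
        else:
            n_incompatible += 1
            continue
        wa.append(weight_a)
        wb.append(aligned_b)
    n_pairs = len(wa)
    fraction = len(shared) / len(union) if union else 0.0
    try:
        r = pearson_with_ci(wa, wb).r if n_pairs >= 3 else None
    except InsufficientDataSignal:
        r = None
    if r is None:
        logger.info("weight r undefined over %d aligned shared pairs", n_pairs)
    return WeightSharing(r=r, n_pairs=n_pairs, fraction_shared=fraction,
                         n_union_pairs=len(union),
                         n_allele_incompatible=n_incompatible)


def threshold_sweep(res_a: TwasResultSet, res_b: TwasResultSet,
                    thresholds: Sequence[float]) -> pd.DataFrame:
    """Effect-size correlation as a function of discovery p-value threshold.

    At each threshold t, co-tested genes with nominal p < t in the discovery
    set (``res_a``) are kept and their z-scores correlated against the
    companion set. Points with fewer than 3 genes carry r = NaN ("absent").
    """
    rows = []
    pa = res_a.table.set_index("gene")["pvalue"]
    for t in thresholds:
        if not (0 < t <= 1):
            raise ValueError(f"threshold {t} outside (0, 1]")
        # p-values never exceed 1, so t = 1.0 means "no filtering"
        genes = set(pa.index[pa < t]) if t < 1.0 else set(pa.index)
        try:
            sc = correlate_effects(res_a, res_b, genes=genes, stratum=f"p<{t}")
            rows.append((t, sc.n, sc.r, sc.ci_low, sc.ci_high))
        except InsufficientDataSignal:
            xa, _, common = _paired(res_a, res_b, "zscore", genes)
            rows.append((t, len(common), np.nan, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["threshold", "n", "r", "ci_low", "ci_high"])


def combine_results_any(results: Sequence[TwasResultSet], model_id: str
                        ) -> TwasResultSet:
    """Aggregate several result sets by the ANY rule.

    Per gene, the association with the smallest FDR-adjusted p across the
    input sets is kept (so a gene is significant in the aggregate iff it is
    significant in any member). Used to pool ancestry-specific models into
    one column for comparison against a single reference model.
    """
    if not results:
        raise AdmixTwasError("no result sets to combine")
    trait_ids = {r.trait_id for r in results}
    if len(trait_ids) != 1:
        raise AdmixTwasError(f"cannot combine across traits: {sorted(trait_ids)}")
    combined = pd.concat([r.table for r in results], ignore_index=True)
    combined = combined.sort_values(["gene", "fdr_p", "pvalue", "model_id"],
                                    kind="mergesort")
    best = combined.drop_duplicates("gene", keep="first").reset_index(drop=True)
    best = best.assign(model_id=model_id)
    return TwasResultSet(model_id=model_id, trait_id=trait_ids.pop(), table=best)


@dataclass
class ComparisonReport:
    """All comparison outputs for one (trait, model A, model B) triple."""

    trait_id: str
    model_a: str
    model_b: str
    #: long-form: statistic, stratum, n, r, ci_low, ci_high
    correlations: pd.DataFrame
    #: one row per co-tested gene: gene, sharing_class, significance_class,
    #: n_shared_snps
    gene_classes: pd.DataFrame
    #: scalar sharing statistics
    sharing_summary: dict
    weight_sharing: WeightSharing
    sweep: pd.DataFrame | None = None

    def to_dir(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.correlations.to_csv(out / "correlations.csv", index=False)
        sharing = dict(self.sharing_summary)
        sharing.update({
            "weight_r": "" if self.weight_sharing.r is None else self.weight_sharing.r,
            "weight_n_pairs": self.weight_sharing.n_pairs,
            "fraction_snp_features_shared": self.weight_sharing.fraction_shared,
        })
        pd.DataFrame([sharing]).to_csv(out / "sharing.csv", index=False)
        self.gene_classes.to_csv(out / "gene_classes.csv", index=False)
        if self.sweep is not None:
            self.sweep.to_csv(out / "sweep.csv", index=False)


def build_report(trait_id: str, res_a: TwasResultSet, res_b: TwasResultSet,
                 model_a: PredictionModel, model_b: PredictionModel,
                 gwas: GwasSumStats, sig_threshold: float = 0.05,
                 sweep_thresholds: Sequence[float] = (1.0, 0.5, 0.1, 0.05, 0.01,
                                                      1e-3, 1e-4),
                 ) -> ComparisonReport:
    """Populate every stratum of the cross-model comparison for one trait."""
    feats_a = gwas_restricted_features(model_a, gwas)
    feats_b = gwas_restricted_features(model_b, gwas)

    fdr_a, fdr_b = res_a.fdr(), res_b.fdr()
    co_tested = sorted(res_a.tested_genes() & res_b.tested_genes())

    rows = []
    for gid in co_tested:
        sa = feats_a.get(gid, set())
        sb = feats_b.get(gid, set())
        share = sharing_class(sa, sb) if (sa or sb) else "undefined"
        sig = significance_class(float(fdr_a[gid]), float(fdr_b[gid]), sig_threshold)
        rows.append((gid, share, sig, len(sa & sb)))
    gene_classes = pd.DataFrame(rows, columns=["gene", "sharing_class",
                                               "significance_class", "n_shared_snps"])

    def add_corr(acc, statistic, stratum, genes):
        for name, fn in (("effect", correlate_effects),
                         ("pvalue_raw", lambda a, b, genes, stratum:
                          correlate_pvalues(a, b, genes, "raw", stratum)),
                         ("pvalue_neglog10", lambda a, b, genes, stratum:
                          correlate_pvalues(a, b, genes, "neglog10", stratum))):
            if name != statistic:
                continue
            try:
                sc = fn(res_a, res_b, genes=genes, stratum=stratum)
                acc.append((statistic, stratum, sc.n, sc.r, sc.ci_low, sc.ci_high))
            except InsufficientDataSignal:
                acc.append((statistic, stratum, len(list(genes)), np.nan, np.nan, np.nan))

    acc: list[tuple] = []
    strata: dict[str, list[str]] = {"all": co_tested}
    for sig in SIGNIFICANCE_CLASSES:
        sel = gene_classes[gene_classes["significance_class"] == sig]["gene"]
        strata[f"sig={sig}"] = list(sel)
        for share in ("shared_distinct", "shared_overlapping"):
            sel2 = gene_classes[(gene_classes["significance_class"] == sig)
                                & (gene_classes["sharing_class"] == share)]["gene"]
            strata[f"sig={sig},share={share}"] = list(sel2)
    for share in ("shared_distinct", "shared_overlapping"):
        sel = gene_classes[gene_classes["sharing_class"] == share]["gene"]
        strata[f"share={share}"] = list(sel)
    strata["sig_any"] = list(
        gene_classes[gene_classes["significance_class"] != "none"]["gene"])

    for stratum, genes in strata.items():
        for statistic in ("effect", "pvalue_raw", "pvalue_neglog10"):
            add_corr(acc, statistic, stratum, genes)
    correlations = pd.DataFrame(
        acc, columns=["statistic", "stratum", "n", "r", "ci_low", "ci_high"])

    # sharing summary over genes carried (post GWAS restriction) by both models
    both_nonempty = [g for g in set(feats_a) & set(feats_b)
                     if feats_a[g] and feats_b[g]]
    shared_counts = np.array([len(feats_a[g] & feats_b[g]) for g in both_nonempty])
    med_a = float(np.median([len(s) for s in feats_a.values() if s])) \
        if any(feats_a.values()) else float("nan")
    med_b = float(np.median([len(s) for s in feats_b.values() if s])) \
        if any(feats_b.values()) else float("nan")
    sharing_summary = {
        "n_co_carried_genes": len(both_nonempty),
        "fraction_genes_zero_shared_snps":
            float(np.mean(shared_counts == 0)) if len(shared_counts) else float("nan"),
        "mean_shared_snps_per_gene":
            float(np.mean(shared_counts)) if len(shared_counts) else float("nan"),
        "median_snps_per_gene_a": med_a,
        "median_snps_per_gene_b": med_b,
    }

    weight_sharing = correlate_shared_snp_weights(model_a, model_b, gwas)
    sweep = threshold_sweep(res_a, res_b, sweep_thresholds)
    return ComparisonReport(trait_id=trait_id, model_a=model_a.model_id,
                            model_b=model_b.model_id, correlations=correlations,
                            gene_classes=gene_classes,
                            sharing_summary=sharing_summary,
                            weight_sharing=weight_sharing, sweep=sweep)
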