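"""Gene-level association from GWAS summary statistics and expression weights.

The summary-statistic TWAS z-score for a gene g combines the model's SNP
weights w, the GWAS per-SNP z-scores z (oriented to the model's effect
alleles), and an LD-reference SNP covariance Gamma:

    z_g = sum_l w_l * sigma_l * z_l / sigma_g

with sigma_l = sqrt(Gamma_ll) the reference dosage standard deviation of SNP
l and sigma_g = sqrt(w' Gamma w) the reference standard deviation of the
gene's imputed expression. Under the null and a matched LD reference, z_g is
standard normal, so a two-sided normal p-value applies; within each
(model, trait) pairing the p-values are Benjamini-Hochberg adjusted.

The statistic is invariant to SNP relabeling/reordering, to simultaneous
allele flips in model and GWAS, and to positive rescaling of a gene's
weights.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (CovarianceError, DegenerateVarianceSignal,
                         NoOverlapSignal, AdmixTwasError)
from .gwas_io import GwasSumStats, HarmonizedGene, RegionMask, apply_region_mask, harmonize
from .model_io import CovarianceTable, PredictionModel

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300
VAR_TOL = 1e-12

RESULT_COLUMNS = ["gene", "gene_name", "zscore", "effect_size", "pvalue", "fdr_p",
                  "n_snps_used", "n_snps_in_model", "model_id", "trait_id"]


def gene_zscore(h: HarmonizedGene, cov_snp_ids: Sequence[str],
                cov_matrix: np.ndarray) -> tuple[float, int]:
    """The gene-level z-score from harmonized weights/z and an LD reference.

    Model SNPs absent from the covariance reference are dropped first (the
    convention of summary-statistic TWAS tools); the gene is skipped via a
    typed signal if none remain or the imputed-expression variance is
    numerically zero.
    """
    index = {s: i for i, s in enumerate(cov_snp_ids)}
    keep = [k for k, s in enumerate(h.snp_ids) if s in index]
    n_cov_dropped = len(h.snp_ids) - len(keep)
    if n_cov_dropped:
        logger.debug("%s: %d SNPs absent from covariance reference",
                     h.gene_id, n_cov_dropped)
    if not keep:
        raise NoOverlapSignal(h.gene_id, "no model SNP in covariance reference")
    # canonical (lexicographic) SNP order: the statistic is then bit-for-bit
    # invariant to how the caller ordered the gene's SNPs
    keep.sort(key=lambda k: h.snp_ids[k])
    idx = np.array([index[h.snp_ids[k]] for k in keep], dtype=int)
    w = h.weights[np.array(keep, dtype=int)]
    z = h.gwas_z[np.array(keep, dtype=int)]
    gamma = np.asarray(cov_matrix, dtype=float)[np.ix_(idx, idx)]
    if not np.all(np.isfinite(gamma)):
        raise CovarianceError(f"{h.gene_id}: non-finite covariance entries")
    sigma_l = np.sqrt(np.clip(np.diag(gamma), 0.0, None))
    var_g = float(w @ gamma @ w)
    if var_g <= VAR_TOL:
        raise DegenerateVarianceSignal(h.gene_id, f"w'Gamma w = {var_g:.3g}")
    zscore = float(np.sum(w * sigma_l * z) / math.sqrt(var_g))
    return zscore, len(keep)


def zscore_pvalue(z) -> np.ndarray:
    """Two-sided standard-normal tail probability, floored at 1e-300."""
    p = 2.0 * stats.norm.sf(np.abs(np.asarray(z, dtype=float)))
    return np.maximum(p, P_FLOOR)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending order statistics,
    capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


@dataclass
class TwasResultSet:
    """Gene-level associations for one (model, trait) pairing.

    ``table`` has RESULT_COLUMNS with one row per surviving gene; FDR is
    adjusted within this set only. ``skip_log`` records genes that produced
    no association, with a reason code.
    """

    model_id: str
    trait_id: str
    table: pd.DataFrame
    skip_log: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene", "reason"]))

    def __post_init__(self):
        if not self.table.empty and not self.table["gene"].is_unique:
            raise AdmixTwasError("duplicate gene in TwasResultSet")

    @property
    def n_genes(self) -> int:
        return len(self.table)

    def tested_genes(self) -> set[str]:
        return set(self.table["gene"])

    def zscores(self) -> pd.Series:
        return self.table.set_index("gene")["zscore"]

    def pvalues(self) -> pd.Series:
        return self.table.set_index("gene")["pvalue"]

    def fdr(self) -> pd.Series:
        return self.table.set_index("gene")["fdr_p"]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, model_id: str | None = None,
                 trait_id: str | None = None) -> "TwasResultSet":
        table = pd.read_csv(path, dtype={"gene": str, "gene_name": str,
                                         "model_id": str, "trait_id": str})
        missing = [c for c in RESULT_COLUMNS if c not in table.columns]
        if missing:
            raise AdmixTwasError(f"{path}: missing result column(s) {missing}")
        mid = model_id or (table["model_id"].iloc[0] if len(table) else "unknown")
        tid = trait_id or (table["trait_id"].iloc[0] if len(table) else "unknown")
        return cls(model_id=mid, trait_id=tid, table=table)


def significant_set(rs: TwasResultSet, threshold: float = 0.05) -> set[str]:
    """Genes with FDR-adjusted p strictly below the threshold."""
    t = rs.table
    return set(t.loc[t["fdr_p"] < threshold, "gene"])


@dataclass(frozen=True)
class _Assoc:
    gene_id: str
    gene_name: str
    zscore: float
    n_snps_used: int
    n_snps_in_model: int
    mean_n: float


def run_twas(model: PredictionModel, gwas: GwasSumStats, cov: CovarianceTable,
             masks: Iterable[RegionMask] = (),
             gene_positions: Mapping[str, tuple[str, int, int]] | None = None,
             ) -> TwasResultSet:
    """Full pipeline for one (model, trait) pairing.

    harmonize -> gene z-score -> two-sided p -> region masking ->
    Benjamini-Hochberg FDR over the surviving genes. Genes skipped along the
    way are reported in the result's ``skip_log`` with reason codes.
    """
    masks = list(masks)
    assocs: list[_Assoc] = []
    skips: list[tuple[str, str]] = []
    n_by_snp = None
    if gwas.table["n"].notna().any():
        n_by_snp = gwas.table["n"].astype(float).to_dict()
    for gid in sorted(model.genes):
        gm = model.genes[gid]
        try:
            h = harmonize(gwas, gm)
        except NoOverlapSignal as sig:
            skips.append((gid, sig.reason))
            continue
        if gid not in cov.entries:
            skips.append((gid, "no-covariance"))
            continue
        labels, matrix = cov.entries[gid]
        try:
            z, n_used = gene_zscore(h, labels, matrix)
        except (NoOverlapSignal, DegenerateVarianceSignal) as sig:
            skips.append((gid, sig.reason))
            continue
        mean_n = float("nan")
        if n_by_snp is not None:
            ns = [n_by_snp.get(s) for s in h.snp_ids]
            ns = [v for v in ns if v is not None and np.isfinite(v)]
            if ns:
                mean_n = float(np.mean(ns))
        assocs.append(_Assoc(gid, gm.gene_name, z, n_used, gm.n_features, mean_n))

    removed: list[_Assoc] = []
    if masks and assocs:
        positions = dict(gene_positions) if gene_positions is not None \
            else model.gene_positions()
        assocs, removed = apply_region_mask(assocs, positions, masks, model.model_id)
        skips.extend((a.gene_id, "region-masked") for a in removed)

    if assocs:
        z = np.array([a.zscore for a in assocs])
        p = zscore_pvalue(z)
        q = bh_fdr(p)
        eff = np.array([a.zscore / math.sqrt(a.mean_n)
                        if np.isfinite(a.mean_n) and a.mean_n > 0 else a.zscore
                        for a in assocs])
        table = pd.DataFrame({
            "gene": [a.gene_id for a in assocs],
            "gene_name": [a.gene_name for a in assocs],
            "zscore": z,
            "effect_size": eff,
            "pvalue": p,
            "fdr_p": q,
            "n_snps_used": [a.n_snps_used for a in assocs],
            "n_snps_in_model": [a.n_snps_in_model for a in assocs],
            "model_id": model.model_id,
            "trait_id": gwas.trait_id,
        })
    else:
        logger.warning("run_twas(%s, %s): empty result set",
                       model.model_id, gwas.trait_id)
        table = pd.DataFrame(columns=RESULT_COLUMNS)
    skip_log = pd.DataFrame(skips, columns=["gene", "reason"])
    return TwasResultSet(model_id=model.model_id, trait_id=gwas.trait_id,
                         table=table, skip_log=skip_log)
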