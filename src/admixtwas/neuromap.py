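"""Map trait-associated gene sets onto neuroimaging-derived phenotypes.

A precomputed repository links gene expression (GReX) to neuroimaging
derived phenotypes (NIDPs): cortical area/thickness/volume in the Desikan
parcellation and subcortical volumes, each with a signed effect and p-value.
Given the significant gene set of a trait, the repository is subset to those
genes, Benjamini-Hochberg adjusted within the subset, and thresholded;
surviving gene-NIDP pairs are summarized per brain region (mean effect) and
scored for model specificity: the fraction of NIDPs whose every surviving
association is driven by genes found only by one model.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import FormatError
from .twas_engine import bh_fdr

REPO_COLUMNS = ["gene", "nidp_id", "atlas", "measure", "hemisphere", "region",
                "effect", "pvalue"]
ATLASES = ("Desikan", "Subcortex")
MEASURES = ("area", "thickness", "volume")
HEMISPHERES = ("left", "right", "bilateral")


def load_repository(path) -> pd.DataFrame:
    """Read and validate a gene->NIDP association repository TSV."""
    path = Path(path)
    repo = pd.read_csv(path, sep="\t", dtype={"gene": str, "nidp_id": str})
    missing = [c for c in REPO_COLUMNS if c not in repo.columns]
    if missing:
        raise FormatError(f"{path}: missing repository column(s) {missing}")
    dup = repo.duplicated(subset=["gene", "nidp_id"])
    if dup.any():
        first = repo.loc[dup, ["gene", "nidp_id"]].iloc[0]
        raise FormatError(f"{path}: duplicate (gene, nidp) pair "
                          f"({first['gene']}, {first['nidp_id']})")
    for col, allowed in (("atlas", ATLASES), ("measure", MEASURES),
                         ("hemisphere", HEMISPHERES)):
        bad = set(repo[col]) - set(allowed)
        if bad:
            raise FormatError(f"{path}: invalid {col} value(s) {sorted(bad)}")
    if ((repo["pvalue"] <= 0) | (repo["pvalue"] > 1)).any():
        raise FormatError(f"{path}: p-values must lie in (0, 1]")
    return repo.reset_index(drop=True)


def write_repository(repo: pd.DataFrame, path) -> None:
    repo[REPO_COLUMNS].to_csv(path, sep="\t", index=False)


def query_trait_nidps(gene_set: Iterable[str], repo: pd.DataFrame,
                      fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Subset the repository to a gene set and FDR-threshold within it.

    The FDR universe is the queried subset: p-values are re-adjusted over
    exactly the (gene, NIDP) rows whose gene is in ``gene_set``, and rows
    with adjusted p strictly below the threshold survive. Returns the
    surviving rows with an added ``fdr_p`` column.
    """
    gene_set = set(gene_set)
    if not gene_set:
        raise FormatError("empty gene set")
    subset = repo[repo["gene"].isin(gene_set)].copy()
    if subset.empty:
        return subset.assign(fdr_p=pd.Series(dtype=float))
    subset["fdr_p"] = bh_fdr(subset["pvalue"].to_numpy())
    return subset[subset["fdr_p"] < fdr_threshold].reset_index(drop=True)


def region_mean_effects(assocs: pd.DataFrame) -> pd.DataFrame:
    """Mean effect of surviving gene-NIDP pairs per brain region.

    Groups by (atlas, region, measure, hemisphere); pair counts are conserved
    (the group sizes sum to the number of input rows).
    """
    if assocs.empty:
        return pd.DataFrame(columns=["atlas", "region", "measure", "hemisphere",
                                     "mean_effect", "n_pairs"])
    grouped = (assocs.groupby(["atlas", "region", "measure", "hemisphere"],
                              sort=True)["effect"]
               .agg(mean_effect="mean", n_pairs="size")
               .reset_index())
    grouped["n_pairs"] = grouped["n_pairs"].astype(int)
    return grouped


def model_specific_fraction(assocs: pd.DataFrame,
                            a_specific_genes: Iterable[str]) -> pd.DataFrame:
    """Fraction of NIDPs driven solely by model-A-specific genes, per measure.

    An NIDP counts toward the numerator iff *every* surviving gene-NIDP pair
    for that NIDP involves a gene from ``a_specific_genes``. NIDP identity is
    ``nidp_id`` (bilateral homologs count separately). Rows with measure
    "overall" aggregate across measure types.
    """
    a_specific = set(a_specific_genes)
    if assocs.empty:
        raise FormatError("no surviving gene-NIDP associations: fraction undefined")
    rows = []
    frames = [("overall", assocs)]
    frames += [(m, g) for m, g in assocs.groupby("measure", sort=True)]
    for measure, grp in frames:
        only_a = grp.groupby("nidp_id")["gene"].agg(
            lambda genes: set(genes) <= a_specific)
        total = len(only_a)
        numer = int(only_a.sum())
        rows.append({"measure": measure, "n_nidps_total": total,
                     "n_nidps_only_a_specific": numer,
                     "fraction": numer / total})
    return pd.DataFrame(rows)
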