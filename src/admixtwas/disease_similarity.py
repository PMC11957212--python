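"""Cross-disease transcriptomic similarity within one expression model.

For each pair of traits analyzed under the same model, the Pearson
correlation of gene z-scores is computed over the genes that are
FDR-significant in at least one of the two traits (configurable to require
both) and tested in both. Assembled across all trait pairs this yields the
correlogram matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._stats import pearson_with_ci
from .exceptions import AdmixTwasError, InsufficientDataSignal
from .twas_engine import TwasResultSet, significant_set


@dataclass(frozen=True)
class DiseasePairCorrelation:
    trait_a: str
    trait_b: str
    model_id: str
    n_shared_genes: int
    r: float | None  # None when fewer than 3 usable genes ("absent cell")


def disease_pair_correlation(res_a: TwasResultSet, res_b: TwasResultSet,
                             sig_threshold: float = 0.05,
                             sig_rule: str = "either") -> DiseasePairCorrelation:
    """Correlate z-scores of two traits' results under one model.

    Gene set: significant (strict FDR < threshold) in either trait (or in
    both, with ``sig_rule="both"``), intersected with genes tested in both.
    """
    if res_a.model_id != res_b.model_id:
        raise AdmixTwasError(
            f"result sets from different models: {res_a.model_id} vs {res_b.model_id}")
    sig_a = significant_set(res_a, sig_threshold)
    sig_b = significant_set(res_b, sig_threshold)
    if sig_rule == "either":
        sig = sig_a | sig_b
    elif sig_rule == "both":
        sig = sig_a & sig_b
    else:
        raise ValueError(f"unknown sig_rule {sig_rule!r}")
    genes = sorted(sig & res_a.tested_genes() & res_b.tested_genes())
    za = res_a.zscores()
    zb = res_b.zscores()
    try:
        ci = pearson_with_ci(za.loc[genes], zb.loc[genes])
        r: float | None = ci.r
    except InsufficientDataSignal:
        r = None
    return DiseasePairCorrelation(trait_a=res_a.trait_id, trait_b=res_b.trait_id,
                                  model_id=res_a.model_id,
                                  n_shared_genes=len(genes), r=r)


def correlogram_matrix(results: Sequence[TwasResultSet], sig_threshold: float = 0.05,
                       sig_rule: str = "either"
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Symmetric trait-by-trait correlation matrix plus a long-form table.

    Diagonal cells are exactly 1; absent cells (fewer than 3 usable genes)
    are NaN in the matrix and flagged in the long-form table.
    """
    if not results:
        raise AdmixTwasError("no result sets")
    model_ids = {r.model_id for r in results}
    if len(model_ids) != 1:
        raise AdmixTwasError(f"result sets span several models: {sorted(model_ids)}")
    traits = [r.trait_id for r in results]
    if len(set(traits)) != len(traits):
        raise AdmixTwasError("duplicate trait_id among result sets")
    k = len(results)
    mat = np.full((k, k), np.nan)
    np.fill_diagonal(mat, 1.0)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            pair = disease_pair_correlation(results[i], results[j],
                                            sig_threshold, sig_rule)
            if pair.r is not None:
                mat[i, j] = mat[j, i] = pair.r
            rows.append({"trait_a": pair.trait_a, "trait_b": pair.trait_b,
                         "model_id": pair.model_id,
                         "n_shared_genes": pair.n_shared_genes,
                         "r": np.nan if pair.r is None else pair.r})
    matrix = pd.DataFrame(mat, index=traits, columns=traits)
    long_form = pd.DataFrame(rows)
    return matrix, long_form


def plot_correlogram(matrix: pd.DataFrame, path) -> None:
    """Dot-style correlogram (size and color encode r)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    traits = list(matrix.columns)
    k = len(traits)
    fig, ax = plt.subplots(figsize=(1.0 + 0.6 * k, 1.0 + 0.6 * k))
    xs, ys, sizes, colors = [], [], [], []
    for i in range(k):
        for j in range(k):
            r = matrix.iloc[i, j]
            if np.isnan(r):
                continue
            xs.append(j)
            ys.append(k - 1 - i)
            sizes.append(60 + 240 * abs(r))
            colors.append(r)
    sc = ax.scatter(xs, ys, s=sizes, c=colors, cmap="RdBu_r", vmin=-1, vmax=1,
                    edgecolors="grey", linewidths=0.5)
    ax.set_xticks(range(k), traits, rotation=45, ha="right")
    ax.set_yticks(range(k), traits[::-1])
    ax.set_xlim(-0.5, k - 0.5)
    ax.set_ylim(-0.5, k - 0.5)
    fig.colorbar(sc, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
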