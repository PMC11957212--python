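"""Small statistical helpers used throughout: Pearson r with a Fisher-z
confidence interval, and gene-id normalization."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import InsufficientDataSignal


def strip_gene_version(gene_id: str) -> str:
    """Drop a trailing Ensembl version suffix: ``ENSG000001.5`` -> ``ENSG000001``."""
    base, dot, version = gene_id.rpartition(".")
    if dot and version.isdigit():
        return base
    return gene_id


@dataclass(frozen=True)
class PearsonCI:
    """Pearson correlation with a 95% Fisher-z confidence interval."""

    r: float
    n: int
    ci_low: float
    ci_high: float


def pearson_with_ci(x, y, min_n: int = 3, conf: float = 0.95) -> PearsonCI:
    """Pearson r over paired vectors with a Fisher-z interval.

    The interval uses the classical large-sample form
    ``tanh(atanh(r) +/- z_crit / sqrt(n - 3))``; for n == 3 the standard
    error is undefined and the interval degenerates to (-1, 1).

    Raises
    ------
    InsufficientDataSignal
        If fewer than ``min_n`` pairs remain after dropping non-finite pairs,
        or either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < min_n:
        raise InsufficientDataSignal(f"need >= {min_n} pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InsufficientDataSignal("constant vector: correlation undefined")
    r = float(stats.pearsonr(x, y).statistic)
    if n <= 3:
        lo, hi = -1.0, 1.0
    else:
        zcrit = stats.norm.ppf(0.5 + conf / 2.0)
        # atanh diverges at |r| = 1; clip just inside the open interval
        z = math.atanh(max(-1.0 + 1e-15, min(1.0 - 1e-15, r)))
        se = 1.0 / math.sqrt(n - 3)
        lo, hi = math.tanh(z - zcrit * se), math.tanh(z + zcrit * se)
    return PearsonCI(r=r, n=int(n), ci_low=lo, ci_high=hi)
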