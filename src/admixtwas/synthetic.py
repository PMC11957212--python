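"""Two-population synthetic scaffold for the whole pipeline.

The generator emulates the data-generating process behind cross-ancestry
TWAS at desk scale:

* Two populations ("A", "B") diverge from a shared ancestral allele
  frequency under the Balding-Nichols model (population frequencies are Beta
  distributed around the ancestral frequency with spread set by Fst).
* Within each gene's cis block, LD follows a population-specific AR(1)
  autocorrelation: genotypes are produced by thresholding correlated latent
  Gaussians per haplotype, so dosages are 0/1/2 with Hardy-Weinberg structure
  and tunable, analytically simple LD.
* Expression is controlled by a few causal cis-eQTLs whose effects are
  *shared* across populations (the biology is common; only allele
  frequencies and LD differ). Each population trains its own sparse weight
  model on its own cohort, which reproduces the phenomenon under study:
  different populations tag the same causal signal through largely different
  SNP sets.
* A trait is mediated by genetically regulated expression (GReX): a subset
  of genes receives a nonzero gene-trait effect alpha_g, and GWAS z-scores
  come from per-SNP regressions in a GWAS cohort.

An individual-level oracle (regression of the phenotype on individually
imputed expression) provides the independent check that the
summary-statistic gene z-score must reproduce.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .exceptions import ConfigError, AdmixTwasError
from .gwas_io import GwasSumStats
from .model_io import (CovarianceTable, GeneModel, PredictionModel, SnpFeature,
                       write_covariance, write_model)

POPULATIONS = ("A", "B")
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("A", "T"), ("C", "G")]

# rng stream labels, combined with the seed so each stage draws independently
_STAGE_PANEL, _STAGE_EXPR, _STAGE_TRAIT, _STAGE_NIDP = 11, 13, 17, 19


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic two-population experiment.

    Defaults are the standard conditions used throughout the analyses:
    300 genes with 30 cis SNPs each, Fst 0.15 between populations, strong
    versus moderate cis LD (AR(1) rho 0.8 / 0.3), 3 causal eQTLs per gene
    explaining 25% of expression variance, 20% of genes trait-causal with
    GReX explaining 30% of trait variance, training cohorts of 500 per
    population and a GWAS cohort of 20,000. The per-population sparsity
    targets (28 and 8 SNPs) match the realized medians of the real admixed
    and European whole-blood models.
    """

    n_genes: int = 300
    snps_per_gene: int = 30
    ld_rho: tuple[float, float] = (0.8, 0.3)
    fst: float = 0.15
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal_eqtl_per_gene: int = 3
    h2_expr: float = 0.25
    prop_causal_genes: float = 0.2
    h2_trait: float = 0.3
    n_train: int = 500
    n_gwas: int = 20_000
    weight_method: str = "topk_marginal"
    topk: tuple[int, int] = (28, 8)
    min_cv_r2: float = 0.01
    #: cohort minor-allele-frequency floor for a SNP to enter model training,
    #: applied per population (the usual genotype QC step); with divergent
    #: frequencies this makes eligibility itself population-specific
    model_maf_min: float = 0.0
    gwas_population: str = "mix"  # "A", "B", or "mix" (half/half)
    seed: int = 42

    def __post_init__(self):
        if self.n_genes < 1 or self.snps_per_gene < 1:
            raise ConfigError("n_genes and snps_per_gene must be >= 1")
        if not all(0.0 <= r < 1.0 for r in self.ld_rho):
            raise ConfigError("ld_rho entries must lie in [0, 1)")
        if not (0.0 < self.fst < 1.0):
            raise ConfigError("fst must lie in (0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigError("maf_range must satisfy 0 < lo <= hi < 1")
        if not (0.0 <= self.h2_expr < 1.0):
            raise ConfigError("h2_expr must lie in [0, 1)")
        if not (0.0 <= self.h2_trait < 1.0):
            raise ConfigError("h2_trait must lie in [0, 1)")
        if not (0.0 <= self.prop_causal_genes <= 1.0):
            raise ConfigError("prop_causal_genes must lie in [0, 1]")
        if self.prop_causal_genes > 0 and self.n_genes >= 1 and self.h2_trait == 0 \
                and round(self.prop_causal_genes * self.n_genes) >= 1:
            raise ConfigError("h2_trait=0 with causal genes present is contradictory")
        if self.n_train < 2 or self.n_gwas < 3:
            raise ConfigError("cohort sizes too small")
        if self.weight_method not in ("topk_marginal", "coordinate_lasso"):
            raise ConfigError(f"unknown weight_method {self.weight_method!r}")
        if self.gwas_population not in ("A", "B", "mix"):
            raise ConfigError(f"unknown gwas_population {self.gwas_population!r}")
        if self.n_causal_eqtl_per_gene > self.snps_per_gene:
            raise ConfigError("more causal eQTLs than SNPs per gene")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ld_rho"] = list(self.ld_rho)
        d["maf_range"] = list(self.maf_range)
        d["topk"] = list(self.topk)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        for key in ("ld_rho", "maf_range", "topk"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _rng(stage: int, seed: int) -> np.random.Generator:
    return np.random.default_rng([stage, seed])


@dataclass
class Panel:
    """Genotype panel for both training cohorts and the GWAS cohort."""

    cfg: SimConfig
    gene_ids: list[str]
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ref_allele: np.ndarray
    eff_allele: np.ndarray
    ancestral_freq: np.ndarray
    pop_freq: dict[str, np.ndarray]
    #: cohort name -> int8 dosage matrix (n_individuals x n_snps)
    cohorts: dict[str, np.ndarray]
    #: cohort name -> per-row population label ("A"/"B")
    cohort_labels: dict[str, np.ndarray]
    gene_slices: dict[str, slice]

    _snp_index: dict[str, int] | None = field(default=None, repr=False)

    @property
    def n_snps(self) -> int:
        return self.snp_ids.size

    def snp_index(self) -> dict[str, int]:
        if self._snp_index is None:
            self._snp_index = {s: i for i, s in enumerate(self.snp_ids)}
        return self._snp_index

    def dosages(self, cohort: str, snp_ids: Sequence[str]) -> np.ndarray:
        index = self.snp_index()
        missing = [s for s in snp_ids if s not in index]
        if missing:
            raise AdmixTwasError(f"SNPs absent from panel: {missing[:5]}")
        idx = np.array([index[s] for s in snp_ids], dtype=int)
        return self.cohorts[cohort][:, idx].astype(float)


def _ar1_latent(rng: np.random.Generator, n: int, k: int, rho: float) -> np.ndarray:
    x = rng.standard_normal((n, k))
    if rho > 0:
        scale = np.sqrt(1.0 - rho * rho)
        for l in range(1, k):
            x[:, l] = rho * x[:, l - 1] + scale * x[:, l]
    return x


def simulate_panel(cfg: SimConfig) -> Panel:
    """Draw the two-population genotype panel.

    Ancestral frequencies are Uniform(maf_range); population frequencies are
    Balding-Nichols Beta draws (redrawn up to 20 times if numerically
    monomorphic); dosages come from two thresholded AR(1)-correlated latent
    Gaussian haplotypes per individual.
    """
    rng = _rng(_STAGE_PANEL, cfg.seed)
    n_snps = cfg.n_genes * cfg.snps_per_gene
    anc = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=n_snps)

    shape = (1.0 - cfg.fst) / cfg.fst
    pop_freq: dict[str, np.ndarray] = {}
    for pop in POPULATIONS:
        freq = rng.beta(anc * shape, (1.0 - anc) * shape)
        bad = (freq < 1e-4) | (freq > 1 - 1e-4)
        retries = 0
        while bad.any():
            retries += 1
            if retries > 20:
                raise AdmixTwasError(
                    f"population {pop}: {int(bad.sum())} SNPs monomorphic after 20 redraws")
            freq[bad] = rng.beta(anc[bad] * shape, (1.0 - anc[bad]) * shape)
            bad = (freq < 1e-4) | (freq > 1 - 1e-4)
        pop_freq[pop] = freq

    gene_ids = [f"G{g:04d}" for g in range(cfg.n_genes)]
    gene_slices = {gid: slice(g * cfg.snps_per_gene, (g + 1) * cfg.snps_per_gene)
                   for g, gid in enumerate(gene_ids)}
    snp_ids = np.array([f"rs{i + 1:07d}" for i in range(n_snps)])
    # genes parked on chr1..22 well away from the default masked windows
    chrom = np.empty(n_snps, dtype=object)
    pos = np.empty(n_snps, dtype=np.int64)
    for g, gid in enumerate(gene_ids):
        sl = gene_slices[gid]
        chrom[sl] = str((g % 22) + 1)
        base = 100_000_000 + (g // 22) * 1_000_000
        pos[sl] = base + np.arange(cfg.snps_per_gene) * 1_000
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n_snps)
    ref_allele = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    eff_allele = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])

    cohort_pops: dict[str, list[tuple[str, int]]] = {
        "train_A": [("A", cfg.n_train)],
        "train_B": [("B", cfg.n_train)],
    }
    if cfg.gwas_population == "mix":
        half = cfg.n_gwas // 2
        cohort_pops["gwas"] = [("A", half), ("B", cfg.n_gwas - half)]
    else:
        cohort_pops["gwas"] = [(cfg.gwas_population, cfg.n_gwas)]

    cohorts = {name: np.empty((sum(n for _, n in parts), n_snps), dtype=np.int8)
               for name, parts in cohort_pops.items()}
    cohort_labels = {name: np.concatenate([np.full(n, pop) for pop, n in parts])
                     for name, parts in cohort_pops.items()}
    thresholds = {pop: stats.norm.ppf(pop_freq[pop]) for pop in POPULATIONS}
    for gid in gene_ids:
        sl = gene_slices[gid]
        k = cfg.snps_per_gene
        for name, parts in cohort_pops.items():
            row = 0
            for pop, n in parts:
                rho = cfg.ld_rho[0] if pop == "A" else cfg.ld_rho[1]
                thr = thresholds[pop][sl]
                hap1 = _ar1_latent(rng, n, k, rho) < thr
                hap2 = _ar1_latent(rng, n, k, rho) < thr
                cohorts[name][row:row + n, sl] = (hap1.astype(np.int8)
                                                  + hap2.astype(np.int8))
                row += n
    return Panel(cfg=cfg, gene_ids=gene_ids, snp_ids=snp_ids, chrom=chrom,
                 pos=pos, ref_allele=ref_allele, eff_allele=eff_allele,
                 ancestral_freq=anc, pop_freq=pop_freq, cohorts=cohorts,
                 cohort_labels=cohort_labels, gene_slices=gene_slices)


@dataclass
class SimTruth:
    """Ground truth for recovery tests."""

    causal_snps: dict[str, list[str]]
    causal_effects: dict[str, np.ndarray]
    #: gene -> gene-trait effect; zero until a trait is simulated, and zero
    #: for non-causal genes afterwards
    alpha: dict[str, float]
    #: population -> gene -> realized 5-fold cv r^2 (all genes, pre-filter)
    cv_r2: dict[str, dict[str, float]]
    #: population -> gene -> selected SNP ids (possibly empty)
    selected: dict[str, dict[str, list[str]]]


def _train_weights(G: np.ndarray, expr: np.ndarray, k: int, method: str,
                   maf_min: float = 0.0) -> np.ndarray | None:
    """Sparse weights for one gene in one population; None if nothing selected.

    ``topk_marginal``: rank SNPs by |marginal correlation| with expression in
    the training cohort, keep the top k, fit joint least squares on the kept
    set. ``coordinate_lasso``: L1 path with 5-fold cross-validated penalty.
    Returns a dense weight vector over the gene's SNPs (zeros off-support).
    """
    n, p = G.shape
    Gc = G - G.mean(axis=0)
    sd = Gc.std(axis=0)
    freq = G.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    usable = (sd > 0) & (maf >= maf_min)
    if not usable.any():
        return None
    ec = expr - expr.mean()
    if ec.std() == 0:
        return None
    if method == "topk_marginal":
        corr = np.zeros(p)
        denom = sd * ec.std()
        good = usable & (denom > 0)
        corr[good] = (Gc.T @ ec / n)[good] / denom[good]
        k_eff = min(k, int(good.sum()), max(n - 2, 1))
        order = np.argsort(-np.abs(corr), kind="mergesort")[:k_eff]
        sel = np.sort(order)
        coef, *_ = np.linalg.lstsq(Gc[:, sel], ec, rcond=None)
        w = np.zeros(p)
        w[sel] = coef
    else:  # coordinate_lasso
        from sklearn.linear_model import LassoCV
        model = LassoCV(cv=5, alphas=30, random_state=0, max_iter=5000)
        model.fit(Gc[:, usable], ec)
        w = np.zeros(p)
        w[usable] = model.coef_
    if not np.any(w != 0):
        return None
    return w


def _cv_r2(G: np.ndarray, expr: np.ndarray, support: np.ndarray, folds: int = 5) -> float:
    """Out-of-fold r^2 refitting least squares on a fixed support.

    The support comes from the full training data, so this is mildly
    optimistic relative to re-selecting within each fold; adequate for a
    model-quality summary statistic.
    """
    n = G.shape[0]
    if support.sum() == 0 or n < 2 * folds:
        return 0.0
    Gs = G[:, support]
    pred = np.empty(n)
    bounds = np.linspace(0, n, folds + 1).astype(int)
    for f in range(folds):
        test = np.zeros(n, dtype=bool)
        test[bounds[f]:bounds[f + 1]] = True
        Xtr, ytr = Gs[~test], expr[~test]
        mu_x, mu_y = Xtr.mean(axis=0), ytr.mean()
        coef, *_ = np.linalg.lstsq(Xtr - mu_x, ytr - mu_y, rcond=None)
        pred[test] = (Gs[test] - mu_x) @ coef + mu_y
    if np.std(pred) == 0 or np.std(expr) == 0:
        return 0.0
    r = float(np.corrcoef(pred, expr)[0, 1])
    return float(min(max(r * r, 0.0), 1.0))


def simulate_expression_and_weights(panel: Panel, cfg: SimConfig | None = None
                                    ) -> tuple[PredictionModel, PredictionModel, SimTruth]:
    """Shared causal eQTL architecture; per-population sparse weight models.

    Expression in each cohort is the causal-dosage signal plus noise scaled
    so the causal component explains ``h2_expr`` of variance in that cohort.
    A gene enters a population's model only if weight training selects at
    least one SNP and the realized 5-fold cv r^2 clears ``min_cv_r2``.
    """
    cfg = cfg or panel.cfg
    rng = _rng(_STAGE_EXPR, cfg.seed)
    truth = SimTruth(causal_snps={}, causal_effects={},
                     alpha={gid: 0.0 for gid in panel.gene_ids},
                     cv_r2={pop: {} for pop in POPULATIONS},
                     selected={pop: {} for pop in POPULATIONS})
    genes: dict[str, dict[str, GeneModel]] = {pop: {} for pop in POPULATIONS}

    for gid in panel.gene_ids:
        sl = panel.gene_slices[gid]
        k_block = cfg.snps_per_gene
        causal_idx = np.sort(rng.choice(k_block, size=cfg.n_causal_eqtl_per_gene,
                                        replace=False))
        effects = rng.standard_normal(cfg.n_causal_eqtl_per_gene)
        truth.causal_snps[gid] = list(panel.snp_ids[sl][causal_idx])
        truth.causal_effects[gid] = effects

        for pop, cohort in (("A", "train_A"), ("B", "train_B")):
            G = panel.cohorts[cohort][:, sl].astype(float)
            genetic = G[:, causal_idx] @ effects if cfg.h2_expr > 0 else \
                np.zeros(G.shape[0])
            var_g = float(np.var(genetic))
            if cfg.h2_expr > 0 and var_g > 0:
                noise_sd = np.sqrt(var_g * (1.0 - cfg.h2_expr) / cfg.h2_expr)
            else:
                genetic = np.zeros(G.shape[0])
                noise_sd = 1.0
            expr = genetic + rng.standard_normal(G.shape[0]) * noise_sd

            k_target = cfg.topk[0] if pop == "A" else cfg.topk[1]
            w = _train_weights(G, expr, k_target, cfg.weight_method,
                               maf_min=cfg.model_maf_min)
            if w is None:
                truth.cv_r2[pop][gid] = 0.0
                truth.selected[pop][gid] = []
                continue
            support = w != 0
            r2 = _cv_r2(G, expr, support)
            truth.cv_r2[pop][gid] = r2
            sel_ids = list(panel.snp_ids[sl][support])
            truth.selected[pop][gid] = sel_ids
            if r2 < cfg.min_cv_r2:
                continue
            abs_idx = np.arange(sl.start, sl.stop)[support]
            features = [SnpFeature(snp_id=panel.snp_ids[i],
                                   ref_allele=panel.ref_allele[i],
                                   eff_allele=panel.eff_allele[i],
                                   weight=float(wv),
                                   chrom=str(panel.chrom[i]),
                                   pos=int(panel.pos[i]))
                        for i, wv in zip(abs_idx, w[support])]
            genes[pop][gid] = GeneModel(gene_id=gid, gene_name=f"{gid}_sym",
                                        features=features, cv_r2=r2)

    model_a = PredictionModel(model_id="SYN_A", genes=genes["A"],
                              ancestry_label="synthetic population A")
    model_b = PredictionModel(model_id="SYN_B", genes=genes["B"],
                              ancestry_label="synthetic population B")
    return model_a, model_b, truth


def _grex_matrix(panel: Panel, truth: SimTruth, cohort: str,
                 gene_ids: Sequence[str]) -> np.ndarray:
    """True (causal-component) GReX per individual for the given genes."""
    n = panel.cohorts[cohort].shape[0]
    out = np.empty((n, len(gene_ids)))
    for j, gid in enumerate(gene_ids):
        G = panel.dosages(cohort, truth.causal_snps[gid])
        out[:, j] = G @ truth.causal_effects[gid]
    return out


def simulate_trait_gwas(panel: Panel, truth: SimTruth, cfg: SimConfig | None = None,
                        trait_id: str = "SYN_TRAIT"
                        ) -> tuple[GwasSumStats, np.ndarray]:
    """GReX-mediated phenotype and per-SNP GWAS in the GWAS cohort.

    A fraction of genes receives alpha_g ~ N(0,1) acting on its standardized
    true GReX; noise is scaled so GReX explains ``h2_trait`` of trait
    variance. Per-SNP z-scores are simple-regression statistics. ``truth``
    is updated in place with the drawn alphas.
    """
    cfg = cfg or panel.cfg
    rng = _rng(_STAGE_TRAIT, cfg.seed)
    n_causal = int(round(cfg.prop_causal_genes * cfg.n_genes))
    if n_causal > 0 and cfg.h2_trait == 0:
        raise ConfigError("h2_trait=0 with prop_causal_genes>0")
    causal_genes = sorted(rng.choice(panel.gene_ids, size=n_causal, replace=False)) \
        if n_causal else []
    alphas = rng.standard_normal(n_causal)
    for gid in panel.gene_ids:
        truth.alpha[gid] = 0.0
    n = panel.cohorts["gwas"].shape[0]
    y_gen = np.zeros(n)
    if n_causal:
        grex = _grex_matrix(panel, truth, "gwas", causal_genes)
        sd = grex.std(axis=0)
        ok = sd > 0
        grex_std = np.zeros_like(grex)
        grex_std[:, ok] = (grex[:, ok] - grex[:, ok].mean(axis=0)) / sd[ok]
        alphas = np.where(ok, alphas, 0.0)
        for gid, a in zip(causal_genes, alphas):
            truth.alpha[gid] = float(a)
        y_gen = grex_std @ alphas
    var_gen = float(np.var(y_gen))
    if var_gen > 0:
        noise_sd = np.sqrt(var_gen * (1.0 - cfg.h2_trait) / cfg.h2_trait)
    else:
        noise_sd = 1.0
    y = y_gen + rng.standard_normal(n) * noise_sd

    table = _per_snp_gwas(panel, y, trait_id)
    return GwasSumStats(trait_id=trait_id, table=table), y


def _center_within(x: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Subtract group means — the ancestry-covariate adjustment that real
    multi-ancestry GWAS apply (here exact, since ancestry is discrete)."""
    out = np.array(x, dtype=float, copy=True)
    for lab in np.unique(labels):
        m = labels == lab
        out[m] = out[m] - out[m].mean(axis=0)
    return out


def _per_snp_gwas(panel: Panel, y: np.ndarray, trait_id: str) -> pd.DataFrame:
    """Ancestry-adjusted simple-regression beta, se, z of y on each dosage."""
    n = y.size
    labels = panel.cohort_labels["gwas"]
    yc = _center_within(y, labels)
    var_y = float(yc @ yc) / (n - 1)
    rows = {k: [] for k in ("snp_id", "chrom", "pos", "a1", "a2",
                            "zscore", "beta", "se")}
    for gid in panel.gene_ids:
        sl = panel.gene_slices[gid]
        G = panel.cohorts["gwas"][:, sl].astype(float)
        Gc = _center_within(G, labels)
        var_g = (Gc * Gc).sum(axis=0) / (n - 1)
        poly = var_g > 0
        cov = (yc @ Gc) / (n - 1)
        beta = np.zeros_like(var_g)
        beta[poly] = cov[poly] / var_g[poly]
        r = np.zeros_like(var_g)
        r[poly] = cov[poly] / np.sqrt(var_g[poly] * var_y)
        r = np.clip(r, -1 + 1e-12, 1 - 1e-12)
        se = np.full_like(var_g, np.nan)
        se[poly] = np.sqrt(np.maximum(var_y * (1 - r[poly] ** 2), 0.0)
                           / (var_g[poly] * (n - 2)))
        z = np.where(poly & (se > 0), beta / se, 0.0)
        keep = poly
        idx = np.arange(sl.start, sl.stop)[keep]
        rows["snp_id"].extend(panel.snp_ids[idx])
        rows["chrom"].extend(panel.chrom[idx])
        rows["pos"].extend(panel.pos[idx])
        rows["a1"].extend(panel.eff_allele[idx])
        rows["a2"].extend(panel.ref_allele[idx])
        rows["zscore"].extend(z[keep])
        rows["beta"].extend(beta[keep])
        rows["se"].extend(se[keep])
    table = pd.DataFrame(rows)
    table["pos"] = table["pos"].astype("Int64")
    table["n"] = pd.array([n] * len(table), dtype="Int64")
    return table.set_index("snp_id")


def simulate_multi_trait_gwas(panel: Panel, truth: SimTruth,
                              trait_ids: Sequence[str],
                              trait_corr: np.ndarray,
                              cfg: SimConfig | None = None
                              ) -> tuple[dict[str, GwasSumStats], pd.DataFrame]:
    """Several GReX-mediated traits with correlated gene-effect vectors.

    For each causal gene, the per-trait effects alpha_{g,.} are drawn from a
    multivariate normal with the supplied trait-by-trait correlation, so the
    planted cross-trait transcriptomic similarity equals ``trait_corr`` up to
    sampling noise. Returns per-trait summary statistics and the alpha table.
    """
    cfg = cfg or panel.cfg
    k = len(trait_ids)
    trait_corr = np.asarray(trait_corr, dtype=float)
    if trait_corr.shape != (k, k) or not np.allclose(trait_corr, trait_corr.T):
        raise ConfigError("trait_corr must be a symmetric k x k matrix")
    rng = _rng(_STAGE_TRAIT, cfg.seed)
    n_causal = int(round(cfg.prop_causal_genes * cfg.n_genes))
    if n_causal == 0:
        raise ConfigError("multi-trait simulation needs causal genes")
    causal_genes = sorted(rng.choice(panel.gene_ids, size=n_causal, replace=False))
    chol = np.linalg.cholesky(trait_corr + 1e-10 * np.eye(k))
    alpha = rng.standard_normal((n_causal, k)) @ chol.T

    grex = _grex_matrix(panel, truth, "gwas", causal_genes)
    sd = grex.std(axis=0)
    ok = sd > 0
    grex_std = np.zeros_like(grex)
    grex_std[:, ok] = (grex[:, ok] - grex[:, ok].mean(axis=0)) / sd[ok]
    alpha[~ok, :] = 0.0

    n = grex.shape[0]
    out: dict[str, GwasSumStats] = {}
    for t, tid in enumerate(trait_ids):
        y_gen = grex_std @ alpha[:, t]
        var_gen = float(np.var(y_gen))
        noise_sd = np.sqrt(var_gen * (1 - cfg.h2_trait) / cfg.h2_trait) \
            if var_gen > 0 else 1.0
        y = y_gen + rng.standard_normal(n) * noise_sd
        out[tid] = GwasSumStats(trait_id=tid, table=_per_snp_gwas(panel, y, tid))
    alpha_table = pd.DataFrame(alpha, index=causal_genes, columns=list(trait_ids))
    alpha_table.index.name = "gene"
    return out, alpha_table


def compute_reference_covariance(panel: Panel, model: PredictionModel,
                                 cohort: str = "train_A") -> CovarianceTable:
    """Empirical per-gene dosage covariance over a designated cohort."""
    if panel.cohorts[cohort].shape[0] < 2:
        raise AdmixTwasError("covariance undefined for a single-individual cohort")
    table = CovarianceTable()
    for gid in sorted(model.genes):
        gm = model.genes[gid]
        G = panel.dosages(cohort, gm.snp_ids)
        mat = np.cov(G, rowvar=False, ddof=1)
        mat = np.atleast_2d(mat)
        table.add(gid, gm.snp_ids, mat)
    return table


def individual_oracle_twas(panel: Panel, model: PredictionModel,
                           phenotypes: np.ndarray, cohort: str = "gwas"
                           ) -> pd.DataFrame:
    """Individual-level oracle: regress y on individually imputed expression.

    Per gene, predicted expression is dosage @ weights; the oracle z is the
    t-statistic of the simple regression of the phenotype on it (reported on
    the z scale). Genes with zero-variance prediction are skipped.
    """
    y = np.asarray(phenotypes, dtype=float)
    n = y.size
    if panel.cohorts[cohort].shape[0] != n:
        raise AdmixTwasError("phenotype length does not match cohort size")
    labels = panel.cohort_labels[cohort]
    yc = _center_within(y, labels)
    rows = []
    for gid in sorted(model.genes):
        gm = model.genes[gid]
        pred = panel.dosages(cohort, gm.snp_ids) @ gm.weights
        pred = _center_within(pred, labels)
        if np.std(pred) == 0:
            continue
        r = float(np.corrcoef(yc, pred)[0, 1])
        r = min(max(r, -1 + 1e-15), 1 - 1e-15)
        z = r * np.sqrt((n - 2) / (1 - r * r))
        rows.append((gid, z, float(np.std(pred))))
    return pd.DataFrame(rows, columns=["gene", "oracle_z", "pred_sd"])


def snp_set_jaccard(model_a: PredictionModel, model_b: PredictionModel
                    ) -> pd.Series:
    """Per-gene Jaccard index of SNP-feature sets over co-carried genes."""
    out = {}
    for gid in sorted(set(model_a.genes) & set(model_b.genes)):
        sa = set(model_a.genes[gid].snp_ids)
        sb = set(model_b.genes[gid].snp_ids)
        out[gid] = len(sa & sb) / len(sa | sb)
    return pd.Series(out, dtype=float)


# ---------------------------------------------------------------------------
# NIDP repository fixture

_DESIKAN_REGIONS = ["superiorfrontal", "precentral", "insula", "fusiform",
                    "lateraloccipital", "superiortemporal"]
_SUBCORTEX_REGIONS = ["putamen", "thalamus", "hippocampus", "amygdala", "caudate"]


def simulate_nidp_repository(gene_ids: Sequence[str],
                             associated_genes: Sequence[str],
                             seed: int,
                             n_nidps: int = 40) -> pd.DataFrame:
    """Synthetic gene->NIDP association repository.

    Each NIDP is a (atlas, region, measure, hemisphere) quadruple; a few
    driver genes from ``associated_genes`` get small p-values and planted
    effects, and 2-7 random background gene-NIDP rows per NIDP get null
    p-values.
    """
    rng = _rng(_STAGE_NIDP, seed)
    associated = list(associated_genes)
    gene_ids = list(gene_ids)
    rows = []
    seen: set[tuple[str, str]] = set()
    for i in range(n_nidps):
        if rng.uniform() < 0.6:
            atlas = "Desikan"
            region = _DESIKAN_REGIONS[int(rng.integers(len(_DESIKAN_REGIONS)))]
            measure = ("area", "thickness", "volume")[int(rng.integers(3))]
        else:
            atlas = "Subcortex"
            region = _SUBCORTEX_REGIONS[int(rng.integers(len(_SUBCORTEX_REGIONS)))]
            measure = "volume"
        hemisphere = ("left", "right", "bilateral")[int(rng.integers(3))]
        nidp_id = f"NIDP{i:04d}_{atlas}_{region}_{measure}_{hemisphere}"
        n_drivers = int(rng.integers(1, 4))
        if associated:
            drivers = rng.choice(associated, size=min(n_drivers, len(associated)),
                                 replace=False)
        else:
            drivers = []
        for g in drivers:
            if (g, nidp_id) in seen:
                continue
            seen.add((g, nidp_id))
            rows.append((g, nidp_id, atlas, measure, hemisphere, region,
                         float(rng.standard_normal() * 2.0),
                         float(10 ** rng.uniform(-6, -3))))
        for _ in range(int(rng.integers(2, 8))):
            g = gene_ids[int(rng.integers(len(gene_ids)))]
            if (g, nidp_id) in seen:
                continue
            seen.add((g, nidp_id))
            rows.append((g, nidp_id, atlas, measure, hemisphere, region,
                         float(rng.standard_normal() * 0.3),
                         float(rng.uniform(0.05, 1.0))))
    repo = pd.DataFrame(rows, columns=["gene", "nidp_id", "atlas", "measure",
                                       "hemisphere", "region", "effect", "pvalue"])
    return repo.sort_values(["nidp_id", "gene"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# named study conditions


def oracle_config(seed: int = 42) -> SimConfig:
    """Summary-vs-individual oracle fixture: 100 genes, 2,000 GWAS individuals."""
    return SimConfig(n_genes=100, snps_per_gene=30, n_gwas=2_000, n_train=500,
                     seed=seed)


def null_config(seed: int = 42) -> SimConfig:
    """Global null: 2,000 genes, no trait-causal genes, matched-population GWAS."""
    return SimConfig(n_genes=2_000, snps_per_gene=30, prop_causal_genes=0.0,
                     h2_trait=0.0, n_gwas=2_000, n_train=300,
                     gwas_population="A", seed=seed)


def recovery_config(seed: int = 42) -> SimConfig:
    """Parameter-recovery conditions: the package defaults."""
    return SimConfig(n_genes=300, snps_per_gene=30, n_gwas=20_000,
                     h2_trait=0.3, prop_causal_genes=0.2, seed=seed)


def divergence_config(seed: int = 42) -> SimConfig:
    """Divergent-architecture conditions.

    Wide cis candidate pools (300 SNPs/gene) so the two models' sparse
    selections (28 vs 8) can genuinely diverge, strong population
    differentiation (Fst 0.15) with contrasting LD (rho 0.8 vs 0.3), an
    allele-frequency range reaching down to 0.02 so causal eQTLs differ in
    power between populations, and training cohorts of 800 so each model is
    individually accurate. Under these conditions the per-gene SNP-set
    Jaccard between the two models has median below 0.1 — the models tag the
    shared causal signal through almost entirely different SNPs.
    """
    return SimConfig(n_genes=150, snps_per_gene=300, fst=0.15, ld_rho=(0.8, 0.3),
                     maf_range=(0.02, 0.5), n_gwas=10_000, n_train=800,
                     h2_trait=0.3, prop_causal_genes=0.25, seed=seed)


# ---------------------------------------------------------------------------
# fixture export


def sparse_overlap_config(seed: int = 42) -> SimConfig:
    """Eligibility-divergence conditions: most genes share no SNP features.

    Causal alleles drawn down to frequency 0.01 plus a cohort MAF filter of
    0.10 make SNP eligibility itself population-specific, and a modest
    expression heritability with a cv-r2 floor makes gene membership
    model-specific — so the two models rely on largely or entirely distinct
    SNP sets, the regime the cross-model comparison is designed to probe.
    """
    return SimConfig(n_genes=80, snps_per_gene=150, fst=0.15, ld_rho=(0.8, 0.3),
                     maf_range=(0.01, 0.25), model_maf_min=0.10, h2_expr=0.08,
                     min_cv_r2=0.06, n_train=300, n_gwas=100, seed=seed)


def export_fixture(cfg: SimConfig, out_dir, trait_id: str = "SYN_TRAIT") -> dict:
    """Run the full generator and write a text fixture bundle.

    Writes both prediction models (TSV + metadata sidecars), per-model
    covariance references, GWAS summary statistics, the truth table, a
    synthetic NIDP repository, and a manifest with the seed and realized
    summary statistics. Byte-identical across re-runs with the same config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel = simulate_panel(cfg)
    model_a, model_b, truth = simulate_expression_and_weights(panel, cfg)
    gwas, y = simulate_trait_gwas(panel, truth, cfg, trait_id=trait_id)

    write_model(model_a, out / "model_A.tsv")
    write_model(model_b, out / "model_B.tsv")
    cov_a = compute_reference_covariance(panel, model_a, cohort="train_A")
    cov_b = compute_reference_covariance(panel, model_b, cohort="train_B")
    write_covariance(cov_a, out / "covariance_A.txt.gz")
    write_covariance(cov_b, out / "covariance_B.txt.gz")

    gtab = gwas.table.reset_index()
    gtab.to_csv(out / f"gwas_{trait_id}.tsv", sep="\t", index=False)

    truth_rows = [{"gene": gid,
                   "alpha": truth.alpha[gid],
                   "causal_snps": ",".join(truth.causal_snps[gid]),
                   "causal_effects": ",".join(repr(v) for v in truth.causal_effects[gid]),
                   "cv_r2_A": truth.cv_r2["A"].get(gid, float("nan")),
                   "cv_r2_B": truth.cv_r2["B"].get(gid, float("nan"))}
                  for gid in panel.gene_ids]
    pd.DataFrame(truth_rows).to_csv(out / "truth.tsv", sep="\t", index=False)

    sig_like = [gid for gid in panel.gene_ids if truth.alpha[gid] != 0.0]
    repo = simulate_nidp_repository(panel.gene_ids, sig_like or panel.gene_ids[:10],
                                    seed=cfg.seed)
    repo.to_csv(out / "nidp_repository.tsv", sep="\t", index=False)

    jac = snp_set_jaccard(model_a, model_b)
    manifest = {
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "trait_id": trait_id,
        "realized": {
            "n_genes_model_A": model_a.n_genes,
            "n_genes_model_B": model_b.n_genes,
            "median_snps_per_gene_A": float(np.median(
                [g.n_features for g in model_a.genes.values()])) if model_a.n_genes else None,
            "median_snps_per_gene_B": float(np.median(
                [g.n_features for g in model_b.genes.values()])) if model_b.n_genes else None,
            "median_cv_r2_A": float(np.median(list(truth.cv_r2["A"].values()))),
            "median_cv_r2_B": float(np.median(list(truth.cv_r2["B"].values()))),
            "median_snp_set_jaccard": float(jac.median()) if len(jac) else None,
            "n_gwas_snps": int(gwas.n_snps),
        },
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
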