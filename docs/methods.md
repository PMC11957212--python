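# Methods

## The gene-level statistic

For a gene g with model weights `w` (oriented to each SNP's effect allele),
harmonized GWAS z-scores `z`, and an LD-reference dosage covariance `Γ`
restricted to the gene's SNPs, the summary-statistic TWAS z-score is

    z_g = Σ_l w_l σ_l z_l / σ_g,   σ_l = √Γ_ll,   σ_g = √(wᵀ Γ w).

`σ_g` is the reference-panel standard deviation of the gene's imputed
(genetically regulated) expression; under the null hypothesis of no
gene–trait association, and when the reference LD matches the GWAS
population, `z_g` is standard normal. Two-sided normal p-values follow,
floored at 1e-300; Benjamini–Hochberg step-up adjustment is applied within
each (model, trait) result set, treated as an independent study; the
significance rule everywhere is the strict inequality `FDR p < 0.05`.

Properties the implementation guarantees (and the tests assert):

- invariance to SNP relabeling/reordering — internally SNPs are processed
  in canonical lexicographic order, so the result is bit-for-bit identical
  regardless of input order;
- invariance to simultaneous allele flips (model weight, GWAS z, and the
  corresponding covariance row/column all change sign — the statistic does
  not);
- invariance to positive rescaling of a gene's weight vector;
- SNPs missing from the covariance reference are dropped (logged), and a
  gene is skipped with a typed reason code when no SNP remains or when
  `σ_g² ≤ 1e-12`.

## Harmonization and masking

GWAS records are matched to model SNPs by rsID. If the GWAS effect/other
allele pair equals the model's effect/reference pair the z-score is kept;
if it is exactly swapped the z-score is negated; any other combination
drops the SNP with a per-gene count. Strand-ambiguous SNPs (A/T, C/G) are
matched literally — deterministic and logged, rather than guessed from
allele frequencies that the input may not carry.

Region masks act on gene-level *results* by interval overlap of the gene's
SNP span, not on GWAS SNPs. Defaults (GRCh38, 1-based inclusive,
configurable): MHC chr6:25,000,000–34,000,000 for every model; the
inversion polymorphism regions chr8:7,000,000–13,000,000 and
chr17:43,000,000–47,000,000 only for models flagged European-dominant,
since those inversions are disproportionately captured in European ancestry
and violate the LD assumptions behind the statistic. FDR is computed after
masking, over surviving genes.

## Cross-model comparison

Both models are first restricted to GWAS-interrogated SNPs. Genes are
classified on two axes: SNP-feature sharing (`A_only`, `B_only`,
`shared_distinct` — both models carry the gene with disjoint SNP sets —
`shared_overlapping` — at least one SNP shared) and significance pattern
(`none`/`A_only`/`B_only`/`both` by strict FDR < 0.05; a gene absent from a
model counts as not significant there and is flagged). Pearson correlations
of z-scores and of p-values are reported per stratum with Fisher-z 95%
intervals (`tanh(atanh r ± 1.96/√(n−3))`); strata with fewer than 3 genes
are reported absent rather than as a number. P-value correlations are
emitted both raw and on the −log10 scale, explicitly labeled, because the
two transforms answer slightly different questions and neither is
canonical. Shared-SNP weight correlations sign-align the two encodings
first (a pair encoding opposite effect alleles has one weight negated);
allele-incompatible pairs are dropped and counted. The threshold sweep
filters co-tested genes on the *discovery* set's nominal p-value and
correlates z-scores against the unfiltered companion set. When several
ancestry-specific models are pooled against one reference model, the ANY
rule applies: per gene the association with the smallest FDR across members
is kept.

## Disease similarity and neuroimaging mapping

For two traits under the same model, the correlated gene set is
{significant in either trait} ∩ {tested in both}; the either-rule maximizes
n and is configurable to require both. The correlogram matrix is symmetric
with exact unit diagonal; cells with n < 3 stay empty.

The neuroimaging stage consumes a repository of precomputed gene → NIDP
associations (Desikan cortical area/thickness/volume, subcortical volumes;
signed effect and p-value per pair). A trait's significant gene set selects
the matching repository rows, BH adjustment is re-run **within the queried
subset** (the repository-wide adjusted values would answer a different
question; this choice is deliberate and local), and pairs with adjusted
p < threshold survive. Region summaries average effects within
(atlas, region, measure, hemisphere) and conserve pair counts. The
model-specificity statistic counts an NIDP (by `nidp_id`, so bilateral
homologs count separately) iff *every* surviving pair for it involves a
gene significant only in the A-side model.

## The synthetic generator

The generator reproduces, at desk scale, the mechanism that makes
cross-ancestry TWAS interesting: **shared causal biology tagged through
population-specific LD and allele frequencies.**

- *Genotypes.* Ancestral allele frequencies are Uniform over `maf_range`;
  each population's frequencies are Balding–Nichols Beta draws with
  differentiation `fst` (monomorphic draws are redrawn, capped at 20).
  Within each gene's cis block, two latent AR(1)-correlated Gaussian
  haplotypes per individual are thresholded at the population frequency
  quantile, giving 0/1/2 dosages with Hardy–Weinberg structure and tunable
  LD. Dosage correlation is attenuated relative to the latent ρ
  (dichotomization), which is acceptable: LD only needs to be controllable,
  not calibrated to a map.
- *Expression.* Each gene has `n_causal_eqtl_per_gene` causal cis SNPs with
  N(0,1) effects, identical in both populations; noise is scaled per cohort
  so the causal component explains `h2_expr` of expression variance.
- *Weight training.* Default `topk_marginal`: rank SNPs by |marginal
  correlation| in the training cohort, keep the top k (k = 28 and 8 for the
  two populations — the realized medians of the real admixed and European
  whole-blood models), fit joint least squares on the kept set.
  `coordinate_lasso` (cross-validated L1) is available for realism. A
  cohort minor-allele-frequency floor (`model_maf_min`) makes SNP
  *eligibility* population-specific, the main driver of fully disjoint
  feature sets. Model quality is summarized by 5-fold out-of-fold r²
  (support fixed from the full fit — mildly optimistic, adequate for a
  summary); genes below `min_cv_r2` are omitted from that model, which is
  how genes tested in only one model arise.
- *Trait.* A fraction `prop_causal_genes` of genes receives
  `α_g ~ N(0,1)` acting on standardized true GReX (the causal genetic
  component of expression, not the noisy trained prediction); noise is
  scaled so GReX explains `h2_trait` of trait variance. Per-SNP GWAS
  z-scores are simple-regression statistics with exact within-population
  centering of phenotype and dosages — the discrete-ancestry analogue of
  the principal-component adjustment every multi-ancestry GWAS applies.
  Without it, ancestry-frequency confounding inflates associations genome
  wide. A multi-trait variant draws per-gene effect vectors from a
  multivariate normal with a planted trait-by-trait correlation, for
  correlogram tests.
- *Oracle.* The individual-level oracle imputes expression per individual
  (dosage · weights) and regresses the phenotype on it (same ancestry
  adjustment); the summary statistic must track it (r > 0.98 at the test
  conditions; exact for single-SNP genes up to the sign of the weight).
- Every stage is a pure function of (config, seed); covariance exports are
  gzipped with fixed mtime and empty embedded filename so identical
  configurations are byte-identical on disk.

### Named study conditions and their rationale

- `oracle_config` — 100 genes × 30 SNPs, 2,000 GWAS individuals: small
  enough to run in seconds, large enough that oracle concordance is
  estimated over ~100 genes. The LD reference here is the GWAS cohort
  itself, because the oracle-equivalence claim is about the statistic, not
  about reference mismatch.
- `null_config` — 2,000 genes, no causal genes, single-population GWAS with
  a matched reference: the calibration claim (|z| > 1.96 near 5%, BH
  discoveries near zero) holds when the reference matches the GWAS
  population. With a mismatched reference the variance of `z_g` departs
  from 1 — a known property of the statistic, not a bug, and the reason the
  packaged default uses each model's own training population for its
  shipped covariance while the calibration experiment uses the matched
  design.
- `recovery_config` — the package defaults (300 genes × 30 SNPs, 20,000
  GWAS individuals, 20% causal genes, h²_GReX→trait = 0.3): gene z-scores
  correlate > 0.9 with the planted α over causal genes under both models.
- `divergence_config` — 150 genes with **300** candidate cis SNPs each,
  Fst 0.15, ρ = (0.8, 0.3), frequencies down to 0.02, training cohorts of
  800. The wide candidate pool is essential: with 30 candidates and k = 28
  the two models would overlap by construction. Under these conditions the
  per-gene SNP-set Jaccard median is below 0.1 while each model remains
  individually accurate — so the cross-model effect correlation over
  significant genes stays high while p-value correlation does not, the
  phenomenon the whole comparison framework exists to quantify.
- `sparse_overlap_config` — low-frequency causal alleles plus a 0.10 cohort
  MAF filter and a cv-r² floor: most genes end up sharing *no* SNP features
  (and some appear in only one model), the regime where sharing classes and
  model-specificity annotations carry information.

`h2_expr = 0.25` by default so realized cross-validated r² medians land on
the scale reported for real whole-blood models (≈ 0.12–0.25).

## Numerical choices

- p-values floored at 1e-300; BH input validated to (0, 1].
- Model weight TSVs are written at full `repr` precision and re-read with
  round-trip float parsing, so read∘write is exact to the last bit.
- Pearson r via scipy; Fisher-z interval degenerates to (−1, 1) at n = 3;
  correlations over constant vectors are "absent", not NaN.
- Cells, sweep points, and correlogram entries with n < 3 are reported as
  absent; they never silently become numbers.
- `effect_size` is reported as `zscore/√n̄` when the GWAS carries per-SNP
  sample sizes (n̄ = mean over the gene's used SNPs) and as the z-score
  otherwise; all cross-model correlation analyses use the z-score.

## What the tests do and do not show

The generator's LD is block-AR(1): it has no long-range LD, no realistic
recombination-map structure, no relatedness, no imputation uncertainty, and
its "admixed" cohort is a discrete half/half mixture rather than
continuous individual-level admixture. Traits are purely GReX-mediated with
Gaussian effects — no direct (non-expression) SNP effects, no
gene–environment interplay. Passing tests therefore demonstrate that the
statistics, classifications, and pipelines are implemented correctly and
behave as the theory predicts under a controlled generative model; they do
not certify performance on real cohort data, where reference mismatch,
strand ambiguity, and uncontrolled confounding are all harsher.

## Known limitations

- rsID-based SNP identity by default (a chrom:pos:sorted-alleles key mode
  exists for the GWAS side but models key on rsID, as PrediXcan models do).
- No INDEL handling, no genome-build liftover, no X chromosome.
- The within-query FDR universe for neuroimaging mapping is a deliberate,
  documented choice; repositories shipping pre-adjusted values should be
  thresholded upstream instead.
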