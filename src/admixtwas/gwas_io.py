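"""GWAS summary statistics: reading, allele harmonization, region masking.

Harmonization orients each GWAS z-score to the prediction model's effect
allele before the gene-level statistic is formed: if the GWAS effect allele
matches the model's effect allele the z-score is kept, if the allele pair is
swapped the z-score is negated, and any other allele combination is dropped
and counted. Strand-ambiguous SNPs (A/T, C/G) are matched literally — the
match is deterministic and the dropped/flipped counts are logged, which is
preferable to silent frequency-based guessing when frequency columns may be
absent.

Region masks remove gene-level *results* (not GWAS SNPs) whose gene interval
overlaps a masked window. The defaults (GRCh38, 1-based inclusive) are the
MHC on chromosome 6 for every model and the chromosome 8p23 and 17q21.31
inversion polymorphism regions for the European-dominant model only, since
those inversions are disproportionately detected in European ancestry and
violate the LD assumptions behind the gene-level statistic.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, NoOverlapSignal
from .model_io import GeneModel

logger = logging.getLogger(__name__)

#: GRCh38 default windows, 1-based inclusive.
MHC_REGION = ("6", 25_000_000, 34_000_000)
CHR8_INVERSION = ("8", 7_000_000, 13_000_000)
CHR17_INVERSION = ("17", 43_000_000, 47_000_000)


@dataclass
class GwasSumStats:
    """Per-SNP association records for one trait, keyed by SNP id.

    ``table`` columns: snp_id (index), chrom, pos, a1 (effect allele), a2,
    zscore, beta, se, n. ``zscore`` is always populated (beta/se when a z
    column is absent).
    """

    trait_id: str
    table: pd.DataFrame

    def __post_init__(self):
        if self.table.index.name != "snp_id":
            raise FormatError("GwasSumStats table must be indexed by snp_id")
        if not self.table.index.is_unique:
            raise FormatError("duplicate snp_id in GwasSumStats")

    @property
    def n_snps(self) -> int:
        return len(self.table)

    def snp_ids(self) -> set[str]:
        return set(self.table.index)

    def allele_z_lookup(self) -> dict[str, tuple[str, str, float]]:
        """snp_id -> (a1, a2, zscore); built lazily, cached on the instance."""
        cache = getattr(self, "_lookup_cache", None)
        if cache is None:
            t = self.table
            cache = dict(zip(t.index,
                             zip(t["a1"], t["a2"], t["zscore"].astype(float))))
            object.__setattr__(self, "_lookup_cache", cache)
        return cache


@dataclass(frozen=True)
class RegionMask:
    """A genomic window to censor, with a model predicate.

    ``applies_to`` is "all" or a tuple of model ids. Coordinates are 1-based
    inclusive.
    """

    chrom: str
    start: int
    end: int
    applies_to: str | tuple[str, ...] = "all"
    label: str = ""

    def __post_init__(self):
        if self.start > self.end:
            raise FormatError(f"mask {self.label or self.chrom}: start > end")

    def matches_model(self, model_id: str) -> bool:
        if self.applies_to == "all":
            return True
        if isinstance(self.applies_to, str):
            return model_id == self.applies_to
        return model_id in self.applies_to

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return str(chrom) == self.chrom and start <= self.end and self.start <= end


def default_region_masks(european_models: Sequence[str] = ("GTEx_WB",)) -> list[RegionMask]:
    """MHC mask for all models; inversion masks for European-dominant model(s)."""
    eur = tuple(european_models)
    return [
        RegionMask(*MHC_REGION, applies_to="all", label="MHC"),
        RegionMask(*CHR8_INVERSION, applies_to=eur, label="chr8_inversion"),
        RegionMask(*CHR17_INVERSION, applies_to=eur, label="chr17_inversion"),
    ]


@dataclass
class HarmonizedGene:
    """A gene's model weights aligned with model-oriented GWAS z-scores."""

    gene_id: str
    snp_ids: list[str]
    weights: np.ndarray
    gwas_z: np.ndarray
    n_dropped: int = 0

    def __post_init__(self):
        if not (len(self.snp_ids) == len(self.weights) == len(self.gwas_z) >= 1):
            raise FormatError(f"{self.gene_id}: misaligned harmonized arrays")


def position_key(chrom, pos, a1: str, a2: str) -> str:
    """Order-independent chrom:pos:alleles SNP key (alleles sorted)."""
    lo, hi = sorted((a1, a2))
    return f"{chrom}:{pos}:{lo}:{hi}"


DEFAULT_COLUMN_MAP = {
    "snp": "snp_id", "a1": "a1", "a2": "a2", "chrom": "chrom", "pos": "pos",
    "z": "zscore", "beta": "beta", "se": "se", "n": "n",
}


def read_gwas(path, column_map: Mapping[str, str] | None = None,
              trait_id: str | None = None, sep: str | None = None,
              key_mode: str = "rsid") -> GwasSumStats:
    """Read delimited GWAS summary statistics.

    ``column_map`` maps canonical field names (snp, a1, a2, chrom, pos, z,
    beta, se, n) to the file's column headers. Either a z column or both
    beta and se must be mappable; z is computed as beta/se where absent.
    Records with se <= 0 or non-finite z are rejected with a logged count;
    duplicated snp_id keeps the first occurrence.

    ``key_mode="chrom_pos_alleles"`` re-keys records by the
    order-independent chrom:pos:sorted-alleles key instead of rsID (the
    prediction model must then be read with the same mode).
    """
    path = Path(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        for key, col in column_map.items():
            if key not in DEFAULT_COLUMN_MAP:
                raise FormatError(f"unknown GWAS field {key!r} in column map")
            cmap[key] = col

    df = pd.read_csv(path, sep=sep or r"\s+", dtype=str, engine="python")
    present = {key: cmap[key] for key in cmap if cmap[key] in df.columns}
    for required in ("snp", "a1", "a2"):
        if required not in present:
            raise FormatError(f"{path}: cannot map required field {required!r} "
                              f"(looked for column {cmap[required]!r})")
    if "z" not in present and not ("beta" in present and "se" in present):
        raise FormatError(f"{path}: need a z column or both beta and se")

    out = pd.DataFrame({"snp_id": df[present["snp"]].astype(str)})
    out["a1"] = df[present["a1"]].str.upper()
    out["a2"] = df[present["a2"]].str.upper()
    out["chrom"] = df[present["chrom"]].astype(str) if "chrom" in present else pd.NA
    for key, dtype in (("pos", "Int64"), ("n", "Int64")):
        out[key] = (pd.to_numeric(df[present[key]], errors="coerce").astype(dtype)
                    if key in present else pd.NA)
    for key in ("beta", "se"):
        out[key] = (pd.to_numeric(df[present[key]], errors="coerce")
                    if key in present else np.nan)
    if "z" in present:
        out["zscore"] = pd.to_numeric(df[present["z"]], errors="coerce")
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            out["zscore"] = out["beta"] / out["se"]

    bad_se = out["se"].notna() & (out["se"] <= 0)
    bad_alleles = out["a1"] == out["a2"]
    bad_z = ~np.isfinite(out["zscore"].to_numpy(dtype=float))
    bad = bad_se | bad_alleles | bad_z
    if bad.any():
        logger.info("%s: rejected %d records (se<=0, a1==a2, or non-finite z)",
                    path, int(bad.sum()))
        out = out[~bad]

    if key_mode == "chrom_pos_alleles":
        if "chrom" not in present or "pos" not in present:
            raise FormatError(f"{path}: key_mode=chrom_pos_alleles needs "
                              "chrom and pos columns")
        out["snp_id"] = [position_key(c, p, a1, a2) for c, p, a1, a2 in
                         zip(out["chrom"], out["pos"], out["a1"], out["a2"])]
    elif key_mode != "rsid":
        raise ValueError(f"unknown key_mode {key_mode!r}")

    dup = out["snp_id"].duplicated()
    if dup.any():
        logger.info("%s: dropped %d duplicate snp_id records (kept first)",
                    path, int(dup.sum()))
        out = out[~dup]
    out = out.set_index("snp_id")
    return GwasSumStats(trait_id=trait_id or path.stem, table=out)


def harmonize(gwas: GwasSumStats, gene: GeneModel) -> HarmonizedGene:
    """Align a gene's model weights with model-oriented GWAS z-scores.

    Raises NoOverlapSignal when no model SNP can be used.
    """
    snp_ids: list[str] = []
    weights: list[float] = []
    zs: list[float] = []
    n_dropped = 0
    lookup = gwas.allele_z_lookup()
    for f in gene.features:
        rec = lookup.get(f.snp_id)
        if rec is None:
            n_dropped += 1
            continue
        a1, a2, z = rec
        if (a1, a2) == (f.eff_allele, f.ref_allele):
            oriented = z
        elif (a1, a2) == (f.ref_allele, f.eff_allele):
            oriented = -z
        else:
            n_dropped += 1
            continue
        snp_ids.append(f.snp_id)
        weights.append(f.weight)
        zs.append(oriented)
    if not snp_ids:
        raise NoOverlapSignal(gene.gene_id, "no model SNP usable in GWAS")
    return HarmonizedGene(gene_id=gene.gene_id, snp_ids=snp_ids,
                          weights=np.array(weights), gwas_z=np.array(zs),
                          n_dropped=n_dropped)


def apply_region_mask(results, gene_positions: Mapping[str, tuple[str, int, int]],
                      masks: Iterable[RegionMask], model_id: str):
    """Split associations into (kept, removed) by masked-window overlap.

    ``results`` is any iterable of objects with a ``gene_id`` attribute (or
    mapping key). A result is removed iff its gene interval overlaps any mask
    whose ``applies_to`` matches ``model_id``. Removal counts are logged per
    mask label.
    """
    results = list(results)
    masks = [m for m in masks]
    missing = [getattr(r, "gene_id") for r in results
               if getattr(r, "gene_id") not in gene_positions]
    if missing:
        raise FormatError(f"missing gene positions for: {sorted(set(missing))}")
    kept, removed = [], []
    counts: dict[str, int] = {}
    for r in results:
        chrom, start, end = gene_positions[r.gene_id]
        hit = None
        for m in masks:
            if m.matches_model(model_id) and m.overlaps(str(chrom), start, end):
                hit = m
                break
        if hit is None:
            kept.append(r)
        else:
            removed.append(r)
            counts[hit.label or f"{hit.chrom}:{hit.start}-{hit.end}"] = (
                counts.get(hit.label or f"{hit.chrom}:{hit.start}-{hit.end}", 0) + 1)
    for label, n in counts.items():
        logger.info("mask %s removed %d results for model %s", label, n, model_id)
    return kept, removed


def read_region_masks(path) -> list[RegionMask]:
    """Read a 4-column mask file: ``chrom start end applies_to``.

    Coordinates are 1-based inclusive (unlike BED). ``applies_to`` is "all"
    or a comma-separated list of model ids.
    """
    masks = []
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith("#") or parts[0] == "chrom":
                continue
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            chrom, start, end, applies = parts[:4]
            applies_to = "all" if applies == "all" else tuple(applies.split(","))
            masks.append(RegionMask(chrom=chrom, start=int(start), end=int(end),
                                    applies_to=applies_to, label=f"line{lineno}"))
    return masks
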