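"""Reading, validating, writing and summarizing expression prediction models.

A *prediction model* maps each gene to a sparse set of SNP features with
signed weights: imputed (genetically regulated) expression of a gene is the
weighted sum of effect-allele dosages over its features. Two on-disk dialects
are supported:

* the PrediXcan SQLite schema (tables ``weights`` and ``extra``), the format
  real whole-blood models ship in, and
* a plain-text TSV dialect (weights file plus a ``.genes.tsv`` metadata
  sidecar), the canonical format for tests and fixtures.

SNP--SNP dosage covariance references (one symmetric matrix per gene over
that gene's model SNPs) are read and written as whitespace-delimited triplet
text, optionally gzipped.
"""

from __future__ import annotations

import gzip
import logging
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._stats import strip_gene_version
from .exceptions import CovarianceError, EmptyModelError, FormatError

logger = logging.getLogger(__name__)

_WEIGHT_COLUMNS = ["gene", "snp_id", "chrom", "pos", "ref_allele", "eff_allele", "weight"]
_META_COLUMNS = ["gene", "gene_name", "cv_r2"]


@dataclass(frozen=True)
class SnpFeature:
    """One SNP carried in a gene's prediction model with a nonzero weight.

    ``weight`` is the expression change per copy of ``eff_allele``.
    ``chrom``/``pos`` may be unknown (PrediXcan SQLite stores neither).
    """

    snp_id: str
    ref_allele: str
    eff_allele: str
    weight: float
    chrom: str | None = None
    pos: int | None = None

    def __post_init__(self):
        if self.eff_allele == self.ref_allele:
            raise FormatError(
                f"SNP {self.snp_id}: effect allele equals reference allele "
                f"({self.eff_allele})"
            )
        if not np.isfinite(self.weight) or self.weight == 0:
            raise FormatError(f"SNP {self.snp_id}: weight must be finite and nonzero")


@dataclass
class GeneModel:
    """A gene's feature set plus training metadata.

    ``cv_r2`` is the cross-validated squared correlation between predicted
    and measured expression in the training cohort.
    """

    gene_id: str
    gene_name: str
    features: list[SnpFeature]
    cv_r2: float

    def __post_init__(self):
        if len(self.features) < 1:
            raise FormatError(f"gene {self.gene_id}: needs >= 1 SNP feature")
        if not (0.0 <= self.cv_r2 <= 1.0):
            raise FormatError(f"gene {self.gene_id}: cv_r2 {self.cv_r2} outside [0,1]")
        seen = set()
        for f in self.features:
            if f.snp_id in seen:
                raise FormatError(f"gene {self.gene_id}: duplicate SNP {f.snp_id}")
            seen.add(f.snp_id)

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def snp_ids(self) -> list[str]:
        return [f.snp_id for f in self.features]

    @property
    def weights(self) -> np.ndarray:
        return np.array([f.weight for f in self.features], dtype=float)


@dataclass
class PredictionModel:
    """A named collection of gene models for one training ancestry."""

    model_id: str
    genes: dict[str, GeneModel]
    ancestry_label: str = ""

    def __post_init__(self):
        for gid, gm in self.genes.items():
            if gid != gm.gene_id:
                raise FormatError(f"gene map key {gid} != gene_id {gm.gene_id}")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def gene_positions(self) -> dict[str, tuple[str, int, int]]:
        """Per-gene (chrom, min pos, max pos) span of its SNP features.

        Genes whose features lack coordinates are omitted.
        """
        out: dict[str, tuple[str, int, int]] = {}
        for gid, gm in self.genes.items():
            coords = [(f.chrom, f.pos) for f in gm.features if f.chrom is not None and f.pos is not None]
            if not coords:
                continue
            chroms = {c for c, _ in coords}
            if len(chroms) != 1:
                continue
            positions = [p for _, p in coords]
            out[gid] = (coords[0][0], min(positions), max(positions))
        return out


@dataclass
class CovarianceTable:
    """Per-gene symmetric SNP--SNP dosage covariance with index labels."""

    entries: dict[str, tuple[list[str], np.ndarray]] = field(default_factory=dict)

    def add(self, gene_id: str, snp_ids: list[str], matrix: np.ndarray) -> None:
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (len(snp_ids), len(snp_ids)):
            raise CovarianceError(f"{gene_id}: matrix shape {matrix.shape} != {len(snp_ids)} SNPs")
        if not np.allclose(matrix, matrix.T, atol=1e-8):
            raise CovarianceError(f"{gene_id}: matrix not symmetric")
        if np.any(np.diag(matrix) < 0):
            raise CovarianceError(f"{gene_id}: negative diagonal entry")
        self.entries[gene_id] = (list(snp_ids), matrix)

    def restrict(self, gene_id: str, snp_ids: Iterable[str]) -> tuple[list[str], np.ndarray]:
        """Sub-matrix over the requested SNPs, keeping their given order and
        silently dropping SNPs absent from the reference."""
        labels, mat = self.entries[gene_id]
        index = {s: i for i, s in enumerate(labels)}
        kept = [s for s in snp_ids if s in index]
        idx = np.array([index[s] for s in kept], dtype=int)
        return kept, mat[np.ix_(idx, idx)]


# ---------------------------------------------------------------------------
# model reading / writing


def _meta_path(path: Path) -> Path:
    p = Path(path)
    return p.with_suffix(".genes.tsv") if p.suffix == ".tsv" else Path(str(p) + ".genes.tsv")


def read_model(path, format: str = "tsv", model_id: str | None = None,
               ancestry_label: str = "", key_mode: str = "rsid") -> PredictionModel:
    """Read a prediction model from disk.

    Gene identifiers are version-stripped on read so the same gene matches
    across models built on different annotation freezes. Zero-weight rows are
    dropped with a logged count. ``n_features`` is recomputed from weight rows
    and checked against stored metadata when the metadata carries it.
    ``key_mode="chrom_pos_alleles"`` re-keys SNPs by the order-independent
    chrom:pos:sorted-alleles key (requires coordinates, so TSV models only).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        weights, meta = _read_tsv_tables(path)
    elif format == "sqlite_db":
        weights, meta = _read_sqlite_tables(path)
    else:
        raise ValueError(f"unknown model format {format!r}")

    n_zero = int((weights["weight"] == 0).sum())
    if n_zero:
        logger.info("dropped %d zero-weight rows from %s", n_zero, path)
        weights = weights[weights["weight"] != 0]

    if key_mode == "chrom_pos_alleles":
        if weights["chrom"].isna().any() or weights["pos"].isna().any():
            raise FormatError(f"{path}: key_mode=chrom_pos_alleles needs "
                              "chrom and pos for every SNP")
        lo = weights[["ref_allele", "eff_allele"]].min(axis=1)
        hi = weights[["ref_allele", "eff_allele"]].max(axis=1)
        weights = weights.assign(snp_id=[
            f"{c}:{int(p)}:{a}:{b}" for c, p, a, b in
            zip(weights["chrom"], weights["pos"], lo, hi)])
    elif key_mode != "rsid":
        raise ValueError(f"unknown key_mode {key_mode!r}")

    weights = weights.assign(gene=weights["gene"].map(strip_gene_version))
    meta = meta.assign(gene=meta["gene"].map(strip_gene_version))
    meta_by_gene = meta.set_index("gene")

    genes: dict[str, GeneModel] = {}
    for gid, grp in weights.groupby("gene", sort=True):
        features = [
            SnpFeature(
                snp_id=row.snp_id,
                ref_allele=row.ref_allele,
                eff_allele=row.eff_allele,
                weight=float(row.weight),
                chrom=(None if pd.isna(row.chrom) else str(row.chrom)),
                pos=(None if pd.isna(row.pos) else int(row.pos)),
            )
            for row in grp.itertuples()
        ]
        if gid in meta_by_gene.index:
            m = meta_by_gene.loc[gid]
            gene_name = str(m["gene_name"])
            cv_r2 = float(m["cv_r2"])
            stored_n = m.get("n_features")
            if stored_n is not None and not pd.isna(stored_n) and int(stored_n) != len(features):
                logger.warning(
                    "%s: stored n_features=%d, recomputed %d from weight rows",
                    gid, int(stored_n), len(features),
                )
        else:
            gene_name, cv_r2 = gid, 0.0
        genes[gid] = GeneModel(gene_id=gid, gene_name=gene_name, features=features, cv_r2=cv_r2)

    if not genes:
        raise EmptyModelError(f"{path}: model contains no genes with nonzero weights")
    return PredictionModel(model_id=model_id or path.stem, genes=genes,
                           ancestry_label=ancestry_label)


def _read_tsv_tables(path: Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    # round_trip float parsing: the weight precision contract is exact
    weights = pd.read_csv(path, sep="\t", dtype={"chrom": str, "snp_id": str},
                          float_precision="round_trip")
    missing = [c for c in _WEIGHT_COLUMNS if c not in weights.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    mpath = _meta_path(path)
    if mpath.exists():
        meta = pd.read_csv(mpath, sep="\t", float_precision="round_trip")
        missing = [c for c in _META_COLUMNS if c not in meta.columns]
        if missing:
            raise FormatError(f"{mpath}: missing required column(s) {missing}")
    else:
        meta = pd.DataFrame(columns=_META_COLUMNS)
    return weights, meta


def _read_sqlite_tables(path: Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    with sqlite3.connect(path) as con:
        try:
            weights = pd.read_sql_query("SELECT * FROM weights", con)
            extra = pd.read_sql_query("SELECT * FROM extra", con)
        except (sqlite3.DatabaseError, pd.errors.DatabaseError) as exc:
            raise FormatError(f"{path}: not a PrediXcan model database ({exc})") from exc
    for col in ("rsid", "gene", "weight", "ref_allele", "eff_allele"):
        if col not in weights.columns:
            raise FormatError(f"{path}: weights table missing column {col!r}")
    weights = weights.rename(columns={"rsid": "snp_id"})
    weights["chrom"] = pd.NA
    weights["pos"] = pd.NA
    rename = {"genename": "gene_name", "pred.perf.R2": "cv_r2", "n.snps.in.model": "n_features"}
    extra = extra.rename(columns=rename)
    for col in ("gene", "gene_name", "cv_r2"):
        if col not in extra.columns:
            raise FormatError(f"{path}: extra table missing column {col!r}")
    return weights[_WEIGHT_COLUMNS], extra


def write_model(model: PredictionModel, path, format: str = "tsv") -> None:
    """Write a model losslessly; ``read_model`` round-trips it.

    Weights are written with ``repr`` precision so values as small as 1e-12
    survive the round trip exactly.
    """
    if model.n_genes == 0:
        raise EmptyModelError("refusing to write a model with zero genes")
    path = Path(path)
    rows = []
    meta_rows = []
    for gid in sorted(model.genes):
        gm = model.genes[gid]
        meta_rows.append((gid, gm.gene_name, gm.cv_r2, gm.n_features))
        for f in gm.features:
            rows.append((gid, f.snp_id,
                         "" if f.chrom is None else f.chrom,
                         "" if f.pos is None else f.pos,
                         f.ref_allele, f.eff_allele, f.weight))
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(_WEIGHT_COLUMNS) + "\n")
            for gid, snp, chrom, pos, ref, eff, w in rows:
                fh.write(f"{gid}\t{snp}\t{chrom}\t{pos}\t{ref}\t{eff}\t{w!r}\n")
        with open(_meta_path(path), "w") as fh:
            fh.write("\t".join(_META_COLUMNS + ["n_features"]) + "\n")
            for gid, name, r2, n in meta_rows:
                fh.write(f"{gid}\t{name}\t{r2!r}\t{n}\n")
    elif format == "sqlite_db":
        if path.exists():
            path.unlink()
        with sqlite3.connect(path) as con:
            con.execute("CREATE TABLE weights (rsid TEXT, gene TEXT, weight REAL,"
                        " ref_allele TEXT, eff_allele TEXT)")
            con.execute('CREATE TABLE extra (gene TEXT, genename TEXT,'
                        ' "pred.perf.R2" REAL, "n.snps.in.model" INTEGER)')
            con.executemany(
                "INSERT INTO weights VALUES (?,?,?,?,?)",
                [(snp, gid, w, ref, eff) for gid, snp, _, _, ref, eff, w in rows],
            )
            con.executemany("INSERT INTO extra VALUES (?,?,?,?)", meta_rows)
    else:
        raise ValueError(f"unknown model format {format!r}")


def model_summary(model: PredictionModel) -> dict:
    """Per-model medians used for cross-model comparison tables."""
    if model.n_genes == 0:
        raise EmptyModelError("empty model has no summary")
    snps_per_gene = [gm.n_features for gm in model.genes.values()]
    all_weights = np.concatenate([gm.weights for gm in model.genes.values()])
    cv_r2s = [gm.cv_r2 for gm in model.genes.values()]
    return {
        "model_id": model.model_id,
        "n_genes": model.n_genes,
        "n_snps": int(len(all_weights)),
        "median_snps_per_gene": float(np.median(snps_per_gene)),
        "median_abs_weight": float(np.median(np.abs(all_weights))),
        "median_cv_r2": float(np.median(cv_r2s)),
    }


# ---------------------------------------------------------------------------
# covariance reading / writing


def read_covariance(path) -> CovarianceTable:
    """Assemble per-gene covariance matrices from triplet text.

    Each data line is ``GENE RSID1 RSID2 VALUE`` (whitespace-delimited, header
    required; gzip detected by suffix). Duplicate (i, j)/(j, i) entries that
    disagree beyond 1e-8 are rejected.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    per_gene: dict[str, dict[tuple[str, str], float]] = {}
    order: dict[str, list[str]] = {}
    with opener(path, "rt") as fh:
        header = fh.readline()
        if not header.strip():
            raise FormatError(f"{path}: empty covariance file")
        for lineno, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 fields, got {len(parts)}")
            gene, s1, s2, raw = parts
            gene = strip_gene_version(gene)
            try:
                value = float(raw)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric value {raw!r}") from exc
            cells = per_gene.setdefault(gene, {})
            snps = order.setdefault(gene, [])
            for s in (s1, s2):
                if s not in snps:
                    snps.append(s)
            key = (s1, s2)
            rkey = (s2, s1)
            for k in (key, rkey):
                if k in cells and abs(cells[k] - value) > 1e-8:
                    raise CovarianceError(
                        f"{path}:{lineno}: conflicting entries for {gene} {s1}/{s2}: "
                        f"{cells[k]} vs {value}"
                    )
            cells[key] = value
            cells[rkey] = value
    table = CovarianceTable()
    for gene, snps in order.items():
        cells = per_gene[gene]
        k = len(snps)
        mat = np.full((k, k), np.nan)
        for i, si in enumerate(snps):
            for j, sj in enumerate(snps):
                if (si, sj) in cells:
                    mat[i, j] = cells[(si, sj)]
        if np.isnan(mat).any():
            missing = int(np.isnan(mat).sum())
            raise CovarianceError(f"{path}: gene {gene}: {missing} covariance cells missing")
        if np.any(np.diag(mat) < 0):
            raise CovarianceError(f"{path}: gene {gene}: negative diagonal variance")
        table.add(gene, snps, mat)
    return table


def write_covariance(table: CovarianceTable, path) -> None:
    """Write upper-triangle triplets; gzip when the path ends in .gz.

    The gzip stream is written with mtime=0 so identical tables produce
    byte-identical files.
    """
    path = Path(path)
    lines = ["GENE RSID1 RSID2 VALUE\n"]
    for gene in sorted(table.entries):
        snps, mat = table.entries[gene]
        for i in range(len(snps)):
            for j in range(i, len(snps)):
                lines.append(f"{gene} {snps[i]} {snps[j]} {float(mat[i, j])!r}\n")
    payload = "".join(lines).encode()
    if path.suffix == ".gz":
        # fixed mtime and empty embedded filename: identical tables give
        # byte-identical archives
        with open(path, "wb") as raw:
            with gzip.GzipFile(filename="", fileobj=raw, mode="wb", mtime=0) as gz:
                gz.write(payload)
    else:
        path.write_bytes(payload)
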