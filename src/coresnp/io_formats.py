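"""Readers and writers for genotype, phenotype and result tables.

Genotypes are held as an additive dosage matrix: for each sample and
biallelic SNP, the count of alternate alleles (0, 1 or 2). Missing calls
are kept as an explicit sentinel until :func:`coresnp.preprocess.impute_missing`
is applied; loading never silently converts a missing call to a dosage.

Coordinate conventions: internal positions are 1-based (VCF convention);
the BED-like export is 0-based half-open.
"""
from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger("coresnp")

#: Sentinel for a missing genotype in the int8 dosage matrix.
MISSING: int = -1

_MISSING_TOKENS = {"", ".", "NA", "NaN", "nan", "na"}


# ---------------------------------------------------------------------------
# Core data types
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Sample x SNP dosage matrix with an explicit missingness sentinel.

    Parameters
    ----------
    dosages
        Integer array of shape ``(n_samples, n_snps)`` with entries in
        ``{0, 1, 2}`` or :data:`MISSING`.
    sample_ids
        Unique sample identifiers, aligned to rows.
    snp_ids
        Unique SNP identifiers, aligned to columns.
    """

    dosages: np.ndarray
    sample_ids: list[str]
    snp_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D matrix")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.snp_ids = [str(s) for s in self.snp_ids]
        n, p = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.snp_ids) != p:
            raise ValueError(f"{len(self.snp_ids)} SNP ids for {p} columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids are not unique")
        if len(set(self.snp_ids)) != p:
            raise ValueError("SNP ids are not unique")
        bad = (self.dosages != MISSING) & ((self.dosages < 0) | (self.dosages > 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid dosage {int(self.dosages[i, j])} at sample "
                f"{self.sample_ids[i]!r}, SNP {self.snp_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean mask, True where the genotype call is missing."""
        return self.dosages == MISSING

    def missing_rates(self) -> np.ndarray:
        """Per-SNP fraction of missing calls."""
        return self.missing_mask.mean(axis=0)

    def subset_snps(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(indices, dtype=int)
        return GenotypeMatrix(
            self.dosages[:, idx],
            list(self.sample_ids),
            [self.snp_ids[j] for j in idx],
        )

    def subset_samples(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(indices, dtype=int)
        return GenotypeMatrix(
            self.dosages[idx, :],
            [self.sample_ids[i] for i in idx],
            list(self.snp_ids),
        )

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"unknown SNP id {snp_id!r}") from None


@dataclass(frozen=True)
class SnpMeta:
    """Genomic coordinates of one SNP (1-based position)."""

    snp_id: str
    chrom: str
    pos: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")


@dataclass
class PhenotypeTable:
    """Per-sample continuous trait values, optionally with 3-level labels.

    ``levels`` is None until quartile discretization assigns each sample
    to Level 1 (lowest quartile), 2 (interquartile) or 3 (highest quartile).
    """

    sample_ids: list[str]
    values: np.ndarray
    levels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids are not unique")
        if self.values.shape != (len(self.sample_ids),):
            raise ValueError("values must align with sample ids")
        if self.levels is not None:
            self.levels = np.asarray(self.levels, dtype=int)
            if self.levels.shape != self.values.shape:
                raise ValueError("levels must align with values")
            if not np.isin(self.levels, (1, 2, 3)).all():
                raise ValueError("levels must be in {1, 2, 3}")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def aligned_to(self, sample_ids: Sequence[str]) -> "PhenotypeTable":
        """Reorder/subset rows to the given sample id sequence."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            idx = [index[s] for s in sample_ids]
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} has no phenotype") from None
        return PhenotypeTable(
            [self.sample_ids[i] for i in idx],
            self.values[idx],
            None if self.levels is None else self.levels[idx],
        )


def check_meta_sorted(meta: Sequence[SnpMeta]) -> None:
    """Raise if positions are not ascending within each chromosome block."""
    for prev, cur in zip(meta, meta[1:]):
        if cur.chrom == prev.chrom and cur.pos < prev.pos:
            raise ValueError(
                f"SNP metadata not sorted: {cur.snp_id} at {cur.chrom}:{cur.pos} "
                f"follows {prev.snp_id} at {prev.chrom}:{prev.pos}"
            )


# ---------------------------------------------------------------------------
# Genotype input
# ---------------------------------------------------------------------------

def read_vcf_genotypes(
    path: str | Path, biallelic_only: bool = True
) -> tuple[GenotypeMatrix, list[SnpMeta]]:
    """Load a VCF (optionally bgzipped) into a dosage matrix.

    Dosage is the per-sample count of alternate alleles; half-missing or
    fully missing GT calls become :data:`MISSING`. Phased ("|") and
    unphased ("/") separators are treated identically. Multiallelic sites
    are dropped when ``biallelic_only`` is set.
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path, gts012=False)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise ValueError(f"cannot parse VCF {path!r}: {exc}") from exc

    sample_ids = list(vcf.samples)
    columns: list[np.ndarray] = []
    snp_ids: list[str] = []
    meta: list[SnpMeta] = []
    seen: set[str] = set()
    n_multi = 0
    for record_no, variant in enumerate(vcf, start=1):
        if biallelic_only and len(variant.ALT) != 1:
            n_multi += 1
            continue
        snp_id = variant.ID if variant.ID not in (None, ".") else (
            f"{variant.CHROM}:{variant.POS}"
        )
        if snp_id in seen:
            raise ValueError(f"duplicate SNP id {snp_id!r} (record {record_no})")
        seen.add(snp_id)
        col = np.empty(len(sample_ids), dtype=np.int8)
        for i, gt in enumerate(variant.genotypes):
            alleles = gt[:-1]  # final element is the phasing flag
            if any(a < 0 for a in alleles):
                col[i] = MISSING
            else:
                col[i] = sum(1 for a in alleles if a != 0)
        columns.append(col)
        snp_ids.append(snp_id)
        meta.append(SnpMeta(snp_id, str(variant.CHROM), int(variant.POS)))
    vcf.close()
    if n_multi:
        logger.info("dropped %d non-biallelic site(s) from %s", n_multi, path)
    if not columns:
        raise ValueError(f"no usable variant records in {path!r}")
    dosages = np.stack(columns, axis=1)
    return GenotypeMatrix(dosages, sample_ids, snp_ids), meta


def _open_reader(path: Path, dialect: str):
    if dialect in ("tsv", "excel-tab"):
        return csv.reader(path.open(newline=""), delimiter="\t")
    if dialect == "csv":
        return csv.reader(path.open(newline=""))
    raise ValueError(f"unknown dialect {dialect!r}; use 'tsv' or 'csv'")


def read_genotype_table(
    path: str | Path,
    dialect: str = "tsv",
    metadata_path: str | Path | None = None,
) -> tuple[GenotypeMatrix, list[SnpMeta]]:
    """Load a delimited dosage table: samples in rows, SNPs in columns.

    The header row carries SNP ids (first field names the sample-id
    column). Cells must be 0, 1, 2 or a missing token (NA, ".", empty).
    An optional sidecar metadata file (columns snp_id, chrom, pos) supplies
    coordinates; without one, SNPs are placed on a single placeholder
    chromosome ``"un"`` at 1-based column order positions.
    """
    path = Path(path)
    reader = _open_reader(path, dialect)
    rows = list(reader)
    if not rows:
        raise ValueError(f"empty genotype table {path}")
    header = rows[0]
    snp_ids = [h.strip() for h in header[1:]]
    if not snp_ids:
        raise ValueError(f"genotype table {path} has no SNP columns")
    p = len(snp_ids)
    sample_ids: list[str] = []
    dosages = np.empty((len(rows) - 1, p), dtype=np.int8)
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != p + 1:
            raise ValueError(
                f"{path} line {r}: expected {p + 1} fields, found {len(row)}"
            )
        sample_ids.append(row[0].strip())
        for c, token in enumerate(row[1:]):
            token = token.strip()
            if token in _MISSING_TOKENS:
                dosages[r - 2, c] = MISSING
            elif token in ("0", "1", "2"):
                dosages[r - 2, c] = int(token)
            else:
                raise ValueError(
                    f"{path} line {r}, column {snp_ids[c]!r}: "
                    f"invalid dosage token {token!r}"
                )
    gm = GenotypeMatrix(dosages, sample_ids, snp_ids)
    if metadata_path is not None:
        meta = read_snp_metadata(metadata_path, dialect=dialect)
        by_id = {m.snp_id: m for m in meta}
        missing_ids = [s for s in snp_ids if s not in by_id]
        if missing_ids:
            raise ValueError(
                f"metadata {metadata_path} lacks entries for SNP(s) "
                f"{missing_ids[:5]}"
            )
        meta = [by_id[s] for s in snp_ids]
    else:
        meta = [SnpMeta(s, "un", j + 1) for j, s in enumerate(snp_ids)]
    return gm, meta


def read_snp_metadata(path: str | Path, dialect: str = "tsv") -> list[SnpMeta]:
    """Read a (snp_id, chrom, pos) table, header required."""
    path = Path(path)
    reader = _open_reader(path, dialect)
    rows = list(reader)
    if not rows or [h.strip().lower() for h in rows[0][:3]] != ["snp_id", "chrom", "pos"]:
        raise ValueError(f"{path}: expected header snp_id, chrom, pos")
    meta = []
    for r, row in enumerate(rows[1:], start=2):
        if len(row) < 3:
            raise ValueError(f"{path} line {r}: expected 3 fields")
        meta.append(SnpMeta(row[0].strip(), row[1].strip(), int(row[2])))
    if len({m.snp_id for m in meta}) != len(meta):
        raise ValueError(f"{path}: duplicate SNP ids in metadata")
    return meta


def write_genotype_table(
    gm: GenotypeMatrix,
    path: str | Path,
    meta: Sequence[SnpMeta] | None = None,
    metadata_path: str | Path | None = None,
) -> None:
    """Write the dosage matrix as TSV (missing as NA), plus optional sidecar."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["sample_id", *gm.snp_ids])
        for i, sid in enumerate(gm.sample_ids):
            row = [
                "NA" if d == MISSING else str(int(d)) for d in gm.dosages[i]
            ]
            writer.writerow([sid, *row])
    if meta is not None and metadata_path is not None:
        with Path(metadata_path).open("w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["snp_id", "chrom", "pos"])
            for m in meta:
                writer.writerow([m.snp_id, m.chrom, m.pos])


# ---------------------------------------------------------------------------
# Phenotype input
# ---------------------------------------------------------------------------

def read_phenotype_table(path: str | Path, dialect: str = "tsv") -> PhenotypeTable:
    """Read a (sample_id, value) table; unparseable values are dropped.

    The number of dropped rows is logged; a table with no parseable row
    at all is an error, as is a duplicated sample id.
    """
    path = Path(path)
    reader = _open_reader(path, dialect)
    rows = list(reader)
    if not rows:
        raise ValueError(f"empty phenotype table {path}")
    start = 0
    # tolerate a header row; detect it by an unparseable second field
    if len(rows[0]) >= 2:
        try:
            float(rows[0][1])
        except ValueError:
            start = 1
    sample_ids: list[str] = []
    values: list[float] = []
    n_dropped = 0
    for r, row in enumerate(rows[start:], start=start + 1):
        if len(row) < 2:
            n_dropped += 1
            continue
        try:
            v = float(row[1])
        except ValueError:
            n_dropped += 1
            continue
        if math.isnan(v):
            n_dropped += 1
            continue
        sample_ids.append(row[0].strip())
        values.append(v)
    if n_dropped:
        logger.warning("dropped %d unparseable phenotype row(s) from %s", n_dropped, path)
    if not sample_ids:
        raise ValueError(f"no parseable phenotype rows in {path}")
    if len(set(sample_ids)) != len(sample_ids):
        dup = next(s for s in sample_ids if sample_ids.count(s) > 1)
        raise ValueError(f"duplicate sample id {dup!r} in {path}")
    return PhenotypeTable(sample_ids, np.asarray(values))


def write_phenotype_table(pheno: PhenotypeTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        if pheno.levels is None:
            writer.writerow(["sample_id", "value"])
            for s, v in zip(pheno.sample_ids, pheno.values):
                writer.writerow([s, repr(float(v))])
        else:
            writer.writerow(["sample_id", "value", "level"])
            for s, v, l in zip(pheno.sample_ids, pheno.values, pheno.levels):
                writer.writerow([s, repr(float(v)), int(l)])


# ---------------------------------------------------------------------------
# Result output (ScoreTable / IFSCurve / GridResult / comparison tables)
# ---------------------------------------------------------------------------

def write_results(obj, path: str | Path, format: str = "tsv") -> None:
    """Serialise a framework result object.

    Supported combinations:

    ========================  =================
    object                    formats
    ========================  =================
    ScoreTable                tsv, json
    IFSCurve                  json
    GridResult                json
    pandas.DataFrame          tsv, bed
    ========================  =================

    BED-like output is 0-based half-open and expects columns
    (chrom, start, end, snp_id, method).
    """
    import pandas as pd

    from .feature_scoring import ScoreTable
    from .ifs_engine import GridResult, IFSCurve

    path = Path(path)
    if isinstance(obj, ScoreTable):
        if format == "tsv":
            with path.open("w", newline="") as fh:
                fh.write(f"# method: {obj.method}\n")
                fh.write(f"# target_mode: {obj.target_mode}\n")
                writer = csv.writer(fh, delimiter="\t")
                writer.writerow(["snp_id", "score", "rank"])
                for s, sc, rk in zip(obj.snp_ids, obj.scores, obj.ranks):
                    writer.writerow([s, repr(float(sc)), int(rk)])
        elif format == "json":
            path.write_text(json.dumps(obj.to_dict(), indent=1))
        else:
            raise ValueError(f"ScoreTable cannot be written as {format!r}")
    elif isinstance(obj, (IFSCurve, GridResult)):
        if format != "json":
            raise ValueError(f"{type(obj).__name__} must be written as json")
        path.write_text(json.dumps(obj.to_dict(), indent=1))
    elif isinstance(obj, pd.DataFrame):
        if format == "tsv":
            obj.to_csv(path, sep="\t", index=False)
        elif format == "bed":
            obj.to_csv(path, sep="\t", index=False, header=False)
        else:
            raise ValueError(f"DataFrame cannot be written as {format!r}")
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")


def read_score_table(path: str | Path):
    """Read back a ScoreTable written by :func:`write_results` (tsv or json)."""
    from .feature_scoring import ScoreTable

    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith("{"):
        return ScoreTable.from_dict(json.loads(text))
    method = target_mode = None
    snp_ids: list[str] = []
    scores: list[float] = []
    ranks: list[int] = []
    for line in text.splitlines():
        if line.startswith("# method:"):
            method = line.split(":", 1)[1].strip()
        elif line.startswith("# target_mode:"):
            target_mode = line.split(":", 1)[1].strip()
        elif line.startswith("#") or line.startswith("snp_id"):
            continue
        elif line.strip():
            sid, sc, rk = line.split("\t")
            snp_ids.append(sid)
            scores.append(float(sc))
            ranks.append(int(rk))
    if method is None or target_mode is None:
        raise ValueError(f"{path}: missing method/target_mode header comments")
    return ScoreTable(
        method, target_mode, snp_ids, np.asarray(scores), np.asarray(ranks, dtype=int)
    )


def read_ifs_curve(path: str | Path):
    from .ifs_engine import IFSCurve

    return IFSCurve.from_dict(json.loads(Path(path).read_text()))


def read_grid_result(path: str | Path):
    from .ifs_engine import GridResult

    return GridResult.from_dict(json.loads(Path(path).read_text()))
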