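"""Genotype/phenotype preprocessing ahead of SNP ranking.

Four steps: per-SNP mode imputation of missing calls, quartile
discretization of the continuous trait into three ordinal levels,
a deterministic (optionally level-stratified) train/test partition, and
sliding-window LD pruning on pairwise dosage r².

The pruning defaults (window 1000 SNPs, step 100, r² > 0.1) mirror the
PLINK ``--indep-pairwise 1000 100 0.1`` parameterisation commonly used to
thin dense SNP panels before feature selection. PLINK itself leaves the
within-window removal order implementation-defined; here the rule is fixed
and deterministic: of an offending pair, drop the SNP with the larger
pre-imputation missing rate, breaking ties toward the later position.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import (
    MISSING,
    GenotypeMatrix,
    PhenotypeTable,
    SnpMeta,
    check_meta_sorted,
)

logger = logging.getLogger("coresnp")


@dataclass(frozen=True)
class PruneConfig:
    """LD pruning parameters; window and step are in SNP counts."""

    window: int = 1000
    step: int = 100
    r2_threshold: float = 0.1

    def __post_init__(self) -> None:
        if self.window < 1 or self.step < 1:
            raise ValueError("window and step must be positive")
        if self.step > self.window:
            raise ValueError("step must not exceed window")
        if not 0.0 <= self.r2_threshold <= 1.0:
            raise ValueError("r2_threshold must be in [0, 1]")


@dataclass(frozen=True)
class SplitSpec:
    """Hold-out partition: |test| = round(test_fraction * n)."""

    test_fraction: float = 0.2
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")


def impute_missing(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing call with the per-SNP modal dosage.

    Ties between dosage counts resolve to the smaller dosage, keeping the
    result deterministic. SNPs with no observed call at all are dropped
    (logged).
    """
    dos = g.dosages.copy()
    keep: list[int] = []
    dropped = 0
    for j in range(g.n_snps):
        col = dos[:, j]
        observed = col[col != MISSING]
        if observed.size == 0:
            dropped += 1
            continue
        keep.append(j)
        if observed.size < col.size:
            counts = np.bincount(observed, minlength=3)
            mode = int(np.argmax(counts))  # argmax takes the first max -> smaller dosage
            col[col == MISSING] = mode
    if dropped:
        logger.warning("dropped %d entirely missing SNP column(s)", dropped)
    out = GenotypeMatrix(dos, list(g.sample_ids), list(g.snp_ids))
    return out.subset_snps(keep) if dropped else out


def quartile_levels(values: np.ndarray) -> np.ndarray:
    """Rank-based 3-level assignment: lowest 25% -> 1, middle 50% -> 2, top 25% -> 3.

    Assignment is by rank, not value: samples are stably sorted (ties keep
    input order), the first ``floor(n/4)`` become Level 1 and the last
    ``n - floor(3n/4)`` Level 3, so the level proportions are exact
    regardless of tied trait values.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 4:
        raise ValueError(f"need at least 4 samples to discretize, got {n}")
    order = np.argsort(values, kind="stable")
    n1 = n // 4
    n3_start = (3 * n) // 4
    levels = np.empty(n, dtype=int)
    levels[order[:n1]] = 1
    levels[order[n1:n3_start]] = 2
    levels[order[n3_start:]] = 3
    return levels


def discretize_quartiles(p: PhenotypeTable) -> PhenotypeTable:
    """Return a copy of the phenotype table with quartile levels attached."""
    return PhenotypeTable(list(p.sample_ids), p.values.copy(), quartile_levels(p.values))


def split_train_test(
    sample_ids: Sequence[str],
    spec: SplitSpec,
    levels: np.ndarray | None = None,
) -> tuple[list[str], list[str]]:
    """Deterministic hold-out partition of sample ids.

    The test set has exactly ``round(test_fraction * n)`` members. In
    stratified mode the per-level test counts follow largest-remainder
    apportionment, so each level's share deviates from exact
    proportionality by at most one sample.
    """
    sample_ids = [str(s) for s in sample_ids]
    n = len(sample_ids)
    if len(set(sample_ids)) != n:
        raise ValueError("sample ids are not unique")
    n_test = int(round(spec.test_fraction * n))
    if n_test < 1:
        raise ValueError("test_fraction * n < 1: no test sample would remain")
    if n_test >= n:
        raise ValueError("test set would swallow every sample")
    rng = np.random.default_rng(spec.seed)
    if spec.stratified:
        if levels is None:
            raise ValueError("stratified split requires levels")
        levels = np.asarray(levels)
        if levels.shape != (n,):
            raise ValueError("levels must align with sample ids")
        uniq = np.unique(levels)
        counts = {lv: int((levels == lv).sum()) for lv in uniq}
        ideal = {lv: n_test * counts[lv] / n for lv in uniq}
        alloc = {lv: int(np.floor(ideal[lv])) for lv in uniq}
        short = n_test - sum(alloc.values())
        # distribute the remainder by largest fractional part, ties to the
        # smaller level label for determinism
        order = sorted(uniq, key=lambda lv: (-(ideal[lv] - alloc[lv]), lv))
        for lv in order[:short]:
            alloc[lv] += 1
        test_idx: list[int] = []
        for lv in uniq:
            members = np.flatnonzero(levels == lv)
            chosen = rng.choice(members, size=alloc[lv], replace=False)
            test_idx.extend(int(i) for i in chosen)
    else:
        test_idx = [int(i) for i in rng.permutation(n)[:n_test]]
    test_set = set(test_idx)
    train = [sample_ids[i] for i in range(n) if i not in test_set]
    test = [sample_ids[i] for i in sorted(test_set)]
    return train, test


def genotype_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors (LD r²).

    A zero-variance vector yields r² = 0 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("dosage vectors must be 1-D and of equal length")
    dx = x - x.mean()
    dy = y - y.mean()
    vx = float(dx @ dx)
    vy = float(dy @ dy)
    if vx == 0.0 or vy == 0.0:
        return 0.0
    cov = float(dx @ dy)
    return cov * cov / (vx * vy)


def _pairwise_r2(sub: np.ndarray) -> np.ndarray:
    """r² between all column pairs of a dosage submatrix; zero-variance -> 0."""
    x = sub.astype(float)
    x -= x.mean(axis=0)
    norms = np.sqrt((x * x).sum(axis=0))
    ok = norms > 0
    x[:, ok] /= norms[ok]
    r = x.T @ x
    r2 = r * r
    r2[~ok, :] = 0.0
    r2[:, ~ok] = 0.0
    return r2


def ld_prune(
    g: GenotypeMatrix,
    meta: Sequence[SnpMeta],
    cfg: PruneConfig = PruneConfig(),
    missing_rates: np.ndarray | None = None,
) -> list[str]:
    """Greedy sliding-window LD pruning; returns the kept SNP ids.

    Windows of ``cfg.window`` SNPs advance by ``cfg.step`` within each
    chromosome. Within a window, while any kept pair exceeds the r²
    threshold, the member with the larger pre-imputation missing rate is
    removed (tie: the later position). Offending pairs are resolved in
    decreasing r² order (ties by column order) so the result is fully
    deterministic.

    ``missing_rates`` are the per-SNP missing fractions recorded before
    imputation; omit them to fall back on the positional tie-break alone.
    """
    if len(meta) != g.n_snps:
        raise ValueError("metadata does not align with genotype columns")
    for m, sid in zip(meta, g.snp_ids):
        if m.snp_id != sid:
            raise ValueError(f"metadata order mismatch at SNP {sid!r}")
    check_meta_sorted(meta)
    if (g.dosages == MISSING).any():
        raise ValueError("ld_prune requires imputed genotypes (no missing calls)")
    if missing_rates is None:
        missing_rates = np.zeros(g.n_snps)
    else:
        missing_rates = np.asarray(missing_rates, dtype=float)
        if missing_rates.shape != (g.n_snps,):
            raise ValueError("missing_rates must align with SNP columns")

    kept = np.ones(g.n_snps, dtype=bool)
    chroms = [m.chrom for m in meta]
    # contiguous chromosome blocks (meta is sorted, so each chrom is one block)
    boundaries = [0] + [
        i for i in range(1, g.n_snps) if chroms[i] != chroms[i - 1]
    ] + [g.n_snps]
    for b in range(len(boundaries) - 1):
        lo, hi = boundaries[b], boundaries[b + 1]
        start = lo
        while True:
            end = min(start + cfg.window, hi)
            _prune_window(g.dosages, kept, start, end, cfg.r2_threshold, missing_rates)
            if end >= hi:
                break
            start += cfg.step
    return [g.snp_ids[j] for j in np.flatnonzero(kept)]


def _prune_window(
    dosages: np.ndarray,
    kept: np.ndarray,
    start: int,
    end: int,
    threshold: float,
    missing_rates: np.ndarray,
) -> None:
    idx = np.flatnonzero(kept[start:end]) + start
    if idx.size < 2:
        return
    r2 = _pairwise_r2(dosages[:, idx])
    np.fill_diagonal(r2, 0.0)
    active = np.ones(idx.size, dtype=bool)
    while True:
        masked = np.where(np.outer(active, active), r2, 0.0)
        np.fill_diagonal(masked, 0.0)
        flat = int(np.argmax(masked))
        a, b = divmod(flat, idx.size)
        if masked[a, b] <= threshold:
            break
        ja, jb = int(idx[a]), int(idx[b])
        if missing_rates[ja] > missing_rates[jb]:
            drop = a
        elif missing_rates[jb] > missing_rates[ja]:
            drop = b
        else:
            drop = b if jb > ja else a  # tie -> later position
        active[drop] = False
        kept[idx[drop]] = False
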