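"""Genotype-phenotype simulator with planted causal SNPs.

Generates a dosage matrix (optionally with LD blocks and missing calls)
and an additive quantitative trait with a controlled heritability, so
every pipeline stage — pruning, discretization, ranking, incremental
selection — can be exercised against a known ground truth.

The model is deliberately simple and analytically transparent:

* each SNP draws a minor-allele frequency from ``maf_range`` and each
  sample two independent allele draws, giving ``Binomial(2, f_j)``
  dosages in linkage equilibrium;
* within an LD block, the two allele draws come from thresholding a
  latent first-order autoregressive Gaussian (correlation ``ld_rho``
  between adjacent SNPs), preserving each SNP's marginal frequency while
  inducing tunable adjacent-pair r²;
* the trait is ``value = G + E + baseline`` with genetic value
  ``G_i = sum_causal beta_j * dosage_ij``; the environmental noise is
  rescaled so that ``Var(G) / (Var(G) + Var(E))`` equals the requested
  heritability *on the realized sample*, keeping downstream checks tight
  at moderate n. ``h2 = 0`` yields a trait independent of genotype.

SNPs are laid out sequentially on 12 chromosomes (a rice-like karyotype)
at 1 kb spacing.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .io_formats import MISSING, GenotypeMatrix, PhenotypeTable, SnpMeta
from .feature_scoring import ScoreTable

N_CHROMOSOMES = 12
_SNP_SPACING = 1000
#: Location constant keeping simulated trait values positive (days-like scale).
BASELINE = 100.0


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for one synthetic dataset."""

    n_samples: int = 500
    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal: int = 20
    effect_sizes: tuple[float, ...] | None = None  # None -> drawn N(0, 1)
    heritability: float = 0.6
    ld_block_size: int = 1
    ld_rho: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_snps < 1:
            raise ValueError("n_samples and n_snps must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not 0 <= self.n_causal <= self.n_snps:
            raise ValueError("n_causal must be in [0, n_snps]")
        if self.effect_sizes is not None and len(self.effect_sizes) != self.n_causal:
            raise ValueError("effect_sizes length must equal n_causal")
        if not 0.0 <= self.heritability < 1.0:
            raise ValueError("heritability must be in [0, 1)")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must be in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of a simulated trait: causal SNP ids and their betas."""

    causal_ids: tuple[str, ...]
    betas: tuple[float, ...]


def _chromosome_layout(p: int) -> list[SnpMeta]:
    per_chrom = -(-p // N_CHROMOSOMES)  # ceil
    meta = []
    for j in range(p):
        chrom = j // per_chrom + 1
        offset = j % per_chrom
        meta.append(SnpMeta(f"snp{j}", f"chr{chrom:02d}", (offset + 1) * _SNP_SPACING))
    return meta


def simulate_genotypes(cfg: SimConfig) -> tuple[GenotypeMatrix, list[SnpMeta]]:
    """Draw a dosage matrix per the simulation config (bit-reproducible)."""
    rng = np.random.default_rng(cfg.seed)
    n, p = cfg.n_samples, cfg.n_snps
    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=p)
    meta = _chromosome_layout(p)

    if cfg.ld_rho > 0.0 and cfg.ld_block_size > 1:
        thresholds = norm.ppf(maf)
        dosages = np.zeros((n, p), dtype=np.int8)
        for _ in range(2):  # two independent allele draws per sample
            z = rng.standard_normal((n, p))
            # AR(1) within each block; blocks never span chromosomes
            for j in range(1, p):
                same_block = (j % cfg.ld_block_size != 0) and (
                    meta[j].chrom == meta[j - 1].chrom
                )
                if same_block:
                    z[:, j] = cfg.ld_rho * z[:, j - 1] + np.sqrt(
                        1.0 - cfg.ld_rho**2
                    ) * z[:, j]
            dosages += (z < thresholds).astype(np.int8)
    else:
        dosages = rng.binomial(2, maf, size=(n, p)).astype(np.int8)

    if cfg.missing_rate > 0.0:
        mask = rng.random((n, p)) < cfg.missing_rate
        dosages[mask] = MISSING

    sample_ids = [f"s{i:05d}" for i in range(n)]
    return GenotypeMatrix(dosages, sample_ids, [m.snp_id for m in meta]), meta


def simulate_phenotype(
    g: GenotypeMatrix, cfg: SimConfig
) -> tuple[PhenotypeTable, PlantedTruth]:
    """Additive trait on a simulated (or any) genotype matrix.

    Causal SNPs are drawn without replacement (seeded from the config);
    effect sizes default to standard-normal draws. Requires imputed
    genotypes.
    """
    if g.missing_mask.any():
        raise ValueError("simulate_phenotype requires imputed genotypes")
    rng = np.random.default_rng((cfg.seed, 1))
    causal_idx = np.sort(rng.choice(g.n_snps, size=cfg.n_causal, replace=False))
    if cfg.effect_sizes is None:
        betas = rng.standard_normal(cfg.n_causal)
    else:
        betas = np.asarray(cfg.effect_sizes, dtype=float)

    X = g.dosages.astype(float)
    genetic = X[:, causal_idx] @ betas if cfg.n_causal else np.zeros(g.n_samples)
    var_g = float(genetic.var())
    h2 = cfg.heritability
    if h2 > 0.0 and var_g == 0.0:
        raise ValueError("h2 > 0 requires non-zero genetic variance")

    noise = rng.standard_normal(g.n_samples)
    noise = (noise - noise.mean()) / noise.std()  # exact sample moments
    if h2 == 0.0:
        values = noise + BASELINE  # trait independent of genotype
    else:
        var_e = var_g * (1.0 - h2) / h2
        values = genetic + noise * np.sqrt(var_e)
        values = values - values.min() + BASELINE  # keep values positive
    pheno = PhenotypeTable(list(g.sample_ids), values)
    truth = PlantedTruth(
        tuple(g.snp_ids[int(j)] for j in causal_idx),
        tuple(float(b) for b in betas),
    )
    return pheno, truth


def planted_recovery_rate(
    score_table: ScoreTable, causal_ids, top_m: int
) -> float:
    """Fraction of causal SNPs ranked within the top m (1.0 if none planted)."""
    if top_m > len(score_table):
        raise ValueError("top_m exceeds the number of scored SNPs")
    causal = list(causal_ids)
    if not causal:
        return 1.0
    top = set(score_table.top_ids(top_m))
    return sum(1 for c in causal if c in top) / len(causal)
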