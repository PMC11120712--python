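"""Filter statistics for SNP relevance ranking.

Three univariate scorers map one SNP dosage column plus the target to a
non-negative relevance score:

* **ANOVA F** — ratio of between-group to within-group mean squares
  against the 3-level trait (categorical mode), or the univariate
  linear-regression F statistic against the continuous trait
  (quantitative mode).
* **Fisher score** — between-class scatter over within-class scatter,
  ``sum_k n_k (mu_k - mu)^2 / (sum_k n_k sigma_k^2 + eps)`` with
  population (divide-by-n_k) within-class variances. Being class-based by
  definition, it is always computed against the discretized levels.
* **MIC** — maximal information coefficient: the maximum, over
  axis-parallel grids whose cell-count product does not exceed the budget
  ``B(n) = max(min_budget, n^alpha)``, of the binned mutual information
  normalised by ``log2(min(nx, ny))``. An exhaustive grid enumeration
  serves as the exact reference on small samples; a dynamic-programming
  search (equipartition one axis, optimise the other's cut points) covers
  larger samples.

Ranks are assigned in decreasing score order with ties broken by column
order, so a ranking is a pure function of its inputs.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import GenotypeMatrix, PhenotypeTable

#: Denominator guard for perfectly separable features in the Fisher score.
FISHER_EPS = 1e-12

METHODS = ("anova", "fscore", "mic")
TARGET_MODES = ("quantitative", "categorical")


@dataclass
class ScoreTable:
    """Per-SNP relevance scores and ranks for one scorer and target mode."""

    method: str
    target_mode: str
    snp_ids: list[str]
    scores: np.ndarray
    ranks: np.ndarray

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.target_mode not in TARGET_MODES:
            raise ValueError(f"unknown target mode {self.target_mode!r}")
        self.snp_ids = [str(s) for s in self.snp_ids]
        self.scores = np.asarray(self.scores, dtype=float)
        self.ranks = np.asarray(self.ranks, dtype=int)
        p = len(self.snp_ids)
        if self.scores.shape != (p,) or self.ranks.shape != (p,):
            raise ValueError("scores/ranks must align with SNP ids")
        if sorted(self.ranks) != list(range(1, p + 1)):
            raise ValueError("ranks must be a permutation of 1..p")

    def __len__(self) -> int:
        return len(self.snp_ids)

    def top_ids(self, k: int) -> list[str]:
        """SNP ids with rank <= k, in rank order."""
        if k > len(self):
            raise ValueError(f"k={k} exceeds table size {len(self)}")
        order = np.argsort(self.ranks)
        return [self.snp_ids[j] for j in order[:k]]

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "target_mode": self.target_mode,
            "snp_ids": self.snp_ids,
            "scores": [float(s) for s in self.scores],
            "ranks": [int(r) for r in self.ranks],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScoreTable":
        return cls(
            d["method"], d["target_mode"], d["snp_ids"],
            np.asarray(d["scores"]), np.asarray(d["ranks"], dtype=int),
        )


@dataclass(frozen=True)
class MicConfig:
    """MIC search parameters.

    ``alpha`` sets the grid budget exponent in ``B(n) = max(min_budget,
    n^alpha)``; grids must satisfy ``nx * ny <= B(n)`` with at least two
    bins per axis. ``mode`` selects exhaustive enumeration, the DP
    approximation, or (default) automatic dispatch: exhaustive whenever
    ``n <= exhaustive_n``, where the full enumeration is cheap and exact.
    ``max_candidates`` caps the number of cut-point candidates per axis in
    the DP to bound its cost on large samples.
    """

    alpha: float = 0.6
    min_budget: int = 4
    mode: str = "auto"
    exhaustive_n: int = 40
    max_candidates: int = 64

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")
        if self.min_budget < 4:
            raise ValueError("min_budget must be >= 4 (a 2x2 grid)")
        if self.mode not in ("auto", "exhaustive", "approximate"):
            raise ValueError(f"unknown MIC mode {self.mode!r}")

    def budget(self, n: int) -> float:
        return max(float(self.min_budget), float(n) ** self.alpha)


# ---------------------------------------------------------------------------
# ANOVA F
# ---------------------------------------------------------------------------

def anova_f(x: np.ndarray, target: np.ndarray, mode: str = "categorical") -> float:
    """ANOVA/regression F statistic of one feature against the target.

    Categorical mode: one-way ANOVA F over the target's groups. Quantitative
    mode: the univariate regression F, ``(n-2) r^2 / (1 - r^2)``. A constant
    feature scores 0; zero residual variance with non-zero explained
    variance yields ``inf`` (ranked above every finite score).
    """
    x = np.asarray(x, dtype=float)
    target = np.asarray(target)
    if x.shape != target.shape or x.ndim != 1:
        raise ValueError("feature and target must be 1-D and aligned")
    if np.ptp(x) == 0.0:
        return 0.0
    if mode == "categorical":
        groups = [x[target == g] for g in np.unique(target)]
        groups = [g for g in groups if g.size > 0]
        k = len(groups)
        n = x.size
        if k < 2:
            raise ValueError("need at least 2 non-empty groups")
        if n <= k:
            raise ValueError("need more samples than groups")
        grand = x.mean()
        ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        if ss_within == 0.0:
            return math.inf if ss_between > 0.0 else 0.0
        return float((ss_between / (k - 1)) / (ss_within / (n - k)))
    if mode == "quantitative":
        y = target.astype(float)
        n = x.size
        if n < 3:
            raise ValueError("regression F needs at least 3 samples")
        if np.ptp(y) == 0.0:
            return 0.0
        dx = x - x.mean()
        dy = y - y.mean()
        r2 = (dx @ dy) ** 2 / ((dx @ dx) * (dy @ dy))
        if r2 >= 1.0:
            return math.inf
        return float((n - 2) * r2 / (1.0 - r2))
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Fisher score
# ---------------------------------------------------------------------------

def fisher_score(x: np.ndarray, levels: np.ndarray) -> float:
    """Between-class over within-class scatter of one feature."""
    x = np.asarray(x, dtype=float)
    levels = np.asarray(levels)
    if x.shape != levels.shape or x.ndim != 1:
        raise ValueError("feature and levels must be 1-D and aligned")
    classes = np.unique(levels)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    grand = x.mean()
    num = 0.0
    den = 0.0
    for c in classes:
        xc = x[levels == c]
        num += xc.size * (xc.mean() - grand) ** 2
        den += xc.size * xc.var()  # population variance
    return float(num / (den + FISHER_EPS))


# ---------------------------------------------------------------------------
# MIC
# ---------------------------------------------------------------------------

def _cut_positions(sorted_vals: np.ndarray) -> np.ndarray:
    """Indices i such that a grid line may fall between sorted_vals[i-1] and [i]."""
    return np.flatnonzero(np.diff(sorted_vals) > 0) + 1


def _mutual_information(xb: np.ndarray, yb: np.ndarray, nx: int, ny: int) -> float:
    """I(xb; yb) in bits from integer bin labels."""
    joint = np.zeros((nx, ny))
    np.add.at(joint, (xb, yb), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    return float(
        (joint[nz] * np.log2(joint[nz] / np.outer(px, py)[nz])).sum()
    )


def _admissible_shapes(budget: float) -> list[tuple[int, int]]:
    shapes = []
    nx = 2
    while nx * 2 <= budget:
        ny = 2
        while nx * ny <= budget:
            shapes.append((nx, ny))
            ny += 1
        nx += 1
    return shapes


_MAX_ORACLE_GRIDS = 2_000_000


def _mic_exhaustive(x: np.ndarray, y: np.ndarray, cfg: MicConfig) -> float:
    n = x.size
    budget = cfg.budget(n)
    sx = np.sort(x)
    sy = np.sort(y)
    cuts_x = _cut_positions(sx)
    cuts_y = _cut_positions(sy)
    if cuts_x.size == 0 or cuts_y.size == 0:
        return 0.0  # a constant variable carries no information
    order_x = np.argsort(x, kind="stable")
    order_y = np.argsort(y, kind="stable")
    rank_x = np.empty(n, dtype=int)
    rank_x[order_x] = np.arange(n)
    rank_y = np.empty(n, dtype=int)
    rank_y[order_y] = np.arange(n)

    total = 0
    for nx, ny in _admissible_shapes(budget):
        total += math.comb(cuts_x.size, nx - 1) * math.comb(cuts_y.size, ny - 1)
    if total > _MAX_ORACLE_GRIDS:
        raise ValueError(
            f"exhaustive MIC would enumerate {total} grids; use approximate mode"
        )

    best = 0.0
    for nx, ny in _admissible_shapes(budget):
        if cuts_x.size < nx - 1 or cuts_y.size < ny - 1:
            continue
        norm = math.log2(min(nx, ny))
        for cx in itertools.combinations(cuts_x, nx - 1):
            xb = np.searchsorted(np.asarray(cx), rank_x, side="right")
            for cy in itertools.combinations(cuts_y, ny - 1):
                yb = np.searchsorted(np.asarray(cy), rank_y, side="right")
                mi = _mutual_information(xb, yb, nx, ny)
                best = max(best, mi / norm)
    return min(best, 1.0)


def mic_oracle(x: np.ndarray, y: np.ndarray, cfg: MicConfig = MicConfig()) -> float:
    """Exact MIC by exhaustive enumeration of every admissible grid.

    All placements of grid lines between consecutive distinct sorted
    values are tried for every admissible (nx, ny) shape, so the result is
    exact by construction. Feasible only for small samples (n <= 60).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and aligned")
    if x.size > 60:
        raise ValueError(
            f"n={x.size} too large for exhaustive enumeration; use mic_score "
            "in approximate mode"
        )
    return _mic_exhaustive(x, y, cfg)


def _equipartition_cuts(vals: np.ndarray, n_bins: int) -> np.ndarray | None:
    """Cut thresholds splitting sorted ``vals`` into ~equal bins at distinct gaps."""
    n = vals.size
    sv = np.sort(vals)
    gaps = _cut_positions(sv)  # allowed cut indices
    if gaps.size < n_bins - 1:
        return None
    targets = np.array([i * n / n_bins for i in range(1, n_bins)])
    chosen: list[int] = []
    available = list(gaps)
    for t in targets:
        k = int(np.argmin(np.abs(np.asarray(available) - t)))
        chosen.append(available.pop(k))
        if not available:
            break
    if len(chosen) < n_bins - 1:
        return None
    chosen = sorted(chosen)
    return np.array([(sv[i - 1] + sv[i]) / 2.0 for i in chosen])


def _dp_optimize(
    opt_vals: np.ndarray,
    fixed_bins: np.ndarray,
    n_fixed: int,
    max_bins: int,
    max_candidates: int,
) -> np.ndarray:
    """Max of H(P) - H(P,Q) over partitions of the optimised axis.

    Returns an array indexed by bin count (position b = best value using
    exactly b+1 bins, in bits). The objective is additive over bins, so a
    prefix DP over candidate cut positions is exact within its candidate
    set.
    """
    n = opt_vals.size
    order = np.argsort(opt_vals, kind="stable")
    sv = opt_vals[order]
    q = fixed_bins[order]
    candidates = _cut_positions(sv)
    if candidates.size > max_candidates:
        sel = np.linspace(0, candidates.size - 1, max_candidates).round().astype(int)
        candidates = candidates[np.unique(sel)]
    bounds = np.concatenate(([0], candidates, [n]))  # prefix end positions
    m = bounds.size
    # cumulative per-fixed-bin counts at each boundary
    onehot = np.zeros((n, n_fixed))
    onehot[np.arange(n), q] = 1.0
    cum = np.zeros((m, n_fixed))
    cum[1:] = np.cumsum(onehot, axis=0)[bounds[1:] - 1]
    # term[j, i]: contribution of a bin covering points (bounds[j], bounds[i]]
    npts = (bounds[None, :] - bounds[:, None]).astype(float)
    valid = npts > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        pb = np.where(valid, npts / n, 1.0)
        term = -pb * np.log2(pb)
        cell = cum[None, :, :] - cum[:, None, :]
        pc = np.where(cell > 0, cell / n, 1.0)
        term += (pc * np.log2(pc)).sum(axis=2)
    term[~valid] = -np.inf

    best = np.full(max_bins, -np.inf)
    f = term[0].copy()  # one bin covering the prefix
    best[0] = f[m - 1]
    for b in range(1, max_bins):
        f = np.max(f[:, None] + term, axis=0)
        best[b] = f[m - 1]
    return best


def mic_score(x: np.ndarray, y: np.ndarray, cfg: MicConfig = MicConfig()) -> float:
    """Maximal information coefficient of two variables, in [0, 1].

    With the default ``auto`` mode, small samples (n <= ``exhaustive_n``)
    are scored by the exact exhaustive search; larger samples use the DP
    approximation: one axis is equipartitioned, the other's cut points are
    optimised by dynamic programming, maximising over admissible grid
    shapes and both orientations. Every grid the DP considers is a valid
    axis-parallel grid, so the approximation never exceeds the exact MIC.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and aligned")
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 observations, got {n}")
    if cfg.mode == "exhaustive" or (cfg.mode == "auto" and n <= cfg.exhaustive_n):
        return _mic_exhaustive(x, y, cfg)

    budget = cfg.budget(n)
    best = 0.0
    for fixed, opt in ((x, y), (y, x)):
        if np.ptp(fixed) == 0.0 or np.ptp(opt) == 0.0:
            continue
        n_fixed_max = int(budget // 2)
        for n_fixed in range(2, n_fixed_max + 1):
            cuts = _equipartition_cuts(fixed, n_fixed)
            if cuts is None:
                break
            fixed_bins = np.searchsorted(cuts, fixed, side="left")
            # H(Q) of the realised fixed-axis partition
            pq = np.bincount(fixed_bins, minlength=n_fixed) / n
            hq = float(-(pq[pq > 0] * np.log2(pq[pq > 0])).sum())
            max_opt = int(budget // n_fixed)
            if max_opt < 2:
                break
            gains = _dp_optimize(opt, fixed_bins, n_fixed, max_opt, cfg.max_candidates)
            for n_opt in range(2, max_opt + 1):
                g = gains[n_opt - 1]
                if not np.isfinite(g):
                    continue
                mic = (hq + g) / math.log2(min(n_fixed, n_opt))
                best = max(best, mic)
    return float(min(max(best, 0.0), 1.0))


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------

def _scores_to_ranks(scores: np.ndarray) -> np.ndarray:
    order = np.argsort(-scores, kind="stable")  # ties keep column order
    ranks = np.empty(scores.size, dtype=int)
    ranks[order] = np.arange(1, scores.size + 1)
    return ranks


def _anova_categorical_all(X: np.ndarray, levels: np.ndarray) -> np.ndarray:
    """Vectorised one-way ANOVA F for every column of X."""
    n, p = X.shape
    classes = np.unique(levels)
    k = classes.size
    grand = X.mean(axis=0)
    ss_between = np.zeros(p)
    ss_within = np.zeros(p)
    for c in classes:
        Xc = X[levels == c]
        mc = Xc.mean(axis=0)
        ss_between += Xc.shape[0] * (mc - grand) ** 2
        ss_within += ((Xc - mc) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / (k - 1)) / (ss_within / (n - k))
    f = np.where(ss_within == 0.0, np.where(ss_between > 0, np.inf, 0.0), f)
    f[np.ptp(X, axis=0) == 0.0] = 0.0
    return f


def _anova_quantitative_all(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    n, p = X.shape
    dx = X - X.mean(axis=0)
    dy = y - y.mean()
    sxy = dy @ dx
    sxx = (dx * dx).sum(axis=0)
    syy = float(dy @ dy)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = sxy**2 / (sxx * syy)
        f = (n - 2) * r2 / (1.0 - r2)
    f = np.where(r2 >= 1.0, np.inf, f)
    f[sxx == 0.0] = 0.0
    if syy == 0.0:
        f[:] = 0.0
    return f


def _fisher_all(X: np.ndarray, levels: np.ndarray) -> np.ndarray:
    classes = np.unique(levels)
    grand = X.mean(axis=0)
    num = np.zeros(X.shape[1])
    den = np.zeros(X.shape[1])
    for c in classes:
        Xc = X[levels == c]
        num += Xc.shape[0] * (Xc.mean(axis=0) - grand) ** 2
        den += Xc.shape[0] * Xc.var(axis=0)
    return num / (den + FISHER_EPS)


def rank_features(
    g: GenotypeMatrix | np.ndarray,
    target,
    method: str,
    mode: str = "categorical",
    cfg: MicConfig | None = None,
) -> ScoreTable:
    """Score every SNP with one filter statistic and rank them.

    ``target`` may be a :class:`PhenotypeTable` (values and levels taken
    as the mode demands) or a plain array (the mode's direct target; the
    Fisher score in quantitative mode then requires a PhenotypeTable with
    levels, since it is class-based by definition).
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    if mode not in TARGET_MODES:
        raise ValueError(f"unknown target mode {mode!r}")
    if isinstance(g, GenotypeMatrix):
        X = g.dosages.astype(float)
        snp_ids = list(g.snp_ids)
    else:
        X = np.asarray(g, dtype=float)
        snp_ids = [f"snp{j}" for j in range(X.shape[1])]
    if isinstance(target, PhenotypeTable):
        values = target.values
        levels = target.levels
    else:
        arr = np.asarray(target)
        values = arr.astype(float)
        levels = arr if mode == "categorical" else None
    y = values if mode == "quantitative" else levels
    if y is None or len(y) != X.shape[0]:
        raise ValueError("target does not align with samples (or levels unset)")

    if method == "anova":
        scores = (
            _anova_quantitative_all(X, np.asarray(values, dtype=float))
            if mode == "quantitative"
            else _anova_categorical_all(X, np.asarray(levels))
        )
    elif method == "fscore":
        if levels is None:
            raise ValueError(
                "fscore requires discretized levels (pass a PhenotypeTable "
                "with levels)"
            )
        scores = _fisher_all(X, np.asarray(levels))
    else:  # mic
        cfg = cfg or MicConfig()
        yv = np.asarray(y, dtype=float)
        scores = np.array([mic_score(X[:, j], yv, cfg) for j in range(X.shape[1])])
    return ScoreTable(method, mode, snp_ids, scores, _scores_to_ranks(scores))
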