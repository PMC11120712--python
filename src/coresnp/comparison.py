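"""Agreement between the SNP panels chosen by different scorers.

Different filter statistics select visibly different SNP sets; this
module quantifies that: per-method top-K id sets, the seven Venn regions
of a three-method comparison, and a BED-like chromosome distribution
table for plotting panel positions along the genome.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .feature_scoring import ScoreTable
from .io_formats import SnpMeta

logger = logging.getLogger("coresnp")

DEFAULT_TOP_K = (300, 1000)


@dataclass
class OverlapReport:
    """Venn region cardinalities of three top-K SNP sets."""

    k: int
    methods: list[str]
    sets: dict[str, set]
    regions: dict[frozenset, int]

    @property
    def triple(self) -> int:
        return self.regions[frozenset(self.methods)]

    def pairwise(self, a: str, b: str) -> int:
        """Size of the full pairwise intersection |A ∩ B| (triple included)."""
        return len(self.sets[a] & self.sets[b])

    @property
    def exactly_one(self) -> int:
        return sum(c for r, c in self.regions.items() if len(r) == 1)

    @property
    def exactly_two(self) -> int:
        return sum(c for r, c in self.regions.items() if len(r) == 2)

    @property
    def union_size(self) -> int:
        return sum(self.regions.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"region": "|".join(sorted(r)), "count": c}
            for r, c in sorted(self.regions.items(), key=lambda rc: sorted(rc[0]))
        ]
        return pd.DataFrame(rows)


def top_k_sets(tables: Sequence[ScoreTable], k: int) -> dict[str, set]:
    """Per-method sets of SNP ids with rank <= k."""
    out: dict[str, set] = {}
    for t in tables:
        if k > len(t):
            raise ValueError(f"k={k} exceeds {t.method} table size {len(t)}")
        if t.method in out:
            raise ValueError(f"duplicate method {t.method!r}")
        out[t.method] = set(t.top_ids(k))
    return out


def venn_counts(sets: dict[str, set], k: int | None = None) -> OverlapReport:
    """All seven Venn region cardinalities of exactly three id sets."""
    if len(sets) != 3:
        raise ValueError(f"need exactly 3 sets, got {len(sets)}")
    methods = list(sets)
    regions: dict[frozenset, int] = {}
    for r in range(1, 4):
        for combo in itertools.combinations(methods, r):
            inside = set.intersection(*(sets[m] for m in combo))
            outside = set.union(
                set(), *(sets[m] for m in methods if m not in combo)
            )
            regions[frozenset(combo)] = len(inside - outside)
    if k is None:
        k = max(len(s) for s in sets.values())
    return OverlapReport(k, methods, {m: set(s) for m, s in sets.items()}, regions)


def chrom_distribution(
    ids: Sequence[str], meta: Sequence[SnpMeta], method: str
) -> pd.DataFrame:
    """BED-like (chrom, start, end, snp_id, method) table of a SNP panel.

    Start/end are 0-based half-open; rows are sorted by (chrom, pos) and
    duplicate input ids are collapsed with a warning.
    """
    by_id = {m.snp_id: m for m in meta}
    seen: set[str] = set()
    rows = []
    n_dup = 0
    for sid in ids:
        if sid in seen:
            n_dup += 1
            continue
        seen.add(sid)
        if sid not in by_id:
            raise KeyError(f"SNP id {sid!r} not present in metadata")
        m = by_id[sid]
        rows.append(
            {
                "chrom": m.chrom,
                "start": m.pos - 1,
                "end": m.pos,
                "snp_id": m.snp_id,
                "method": method,
            }
        )
    if n_dup:
        logger.warning("deduplicated %d repeated SNP id(s) in panel", n_dup)
    frame = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "snp_id", "method"]
    )
    return frame.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
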