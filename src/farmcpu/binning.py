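"""Pseudo-QTN candidate selection by genomic binning.

A scan's p-values are reduced to candidate covariate sets: the genome is
partitioned into fixed-width physical bins, the best marker (smallest p) is
taken per bin, and the top-ranked eligible candidates form one candidate
set per (bin size, set size) combination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .glm import ScanResult
from .store import MarkerInfo, MarkerMatrix

__all__ = [
    "BinConfig",
    "PseudoQTNSet",
    "default_bin_sizes",
    "assign_bins",
    "top_per_bin",
    "build_candidate_sets",
    "filter_correlated",
]

# bin-size ladder keyed to marker count (base pairs)
_BIN_TABLE: list[tuple[int, tuple[int, ...]]] = [
    (10_000, (500, 1_000, 1_500, 2_000)),
    (50_000, (2_500, 5_000, 7_500, 10_000)),
    (60_000, (2_500, 5_000, 7_500, 10_000)),
    (100_000, (5_000, 10_000, 15_000, 20_000)),
    (500_000, (25_000, 50_000, 75_000, 100_000)),
    (1_000_000, (50_000, 100_000, 150_000, 200_000)),
    (5_000_000, (250_000, 500_000, 750_000, 1_000_000)),
]


def default_bin_sizes(m: int) -> tuple[int, ...]:
    """Bin-size ladder for the row of the density table nearest to ``m``."""
    best = min(_BIN_TABLE, key=lambda row: abs(row[0] - m))
    return best[1]


@dataclass
class BinConfig:
    """Binning and set-size grid for candidate selection."""

    bin_sizes: tuple[int, ...] = ()
    qtn_counts: tuple[int, ...] = (10, 20, 30)
    eligibility_threshold: float = 0.01

    def __post_init__(self) -> None:
        self.bin_sizes = tuple(int(b) for b in self.bin_sizes)
        self.qtn_counts = tuple(int(c) for c in self.qtn_counts)
        if any(b <= 0 for b in self.bin_sizes):
            raise ValueError("bin sizes must be positive")
        if any(c <= 0 for c in self.qtn_counts):
            raise ValueError("qtn counts must be positive")
        if list(self.qtn_counts) != sorted(self.qtn_counts):
            raise ValueError("qtn_counts must be ascending")
        if not 0.0 < self.eligibility_threshold <= 1.0:
            raise ValueError("eligibility_threshold must be in (0, 1]")

    def resolved_bin_sizes(self, m: int) -> tuple[int, ...]:
        return self.bin_sizes if self.bin_sizes else default_bin_sizes(m)


@dataclass
class PseudoQTNSet:
    """Marker indices (ascending p) chosen under one (bin_size, qtn_count)."""

    indices: tuple[int, ...]
    bin_size: int
    qtn_count: int

    def __len__(self) -> int:
        return len(self.indices)

    def as_set(self) -> frozenset[int]:
        return frozenset(self.indices)


def assign_bins(info: MarkerInfo, bin_size: int) -> list[tuple[str, int]]:
    """Label each marker with its (chromosome, physical bin index).

    Positions are 1-based, so position ``bin_size`` still falls in bin 0.
    """
    if bin_size <= 0:
        raise ValueError(f"bin size must be positive, got {bin_size}")
    idx = (info.position - 1) // bin_size
    return [(str(c), int(b)) for c, b in zip(info.chromosome, idx)]


def top_per_bin(
    result: ScanResult, bins: list[tuple[str, int]], info: MarkerInfo
) -> list[int]:
    """One marker per bin (smallest p), ranked by ascending p.

    Ties within a bin and in the final ranking break by (chromosome,
    position, marker index) ascending.  Markers with missing p contribute
    nothing.
    """
    p = result.p
    if len(bins) != len(p):
        raise ValueError("bins and p-values are not aligned")
    best: dict[tuple[str, int], int] = {}
    for j in range(len(p)):
        if np.isnan(p[j]):
            continue
        b = bins[j]
        cur = best.get(b)
        if cur is None or _marker_key(p, info, j) < _marker_key(p, info, cur):
            best[b] = j
    return sorted(best.values(), key=lambda j: _marker_key(p, info, j))


def _marker_key(p: np.ndarray, info: MarkerInfo, j: int):
    return (p[j], str(info.chromosome[j]), int(info.position[j]), j)


def build_candidate_sets(
    ranked: dict[int, list[int]], config: BinConfig, result: ScanResult
) -> list[PseudoQTNSet]:
    """One candidate set per (bin_size, qtn_count): the best eligible markers.

    ``ranked`` maps bin size to the ranked per-bin candidates from
    :func:`top_per_bin`.  Sets may be shorter than ``qtn_count`` (or empty)
    when too few candidates pass the eligibility threshold.
    """
    sets = []
    for bin_size, candidates in ranked.items():
        eligible = [
            j for j in candidates if result.p[j] <= config.eligibility_threshold
        ]
        for count in config.qtn_counts:
            sets.append(
                PseudoQTNSet(
                    indices=tuple(eligible[:count]),
                    bin_size=int(bin_size),
                    qtn_count=int(count),
                )
            )
    return sets


def select_candidates(
    result: ScanResult, info: MarkerInfo, config: BinConfig
) -> list[PseudoQTNSet]:
    """Full selection pipeline: bin, take tops, build the candidate grid."""
    ranked = {
        b: top_per_bin(result, assign_bins(info, b), info)
        for b in config.resolved_bin_sizes(result.m)
    }
    return build_candidate_sets(ranked, config, result)


def filter_correlated(
    matrix: MarkerMatrix,
    indices: tuple[int, ...],
    mask: np.ndarray,
    r2_max: float = 0.7,
) -> tuple[int, ...]:
    """Drop the later-ranked member of any pair with squared correlation
    above ``r2_max``, protecting the fixed design's rank."""
    kept: list[int] = []
    kept_cols: list[np.ndarray] = []
    for j in indices:
        x = matrix.values[mask, j]
        sd = x.std()
        if sd < 1e-12:
            continue
        xz = (x - x.mean()) / sd
        ok = True
        for z in kept_cols:
            r = float(xz @ z) / len(xz)
            if r * r > r2_max:
                ok = False
                break
        if ok:
            kept.append(j)
            kept_cols.append(xz)
    return tuple(kept)
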