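"""Synthetic genotype panels and quantitative traits.

Genotypes are built from haplotypes generated by a first-order chain along
each chromosome: every marker's coded-allele frequency is drawn uniformly,
and each adjacent pair attains a target D' (D = D' * Dmax with
Dmax = min(p1*(1-p2), (1-p1)*p2)).  Two independent haplotypes per
individual are summed, so genotypes are additive with zero dominance.

Traits sum geometric QTN effects (effect_base**k for the k-th sampled QTN,
k starting at 1) and add i.i.d. Gaussian noise with variance
(1 - h2) * Var(g) / h2.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .store import MarkerInfo, MarkerMatrix, from_array

__all__ = [
    "SimulationConfig",
    "SimulatedTrait",
    "simulate_haplotypes",
    "simulate_genotypes",
    "simulate_phenotype",
    "estimate_adjacent_dprime",
    "inject_missing",
    "write_dataset",
]


@dataclass
class SimulationConfig:
    n: int
    m: int
    maf_low: float = 0.05
    maf_high: float = 0.5
    dprime: float = 0.75
    n_qtn: int = 3000
    effect_base: float = 0.9
    h2: float = 0.3
    seed: int = 0
    n_chromosomes: int = 10
    marker_spacing: int = 100  # base pairs between adjacent markers

    def __post_init__(self) -> None:
        if self.n < 1 or self.m < 1:
            raise ValueError("n and m must be positive")
        if not 0.0 < self.maf_low <= self.maf_high <= 0.5:
            raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
        if not 0.0 <= self.dprime <= 1.0:
            raise ValueError("dprime must be in [0, 1]")
        if self.n_qtn > self.m:
            raise ValueError("n_qtn cannot exceed the number of markers")
        if not 0.0 < self.h2 <= 1.0:
            raise ValueError(
                "h2 must be in (0, 1]; the noise-variance formula is undefined at h2=0"
            )
        if self.n_chromosomes < 1 or self.n_chromosomes > self.m:
            raise ValueError("n_chromosomes must be in [1, m]")
        if self.marker_spacing < 1:
            raise ValueError("marker_spacing must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class SimulatedTrait:
    """y = g + e with QTN ground truth retained for power evaluation."""

    g: np.ndarray
    e: np.ndarray
    y: np.ndarray
    qtn_indices: np.ndarray
    effects: np.ndarray
    sigma_a2: float
    h2: float


def _chromosome_layout(config: SimulationConfig) -> MarkerInfo:
    sizes = np.full(config.n_chromosomes, config.m // config.n_chromosomes)
    sizes[: config.m % config.n_chromosomes] += 1
    chroms, positions, names = [], [], []
    j = 0
    for c, size in enumerate(sizes, start=1):
        for i in range(size):
            chroms.append(str(c))
            positions.append((i + 1) * config.marker_spacing)
            names.append(f"snp{j + 1}")
            j += 1
    return MarkerInfo(
        name=np.array(names, dtype=object),
        chromosome=np.array(chroms, dtype=object),
        position=np.array(positions, dtype=np.int64),
    )


def simulate_haplotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray, MarkerInfo]:
    """Generate a (2n) x m haplotype panel, its frequencies, and the map."""
    rng = rng or config.rng()
    info = _chromosome_layout(config)
    freqs = rng.uniform(config.maf_low, config.maf_high, size=config.m)
    n_hap = 2 * config.n
    H = np.empty((n_hap, config.m), dtype=np.int8)

    chrom_arr = info.chromosome
    for j in range(config.m):
        p2 = freqs[j]
        new_chrom = j == 0 or chrom_arr[j] != chrom_arr[j - 1]
        if new_chrom:
            H[:, j] = rng.random(n_hap) < p2
            continue
        p1 = freqs[j - 1]
        dmax = min(p1 * (1.0 - p2), (1.0 - p1) * p2)
        D = config.dprime * dmax
        prob_given_1 = np.clip(p2 + D / p1, 0.0, 1.0)
        prob_given_0 = np.clip(p2 - D / (1.0 - p1), 0.0, 1.0)
        pr = np.where(H[:, j - 1] == 1, prob_given_1, prob_given_0)
        H[:, j] = rng.random(n_hap) < pr
    return H, freqs, info


def simulate_genotypes(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    store_path: str | Path | None = None,
) -> tuple[MarkerMatrix, MarkerInfo]:
    """Sum two independent haplotypes per individual into 0/1/2 genotypes.

    With ``store_path`` the matrix is written to a file-backed store;
    otherwise it lives in memory (same interface, no backing file).
    """
    H, _, info = simulate_haplotypes(config, rng)
    G = (H[: config.n] + H[config.n :]).astype(np.float64)
    sample_ids = [f"ind{i + 1}" for i in range(config.n)]
    if store_path is not None:
        matrix = from_array(G, sample_ids, store_path)
    else:
        matrix = MarkerMatrix(
            np.asfortranarray(G), sample_ids, descriptor_path=None, data_path=None
        )
    return matrix, info


def simulate_phenotype(
    matrix: MarkerMatrix,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> SimulatedTrait:
    """Draw QTNs, build genetic values, add heritability-scaled noise."""
    rng = rng or np.random.default_rng(config.seed + 1)
    if config.n_qtn > matrix.m:
        raise ValueError("n_qtn exceeds available markers")
    qtn = rng.choice(matrix.m, size=config.n_qtn, replace=False)
    effects = config.effect_base ** np.arange(1, config.n_qtn + 1)
    g = matrix.values[:, qtn] @ effects
    sigma_a2 = float(np.var(g))
    if sigma_a2 <= 0.0:
        raise ValueError("genetic values are constant; cannot scale noise")
    noise_var = (1.0 - config.h2) * sigma_a2 / config.h2
    e = rng.normal(0.0, np.sqrt(noise_var), size=matrix.n)
    return SimulatedTrait(
        g=g, e=e, y=g + e, qtn_indices=qtn, effects=effects,
        sigma_a2=sigma_a2, h2=config.h2,
    )


def simulate_dataset(
    config: SimulationConfig, store_path: str | Path | None = None
) -> tuple[MarkerMatrix, MarkerInfo, SimulatedTrait]:
    """Genotypes plus phenotype from a single seeded generator."""
    rng = config.rng()
    matrix, info = simulate_genotypes(config, rng, store_path)
    trait = simulate_phenotype(matrix, config, rng)
    return matrix, info, trait


def estimate_adjacent_dprime(H: np.ndarray, info: MarkerInfo) -> np.ndarray:
    """Empirical |D'| for each within-chromosome adjacent marker pair."""
    n_hap, m = H.shape
    out = []
    for j in range(1, m):
        if info.chromosome[j] != info.chromosome[j - 1]:
            continue
        a = H[:, j - 1].astype(np.float64)
        b = H[:, j].astype(np.float64)
        p1, p2 = a.mean(), b.mean()
        if p1 in (0.0, 1.0) or p2 in (0.0, 1.0):
            continue
        D = float((a * b).mean() - p1 * p2)
        if D >= 0:
            dmax = min(p1 * (1 - p2), (1 - p1) * p2)
        else:
            dmax = min(p1 * p2, (1 - p1) * (1 - p2))
        if dmax <= 0:
            continue
        out.append(abs(D) / dmax)
    return np.asarray(out)


def inject_missing(
    matrix: MarkerMatrix, rate: float, rng: np.random.Generator
) -> int:
    """Blank exactly round(rate * n * m) cells (NaN), in place."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    total = matrix.n * matrix.m
    k = int(round(rate * total))
    flat = rng.choice(total, size=k, replace=False)
    rows, cols = np.unravel_index(flat, (matrix.n, matrix.m))
    matrix.values[rows, cols] = np.nan
    matrix.flush()
    return k


def write_dataset(
    matrix: MarkerMatrix,
    info: MarkerInfo,
    trait: SimulatedTrait,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write genotype/map/phenotype/truth TSVs readable by the store module."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": outdir / "genotypes.tsv",
        "map": outdir / "map.tsv",
        "phenotype": outdir / "phenotype.tsv",
        "truth": outdir / "truth.tsv",
    }
    geno = pd.DataFrame(matrix.values, columns=list(info.name))
    geno.insert(0, "sample", matrix.sample_ids)
    geno.to_csv(paths["genotypes"], sep="\t", index=False, na_rep="NA")
    info.to_frame().to_csv(paths["map"], sep="\t", index=False)
    pd.DataFrame({"sample": matrix.sample_ids, "trait": trait.y}).to_csv(
        paths["phenotype"], sep="\t", index=False, na_rep="NA"
    )
    pd.DataFrame(
        {
            "marker": info.name[trait.qtn_indices],
            "index": trait.qtn_indices,
            "effect": trait.effects,
        }
    ).to_csv(paths["truth"], sep="\t", index=False)
    return paths
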