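"""Single-marker OLS scan with a cached fixed design.

The model matrix is split into a constant part (intercept, covariates,
pseudo-QTN genotype columns) and a per-marker variable part.  The constant
part is QR-factorized once; each marker then needs only the projections of
its masked scores onto that basis (two small matrix-vector products), so a
full scan costs O(n_eff * (q + t + 2)) per marker.

Rows with missing phenotype are excluded through an index mask applied when
each marker column is read — the marker matrix itself is never subset or
copied in full.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .store import CovariateMatrix, MarkerInfo, MarkerMatrix

__all__ = ["FixedDesign", "ScanResult", "build_fixed_design", "scan_markers", "scan_parallel"]

#: masked marker variance below this is treated as constant
CONSTANT_VAR_TOL = 1e-12
#: relative residual norm below this marks a marker collinear with the fixed part
COLLINEAR_TOL = 1e-10


class RankDeficiencyError(np.linalg.LinAlgError):
    """The fixed design lost full column rank."""


@dataclass
class FixedDesign:
    """Cached factorization of the constant model-matrix columns.

    ``mask`` indexes the complete-phenotype rows; ``basis`` is an
    orthonormal basis (n_eff x k) of the fixed columns on those rows, and
    ``y_resid`` is the masked phenotype residualized against it.
    """

    mask: np.ndarray
    basis: np.ndarray
    y_masked: np.ndarray
    y_resid: np.ndarray
    rss: float
    n_eff: int
    k: int
    pseudo_qtns: tuple[int, ...]
    column_names: list[str]
    coef: np.ndarray
    coef_se: np.ndarray
    coef_t: np.ndarray
    coef_p: np.ndarray

    @property
    def residual_df(self) -> int:
        """Residual degrees of freedom once a marker column is added."""
        return self.n_eff - self.k - 1


@dataclass
class ScanResult:
    """Per-marker effect, standard error, t statistic and two-sided p.

    Entries are NaN exactly when the marker is constant on the masked
    samples or collinear with the fixed design.
    """

    effect: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    n_used: np.ndarray
    df: int

    @property
    def m(self) -> int:
        return len(self.effect)

    def to_frame(self, info: MarkerInfo) -> pd.DataFrame:
        if len(info) != self.m:
            raise ValueError("marker info length does not match scan result")
        return pd.DataFrame(
            {
                "marker": info.name,
                "chrom": info.chromosome,
                "pos": info.position,
                "n_used": self.n_used,
                "effect": self.effect,
                "se": self.se,
                "t": self.t,
                "p": self.p,
            }
        )


def _as_aligned_y(y, matrix: MarkerMatrix) -> np.ndarray:
    if hasattr(y, "aligned_to"):
        return y.aligned_to(matrix)
    return np.asarray(y, dtype=np.float64)


def build_fixed_design(
    y,
    covariates: CovariateMatrix | np.ndarray | None,
    pseudo_qtns,
    matrix: MarkerMatrix,
) -> FixedDesign:
    """QR-factorize [intercept | covariates | pseudo-QTN columns].

    ``y`` may be a :class:`Phenotype` (aligned by sample ID) or an array
    already in matrix row order.  Missing-phenotype rows define the mask.
    Raises :class:`RankDeficiencyError` naming the first dependent column.
    """
    y = _as_aligned_y(y, matrix)
    if len(y) != matrix.n:
        raise ValueError("phenotype length does not match matrix rows")
    mask = np.flatnonzero(np.isfinite(y))
    n_eff = len(mask)
    if n_eff == 0:
        raise ValueError("zero usable samples after removing missing phenotypes")
    y_masked = y[mask]
    if not np.isfinite(np.var(y_masked)):
        raise ValueError("non-finite phenotype variance")

    if covariates is None:
        cov = np.empty((n_eff, 0))
        cov_names: list[str] = []
    elif isinstance(covariates, CovariateMatrix):
        cov = covariates.aligned_to(matrix)[mask]
        cov_names = list(covariates.names)
    else:
        cov = np.atleast_2d(np.asarray(covariates, dtype=np.float64))
        if cov.shape[0] == matrix.n:
            cov = cov[mask]
        elif cov.shape[0] != n_eff:
            raise ValueError("covariate rows match neither n nor n_eff")
        cov_names = [f"cov{i + 1}" for i in range(cov.shape[1])]

    pseudo_qtns = tuple(int(j) for j in pseudo_qtns)
    for j in pseudo_qtns:
        if not 0 <= j < matrix.m:
            raise IndexError(f"pseudo-QTN index {j} out of range")
    qtn_cols = (
        matrix.values[np.ix_(mask, list(pseudo_qtns))]
        if pseudo_qtns
        else np.empty((n_eff, 0))
    )

    X = np.column_stack([np.ones(n_eff), cov, qtn_cols])
    names = ["intercept", *cov_names, *[f"pseudo_qtn_{j}" for j in pseudo_qtns]]
    k = X.shape[1]
    if n_eff <= k + 1:
        raise ValueError(
            f"not enough complete samples ({n_eff}) for {k} fixed columns plus a marker"
        )

    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if k else 1.0)
    bad = np.flatnonzero(diag < max(tol, 1e-10))
    if bad.size:
        raise RankDeficiencyError(
            f"fixed design is rank deficient at column {names[bad[0]]!r}"
        )

    qty = Q.T @ y_masked
    y_resid = y_masked - Q @ qty
    rss = float(y_resid @ y_resid)

    # fixed-part coefficient tests (used for pseudo-QTN output substitution)
    coef = np.linalg.solve(R, qty)
    df_fixed = n_eff - k
    sigma2 = rss / df_fixed
    Rinv = np.linalg.solve(R, np.eye(k))
    coef_se = np.sqrt(sigma2 * np.sum(Rinv * Rinv, axis=1))
    coef_t = coef / coef_se
    coef_p = 2.0 * stats.t.sf(np.abs(coef_t), df_fixed)

    return FixedDesign(
        mask=mask,
        basis=Q,
        y_masked=y_masked,
        y_resid=y_resid,
        rss=rss,
        n_eff=n_eff,
        k=k,
        pseudo_qtns=pseudo_qtns,
        column_names=names,
        coef=coef,
        coef_se=coef_se,
        coef_t=coef_t,
        coef_p=coef_p,
    )


def _scan_into(
    matrix: MarkerMatrix,
    fixed: FixedDesign,
    start: int,
    stop: int,
    effect: np.ndarray,
    xr2_store: np.ndarray,
    rssm_store: np.ndarray,
) -> None:
    # Per-marker loop with fixed operation order: results are bitwise
    # reproducible for any chunking or worker count.
    Q = fixed.basis
    yr = fixed.y_resid
    mask = fixed.mask
    values = matrix.values
    n_eff = fixed.n_eff
    for j in range(start, stop):
        x = values[mask, j]
        mu = x.mean()
        xc2 = float(x @ x) - n_eff * mu * mu
        if xc2 / n_eff < CONSTANT_VAR_TOL:
            continue
        a = Q.T @ x
        xr = x - Q @ a
        xr2 = float(xr @ xr)
        if xr2 <= COLLINEAR_TOL * xc2:
            continue
        b = float(xr @ yr) / xr2
        rss_m = fixed.rss - b * b * xr2
        effect[j - start] = b
        xr2_store[j - start] = xr2
        rssm_store[j - start] = max(rss_m, 0.0)


def _finalize(
    effect: np.ndarray,
    xr2: np.ndarray,
    rssm: np.ndarray,
    df: int,
    n_eff: int,
) -> ScanResult:
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(rssm / df / xr2)
        t = effect / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
    # exact fits give t = inf, p = 0; clamp into (0, 1]
    p = np.where(np.isfinite(t) & (p <= 0.0), np.nextafter(0.0, 1.0), p)
    p = np.where(np.isnan(t), np.nan, p)
    n_used = np.where(np.isnan(effect), 0, n_eff)
    return ScanResult(effect=effect, se=se, t=t, p=p, n_used=n_used, df=df)


def scan_markers(
    matrix: MarkerMatrix,
    fixed: FixedDesign,
    y=None,
    chunk: tuple[int, int] | None = None,
) -> ScanResult:
    """Scan a marker range serially.

    ``chunk`` is a half-open (start, stop) marker index range; default all
    markers.  ``y`` is accepted for interface symmetry but the masked
    phenotype cached in ``fixed`` is what is used.
    """
    start, stop = chunk if chunk is not None else (0, matrix.m)
    if not (0 <= start <= stop <= matrix.m):
        raise ValueError(f"invalid chunk ({start}, {stop}) for m={matrix.m}")
    size = stop - start
    effect = np.full(size, np.nan)
    xr2 = np.full(size, np.nan)
    rssm = np.full(size, np.nan)
    _scan_into(matrix, fixed, start, stop, effect, xr2, rssm)
    return _finalize(effect, xr2, rssm, fixed.residual_df, fixed.n_eff)


def scan_parallel(
    matrix: MarkerMatrix,
    fixed: FixedDesign,
    y=None,
    n_workers: int = 1,
    chunk_size: int = 512,
) -> ScanResult:
    """Scan all markers across ``n_workers`` threads.

    Each chunk writes into a preallocated slice of the output arrays, so
    results are bitwise identical to a serial scan for any worker count or
    chunk size, and marker order is preserved.
    """
    if n_workers < 1:
        raise ValueError(f"n_workers must be >= 1, got {n_workers}")
    if chunk_size < 1:
        raise ValueError(f"chunk_size must be >= 1, got {chunk_size}")
    m = matrix.m
    effect = np.full(m, np.nan)
    xr2 = np.full(m, np.nan)
    rssm = np.full(m, np.nan)

    bounds = [(s, min(s + chunk_size, m)) for s in range(0, m, chunk_size)]

    def run(b: tuple[int, int]) -> None:
        s, e = b
        _scan_into(matrix, fixed, s, e, effect[s:e], xr2[s:e], rssm[s:e])

    if n_workers == 1 or len(bounds) <= 1:
        for b in bounds:
            run(b)
    else:
        with ThreadPoolExecutor(max_workers=n_workers) as pool:
            list(pool.map(run, bounds))
    return _finalize(effect, xr2, rssm, fixed.residual_df, fixed.n_eff)
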