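"""Random-effects scoring of candidate pseudo-QTN sets.

Each candidate set is scored by the restricted log-likelihood of
``y ~ N(Xb, sigma_a^2 K + sigma_e^2 I)`` where the kinship K is built only
from the pseudo-QTN genotype columns.  The variance ratio
``delta = sigma_e^2 / sigma_a^2`` is profiled by a one-dimensional search
over the spectrum of K projected off X (EMMA-style), so each evaluation
needs a single symmetric eigendecomposition.
"""

from __future__ import annotations

import warnings
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .binning import PseudoQTNSet
from .store import MarkerMatrix

__all__ = [
    "KinshipError",
    "REMLFit",
    "kinship_from_pseudo_qtns",
    "reml_loglik",
    "evaluate_candidate_sets",
    "select_best_config",
]

LOG_DELTA_LO = np.log(1e-5)
LOG_DELTA_HI = np.log(1e5)
_GRID_POINTS = 121


class KinshipError(ValueError):
    """Kinship cannot be built from the given pseudo-QTN set."""


@dataclass
class REMLFit:
    """Profiled variance components for one candidate configuration."""

    sigma_a2: float
    sigma_e2: float
    delta: float
    loglik: float
    config: tuple[int, int] | None = None  # (bin_size, qtn_count)

    @property
    def heritability(self) -> float:
        tot = self.sigma_a2 + self.sigma_e2
        return self.sigma_a2 / tot if tot > 0 else np.nan


def kinship_from_pseudo_qtns(
    matrix: MarkerMatrix, qtn_set, mask: np.ndarray
) -> np.ndarray:
    """VanRaden-style kinship from the pseudo-QTN columns only.

    K = Z_c Z_c' / c with Z_c the pseudo-QTN submatrix centered by twice
    the allele frequency (computed on the masked samples) and
    c = 2 * sum_j p_j (1 - p_j).  Zero-variance columns are dropped with a
    warning; an empty set is an error.
    """
    indices = tuple(qtn_set.indices) if isinstance(qtn_set, PseudoQTNSet) else tuple(qtn_set)
    if len(indices) == 0:
        raise KinshipError("cannot build kinship from an empty pseudo-QTN set")
    Z = matrix.values[np.ix_(np.asarray(mask), list(indices))]
    keep = Z.std(axis=0) >= 1e-12
    if not keep.all():
        dropped = [indices[i] for i in np.flatnonzero(~keep)]
        warnings.warn(
            f"dropping constant pseudo-QTN columns from kinship: {dropped}",
            stacklevel=2,
        )
        Z = Z[:, keep]
    if Z.shape[1] == 0:
        raise KinshipError("all pseudo-QTN columns are constant on the masked samples")
    p = Z.mean(axis=0) / 2.0
    c = float(2.0 * np.sum(p * (1.0 - p)))
    Zc = Z - 2.0 * p
    return (Zc @ Zc.T) / c


def reml_loglik(
    y: np.ndarray, X: np.ndarray, K: np.ndarray, config: tuple[int, int] | None = None
) -> REMLFit:
    """Maximize the restricted likelihood of y ~ N(Xb, sa2*K + se2*I).

    Works in the orthogonal complement of col(X): with A an orthonormal
    basis of that complement, A'y ~ N(0, sa2 * A'KA + se2 * I) and its
    density is the restricted likelihood (invariant to the choice of A).
    delta is profiled on a log grid over [1e-5, 1e5] and refined by bounded
    scalar minimization; endpoints are checked and boundary fits warned.
    """
    y = np.asarray(y, dtype=np.float64)
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[0] != len(y):
        raise ValueError("X rows do not match y")
    n, k = X.shape
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("fixed-effect matrix X is rank deficient")
    if not np.allclose(K, K.T, atol=1e-12):
        raise KinshipError("kinship matrix is not symmetric")

    Qfull, _ = np.linalg.qr(X, mode="complete")
    A = Qfull[:, k:]
    M = A.T @ K @ A
    M = (M + M.T) / 2.0
    lam, U = np.linalg.eigh(M)
    scale = max(1.0, float(lam[-1]))
    if lam[0] < -1e-8 * scale:
        raise KinshipError(f"kinship is not PSD (min projected eigenvalue {lam[0]:.3e})")
    lam = np.clip(lam, 0.0, None)
    eta2 = (U.T @ (A.T @ y)) ** 2
    n_re = n - k

    def neg_restricted_ll(log_delta: float) -> float:
        d = lam + np.exp(log_delta)
        sigma_a2 = float(np.sum(eta2 / d)) / n_re
        return 0.5 * (
            n_re * (np.log(2.0 * np.pi * sigma_a2) + 1.0) + float(np.sum(np.log(d)))
        )

    grid = np.linspace(LOG_DELTA_LO, LOG_DELTA_HI, _GRID_POINTS)
    vals = np.array([neg_restricted_ll(g) for g in grid])
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, _GRID_POINTS - 1)]
    res = minimize_scalar(
        neg_restricted_ll, bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10},
    )
    best_log_delta, best_val = float(res.x), float(res.fun)
    for g, v in ((grid[0], vals[0]), (grid[-1], vals[-1])):
        if v < best_val:
            best_log_delta, best_val = float(g), float(v)

    # delta -> inf limit (no genetic variance) has an exact closed form:
    # the model collapses to y ~ N(Xb, sigma^2 I).
    sigma2_lim = float(np.sum(eta2)) / n_re
    neg_ll_lim = 0.5 * n_re * (np.log(2.0 * np.pi * sigma2_lim) + 1.0)
    if neg_ll_lim < best_val:
        warnings.warn(
            "REML delta profile optimum beyond the search bound; "
            "returning the zero-genetic-variance boundary fit",
            stacklevel=2,
        )
        return REMLFit(
            sigma_a2=0.0,
            sigma_e2=sigma2_lim,
            delta=np.inf,
            loglik=-neg_ll_lim,
            config=config,
        )
    if best_log_delta in (float(grid[0]), float(grid[-1])):
        warnings.warn(
            f"REML delta profile optimum at search boundary (log delta = {best_log_delta:.2f})",
            stacklevel=2,
        )

    delta = float(np.exp(best_log_delta))
    d = lam + delta
    sigma_a2 = float(np.sum(eta2 / d)) / n_re
    return REMLFit(
        sigma_a2=sigma_a2,
        sigma_e2=delta * sigma_a2,
        delta=delta,
        loglik=-best_val,
        config=config,
    )


def evaluate_candidate_sets(
    matrix: MarkerMatrix,
    sets: list[PseudoQTNSet],
    y: np.ndarray,
    X: np.ndarray,
    mask: np.ndarray,
    n_workers: int = 1,
) -> list[REMLFit | None]:
    """REML-score each nonempty candidate set (None for empty sets).

    Identical index tuples are evaluated once and shared.  Evaluations are
    independent; with ``n_workers > 1`` they run on a thread pool and the
    returned list is ordered exactly as ``sets`` (deterministic).
    """
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    unique: dict[tuple[int, ...], list[int]] = {}
    for i, s in enumerate(sets):
        if len(s) > 0:
            unique.setdefault(tuple(s.indices), []).append(i)
    keys = list(unique.keys())

    def score(indices: tuple[int, ...]) -> REMLFit:
        K = kinship_from_pseudo_qtns(matrix, indices, mask)
        return reml_loglik(y, X, K)

    if n_workers == 1 or len(keys) <= 1:
        fits_by_key = {kk: score(kk) for kk in keys}
    else:
        with ThreadPoolExecutor(max_workers=n_workers) as pool:
            results = list(pool.map(score, keys))
        fits_by_key = dict(zip(keys, results))

    out: list[REMLFit | None] = [None] * len(sets)
    for kk, positions in unique.items():
        base = fits_by_key[kk]
        for i in positions:
            s = sets[i]
            out[i] = REMLFit(
                sigma_a2=base.sigma_a2,
                sigma_e2=base.sigma_e2,
                delta=base.delta,
                loglik=base.loglik,
                config=(s.bin_size, s.qtn_count),
            )
    return out


def select_best_config(
    sets: list[PseudoQTNSet], fits: list[REMLFit | None]
) -> tuple[PseudoQTNSet, REMLFit] | None:
    """Pick the fit with maximal restricted log-likelihood.

    Ties break toward fewer pseudo-QTNs, then smaller bin size.  Returns
    None when every candidate set is empty (no pseudo-QTNs this iteration).
    """
    if len(sets) != len(fits):
        raise ValueError("sets and fits are not aligned")
    scored = [(s, f) for s, f in zip(sets, fits) if f is not None]
    if not scored:
        return None
    return max(scored, key=lambda sf: (sf[1].loglik, -len(sf[0]), -sf[0].bin_size))
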