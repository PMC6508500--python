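"""Iteration loop: scan, select pseudo-QTNs, optimize, rescan.

Iteration 1 scans every marker with the user covariates only.  Each later
iteration converts the previous scan's p-values into candidate pseudo-QTN
sets (one per bin-size / set-size pair), scores each set by REML, and
rescans with the winning set added to the fixed design.  The loop stops
when the selected set stops changing or at ``max_iterations``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import binning, glm, reml
from .binning import BinConfig, PseudoQTNSet
from .store import CovariateMatrix, MarkerInfo, MarkerMatrix, Phenotype

__all__ = ["RunConfig", "IterationRecord", "FarmCPUResult", "run_farmcpu", "write_results"]

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ["marker", "chrom", "pos", "n_used", "effect", "se", "t", "p"]


@dataclass
class RunConfig:
    """Knobs for one run of the iterative scan."""

    max_iterations: int = 20
    bin_sizes: tuple[int, ...] = ()
    qtn_counts: tuple[int, ...] = (10, 20, 30)
    eligibility_threshold: float = 0.01
    r2_max: float = 0.7
    workers_scan: int = 1
    workers_reml: int = 1
    reoptimize_bins: bool = True

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")

    def bin_config(self) -> BinConfig:
        return BinConfig(
            bin_sizes=self.bin_sizes,
            qtn_counts=self.qtn_counts,
            eligibility_threshold=self.eligibility_threshold,
        )


@dataclass
class IterationRecord:
    """Audit line for one loop iteration."""

    iteration: int
    pseudo_qtns: tuple[int, ...]
    bin_size: int | None
    qtn_count: int | None
    loglik: float | None
    sigma_a2: float | None
    sigma_e2: float | None


@dataclass
class FarmCPUResult:
    """Final scan table plus the per-iteration audit trail."""

    scan: glm.ScanResult
    info: MarkerInfo
    history: list[IterationRecord]
    converged: bool
    iterations: int
    pseudo_qtns: tuple[int, ...]

    def to_frame(self) -> pd.DataFrame:
        return self.scan.to_frame(self.info)

    def history_frame(self) -> pd.DataFrame:
        rows = [
            {
                "iteration": r.iteration,
                "n_pseudo_qtns": len(r.pseudo_qtns),
                "bin_size": r.bin_size,
                "qtn_count": r.qtn_count,
                "loglik": r.loglik,
                "sigma_a2": r.sigma_a2,
                "sigma_e2": r.sigma_e2,
                "pseudo_qtns": ",".join(str(self.info.name[j]) for j in r.pseudo_qtns),
            }
            for r in self.history
        ]
        return pd.DataFrame(rows)


def _scan(matrix, fixed, config: RunConfig) -> glm.ScanResult:
    # Substitution keeps pseudo-QTN rows testable, so the next selection
    # round can retain (or drop) them on the strength of their covariate fit.
    raw = glm.scan_parallel(matrix, fixed, n_workers=config.workers_scan)
    return _substitute_pseudo_qtn_rows(raw, fixed)


def _substitute_pseudo_qtn_rows(
    result: glm.ScanResult, fixed: glm.FixedDesign
) -> glm.ScanResult:
    """Report covariate-coefficient tests for markers used as pseudo-QTNs.

    A marker serving as a covariate is collinear with the fixed part, so
    its own scan row is missing; its statistics come from its coefficient
    in the final fixed design instead.
    """
    effect = result.effect.copy()
    se = result.se.copy()
    t = result.t.copy()
    p = result.p.copy()
    n_used = result.n_used.copy()
    offset = fixed.k - len(fixed.pseudo_qtns)
    for pos, j in enumerate(fixed.pseudo_qtns):
        col = offset + pos
        effect[j] = fixed.coef[col]
        se[j] = fixed.coef_se[col]
        t[j] = fixed.coef_t[col]
        p[j] = fixed.coef_p[col]
        n_used[j] = fixed.n_eff
    return glm.ScanResult(effect=effect, se=se, t=t, p=p, n_used=n_used, df=result.df)


def run_farmcpu(
    matrix: MarkerMatrix,
    info: MarkerInfo,
    phenotype: Phenotype | np.ndarray,
    covariates: CovariateMatrix | np.ndarray | None = None,
    config: RunConfig | None = None,
) -> FarmCPUResult:
    """Run the iterative fixed/random-effect scan to convergence."""
    config = config or RunConfig()
    if len(info) != matrix.m:
        raise ValueError("marker info length does not match matrix columns")
    bin_config = config.bin_config()

    current: tuple[int, ...] = ()
    fixed = glm.build_fixed_design(phenotype, covariates, current, matrix)
    result = _scan(matrix, fixed, config)
    history = [
        IterationRecord(1, current, None, None, None, None, None)
    ]
    logger.info("iteration 1: plain scan, n_eff=%d", fixed.n_eff)

    # REML fixed effects: intercept + population-structure covariates only
    if covariates is None:
        X_reml = np.ones((fixed.n_eff, 1))
    elif isinstance(covariates, CovariateMatrix):
        X_reml = np.column_stack(
            [np.ones(fixed.n_eff), covariates.aligned_to(matrix)[fixed.mask]]
        )
    else:
        cov = np.atleast_2d(np.asarray(covariates, dtype=np.float64))
        if cov.shape[0] == matrix.n:
            cov = cov[fixed.mask]
        X_reml = np.column_stack([np.ones(fixed.n_eff), cov])

    converged = False
    iterations = 1
    seen: list[frozenset[int]] = [frozenset(current)]

    for it in range(2, config.max_iterations + 1):
        iterations = it
        sets = binning.select_candidates(result, info, bin_config)
        sets = [
            PseudoQTNSet(
                indices=binning.filter_correlated(
                    matrix, s.indices, fixed.mask, config.r2_max
                ),
                bin_size=s.bin_size,
                qtn_count=s.qtn_count,
            )
            for s in sets
        ]
        fits = reml.evaluate_candidate_sets(
            matrix, sets, fixed.y_masked, X_reml, fixed.mask,
            n_workers=config.workers_reml,
        )
        best = reml.select_best_config(sets, fits)
        if best is None:
            new_set: tuple[int, ...] = ()
            best_fit = None
        else:
            new_set = best[0].indices
            best_fit = best[1]

        record = IterationRecord(
            iteration=it,
            pseudo_qtns=new_set,
            bin_size=best[0].bin_size if best else None,
            qtn_count=best[0].qtn_count if best else None,
            loglik=best_fit.loglik if best_fit else None,
            sigma_a2=best_fit.sigma_a2 if best_fit else None,
            sigma_e2=best_fit.sigma_e2 if best_fit else None,
        )
        history.append(record)
        logger.info(
            "iteration %d: %d pseudo-QTNs (bin=%s count=%s loglik=%s) set=%s",
            it, len(new_set), record.bin_size, record.qtn_count,
            record.loglik, hash(frozenset(new_set)),
        )

        if frozenset(new_set) == frozenset(current):
            converged = True
            break
        if len(seen) >= 2 and frozenset(new_set) == seen[-2]:
            # period-2 oscillation: accept the recurring set and stop
            warnings.warn(
                "pseudo-QTN selection oscillates with period 2; "
                "stopping at the recurring set",
                stacklevel=2,
            )
            converged = True
            current = new_set
            fixed = glm.build_fixed_design(phenotype, covariates, current, matrix)
            result = _scan(matrix, fixed, config)
            break

        current = new_set
        seen.append(frozenset(current))
        fixed = glm.build_fixed_design(phenotype, covariates, current, matrix)
        result = _scan(matrix, fixed, config)

    if not converged and config.max_iterations > 1:
        warnings.warn(
            f"pseudo-QTN set did not converge within {config.max_iterations} iterations",
            stacklevel=2,
        )

    return FarmCPUResult(
        scan=result,
        info=info,
        history=history,
        converged=converged,
        iterations=iterations,
        pseudo_qtns=current,
    )


def write_results(result: FarmCPUResult, outdir: str | Path) -> tuple[Path, Path]:
    """Write ``results.tsv`` and ``history.tsv`` under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results_path = outdir / "results.tsv"
    history_path = outdir / "history.tsv"
    frame = result.to_frame()[RESULT_COLUMNS]
    frame.to_csv(results_path, sep="\t", index=False, na_rep="NA")
    result.history_frame().to_csv(history_path, sep="\t", index=False, na_rep="NA")
    return results_path, history_path
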