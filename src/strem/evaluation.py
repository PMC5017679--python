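"""Performance metrics for the simulation study.

Estimates are compared to truth by the shifted log-ratio
``alpha = log((N_hat + 1) / (N + 1))`` (0 for a perfect estimate), by the
slope beta and R^2 of the regression of log(N_hat + 1) on log(N + 1), by
the coverage of 50% / 95% interval estimates, and by the Spearman rank
correlation between true and predicted abundances on a regular 100-km grid.
Replicate-years whose fit did not converge, produced non-finite densities,
or estimated totals below 1 or above 1000 individuals are flagged as failed
and excluded from metric aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .landscape import StudyDomain

__all__ = [
    "alpha_log_ratio",
    "regression_metrics",
    "interval_coverage",
    "EvaluationGrid",
    "grid_rank_correlation",
    "classify_failure",
    "ReplicateResult",
    "aggregate_results",
]


def alpha_log_ratio(n_hat, n_true):
    """alpha = ln((N_hat + 1) / (N + 1)); antisymmetric in its arguments."""
    n_hat = np.asarray(n_hat, dtype=float)
    n_true = np.asarray(n_true, dtype=float)
    if np.any(n_hat < 0) or np.any(n_true < 0):
        raise ValueError("population sizes must be nonnegative")
    out = np.log((n_hat + 1.0) / (n_true + 1.0))
    return float(out) if out.ndim == 0 else out


def regression_metrics(n_hat, n_true) -> tuple[float, float]:
    """(slope beta, R^2) of OLS on the +1-shifted log scale."""
    x = np.log(np.asarray(n_true, dtype=float) + 1.0)
    y = np.log(np.asarray(n_hat, dtype=float) + 1.0)
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.var(x) == 0:
        raise ValueError("true population sizes have zero variance")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.rvalue ** 2)


def interval_coverage(true_values, intervals) -> float:
    """Fraction of intervals (lo, hi) containing the matching true value."""
    true_values = np.asarray(true_values, dtype=float)
    lo = np.array([iv[0] for iv in intervals], dtype=float)
    hi = np.array([iv[1] for iv in intervals], dtype=float)
    if len(lo) != len(true_values):
        raise ValueError("intervals and true values are misaligned")
    if np.any(lo > hi):
        raise ValueError("malformed interval with lo > hi")
    return float(np.mean((lo <= true_values) & (true_values <= hi)))


@dataclass(frozen=True)
class EvaluationGrid:
    """Regular cell grid over the domain bounding box (100-km cells)."""

    x0: float
    y0: float
    nx: int
    ny: int
    cell_km: float = 100.0

    @classmethod
    def for_domain(cls, domain: StudyDomain, cell_km: float = 100.0
                   ) -> "EvaluationGrid":
        x0, y0, x1, y1 = domain.bounds
        return cls(x0=x0, y0=y0, cell_km=cell_km,
                   nx=int(np.ceil((x1 - x0) / cell_km)),
                   ny=int(np.ceil((y1 - y0) / cell_km)))

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    @property
    def centers(self) -> np.ndarray:
        xs = self.x0 + (np.arange(self.nx) + 0.5) * self.cell_km
        ys = self.y0 + (np.arange(self.ny) + 0.5) * self.cell_km
        X, Y = np.meshgrid(xs, ys)
        return np.column_stack([X.ravel(), Y.ravel()])

    def cell_of(self, points: np.ndarray) -> np.ndarray:
        """Flat cell index of each point (clipped to the grid)."""
        points = np.atleast_2d(points)
        ix = np.clip(((points[:, 0] - self.x0) // self.cell_km).astype(int),
                     0, self.nx - 1)
        iy = np.clip(((points[:, 1] - self.y0) // self.cell_km).astype(int),
                     0, self.ny - 1)
        return iy * self.nx + ix

    def true_cell_counts(self, locations: np.ndarray,
                         group_sizes=None) -> np.ndarray:
        """Individuals per cell from a snapshot of agent locations."""
        idx = self.cell_of(locations)
        w = (np.asarray(group_sizes, dtype=float) if group_sizes is not None
             else np.ones(len(idx)))
        return np.bincount(idx, weights=w, minlength=self.n_cells)


def grid_rank_correlation(true_counts: np.ndarray,
                          predicted: np.ndarray) -> float:
    """Spearman rank correlation of per-cell true vs predicted abundances.

    Ties are mid-ranked; all-constant vectors make the correlation
    undefined and return NaN (flagged rather than raised).
    """
    true_counts = np.asarray(true_counts, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if len(true_counts) != len(predicted):
        raise ValueError("grids are misaligned")
    if np.all(true_counts == true_counts[0]) or np.all(predicted == predicted[0]):
        return float("nan")
    rho, _ = stats.spearmanr(true_counts, predicted)
    return float(rho)


def classify_failure(n_hat: float, diagnostics_failed: bool = False,
                     lo: float = 1.0, hi: float = 1000.0) -> bool:
    """Failed = non-convergence, non-finite, or a total outside [lo, hi]."""
    if diagnostics_failed:
        return True
    if not np.isfinite(n_hat):
        return True
    return bool(n_hat < lo or n_hat > hi)


@dataclass
class ReplicateResult:
    """Per-year estimates of one method on one simulation replicate."""

    method: str                   # FMP | ST | T1 | T2
    replicate: int
    years: np.ndarray
    n_true: np.ndarray
    n_hat: np.ndarray
    intervals_95: list = field(default_factory=list)
    intervals_50: list = field(default_factory=list)
    failed: np.ndarray | None = None
    spatial_rho: np.ndarray | None = None   # per-year grid rank correlation

    def __post_init__(self) -> None:
        if self.failed is None:
            self.failed = np.array([classify_failure(n) for n in self.n_hat])

    @property
    def alpha(self) -> np.ndarray:
        return alpha_log_ratio(self.n_hat, self.n_true)


def aggregate_results(results: list[ReplicateResult]) -> pd.DataFrame:
    """Summary table per method, mirroring the simulation-study diagnostics.

    Columns: mean alpha and its SE, 95% quantiles of alpha, regression slope
    beta and R^2 (over non-failed replicate-years pooled), 50%/95% interval
    coverage, failed fraction, and the median spatial rank correlation.
    """
    rows = []
    for method in sorted({r.method for r in results}):
        sub = [r for r in results if r.method == method]
        ok_alpha, ok_true, ok_hat = [], [], []
        cov95, cov50 = [], []
        rhos = []
        n_total = n_failed = 0
        for r in sub:
            ok = ~r.failed
            n_total += len(r.failed)
            n_failed += int(r.failed.sum())
            ok_alpha.append(r.alpha[ok])
            ok_true.append(r.n_true[ok])
            ok_hat.append(r.n_hat[ok])
            if r.intervals_95:
                cov95.extend((iv, t) for iv, t, o in
                             zip(r.intervals_95, r.n_true, ok) if o)
            if r.intervals_50:
                cov50.extend((iv, t) for iv, t, o in
                             zip(r.intervals_50, r.n_true, ok) if o)
            if r.spatial_rho is not None:
                rhos.extend(r.spatial_rho[ok][np.isfinite(r.spatial_rho[ok])])
        alpha = np.concatenate(ok_alpha) if ok_alpha else np.array([])
        row = {"method": method,
               "n_estimates": n_total,
               "failed_fraction": n_failed / n_total if n_total else np.nan}
        if alpha.size:
            row["alpha_mean"] = float(alpha.mean())
            row["alpha_se"] = float(alpha.std(ddof=1) / np.sqrt(len(alpha))) \
                if len(alpha) > 1 else np.nan
            row["alpha_sd"] = float(alpha.std(ddof=1)) if len(alpha) > 1 else np.nan
            row["alpha_q025"] = float(np.quantile(alpha, 0.025))
            row["alpha_q975"] = float(np.quantile(alpha, 0.975))
        truth = np.concatenate(ok_true) if ok_true else np.array([])
        hat = np.concatenate(ok_hat) if ok_hat else np.array([])
        if len(truth) >= 3 and np.var(np.log(truth + 1)) > 0:
            beta, r2 = regression_metrics(hat, truth)
            row["beta"] = beta
            row["r2"] = r2
        if cov95:
            row["coverage_95"] = interval_coverage([t for _, t in cov95],
                                                   [iv for iv, _ in cov95])
        if cov50:
            row["coverage_50"] = interval_coverage([t for _, t in cov50],
                                                   [iv for iv, _ in cov50])
        if rhos:
            row["spatial_rho_median"] = float(np.median(rhos))
        rows.append(row)
    return pd.DataFrame(rows)
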