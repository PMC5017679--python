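"""The Formozov-Malyshev-Pereleshin track-count density estimator.

Under the ideal-gas encounter law E[X] = (2/pi) a E[L] sum_i M_i D_i, the
mean density on the reference habitat is estimated by

    a_hat = (pi / 2) * sum_i X_i / (E[L] * sum_i M_i D_i),

and the total population over the domain is N = a_hat * sum_c h_c A_c
(habitat-weighted area).  Confidence intervals are BCa bootstrap percentile
intervals over transect-year records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .landscape import HabitatRaster, StudyDomain

__all__ = [
    "FmpEstimate",
    "fmp_density",
    "fmp_total",
    "habitat_weighted_area",
    "bootstrap_interval",
    "fmp_estimate",
]


def fmp_density(counts, effort_md, el_km_per_day: float) -> float:
    """FMP density (individuals/km^2 on the reference habitat).

    ``counts`` are the per-record crossing counts X_i and ``effort_md`` the
    matching effective efforts M_i * D_i (km day).  The estimator depends on
    the data only through the two totals.
    """
    counts = np.asarray(counts, dtype=float)
    md = np.asarray(effort_md, dtype=float)
    if el_km_per_day <= 0:
        raise ValueError("E[L] must be positive")
    tot_md = md.sum()
    if tot_md <= 0:
        raise ValueError("total survey effort must be positive")
    return float((np.pi / 2.0) * counts.sum() / (el_km_per_day * tot_md))


def habitat_weighted_area(raster: HabitatRaster, weights: dict,
                          domain: StudyDomain) -> float:
    """sum_c h_c A_c over the domain (km^2 of forest-equivalent habitat)."""
    areas = raster.class_areas(domain)
    h = np.array([float(weights[lab]) for lab in raster.class_labels])
    return float(areas @ h)


def fmp_total(a: float, weighted_area_km2: float) -> float:
    """Total population N = a * habitat-weighted area (h = 1 gives a*|Omega|)."""
    if a < 0:
        raise ValueError("density must be nonnegative")
    return float(a * weighted_area_km2)


def bootstrap_interval(counts, effort_md, el_km_per_day: float,
                       weighted_area_km2: float, rng: np.random.Generator,
                       levels=(0.95, 0.50), n_boot: int = 1000) -> dict:
    """BCa bootstrap intervals of the total population size.

    Transect-year records (the survey's independent sampling units) are
    resampled with replacement.  Degenerate data (all records identical)
    fall back to a plain percentile interval and are flagged.
    """
    counts = np.asarray(counts, dtype=float)
    md = np.asarray(effort_md, dtype=float)
    if len(counts) < 2:
        raise ValueError("need at least 2 records to bootstrap")

    def statistic(x, m, axis=-1):
        tot_m = np.sum(m, axis=axis)
        return np.pi / 2.0 * np.sum(x, axis=axis) / (el_km_per_day * tot_m) \
            * weighted_area_km2

    point = statistic(counts, md)
    out = {"intervals": {}, "method": "BCa", "point": float(point)}
    degenerate = (np.all(counts == counts[0]) and np.all(md == md[0])) \
        or counts.sum() == 0  # statistic is constant under resampling
    for level in sorted(levels, reverse=True):
        if degenerate:
            out["intervals"][level] = (float(point), float(point))
            out["method"] = "degenerate"
            continue
        try:
            res = stats.bootstrap((counts, md), statistic, paired=True,
                                  vectorized=True, axis=-1,
                                  confidence_level=level,
                                  n_resamples=n_boot, method="BCa",
                                  rng=rng)
            ci = (float(res.confidence_interval.low),
                  float(res.confidence_interval.high))
        except Exception:
            res = stats.bootstrap((counts, md), statistic, paired=True,
                                  vectorized=True, axis=-1,
                                  confidence_level=level,
                                  n_resamples=n_boot, method="percentile",
                                  rng=rng)
            ci = (float(res.confidence_interval.low),
                  float(res.confidence_interval.high))
            out["method"] = "percentile"
        lo = min(ci[0], float(point))
        hi = max(ci[1], float(point))
        out["intervals"][level] = (lo, hi)
    # enforce nesting 50% within 95%
    if 0.95 in out["intervals"] and 0.5 in out["intervals"]:
        lo95, hi95 = out["intervals"][0.95]
        lo50, hi50 = out["intervals"][0.5]
        out["intervals"][0.5] = (max(lo50, lo95), min(hi50, hi95))
    return out


@dataclass
class FmpEstimate:
    """Point estimate and bootstrap intervals for one survey year."""

    density: float                    # individuals/km^2 on reference habitat
    total: float                      # individuals over the domain
    intervals: dict = field(default_factory=dict)   # level -> (lo, hi) on N
    n_records: int = 0
    el_km_per_day: float = float("nan")
    total_count: float = float("nan")
    total_effort_md: float = float("nan")
    interval_method: str = "none"


def fmp_estimate(counts, effort_md, el_km_per_day: float,
                 weighted_area_km2: float,
                 rng: np.random.Generator | None = None,
                 levels=(0.95, 0.50), n_boot: int = 1000) -> FmpEstimate:
    """FMP density and total with optional bootstrap intervals."""
    counts = np.asarray(counts, dtype=float)
    md = np.asarray(effort_md, dtype=float)
    a = fmp_density(counts, md, el_km_per_day)
    total = fmp_total(a, weighted_area_km2)
    est = FmpEstimate(density=a, total=total, n_records=len(counts),
                      el_km_per_day=el_km_per_day,
                      total_count=float(counts.sum()),
                      total_effort_md=float(md.sum()))
    if rng is not None and len(counts) >= 2:
        boot = bootstrap_interval(counts, md, el_km_per_day,
                                  weighted_area_km2, rng, levels, n_boot)
        est.intervals = boot["intervals"]
        est.interval_method = boot["method"]
    return est
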