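"""Habitat-weighted numerical integration of density fields.

The expected number of individuals in a region is the integral of
``rho(s, t) = a(s, t) h(s)``; posterior draws of ``a`` on a regular grid are
converted to draws of N by a Riemann sum with fractional boundary cells
weighted by their in-region area fraction.  Credible intervals are
equal-tailed posterior quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .landscape import HabitatRaster, StudyDomain

__all__ = [
    "IntegrationGrid",
    "integration_grid",
    "integrate_population",
    "credible_interval",
    "PopulationEstimate",
    "totals_from_temporal_fit",
    "totals_from_st_fit",
]


@dataclass
class IntegrationGrid:
    """Regular grid over the domain with in-domain area fractions."""

    centers: np.ndarray     # (m, 2) cell centres, km
    fractions: np.ndarray   # (m,) in-domain area fraction per cell
    cell_km: float

    @property
    def cell_area(self) -> float:
        return self.cell_km ** 2

    @property
    def area(self) -> float:
        return float(self.fractions.sum() * self.cell_area)


def integration_grid(domain: StudyDomain, cell_km: float = 5.0,
                     subsample: int = 10) -> IntegrationGrid:
    """Build a grid covering the domain's bounding box.

    Boundary cells get fractional weight from a subsample x subsample
    point-in-polygon count; fully exterior cells are dropped.
    """
    x0, y0, x1, y1 = domain.bounds
    xs = np.arange(x0 + cell_km / 2, x1 + cell_km / 2, cell_km)
    ys = np.arange(y0 + cell_km / 2, y1 + cell_km / 2, cell_km)
    X, Y = np.meshgrid(xs, ys)
    centers = np.column_stack([X.ravel(), Y.ravel()])
    off = (np.arange(subsample) + 0.5) / subsample - 0.5
    OX, OY = np.meshgrid(off, off)
    sub = np.column_stack([OX.ravel(), OY.ravel()]) * cell_km
    pts = centers[:, None, :] + sub[None, :, :]
    flat = pts.reshape(-1, 2)
    inside = domain.contains(flat[:, 0], flat[:, 1])
    frac = inside.reshape(len(centers), -1).mean(axis=1)
    keep = frac > 0
    return IntegrationGrid(centers=centers[keep], fractions=frac[keep],
                           cell_km=cell_km)


def integrate_population(a_draws: np.ndarray, h: np.ndarray,
                         fractions: np.ndarray, cell_area: float
                         ) -> np.ndarray:
    """Riemann-sum posterior draws of N over a region.

    ``a_draws`` has shape (n_draws, m); ``h`` and ``fractions`` are per-cell
    habitat weights and in-region area fractions.
    """
    a_draws = np.atleast_2d(np.asarray(a_draws, dtype=float))
    weights = np.asarray(h, dtype=float) * np.asarray(fractions, dtype=float) \
        * cell_area
    if a_draws.shape[1] != len(weights):
        raise ValueError("density draws do not match the integration grid")
    return a_draws @ weights


def credible_interval(draws, level: float) -> tuple[float, float]:
    """Equal-tailed posterior quantile interval."""
    draws = np.asarray(draws, dtype=float)
    if draws.size < 100:
        raise ValueError("need at least 100 draws for a credible interval")
    alpha = (1.0 - level) / 2.0
    return (float(np.quantile(draws, alpha)),
            float(np.quantile(draws, 1.0 - alpha)))


@dataclass
class PopulationEstimate:
    """Posterior summary of N(region, year)."""

    year: int
    median: float
    intervals: dict = field(default_factory=dict)  # level -> (lo, hi)
    draws: np.ndarray | None = None
    region: str = "domain"

    @classmethod
    def from_draws(cls, year: int, draws: np.ndarray,
                   levels=(0.95, 0.50), keep_draws: bool = True,
                   region: str = "domain") -> "PopulationEstimate":
        ivs = {lv: credible_interval(draws, lv) for lv in levels}
        return cls(year=int(year), median=float(np.median(draws)),
                   intervals=ivs, draws=draws if keep_draws else None,
                   region=region)


def cell_weighted_areas(raster: HabitatRaster, weights: dict,
                        grid: IntegrationGrid) -> np.ndarray:
    """Per-cell habitat-weighted in-domain area: h(center) * frac * cell_area."""
    h_map = np.array([float(weights[lab]) for lab in raster.class_labels])
    codes = raster.habitat_at_or_zero(grid.centers[:, 0], grid.centers[:, 1])
    h = np.where(codes > 0, h_map[np.maximum(codes, 1) - 1], 0.0)
    return h * grid.fractions * grid.cell_area


def totals_from_temporal_fit(fit, weighted_area_km2: float,
                             levels=(0.95, 0.50)) -> list[PopulationEstimate]:
    """Per-year posterior totals from a temporal fit: N_t = a_t * weighted area."""
    a = fit.density_draws()  # (n_draws, T)
    return [PopulationEstimate.from_draws(y, a[:, t] * weighted_area_km2, levels)
            for t, y in enumerate(fit.years)]


def totals_from_st_fit(fit, site_weighted_areas: np.ndarray,
                       levels=(0.95, 0.50)) -> list[PopulationEstimate]:
    """Per-year totals from a spatio-temporal fit whose sites tile the domain.

    ``site_weighted_areas[s]`` is the habitat-weighted in-domain area (km^2)
    represented by site s, so N_t = sum_s a_ts * area_s per draw.
    """
    a = fit.density_draws()  # (n_draws, T, S)
    n = a @ np.asarray(site_weighted_areas, dtype=float)
    return [PopulationEstimate.from_draws(y, n[:, t], levels)
            for t, y in enumerate(fit.years)]
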