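"""Configuration-driven replication harness: simulator -> estimators -> metrics.

One replicate generates a multi-year winter-track-count data set under a
movement scenario, estimates yearly population totals with the FMP
estimator and the Bayesian temporal (T1/T2 priors) and spatio-temporal (ST)
smoothing models, and scores them against the simulated truth.

A ``scale`` factor shrinks the domain area, transect network, survey sample
and population together, so reduced-scale runs preserve the full design's
density and per-transect encounter rates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from . import abundance, fmp, smoothing, survey, telemetry
from .evaluation import (EvaluationGrid, ReplicateResult, aggregate_results,
                         classify_failure, grid_rank_correlation)
from .landscape import (DEFAULT_DOMAIN_KM, HabitatRaster, StudyDomain,
                        generate_synthetic_landscape, uniform_raster)
from .movement import (DemographyConfig, MovementConfig, ScenarioSpec,
                       birth_death_update, init_population,
                       sample_growth_rate, simulate_season)

__all__ = ["ExperimentConfig", "ReplicateData", "run_replicate",
           "estimate_replicate", "run_experiment"]


@dataclass(frozen=True)
class ExperimentConfig:
    """Design of one simulation experiment (defaults = the full WTC design)."""

    scenario: str = "A"
    years: int = 20
    network_size: int = 1610
    surveyed_per_year: int = 500
    collars_per_year: int = 10
    replicates: int = 1
    seed: int = 0
    scale: float = 1.0
    methods: tuple = ("FMP", "T1", "T2")
    season_days: int = 60
    n_boot: int = 1000
    st_cell_km: float = 100.0          # ST aggregation cell (scaled by sqrt(scale))
    landscape_cell_km: float = 0.25
    clustering_scale_km: float = 1.0
    class_proportions: tuple = (0.03, 0.07, 0.70, 0.10, 0.10)
    domain_width_km: float = DEFAULT_DOMAIN_KM[0]
    domain_height_km: float = DEFAULT_DOMAIN_KM[1]
    effort_sample_step_km: float = 0.025
    fit_steps: int = 400
    fit_burn: int = 200
    fit_draws: int = 300
    st_fit_steps: int = 200
    st_fit_burn: int = 100
    st_fit_draws: int = 150

    def __post_init__(self) -> None:
        if not (0 < self.scale <= 1):
            raise ValueError("scale must be in (0, 1]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    # ----------------------------------------------------------- scaled design
    @property
    def lin(self) -> float:
        """Linear shrink factor (areas scale with ``scale``)."""
        return float(np.sqrt(self.scale))

    @property
    def width_km(self) -> float:
        return self.domain_width_km * self.lin

    @property
    def height_km(self) -> float:
        return self.domain_height_km * self.lin

    @property
    def scaled_network(self) -> int:
        return max(int(round(self.network_size * self.scale)), 1)

    @property
    def scaled_surveyed(self) -> int:
        return min(max(int(round(self.surveyed_per_year * self.scale)), 1),
                   self.scaled_network)

    @property
    def scaled_initial_n(self) -> int:
        base = ScenarioSpec.from_code(self.scenario).initial_n
        return max(int(round(base * self.scale)), 1)

    @property
    def scaled_st_cell(self) -> float:
        return self.st_cell_km * self.lin

    # ------------------------------------------------------------------- I/O
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("methods", "class_proportions"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class ReplicateData:
    """All artifacts generated by one simulation replicate."""

    replicate: int
    domain: StudyDomain
    raster: HabitatRaster
    counts: pd.DataFrame           # transect-year records with M and offset
    truth: pd.DataFrame            # year, n_true
    day30: list                    # per year: (locations, group_sizes)
    bursts: list
    el_hat: float
    weight_map: telemetry.HabitatWeightMap | None
    weights_used: dict             # label -> h applied in effort and areas


def _build_landscape(cfg: ExperimentConfig, spec: ScenarioSpec,
                     rng: np.random.Generator):
    domain = StudyDomain.rectangle(cfg.width_km, cfg.height_km)
    extent = (0.0, 0.0, cfg.width_km, cfg.height_km)
    if spec.habitat_selective:
        raster = generate_synthetic_landscape(
            extent, cfg.landscape_cell_km, cfg.class_proportions,
            cfg.clustering_scale_km, rng)
    else:
        raster = uniform_raster(extent, cell_size=5.0)
    return domain, raster


def run_replicate(cfg: ExperimentConfig, replicate: int) -> ReplicateData:
    """Simulate one replicate data set (deterministic given seed + index)."""
    rng = np.random.default_rng(cfg.seed + replicate)
    spec = ScenarioSpec.from_code(cfg.scenario, initial_n=cfg.scaled_initial_n)
    mv = MovementConfig()
    demo = DemographyConfig()
    domain, raster = _build_landscape(cfg, spec, rng)
    constrained = spec.habitat_selective
    network = survey.generate_transect_network(
        cfg.scaled_network, domain, raster, rng,
        min_reference_fraction=0.9 if constrained else 0.0,
        sample_step=cfg.effort_sample_step_km)
    pop = init_population(spec, domain, raster, mv, rng)

    rows, class_lengths = [], []
    truth_rows, day30, bursts = [], [], []
    for year in range(1, cfg.years + 1):
        if year > 1:
            mu = sample_growth_rate(demo, rng)
            pop = birth_death_update(pop, mu, spec, mv, rng)
        truth_rows.append({"year": year, "n_true": pop.total_individuals,
                           "n_agents": pop.n})
        traj = simulate_season(pop, spec, domain, raster, mv, rng,
                               days=cfg.season_days)
        day30.append((traj.locations_at_day(30.0), traj.group_sizes.copy()))
        surveyed = survey.sample_survey_year(
            network, cfg.scaled_surveyed, rng, season_days=cfg.season_days,
            redraw_rotation=not constrained)
        for tr in surveyed:
            lens = survey.perimeter_lengths_by_class(
                tr, raster, domain, cfg.effort_sample_step_km)
            x = survey.count_crossings(traj, tr, mv.steps_per_day)
            rows.append({"transect_id": tr.id, "year": year, "count": x,
                         "counting_day": tr.counting_day,
                         "x_km": tr.center[0], "y_km": tr.center[1],
                         "D_days": tr.accumulation_days})
            class_lengths.append(lens)
        if pop.n > 0:
            for a in telemetry.collar_individuals(pop.n, cfg.collars_per_year,
                                                  rng):
                bursts.append(telemetry.GpsBurst.from_trajectory(traj, int(a)))

    el_hat = telemetry.estimate_daily_distance(bursts, mv.steps_per_day)
    if spec.habitat_selective:
        weight_map = telemetry.estimate_habitat_weights(bursts, raster,
                                                        domain, rng)
        weights_used = {lab: (float(h) if np.isfinite(h) else 0.0)
                        for lab, h in zip(raster.class_labels, weight_map.h)}
    else:
        weight_map = None
        weights_used = {lab: 1.0 for lab in raster.class_labels}

    counts = pd.DataFrame(rows)
    lens = np.asarray(class_lengths)
    h = np.array([weights_used[lab] for lab in raster.class_labels])
    counts["M_km_weighted"] = lens @ h
    counts["offset"] = survey.survey_offset(counts["M_km_weighted"].to_numpy(),
                                            el_hat,
                                            counts["D_days"].to_numpy())
    counts = counts[counts["M_km_weighted"] > 0].reset_index(drop=True)
    return ReplicateData(replicate=replicate, domain=domain, raster=raster,
                         counts=counts, truth=pd.DataFrame(truth_rows),
                         day30=day30, bursts=bursts, el_hat=el_hat,
                         weight_map=weight_map, weights_used=weights_used)


# --------------------------------------------------------------------------
# Estimation on one replicate
# --------------------------------------------------------------------------

def _yearly_totals(counts: pd.DataFrame, years: np.ndarray, el: float):
    x = np.zeros(len(years))
    e = np.zeros(len(years))
    by_year = counts.groupby("year")
    sums = by_year[["count"]].sum()
    md = (counts["M_km_weighted"] * counts["D_days"]).groupby(counts["year"]).sum()
    for i, y in enumerate(years):
        if y in sums.index:
            x[i] = sums.loc[y, "count"]
            e[i] = survey.survey_offset(float(md.loc[y]), el)
    return x, e


def _st_aggregate(counts: pd.DataFrame, egrid: EvaluationGrid, el: float):
    """Aggregate records to grid-cell-years: summed counts and efforts."""
    pts = counts[["x_km", "y_km"]].to_numpy()
    cell = egrid.cell_of(pts)
    md = counts["M_km_weighted"].to_numpy() * counts["D_days"].to_numpy()
    df = pd.DataFrame({"cell": cell, "year": counts["year"].to_numpy(),
                       "count": counts["count"].to_numpy(), "md": md})
    agg = df.groupby(["cell", "year"], as_index=False).sum()
    agg = agg[agg["md"] > 0]
    agg["offset"] = survey.survey_offset(agg["md"].to_numpy(), el)
    return agg


def _cell_weighted_areas(raster: HabitatRaster, domain: StudyDomain,
                         weights: dict, egrid: EvaluationGrid) -> np.ndarray:
    X, Y = raster.cell_centers()
    pts = np.column_stack([X.ravel(), Y.ravel()])
    inside = domain.contains(pts[:, 0], pts[:, 1])
    h_map = np.array([float(weights[lab]) for lab in raster.class_labels])
    hvals = h_map[raster.classes.ravel() - 1] * raster.cell_size ** 2
    idx = egrid.cell_of(pts[inside])
    return np.bincount(idx, weights=hvals[inside], minlength=egrid.n_cells)


def estimate_replicate(data: ReplicateData, cfg: ExperimentConfig
                       ) -> list[ReplicateResult]:
    """Run the configured estimators on one replicate's data."""
    rng = np.random.default_rng([cfg.seed + data.replicate, 1])
    years = data.truth["year"].to_numpy()
    n_true = data.truth["n_true"].to_numpy(dtype=float)
    w_area = fmp.habitat_weighted_area(data.raster, data.weights_used,
                                       data.domain)
    results = []

    if "FMP" in cfg.methods:
        n_hat = np.full(len(years), np.nan)
        iv95, iv50 = [], []
        for i, y in enumerate(years):
            sub = data.counts[data.counts["year"] == y]
            if len(sub) == 0:
                iv95.append((np.nan, np.nan))
                iv50.append((np.nan, np.nan))
                continue
            md = (sub["M_km_weighted"] * sub["D_days"]).to_numpy()
            est = fmp.fmp_estimate(sub["count"].to_numpy(), md, data.el_hat,
                                   w_area, rng=rng, n_boot=cfg.n_boot)
            n_hat[i] = est.total
            iv95.append(est.intervals.get(0.95, (np.nan, np.nan)))
            iv50.append(est.intervals.get(0.5, (np.nan, np.nan)))
        results.append(ReplicateResult(
            method="FMP", replicate=data.replicate, years=years,
            n_true=n_true, n_hat=n_hat, intervals_95=iv95, intervals_50=iv50))

    temporal_priors = {"T1": "default", "T2": "relaxed"}
    for label, prior in temporal_priors.items():
        if label not in cfg.methods or len(years) < 3:
            continue
        x, e = _yearly_totals(data.counts, years, data.el_hat)
        ok = e > 0
        if ok.sum() < 3:
            continue
        fit = smoothing.fit_temporal(x[ok], e[ok], prior=prior, rng=rng,
                                     years=years[ok],
                                     n_walkers=12, n_steps=cfg.fit_steps,
                                     n_burn=cfg.fit_burn,
                                     n_draws=cfg.fit_draws)
        ests = abundance.totals_from_temporal_fit(fit, w_area)
        n_hat = np.full(len(years), np.nan)
        iv95 = [(np.nan, np.nan)] * len(years)
        iv50 = [(np.nan, np.nan)] * len(years)
        failed = np.ones(len(years), dtype=bool)
        pos = {y: i for i, y in enumerate(years)}
        for est in ests:
            i = pos[est.year]
            n_hat[i] = est.median
            iv95[i] = est.intervals[0.95]
            iv50[i] = est.intervals[0.5]
            failed[i] = classify_failure(est.median, fit.failed)
        results.append(ReplicateResult(
            method=label, replicate=data.replicate, years=years,
            n_true=n_true, n_hat=n_hat, intervals_95=iv95, intervals_50=iv50,
            failed=failed))

    if "ST" in cfg.methods and len(years) >= 2:
        egrid = EvaluationGrid.for_domain(data.domain, cfg.scaled_st_cell)
        agg = _st_aggregate(data.counts, egrid, data.el_hat)
        areas = _cell_weighted_areas(data.raster, data.domain,
                                     data.weights_used, egrid)
        sites = egrid.centers
        year_pos = {y: i for i, y in enumerate(years)}
        fit = smoothing.fit_spatiotemporal(
            agg["count"].to_numpy(), agg["offset"].to_numpy(),
            agg["cell"].to_numpy(),
            np.array([year_pos[y] for y in agg["year"]]),
            sites, n_years=len(years), prior="default", rng=rng, years=years,
            n_walkers=12, n_steps=cfg.st_fit_steps, n_burn=cfg.st_fit_burn,
            n_draws=cfg.st_fit_draws)
        ests = abundance.totals_from_st_fit(fit, areas)
        a = fit.density_draws()                       # (draws, T, S)
        pred_cells = np.median(a, axis=0) * areas      # (T, S)
        n_hat = np.array([e.median for e in ests])
        failed = np.array([classify_failure(e.median, fit.failed)
                           for e in ests])
        rho = np.array([grid_rank_correlation(
            egrid.true_cell_counts(locs, gs), pred_cells[t])
            for t, (locs, gs) in enumerate(data.day30)])
        results.append(ReplicateResult(
            method="ST", replicate=data.replicate, years=years,
            n_true=n_true, n_hat=n_hat,
            intervals_95=[e.intervals[0.95] for e in ests],
            intervals_50=[e.intervals[0.5] for e in ests],
            failed=failed, spatial_rho=rho))
    return results


def run_experiment(cfg: ExperimentConfig, out_dir=None):
    """Run all replicates and aggregate the evaluation report.

    Returns ``(report, results)``; with ``out_dir`` the counts, truth,
    per-replicate metrics and the report are written as CSV/YAML.
    """
    all_results: list[ReplicateResult] = []
    all_counts, all_truth = [], []
    weights_dump = {}
    for r in range(cfg.replicates):
        data = run_replicate(cfg, r)
        all_results.extend(estimate_replicate(data, cfg))
        c = data.counts.copy()
        c.insert(0, "replicate", r)
        all_counts.append(c)
        t = data.truth.copy()
        t.insert(0, "replicate", r)
        all_truth.append(t)
        weights_dump[f"replicate_{r}"] = data.weights_used
    report = aggregate_results(all_results)
    if out_dir is not None:
        import pathlib
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.concat(all_counts).to_csv(out / "counts.csv", index=False)
        pd.concat(all_truth).to_csv(out / "truth.csv", index=False)
        report.to_csv(out / "report.csv", index=False)
        cfg.to_yaml(out / "experiment.yaml")
        with open(out / "weights.yaml", "w") as fh:
            yaml.safe_dump(weights_dump, fh)
    return report, all_results
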