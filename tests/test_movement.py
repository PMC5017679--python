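import numpy as np
import pytest

from strem.landscape import StudyDomain, generate_synthetic_landscape, uniform_raster
from strem.movement import (DemographyConfig, MovementConfig, Population,
                            ScenarioSpec, apply_territorial_bias,
                            birth_death_update, daily_path_lengths,
                            draw_crw_step, enforce_boundary,
                            habitat_weighted_step, init_population,
                            sample_growth_rate, simulate_season)

CFG = MovementConfig()


class TestCrwStep:
    def test_turning_angle_resultant_length(self, rng):
        _, heads, _ = draw_crw_step(np.zeros((1, 2)), np.zeros(1), CFG, rng,
                                    size=100_000)
        turns = heads.ravel()
        rho = np.abs(np.mean(np.exp(1j * turns)))
        assert rho == pytest.approx(0.70, abs=0.01)

    def test_mean_step_length(self, rng):
        from math import gamma
        _, _, lens = draw_crw_step(np.zeros((1, 2)), np.zeros(1), CFG, rng,
                                   size=100_000)
        expected = 2.0 * gamma(1.5)  # Weibull(2, 2) mean ~ 1.772 km
        assert lens.mean() == pytest.approx(expected, abs=0.01)

    def test_near_unit_correlation_keeps_heading(self, rng):
        cfg = MovementConfig(turn_correlation=1 - 1e-12)
        _, heads, _ = draw_crw_step(np.zeros((1, 2)), np.full(1, 0.4), cfg,
                                    rng, size=1000)
        assert np.max(np.abs(heads - 0.4)) < 1e-4


class TestTerritorialBias:
    def test_within_radius_unchanged(self, rng):
        loc = np.array([[5.0, 0.0]])   # 5 km from centre, radius is 10
        prop = np.array([1.2])
        out = apply_territorial_bias(loc, prop, np.zeros((1, 2)),
                                     np.array([True]), CFG, rng)
        assert out[0] == 1.2

    def test_zero_bias_weight_identity(self, rng):
        cfg = MovementConfig(bias_weight=0.0)
        loc = np.array([[50.0, 0.0]])
        prop = np.array([0.3])
        out = apply_territorial_bias(loc, prop, np.zeros((1, 2)),
                                     np.array([True]), cfg, rng)
        assert out[0] == 0.3

    def test_replacement_fraction_and_bearing(self, rng):
        n = 10_000
        loc = np.tile([50.0, 0.0], (n, 1))   # 50 km due east of centre
        prop = rng.uniform(-1, 1, size=n)    # proposals never exactly pi
        out = apply_territorial_bias(loc, prop, np.zeros((n, 2)),
                                     np.ones(n, dtype=bool), CFG, rng)
        replaced = out == np.pi              # bearing home is exactly pi
        assert replaced.mean() == pytest.approx(0.30, abs=0.02)
        assert np.array_equal(out[~replaced], prop[~replaced])


class TestGrowthAndDemography:
    def test_growth_rate_distribution(self, rng):
        draws = np.array([sample_growth_rate(DemographyConfig(), rng)
                          for _ in range(100_000)])
        assert np.median(draws) == pytest.approx(1.0, abs=0.01)
        assert draws.mean() == pytest.approx(np.exp(0.005), abs=0.01)
        lo, hi = np.quantile(draws, [0.025, 0.975])
        assert round(lo, 2) == pytest.approx(0.82, abs=0.01)
        assert round(hi, 2) == pytest.approx(1.22, abs=0.01)

    def test_mu_zero_extinction(self, rng):
        spec = ScenarioSpec.from_code("A", initial_n=50)
        pop = _uniform_pop(50, rng)
        out = birth_death_update(pop, 0.0, spec, CFG, rng)
        assert out.n == 0

    def test_mean_successors(self, rng):
        spec = ScenarioSpec.from_code("A", initial_n=200)
        totals = []
        for _ in range(1000):
            pop = _uniform_pop(200, rng)
            totals.append(birth_death_update(pop, 1.0, spec, CFG, rng).n)
        assert np.mean(totals) == pytest.approx(200.0, abs=1.5)

    def test_new_group_sizes_independent_of_parent(self, rng):
        # sizes of freshly produced groups (reproduction events) carry no
        # information about the parent group's size
        spec = ScenarioSpec.from_code("C")
        parent_sizes, new_sizes = [], []
        while len(new_sizes) < 1000:
            size = int(1 + rng.poisson(4))
            single = Population(locations=np.zeros((1, 2)),
                                headings=np.zeros(1),
                                group_sizes=np.array([size], dtype=np.int64),
                                territorial=np.zeros(1, dtype=bool),
                                territory_centers=np.zeros((1, 2)))
            res = birth_death_update(single, 2.0, spec, CFG, rng)
            for s in res.group_sizes[1:]:   # freshly produced groups
                parent_sizes.append(size)
                new_sizes.append(int(s))
        r = np.corrcoef(parent_sizes[:1000], new_sizes[:1000])[0, 1]
        assert abs(r) < 0.1

    def test_surviving_group_keeps_size(self, rng):
        spec = ScenarioSpec.from_code("C")
        single = Population(locations=np.zeros((1, 2)), headings=np.zeros(1),
                            group_sizes=np.array([9], dtype=np.int64),
                            territorial=np.zeros(1, dtype=bool),
                            territory_centers=np.zeros((1, 2)))
        for _ in range(50):
            res = birth_death_update(single, 1.0, spec, CFG, rng)
            if res.n >= 1:
                assert res.group_sizes[0] == 9
                break

    def test_expected_population_constant_over_years(self, rng):
        # martingale property: E[N_t] stays at N_0 under lognormal mu
        spec = ScenarioSpec.from_code("A", initial_n=200)
        demo = DemographyConfig()
        years, reps = 20, 200
        sizes = np.zeros((reps, years))
        for r_i in range(reps):
            pop = _uniform_pop(200, rng)
            for t in range(years):
                mu = sample_growth_rate(demo, rng)
                pop = birth_death_update(pop, mu, spec, CFG, rng)
                sizes[r_i, t] = pop.n
        log_mean = np.log(sizes.mean(axis=0))
        slope = np.polyfit(np.arange(years), log_mean, 1)[0]
        assert abs(slope) < 0.01


class TestInitPopulation:
    def test_scenario_a_counts(self, rng):
        d = StudyDomain.rectangle(100, 100)
        r = uniform_raster(d.bounds, 5.0)
        pop = init_population(ScenarioSpec.from_code("A"), d, r, CFG, rng)
        assert pop.n == 200
        assert np.all(pop.group_sizes == 1)
        assert not pop.territorial.any()

    def test_scenario_c_mean_total(self, rng):
        d = StudyDomain.rectangle(100, 100)
        r = uniform_raster(d.bounds, 5.0)
        spec = ScenarioSpec.from_code("C")
        totals = [init_population(spec, d, r, CFG, rng).total_individuals
                  for _ in range(1000)]
        assert np.mean(totals) == pytest.approx(200.0, abs=2.0)

    def test_scenario_d_zero_variance_is_uniform(self, rng):
        from scipy import stats
        d = StudyDomain.rectangle(100, 100)
        r = uniform_raster(d.bounds, 5.0)
        import dataclasses
        spec = dataclasses.replace(ScenarioSpec.from_code("D", initial_n=2000),
                                   init_field_variance=0.0)
        pop = init_population(spec, d, r, CFG, rng)
        counts, _, _ = np.histogram2d(pop.locations[:, 0],
                                      pop.locations[:, 1],
                                      bins=5, range=[[0, 100], [0, 100]])
        chi2 = ((counts - 80.0) ** 2 / 80.0).sum()
        assert stats.chi2.sf(chi2, 24) > 0.01

    def test_scenario_flag_taxonomy(self):
        flags = {c: ScenarioSpec.from_code(c) for c in "ABCDEF"}
        assert not any([flags["A"].territorial, flags["A"].grouped,
                        flags["A"].habitat_selective,
                        flags["A"].heterogeneous_init])
        assert flags["B"].territorial and not flags["B"].grouped
        assert flags["C"].grouped and flags["C"].initial_n == 40
        assert flags["D"].heterogeneous_init
        assert flags["E"].habitat_selective
        f = flags["F"]
        assert (f.territorial and f.grouped and f.habitat_selective
                and f.heterogeneous_init)


class TestSeason:
    def test_daily_path_length(self, scenario_a_traj):
        from math import gamma
        daily = daily_path_lengths(scenario_a_traj)
        assert daily.size >= 10_000
        expected = 6 * 2 * gamma(1.5)  # ~10.63 km/day
        assert daily.mean() == pytest.approx(expected, rel=0.01)

    def test_all_fixes_inside_domain(self, rng):
        d = StudyDomain.rectangle(30, 30)  # small domain, strong boundary
        r = uniform_raster(d.bounds, 5.0)
        spec = ScenarioSpec.from_code("A", initial_n=20)
        pop = init_population(spec, d, r, CFG, rng)
        traj = simulate_season(pop, spec, d, r, CFG, rng, days=10)
        flat = traj.fixes.reshape(-1, 2)
        assert np.all(d.contains(flat[:, 0], flat[:, 1]))

    def test_zero_days(self, rng):
        d = StudyDomain.rectangle(100, 100)
        r = uniform_raster(d.bounds, 5.0)
        spec = ScenarioSpec.from_code("A", initial_n=5)
        pop = init_population(spec, d, r, CFG, rng)
        traj = simulate_season(pop, spec, d, r, CFG, rng, days=0)
        assert traj.fixes.shape == (5, 1, 2)


class TestHabitatSelection:
    def test_zero_weight_class_never_chosen(self, rng):
        d = StudyDomain.rectangle(40, 40)
        raster = generate_synthetic_landscape(d.bounds, 0.5, (0.5, 0.5), 1.0,
                                              rng=2, class_labels=("good", "bad"),
                                              reference_class=1)
        locs = d.sample_points(200, rng)
        heads = rng.uniform(-np.pi, np.pi, 200)
        pts, _ = habitat_weighted_step(locs, heads, raster,
                                       np.array([1.0, 0.0]), d, CFG, rng)
        assert np.all(raster.habitat_at(pts[:, 0], pts[:, 1]) == 1)

    def test_occupancy_exceeds_area_share(self, rng):
        d = StudyDomain.rectangle(80, 80)
        raster = generate_synthetic_landscape(d.bounds, 0.25, (0.5, 0.5), 0.5,
                                              rng=4, class_labels=("pref", "avoid"),
                                              reference_class=1)
        spec = ScenarioSpec(code="E", initial_n=30, habitat_selective=True,
                            habitat_weights_true={"pref": 1.0, "avoid": 0.5})
        pop = init_population(spec, d, raster, CFG, rng)
        traj = simulate_season(pop, spec, d, raster, CFG, rng, days=60)
        flat = traj.fixes.reshape(-1, 2)
        occ = np.mean(raster.habitat_at(flat[:, 0], flat[:, 1]) == 1)
        assert occ > 0.55  # area share is 0.50, preference 2:1


class TestBoundary:
    def test_inside_proposal_accepted_first_try(self, rng):
        d = StudyDomain.rectangle(10, 10)
        calls = []

        def propose(r):
            calls.append(1)
            return np.array([5.0, 5.0]), 0.0

        pt, _ = enforce_boundary(d, propose, rng)
        assert len(calls) == 1 and d.contains(pt[0], pt[1])

    def test_retry_cap(self, rng):
        d = StudyDomain.rectangle(10, 10)

        def propose(r):
            return np.array([50.0, 50.0]), 0.0

        with pytest.raises(RuntimeError):
            enforce_boundary(d, propose, rng, max_tries=50)


def _uniform_pop(n, rng, grouped=False):
    sizes = 1 + rng.poisson(4, n) if grouped else np.ones(n, dtype=np.int64)
    locs = rng.uniform(0, 100, size=(n, 2))
    return Population(locations=locs,
                      headings=rng.uniform(-np.pi, np.pi, n),
                      group_sizes=np.asarray(sizes, dtype=np.int64),
                      territorial=np.zeros(n, dtype=bool),
                      territory_centers=locs.copy())
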