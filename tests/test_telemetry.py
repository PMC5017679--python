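import numpy as np
import pytest

from strem.landscape import (StudyDomain, generate_synthetic_landscape,
                             uniform_raster)
from strem.movement import (MovementConfig, ScenarioSpec, init_population,
                            simulate_season)
from strem.telemetry import (GpsBurst, bootstrap_weight_intervals,
                             burst_usage, collar_individuals,
                             estimate_daily_distance, estimate_habitat_weights,
                             generate_null_steps, pooled_preferences,
                             relative_weights)


def _straight_burst(n_steps=12, step=1.0):
    xs = np.arange(n_steps + 1) * step
    return GpsBurst(individual_id=0, fixes=np.stack([xs, np.zeros_like(xs)], 1))


class TestDailyDistance:
    def test_stationary_individual(self):
        fixes = np.zeros((13, 2))
        assert estimate_daily_distance([GpsBurst(0, fixes)]) == 0.0

    def test_straight_mover(self):
        assert estimate_daily_distance([_straight_burst()]) == pytest.approx(6.0)

    def test_scenario_a_matches_generative_mean(self, scenario_a_traj):
        bursts = [GpsBurst.from_trajectory(scenario_a_traj, i)
                  for i in range(30)]
        el = estimate_daily_distance(bursts)
        assert el == pytest.approx(10.63, rel=0.02)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            estimate_daily_distance([])


class TestCollaring:
    def test_small_population_all_collared(self, rng):
        assert sorted(collar_individuals(7, 10, rng)) == list(range(7))

    def test_inclusion_probability(self, rng):
        incl = np.zeros(200)
        for _ in range(2000):
            incl[collar_individuals(200, 10, rng)] += 1
        assert incl.mean() / 2000 == pytest.approx(10 / 200, abs=1e-9)
        assert np.all(np.abs(incl / 2000 - 0.05) < 0.03)

    def test_burst_fix_count(self, big_domain, big_raster, rng):
        spec = ScenarioSpec.from_code("A", initial_n=2)
        cfg = MovementConfig()
        pop = init_population(spec, big_domain, big_raster, cfg, rng)
        traj = simulate_season(pop, spec, big_domain, big_raster, cfg, rng,
                               days=60)
        b = GpsBurst.from_trajectory(traj, 0)
        assert len(b.fixes) == 60 * 6 + 1


class TestNullSteps:
    def test_single_step_pair_is_congruent(self, rng):
        # constant turning angle and length: every null step reproduces the
        # realized step exactly
        heads = np.cumsum(np.full(10, 0.3))
        pts = np.vstack([[0.0, 0.0],
                         np.cumsum(np.stack([2 * np.cos(heads),
                                             2 * np.sin(heads)], 1), axis=0)])
        burst = GpsBurst(0, pts)
        d = StudyDomain.rectangle(200, 200, origin=(-100, -100))
        nulls = generate_null_steps(burst, d, rng, n_null=5)
        assert np.allclose(nulls, burst.fixes[2:][:, None, :], atol=1e-9)

    def test_null_lengths_match_empirical_distribution(self, big_domain,
                                                       big_raster,
                                                       scenario_a_traj, rng):
        from scipy import stats
        burst = GpsBurst.from_trajectory(scenario_a_traj, 0)
        nulls = generate_null_steps(burst, big_domain, rng)
        starts = burst.fixes[1:-1][:, None, :]
        null_lens = np.hypot(*(nulls - starts).transpose(2, 0, 1)).ravel()
        ks = stats.ks_2samp(null_lens, burst.step_lengths)
        assert ks.pvalue > 0.01

    def test_degenerate_burst_raises(self, rng):
        d = StudyDomain.rectangle(10, 10)
        with pytest.raises(ValueError):
            generate_null_steps(GpsBurst(0, np.ones((5, 2))), d, rng)


class TestUsage:
    def test_fractions_are_multiples_of_one_over_n_null(self, big_domain,
                                                        scenario_a_traj, rng):
        raster = generate_synthetic_landscape((0, 0, 1500, 1500), 5.0,
                                              (0.5, 0.5), 10.0, rng=1)
        burst = GpsBurst.from_trajectory(scenario_a_traj, 1)
        nulls = generate_null_steps(burst, big_domain, rng, n_null=30)
        # per-step availability fractions are counts out of 30
        flat = nulls.reshape(-1, 2)
        codes = raster.habitat_at_or_zero(flat[:, 0], flat[:, 1])
        per_step = (codes.reshape(-1, 30) == 1).sum(axis=1)
        assert np.all((per_step >= 0) & (per_step <= 30))
        p, q = burst_usage(burst, raster, nulls)
        J = burst.n_steps - 1
        assert np.allclose((q * J * 30) % 1, 0, atol=1e-9)

    def test_partition_sums_to_one(self, big_domain, scenario_a_traj, rng):
        raster = generate_synthetic_landscape((0, 0, 1500, 1500), 5.0,
                                              (0.3, 0.3, 0.4), 10.0, rng=2)
        burst = GpsBurst.from_trajectory(scenario_a_traj, 2)
        nulls = generate_null_steps(burst, big_domain, rng)
        p, q = burst_usage(burst, raster, nulls)
        assert p.sum() == pytest.approx(1.0)
        assert q.sum() == pytest.approx(1.0)

    def test_toy_burst_exact_fractions(self):
        # 3 steps, 2 selection steps; class 2 on the right half-plane
        classes = np.array([[1, 2]], dtype=np.int16)
        from strem.landscape import HabitatRaster
        raster = HabitatRaster(origin=(0.0, 0.0), cell_size=10.0,
                               classes=classes, class_labels=("a", "b"),
                               reference_class=1)
        fixes = np.array([[2.0, 5], [5.0, 5], [8.0, 5], [12.0, 5]])
        burst = GpsBurst(0, fixes)
        # hand-built nulls: step 2 -> 2 in class a / 1 in b; step 3 -> all b
        nulls = np.array([[[1.0, 5], [2.0, 5], [15.0, 5]],
                          [[11.0, 5], [12.0, 5], [13.0, 5]]])
        p, q = burst_usage(burst, raster, nulls)
        assert p.tolist() == [0.5, 0.5]     # endpoints at x=8 (a), x=12 (b)
        assert q.tolist() == [pytest.approx(1 / 3), pytest.approx(2 / 3)]


class TestPreferences:
    def test_usage_equal_to_null_gives_unit_preferences(self):
        usages = [(np.array([0.6, 0.4]), np.array([0.6, 0.4]))] * 3
        w = pooled_preferences(usages)
        assert np.allclose(w, 1.0)

    def test_ratio_of_sums(self):
        usages = [(np.array([0.8, 0.2]), np.array([0.5, 0.5]))] * 2
        w = pooled_preferences(usages)
        assert np.allclose(w, [1.6, 0.4])
        wm = relative_weights(w, 1, ("forest", "water"))
        assert wm.h.tolist() == [1.0, 0.25]

    def test_never_available_class_flagged_undefined(self):
        usages = [(np.array([1.0, 0.0]), np.array([1.0, 0.0]))]
        w = pooled_preferences(usages)
        assert np.isnan(w[1])
        wm = relative_weights(w, 1, ("forest", "water"))
        assert not wm.defined[1]

    def test_zero_reference_preference_raises(self):
        with pytest.raises(ValueError):
            relative_weights(np.array([0.0, 1.0]), 1, ("forest", "water"))


class TestCalibrationOnIndifferentWalker:
    def test_unit_weights_recovered_for_scenario_a(self, rng):
        # a habitat-indifferent walker must yield h ~ 1 for every class
        d = StudyDomain.rectangle(300, 300)
        raster = generate_synthetic_landscape(d.bounds, 0.5,
                                              (0.03, 0.07, 0.70, 0.10, 0.10),
                                              1.0, rng=6)
        spec = ScenarioSpec.from_code("A", initial_n=20)
        cfg = MovementConfig()
        pop = init_population(spec, d, raster, cfg, rng)
        traj = simulate_season(pop, spec, d, raster, cfg, rng, days=60)
        bursts = [GpsBurst.from_trajectory(traj, i) for i in range(20)]
        usages = []
        for b in bursts:
            nulls = generate_null_steps(b, d, rng)
            usages.append(burst_usage(b, raster, nulls))
        w = pooled_preferences(usages)
        wm = relative_weights(w, raster.reference_class, raster.class_labels)
        lo, hi = bootstrap_weight_intervals(usages, raster.reference_class,
                                            rng, n_boot=500)
        for i in range(5):
            if i + 1 == raster.reference_class:
                continue
            assert lo[i] <= 1.0 <= hi[i], \
                f"class {raster.class_labels[i]}: h={wm.h[i]:.3f} " \
                f"CI=({lo[i]:.3f}, {hi[i]:.3f})"

    def test_preference_ordering_recovered_for_scenario_e(self, rng):
        # estimated weights reproduce the preference ordering of the
        # generative weights (forest > wetland > fields/urban > water)
        d = StudyDomain.rectangle(200, 200)
        raster = generate_synthetic_landscape(d.bounds, 0.25,
                                              (0.03, 0.07, 0.70, 0.10, 0.10),
                                              1.0, rng=8)
        spec = ScenarioSpec.from_code("E", initial_n=20)
        cfg = MovementConfig()
        pop = init_population(spec, d, raster, cfg, rng)
        traj = simulate_season(pop, spec, d, raster, cfg, rng, days=60)
        bursts = [GpsBurst.from_trajectory(traj, i) for i in range(20)]
        wm = estimate_habitat_weights(bursts, raster, d, rng)
        h = wm.as_dict()
        assert h["forest"] == 1.0
        assert h["forest"] > h["wetland"] > max(h["artificial"],
                                                h["agricultural"]) \
            > h["water"]
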