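"""ABC-SMC engine: distances, quantiles, populations and posterior summaries."""

import numpy as np
import pytest

from glycokin.smc import (
    ParticlePopulation,
    PriorSpec,
    abc_smc,
    credible_interval,
    map_estimate,
    rmse,
    weighted_quantile,
)


class TestRMSE:
    def test_identical_profiles(self):
        obs = {"E": {"A": 40.0, "B": 60.0}}
        assert rmse(obs, obs) == 0.0

    def test_hand_value(self):
        pred = {"E": {"A": 50.0, "B": 50.0}}
        obs = {"E": {"A": 40.0, "B": 60.0}}
        assert rmse(pred, obs) == pytest.approx(10.0)

    def test_symmetric(self):
        a = {"E": {"A": 30.0, "B": 70.0}}
        b = {"E": {"A": 45.0, "B": 55.0}}
        assert rmse(a, b) == pytest.approx(rmse(b, a))

    def test_missing_predicted_tag_counts_as_zero(self):
        pred = {"E": {"A": 100.0}}
        obs = {"E": {"A": 60.0, "B": 40.0}}
        assert rmse(pred, obs) == pytest.approx(np.sqrt((40.0**2 + 40.0**2) / 2))

    def test_entities_concatenate(self):
        pred = {"E1": {"A": 50.0}, "E2": {"A": 30.0}}
        obs = {"E1": {"A": 40.0}, "E2": {"A": 60.0}}
        assert rmse(pred, obs) == pytest.approx(np.sqrt((100.0 + 900.0) / 2))

    def test_empty_support_is_error(self):
        with pytest.raises(ValueError):
            rmse({}, {})


class TestWeightedQuantile:
    def test_equal_weights_match_linear_interpolation(self):
        values = np.array([1.0, 2.0, 3.0, 4.0])
        weights = np.full(4, 0.25)
        assert weighted_quantile(values, weights, 0.025) == pytest.approx(1.075)
        assert weighted_quantile(values, weights, 0.975) == pytest.approx(3.925)
        assert weighted_quantile(values, weights, 0.5) == pytest.approx(2.5)

    def test_reduces_to_numpy_for_equal_weights(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=11)
        weights = np.full(11, 1 / 11)
        for q in (0.1, 0.37, 0.5, 0.9):
            assert weighted_quantile(values, weights, q) == pytest.approx(
                np.quantile(values, q)
            )

    def test_heavy_weight_pulls_quantile(self):
        values = np.array([0.0, 5.0, 10.0])
        weights = np.array([0.8, 0.1, 0.1])
        assert weighted_quantile(values, weights, 0.5) < 5.0


def _toy_simulator(theta):
    return {"E": {"A": float(theta[0]), "B": 100.0 - float(theta[0])}}


class TestABCSMC:
    def test_scalar_problem_concentrates_on_truth(self):
        prior = PriorSpec(["x"], [(0.0, 100.0)])
        observed = _toy_simulator(np.array([42.0]))
        pops = abc_smc(prior, _toy_simulator, observed, n=100, max_generations=10, seed=5)
        estimate = map_estimate(pops[-1])
        assert estimate[0] == pytest.approx(42.0, rel=0.02)

    def test_epsilon_non_increasing(self):
        prior = PriorSpec(["x"], [(0.0, 100.0)])
        observed = _toy_simulator(np.array([42.0]))
        pops = abc_smc(prior, _toy_simulator, observed, n=50, max_generations=8, seed=1)
        eps = [p.epsilon for p in pops[1:]]
        assert all(e1 >= e2 for e1, e2 in zip(eps, eps[1:]))
        assert all(np.all(p.distances <= p.epsilon) for p in pops[1:])

    def test_weights_normalised_and_inside_prior(self):
        prior = PriorSpec(["x"], [(0.0, 100.0)])
        observed = _toy_simulator(np.array([42.0]))
        pops = abc_smc(prior, _toy_simulator, observed, n=50, max_generations=5, seed=2)
        for pop in pops:
            assert pop.weights.sum() == pytest.approx(1.0)
            assert np.all(pop.particles[:, 0] >= 0.0)
            assert np.all(pop.particles[:, 0] <= 100.0)

    def test_deterministic_given_seed(self):
        prior = PriorSpec(["x"], [(0.0, 100.0)])
        observed = _toy_simulator(np.array([42.0]))
        a = abc_smc(prior, _toy_simulator, observed, n=30, max_generations=4, seed=9)
        b = abc_smc(prior, _toy_simulator, observed, n=30, max_generations=4, seed=9)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.particles, pb.particles)
            np.testing.assert_array_equal(pa.weights, pb.weights)

    def test_failed_simulations_rejected_not_fatal(self):
        calls = {"n": 0}

        def flaky(theta):
            calls["n"] += 1
            if calls["n"] % 3 == 0:
                return None
            return _toy_simulator(theta)

        prior = PriorSpec(["x"], [(0.0, 100.0)])
        observed = _toy_simulator(np.array([42.0]))
        pops = abc_smc(prior, flaky, observed, n=20, max_generations=3, seed=3)
        assert len(pops) == 3
        assert all(len(p.particles) == 20 for p in pops)

    def test_wider_prior_never_narrower_cri(self):
        observed = _toy_simulator(np.array([42.0]))
        widths = []
        for bounds in [(40.0, 44.0), (0.0, 100.0)]:
            prior = PriorSpec(["x"], [bounds])
            pops = abc_smc(prior, _toy_simulator, observed, n=60, max_generations=5, seed=4)
            lo, hi = credible_interval(pops[-1])[0]
            widths.append(hi - lo)
        assert widths[1] >= widths[0]


class TestPosteriorSummaries:
    def test_single_particle_degenerate(self):
        pop = ParticlePopulation(
            particles=np.array([[3.0, 7.0]]), weights=np.array([1.0]),
            distances=np.array([0.0]), epsilon=1.0, generation=0, names=["a", "b"],
        )
        with pytest.warns(UserWarning):
            estimate = map_estimate(pop)
        np.testing.assert_array_equal(estimate, [3.0, 7.0])
        assert credible_interval(pop) == [(3.0, 3.0), (7.0, 7.0)]

    def test_map_lands_in_heavy_cluster(self):
        rng = np.random.default_rng(0)
        light = rng.normal(0.0, 0.05, size=(10, 1))
        heavy = rng.normal(5.0, 0.05, size=(40, 1))
        particles = np.vstack([light, heavy])
        weights = np.concatenate([np.full(10, 0.02), np.full(40, 0.02)])
        pop = ParticlePopulation(
            particles=particles, weights=weights / weights.sum(),
            distances=np.zeros(50), epsilon=1.0, generation=1, names=["x"],
        )
        assert map_estimate(pop)[0] == pytest.approx(5.0, abs=0.5)

    def test_cri_within_prior_support_on_toy_run(self):
        prior = PriorSpec(["x"], [(0.0, 100.0)])
        observed = _toy_simulator(np.array([42.0]))
        pops = abc_smc(prior, _toy_simulator, observed, n=40, max_generations=5, seed=6)
        (lo, hi), = credible_interval(pops[-1])
        assert 0.0 <= lo <= hi <= 100.0
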