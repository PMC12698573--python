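"""Band selectors: fitness oracle, swarm mechanics, SPA/PCA/LASSO/CARS."""

import numpy as np
import pytest

from hypyield.band_selection import (
    ParticleSwarm,
    SwarmConfig,
    attention_pool,
    attention_weights,
    cars_retention_schedule,
    cars_select,
    cv_fitness,
    lasso_select,
    pca_select,
    pso_select,
    pso_update,
    psama_select,
    spa_chain,
    spa_select,
)
from hypyield.errors import ConfigurationError
from hypyield.synthetic import planted_band_data


class TestCvFitness:
    def test_exact_fit_on_noiseless_single_band(self, rng):
        X = rng.random((50, 10))
        y = 3.0 * X[:, 5]
        assert cv_fitness(X, y, [5]) < 1e-8

    def test_informative_subset_beats_noise_subset(self, rng):
        X = rng.random((80, 20))
        y = 2.0 * X[:, 3] + 0.01 * rng.standard_normal(80)
        assert cv_fitness(X, y, [3]) < cv_fitness(X, y, [10, 11, 12])

    def test_deterministic_under_seed(self, rng):
        X, y = rng.random((40, 15)), rng.random(40)
        assert cv_fitness(X, y, [1, 4, 7], seed=3) == cv_fitness(X, y, [1, 4, 7], seed=3)

    def test_empty_subset_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            cv_fitness(rng.random((10, 5)), rng.random(10), [])


class TestPsoUpdate:
    def test_inertia_only(self):
        cfg = SwarmConfig(w=1.0, c1=0.0, c2=0.0)
        x, v = np.array([0.2]), np.array([0.1])
        x2, v2 = pso_update(x, v, x, x, cfg, 0.5, 0.5)
        assert np.allclose(v2, v) and np.allclose(x2, x + v)

    def test_zero_attraction_at_consensus(self):
        cfg = SwarmConfig(w=0.6, c1=1.5, c2=1.5)
        x = np.array([0.4, 0.6])
        v = np.array([0.05, -0.05])
        _, v2 = pso_update(x, v, x, x, cfg, 0.3, 0.7)
        assert np.allclose(v2, 0.6 * v)

    def test_scalar_arithmetic_case(self):
        # w=0.5, v=2, c1=c2=1, r1=r2=0.5, pbest-x=4, gbest-x=8 -> v'=7
        cfg = SwarmConfig(w=0.5, c1=1.0, c2=1.0)
        x = np.array([0.0])
        x2, v2 = pso_update(
            x, np.array([2.0]), np.array([4.0]), np.array([8.0]), cfg, 0.5, 0.5,
            bounds=(-100.0, 100.0),
        )
        assert v2[0] == pytest.approx(7.0)
        assert x2[0] == pytest.approx(7.0)

    def test_position_clipped_to_bounds(self):
        cfg = SwarmConfig(w=1.0, c1=0.0, c2=0.0)
        x2, _ = pso_update(np.array([0.9]), np.array([5.0]), np.array([0.9]),
                           np.array([0.9]), cfg, 0.0, 0.0)
        assert x2[0] == 1.0


class TestAttention:
    def test_identical_keys_give_mean_of_values(self, rng):
        keys = np.tile(rng.random(4), (5, 1))
        values = rng.random((5, 4))
        out = attention_pool(rng.random(4), keys, values)
        assert np.allclose(out, values.mean(axis=0))

    def test_dominant_similarity_selects_its_value(self):
        query = np.array([100.0, 0.0])
        keys = np.array([[1.0, 0.0], [-1.0, 0.0]])
        values = np.array([[5.0, 5.0], [-5.0, -5.0]])
        assert np.allclose(attention_pool(query, keys, values), values[0], atol=1e-10)

    def test_output_is_weighted_sum_of_values(self, rng):
        query, keys, values = rng.random(6), rng.random((8, 6)), rng.random((8, 6))
        w = attention_weights(query, keys)
        assert np.allclose(attention_pool(query, keys, values), w @ values)

    def test_weights_sum_to_one_and_output_in_convex_hull(self, rng):
        for _ in range(200):
            q, k = rng.standard_normal(5), rng.standard_normal((6, 5))
            v = rng.standard_normal((6, 5))
            w = attention_weights(q, k)
            assert np.all(w >= 0) and np.isclose(w.sum(), 1.0)
            out = attention_pool(q, k, v)
            assert np.all(out >= v.min(axis=0) - 1e-12)
            assert np.all(out <= v.max(axis=0) + 1e-12)


class TestSwarmOptimiser:
    def test_sphere_minimised_within_tolerance(self):
        swarm = ParticleSwarm(SwarmConfig(n_particles=30, max_iter=200, seed=0))
        gbest, f, _ = swarm.minimize(lambda x: float(np.sum(x * x)), 30, (-1.0, 1.0))
        assert f < 1e-3

    def test_single_particle_psama_identical_to_pso(self, rng):
        X = rng.random((40, 16))
        y = 2.0 * X[:, 4] + rng.standard_normal(40) * 0.05
        cfg = lambda: SwarmConfig(n_particles=1, max_iter=15, k_bands=3, seed=9)
        a = pso_select(X, y, cfg())
        b = psama_select(X, y, cfg())
        assert a.channel_indices == b.channel_indices
        assert a.fitness == b.fitness

    def test_selector_deterministic_under_seed(self, rng):
        X = rng.random((40, 16))
        y = X[:, 2] + 0.1 * rng.standard_normal(40)
        cfg = lambda: SwarmConfig(n_particles=6, max_iter=8, k_bands=3, seed=4)
        assert pso_select(X, y, cfg()).channel_indices == pso_select(X, y, cfg()).channel_indices

    def test_full_grid_subset_at_saturation(self, rng):
        X = rng.random((30, 6))
        y = rng.random(30)
        cfg = SwarmConfig(n_particles=4, max_iter=2, k_bands=6, seed=1)
        subset = pso_select(X, y, cfg)
        assert subset.channel_indices == list(range(6))
        assert subset.fitness == pytest.approx(cv_fitness(X, y, range(6), seed=1))


class TestSpa:
    def test_orthogonal_columns_selected_by_descending_norm(self):
        norms = [3.0, 5.0, 1.0, 4.0]
        X = np.diag(norms)
        chain = spa_chain(X, 4, start=1)  # start at the largest column
        assert chain == [1, 3, 0, 2]

    def test_matches_brute_force_projection_oracle(self, rng):
        def oracle_chain(X, k, start):
            selected = [start]
            for _ in range(k - 1):
                A = X[:, selected]
                proj = A @ np.linalg.pinv(A)  # projector onto span(selected)
                resid = X - proj @ X
                norms = np.linalg.norm(resid, axis=0)
                norms[selected] = -1
                selected.append(int(np.argmax(norms)))
            return selected

        for trial in range(20):
            X = np.random.default_rng(trial).standard_normal((8, 6))
            start = trial % 6
            assert spa_chain(X, 4, start) == oracle_chain(X, 4, start)

    def test_automatic_start_picks_lowest_fitness_chain(self, rng):
        X = rng.random((30, 8))
        y = 2.0 * X[:, 6] + 0.01 * rng.standard_normal(30)
        subset = spa_select(X, k=2, y=y, seed=0)
        assert 6 in subset.channel_indices


class TestPca:
    def test_planted_variance_channels_recovered(self, rng):
        X = 0.01 * rng.standard_normal((60, 12))
        X[:, :3] += rng.standard_normal((60, 1)) * np.array([5.0, 4.0, 3.0])
        subset = pca_select(X, k=3)
        assert subset.channel_indices == [0, 1, 2]

    def test_duplicate_columns_tie_break_to_lower_index(self, rng):
        x = rng.standard_normal(50)
        X = np.column_stack([x, x.copy(), rng.standard_normal(50) * 0.01])
        subset = pca_select(X, k=1)
        assert subset.channel_indices == [0]

    def test_k_exceeding_band_count_raises(self, rng):
        with pytest.raises(ConfigurationError):
            pca_select(rng.random((10, 4)), k=5)


class TestLasso:
    def test_planted_band_has_largest_coefficient(self, rng):
        X = rng.random((60, 30))
        y = 3.0 * X[:, 17]
        subset = lasso_select(X, y, k_target=5)
        assert subset.channel_indices[0] == 17  # ordered by |coefficient|

    def test_support_size_near_target(self):
        X, y, _ = planted_band_data(n_samples=100, n_bands=50, seed=13)
        subset = lasso_select(X, y, k_target=10)
        assert 1 <= len(subset.channel_indices) <= 12

    def test_full_shrinkage_falls_back_with_warning(self, rng):
        X = rng.random((30, 10))
        y = X[:, 2] + 0.1 * rng.standard_normal(30)
        with pytest.warns(UserWarning, match="non-empty"):
            subset = lasso_select(X, y, k_target=3, alpha_range=(1e6, 1e7))
        assert len(subset.channel_indices) >= 1


class TestCars:
    def test_retention_schedule_boundaries(self):
        counts = cars_retention_schedule(224, 50)
        assert counts[0] == 224 and counts[-1] == 2
        assert np.all(np.diff(counts) <= 0)

    def test_planted_bands_recovered(self):
        X, y, informative = planted_band_data(
            n_samples=80, n_bands=50, n_informative=3, noise_sd=0.005, seed=17
        )
        subset = cars_select(X, y, n_runs=30, seed=17)
        assert set(informative) <= set(subset.channel_indices)

    def test_deterministic_under_seed(self):
        X, y, _ = planted_band_data(n_samples=60, n_bands=40, seed=19)
        a = cars_select(X, y, n_runs=20, seed=5)
        b = cars_select(X, y, n_runs=20, seed=5)
        assert a.channel_indices == b.channel_indices and a.fitness == b.fitness


class TestSelectorsBeatRandomSubsets:
    @pytest.mark.parametrize("method", ["lasso", "cars"])
    def test_fitness_below_random_subset_median(self, method):
        X, y, _ = planted_band_data(n_samples=100, n_bands=60, seed=23)
        if method == "lasso":
            subset = lasso_select(X, y, k_target=8)
        else:
            subset = cars_select(X, y, n_runs=25, seed=23)
        k = len(subset.channel_indices)
        rng = np.random.default_rng(23)
        random_fits = [
            cv_fitness(X, y, rng.choice(60, size=k, replace=False)) for _ in range(20)
        ]
        assert subset.fitness <= np.median(random_fits)
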