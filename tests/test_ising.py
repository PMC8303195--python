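"""Seeded Ising model: energies, flip ratios, sampler, enumeration oracle."""

import math

import numpy as np
import pytest

from irisilo import (
    IsingParams,
    SeedMap,
    SeedViolationError,
    SpinView,
    TemplateError,
    acceptance_ratio,
    enumerate_gibbs,
    metropolis_run,
    unnormalized_prob,
)
from irisilo.ising import edge_disagreements, flip_site


def brute_force_pi(x, params):
    """Independent oracle: enumerate every edge explicitly."""
    v = x.values
    q1, q2 = v.shape
    dv = sum(
        int(v[r, c] != v[r + 1, c]) for r in range(q1 - 1) for c in range(q2)
    )
    dh = sum(
        int(v[r, c] != v[r, (c + 1) % q2]) for r in range(q1) for c in range(q2)
    )
    return math.exp(-2 * params.jv * dv - 2 * params.jh * dh)


def random_spins(rng, shape=(3, 4)):
    return SpinView(rng.integers(0, 2, shape, dtype=np.int8) * 2 - 1)


class TestUnnormalizedProb:
    def test_ground_state_has_weight_one(self):
        assert unnormalized_prob(SpinView(np.ones((3, 4), np.int8)), IsingParams()) == 1.0

    def test_decoupled_limit_is_flat(self, rng):
        params = IsingParams(0.0, 0.0)
        for _ in range(10):
            assert unnormalized_prob(random_spins(rng), params) == 1.0

    def test_matches_brute_force_edge_enumeration(self, rng):
        params = IsingParams(0.2, 0.3)
        for _ in range(50):
            x = random_spins(rng)
            assert unnormalized_prob(x, params) == pytest.approx(
                brute_force_pi(x, params), rel=1e-12
            )

    def test_edge_count_identity(self, rng):
        # d + a must exhaust the edge sets: q2(q1-1) vertical, q1*q2 horizontal
        x = random_spins(rng, (4, 5))
        dv, dh = edge_disagreements(x)
        assert 0 <= dv <= 5 * 3 and 0 <= dh <= 4 * 5


class TestAcceptanceRatio:
    def test_decoupled_limit_always_one(self, rng):
        params = IsingParams(0.0, 0.0)
        x = random_spins(rng)
        assert acceptance_ratio(x, (1, 2), params) == 1.0

    def test_agreeing_neighborhood_closed_form(self):
        x = SpinView(np.ones((3, 4), np.int8))
        params = IsingParams(0.2, 0.3)
        # interior site: 2 vertical + 2 horizontal agreeing neighbors
        assert acceptance_ratio(x, (1, 1), params) == pytest.approx(
            math.exp(-4 * 0.2 - 4 * 0.3), rel=1e-12
        )

    def test_equals_full_pi_ratio_everywhere(self, rng):
        """Local ratio == pi(flip)/pi(x) on 500 random (lattice, site) draws."""
        params = IsingParams(0.2, 0.3)
        for _ in range(500):
            x = random_spins(rng)
            site = (int(rng.integers(3)), int(rng.integers(4)))
            ratio = acceptance_ratio(x, site, params)
            full = unnormalized_prob(flip_site(x, site), params) / unnormalized_prob(
                x, params
            )
            assert ratio == pytest.approx(full, rel=1e-12)

    def test_detailed_balance(self, rng):
        params = IsingParams(0.2, 0.3)
        for _ in range(50):
            x = random_spins(rng)
            site = (int(rng.integers(3)), int(rng.integers(4)))
            y = flip_site(x, site)
            ratio = acceptance_ratio(x, site, params)
            flow_xy = unnormalized_prob(x, params) * min(1.0, ratio)
            flow_yx = unnormalized_prob(y, params) * min(1.0, 1.0 / ratio)
            assert flow_xy == pytest.approx(flow_yx, rel=1e-10)

    def test_seed_site_is_immutable(self):
        x = SpinView(np.ones((3, 4), np.int8))
        seeds = SeedMap((3, 4), np.array([[0, 0]]), np.array([1], np.int8))
        with pytest.raises(SeedViolationError):
            acceptance_ratio(x, (0, 0), IsingParams(), seeds)


class TestEnumeration:
    def test_decoupled_limit_is_uniform(self):
        seeds = SeedMap((2, 3), np.array([[0, 0]]), np.array([1], np.int8))
        table = enumerate_gibbs(seeds, IsingParams(0.0, 0.0))
        assert np.allclose(table.probs, 1 / 32)

    def test_probabilities_sum_to_one(self):
        seeds = SeedMap((2, 3), np.empty((0, 2)), np.empty(0, np.int8))
        table = enumerate_gibbs(seeds, IsingParams())
        assert len(table.states) == 64
        assert table.probs.sum() == pytest.approx(1.0)

    def test_single_free_bit_closed_form(self):
        # freeze everything except (1, 1) on a 3x4 all-up lattice
        q1, q2 = 3, 4
        positions = [[r, c] for r in range(q1) for c in range(q2) if (r, c) != (1, 1)]
        seeds = SeedMap((q1, q2), np.array(positions), np.ones(len(positions), np.int8))
        params = IsingParams(0.2, 0.3)
        table = enumerate_gibbs(seeds, params)
        up = np.ones((q1, q2), np.int8)
        down = up.copy()
        down[1, 1] = -1
        # 2 vertical + 2 horizontal neighbors, all +1
        odds = math.exp(2 * params.jv * 2 + 2 * params.jh * 2)
        assert table.prob(SpinView(up)) / table.prob(SpinView(down)) == pytest.approx(
            odds, rel=1e-12
        )

    def test_refuses_large_free_sets(self):
        seeds = SeedMap((8, 128), np.empty((0, 2)), np.empty(0, np.int8))
        with pytest.raises(ValueError, match="free bits"):
            enumerate_gibbs(seeds, IsingParams())


class TestMetropolisRun:
    def test_fully_frozen_lattice_returns_seed(self):
        q1, q2 = 2, 3
        positions = np.array([[r, c] for r in range(q1) for c in range(q2)])
        spins = np.array([1, -1, 1, -1, 1, -1], np.int8)
        seeds = SeedMap((q1, q2), positions, spins)
        snaps = metropolis_run(seeds, IsingParams(), 100, [0, 50, 100], 0)
        for s in snaps:
            assert (s.values.ravel()[positions[:, 0] * q2 + positions[:, 1]] == spins).all()

    def test_snapshot_zero_is_initial_template(self, rng):
        seeds = SeedMap((2, 3), np.array([[0, 0]]), np.array([1], np.int8))
        init = SpinView(np.where(rng.random((2, 3)) < 0.5, -1, 1).astype(np.int8))
        init_values = init.values.copy()
        init_values[0, 0] = 1
        init = SpinView(init_values)
        snaps = metropolis_run(seeds, IsingParams(), 10, [0, 10], 0, init=init)
        assert snaps[0] == init

    def test_init_outside_seed_space_rejected(self):
        seeds = SeedMap((2, 3), np.array([[0, 0]]), np.array([1], np.int8))
        bad = SpinView(-np.ones((2, 3), np.int8))
        with pytest.raises(TemplateError):
            metropolis_run(seeds, IsingParams(), 10, None, 0, init=bad)

    def test_seed_immutability_along_trajectory(self, rng):
        positions = np.array([[0, 0], [3, 7], [1, 4]])
        spins = np.array([1, -1, 1], np.int8)
        seeds = SeedMap((4, 8), positions, spins)
        snaps = metropolis_run(seeds, IsingParams(), 5000, [100, 2500, 5000], 3)
        for s in snaps:
            assert (s.values[positions[:, 0], positions[:, 1]] == spins).all()

    def test_reproducible_from_rng_seed(self):
        seeds = SeedMap((4, 8), np.array([[0, 0]]), np.array([1], np.int8))
        a = metropolis_run(seeds, IsingParams(), 2000, [1000, 2000], 77)
        b = metropolis_run(seeds, IsingParams(), 2000, [1000, 2000], 77)
        assert all(x == y for x, y in zip(a, b))

    def test_snapshot_beyond_steps_rejected(self):
        seeds = SeedMap((2, 3), np.array([[0, 0]]), np.array([1], np.int8))
        with pytest.raises(ValueError):
            metropolis_run(seeds, IsingParams(), 10, [20], 0)

    def test_long_run_matches_enumeration(self):
        """Empirical law of a thinned chain approaches the exact Gibbs law
        (small version; the full-scale check lives in the acceptance suite)."""
        seeds = SeedMap((2, 3), np.array([[0, 0], [1, 2]]), np.array([1, -1], np.int8))
        snaps = metropolis_run(
            seeds, IsingParams(), 2 * 10**5, list(range(10, 2 * 10**5 + 1, 10)), 5
        )
        table = enumerate_gibbs(seeds, IsingParams())
        assert table.tv_distance(snaps) < 0.05
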