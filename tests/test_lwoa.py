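import numpy as np
import pytest

from netcog.lwoa import (H_SCHEDULES, OptimizerConfig, WhaleSwarm, levy_step,
                         linear_h, mantegna_sigma_mu, modified_h, optimize,
                         woa_update)


class ScriptedRNG:
    """Minimal Generator stand-in returning a scripted uniform sequence."""

    def __init__(self, uniforms):
        self._u = list(uniforms)

    def random(self, size=None):
        if size is None:
            return self._u.pop(0)
        return np.array([self._u.pop(0) for _ in range(int(size))])

    def integers(self, *args, **kwargs):
        return 0

    def normal(self, loc=0.0, scale=1.0, size=None):
        return 0.0 if size is None else np.zeros(size)

    def uniform(self, lo, hi, size=None):
        return (np.asarray(lo) + np.asarray(hi)) / 2.0


class TestConvergenceSchedules:
    def test_linear_endpoints_and_midpoint(self):
        assert linear_h(0, 100) == 2.0
        assert linear_h(100, 100) == 0.0
        assert linear_h(50, 100) == 1.0

    @pytest.mark.parametrize("name", sorted(H_SCHEDULES))
    def test_all_schedules_monotone_nonincreasing(self, name):
        h = H_SCHEDULES[name]
        vals = [h(t, 200) for t in range(201)]
        assert all(b <= a + 1e-12 for a, b in zip(vals, vals[1:]))

    def test_modified_starts_near_two_e_015(self):
        assert 2.0 <= modified_h(1, 200) <= 2.4
        assert modified_h(1, 200) == pytest.approx(2 * np.exp(0.15), rel=0.01)

    def test_modified_decays_slowly_early_fast_late(self):
        early = modified_h(1, 200) - modified_h(50, 200)
        late = modified_h(150, 200) - modified_h(200, 200)
        assert early < late

    def test_schedule_selection_is_isolated_config_state(self):
        base = OptimizerConfig(variant="standard")
        assert base.schedule() is linear_h
        assert OptimizerConfig(variant="levy").schedule() is modified_h
        swapped = OptimizerConfig(variant="standard", h_schedule="modified")
        assert swapped.schedule() is modified_h
        # nothing else differs between the two configs
        assert swapped.population_size == base.population_size
        assert swapped.bounds == base.bounds


class TestMantegna:
    def test_default_stability_index_gives_070(self):
        assert mantegna_sigma_mu(1.5) == pytest.approx(0.6966, abs=1e-4)
        assert round(mantegna_sigma_mu(1.5), 1) == 0.7

    def test_beta_one_closed_form(self):
        # Gamma(2) sin(pi/2) / (Gamma(1) * 1 * 2^0) = 1
        assert mantegna_sigma_mu(1.0) == pytest.approx(1.0, abs=1e-12)

    def test_positive_finite_over_domain(self):
        for beta in np.linspace(0.1, 2.0, 20):
            s = mantegna_sigma_mu(beta)
            assert np.isfinite(s) and s > 0

    @pytest.mark.parametrize("bad", [0.0, -0.5, 2.5])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            mantegna_sigma_mu(bad)


class TestLevyStep:
    def test_seeded_reproducibility(self):
        a = levy_step(1.5, 0.7, np.random.default_rng(8), size=100)
        b = levy_step(1.5, 0.7, np.random.default_rng(8), size=100)
        assert np.array_equal(a, b)

    def test_tail_exponent_matches_stability_index(self):
        rng = np.random.default_rng(9)
        s = np.abs(levy_step(1.5, mantegna_sigma_mu(1.5), rng, size=10 ** 6))
        cs = np.geomspace(5, 50, 8)
        ccdf = np.array([(s > c).mean() for c in cs])
        slope = np.polyfit(np.log(cs), np.log(ccdf), 1)[0]
        assert slope == pytest.approx(-1.5, abs=0.3)

    def test_heavy_tail_but_finite_median(self):
        rng = np.random.default_rng(10)
        s = np.abs(levy_step(1.5, 0.7, rng, size=10 ** 5))
        assert np.median(s) < 5.0
        assert s.max() > 50.0  # occasional very long jumps


def _swarm(positions, best):
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    return WhaleSwarm(positions=positions.copy(),
                      fitness=np.zeros(len(positions)),
                      best_position=np.asarray(best, dtype=float),
                      best_fitness=0.0)


class TestUpdateBranches:
    CONFIG = OptimizerConfig(population_size=2, max_iters=100,
                             bounds=((-100.0, 100.0),), variant="standard")

    def test_degenerate_spiral_moves_by_m3(self):
        # p >= 0.5, r3 = 0.5 at t=0 makes l = 0: e^(b*0) cos(0) = 1
        swarm = _swarm([[2.0], [2.0]], best=[5.0])
        woa_update(swarm, self.CONFIG,
                   ScriptedRNG([0.6, 0.3, 0.3, 0.5] * 2))
        # X* + |X* - X| = 5 + 3 = 8
        assert swarm.positions[0, 0] == pytest.approx(8.0)

    def test_zero_H_collapses_to_best(self):
        # p < 0.5 and r1 = 0.5 gives H = 0: pure convergence to X*
        swarm = _swarm([[2.0], [2.0]], best=[5.0])
        woa_update(swarm, self.CONFIG, ScriptedRNG([0.3, 0.5, 0.7] * 2))
        assert swarm.positions[0, 0] == pytest.approx(5.0)

    def test_branch_frequencies_match_partition(self):
        # at h = 2 (t=0): P(spiral)=.5, P(search)=.25, P(encircle)=.25
        config = OptimizerConfig(population_size=100, max_iters=10,
                                 bounds=((-5.0, 5.0),), variant="standard",
                                 seed=0)
        rng = np.random.default_rng(11)
        swarm = _swarm(rng.uniform(-5, 5, size=(100, 1)), best=[0.0])
        for _ in range(100):
            swarm.iteration = 0  # hold h at 2
            woa_update(swarm, config, rng)
        total = sum(swarm.branch_counts.values())
        assert total == 10 ** 4
        assert swarm.branch_counts["spiral"] / total == pytest.approx(
            0.5, abs=0.02)
        assert swarm.branch_counts["search"] / total == pytest.approx(
            0.25, abs=0.02)
        assert swarm.branch_counts["encircle"] / total == pytest.approx(
            0.25, abs=0.02)

    def test_positions_stay_within_bounds(self):
        config = OptimizerConfig(population_size=10, max_iters=50,
                                 bounds=((-1.0, 1.0), (0.0, 2.0)),
                                 variant="levy", seed=1)
        rng = np.random.default_rng(12)
        swarm = _swarm(rng.uniform(-1, 1, size=(10, 2)) * [1, 0] + [0, 1],
                       best=[0.0, 1.0])
        for _ in range(50):
            woa_update(swarm, config, rng)
        assert (swarm.positions[:, 0] >= -1).all()
        assert (swarm.positions[:, 0] <= 1).all()
        assert (swarm.positions[:, 1] >= 0).all()
        assert (swarm.positions[:, 1] <= 2).all()

    def test_no_random_search_past_linear_midpoint(self):
        """Once h <= 1 (t >= T/2 linearly) |H| < 1, so the exploration
        branch can never fire."""
        config = OptimizerConfig(population_size=10, max_iters=200,
                                 bounds=((-5.0, 5.0),), variant="standard",
                                 seed=2)
        rng = np.random.default_rng(13)
        swarm = _swarm(rng.uniform(-5, 5, size=(10, 1)), best=[0.0])
        searches_at_midpoint = None
        for t in range(200):
            if t == 100:
                searches_at_midpoint = swarm.branch_counts["search"]
            woa_update(swarm, config, rng)
        assert swarm.branch_counts["search"] == searches_at_midpoint


class TestOptimize:
    def test_sphere_reaches_near_zero(self):
        config = OptimizerConfig(population_size=20, max_iters=200,
                                 bounds=((-10.0, 10.0), (-10.0, 10.0)),
                                 variant="levy", seed=3)
        result = optimize(lambda x: float(np.sum(x ** 2)), config)
        assert result.best_fitness < 1e-3

    def test_quadratic_argmin_localized(self):
        config = OptimizerConfig(population_size=20, max_iters=200,
                                 bounds=((0.0, 10.0),), variant="levy",
                                 seed=4)
        result = optimize(lambda x: float((x[0] - 3.0) ** 2), config)
        assert result.best_position[0] == pytest.approx(3.0, abs=0.01)

    def test_trace_nonincreasing_and_deterministic(self):
        config = OptimizerConfig(population_size=10, max_iters=50,
                                 bounds=((-5.0, 5.0), (-5.0, 5.0)),
                                 variant="levy", seed=5)
        obj = lambda x: float(np.sum(x ** 2) + np.sin(x[0]))
        a = optimize(obj, config)
        b = optimize(obj, config)
        assert (np.diff(a.trace) <= 1e-15).all()
        assert np.array_equal(a.trace, b.trace)
        assert np.array_equal(a.best_position, b.best_position)

    def test_standard_variant_also_converges(self):
        config = OptimizerConfig(population_size=20, max_iters=200,
                                 bounds=((-10.0, 10.0), (-10.0, 10.0)),
                                 variant="standard", seed=6)
        result = optimize(lambda x: float(np.sum(x ** 2)), config)
        assert result.best_fitness < 1e-2


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        dict(population_size=1), dict(max_iters=0),
        dict(bounds=((1.0, 0.0),)), dict(beta=0.0), dict(beta=2.5),
        dict(variant="pso"),
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            OptimizerConfig(**kw)
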