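"""Objective, Hooke–Jeeves optimizer, and the multi-start fitting protocol."""

import numpy as np
import pytest

from fumet.estimation import (FitProtocol, TimecourseObjective, fit_quality_r2,
                              hooke_jeeves, multistart_fit)
from fumet.network import linear_chain_network
from fumet.simulator import simulate


def _chain_objective(kinetics, initial, keys, noise_sd=0.0, seed=None,
                     rtol=1e-8, atol=1e-9):
    net = linear_chain_network(list(kinetics), list(initial))
    t = np.arange(1.0, 17.0 + 1e-9, 1.0)
    traj = simulate(net, None, np.concatenate([[0.0], t]), rtol=rtol, atol=atol)
    data = traj.observables().iloc[1:]
    if noise_sd:
        rng = np.random.default_rng(seed)
        data = (data * (1 + rng.normal(0, noise_sd, data.shape))).clip(lower=0)
    return TimecourseObjective(net, data, keys, sim_rtol=rtol, sim_atol=atol)


class TestObjective:
    def test_zero_at_generating_parameters(self):
        obj = _chain_objective([(300.0, 400.0), (150.0, 200.0)],
                               [400.0, 100.0, 10.0],
                               [("r1", "V"), ("r2", "V")])
        assert obj(obj.current_x()) < 1e-12

    def test_linearity_in_weights(self):
        obj = _chain_objective([(300.0, 400.0)], [400.0, 10.0], [("r1", "V")])
        x = obj.current_x() + 0.1
        f1 = obj(x)
        obj.weights = {k: 2 * w for k, w in obj.weights.items()}
        assert obj(x) == pytest.approx(2 * f1, rel=1e-12)

    def test_minimum_located_at_generating_value_by_grid_scan(self):
        # dense 1-D scan is the independent oracle for the objective shape
        obj = _chain_objective([(300.0, 400.0)], [400.0, 10.0], [("r1", "V")])
        x_true = obj.current_x()[0]
        grid = np.linspace(x_true - 0.5, x_true + 0.5, 201)
        values = [obj(np.array([g])) for g in grid]
        assert abs(grid[int(np.argmin(values))] - x_true) <= 0.0051

    def test_simulation_failure_returns_inf(self):
        obj = _chain_objective([(300.0, 400.0)], [400.0, 10.0], [("r1", "V")])
        with pytest.warns(UserWarning, match="simulation failed"):
            f = obj(np.array([400.0]))  # 10**400 overflows the kinetics
        assert f == np.inf


class TestHookeJeeves:
    def test_convex_quadratic_converges(self):
        c = np.array([1.3, -2.1, 0.4])
        res = hooke_jeeves(lambda x: ((x - c) ** 2).sum(), np.zeros(3),
                           [(-5, 5)] * 3)
        assert res.converged
        assert np.abs(res.x - c).max() < 1e-4

    def test_returns_point_no_worse_than_start(self):
        f = lambda x: float(np.cos(3 * x[0]) + 0.1 * x[0] ** 2)
        x0 = np.array([2.0])
        res = hooke_jeeves(f, x0, [(-10, 10)])
        assert res.fx <= f(x0)

    def test_bound_active_optimum_is_flagged(self):
        res = hooke_jeeves(lambda x: float((x[0] - 10) ** 2),
                           np.array([0.0]), [(-1.0, 1.0)])
        assert res.x[0] == pytest.approx(1.0, abs=1e-6)
        assert res.at_bounds[0]

    def test_rosenbrock_beats_grid_refinement_oracle(self):
        ros = lambda x: float((1 - x[0]) ** 2 + 100 * (x[1] - x[0] ** 2) ** 2)
        res = hooke_jeeves(ros, np.array([-1.2, 1.0]), [(-2, 2)] * 2, it_lim=200)
        g = np.linspace(-2, 2, 200)
        grid_best = min(ros(np.array([a, b])) for a in g for b in g)
        assert res.fx <= grid_best

    def test_matches_grid_search_within_two_cells(self):
        f = lambda x: float((x[0] - 0.37) ** 2 + 2 * (x[1] + 1.21) ** 2
                            + 0.5 * x[0] * x[1])
        res = hooke_jeeves(f, np.array([1.5, 1.5]), [(-2, 2)] * 2, it_lim=200)
        g = np.linspace(-2, 2, 200)
        cell = g[1] - g[0]
        vals = np.array([[f(np.array([a, b])) for b in g] for a in g])
        i, j = np.unravel_index(np.argmin(vals), vals.shape)
        assert abs(res.x[0] - g[i]) <= 2 * cell
        assert abs(res.x[1] - g[j]) <= 2 * cell

    def test_nonfinite_start_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            hooke_jeeves(lambda x: np.inf, np.zeros(1), [(-1, 1)])

    def test_deterministic_given_start(self):
        f = lambda x: float((x ** 2).sum() + np.sin(x[0]))
        r1 = hooke_jeeves(f, np.array([0.7, -0.3]), [(-2, 2)] * 2)
        r2 = hooke_jeeves(f, np.array([0.7, -0.3]), [(-2, 2)] * 2)
        assert np.array_equal(r1.x, r2.x) and r1.fx == r2.fx


class TestMultistartFit:
    def test_two_parameter_noiseless_recovery_within_one_percent(self):
        obj = _chain_objective([(300.0, 400.0), (150.0, 200.0)],
                               [400.0, 100.0, 10.0],
                               [("r1", "V"), ("r2", "V")])
        x_true = obj.current_x()
        start = x_true + np.array([0.2, -0.2])
        res = multistart_fit(obj, FitProtocol(), n_attempts=20, start=start)
        assert np.abs(res.bfv / 10 ** x_true - 1).max() < 0.01
        assert np.all(np.isfinite(res.dev_stds))

    def test_objective_monotone_across_chained_attempts(self):
        obj = _chain_objective([(300.0, 400.0)], [400.0, 10.0], [("r1", "V")])
        start = obj.current_x() + 0.3
        res = multistart_fit(obj, FitProtocol(), n_attempts=10, start=start)
        assert all(b <= a + 1e-15 for a, b in zip(res.attempts, res.attempts[1:]))

    def test_identical_attempts_give_zero_spread_convention(self):
        obj = _chain_objective([(300.0, 400.0)], [400.0, 10.0], [("r1", "V")])
        res = multistart_fit(obj, FitProtocol(n_best_attempts=2),
                             n_attempts=5, start=obj.current_x())
        if np.any(res.stds == 0):
            assert np.all(res.dev_stds[res.stds == 0] == 0)

    def test_seeded_runs_are_bit_identical(self):
        results = []
        for _ in range(2):
            obj = _chain_objective([(300.0, 400.0)], [400.0, 10.0],
                                   [("r1", "V")])
            res = multistart_fit(obj, FitProtocol(), n_attempts=6, seed=11,
                                 bounds=[(1.0, 4.0)])
            results.append(res)
        assert np.array_equal(results[0].bfv, results[1].bfv)
        assert results[0].attempts == results[1].attempts

    def test_too_few_attempts_rejected(self):
        obj = _chain_objective([(300.0, 400.0)], [400.0, 10.0], [("r1", "V")])
        with pytest.raises(ValueError, match="n_attempts"):
            multistart_fit(obj, FitProtocol(), n_attempts=3)


def test_fit_quality_r2_on_converged_noisy_fit():
    obj = _chain_objective([(300.0, 400.0), (150.0, 200.0)],
                           [400.0, 100.0, 10.0],
                           [("r1", "V"), ("r2", "V")],
                           noise_sd=0.05, seed=5)
    start = obj.current_x() + np.array([0.15, -0.15])
    multistart_fit(obj, FitProtocol(), n_attempts=20, start=start)
    assert fit_quality_r2(obj) >= 0.99
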