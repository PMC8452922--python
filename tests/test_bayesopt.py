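import numpy as np
import pytest
from scipy import stats

from plaqueifem.bayesopt import (OptimizationRecord, SearchSpace, Surrogate,
                                 default_search_space, fit_gp, invert_gp,
                                 minimize)
from plaqueifem.errors import ConfigurationError, PlaqueIfemError
from plaqueifem.materials import check_yeoh_stability


def quadratic_cost(space, x_star):
    z_star = space.to_unit(np.asarray(x_star, dtype=float))

    def cost(x):
        return float(np.sum((space.to_unit(x) - z_star) ** 2))

    return cost


def test_search_space_round_trip_with_log_axes():
    space = default_search_space()
    x = np.array([1.34, 0.20, 0.36, 5.90, -0.27, 190.48])
    z = space.to_unit(x)
    assert np.all((0 <= z) & (z <= 1))
    assert np.allclose(space.from_unit(z), x, rtol=1e-12)
    # published fits all lie inside the default bounds
    from plaqueifem.reporting import packaged_fit_table
    t = packaged_fit_table()
    for _, r in t.iterrows():
        v = [r.c1_kPa, r.c2_kPa, r.c3_kPa]
        assert np.all(np.asarray(v) >= np.asarray(space.lower[:3]))
        assert np.all(np.asarray(v) <= np.asarray(space.upper[:3]))


def test_minimizer_finds_interior_quadratic_optimum():
    space = default_search_space()
    x_star = np.array([1.5, 10.0, 2.0, 8.0, -20.0, 150.0])
    rec = minimize(quadratic_cost(space, x_star), space, n_init=40, budget=200,
                   seed=2)
    assert rec.best_y < 1e-2
    assert np.all(np.abs(space.to_unit(rec.best_x) - space.to_unit(x_star))
                  < 0.05)


def test_minimizer_is_deterministic_for_fixed_seed():
    space = SearchSpace((0.0, 0.0), (1.0, 1.0))

    def cost(x):
        return float((x[0] - 0.4) ** 2 + (x[1] - 0.6) ** 2)

    a = minimize(cost, space, n_init=8, budget=20, seed=9)
    b = minimize(cost, space, n_init=8, budget=20, seed=9)
    assert np.array_equal(a.x, b.x)
    assert np.array_equal(a.y, b.y)


def test_constant_cost_does_not_crash():
    space = SearchSpace((0.0,), (1.0,))
    rec = minimize(lambda x: 1.0, space, n_init=5, budget=12, seed=0)
    assert np.all(rec.best_trace() == 1.0)


def test_budget_one_returns_single_unconverged_evaluation():
    space = SearchSpace((0.0,), (1.0,))
    rec = minimize(lambda x: float(x[0]), space, n_init=5, budget=1, seed=0)
    assert len(rec.y) == 1
    assert rec.termination == "budget"


def test_failed_evaluations_are_penalized_not_fatal():
    space = SearchSpace((0.0,), (1.0,))
    calls = []

    def cost(x):
        calls.append(x[0])
        if x[0] > 0.5:
            raise PlaqueIfemError("solver diverged")
        return float(x[0])

    rec = minimize(cost, space, n_init=8, budget=16, seed=1)
    assert rec.failed.any()
    assert np.all(rec.y[rec.failed] >= 10.0 * rec.y[~rec.failed].max())


def test_all_failures_raise():
    space = SearchSpace((0.0,), (1.0,))

    def cost(x):
        raise PlaqueIfemError("nope")

    with pytest.raises(PlaqueIfemError):
        minimize(cost, space, n_init=4, budget=6, seed=0)


def test_reject_mode_only_evaluates_stable_triplets():
    space = default_search_space()
    rec = minimize(quadratic_cost(space, [1.0, 0.0, 1.0, 5.0, 0.0, 100.0]),
                   space, n_init=20, budget=35, seed=4)
    for x in rec.x:
        assert check_yeoh_stability(*x[:3]).stable
        assert check_yeoh_stability(*x[3:]).stable


def test_best_trace_is_monotone_nonincreasing():
    space = default_search_space()
    rec = minimize(quadratic_cost(space, [1.0, 0.0, 1.0, 5.0, 0.0, 100.0]),
                   space, n_init=15, budget=40, seed=6)
    assert np.all(np.diff(rec.best_trace()) <= 0)


# ---------------------------------------------------------------- surrogate

def test_gp_posterior_mean_tracks_a_smooth_function():
    space = SearchSpace((0.0,), (2 * np.pi,))
    x = np.linspace(0.0, 2 * np.pi, 20)[:, None]
    y = 1.5 + np.sin(x[:, 0])
    sur = Surrogate(space, x, y, seed=0, n_restarts=3)
    held = np.linspace(0.3, 2 * np.pi - 0.3, 25)[:, None]
    rmse = np.sqrt(np.mean((sur.mean(held) - (1.5 + np.sin(held[:, 0]))) ** 2))
    assert rmse < 0.05
    assert np.all(sur.std(held) >= 0.0)
    # near-interpolation at the training inputs
    assert np.max(np.abs(sur.mean(x) - y)) < 0.05


def test_gp_predictions_invariant_to_data_ordering():
    space = SearchSpace((0.0,), (1.0,))
    rng = np.random.default_rng(3)
    x = rng.uniform(size=(15, 1))
    y = 1.0 + x[:, 0] ** 2
    perm = rng.permutation(15)
    a = Surrogate(space, x, y, seed=0, n_restarts=0)
    b = Surrogate(space, x[perm], y[perm], seed=0, n_restarts=0)
    q = np.linspace(0, 1, 11)[:, None]
    assert np.allclose(a.mean(q), b.mean(q), rtol=1e-4)


def test_gp_requires_two_distinct_points():
    space = SearchSpace((0.0,), (1.0,))
    with pytest.raises(ConfigurationError):
        Surrogate(space, np.array([[0.5], [0.5]]), np.array([1.0, 1.0]))


# ---------------------------------------------------------------- inversion

@pytest.fixture(scope="module")
def parabola_surrogate():
    space = SearchSpace((-1.0,), (1.0,))
    x = np.linspace(-1.0, 1.0, 41)[:, None]
    sur = Surrogate(space, x, x[:, 0] ** 2, seed=1, n_restarts=3)
    return space, sur


def test_inversion_concentrates_in_the_analytic_sublevel_set(parabola_surrogate):
    """For f(x) = x^2 with threshold 0.05 the sub-level set is
    |x| <= sqrt(0.05) ~ 0.224."""
    space, sur = parabola_surrogate
    rep = invert_gp(sur, 0.0, space, n_samples=300, seed=3,
                    best_parameters=[0.0])
    inside = np.abs(rep.samples[:, 0]) <= 0.3
    assert inside.mean() > 0.95
    assert abs(np.median(rep.samples[:, 0])) < 0.1
    assert rep.agreement[0]


def test_inversion_with_infinite_threshold_is_uniform(parabola_surrogate):
    space, sur = parabola_surrogate
    rep = invert_gp(sur, 0.0, space, n_samples=400, seed=5,
                    threshold=np.inf, best_parameters=[0.0])
    u = (rep.samples[:, 0] + 1.0) / 2.0
    _, pvalue = stats.kstest(u, "uniform")
    assert pvalue > 0.01


def test_inversion_is_deterministic_and_detects_empty_sets(parabola_surrogate):
    space, sur = parabola_surrogate
    a = invert_gp(sur, 0.0, space, n_samples=50, seed=7, best_parameters=[0.0])
    b = invert_gp(sur, 0.0, space, n_samples=50, seed=7, best_parameters=[0.0])
    assert np.array_equal(a.samples, b.samples)
    with pytest.raises(ConfigurationError):
        invert_gp(sur, 0.0, space, n_samples=10, seed=1, threshold=-1.0)


def test_fit_gp_from_record():
    space = SearchSpace((0.0,), (1.0,))
    x = np.linspace(0, 1, 12)[:, None]
    rec = OptimizationRecord(x=x, y=1.0 + (x[:, 0] - 0.4) ** 2,
                             failed=np.zeros(12, bool), n_init=12, seed=0,
                             termination="budget", space=space)
    sur = fit_gp(rec)
    assert abs(sur.mean([[0.4]])[0] - 1.0) < 0.05
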