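import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pkaswarm.optimizer import (
    MODE_SELF_ADAPTIVE,
    OptimizerConfig,
    Particle,
    adaptive_inertia,
    assign_subgroups,
    convergence_params,
    divergence_inertia,
    optimize,
    plain_pso_config,
    population_entropy,
    random_search,
    update_position,
    update_velocity,
)

from conftest import sphere


def make_particle(x, v, pbest):
    return Particle(
        position=np.asarray(x, float),
        velocity=np.asarray(v, float),
        best_position=np.asarray(pbest, float),
    )


# ---------------------------------------------------------------------------
# elementary update rules
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "x, v, pbest, gbest, omega, c1, c2, expected",
    [
        ((1.0, 2.0), (0.0, 0.0), (1.0, 2.0), (1.0, 2.0), 0.3, 1.7, 2.1, (0.0, 0.0)),
        ((0.0, 0.0), (2.0, -1.0), (0.0, 0.0), (0.0, 0.0), 1.0, 0.0, 0.0, (2.0, -1.0)),
        ((0.0,), (1.0,), (2.0,), (4.0,), 0.5, 1.0, 1.0, (6.5,)),
    ],
)
def test_update_velocity_examples(x, v, pbest, gbest, omega, c1, c2, expected):
    p = make_particle(x, v, pbest)
    np.testing.assert_allclose(
        update_velocity(p, np.asarray(gbest, float), omega, c1, c2), expected
    )


def test_update_velocity_dimension_mismatch():
    p = make_particle((0.0, 0.0), (0.0, 0.0), (0.0, 0.0))
    with pytest.raises(ValueError, match="dimension"):
        update_velocity(p, np.zeros(3), 0.5, 1.0, 1.0)


def test_update_velocity_clamps_to_max_speed():
    p = make_particle((0.0,), (0.0,), (100.0,))
    v = update_velocity(p, np.array([100.0]), 0.5, 1.0, 1.0, v_max=np.array([3.0]))
    assert v[0] == pytest.approx(3.0)


@pytest.mark.parametrize(
    "x, v, bounds, expected",
    [
        ((1.0, 2.0), (0.0, 0.0), None, (1.0, 2.0)),
        ((1.0,), (-3.0,), (np.array([0.0]), np.array([10.0])), (0.0,)),
        ((0.0, 0.0), (1.0, 1.0), None, (1.0, 1.0)),
    ],
)
def test_update_position_examples(x, v, bounds, expected):
    p = make_particle(x, np.zeros_like(np.asarray(x, float)), x)
    np.testing.assert_allclose(update_position(p, np.asarray(v, float), bounds), expected)


def test_adaptive_inertia_schedule():
    cfg = OptimizerConfig(omega_max=0.9, omega_min=0.4, it_max=100)
    assert adaptive_inertia(0.0, 1.0, 0, cfg) == pytest.approx(0.9)
    assert adaptive_inertia(0.0, 1.0, 100, cfg) == pytest.approx(0.4)
    # Pgbest/Plbest_ave = 1 at k=0 gives raw -0.1, clamped up to omega_min
    assert adaptive_inertia(1.0, 1.0, 0, cfg) == pytest.approx(0.4)


def test_adaptive_inertia_zero_denominator_falls_back_linear():
    cfg = OptimizerConfig(omega_max=0.9, omega_min=0.4, it_max=100)
    with pytest.warns(RuntimeWarning, match="linear"):
        val = adaptive_inertia(0.0, 0.0, 50, cfg)
    assert val == pytest.approx(0.9 - 0.5 * 0.5)


def test_convergence_params_values_and_bounds():
    omega, phi = convergence_params(2.0 / math.pi)
    assert (omega, phi) == (pytest.approx(0.65), pytest.approx(0.1))
    omega, phi = convergence_params(1.0 / math.pi)
    assert omega == pytest.approx(0.0, abs=1e-12)
    assert phi == pytest.approx(0.0, abs=1e-12)
    for e in (0.01, 0.5, 1.0, 3.3, 100.0):
        omega, phi = convergence_params(e)
        assert 0.0 <= omega <= 0.65 and 0.0 <= phi <= 0.1
    with pytest.raises(ValueError):
        convergence_params(0.0)


def test_divergence_inertia_values_cap_and_limit():
    cfg = OptimizerConfig(lambda_div=2.0, omega_div_max=1.5)
    assert divergence_inertia(1.0, 0.1, cfg) == pytest.approx(1.2)
    assert divergence_inertia(5.0, 0.0, cfg) == pytest.approx(1.0)
    assert divergence_inertia(1e6, 0.1, cfg) == pytest.approx(1.0, abs=1e-6)
    assert divergence_inertia(0.01, 3.0, cfg) == pytest.approx(1.5)  # capped


# ---------------------------------------------------------------------------
# entropy machinery
# ---------------------------------------------------------------------------


def test_assign_subgroups_identical_and_single_group():
    pos = np.ones((6, 3))
    np.testing.assert_array_equal(assign_subgroups(pos, 4), np.zeros(6, dtype=int))
    np.testing.assert_array_equal(
        assign_subgroups(np.random.default_rng(0).normal(size=(5, 2)), 1),
        np.zeros(5, dtype=int),
    )


def test_assign_subgroups_even_line_gives_equal_bins():
    pos = np.column_stack([np.arange(8.0), np.zeros(8)])
    labels = assign_subgroups(pos, 4)
    np.testing.assert_array_equal(labels, [0, 0, 1, 1, 2, 2, 3, 3])


def test_assign_subgroups_with_bounds_tracks_concentration():
    """A swarm filling the box spreads over many cells; a contracted swarm
    concentrates into few, so its entropy drops."""
    lo, hi = np.full(3, -10.0), np.full(3, 10.0)
    rng = np.random.default_rng(0)
    wide = rng.uniform(-10, 10, size=(60, 3))
    tight = rng.uniform(2.5, 2.7, size=(60, 3))  # off-centre, inside one cell
    e_wide = population_entropy(assign_subgroups(wide, 10, bounds=(lo, hi)), 10)
    e_tight = population_entropy(assign_subgroups(tight, 10, bounds=(lo, hi)), 10)
    assert e_wide > 2.0
    assert e_tight < 0.5
    assert e_tight < e_wide


@pytest.mark.parametrize(
    "labels, Q, expected",
    [
        ([0, 0, 1, 1, 2, 2, 3, 3], 4, 2.0),
        ([1] * 9, 4, 0.0),
        ([0, 0, 0, 0, 1, 1, 2, 3], 4, 1.75),
    ],
)
def test_population_entropy_hand_values(labels, Q, expected):
    assert population_entropy(labels, Q) == pytest.approx(expected)


def test_population_entropy_rejects_bad_input():
    with pytest.raises(ValueError):
        population_entropy([], 4)
    with pytest.raises(ValueError):
        population_entropy([0, 4], 4)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    labels=st.lists(st.integers(0, 7), min_size=1, max_size=60),
)
def test_population_entropy_bounds_and_extremes(labels):
    """0 <= E <= log2(Q); zero iff one subgroup; log2(Q) iff all counts equal."""
    Q = 8
    e = population_entropy(labels, Q)
    assert -1e-12 <= e <= math.log2(Q) + 1e-12
    counts = np.bincount(labels, minlength=Q)
    if len(set(labels)) == 1:
        assert e == pytest.approx(0.0, abs=1e-12)
    nonzero = counts[counts > 0]
    if len(nonzero) == Q and len(set(nonzero)) == 1:
        assert e == pytest.approx(math.log2(Q))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def test_config_validation_errors():
    with pytest.raises(ValueError):
        OptimizerConfig(m=1)
    with pytest.raises(ValueError):
        OptimizerConfig(omega_min=0.9, omega_max=0.4)
    with pytest.raises(ValueError):
        OptimizerConfig(E_low=2.0, E_high=1.0)
    with pytest.raises(ValueError):
        OptimizerConfig(lambda_div=0.0)


def test_config_default_entropy_thresholds_scale_with_Q():
    cfg = OptimizerConfig(Q=16)
    e_low, e_high = cfg.entropy_thresholds()
    assert e_low == pytest.approx(0.3 * 4.0)
    assert e_high == pytest.approx(0.7 * 4.0)


def test_config_yaml_roundtrip(tmp_path):
    cfg = OptimizerConfig(m=17, it_max=123, E_low=0.5, E_high=2.5, seed=9)
    path = tmp_path / "opt.yaml"
    import yaml

    path.write_text(yaml.safe_dump(cfg.to_dict()))
    loaded = OptimizerConfig.from_yaml(path)
    assert loaded == cfg


# ---------------------------------------------------------------------------
# the optimizer loop
# ---------------------------------------------------------------------------


def test_constant_objective_gbest_fixed_from_first_iteration(tiny_config):
    result = optimize(lambda x: 7.5, tiny_config, dim=3)
    assert result.best_fitness == 7.5
    assert (result.trace["global_best_fitness"] == 7.5).all()


def test_optimize_is_bit_reproducible():
    cfg = OptimizerConfig(m=12, it_max=30, seed=42)
    r1 = optimize(lambda x: float(np.sum(x**2)), cfg, dim=3)
    r2 = optimize(lambda x: float(np.sum(x**2)), cfg, dim=3)
    np.testing.assert_array_equal(r1.best_position, r2.best_position)
    assert r1.best_fitness == r2.best_fitness
    assert r1.trace.equals(r2.trace)


def test_global_best_is_monotone_nonincreasing():
    cfg = OptimizerConfig(m=15, it_max=80, seed=3)
    result = optimize(sphere, cfg, dim=4, vectorized=True)
    g = result.trace["global_best_fitness"].to_numpy()
    assert np.all(np.diff(g) <= 0.0)


def test_non_finite_objective_treated_as_worst():
    def nasty(x):
        return math.inf if x[0] > 0 else float(np.sum(x**2))

    cfg = OptimizerConfig(m=10, it_max=20, seed=1)
    with pytest.warns(RuntimeWarning, match="non-finite"):
        result = optimize(nasty, cfg, dim=2)
    assert math.isfinite(result.best_fitness)


def test_trace_schema_and_modes():
    cfg = OptimizerConfig(m=20, it_max=60, seed=0)
    result = optimize(sphere, cfg, dim=3, vectorized=True)
    assert list(result.trace.columns) == [
        "iteration",
        "entropy_bits",
        "mode",
        "global_best_fitness",
        "omega",
        "c1",
        "c2",
        "dispersion",
    ]
    assert set(result.trace["mode"]).issubset(
        {"converge", "diverge", "self_adaptive"}
    )
    assert (result.trace["entropy_bits"] >= 0).all()
    assert (result.trace["entropy_bits"] <= math.log2(cfg.Q) + 1e-12).all()


def test_min_error_stops_early():
    cfg = OptimizerConfig(m=30, it_max=2000, min_error=1e-3, seed=0)
    result = optimize(sphere, cfg, dim=2, vectorized=True)
    assert result.best_fitness <= 1e-3
    assert len(result.trace) < 2000


def test_sphere_reaches_global_minimum_region():
    """With default study parameters the optimizer solves the 5-d sphere to
    1e-4 in at least 19 of 20 seeded runs."""
    finals = []
    for seed in range(20):
        cfg = OptimizerConfig(seed=seed)
        finals.append(optimize(sphere, cfg, dim=5, vectorized=True).best_fitness)
    assert sum(f <= 1e-4 for f in finals) >= 19


def test_pure_convergence_strategy_halves_dispersion_per_window():
    """Contraction parameters shrink swarm spread by >=50% over every
    100-iteration window (while above the numerical floor)."""
    for seed in range(10):
        cfg = OptimizerConfig(
            m=30,
            it_max=200,
            seed=seed,
            constant_inertia=0.65,
            constant_factors=(0.05, 0.05),
            min_error=0.0,
        )
        disp = optimize(sphere, cfg, dim=5, vectorized=True).trace[
            "dispersion"
        ].to_numpy()
        for k in range(0, 100, 20):
            if disp[k] < 1e-12:
                break
            assert disp[k + 100] <= 0.5 * disp[k]


def test_pure_divergence_strategy_grows_dispersion():
    for seed in range(10):
        cfg = OptimizerConfig(m=30, it_max=50, seed=seed, constant_inertia=1.2,
                              min_error=0.0)
        init = np.random.default_rng(seed).uniform(-0.5, 0.5, (30, 5))
        disp = optimize(
            sphere, cfg, dim=5, init_positions=init, vectorized=True
        ).trace["dispersion"].to_numpy()
        assert disp[-1] > disp[0]


def test_reduces_to_plain_pso_with_constant_coefficients():
    """Entropy branching off + constant factors => trajectories identical to
    an independently coded classical PSO (Eqs. of motion plus the documented
    clamp and boundary rules)."""
    m, dim, iters, seed = 8, 2, 10, 3
    lo, hi = np.full(dim, -100.0), np.full(dim, 100.0)
    omega, c1, c2 = 0.7, 1.2, 1.7

    def obj(x):
        return float((x[0] - 1.0) ** 2 + (x[1] + 2.0) ** 2)

    cfg = OptimizerConfig(
        m=m,
        it_max=iters,
        seed=seed,
        bounds=(-100.0, 100.0),
        force_mode=MODE_SELF_ADAPTIVE,
        constant_factors=(c1, c2),
        constant_inertia=omega,
        min_error=0.0,
    )
    result = optimize(obj, cfg, dim=dim)

    # --- independent reference ---
    rng = np.random.default_rng(seed)
    span = hi - lo
    X = rng.uniform(lo, hi, (m, dim))
    V = rng.uniform(-1.0, 1.0, (m, dim)) * (0.1 * span)
    v_max = 0.2 * span
    fit = np.array([obj(x) for x in X])
    pbest, pfit = X.copy(), fit.copy()
    gi = int(np.argmin(pfit))
    gbest, gfit = pbest[gi].copy(), float(pfit[gi])
    trace = []
    for _ in range(iters):
        V = omega * V + c1 * (pbest - X) + c2 * (gbest - X)
        V = np.clip(V, -v_max, v_max)
        X = X + V
        oob = (X < lo) | (X > hi)
        X = np.clip(X, lo, hi)
        V[oob] = 0.0
        fit = np.array([obj(x) for x in X])
        better = fit < pfit
        pbest[better] = X[better]
        pfit[better] = fit[better]
        gi = int(np.argmin(pfit))
        if pfit[gi] < gfit:
            gbest, gfit = pbest[gi].copy(), float(pfit[gi])
        trace.append(gfit)

    np.testing.assert_allclose(
        result.trace["global_best_fitness"].to_numpy(), trace, rtol=0, atol=1e-12
    )
    np.testing.assert_allclose(result.best_position, gbest, rtol=0, atol=1e-12)


def test_random_search_budget_and_determinism():
    cfg = OptimizerConfig(m=10, it_max=25, seed=7, min_error=0.0)
    r1 = random_search(sphere, cfg, dim=3, vectorized=True)
    r2 = random_search(sphere, cfg, dim=3, vectorized=True)
    assert r1.n_evaluations == 250
    assert r1.best_fitness == r2.best_fitness
    g = r1.trace["global_best_fitness"].to_numpy()
    assert np.all(np.diff(g) <= 0.0)


def test_plain_pso_config_flags():
    cfg = plain_pso_config(base=OptimizerConfig(m=9, seed=2))
    assert cfg.force_mode == MODE_SELF_ADAPTIVE
    assert cfg.constant_inertia is not None
    assert cfg.constant_factors is not None
    assert cfg.randomize_accel
    assert cfg.m == 9 and cfg.seed == 2


def test_init_positions_override_is_clipped_and_used():
    cfg = OptimizerConfig(m=6, it_max=5, seed=0, bounds=(-1.0, 1.0), min_error=0.0)
    init = np.full((6, 2), 100.0)  # far outside the box
    result = optimize(sphere, cfg, dim=2, init_positions=init, vectorized=True)
    assert result.best_fitness <= 2.0 + 1e-9  # clipped to the corner (1, 1)
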