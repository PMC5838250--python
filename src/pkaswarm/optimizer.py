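"""Chaotic self-adaptive PSO with population-entropy-driven convergence/divergence.

This module implements the CSAPSO-EDCD optimizer: a particle swarm whose
inertia weight and learning factors are switched each iteration according to
the Shannon entropy of the particle distribution.

Every iteration the swarm is partitioned into ``Q`` disjoint subgroups and
the population entropy ``E_t = -sum p_i log2 p_i`` (``p_i`` = subgroup
occupancy fraction) is computed.  Three regimes follow:

* ``E_t > E_high`` — the swarm is widely dispersed (exploring); a
  *convergence* parameter set ``omega = 0.65 |sin(1/E_t)|``,
  ``phi = 0.1 |sin(1/E_t)|`` (``phi`` = c1 + c2) contracts it toward the
  incumbent bests.
* ``E_t < E_low`` — the swarm has collapsed (exploiting); a *divergence*
  inertia ``omega = 1 + lambda * phi / E_t`` (> 1) re-expands it.
* otherwise — a chaotic *self-adaptive* regime: inertia from a
  fitness-ratio schedule and learning factors drawn from seeded Lorenz
  chaotic streams, one stream per particle (see :mod:`pkaswarm.lorenz`).

The velocity update is the standard PSO rule

    v <- omega * v + c1 * (p_i - x) + c2 * (p_g - x)

deliberately *without* the classical uniform random multipliers on the
attraction terms: the chaotic learning factors supply the stochasticity.
``OptimizerConfig.randomize_accel`` restores the classical randomized update
for plain-PSO baselines.

Minimization convention throughout.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .lorenz import ChaoticFactorBank, LORENZ_PARAMS

__all__ = [
    "Particle",
    "SwarmState",
    "OptimizerConfig",
    "OptimizeResult",
    "MODE_CONVERGE",
    "MODE_DIVERGE",
    "MODE_SELF_ADAPTIVE",
    "update_velocity",
    "update_position",
    "adaptive_inertia",
    "assign_subgroups",
    "population_entropy",
    "convergence_params",
    "divergence_inertia",
    "optimize",
    "random_search",
    "plain_pso_config",
    "save_trace",
]

_logger = logging.getLogger(__name__)

MODE_CONVERGE = "converge"
MODE_DIVERGE = "diverge"
MODE_SELF_ADAPTIVE = "self_adaptive"

TRACE_COLUMNS = [
    "iteration",
    "entropy_bits",
    "mode",
    "global_best_fitness",
    "omega",
    "c1",
    "c2",
    "dispersion",
]


@dataclass
class Particle:
    """One swarm member: current state plus personal-best memory."""

    position: np.ndarray
    velocity: np.ndarray
    best_position: np.ndarray
    best_fitness: float = math.inf

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.best_position = np.asarray(self.best_position, dtype=float)
        d = self.position.shape
        if self.velocity.shape != d or self.best_position.shape != d:
            raise ValueError("position, velocity and best_position must share dimension")


@dataclass
class SwarmState:
    """Snapshot of the whole swarm at one iteration."""

    particles: list[Particle]
    global_best_position: np.ndarray
    global_best_fitness: float
    iteration: int = 0
    entropy: float = 0.0
    mode: str = MODE_SELF_ADAPTIVE


@dataclass
class OptimizerConfig:
    """Tunable parameters of the CSAPSO-EDCD optimizer.

    Field names mirror the on-disk configuration-file keys exactly; see
    :meth:`from_yaml`.  Defaults are the study conditions: 50 particles,
    2000 iterations, minimum-error stop 1e-7, Lorenz parameters
    (10, 8/3, 28), divergence coefficient lambda = 2.
    """

    m: int = 50
    it_max: int = 2000
    min_error: float = 1e-7
    omega_max: float = 0.9
    omega_min: float = 0.4
    E_high: Optional[float] = None  # default 0.7 * log2(Q)
    E_low: Optional[float] = None  # default 0.3 * log2(Q)
    lambda_div: float = 2.0
    Q: int = 10
    lorenz_params: tuple[float, float, float] = LORENZ_PARAMS
    lorenz_dt: float = 0.01
    lorenz_burn_in: int = 1000
    lorenz_stride: int = 10
    factor_range: tuple[float, float] = (0.5, 2.5)
    omega_div_max: float = 1.5
    velocity_clamp_frac: float = 0.2
    bounds: tuple = (-10.0, 10.0)
    seed: int = 0
    # --- behaviour switches, mainly for baselines and diagnostics ---
    force_mode: Optional[str] = None
    constant_factors: Optional[tuple[float, float]] = None
    constant_inertia: Optional[float] = None
    randomize_accel: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.m < 2:
            raise ValueError("m (particle count) must be >= 2")
        if self.it_max < 1:
            raise ValueError("it_max must be >= 1")
        if not (0 <= self.omega_min < self.omega_max):
            raise ValueError("need 0 <= omega_min < omega_max")
        if self.lambda_div <= 0:
            raise ValueError("lambda_div must be positive")
        if self.Q < 1:
            raise ValueError("Q must be >= 1")
        e_low, e_high = self.entropy_thresholds()
        max_e = math.log2(self.Q) if self.Q > 1 else 0.0
        if self.Q > 1 and not (0 <= e_low < e_high <= max_e + 1e-12):
            raise ValueError("need 0 <= E_low < E_high <= log2(Q)")
        if self.force_mode not in (None, MODE_CONVERGE, MODE_DIVERGE, MODE_SELF_ADAPTIVE):
            raise ValueError(f"unknown force_mode {self.force_mode!r}")

    def entropy_thresholds(self) -> tuple[float, float]:
        """(E_low, E_high) in bits, defaulting to (0.3, 0.7) * log2(Q)."""
        max_e = math.log2(self.Q) if self.Q > 1 else 1.0
        e_high = 0.7 * max_e if self.E_high is None else self.E_high
        e_low = 0.3 * max_e if self.E_low is None else self.E_low
        return e_low, e_high

    def resolve_bounds(self, dim: int) -> tuple[np.ndarray, np.ndarray]:
        """Per-dimension (lower, upper) arrays from scalar or vector bounds."""
        lower, upper = self.bounds
        lo = np.broadcast_to(np.asarray(lower, dtype=float), (dim,)).copy()
        hi = np.broadcast_to(np.asarray(upper, dtype=float), (dim,)).copy()
        if np.any(lo >= hi):
            raise ValueError("lower bounds must be strictly below upper bounds")
        return lo, hi

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["lorenz_params"] = list(self.lorenz_params)
        d["factor_range"] = list(self.factor_range)
        if isinstance(d["bounds"], tuple):
            d["bounds"] = [
                b.tolist() if isinstance(b, np.ndarray) else b for b in d["bounds"]
            ]
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "OptimizerConfig":
        kwargs = dict(data)
        for key in ("lorenz_params", "factor_range", "bounds", "constant_factors"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "OptimizerConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a key-value mapping")
        return cls.from_dict(data)


@dataclass
class OptimizeResult:
    """Outcome of one optimizer run: best solution plus per-iteration trace."""

    best_position: np.ndarray
    best_fitness: float
    trace: pd.DataFrame
    n_evaluations: int = 0

    def __iter__(self):  # allow tuple unpacking (pos, fit, trace)
        return iter((self.best_position, self.best_fitness, self.trace))


# ---------------------------------------------------------------------------
# elementary update rules
# ---------------------------------------------------------------------------


def update_velocity(
    particle: Particle,
    global_best: np.ndarray,
    omega: float,
    c1: float,
    c2: float,
    v_max: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Standard PSO velocity rule (no random multipliers), optionally clamped."""
    g = np.asarray(global_best, dtype=float)
    if g.shape != particle.position.shape:
        raise ValueError("global_best dimension does not match particle dimension")
    for val in (omega, c1, c2):
        if not np.isfinite(val):
            raise ValueError("omega, c1, c2 must be finite")
    v = (
        omega * particle.velocity
        + c1 * (particle.best_position - particle.position)
        + c2 * (g - particle.position)
    )
    if v_max is not None:
        v = np.clip(v, -v_max, v_max)
    return v


def update_position(
    particle: Particle,
    new_velocity: np.ndarray,
    bounds: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> np.ndarray:
    """Position rule ``x + v`` with the clip-to-bounds boundary rule."""
    v = np.asarray(new_velocity, dtype=float)
    if v.shape != particle.position.shape:
        raise ValueError("velocity dimension does not match particle dimension")
    x = particle.position + v
    if bounds is not None:
        lo, hi = bounds
        x = np.clip(x, lo, hi)
    return x


def adaptive_inertia(
    pgbest_k: float, plbest_ave: float, k: int, config: OptimizerConfig
) -> float:
    """Self-adaptive inertia schedule.

    ``omega = omega_max - Pgbest(k)/Plbest_ave - (omega_max - omega_min) * k/k_max``
    clamped into [omega_min, omega_max].  ``Plbest_ave`` is the mean of the
    current personal-best fitnesses; if it is zero the fitness-ratio term is
    dropped and a plain linear decay is used (with a warning).
    """
    linear = (config.omega_max - config.omega_min) * k / config.it_max
    if plbest_ave == 0.0:
        warnings.warn(
            "adaptive_inertia: mean personal-best fitness is zero; "
            "falling back to the linear inertia schedule",
            RuntimeWarning,
            stacklevel=2,
        )
        raw = config.omega_max - linear
    else:
        raw = config.omega_max - pgbest_k / plbest_ave - linear
    return float(min(max(raw, config.omega_min), config.omega_max))


def assign_subgroups(
    positions: Sequence, Q: int, bounds=None
) -> np.ndarray:
    """Partition particles into ``Q`` subgroups for the entropy measure.

    The grouping projects positions onto their first principal axis and bins
    the projections into ``Q`` equal-width cells.  Deterministic given the
    positions (the principal axis sign is fixed by making its
    largest-magnitude component positive).

    With ``bounds`` given (per-dimension ``(lower, upper)`` arrays, as the
    optimizer supplies), the cells cover the *projection of the search box*,
    so the entropy genuinely tracks swarm concentration: a swarm contracting
    into a small region ends up in ever fewer cells and its entropy falls.
    Without bounds the cells cover the observed span of the projections, a
    scale-free variant useful for inspecting a swarm in isolation.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.size == 0:
        raise ValueError("positions must be non-empty")
    if pos.ndim == 1:
        pos = pos.reshape(-1, 1)
    n = pos.shape[0]
    if Q < 1:
        raise ValueError("Q must be >= 1")
    if Q == 1 or n == 1:
        return np.zeros(n, dtype=int)
    centered = pos - pos.mean(axis=0)
    if pos.shape[1] == 1:
        axis = np.ones(1)
        proj = centered[:, 0]
    else:
        # leading right singular vector = first principal axis
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        axis = vt[0]
        pivot = int(np.argmax(np.abs(axis)))
        if axis[pivot] < 0:
            axis = -axis
        proj = centered @ axis
    if bounds is not None:
        lo = np.asarray(bounds[0], dtype=float).ravel()
        hi = np.asarray(bounds[1], dtype=float).ravel()
        # the box projects onto the axis as an interval of this half-width
        # around the box centre; proj is relative to the swarm mean, so
        # re-centre on the box centre first
        half = 0.5 * float(np.abs(axis) @ (hi - lo))
        shift = float((pos.mean(axis=0) - 0.5 * (lo + hi)) @ axis)
        left, span = -half - shift, 2.0 * half
    else:
        left, span = proj.min(), proj.max() - proj.min()
    if span <= 1e-300:
        return np.zeros(n, dtype=int)
    labels = np.floor((proj - left) / span * Q).astype(int)
    return np.clip(labels, 0, Q - 1)


def population_entropy(subgroup_labels: Sequence[int], Q: int) -> float:
    """Shannon entropy (bits) of the subgroup occupancy distribution.

    Returns ``-sum p_i log2 p_i`` over non-empty subgroups; lies in
    [0, log2(Q)].
    """
    labels = np.asarray(subgroup_labels, dtype=int)
    if labels.size == 0:
        raise ValueError("subgroup label vector must be non-empty")
    if np.any(labels < 0) or np.any(labels >= Q):
        raise ValueError("labels must lie in [0, Q)")
    counts = np.bincount(labels, minlength=Q)
    p = counts[counts > 0] / labels.size
    return float(-(p * np.log2(p)).sum())


def convergence_params(E_t: float) -> tuple[float, float]:
    """Convergence-regime parameters ``(omega, phi)``.

    ``omega = 0.65 |sin(1/E_t)|`` and ``phi = 0.1 |sin(1/E_t)|`` with
    ``phi = c1 + c2``; the pair always satisfies the convergence condition
    (inertia < 1, learning-factor sum < 3).  Requires ``E_t > 0``.
    """
    if E_t <= 0:
        raise ValueError("convergence_params requires E_t > 0")
    s = abs(math.sin(1.0 / E_t))
    return 0.65 * s, 0.1 * s


def divergence_inertia(E_t: float, phi: float, config: OptimizerConfig) -> float:
    """Divergence-regime inertia ``1 + lambda * phi / E_t``, capped.

    Strictly above 1 for ``phi > 0`` (particles spread); capped at
    ``omega_div_max`` because an uncapped value explodes velocities within a
    few iterations.  A non-positive entropy is floored at ``E_low``.
    """
    if phi < 0:
        raise ValueError("phi must be >= 0")
    if E_t <= 0:
        e_low, _ = config.entropy_thresholds()
        _logger.debug("divergence_inertia: non-positive entropy floored at E_low")
        E_t = max(e_low, 1e-12)
    omega = 1.0 + config.lambda_div * phi / E_t
    return float(min(omega, config.omega_div_max))


# ---------------------------------------------------------------------------
# main loop
# ---------------------------------------------------------------------------


def _evaluate(objective: Callable, X: np.ndarray, vectorized: bool) -> np.ndarray:
    if vectorized:
        vals = np.asarray(objective(X), dtype=float).ravel()
        if vals.shape != (X.shape[0],):
            raise ValueError("vectorized objective must return one value per row")
    else:
        vals = np.array([float(objective(x)) for x in X])
    bad = ~np.isfinite(vals)
    if bad.any():
        warnings.warn(
            f"objective returned non-finite values for {int(bad.sum())} particle(s); "
            "treated as +inf",
            RuntimeWarning,
            stacklevel=3,
        )
        vals = np.where(bad, np.inf, vals)
    return vals


def optimize(
    objective: Callable,
    config: OptimizerConfig,
    dim: Optional[int] = None,
    init_positions: Optional[np.ndarray] = None,
    vectorized: bool = False,
) -> OptimizeResult:
    """Run the CSAPSO-EDCD loop and return the best solution plus trace.

    Parameters
    ----------
    objective
        Function mapping a position vector to a finite scalar (minimized).
        With ``vectorized=True`` it receives the full ``(m, d)`` position
        matrix and must return ``m`` values.
    config
        Optimizer parameters; ``config.bounds`` defines the search box.
    dim
        Problem dimension; required when ``config.bounds`` is a scalar pair.
    init_positions
        Optional ``(k, d)`` array overriding the first ``k`` initial
        particle positions (used e.g. to inject anchor solutions).

    The loop per iteration: measure population entropy, pick the regime
    (converge / diverge / self-adaptive), update velocities and positions,
    re-evaluate, and update personal/global bests.  Stops at ``it_max``
    iterations or when the global best fitness drops to ``min_error``.
    Bit-reproducible given ``config.seed``.
    """
    if dim is None:
        lower = np.asarray(config.bounds[0], dtype=float)
        if lower.ndim == 0:
            raise ValueError("dim is required when bounds are scalar")
        dim = lower.size
    lo, hi = config.resolve_bounds(dim)
    span = hi - lo
    v_max = config.velocity_clamp_frac * span
    e_low, e_high = config.entropy_thresholds()

    rng = np.random.default_rng(config.seed)
    X = rng.uniform(lo, hi, size=(config.m, dim))
    V = rng.uniform(-1.0, 1.0, size=(config.m, dim)) * (0.1 * span)
    if init_positions is not None:
        init_positions = np.asarray(init_positions, dtype=float)
        k = init_positions.shape[0]
        X[:k] = np.clip(init_positions, lo, hi)

    chaos: Optional[ChaoticFactorBank] = None
    if config.constant_factors is None:
        chaos = ChaoticFactorBank(
            n_streams=config.m,
            seed=config.seed + 1,
            dt=config.lorenz_dt,
            stride=config.lorenz_stride,
            burn_in=config.lorenz_burn_in,
            params=config.lorenz_params,
            factor_range=config.factor_range,
        )

    fit = _evaluate(objective, X, vectorized)
    pbest = X.copy()
    pbest_fit = fit.copy()
    g_idx = int(np.argmin(pbest_fit))
    gbest = pbest[g_idx].copy()
    gbest_fit = float(pbest_fit[g_idx])
    n_evals = config.m

    trace: dict[str, list] = {col: [] for col in TRACE_COLUMNS}

    for k in range(1, config.it_max + 1):
        if gbest_fit <= config.min_error:
            break
        labels = assign_subgroups(X, config.Q, bounds=(lo, hi))
        entropy = population_entropy(labels, config.Q)

        if config.constant_factors is not None:
            c1c = np.full(config.m, config.constant_factors[0])
            c2c = np.full(config.m, config.constant_factors[1])
        else:
            assert chaos is not None
            c1c, c2c = chaos.next_factors()  # one chaotic pair per particle

        mode = config.force_mode
        if mode is None:
            if entropy > e_high:
                mode = MODE_CONVERGE
            elif entropy < e_low:
                mode = MODE_DIVERGE
            else:
                mode = MODE_SELF_ADAPTIVE

        if mode == MODE_CONVERGE and entropy > 0:
            omega, phi = convergence_params(entropy)
            c1 = c2 = np.full(config.m, phi / 2.0)
        elif mode == MODE_DIVERGE:
            c1, c2 = c1c, c2c
            omega = divergence_inertia(
                max(entropy, 0.0), float(np.mean(c1 + c2)), config
            )
        else:  # self-adaptive (also the guard for converge at E_t <= 0)
            mode = MODE_SELF_ADAPTIVE
            c1, c2 = c1c, c2c
            omega = adaptive_inertia(gbest_fit, float(pbest_fit.mean()), k, config)

        if config.constant_inertia is not None:
            omega = config.constant_inertia

        if config.randomize_accel:
            r1 = rng.random((config.m, dim))
            r2 = rng.random((config.m, dim))
        else:
            r1 = r2 = 1.0

        c1col = c1[:, None]
        c2col = c2[:, None]
        V = omega * V + c1col * r1 * (pbest - X) + c2col * r2 * (gbest - X)
        np.clip(V, -v_max, v_max, out=V)
        X = X + V
        out_of_bounds = (X < lo) | (X > hi)
        if out_of_bounds.any():
            np.clip(X, lo, hi, out=X)
            V[out_of_bounds] = 0.0  # zero the offending velocity component

        fit = _evaluate(objective, X, vectorized)
        n_evals += config.m
        improved = fit < pbest_fit  # strict: earlier incumbent kept on ties
        pbest[improved] = X[improved]
        pbest_fit[improved] = fit[improved]
        g_idx = int(np.argmin(pbest_fit))
        if pbest_fit[g_idx] < gbest_fit:
            gbest = pbest[g_idx].copy()
            gbest_fit = float(pbest_fit[g_idx])

        centroid = X.mean(axis=0)
        dispersion = float(np.linalg.norm(X - centroid, axis=1).mean())
        trace["iteration"].append(k)
        trace["entropy_bits"].append(entropy)
        trace["mode"].append(mode)
        trace["global_best_fitness"].append(gbest_fit)
        trace["omega"].append(omega)
        trace["c1"].append(float(np.mean(c1)))
        trace["c2"].append(float(np.mean(c2)))
        trace["dispersion"].append(dispersion)

    return OptimizeResult(
        best_position=gbest,
        best_fitness=gbest_fit,
        trace=pd.DataFrame(trace),
        n_evaluations=n_evals,
    )


def random_search(
    objective: Callable,
    config: OptimizerConfig,
    dim: Optional[int] = None,
    vectorized: bool = False,
) -> OptimizeResult:
    """Pure random-sampling baseline at the same evaluation budget.

    Draws ``it_max`` batches of ``m`` uniform positions and keeps the best —
    the 'unoptimized' reference point for the optimizer comparisons.
    """
    if dim is None:
        lower = np.asarray(config.bounds[0], dtype=float)
        if lower.ndim == 0:
            raise ValueError("dim is required when bounds are scalar")
        dim = lower.size
    lo, hi = config.resolve_bounds(dim)
    rng = np.random.default_rng(config.seed)
    gbest = None
    gbest_fit = math.inf
    trace: dict[str, list] = {col: [] for col in TRACE_COLUMNS}
    n_evals = 0
    for k in range(1, config.it_max + 1):
        X = rng.uniform(lo, hi, size=(config.m, dim))
        vals = _evaluate(objective, X, vectorized)
        n_evals += config.m
        i = int(np.argmin(vals))
        if vals[i] < gbest_fit:
            gbest_fit = float(vals[i])
            gbest = X[i].copy()
        trace["iteration"].append(k)
        trace["entropy_bits"].append(math.nan)
        trace["mode"].append("random")
        trace["global_best_fitness"].append(gbest_fit)
        trace["omega"].append(math.nan)
        trace["c1"].append(math.nan)
        trace["c2"].append(math.nan)
        trace["dispersion"].append(math.nan)
        if gbest_fit <= config.min_error:
            break
    return OptimizeResult(
        best_position=gbest,
        best_fitness=gbest_fit,
        trace=pd.DataFrame(trace),
        n_evaluations=n_evals,
    )


def plain_pso_config(
    base: Optional[OptimizerConfig] = None,
    omega: float = 0.729,
    c1: float = 1.494,
    c2: float = 1.494,
    randomize: bool = True,
    **overrides,
) -> OptimizerConfig:
    """Configuration reducing the loop to a classical PSO baseline.

    Fixes the inertia and learning factors (default: Clerc-constriction
    equivalents) and, by default, restores the uniform random multipliers on
    the attraction terms.  Entropy is still measured for the trace but never
    switches the regime.
    """
    base = base if base is not None else OptimizerConfig()
    return dataclasses.replace(
        base,
        force_mode=MODE_SELF_ADAPTIVE,
        constant_inertia=omega,
        constant_factors=(c1, c2),
        randomize_accel=randomize,
        **overrides,
    )


def save_trace(trace: pd.DataFrame, path) -> None:
    """Write a per-iteration trace as delimited text (CSV, one row/iteration)."""
    trace.to_csv(path, index=False)
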