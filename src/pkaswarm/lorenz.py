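"""Lorenz chaotic sequence source for the swarm learning factors.

The optimizer's cognitive and social acceleration coefficients (c1, c2) are
drawn from a trajectory of the Lorenz system

    dx/dt = -a (x - y)
    dy/dt = r x - y - x z
    dz/dt = x y - b z

with the canonical chaotic parameters (a, b, r) = (10, 8/3, 28).  The raw x
and y coordinates are affinely rescaled from the attractor envelope
(|x|, |y| < 30 for the canonical parameters) into a configured
learning-factor range, by default [0.5, 2.5]: raw Lorenz coordinates are
frequently negative, and a negative learning factor repels a particle from
both attractors, which contradicts the convergence behaviour the factors are
meant to provide.  Rescaling preserves the ordering and ergodicity of the
chaotic sequence.

Integration is fixed-step classical RK4 with dt = 0.01, a burn-in of 1000
steps to leave the transient, and one (c1, c2) sample every 10 steps.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "LorenzState",
    "LORENZ_PARAMS",
    "X_ENVELOPE",
    "Y_ENVELOPE",
    "Z_ENVELOPE",
    "lorenz_advance",
    "chaotic_learning_factors",
    "ChaoticFactorSequence",
    "ChaoticFactorBank",
]

#: canonical chaotic control parameters (a, b, r)
LORENZ_PARAMS: tuple[float, float, float] = (10.0, 8.0 / 3.0, 28.0)

#: assertable attractor envelope (post-transient) for the canonical parameters
X_ENVELOPE: tuple[float, float] = (-30.0, 30.0)
Y_ENVELOPE: tuple[float, float] = (-30.0, 30.0)
Z_ENVELOPE: tuple[float, float] = (0.0, 55.0)


@dataclass(frozen=True)
class LorenzState:
    """A point on a Lorenz trajectory plus accumulated integration time."""

    x: float
    y: float
    z: float
    t: float = 0.0


def _deriv(x: float, y: float, z: float, a: float, b: float, r: float):
    return (-a * (x - y), r * x - y - x * z, x * y - b * z)


def lorenz_advance(
    state: LorenzState,
    n_steps: int,
    dt: float = 0.01,
    params: tuple[float, float, float] = LORENZ_PARAMS,
) -> LorenzState:
    """Integrate the Lorenz system ``n_steps`` fixed RK4 steps of size ``dt``.

    Raises ``ArithmeticError`` if the state leaves the finite range (dt too
    large for the requested parameters).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if dt <= 0:
        raise ValueError("dt must be positive")
    a, b, r = params
    x, y, z = state.x, state.y, state.z
    for _ in range(n_steps):
        k1 = _deriv(x, y, z, a, b, r)
        k2 = _deriv(x + 0.5 * dt * k1[0], y + 0.5 * dt * k1[1], z + 0.5 * dt * k1[2], a, b, r)
        k3 = _deriv(x + 0.5 * dt * k2[0], y + 0.5 * dt * k2[1], z + 0.5 * dt * k2[2], a, b, r)
        k4 = _deriv(x + dt * k3[0], y + dt * k3[1], z + dt * k3[2], a, b, r)
        x += dt * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0]) / 6.0
        y += dt * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1]) / 6.0
        z += dt * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2]) / 6.0
        if not (np.isfinite(x) and np.isfinite(y) and np.isfinite(z)):
            raise ArithmeticError(
                "Lorenz integration diverged to a non-finite state; reduce dt"
            )
    return LorenzState(x=x, y=y, z=z, t=state.t + n_steps * dt)


def _affine_map(value: float, envelope: tuple[float, float], target: tuple[float, float]) -> float:
    lo, hi = envelope
    tlo, thi = target
    v = min(max(value, lo), hi)  # clip rare excursions outside the envelope
    return tlo + (v - lo) / (hi - lo) * (thi - tlo)


def chaotic_learning_factors(
    state: LorenzState,
    dt: float = 0.01,
    stride: int = 10,
    params: tuple[float, float, float] = LORENZ_PARAMS,
    factor_range: tuple[float, float] = (0.5, 2.5),
) -> tuple[float, float, LorenzState]:
    """Advance one sampling interval and map (x, y) to learning factors.

    Returns ``(c1, c2, new_state)`` with ``c1 = map(x)``, ``c2 = map(y)``;
    both lie in ``factor_range`` by construction.
    """
    new_state = lorenz_advance(state, stride, dt=dt, params=params)
    c1 = _affine_map(new_state.x, X_ENVELOPE, factor_range)
    c2 = _affine_map(new_state.y, Y_ENVELOPE, factor_range)
    return c1, c2, new_state


def _advance_arrays(
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    n_steps: int,
    dt: float,
    params: tuple[float, float, float],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """RK4-advance a batch of independent Lorenz states, vectorized."""
    a, b, r = params

    def f(x, y, z):
        return -a * (x - y), r * x - y - x * z, x * y - b * z

    h = dt
    for _ in range(n_steps):
        k1x, k1y, k1z = f(x, y, z)
        k2x, k2y, k2z = f(x + 0.5 * h * k1x, y + 0.5 * h * k1y, z + 0.5 * h * k1z)
        k3x, k3y, k3z = f(x + 0.5 * h * k2x, y + 0.5 * h * k2y, z + 0.5 * h * k2z)
        k4x, k4y, k4z = f(x + h * k3x, y + h * k3y, z + h * k3z)
        x = x + h * (k1x + 2 * k2x + 2 * k3x + k4x) / 6.0
        y = y + h * (k1y + 2 * k2y + 2 * k3y + k4y) / 6.0
        z = z + h * (k1z + 2 * k2z + 2 * k3z + k4z) / 6.0
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y)) and np.all(np.isfinite(z))):
        raise ArithmeticError("Lorenz integration diverged to a non-finite state; reduce dt")
    return x, y, z


class ChaoticFactorBank:
    """Batch of independent seeded Lorenz streams, one per particle.

    Giving each particle its own chaotic (c1, c2) stream decorrelates the
    swarm: at any iteration a fraction of the particles draws a
    learning-factor sum in the contractive regime (refining the incumbent
    best) while the rest explores, instead of the whole swarm sharing one
    coefficient pair.  Streams start at (1, 1, 1) plus small seeded jitter
    and discard a common transient.
    """

    def __init__(
        self,
        n_streams: int,
        seed: int = 0,
        dt: float = 0.01,
        stride: int = 10,
        burn_in: int = 1000,
        params: tuple[float, float, float] = LORENZ_PARAMS,
        factor_range: tuple[float, float] = (0.5, 2.5),
    ) -> None:
        if n_streams < 1:
            raise ValueError("n_streams must be >= 1")
        rng = np.random.default_rng(seed)
        jitter = rng.uniform(-0.1, 0.1, size=(n_streams, 3))
        self._x = 1.0 + jitter[:, 0]
        self._y = 1.0 + jitter[:, 1]
        self._z = 1.0 + jitter[:, 2]
        self.dt = dt
        self.stride = stride
        self.params = params
        self.factor_range = factor_range
        if burn_in > 0:
            self._x, self._y, self._z = _advance_arrays(
                self._x, self._y, self._z, burn_in, dt, params
            )

    def next_factors(self) -> tuple[np.ndarray, np.ndarray]:
        """Advance every stream one sampling interval; (c1, c2) arrays."""
        self._x, self._y, self._z = _advance_arrays(
            self._x, self._y, self._z, self.stride, self.dt, self.params
        )
        lo, hi = X_ENVELOPE
        tlo, thi = self.factor_range
        c1 = tlo + (np.clip(self._x, lo, hi) - lo) / (hi - lo) * (thi - tlo)
        c2 = tlo + (np.clip(self._y, lo, hi) - lo) / (hi - lo) * (thi - tlo)
        return c1, c2


class ChaoticFactorSequence:
    """Seeded, burn-in-discarded stream of chaotic (c1, c2) pairs.

    The initial condition is (1, 1, 1) plus a small seeded jitter so that
    different optimizer seeds sample decorrelated stretches of the attractor,
    and the transient is discarded before the first sample.
    """

    def __init__(
        self,
        seed: int = 0,
        dt: float = 0.01,
        stride: int = 10,
        burn_in: int = 1000,
        params: tuple[float, float, float] = LORENZ_PARAMS,
        factor_range: tuple[float, float] = (0.5, 2.5),
    ) -> None:
        rng = np.random.default_rng(seed)
        jitter = rng.uniform(-0.1, 0.1, size=3)
        state = LorenzState(1.0 + jitter[0], 1.0 + jitter[1], 1.0 + jitter[2])
        if burn_in > 0:
            state = lorenz_advance(state, burn_in, dt=dt, params=params)
        self.state = state
        self.dt = dt
        self.stride = stride
        self.params = params
        self.factor_range = factor_range

    def next_factors(self) -> tuple[float, float]:
        c1, c2, self.state = chaotic_learning_factors(
            self.state,
            dt=self.dt,
            stride=self.stride,
            params=self.params,
            factor_range=self.factor_range,
        )
        return c1, c2
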