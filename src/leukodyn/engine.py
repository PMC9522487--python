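"""Numerical machinery: ODE integration, map iteration, basin sampling.

Two integration paths are provided.  The default is scipy's adaptive RK45
with tight tolerances; a hand-rolled fixed-step classical RK4 is kept for
bitwise-reproducible runs and for batched integration of many initial
conditions at once (used by the basin mapper, where the decoupled grid of
states is advanced as one array).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

log = logging.getLogger(__name__)

#: drift off the simplex above which states are renormalized
RENORM_TOL = 1e-12


@dataclass(frozen=True)
class IntegratorConfig:
    """Integration settings (time in days)."""

    method: str = "rk45"  # "rk45" adaptive or "rk4" fixed-step
    dt: float = 0.01
    t_end: float = 100.0
    abs_tol: float = 1e-9
    rel_tol: float = 1e-9
    renormalize_simplex: bool = False

    def __post_init__(self):
        if self.method not in ("rk45", "rk4"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.dt <= 0 or self.t_end <= 0 or self.abs_tol <= 0 or self.rel_tol <= 0:
            raise ValueError("dt, t_end and tolerances must be positive")


@dataclass(frozen=True)
class Trajectory:
    """Time-stamped sequence of states."""

    times: np.ndarray  # shape (n,)
    states: np.ndarray  # shape (n, dim)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        states = np.atleast_2d(np.asarray(self.states, dtype=float))
        if states.shape[0] != times.shape[0]:
            raise ValueError("times and states must have equal length")
        if times.shape[0] > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "states", states)

    @property
    def final(self) -> np.ndarray:
        return self.states[-1]


def _simplex_renormalize(y: np.ndarray) -> np.ndarray:
    y = np.clip(y, 0.0, 1.0)
    s = y.sum(axis=-1, keepdims=True)
    drift = np.abs(s - 1.0)
    if np.any(drift > RENORM_TOL):
        y = y / s
    return y


def _rk4_step(rhs, t: float, y: np.ndarray, dt: float) -> np.ndarray:
    k1 = np.asarray(rhs(t, y))
    k2 = np.asarray(rhs(t + dt / 2.0, y + dt / 2.0 * k1))
    k3 = np.asarray(rhs(t + dt / 2.0, y + dt / 2.0 * k2))
    k4 = np.asarray(rhs(t + dt, y + dt * k3))
    return y + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def integrate(
    rhs: Callable,
    x0,
    config: IntegratorConfig = IntegratorConfig(),
    meta: dict | None = None,
) -> Trajectory:
    """Integrate ``dy/dt = rhs(t, y)`` from ``y(0) = x0`` to ``t_end``.

    Model singularities raised inside ``rhs`` propagate with the offending
    time attached (see :class:`leukodyn.leslie.GowerSingularityError`).
    States are renormalized onto the simplex after each stored step when
    ``renormalize_simplex`` is set.
    """
    y0 = np.atleast_1d(np.asarray(x0, dtype=float))
    post = _simplex_renormalize if config.renormalize_simplex else None
    if config.method == "rk4":
        n_steps = int(np.ceil(config.t_end / config.dt))
        times = np.empty(n_steps + 1)
        states = np.empty((n_steps + 1, y0.shape[0]))
        times[0], states[0] = 0.0, y0
        t, y = 0.0, y0
        for k in range(n_steps):
            dt = min(config.dt, config.t_end - t)
            y = _rk4_step(rhs, t, y, dt)
            if post is not None:
                y = post(y)
            t = t + dt
            times[k + 1], states[k + 1] = t, y
        return Trajectory(times, states, dict(meta or {}))
    sol = solve_ivp(
        rhs,
        (0.0, config.t_end),
        y0,
        method="RK45",
        rtol=config.rel_tol,
        atol=config.abs_tol,
        dense_output=False,
    )
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    states = sol.y.T
    if post is not None:
        states = post(states)
    return Trajectory(sol.t, states, dict(meta or {}))


def iterate_map(step: Callable, x0, n_steps: int, meta: dict | None = None) -> Trajectory:
    """Iterate a discrete map ``x -> step(x)`` for ``n_steps`` applications.

    ``n_steps = 0`` returns the initial state alone; times are 0, 1, ..., n.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be non-negative")
    y = np.atleast_1d(np.asarray(x0, dtype=float))
    states = [y]
    for _ in range(n_steps):
        y = np.atleast_1d(np.asarray(step(y), dtype=float))
        states.append(y)
    return Trajectory(np.arange(n_steps + 1, dtype=float), np.array(states), dict(meta or {}))


@dataclass(frozen=True)
class BasinResult:
    """Grid of initial conditions labeled by attained attractor."""

    points: np.ndarray  # (N, dim) initial conditions
    labels: np.ndarray  # (N,) index into attractors, -1 for "none"
    finals: np.ndarray  # (N, dim) states at t_end
    attractors: np.ndarray  # (n_attr, dim)
    fractions: dict  # attractor index (or "none") -> fraction of grid

    def fraction_of(self, index: int) -> float:
        return self.fractions.get(index, 0.0)


def basin_sample(
    rhs: Callable,
    bounds: Sequence[tuple[float, float]],
    resolution: int | Sequence[int],
    attractors,
    t_end: float = 500.0,
    dt: float = 0.05,
    capture_radius: float = 1e-2,
) -> BasinResult:
    """Map basins of attraction on a rectangular grid of initial conditions.

    The grid (inclusive of bounds endpoints) is advanced as one batch with
    fixed-step RK4 — ``rhs(t, Y)`` must accept an (N, dim) array — and each
    point is labeled by the attractor within ``capture_radius`` of its state
    at ``t_end``, or -1 ("none") if it resolves to no listed attractor.
    """
    attractors = np.atleast_2d(np.asarray(attractors, dtype=float))
    if len(attractors) != len({tuple(a) for a in attractors}):
        raise ValueError("attractors must be distinct")
    axes = []
    res = np.broadcast_to(np.asarray(resolution), (len(bounds),))
    for (lo, hi), r in zip(bounds, res):
        if hi <= lo or int(r) < 1:
            raise ValueError("invalid grid specification")
        axes.append(np.linspace(lo, hi, int(r) + 1))
    mesh = np.meshgrid(*axes, indexing="ij")
    points = np.stack([m.ravel() for m in mesh], axis=-1)

    y = points.copy()
    t = 0.0
    n_steps = int(np.ceil(t_end / dt))
    for _ in range(n_steps):
        h = min(dt, t_end - t)
        y = _rk4_step(rhs, t, y, h)
        t += h
    dists = np.linalg.norm(y[:, None, :] - attractors[None, :, :], axis=-1)
    nearest = np.argmin(dists, axis=1)
    captured = dists[np.arange(len(y)), nearest] <= capture_radius
    labels = np.where(captured, nearest, -1)

    fractions: dict = {}
    for idx in range(len(attractors)):
        fractions[idx] = float(np.mean(labels == idx))
    fractions["none"] = float(np.mean(labels == -1))
    if fractions["none"] > 0:
        log.warning("basin_sample: %.1f%% of grid points unresolved", 100 * fractions["none"])
    return BasinResult(points, labels, y, attractors, fractions)
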