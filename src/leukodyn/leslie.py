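"""Leslie-Gower predator-prey dynamics of healthy vs. cancerous leukocytes.

Healthy leukocytes (leu, density ``i``) are the prey; cancerous leukocytes
(c.leu, density ``l``) are the predator.  The flow is

    di/dt = (r1 - c1*l - b*i) * i
    dl/dt = (r2 - c2*l/i) * l

where ``c2*l/i`` is the Gower term: the predator's per-capita growth is
penalized in proportion to the predator-to-prey ratio, so the predator's
effective carrying capacity scales with prey abundance.  Densities are in
units of 1e9 cells/liter, time in days.

The unique coexistence equilibrium has the closed form

    E = ( r1*c2 / (b*c2 + c1*r2),  r1*r2 / (b*c2 + c1*r2) )

with Jacobian

    J(E) = [[-r1*b*c2/D, -r1*c1*c2/D], [r2^2/c2, -r2]],   D = b*c2 + c1*r2,

whose determinant is identically ``r1*r2`` and whose trace is negative for
positive rates, so E is always locally attracting — a node when
``(sqrt(r1) - sqrt(r2))^2 >= r1*c1*r2/D`` and a focus otherwise (this
criterion is exactly the sign of the discriminant).

A separate fitness layer gives the per-capita merit functions

    H1 = r1*(k - i)/k - b*l        (logistic prey fitness minus predation)
    H2 = r2*(1 - l/(c*b*i))        (predator fitness, prey-limited)

and their difference-equation form ``i_{t+1} = i*(1 + H1)``,
``l_{t+1} = l*(1 + H2)``; ``k`` is the prey carrying capacity and ``c`` the
nutritional-value constant of the prey.  These forms enter only the map, not
the equilibrium or stability results above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .linear_stability import StabilityReport, stability_report

#: guard for the Gower term l/i as i -> 0
GOWER_EPS = 1e-12


class GowerSingularityError(ValueError):
    """Raised when the Gower term l/i is evaluated at vanishing prey density."""

    def __init__(self, message: str, t: float | None = None):
        super().__init__(message)
        self.t = t


@dataclass(frozen=True)
class LeslieParams:
    """Rate constants of the Leslie-Gower model (rates in 1/day).

    ``k`` (prey carrying capacity) and ``c`` (nutritional value of prey)
    enter only the fitness functions and the difference-equation map.
    """

    r1: float
    c1: float
    b: float
    r2: float
    c2: float
    k: float = 100.0
    c: float = 1.0

    def __post_init__(self):
        if not (self.r1 > 0 and self.r2 > 0 and self.c2 > 0 and self.b > 0):
            raise ValueError("r1, r2, c2, b must be positive")
        if self.c1 < 0:
            raise ValueError("c1 must be non-negative")
        if not (self.k > 0 and self.c > 0):
            raise ValueError("k and c must be positive")

    @property
    def D(self) -> float:
        """The recurring denominator ``b*c2 + c1*r2``."""
        return self.b * self.c2 + self.c1 * self.r2

    def to_dict(self) -> dict:
        return {f: getattr(self, f) for f in ("r1", "c1", "b", "r2", "c2", "k", "c")}


@dataclass(frozen=True)
class PopulationState:
    """Cell densities (1e9 cells/liter) at time ``t`` (days)."""

    i: float
    l: float
    t: float = 0.0

    def __post_init__(self):
        if self.i < 0 or self.l < 0:
            raise ValueError("densities must be non-negative")


@dataclass(frozen=True)
class CoexistenceEquilibrium:
    x_star: float
    y_star: float

    def as_tuple(self) -> tuple[float, float]:
        return (self.x_star, self.y_star)


def truncate(value: float, decimals: int = 2) -> float:
    """Truncate (not round) toward zero — the reporting convention used here."""
    scale = 10**decimals
    return math.trunc(value * scale) / scale


def leslie_rhs(params: LeslieParams, state: PopulationState) -> tuple[float, float]:
    """Right-hand side (di/dt, dl/dt) of the Leslie-Gower flow."""
    i, l = state.i, state.l
    if l > 0 and i <= GOWER_EPS:
        raise GowerSingularityError(
            f"Gower term l/i diverges at i={i} with l={l}", t=state.t
        )
    didt = (params.r1 - params.c1 * l - params.b * i) * i
    dldt = 0.0 if l == 0 else (params.r2 - params.c2 * l / i) * l
    return (didt, dldt)


def leslie_fitness(params: LeslieParams, state: PopulationState) -> tuple[float, float]:
    """Per-capita fitnesses (H1, H2) of prey and predator."""
    i, l = state.i, state.l
    if i <= GOWER_EPS:
        raise GowerSingularityError(f"prey density i={i} too small for fitness", t=state.t)
    H1 = params.r1 * (params.k - i) / params.k - params.b * l
    H2 = params.r2 * (1.0 - l / (params.c * params.b * i))
    return (H1, H2)


def leslie_map_step(
    params: LeslieParams, state: PopulationState, per_capita: str = "fitness"
) -> PopulationState:
    """One step of the difference equation ``state * (1 + per-capita growth)``.

    ``per_capita="fitness"`` uses the merit functions (H1, H2);
    ``per_capita="ode"`` uses the flow's own per-capita forms
    ``(r1 - c1*l - b*i, r2 - c2*l/i)``, under which the coexistence
    equilibrium is a fixed point of the map.  Negative densities produced by
    overshoot are floored at 0.
    """
    i, l = state.i, state.l
    if i == 0 and l == 0:
        return PopulationState(0.0, 0.0, state.t + 1.0)
    if per_capita == "fitness":
        g1, g2 = leslie_fitness(params, state)
    elif per_capita == "ode":
        if l > 0 and i <= GOWER_EPS:
            raise GowerSingularityError(
                f"Gower term l/i diverges at i={i} with l={l}", t=state.t
            )
        g1 = params.r1 - params.c1 * l - params.b * i
        g2 = params.r2 - (params.c2 * l / i if l > 0 else 0.0)
    else:
        raise ValueError(f"unknown per-capita form {per_capita!r}")
    i_next = max(i * (1.0 + g1), 0.0)
    l_next = max(l * (1.0 + g2), 0.0)
    return PopulationState(i_next, l_next, state.t + 1.0)


def coexistence_equilibrium(params: LeslieParams) -> CoexistenceEquilibrium:
    """Closed-form interior steady state E = (r1*c2/D, r1*r2/D)."""
    D = params.D
    if D <= 0:
        raise ValueError("degenerate parameters: b*c2 + c1*r2 must be positive")
    return CoexistenceEquilibrium(params.r1 * params.c2 / D, params.r1 * params.r2 / D)


def jacobian_at_equilibrium(params: LeslieParams) -> np.ndarray:
    """Jacobian of the flow at the coexistence equilibrium (closed form)."""
    D = params.D
    if D <= 0:
        raise ValueError("degenerate parameters: b*c2 + c1*r2 must be positive")
    return np.array(
        [
            [-params.r1 * params.b * params.c2 / D, -params.r1 * params.c1 * params.c2 / D],
            [params.r2**2 / params.c2, -params.r2],
        ]
    )


def characteristic_coefficients(params: LeslieParams) -> tuple[float, float]:
    """(linear, constant) coefficients of ``lambda^2 + p*lambda + q = 0`` at E.

    The constant term simplifies symbolically to ``r1*r2``.
    """
    D = params.D
    if D <= 0:
        raise ValueError("degenerate parameters: b*c2 + c1*r2 must be positive")
    linear = (params.r1 * params.b * params.c2 + params.r2 * D) / D
    constant = (params.r1 * params.b * params.r2 * params.c2 + params.r1 * params.c1 * params.r2**2) / D
    return (linear, constant)


def node_focus_criterion(params: LeslieParams) -> tuple[float, float, str]:
    """Node-vs-focus test at E.

    Returns ``(lhs, rhs, label)`` with ``lhs = (sqrt(r1) - sqrt(r2))^2`` and
    ``rhs = r1*c1*r2/D``; the equilibrium is a node when ``lhs >= rhs`` and a
    focus otherwise.  The test is equivalent to the sign of the discriminant
    of the Jacobian at E.
    """
    D = params.D
    lhs = (math.sqrt(params.r1) - math.sqrt(params.r2)) ** 2
    rhs = params.r1 * params.c1 * params.r2 / D
    return (lhs, rhs, "node" if lhs >= rhs else "focus")


def reported_trace_quantity(params: LeslieParams) -> float:
    """The eigenvalue-sum quantity ``(r2*D - r1*b*c2)/D`` used in reports.

    This is not the trace of the Jacobian at E (which is
    ``-(r1*b*c2 + r2*D)/D``, always negative for positive rates); it is the
    separate reporting convention kept alongside the true trace.
    """
    D = params.D
    return (params.r2 * D - params.r1 * params.b * params.c2) / D


def leslie_stability_report(params: LeslieParams) -> StabilityReport:
    """Full stability report at the coexistence equilibrium.

    Includes the node/focus criterion values and the reported trace quantity
    in the ``extra`` payload.
    """
    eq = coexistence_equilibrium(params)
    J = jacobian_at_equilibrium(params)
    lhs, rhs, label = node_focus_criterion(params)
    return stability_report(
        J,
        point=eq.as_tuple(),
        extra={
            "criterion_lhs": lhs,
            "criterion_rhs": rhs,
            "criterion_label": label,
            "reported_trace_quantity": reported_trace_quantity(params),
        },
    )


def leslie_vector_field(params: LeslieParams):
    """Batchable vector field ``f(t, Y)`` with Y of shape (2,) or (N, 2).

    Raises :class:`GowerSingularityError` (with the offending time) if any
    prey density reaches the guard while its predator density is positive.
    """

    def f(t, y):
        y = np.asarray(y, dtype=float)
        i, l = y[..., 0], y[..., 1]
        bad = (i <= GOWER_EPS) & (l > 0)
        if np.any(bad):
            raise GowerSingularityError(
                f"Gower term l/i diverges (prey extinct with predators present) at t={t}",
                t=float(t),
            )
        didt = (params.r1 - params.c1 * l - params.b * i) * i
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(l > 0, l / np.maximum(i, GOWER_EPS), 0.0)
        dldt = (params.r2 - params.c2 * ratio) * l
        return np.stack([didt, dldt], axis=-1)

    return f
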