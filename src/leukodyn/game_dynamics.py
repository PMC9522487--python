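"""Hawk-Dove and n-strategy replicator dynamics for leukocyte populations.

The contest between cancerous leukocytes (c.leu, the Hawks) and healthy
leukocytes (leu, the Doves) is modelled on the frequency simplex.  Two layers
are provided:

* the general n-strategy replicator equation
  ``x_i' = x_i * (H_i - Hbar)`` with fitness ``H = A x`` and mean fitness
  ``Hbar = x^T A x`` for an arbitrary payoff matrix ``A``;
* the one-dimensional Hawk-Dove flow
  ``x1' = (a*x1 - b*x2) * x1 * x2`` with ``x2 = 1 - x1``, whose three fixed
  points are the monomorphic states 0 and 1 and the interior (dimorphic)
  point ``x* = b/(a+b)``.

Note the 1-D flow is a coordination dynamic: under it both monomorphic
states are attracting and the interior point is the separatrix between their
basins, so the basin of the all-leu state has size ``b/(a+b)``.  It is *not*
the replicator flow of the normalized anti-diagonal matrix
``[[0, -a], [b, 0]]`` (which `hawkdove_payoff_matrix` builds and
`replicator_rhs_n` integrates); the two layers are deliberately kept
separate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: residual below which a frequency counts as a fixed point of the 1-D flow
FIXED_POINT_TOL = 1e-9
#: |derivative| below which a fixed point is reported degenerate
DEGENERACY_TOL = 1e-12
#: allowed drift off the simplex before a state is rejected
SIMPLEX_TOL = 1e-9


@dataclass(frozen=True)
class PayoffMatrix:
    """Square payoff matrix a_ij (dimensionless fitness units)."""

    entries: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self):
        A = np.atleast_2d(np.asarray(self.entries, dtype=float))
        if A.ndim != 2 or A.shape[0] != A.shape[1] or A.shape[0] < 2:
            raise ValueError(f"payoff matrix must be square with n >= 2, got {A.shape}")
        if not np.all(np.isfinite(A)):
            raise ValueError("payoff entries must be finite")
        object.__setattr__(self, "entries", A)
        labels = tuple(self.labels) or tuple(f"S{i + 1}" for i in range(A.shape[0]))
        if len(labels) != A.shape[0]:
            raise ValueError("one label per strategy required")
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return self.entries.shape[0]


@dataclass(frozen=True)
class CellCountState:
    """Absolute cell counts (cells/liter): c.leu P_L, leu P_I."""

    P_L: float
    P_I: float
    t: float = 0.0

    def __post_init__(self):
        if self.P_L < 0 or self.P_I < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def p(self) -> float:
        """Total cell count."""
        return self.P_L + self.P_I


@dataclass(frozen=True)
class ReplicatorState:
    """Strategy frequencies on the simplex at time ``t`` (days)."""

    x: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        _check_simplex(x)
        object.__setattr__(self, "x", x)


@dataclass(frozen=True)
class FixedPoint1D:
    """A stationary frequency of the 1-D Hawk-Dove flow."""

    x: float
    kind: str  # monomorphic_0 | monomorphic_1 | interior
    stability: str  # stable | unstable | degenerate
    derivative: float

    def to_dict(self) -> dict:
        return {
            "x": self.x,
            "kind": self.kind,
            "stability": self.stability,
            "derivative": self.derivative,
        }


def _check_simplex(x: np.ndarray, tol: float = SIMPLEX_TOL) -> np.ndarray:
    if np.any(x < -tol) or np.any(x > 1 + tol) or abs(x.sum() - 1.0) > tol:
        raise ValueError(f"state {x} is off the frequency simplex (tol={tol})")
    return x


def _entries(A) -> np.ndarray:
    return A.entries if isinstance(A, PayoffMatrix) else np.asarray(A, dtype=float)


def _frequencies(x) -> np.ndarray:
    return x.x if isinstance(x, ReplicatorState) else np.asarray(x, dtype=float)


def hawkdove_payoff_matrix(a: float, b: float) -> PayoffMatrix:
    """Normalized Hawk-Dove payoff matrix ``[[0, -a], [b, 0]]``.

    The diagonal is zero (same-type encounters are neutral) and the
    c.leu-vs-leu interplay carries the negative payoff ``-a``; ``a`` and
    ``b`` must be positive.
    """
    if not (a > 0 and b > 0):
        raise ValueError(f"payoff constants must be positive, got a={a}, b={b}")
    return PayoffMatrix(np.array([[0.0, -a], [b, 0.0]]), labels=("c.leu", "leu"))


def frequencies_from_counts(counts: CellCountState) -> ReplicatorState:
    """Convert absolute counts to simplex frequencies (x1 = P_L/p)."""
    p = counts.p
    if p <= 0:
        raise ZeroDivisionError("total cell count is zero; frequencies undefined")
    return ReplicatorState(np.array([counts.P_L / p, counts.P_I / p]), t=counts.t)


def strategy_fitness(A, x) -> np.ndarray:
    """Per-strategy fitness vector ``H = A x``."""
    A, x = _entries(A), _frequencies(x)
    if A.shape[1] != x.shape[0]:
        raise ValueError(f"shape mismatch: A is {A.shape}, x has length {x.shape[0]}")
    return A @ x


def mean_fitness(A, x) -> float:
    """Population mean fitness ``x^T A x``."""
    x = _frequencies(x)
    return float(x @ strategy_fitness(A, x))


def replicator_rhs_n(A, x) -> np.ndarray:
    """Replicator velocity ``x_i * ((Ax)_i - x^T A x)``; components sum to 0."""
    x = _frequencies(x)
    _check_simplex(x)
    H = strategy_fitness(A, x)
    return x * (H - x @ H)


def hawkdove_rhs(a: float, b: float, x1):
    """Velocity of the c.leu frequency: ``(a*x1 - b*(1-x1)) * x1 * (1-x1)``.

    Vectorized over ``x1``; the companion leu velocity is the exact negation.
    """
    x1 = np.asarray(x1, dtype=float)
    if np.any(x1 < 0) or np.any(x1 > 1):
        raise ValueError("frequency x1 must lie in [0, 1]")
    out = (a * x1 - b * (1.0 - x1)) * x1 * (1.0 - x1)
    return float(out) if out.ndim == 0 else out


def hawkdove_rhs_derivative(a: float, b: float, x1: float) -> float:
    """d/dx1 of `hawkdove_rhs` — the 1-D stability test."""
    q = x1 - x1 * x1
    return (a + b) * q + ((a + b) * x1 - b) * (1.0 - 2.0 * x1)


def classify_fixed_point_1d(a: float, b: float, x_star: float) -> str:
    """Stability of a fixed point of the 1-D flow by the derivative-sign test."""
    if abs(hawkdove_rhs(a, b, x_star)) > FIXED_POINT_TOL:
        raise ValueError(f"x={x_star} is not a fixed point of the Hawk-Dove flow")
    d = hawkdove_rhs_derivative(a, b, x_star)
    if abs(d) < DEGENERACY_TOL:
        return "degenerate"
    return "stable" if d < 0 else "unstable"


def hawkdove_fixed_points(a: float, b: float) -> tuple[FixedPoint1D, ...]:
    """The three stationary points 0, 1 and ``x* = b/(a+b)``, with stability."""
    if not (a > 0 and b > 0):
        raise ValueError(f"payoff constants must be positive, got a={a}, b={b}")
    points = (
        (0.0, "monomorphic_0"),
        (1.0, "monomorphic_1"),
        (b / (a + b), "interior"),
    )
    return tuple(
        FixedPoint1D(
            x=x,
            kind=kind,
            stability=classify_fixed_point_1d(a, b, x),
            derivative=hawkdove_rhs_derivative(a, b, x),
        )
        for x, kind in points
    )


def hawkdove_vector_field(a: float, b: float):
    """Batchable vector field ``f(t, Y)`` for the engine (Y shape (..., 1))."""

    def f(t, y):
        y = np.asarray(y, dtype=float)
        return hawkdove_rhs(a, b, np.clip(y, 0.0, 1.0))

    return f


def replicator_vector_field(A):
    """Vector field ``f(t, x)`` of the n-strategy replicator equation."""
    A = _entries(A)

    def f(t, x):
        x = np.asarray(x, dtype=float)
        H = A @ x
        return x * (H - x @ H)

    return f
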