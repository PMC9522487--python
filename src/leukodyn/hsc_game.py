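"""Two-coalition replicator game for hematopoietic stem-cell transplantation.

After an HSC transplant three cell players interact — the graft (HSC),
healthy leukocytes (leu) and cancerous leukocytes (c.leu) — with two
coalition structures of clinical interest:

* favourable (HSC, leu) vs. unfavourable (c.leu): the graft boosts the
  immune response;
* favourable (leu) vs. unfavourable (c.leu, HSC): the graft-versus-host-like
  outcome.

Each coalition game is a normalized 2x2 contest (zero diagonal) summarized
by a single payoff constant per game: ``a1, a2`` for game (i) and ``b1, b2``
for game (ii), with ``m = a1 + a2`` and ``n = b1 + b2``.  Coupling the two
games gives the planar replicator system

    dx1/dt = x1*(1 - x1)*(a1 - m*x2)
    dx2/dt = x2*(1 - x2)*(b1 - n*x1)

on the unit square: the four corners are always stationary and the mixed
point ``(x1*, x2*) = (b1/n, a1/m)`` exists in the interior when both ratios
lie in (0, 1).  The Jacobian at the mixed point has zero diagonal, so its
eigenvalues are ``+-sqrt(J12*J21)``: a saddle when the product is positive
(a1 and b1 of the same sign) and a linear center (closed orbits) when it is
negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .linear_stability import StabilityReport, stability_report

#: tolerance below which the eigenvalue product counts as degenerate
DEGENERACY_TOL = 1e-12


@dataclass(frozen=True)
class CoalitionPayoffs:
    """Normalized payoff constants of the two coalition games."""

    a1: float
    a2: float
    b1: float
    b2: float

    def __post_init__(self):
        for name in ("a1", "a2", "b1", "b2"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"payoff constant {name} must be finite")

    @property
    def m(self) -> float:
        return self.a1 + self.a2

    @property
    def n(self) -> float:
        return self.b1 + self.b2

    def to_dict(self) -> dict:
        return {"a1": self.a1, "a2": self.a2, "b1": self.b1, "b2": self.b2}


@dataclass(frozen=True)
class CoalitionState:
    """Frequencies of favourable play in the two populations at time t (days)."""

    x1: float
    x2: float
    t: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.x1 <= 1.0 and 0.0 <= self.x2 <= 1.0):
            raise ValueError(f"state ({self.x1}, {self.x2}) outside the unit square")


@dataclass(frozen=True)
class TransplantCounts:
    """Post-chemotherapy cell counts used to seed the transplant scenarios.

    Stored verbatim as reported (the NK count 2.08e-7 is dimensionally
    implausible — a fractional cell — and is kept uninterpreted).
    """

    nk: float = 2.08e-7
    leu: float = 5.00e8
    cd34_infused: float = 9.19e6  # cells/kg recipient body weight
    cd34_number: float = 3.47e4  # cells/kg
    cleu_major: float = 4.31e-1
    cleu_minor: float = 1.42e-6

    def __post_init__(self):
        for name in ("nk", "leu", "cd34_infused", "cd34_number", "cleu_major", "cleu_minor"):
            if getattr(self, name) < 0:
                raise ValueError(f"count {name} must be non-negative")

    def to_dict(self) -> dict:
        return {
            f: getattr(self, f)
            for f in ("nk", "leu", "cd34_infused", "cd34_number", "cleu_major", "cleu_minor")
        }


#: verbatim payoff-matrix fixtures for the two transplant simulations
FIXTURES: dict[str, np.ndarray] = {
    # favourable (leu) vs. unfavourable (HSC, c.leu)
    "leu_vs_hsc_cleu": np.array([[0.0, 5.0e8], [9.2247e6, 0.0]]),
    # favourable (HSC, leu) vs. unfavourable (c.leu)
    "hsc_leu_vs_cleu": np.array([[0.0, 1009224700.0], [0.431001, 0.0]]),
}


def transplant_payoff_fixture(which: str) -> np.ndarray:
    """Return a copy of one of the two transplant payoff matrices."""
    if which not in FIXTURES:
        raise KeyError(
            f"unknown fixture {which!r}; expected one of {sorted(FIXTURES)}"
        )
    return FIXTURES[which].copy()


def _check_square_state(s: CoalitionState | tuple) -> tuple[float, float, float]:
    if isinstance(s, CoalitionState):
        return s.x1, s.x2, s.t
    x1, x2 = float(s[0]), float(s[1])
    if not (0.0 <= x1 <= 1.0 and 0.0 <= x2 <= 1.0):
        raise ValueError(f"state ({x1}, {x2}) outside the unit square")
    return x1, x2, 0.0


def coalition_rhs(p: CoalitionPayoffs, s) -> tuple[float, float]:
    """Replicator velocities (dx1/dt, dx2/dt) of the coupled coalition games."""
    x1, x2, _ = _check_square_state(s)
    dx1 = x1 * (1.0 - x1) * (p.a1 - p.m * x2)
    dx2 = x2 * (1.0 - x2) * (p.b1 - p.n * x1)
    return (dx1, dx2)


def mixed_point(p: CoalitionPayoffs) -> tuple[float, float]:
    """The formal mixed-strategy point ``(b1/n, a1/m)``.

    Requires ``m != 0`` and ``n != 0``; the point may lie outside the open
    unit square, in which case it is a formal (virtual) equilibrium only.
    """
    if p.m == 0 or p.n == 0:
        raise ValueError("degenerate payoffs: m and n must be nonzero for a mixed point")
    return (p.b1 / p.n, p.a1 / p.m)


def coalition_fixed_points(p: CoalitionPayoffs) -> list[tuple[float, float]]:
    """All rest points on the closed unit square.

    The four corners always; the mixed point only when it lies strictly
    inside the square.  Degenerate ``m = 0`` or ``n = 0`` omits the interior
    point.
    """
    points: list[tuple[float, float]] = [(0.0, 0.0), (1.0, 0.0), (0.0, 1.0), (1.0, 1.0)]
    if p.m != 0 and p.n != 0:
        x1s, x2s = mixed_point(p)
        if 0.0 < x1s < 1.0 and 0.0 < x2s < 1.0:
            points.append((x1s, x2s))
    return points


def interior_jacobian(p: CoalitionPayoffs) -> np.ndarray:
    """Jacobian at the mixed point: zero diagonal, off-diagonal closed forms.

    ``J12 = -x1*(1-x1*)*m`` and ``J21 = -x2*(1-x2*)*n`` evaluated at the
    formal mixed point.
    """
    x1s, x2s = mixed_point(p)
    return np.array(
        [
            [0.0, -x1s * (1.0 - x1s) * p.m],
            [-x2s * (1.0 - x2s) * p.n, 0.0],
        ]
    )


def classify_interior(p: CoalitionPayoffs) -> str:
    """Saddle / center / degenerate label of the mixed point.

    With a zero-diagonal Jacobian the eigenvalues are ``+-sqrt(J12*J21)``:
    real of opposite signs (saddle) when the product is positive, a pure
    imaginary pair (center, closed orbits) when negative.
    """
    J = interior_jacobian(p)
    prod = J[0, 1] * J[1, 0]
    if abs(prod) < DEGENERACY_TOL:
        return "degenerate"
    return "saddle" if prod > 0 else "center"


def saddle_report(M) -> StabilityReport:
    """Stability report (trace, det, discriminant, eigenvalues, label) of M."""
    return stability_report(M)


def coalition_vector_field(p: CoalitionPayoffs):
    """Batchable vector field ``f(t, Y)`` with Y of shape (2,) or (N, 2)."""

    def f(t, y):
        y = np.asarray(y, dtype=float)
        x1 = np.clip(y[..., 0], 0.0, 1.0)
        x2 = np.clip(y[..., 1], 0.0, 1.0)
        dx1 = x1 * (1.0 - x1) * (p.a1 - p.m * x2)
        dx2 = x2 * (1.0 - x2) * (p.b1 - p.n * x1)
        return np.stack([dx1, dx2], axis=-1)

    return f
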