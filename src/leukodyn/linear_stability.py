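"""Linear stability toolkit for 2x2 Jacobians.

Both the Leslie-Gower model and the coalition replicator games reduce their
local stability questions to the trace-determinant plane of a 2x2 Jacobian:
the eigenvalues are the roots of ``lambda^2 - tau*lambda + det`` and the
equilibrium class (node, focus, saddle, center) follows from the signs of the
determinant, the trace and the discriminant ``tau^2 - 4*det``.
"""

from __future__ import annotations

import cmath
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: default tolerance for sign tests; boundary cases are reported "degenerate"
SIGN_TOL = 1e-12

LABELS = (
    "stable node",
    "unstable node",
    "stable focus",
    "unstable focus",
    "saddle",
    "center",
    "degenerate",
)


def _as_2x2(J) -> np.ndarray:
    J = np.asarray(J, dtype=float)
    if J.shape != (2, 2):
        raise ValueError(f"expected a 2x2 matrix, got shape {J.shape}")
    if not np.all(np.isfinite(J)):
        raise ValueError("Jacobian entries must be finite")
    return J


def eigenvalues_2x2(J) -> tuple[complex, complex]:
    """Eigenvalues of a 2x2 matrix from the closed-form quadratic.

    Returns the roots of ``lambda^2 - tau*lambda + det`` sorted by real part,
    then imaginary part, so reports are deterministic.
    """
    J = _as_2x2(J)
    tau = J[0, 0] + J[1, 1]
    det = J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0]
    root = cmath.sqrt(complex(tau * tau - 4.0 * det))
    lam = ((tau - root) / 2.0, (tau + root) / 2.0)
    return tuple(sorted(lam, key=lambda z: (z.real, z.imag)))


def classify_2x2(J, tol: float = SIGN_TOL) -> str:
    """Classify a 2x2 Jacobian on the trace-determinant plane.

    ``det < -tol`` is a saddle; positive determinant splits into node
    (non-negative discriminant) or focus (negative discriminant), stable iff
    the trace is negative; zero trace with positive determinant is a center.
    Anything within ``tol`` of a boundary is reported degenerate rather than
    guessed.
    """
    J = _as_2x2(J)
    tau = J[0, 0] + J[1, 1]
    det = J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0]
    disc = tau * tau - 4.0 * det
    if det < -tol:
        return "saddle"
    if det > tol:
        if abs(tau) <= tol:
            return "center"
        stable = "stable" if tau < 0 else "unstable"
        if disc >= tol:
            return f"{stable} node"
        if disc < -tol:
            return f"{stable} focus"
    return "degenerate"


@dataclass(frozen=True)
class StabilityReport:
    """Equilibrium point, Jacobian and its trace-determinant classification."""

    point: tuple[float, ...]
    jacobian: tuple[tuple[float, float], tuple[float, float]]
    trace: float
    det: float
    discriminant: float
    eigenvalues: tuple[complex, complex]
    label: str
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "point": list(self.point),
            "jacobian": [list(row) for row in self.jacobian],
            "trace": self.trace,
            "det": self.det,
            "discriminant": self.discriminant,
            "eigenvalues": [{"re": z.real, "im": z.imag} for z in self.eigenvalues],
            "label": self.label,
        }
        d.update(self.extra)
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def stability_report(
    J,
    point: Sequence[float] = (),
    tol: float = SIGN_TOL,
    extra: dict | None = None,
) -> StabilityReport:
    """Assemble the full :class:`StabilityReport` for a 2x2 Jacobian."""
    J = _as_2x2(J)
    tau = float(J[0, 0] + J[1, 1])
    det = float(J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0])
    return StabilityReport(
        point=tuple(float(v) for v in point),
        jacobian=((J[0, 0], J[0, 1]), (J[1, 0], J[1, 1])),
        trace=tau,
        det=det,
        discriminant=tau * tau - 4.0 * det,
        eigenvalues=eigenvalues_2x2(J),
        label=classify_2x2(J, tol=tol),
        extra=dict(extra or {}),
    )
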