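"""Equilibria of the circuit and asymptotic-stability certification.

The equilibrium condition is 0 = A ybar + C (ybar o ybar) + b.  Because the
only quadratic term is beta * LC^2 in the SNcVTA row, the system reduces to a
scalar quadratic: writing u = -A^-1 b and w = -A^-1 e_SNcVTA, every
equilibrium has the form ybar = u + beta * LC^2 * w with LC solving

    q LC^2 - LC + u_LC = 0,       q = beta * w_LC,

so there are at most two equilibria.  The principal branch
LC = 2 u_LC / (1 + sqrt(1 - 4 q u_LC)) is continuous in beta -> 0 and selects
the physiological root.  A damped Newton iteration from a configurable guess
(default: the literature rest rates) is kept as the generic root-finder and
cross-checked against the closed form in the test suite.

Asymptotic stability is certified by linearization: the Jacobian
J = A + 2 C diag(y) must have every eigenvalue real part below a small
negative margin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .constants import REST_RATES_HZ
from .model import AREAS, ModelMatrices

__all__ = [
    "EquilibriumError",
    "StabilityReport",
    "default_guess",
    "find_equilibrium",
    "closed_form_equilibria",
    "physiological_equilibrium",
    "jacobian",
    "is_asymptotically_stable",
]

DEFAULT_MARGIN = 1e-6


class EquilibriumError(RuntimeError):
    """Raised when no equilibrium can be located."""


def default_guess() -> np.ndarray:
    """Literature rest rates, the physiological starting point."""
    return np.array([REST_RATES_HZ[a] for a in AREAS])


def jacobian(m: ModelMatrices, y: np.ndarray) -> np.ndarray:
    """Linearization A + 2 C diag(y) of the right-hand side at ``y``."""
    y = np.asarray(y, dtype=float)
    return m.A + 2.0 * m.C * y[None, :]


def find_equilibrium(
    m: ModelMatrices,
    guess: np.ndarray | None = None,
    tol: float = 1e-12,
    max_iter: int = 200,
) -> np.ndarray:
    """Damped Newton iteration for the equilibrium near ``guess``.

    Converges when the residual infinity-norm drops below
    ``tol * max(1, ||b||_inf)``.  The quadratic term admits up to two roots;
    the iteration selects the one in the guess's basin, so a failure suggests
    retrying from a different guess.
    """
    y = default_guess() if guess is None else np.asarray(guess, dtype=float).copy()
    if not np.all(np.isfinite(y)):
        raise ValueError("guess must be finite")
    scale = max(1.0, float(np.max(np.abs(m.b))))

    def residual(v):
        return m.A @ v + m.C @ (v * v) + m.b

    r = residual(y)
    for _ in range(max_iter):
        if np.max(np.abs(r)) < tol * scale:
            return y
        J = jacobian(m, y)
        try:
            step = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError as exc:
            raise EquilibriumError(
                f"singular Jacobian during Newton iteration: {exc}; try another guess"
            ) from None
        lam = 1.0
        norm = np.linalg.norm(r)
        for _ in range(40):
            y_new = y + lam * step
            r_new = residual(y_new)
            if np.linalg.norm(r_new) < norm or lam < 1e-12:
                break
            lam *= 0.5
        y, r = y_new, r_new
    if np.max(np.abs(r)) < tol * scale:
        return y
    raise EquilibriumError(
        "Newton iteration did not converge; the quadratic term admits up to "
        "two roots - try a different guess"
    )


def closed_form_equilibria(m: ModelMatrices) -> list[np.ndarray]:
    """All real equilibria via the scalar-quadratic reduction (0, 1 or 2).

    The first entry, when present, is the principal (physiological) branch.
    """
    nz = np.argwhere(m.C != 0.0)
    u = np.linalg.solve(m.A, -m.b)
    if nz.size == 0:
        return [u]
    (i0, j0) = nz[0]
    beta = m.C[i0, j0]
    w = np.linalg.solve(m.A, -np.eye(len(AREAS))[i0])
    q = beta * w[j0]
    uj = u[j0]
    if q == 0.0:
        return [u]
    disc = 1.0 - 4.0 * q * uj
    if disc < 0.0:
        return []
    sq = np.sqrt(disc)
    roots = [2.0 * uj / (1.0 + sq)] if sq == 0.0 else [2.0 * uj / (1.0 + sq), (1.0 + sq) / (2.0 * q)]
    return [u + beta * L * L * w for L in roots]


def physiological_equilibrium(m: ModelMatrices) -> np.ndarray:
    """Principal-branch equilibrium; raises if none exists."""
    try:
        eqs = closed_form_equilibria(m)
    except np.linalg.LinAlgError:
        raise EquilibriumError("A is singular; no unique equilibrium") from None
    if not eqs:
        raise EquilibriumError("no real equilibrium (negative discriminant)")
    return eqs[0]


@dataclass
class StabilityReport:
    """Linearized stability verdict at an equilibrium."""

    equilibrium: np.ndarray
    jacobian: np.ndarray
    eigenvalues: np.ndarray
    max_real_part: float
    margin: float
    stable: bool

    def to_dict(self) -> dict:
        return {
            "equilibrium_hz": dict(zip(AREAS, (float(v) for v in self.equilibrium))),
            "eigenvalues": [[float(z.real), float(z.imag)] for z in self.eigenvalues],
            "max_real_part_per_s": float(self.max_real_part),
            "margin_per_s": float(self.margin),
            "stable": bool(self.stable),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def is_asymptotically_stable(
    m: ModelMatrices,
    ybar: np.ndarray,
    margin: float = DEFAULT_MARGIN,
) -> StabilityReport:
    """Certify asymptotic stability of the equilibrium ``ybar``.

    Stable iff every eigenvalue of the Jacobian at ``ybar`` has real part
    below ``-margin`` (a strict-negativity test is numerically fragile).
    """
    J = jacobian(m, ybar)
    eig = np.linalg.eigvals(J)
    max_real = float(np.max(eig.real))
    return StabilityReport(
        equilibrium=np.asarray(ybar, dtype=float),
        jacobian=J,
        eigenvalues=eig,
        max_real_part=max_real,
        margin=margin,
        stable=max_real < -margin,
    )
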