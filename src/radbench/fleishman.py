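"""Fleishman power-method marginals.

A non-normal variable with zero mean, unit variance, skewness ``g1`` and
excess kurtosis ``g2`` is represented as a cubic polynomial of a standard
normal Z:

    Y = a + b Z + c Z**2 + d Z**3,   a = -c.

The coefficients solve the classical three-moment system

    b**2 + 6 b d + 2 c**2 + 15 d**2                       = 1
    2 c (b**2 + 24 b d + 105 d**2 + 2)                    = g1
    24 [ b d + c**2 (1 + b**2 + 28 b d)
         + d**2 (12 + 48 b d + 141 c**2 + 225 d**2) ]     = g2

The system is multi-modal; we run a multi-start root search and keep the
solution continuous with the normal case (b > 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = ["FleishmanCoefficients", "FleishmanInfeasibleError", "solve_fleishman", "fleishman_feasible"]

#: residual tolerance for accepting a root of the moment system
RESIDUAL_TOL = 1e-8

#: starting points (b, c, d) for the multi-start search; (1, 0, 0) is the
#: normal case, the others probe the skewed / heavy-tailed branches
START_POINTS = (
    (1.0, 0.0, 0.0),
    (0.9, 0.1, 0.0),
    (0.9, 0.2, 0.05),
    (0.8, 0.3, 0.05),
    (0.7, 0.4, 0.1),
    (0.5, 0.3, 0.2),
    (0.3, 0.2, 0.3),
    (1.1, 0.05, -0.05),
)


class FleishmanInfeasibleError(ValueError):
    """Raised when no real Fleishman solution exists for (g1, g2)."""


@dataclass(frozen=True)
class FleishmanCoefficients:
    """Coefficients of Y = a + b Z + c Z**2 + d Z**3 with a = -c."""

    b: float
    c: float
    d: float

    @property
    def a(self) -> float:
        return -self.c

    def __call__(self, z: np.ndarray) -> np.ndarray:
        """Apply the polynomial to standard-normal draws."""
        z = np.asarray(z, dtype=float)
        return self.a + z * (self.b + z * (self.c + z * self.d))

    def variance_residual(self) -> float:
        b, c, d = self.b, self.c, self.d
        return abs(b * b + 6 * b * d + 2 * c * c + 15 * d * d - 1.0)


def _moment_system(x: np.ndarray, g1: float, g2: float) -> list[float]:
    b, c, d = x
    v = b * b + 6 * b * d + 2 * c * c + 15 * d * d - 1.0
    s = 2 * c * (b * b + 24 * b * d + 105 * d * d + 2.0) - g1
    k = 24 * (
        b * d
        + c * c * (1.0 + b * b + 28 * b * d)
        + d * d * (12.0 + 48 * b * d + 141 * c * c + 225 * d * d)
    ) - g2
    return [v, s, k]


def _solve_nonneg_skew(g1: float, g2: float) -> FleishmanCoefficients | None:
    """Root search for g1 >= 0; returns None when no root is found."""
    best: tuple[float, np.ndarray] | None = None
    for x0 in START_POINTS:
        sol = optimize.root(_moment_system, x0, args=(g1, g2), method="hybr", tol=1e-12)
        res = float(np.max(np.abs(_moment_system(sol.x, g1, g2))))
        if res < RESIDUAL_TOL:
            b, c, d = sol.x
            if b <= 0:  # use the sign-symmetric mirror with b > 0
                b, c, d = -b, c, -d
                if float(np.max(np.abs(_moment_system([b, c, d], g1, g2)))) >= RESIDUAL_TOL:
                    continue
            # prefer the branch continuous with the normal solution
            dist = (b - 1.0) ** 2 + c * c + d * d
            if best is None or dist < best[0]:
                best = (dist, np.array([b, c, d]))
    if best is None:
        return None
    b, c, d = best[1]
    return FleishmanCoefficients(float(b), float(c), float(d))


def solve_fleishman(skewness: float, excess_kurtosis: float) -> FleishmanCoefficients:
    """Solve the Fleishman system for the given skewness / excess kurtosis.

    Returns the b > 0 solution; for negative skewness the c coefficient of
    the mirrored positive-skew solution is negated (sign symmetry of the
    system). Raises :class:`FleishmanInfeasibleError` outside the feasible
    region.
    """
    g1, g2 = float(skewness), float(excess_kurtosis)
    if g1 == 0.0 and g2 == 0.0:
        return FleishmanCoefficients(1.0, 0.0, 0.0)
    coef = _solve_nonneg_skew(abs(g1), g2)
    if coef is None:
        raise FleishmanInfeasibleError(
            f"no Fleishman solution for skewness={g1}, excess kurtosis={g2}"
        )
    if g1 < 0:
        coef = FleishmanCoefficients(coef.b, -coef.c, coef.d)
    return coef


def fleishman_feasible(skewness: float, excess_kurtosis: float) -> bool:
    """True iff the Fleishman moment system admits a real solution."""
    try:
        solve_fleishman(skewness, excess_kurtosis)
        return True
    except FleishmanInfeasibleError:
        return False
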