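"""Hertz contact mechanics for a rigid sphere on an elastic half-space.

The forward model used throughout the package is

    F(delta) = (4/3) * E / (1 - nu**2) * sqrt(R) * delta**1.5

for indentation depth ``delta >= 0``, Young's modulus ``E`` (Pa), Poisson
ratio ``nu`` and indenter radius ``R`` (m). During an AFM ramp the piezo
travel z couples to the cantilever deflection: the indentation is
``delta = (z - z0) - F/k`` for spring constant ``k``, so the force measured
at a given piezo position solves a scalar fixed-point equation, handled by
:func:`force_at_travel`.
"""
from __future__ import annotations

import numpy as np


def hertz_prefactor(E: float, R: float, nu: float) -> float:
    """Prefactor A with F = A * delta**1.5 (A in N / m^1.5)."""
    if E < 0:
        raise ValueError("E must be non-negative")
    if R <= 0:
        raise ValueError("R must be positive")
    return (4.0 / 3.0) * E / (1.0 - nu**2) * np.sqrt(R)


def hertz_force(delta, E: float, R: float, nu: float):
    """Hertz force (N) at indentation depth ``delta`` (m); vectorized."""
    delta = np.asarray(delta, dtype=float)
    return hertz_prefactor(E, R, nu) * np.clip(delta, 0.0, None) ** 1.5


def indentation_at_force(F: float, E: float, R: float, nu: float) -> float:
    """Invert the Hertz law: depth (m) at which the force reaches ``F``."""
    A = hertz_prefactor(E, R, nu)
    if A == 0:
        return np.inf
    return (F / A) ** (2.0 / 3.0)


def force_at_travel(s, E: float, R: float, nu: float, k: float,
                    tol: float = 1e-16, max_iter: int = 100):
    """Force (N) at tip travel past contact ``s = z - z0`` (m), accounting
    for cantilever deflection: solves F = A*(s - F/k)**1.5 per sample.

    Newton iteration on the monotone residual; vectorized over ``s``.
    Entries with ``s <= 0`` return 0.
    """
    s = np.atleast_1d(np.asarray(s, dtype=float))
    A = hertz_prefactor(E, R, nu)
    F = np.zeros_like(s)
    pos = s > 0
    if A == 0 or not np.any(pos):
        return F if F.shape else float(F)
    sp = s[pos]
    f = np.zeros_like(sp)
    for _ in range(max_iter):
        d = np.clip(sp - f / k, 0.0, None)
        g = A * d**1.5 - f
        gp = -1.5 * (A / k) * np.sqrt(d) - 1.0
        step = g / gp
        f_new = np.clip(f - step, 0.0, k * sp)
        if np.max(np.abs(f_new - f)) < tol * (1.0 + np.max(f_new)):
            f = f_new
            break
        f = f_new
    F[pos] = f
    return F
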