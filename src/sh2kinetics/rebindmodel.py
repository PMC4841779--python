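"""Membrane-occupancy kinetics and diffusion-limited on-rate estimates.

The bound-SH2 population obeys the linear balance

    d[mem:SH2]/dt = gamma_on(t) - lambda_off(t) * [mem:SH2](t)

whose integrating-factor solution is

    [mem:SH2](t) = c * exp(-L(t)) + exp(-L(t)) * int_0^t gamma(u) exp(L(u)) du,
    L(t) = int_0^t lambda(u) du.

Both a numeric ODE integration and a quadrature evaluation of the analytic
solution are provided; they cross-validate each other to ~1e-6 relative
error.  The analytic path is evaluated in the numerically stable form
int gamma(u) exp(-(L(t)-L(u))) du, in which every exponent is non-positive,
so arbitrarily large cumulative off-rates never overflow.

Also here: the two back-of-envelope diffusion-limited on-rate estimates,
k_on = k_off / K_d and the Smoluchowski-style upper bound 4*pi*D*s/N for a
cluster of N sites of overall size s.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

AVOGADRO = 6.02214076e23
LITERS_PER_UM3 = 1e-15

#: Refinement factor: internal quadrature substeps per output grid step.
_QUAD_REFINE = 16


class RateProfile:
    """Piecewise-linear rate profile gamma(t) or lambda(t).

    Wraps measured windowed estimates (or any (t, y) table) into a callable;
    values outside the sampled range are held at the end values.
    """

    def __init__(self, t: np.ndarray, y: np.ndarray):
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(t) != len(y) or len(t) < 1:
            raise ValueError("rate profile needs matching non-empty t and y")
        if np.any(np.diff(t) <= 0):
            raise ValueError("rate profile times must be strictly increasing")
        self.t = t
        self.y = y

    def __call__(self, t):
        return np.interp(t, self.t, self.y)

    @classmethod
    def constant(cls, value: float) -> "RateProfile":
        return cls(np.array([0.0, 1.0]), np.array([value, value]))


def _as_callable(rate) -> Callable:
    if callable(rate):
        return rate
    if np.isscalar(rate):
        return lambda t, v=float(rate): np.full_like(np.asarray(t, dtype=float), v)
    raise TypeError("rate must be callable, scalar, or RateProfile")


@dataclass
class OccupancyCurve:
    """Membrane-bound SH2 abundance over time."""

    t: np.ndarray
    occupancy: np.ndarray
    provenance: str             # "numeric" | "analytic"

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_s": self.t, "mem_sh2": self.occupancy, "provenance": self.provenance}
        )


def _validate_rates(gamma, lam, t_grid):
    g = _as_callable(gamma)
    l = _as_callable(lam)
    t_grid = np.asarray(t_grid, dtype=float)
    if len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be increasing with >= 2 points")
    lam_vals = np.atleast_1d(l(t_grid))
    if np.any(lam_vals < 0):
        raise ValueError("negative lambda_off input")
    return g, l, t_grid


def integrate_occupancy(
    gamma_on,
    lambda_off,
    t_grid: np.ndarray,
    initial: float = 0.0,
) -> OccupancyCurve:
    """Numerically integrate the occupancy balance on ``t_grid``.

    ``gamma_on`` and ``lambda_off`` are callables of time (or scalars /
    RateProfiles) in consistent units: occupancy-units per second and 1/s.
    Adaptive RK integration with tight tolerances, dense output on the grid.
    """
    g, l, t_grid = _validate_rates(gamma_on, lambda_off, t_grid)

    def rhs(t, y):
        return [float(g(t)) - float(l(t)) * y[0]]

    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        [float(initial)],
        t_eval=t_grid,
        method="RK45",
        rtol=1e-10,
        atol=1e-12,
        max_step=(t_grid[-1] - t_grid[0]) / 50,
    )
    if not sol.success:
        raise RuntimeError(f"occupancy integration failed: {sol.message}")
    return OccupancyCurve(t=t_grid, occupancy=sol.y[0], provenance="numeric")


def analytic_occupancy(
    gamma_on,
    lambda_off,
    t_grid: np.ndarray,
    c: float = 0.0,
) -> OccupancyCurve:
    """Evaluate the integrating-factor solution on ``t_grid``.

    ``c`` is the integration constant, equal to the occupancy at t_grid[0]
    (the particular integral vanishes there).  Inner integrals use composite
    Simpson quadrature on a refined grid; the convolution integral is
    accumulated in the shifted form with non-positive exponents only.
    """
    g, l, t_grid = _validate_rates(gamma_on, lambda_off, t_grid)

    # refined grid: _QUAD_REFINE substeps per output interval
    fine = [np.array([t_grid[0]])]
    for a, b in zip(t_grid[:-1], t_grid[1:]):
        fine.append(np.linspace(a, b, _QUAD_REFINE + 1)[1:])
    tf = np.concatenate(fine)
    a = tf[:-1]
    b = tf[1:]
    h = b - a
    m = 0.5 * (a + b)
    q1 = 0.5 * (m + b)  # 3/4 point, for the half-interval Simpson

    lam_a = np.atleast_1d(l(a)).astype(float)
    lam_m = np.atleast_1d(l(m)).astype(float)
    lam_b = np.atleast_1d(l(b)).astype(float)
    lam_q = np.atleast_1d(l(q1)).astype(float)
    gam_a = np.atleast_1d(g(a)).astype(float)
    gam_m = np.atleast_1d(g(m)).astype(float)
    gam_b = np.atleast_1d(g(b)).astype(float)

    # per-step Simpson increments of L = int lambda (O(h^5) local error)
    dL = h / 6.0 * (lam_a + 4.0 * lam_m + lam_b)
    # int_{m}^{b} lambda, Simpson on the half interval
    dL_mb = h / 12.0 * (lam_m + 4.0 * lam_q + lam_b)
    # per-step Simpson for J = int_a^b gamma(u) exp(-(L(b) - L(u))) du;
    # all exponents non-positive -> overflow-safe for any cumulative L
    J = h / 6.0 * (
        gam_a * np.exp(-dL) + 4.0 * gam_m * np.exp(-dL_mb) + gam_b
    )

    # sequential accumulation of the shifted convolution integral
    n = len(tf)
    L = np.concatenate([[0.0], np.cumsum(dL)])
    I = np.zeros(n)
    decay = np.exp(-dL)
    for k in range(1, n):
        I[k] = I[k - 1] * decay[k - 1] + J[k - 1]
    occ_fine = c * np.exp(-L) + I

    idx = np.searchsorted(tf, t_grid)
    return OccupancyCurve(t=t_grid, occupancy=occ_fine[idx], provenance="analytic")


def compare_solutions(
    gamma_on, lambda_off, t_grid: np.ndarray, initial: float = 0.0
) -> float:
    """Max relative deviation between analytic and numeric solutions
    (normalized by the numeric solution's max magnitude)."""
    num = integrate_occupancy(gamma_on, lambda_off, t_grid, initial=initial)
    ana = analytic_occupancy(gamma_on, lambda_off, t_grid, c=initial)
    scale = max(np.max(np.abs(num.occupancy)), np.finfo(float).tiny)
    return float(np.max(np.abs(num.occupancy - ana.occupancy)) / scale)


# ----------------------------------------------------------------------
# Diffusion-limited on-rate estimates
# ----------------------------------------------------------------------

def on_rate_from_kd(k_off: float, K_d: float) -> float:
    """Effective association rate k_on = k_off / K_d (M^-1 s^-1).

    With the membrane-measured effective off-rate ~1/s and K_d ~1 uM this
    gives the ~1e6 M^-1 s^-1 diffusion-limited estimate.
    """
    if k_off <= 0:
        raise ValueError("k_off must be positive")
    if K_d <= 0:
        raise ValueError("K_d must be positive")
    return k_off / K_d


def smoluchowski_upper_bound(D: float, s: float, N: float) -> float:
    """Upper bound 4*pi*D*s/N on the per-site diffusion-limited on-rate.

    D in um^2/s, s (the cluster size) in um, N the number of phosphosites
    sharing the cluster; the volumetric rate 4*pi*D*s/N (um^3/s) is converted
    to M^-1 s^-1 via 1e-15 L/um^3 and Avogadro's number.
    """
    if D < 0 or s < 0:
        raise ValueError("D and s must be non-negative")
    if N <= 0:
        raise ValueError("N must be positive")
    rate_um3_s = 4.0 * np.pi * D * s / N
    return rate_um3_s * LITERS_PER_UM3 * AVOGADRO


def gamma_per_min_to_per_s(gamma_per_min: np.ndarray) -> np.ndarray:
    """Convert gamma_on from events/min (the reporting unit) to events/s
    (the integration unit)."""
    return np.asarray(gamma_per_min, dtype=float) / 60.0
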