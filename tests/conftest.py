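"""Shared fixtures and independent numerical oracles.

The oracles here deliberately avoid the package's own discretizations:
two-compartment kinetics are integrated with ``scipy.integrate.solve_ivp``
at tight tolerance, and root finding for the solubility intersection uses
plain bisection.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from saltivivc import ConcentrationTimeProfile, DispositionParams, SaltSystem
from saltivivc.datasets import DKT_DISPOSITION, DKT_SYSTEM


@pytest.fixture(scope="session")
def dkt_system() -> SaltSystem:
    return DKT_SYSTEM


@pytest.fixture(scope="session")
def disposition() -> DispositionParams:
    return DKT_DISPOSITION


def ode_two_compartment(
    params: DispositionParams,
    t_eval_h: np.ndarray,
    *,
    bolus: float = 0.0,
    rate_fn=None,
    rtol: float = 1e-11,
):
    """Reference integration of the two-compartment system.

    Returns (central_amounts, peripheral_amounts) at ``t_eval_h``.
    ``rate_fn(t)`` is the absorption-rate input [mass/h].
    """

    def rhs(t, x):
        r = rate_fn(t) if rate_fn is not None else 0.0
        xc, xp = x
        return [
            r - (params.k10 + params.k12) * xc + params.k21 * xp,
            params.k12 * xc - params.k21 * xp,
        ]

    sol = solve_ivp(
        rhs, (t_eval_h[0], t_eval_h[-1]), [bolus, 0.0],
        t_eval=t_eval_h, rtol=rtol, atol=1e-12, method="LSODA", max_step=0.05,
    )
    assert sol.success
    return sol.y[0], sol.y[1]


def bisect(f, lo, hi, tol=1e-10):
    """Plain bisection root finder (independent of scipy.optimize)."""
    flo = f(lo)
    assert flo * f(hi) < 0, "root not bracketed"
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if abs(hi - lo) < tol:
            return mid
        if flo * fm <= 0:
            hi = mid
        else:
            lo, flo = mid, fm
    return 0.5 * (lo + hi)


def first_order_absorption_profile(
    params: DispositionParams,
    amount: float,
    ka: float,
    times_h: np.ndarray,
    *,
    fine_dt_h: float = 1.0 / 240.0,
) -> ConcentrationTimeProfile:
    """Noise-free oral profile for X_A(t) = amount·(1 − exp(−ka·t)).

    Built by exact piecewise-constant-rate propagation on a fine grid and
    sampled at ``times_h``; serves as the forward oracle for deconvolution.
    """
    from saltivivc import simulate_oral

    grid = np.arange(0.0, times_h[-1] + fine_dt_h / 2, fine_dt_h)
    xa = amount * (1.0 - np.exp(-ka * grid))
    rates = np.diff(xa) / np.diff(grid)
    fine = simulate_oral(params, grid, rates, time_unit="h")
    conc = np.interp(times_h, grid, fine.concentrations)
    return ConcentrationTimeProfile(
        times=times_h, concentrations=conc, unit="ug/mL",
        label="oral_first_order", time_unit="h",
    )
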