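"""Finite-difference reference solution of radial diffusion with a film boundary.

Independent numerical cross-check for the eigenvalue-series release model:
solves the dimensionless diffusion problem

    dc/dtau = (1/r^2) d/dr (r^2 dc/dr),   0 < r < 1
    c(r, 0) = 1
    dc/dr|_{r=1} = -L c(1, tau)           (Robin / film condition)
    dc/dr|_{r=0} = 0                      (symmetry)

by Crank-Nicolson time stepping on the substituted variable u = r c, for
which the PDE becomes the plain heat equation u_tau = u_rr with u(0) = 0 and
u_r(1) = (1 - L) u(1).  The released fraction is

    F(tau) = 1 - 3 * integral_0^1 c r^2 dr = 1 - 3 * integral_0^1 u r dr.

A few backward-Euler startup steps damp the spurious oscillations
Crank-Nicolson produces for the incompatible initial/boundary data at tau = 0
(Rannacher smoothing).  This module shares no code with the series model; it
exists purely as an oracle for validation.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve_banded

__all__ = ["released_fraction_fd"]


def _step_matrix(n: int, dr: float, dtau: float, biot: float, theta: float):
    """Banded LHS matrix and RHS operator weights for a theta-scheme step.

    Unknowns are u_1..u_N on r_i = i*dr (u_0 = 0 is eliminated).  The Robin
    condition enters through a ghost node u_{N+1} = u_{N-1} + 2 dr (1-L) u_N
    in the second-difference stencil at i = N.
    """
    lam = dtau / dr**2
    main = np.full(n, 1.0 + 2.0 * theta * lam)
    lower = np.full(n - 1, -theta * lam)
    upper = np.full(n - 1, -theta * lam)
    # boundary row i = N: u_{N-1} coefficient doubles, diagonal picks up Robin term
    lower[-1] = -2.0 * theta * lam
    main[-1] = 1.0 + 2.0 * theta * lam - 2.0 * theta * lam * dr * (1.0 - biot)
    ab = np.zeros((3, n))
    ab[0, 1:] = upper
    ab[1, :] = main
    ab[2, :-1] = lower
    return ab, lam


def _apply_rhs(u: np.ndarray, dr: float, lam: float, biot: float, theta: float) -> np.ndarray:
    """Explicit part (1 + (1-theta) dtau Laplacian) u, with the same ghost node."""
    w = 1.0 - theta
    rhs = u.copy()
    if w == 0.0:
        return rhs
    lap = np.empty_like(u)
    lap[0] = u[1] - 2.0 * u[0]  # u_0 = 0
    lap[1:-1] = u[:-2] - 2.0 * u[1:-1] + u[2:]
    lap[-1] = 2.0 * u[-2] - 2.0 * u[-1] + 2.0 * dr * (1.0 - biot) * u[-1]
    return rhs + w * lam * lap


def released_fraction_fd(
    biot: float,
    taus,
    n_r: int = 400,
    dtau_max: float = 1e-4,
    n_startup: int = 8,
) -> np.ndarray:
    """Released fraction F(tau) from the Crank-Nicolson solution.

    Parameters
    ----------
    biot : float
        Dimensionless Biot number L > 0.
    taus : array-like
        Strictly increasing positive output times (dimensionless).
    n_r : int
        Number of radial intervals on [0, 1].
    dtau_max : float
        Cap on the time step; early steps are refined further (the step is
        also limited to tau/200 so the initial boundary layer is resolved).
    n_startup : int
        Number of initial backward-Euler sub-steps (Rannacher smoothing).

    Returns
    -------
    numpy.ndarray
        F at each requested tau, in [0, 1].
    """
    taus = np.atleast_1d(np.asarray(taus, dtype=float))
    if np.any(taus <= 0) or (taus.size > 1 and np.any(np.diff(taus) <= 0)):
        raise ValueError("taus must be positive and strictly increasing")
    if biot <= 0:
        raise ValueError("biot must be > 0")
    dr = 1.0 / n_r
    r = np.linspace(0.0, 1.0, n_r + 1)
    u = r.copy()[1:]  # u = r c, c(r,0) = 1; u_0 eliminated

    tau_now = 0.0
    out = np.empty_like(taus)
    # trapezoid weights for 3 * int u r dr on the full grid (u_0 = 0)
    w_trap = np.full(n_r + 1, dr)
    w_trap[0] = w_trap[-1] = dr / 2.0

    def emit(u_in: np.ndarray) -> float:
        full = np.concatenate(([0.0], u_in))
        return float(np.clip(1.0 - 3.0 * np.sum(w_trap * full * r), 0.0, 1.0))

    # backward-Euler startup over a tiny initial interval
    tau0 = min(taus[0] * 0.01, dtau_max)
    sub = tau0 / n_startup
    ab_be, _ = _step_matrix(n_r, dr, sub, biot, theta=1.0)
    for _ in range(n_startup):
        u = solve_banded((1, 1), ab_be, u)
    tau_now = tau0

    for j, tau_target in enumerate(taus):
        while tau_now < tau_target - 1e-15:
            dtau = min(dtau_max, max(tau_now / 200.0, 1e-7), tau_target - tau_now)
            ab, lam = _step_matrix(n_r, dr, dtau, biot, theta=0.5)
            rhs = _apply_rhs(u, dr, lam, biot, theta=0.5)
            u = solve_banded((1, 1), ab, rhs)
            tau_now += dtau
        out[j] = emit(u)
    return out
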