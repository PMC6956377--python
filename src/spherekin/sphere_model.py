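"""Non-steady-state Fickian release from a sphere with a boundary-layer resistance.

The model describes cumulative fractional release ``M_t / M_inf`` of a drug
dissolved in a spherical polymer matrix of radius ``R``, with effective
diffusion coefficient ``D_eff`` inside the sphere and a mass-transfer
coefficient ``h`` across the external boundary layer (film).  The governing
dimensionless group is the mass-transfer Biot number ``L = h R / D_eff``:
large ``L`` means internal diffusion controls the release, small ``L`` means
the external film does.

The series solution is

    M_t/M_inf = 1 - sum_n 6 L^2 / (beta_n^2 (beta_n^2 + L^2 - L))
                        * exp(-beta_n^2 D_eff t / R^2)

where the eigenvalues ``beta_n`` are the positive roots of the transcendental
equation ``beta cot(beta) + L - 1 = 0``.  For large ``L`` the roots approach
multiples of pi and the series reduces to the classical film-free sphere
solution ``1 - (6/pi^2) sum exp(-n^2 pi^2 tau) / n^2`` with dimensionless
time ``tau = D_eff t / R^2``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ModelParams",
    "EigenvalueSet",
    "ReleaseCurve",
    "solve_eigenvalues",
    "biot_number",
    "fractional_release",
    "fractional_release_large_L",
    "LARGE_L_THRESHOLD",
    "DEFAULT_RADIUS_M",
]

#: Biot number above which the film resistance is negligible and the
#: simplified (film-free) series may be dispatched automatically.
LARGE_L_THRESHOLD = 1e3

#: Default sphere radius: half of the 101.4 um volume-median diameter of the
#: estradiol-loaded microspheres measured by laser diffraction.
DEFAULT_RADIUS_M = 50.7e-6

# Numerical controls for the series evaluation (see docs/methods.md).
_BRACKET_EPS = 1e-9
_BISECT_WIDTH = 1e-12
_TERM_TOL = 1e-10
_TAIL_TOL = 1e-8
_MAX_TERMS = 10_000
_TAU_FLOOR = 1e-6


class InvalidParameterError(ValueError):
    """A physical parameter violates its domain (must be positive, etc.)."""


class NumericalFailureError(RuntimeError):
    """A numerical routine failed (e.g. an eigenvalue bracket without a root)."""


@dataclass(frozen=True)
class ModelParams:
    """Physical triple governing one release curve.

    Attributes
    ----------
    d_eff : float
        Effective diffusion coefficient in the polymer matrix, m^2/s.
    h : float
        Boundary-layer mass-transfer coefficient, m/s.
    radius : float
        Sphere radius R, m.
    """

    d_eff: float
    h: float
    radius: float = DEFAULT_RADIUS_M

    def __post_init__(self) -> None:
        for name in ("d_eff", "h", "radius"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise InvalidParameterError(f"{name} must be finite and > 0, got {v!r}")

    @property
    def biot(self) -> float:
        """Dimensionless Biot number L = h R / D_eff."""
        return self.h * self.radius / self.d_eff

    def tau(self, times: np.ndarray) -> np.ndarray:
        """Dimensionless time D_eff * t / R^2 for times in seconds."""
        return self.d_eff * np.asarray(times, dtype=float) / self.radius**2


@dataclass(frozen=True)
class EigenvalueSet:
    """First ``n_terms`` positive roots of ``beta cot(beta) + L - 1 = 0``."""

    biot: float
    roots: np.ndarray
    n_terms: int

    def __post_init__(self) -> None:
        roots = np.asarray(self.roots, dtype=float)
        object.__setattr__(self, "roots", roots)
        if roots.shape != (self.n_terms,):
            raise InvalidParameterError("roots length must equal n_terms")
        if not (np.all(roots > 0) and np.all(np.diff(roots) > 0)):
            raise InvalidParameterError("roots must be strictly positive and increasing")


@dataclass
class ReleaseCurve:
    """Cumulative fractional release M_t/M_inf observed over time.

    ``times`` are in seconds and must be strictly increasing.  Fractions are
    dimensionless; measurement noise means observed fractions need not be
    monotone, but model-generated curves are.  ``normalization_mode`` records
    whether amounts were divided by the final observed released amount
    (``final_observed``, the M_inf of the model equation) or by the loaded
    dose (``loaded_dose``).
    """

    times: np.ndarray
    fractions: np.ndarray
    replicate_id: str = "r1"
    normalization_mode: str = "final_observed"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.fractions.shape:
            raise InvalidParameterError("times and fractions must be 1-D and equal length")
        if np.any(self.times < 0):
            raise InvalidParameterError("times must be non-negative")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise InvalidParameterError("times must be strictly increasing")
        if self.normalization_mode not in ("final_observed", "loaded_dose"):
            raise InvalidParameterError(
                f"unknown normalization_mode {self.normalization_mode!r}"
            )
        if self.normalization_mode == "loaded_dose" and np.any(self.fractions < 0):
            raise InvalidParameterError("loaded-dose fractions must be >= 0")

    def __len__(self) -> int:
        return self.times.size


def _residual(beta: np.ndarray, biot) -> np.ndarray:
    """Residual of the eigenvalue equation, beta*cot(beta) + L - 1."""
    return beta / np.tan(beta) + biot - 1.0


def _eigen_brackets(biot: np.ndarray, n_terms: int) -> tuple[np.ndarray, np.ndarray]:
    """Half-open brackets of width pi holding exactly one root each.

    For the n-th root (n >= 2) the bracket is ((n-1)pi + eps, n pi - eps);
    the residual runs from +inf to -inf inside it, so a sign change is
    guaranteed for any L > 0.  The first root lies in (eps, pi - eps), and for
    L <= 1 it is confined to (eps, pi/2] (at L = 1 the equation reduces to
    cot(beta) = 0 with the root exactly at pi/2).
    """
    biot = np.atleast_1d(np.asarray(biot, dtype=float))
    n = np.arange(1, n_terms + 1, dtype=float)
    lo = np.broadcast_to((n - 1.0) * np.pi + _BRACKET_EPS, biot.shape + (n_terms,)).copy()
    hi = np.broadcast_to(n * np.pi - _BRACKET_EPS, biot.shape + (n_terms,)).copy()
    hi[..., 0] = np.where(biot <= 1.0, np.pi / 2.0, np.pi - _BRACKET_EPS)
    return lo, hi


def _solve_eigenvalues_batch(biot: np.ndarray, n_terms: int) -> np.ndarray:
    """Vectorised bisection + one Newton polish over a batch of Biot numbers.

    Returns an array of shape ``biot.shape + (n_terms,)``.
    """
    biot = np.atleast_1d(np.asarray(biot, dtype=float))
    lo, hi = _eigen_brackets(biot, n_terms)
    b = biot[..., None]
    f_lo = _residual(lo, b)
    # Bisection keeps the invariant f(lo) > 0 >= f(hi); iterate until the
    # bracket width falls below _BISECT_WIDTH (pi / 2^k < 1e-12 at k = 52).
    n_iter = int(np.ceil(np.log2(np.pi / _BISECT_WIDTH)))
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        f_mid = _residual(mid, b)
        take_lo = (f_mid > 0) == (f_lo > 0)
        lo = np.where(take_lo, mid, lo)
        hi = np.where(take_lo, hi, mid)
    beta = 0.5 * (lo + hi)
    # One Newton polish; d/dbeta [beta cot beta] = cot(beta) - beta / sin^2(beta)
    with np.errstate(all="ignore"):
        cot = 1.0 / np.tan(beta)
        deriv = cot - beta / np.sin(beta) ** 2
        step = _residual(beta, b) / deriv
        polished = beta - step
        ok = np.isfinite(polished) & (polished > lo - _BISECT_WIDTH) & (polished < hi + _BISECT_WIDTH)
        beta = np.where(ok, polished, beta)
    return beta


def solve_eigenvalues(biot: float, n_terms: int, tol: float = 1e-9) -> EigenvalueSet:
    """Solve ``beta cot(beta) + L - 1 = 0`` for the first ``n_terms`` roots.

    Parameters
    ----------
    biot : float
        Dimensionless Biot number L > 0.
    n_terms : int
        Number of roots requested, >= 1.
    tol : float
        Maximum absolute residual accepted at each returned root.

    Returns
    -------
    EigenvalueSet
        Roots in strictly increasing order; root ``n`` lies in its
        half-open bracket of width pi.

    Raises
    ------
    InvalidParameterError
        If ``biot``, ``n_terms`` or ``tol`` is non-positive.
    NumericalFailureError
        If any root fails the residual tolerance (names the root index).
    """
    if not np.isfinite(biot) or biot <= 0:
        raise InvalidParameterError(f"biot must be finite and > 0, got {biot!r}")
    if int(n_terms) != n_terms or n_terms < 1:
        raise InvalidParameterError(f"n_terms must be a positive integer, got {n_terms!r}")
    if tol <= 0:
        raise InvalidParameterError(f"tol must be > 0, got {tol!r}")
    roots = _solve_eigenvalues_batch(np.array([biot]), int(n_terms))[0]
    res = np.abs(_residual(roots, biot))
    # Near the cotangent poles (large L) the residual slope is enormous, so a
    # machine-exact root can still have a large raw residual; the tolerance is
    # therefore applied to the derivative-scaled residual |f| / max(1, |f'|),
    # which bounds the error in the root itself.
    with np.errstate(all="ignore"):
        deriv = np.abs(1.0 / np.tan(roots) - roots / np.sin(roots) ** 2)
    scaled = res / np.maximum(1.0, deriv)
    bad = np.nonzero(np.minimum(res, scaled) > tol)[0]
    if bad.size:
        raise NumericalFailureError(
            f"eigenvalue {bad[0] + 1} (of {n_terms}) failed residual tolerance: "
            f"|residual| = {res[bad[0]]:.3e} > {tol:.3e} at L = {biot:g}"
        )
    return EigenvalueSet(biot=float(biot), roots=roots, n_terms=int(n_terms))


def biot_number(params: ModelParams) -> float:
    """Dimensionless mass-transfer Biot number L = h R / D_eff."""
    return params.biot


def _n_terms_for_tau(tau_min: float) -> int:
    """Adaptive truncation: number of series terms for smallest tau requested.

    Terms decay like exp(-beta_n^2 tau) with beta_n <= n pi, and the
    coefficients are bounded by 6/(n^2 pi^2) (and by 6 L^2 / beta_1^4 overall),
    so the tail is geometric in exp(-pi^2 tau).  We keep terms until the next
    term magnitude is below _TERM_TOL and the geometric tail bound is below
    _TAIL_TOL, which for beta_n ~ (n - 1/2) pi means
    n > sqrt(ln(1/tol) / tau) / pi, padded for the sub-pi first roots.
    """
    need = np.sqrt(np.log(1.0 / min(_TERM_TOL, _TAIL_TOL)) / tau_min) / np.pi
    return int(np.clip(np.ceil(need) + 10, 8, _MAX_TERMS))


def _series_coefficients(biot: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Series coefficients 6 L^2 / (beta_n^2 (beta_n^2 + L^2 - L))."""
    b = np.asarray(biot, dtype=float)[..., None]
    return 6.0 * b**2 / (beta**2 * (beta**2 + b**2 - b))


def _fractional_release_tau(
    biot: np.ndarray, tau: np.ndarray, n_terms: int
) -> np.ndarray:
    """Batched series evaluation on dimensionless time.

    ``biot`` has shape (P,), ``tau`` shape (P, T) or (T,); returns (P, T).
    Values are clipped to [0, 1]; tau below _TAU_FLOOR maps to 0 exactly.
    """
    biot = np.atleast_1d(np.asarray(biot, dtype=float))
    tau = np.asarray(tau, dtype=float)
    if tau.ndim == 1:
        tau = np.broadcast_to(tau, (biot.size, tau.size))
    beta = _solve_eigenvalues_batch(biot, n_terms)  # (P, N)
    coef = _series_coefficients(biot, beta)  # (P, N)
    # exp(-beta^2 tau): (P, N, T); small problems only, so dense is fine
    expo = np.exp(-(beta[:, :, None] ** 2) * tau[:, None, :])
    frac = 1.0 - np.einsum("pn,pnt->pt", coef, expo)
    frac = np.clip(frac, 0.0, 1.0)
    frac[tau < _TAU_FLOOR] = 0.0
    return frac


def fractional_release(
    params: ModelParams,
    times,
    n_terms: int | None = None,
    tol: float = 1e-9,
) -> np.ndarray:
    """Cumulative fractional release M_t/M_inf at the given times (seconds).

    Evaluates the eigenvalue series with the film-resistance coefficients.
    Truncation is adaptive on the smallest requested dimensionless time
    (hard cap 10^4 terms); times with tau = D_eff t / R^2 below 1e-6 return
    0 with a logged note, because the series converges too slowly there to
    certify a value and the physical release is negligible.

    Parameters
    ----------
    params : ModelParams
    times : array-like of float
        Non-negative instants, seconds.
    n_terms : int, optional
        Fixed number of series terms; default adapts to the time grid.
    tol : float
        Residual tolerance passed to the eigenvalue solver.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(times < 0):
        raise InvalidParameterError("times must be non-negative")
    tau = params.tau(times)
    live = tau >= _TAU_FLOOR
    if not np.any(live):
        if times.size:
            logger.info(
                "all requested times have tau < %.0e; returning 0 (series not evaluated)",
                _TAU_FLOOR,
            )
        return np.zeros_like(tau)
    if np.any(~live):
        logger.info(
            "%d time(s) with tau < %.0e set to 0 without series evaluation",
            int(np.sum(~live)),
            _TAU_FLOOR,
        )
    if n_terms is None:
        n_terms = _n_terms_for_tau(float(tau[live].min()))
    solve_eigenvalues(params.biot, min(int(n_terms), 32), tol)  # residual check
    return _fractional_release_tau(np.array([params.biot]), tau, int(n_terms))[0]


def fractional_release_large_L(
    params: ModelParams, times, n_terms: int | None = None
) -> np.ndarray:
    """Simplified series for negligible film resistance (large Biot number).

    Evaluates ``1 - (6/pi^2) sum_n exp(-n^2 pi^2 D_eff t / R^2) / n^2``,
    the limit of the full solution as L -> inf where the eigenvalues become
    multiples of pi.  Intended for L >= LARGE_L_THRESHOLD; h is ignored.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(times < 0):
        raise InvalidParameterError("times must be non-negative")
    tau = params.tau(times)
    live = tau >= _TAU_FLOOR
    out = np.zeros_like(tau)
    if not np.any(live):
        return out
    if n_terms is None:
        n_terms = _n_terms_for_tau(float(tau[live].min()))
    n = np.arange(1, int(n_terms) + 1, dtype=float)
    expo = np.exp(-np.pi**2 * n[:, None] ** 2 * tau[None, live])
    out[live] = np.clip(1.0 - (6.0 / np.pi**2) * np.sum(expo / n[:, None] ** 2, axis=0), 0.0, 1.0)
    return out
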