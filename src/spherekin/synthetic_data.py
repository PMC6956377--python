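"""Synthetic release curves and gravimetric series for end-to-end testing.

Curves are generated by the forward sphere model under named scenarios and
corrupted with additive Gaussian noise on the fraction scale (truncated to
[0, 1]), emulating normalized spectrophotometric or gamma-count readouts.
The built-in scenarios reproduce the two in-vitro release regimes of the
estradiol microspheres — a fast methanol:water medium and a slow aqueous
surfactant (SLS) medium — plus a low-Biot regime where the external film
dominates and h is well identified.

The default time design places 12 log-spaced sampling instants spanning
model fractions of roughly 0.05 to 0.99, which covers both the early,
film-sensitive part of the curve and the late, diffusion-sensitive tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .release_metrics import GravimetricSample
from .sphere_model import (
    DEFAULT_RADIUS_M,
    InvalidParameterError,
    ModelParams,
    ReleaseCurve,
    fractional_release,
)

__all__ = [
    "Scenario",
    "builtin_scenarios",
    "generate_release_curve",
    "generate_gravimetric_series",
    "design_times",
]


class InvalidDesignError(ValueError):
    """A time design or noise profile violates the generator's contract."""


@dataclass(frozen=True)
class Scenario:
    """One simulated release condition with known ground truth."""

    name: str
    true_params: ModelParams
    n_times: int = 12
    frac_span: tuple[float, float] = (0.05, 0.99)
    noise_sd: float = 0.02
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise InvalidDesignError("noise_sd must be >= 0")
        if self.n_times < 3:
            raise InvalidDesignError("time design must yield >= 3 points")
        lo, hi = self.frac_span
        if not (0 < lo < hi < 1):
            raise InvalidDesignError("frac_span must satisfy 0 < lo < hi < 1")


def _time_at_fraction(params: ModelParams, frac: float) -> float:
    """Invert the (monotone) forward model: time at which release reaches frac."""
    lo, hi = 1e-6, 1.0
    # bracket in dimensionless time, then bisect; release at tau=10 is ~1
    while fractional_release(params, [hi * params.radius**2 / params.d_eff])[0] < frac:
        hi *= 4.0
        if hi > 1e4:
            raise InvalidDesignError(f"release never reaches {frac}")
    for _ in range(80):
        mid = np.sqrt(lo * hi)
        f = fractional_release(params, [mid * params.radius**2 / params.d_eff])[0]
        if f < frac:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi) * params.radius**2 / params.d_eff)


def design_times(
    params: ModelParams, n_times: int = 12, frac_span: tuple[float, float] = (0.05, 0.99)
) -> np.ndarray:
    """Log-spaced sampling instants spanning the requested fraction range."""
    t_lo = _time_at_fraction(params, frac_span[0])
    t_hi = _time_at_fraction(params, frac_span[1])
    return np.geomspace(t_lo, t_hi, n_times)


def builtin_scenarios() -> dict[str, Scenario]:
    """Named scenarios parameterized from the fitted microsphere constants.

    ``meoh_water`` and ``sls`` carry the estimated (D_eff, h) for
    estradiol release in methanol:water (50:50) and aqueous SLS 1%
    respectively, with R = 50.7 um (half the volume-median diameter);
    ``low_biot`` shares the SLS diffusivity but a film coefficient giving
    L = 1, where h is strongly identified.
    """
    r = DEFAULT_RADIUS_M
    scenarios = [
        Scenario("meoh_water", ModelParams(d_eff=2.28e-15, h=7.56e-10, radius=r)),
        Scenario("sls", ModelParams(d_eff=5.58e-16, h=4.01e-10, radius=r)),
        Scenario("low_biot", ModelParams(d_eff=5.58e-16, h=5.58e-16 / r, radius=r)),
    ]
    return {s.name: s for s in scenarios}


def generate_release_curve(scenario: Scenario) -> list[ReleaseCurve]:
    """Simulate the scenario's replicates.

    Each replicate shares the time design; fractions are the forward-model
    values plus iid Gaussian noise of SD ``noise_sd``, truncated to [0, 1].
    Reproducible from ``scenario.seed``.
    """
    times = design_times(scenario.true_params, scenario.n_times, scenario.frac_span)
    if times.size < 3:
        raise InvalidDesignError("time design produced fewer than 3 points")
    clean = fractional_release(scenario.true_params, times)
    rng = np.random.default_rng(scenario.seed)
    curves = []
    for i in range(scenario.n_replicates):
        noisy = clean + rng.normal(0.0, scenario.noise_sd, size=clean.shape)
        noisy = np.clip(noisy, 0.0, 1.0)
        curves.append(
            ReleaseCurve(
                times=times,
                fractions=noisy,
                replicate_id=f"{scenario.name}_r{i + 1}",
                normalization_mode="final_observed",
            )
        )
    return curves


def generate_gravimetric_series(
    w0: float,
    loss_profile: dict[float, float],
    uptake_profile: dict[float, float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[GravimetricSample]:
    """Construct weight triples matching target mass-loss/uptake trajectories.

    Parameters
    ----------
    w0 : float
        Initial sample weight, mg.
    loss_profile, uptake_profile : dict
        Maps time (seconds) -> expected mass loss % and water uptake %.
        Both must cover the same times.
    noise_sd : float
        SD of Gaussian noise added to the loss and uptake percentages
        (percentage points); noisy losses are confined to (-inf, 100) and
        uptakes to [0, inf) so the weight invariants hold.
    seed : int
        Reproducibility seed.

    Returns
    -------
    list of GravimetricSample
        One sample per time, in time order.
    """
    if w0 <= 0:
        raise InvalidParameterError("w0 must be > 0")
    if set(loss_profile) != set(uptake_profile):
        raise InvalidDesignError("loss and uptake profiles must cover the same times")
    for t, loss in loss_profile.items():
        if loss >= 100.0:
            raise InvalidDesignError(f"loss {loss}% at t={t} implies non-positive dry weight")
    for t, upt in uptake_profile.items():
        if upt < 0.0:
            raise InvalidDesignError(f"uptake {upt}% at t={t} implies wet < dry weight")
    rng = np.random.default_rng(seed)
    samples = []
    for t in sorted(loss_profile):
        loss = loss_profile[t] + rng.normal(0.0, noise_sd)
        upt = uptake_profile[t] + rng.normal(0.0, noise_sd)
        loss = min(loss, 99.99)
        upt = max(upt, 0.0)
        wd = w0 * (1.0 - loss / 100.0)
        ww = wd * (1.0 + upt / 100.0)
        samples.append(GravimetricSample(w0=w0, ww=ww, wd=wd, time=float(t)))
    return samples
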