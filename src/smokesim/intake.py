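"""Cigarette-lighting renewal process and the intake-rate law.

Lighting a cigarette is a point process whose intensity grows with the
uncontrolled urge ``u = max(C - S, 0)`` and, optionally, with the time
elapsed since the last cigarette (the urge builds up while lighting is
postponed)::

    lambda(t) = (alpha + beta * t) * u,

with the clock reset to 0 each time a cigarette is finished, so the
process is a renewal process (inter-event times are i.i.d.; they are
exponential only for ``beta = 0``).  The expected waiting time to the
next cigarette is the survival integral

    E[T] = integral_0^inf exp(-Lambda(t)) dt,
    Lambda(t) = u * (alpha*t + beta*t**2/2),

and its reciprocal is the mean intake rate.

Units: ``alpha`` and ``beta`` are expressed directly as intake-rate
coefficients, in mg of absorbed nicotine per hour per unit urge, so
that the constant-urge intake law reduces exactly to ``Q = alpha * u``
(the deterministic model's ``f * u`` with ``alpha = f``).  Division by
the nicotine absorbed per cigarette (``m = 1.7 mg * 25% = 0.425 mg``)
converts an intake rate to cigarettes per hour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

__all__ = [
    "IntensityParams",
    "cumulative_intensity",
    "expected_waiting_time",
    "intake_rate",
    "intake_to_cigarettes_per_hour",
    "sample_lighting_times",
]

#: survival below this level truncates the waiting-time integral
_SURVIVAL_FLOOR = 1e-12


@dataclass(frozen=True)
class IntensityParams:
    """Coefficients of the time-dependent lighting intensity.

    ``alpha`` [mg/h per unit urge] is the base intensity, ``beta``
    [mg/h^2 per unit urge] the linear urge growth while lighting is
    postponed, and ``m`` [mg] the nicotine absorbed per cigarette.
    Defaults are the constant-urge calibration (0.68, 0); the
    increasing-urge variant uses (0.6, 0.013).
    """

    alpha: float = 0.68
    beta: float = 0.0
    m: float = 0.425

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be positive, got {self.alpha!r}")
        if self.beta < 0:
            raise ValueError(f"beta must be non-negative, got {self.beta!r}")
        if not self.m > 0:
            raise ValueError(f"m must be positive, got {self.m!r}")


def cumulative_intensity(
    t: float | np.ndarray, u: float, params: IntensityParams
) -> float | np.ndarray:
    """Integrated intensity Lambda(t) = u*(alpha*t + beta*t^2/2)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    if u < 0:
        raise ValueError(f"urge u must be non-negative, got {u!r}")
    lam = u * (params.alpha * t + 0.5 * params.beta * t * t)
    return float(lam) if lam.ndim == 0 else lam


def _truncation_time(u: float, params: IntensityParams) -> float:
    """Time at which exp(-Lambda) drops below the survival floor."""
    target = -math.log(_SURVIVAL_FLOOR)  # Lambda level ~27.6
    a, b = params.alpha, params.beta
    if b == 0.0:
        return target / (a * u)
    # solve u*(a*t + b*t^2/2) = target for the positive root
    return (-a + math.sqrt(a * a + 2.0 * b * target / u)) / b


def expected_waiting_time(u: float, params: IntensityParams) -> float:
    """Expected time [h] until the next cigarette at constant urge u.

    Evaluates the survival integral by adaptive quadrature, truncated
    where the integrand falls below 1e-12.  Returns ``math.inf`` for
    ``u = 0`` (no urge, no event, ever).  For ``beta = 0`` the result
    equals ``1/(alpha*u)`` to quadrature tolerance.
    """
    if u < 0:
        raise ValueError(f"urge u must be non-negative, got {u!r}")
    if u == 0.0:
        return math.inf
    upper = _truncation_time(u, params)
    val, _err = quad(
        lambda t: math.exp(-cumulative_intensity(t, u, params)),
        0.0,
        upper,
        epsabs=1e-10,
        epsrel=1e-10,
        limit=200,
    )
    return val


def intake_rate(u: float, params: IntensityParams) -> float:
    """Mean nicotine intake rate Q [mg/h] at constant urge u.

    The reciprocal of the expected waiting time, in the intake-rate
    units of ``alpha`` (so that ``beta = 0`` gives exactly
    ``Q = alpha*u``); zero at zero urge.
    """
    if u == 0.0:
        return 0.0
    return 1.0 / expected_waiting_time(u, params)


def intake_to_cigarettes_per_hour(Q: float, params: IntensityParams) -> float:
    """Convert an intake rate [mg/h] to cigarettes per hour."""
    return Q / params.m


def _invert_cumulative(e: float, u: float, params: IntensityParams) -> float:
    """Solve Lambda(t) = e for t (closed form)."""
    a, b = params.alpha, params.beta
    if b == 0.0:
        return e / (a * u)
    return (-a + math.sqrt(a * a + 2.0 * b * e / u)) / b


def sample_lighting_times(
    u: float,
    params: IntensityParams,
    horizon: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample cigarette-lighting times on [0, horizon] at constant urge.

    Inter-event times are drawn by inversion of the cumulative
    intensity, with the intensity clock reset after each event
    (renewal convention).  For ``beta = 0`` they are i.i.d.
    exponential with rate ``alpha*u``.
    """
    if not horizon > 0:
        raise ValueError(f"horizon must be positive, got {horizon!r}")
    if u < 0:
        raise ValueError(f"urge u must be non-negative, got {u!r}")
    if u == 0.0:
        return np.array([], dtype=float)
    times: list[float] = []
    t = 0.0
    while True:
        wait = _invert_cumulative(rng.exponential(), u, params)
        t += wait
        if t > horizon:
            break
        times.append(t)
    return np.asarray(times, dtype=float)
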