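"""Deterministic core of the nicotine--craving model.

Two coupled rate equations describe a smoker's state: the amount of
nicotine in the body ``N`` [mg] and a dimensionless craving level
``C`` in [0, 1] that scales with the fraction of activated nicotinic
acetylcholine receptors.  A control level ``S`` (self-control plus
societal pressure, on the craving scale) subtracts from craving in the
intake law::

    dN/dt = f * max(C - S, 0) - r * N
    dC/dt = b * (1 - C) * N - v * C

Intake is clamped at zero: a controlled person with ``C <= S`` does not
smoke.  Because ``f`` and ``r`` are roughly a hundredfold larger than
``b`` and ``v``, ``N`` is a fast variable slaved to the slow craving
dynamics after a transient of a few ``1/r``.

For fixed ``S`` the system has one or three equilibria.  On the smoking
branch (``C > S``) the equilibrium craving solves the quadratic

    a*C**2 - (a*(1 + S) - v)*C + a*S = 0,      a = b*f/r,

and the no-smoking equilibrium ``(0, 0)`` exists whenever ``S >= 0``.
Between the two fold points of this quadratic the system is bistable:
steady smoking and abstinence coexist, and transitions between them
(quitting, relapse) are driven by movements of ``S``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "ModelParams",
    "State",
    "Equilibrium",
    "BifurcationDiagram",
    "derive_rate_constants",
    "rhs",
    "quasi_steady_N",
    "find_equilibria",
    "bistable_interval",
    "equilibrium_craving_from_intake",
    "bifurcation_diagram",
    "integrate_deterministic",
]

#: hours of "awake" time per model day; nights are skipped
DAY_HOURS = 16.0


def _require_positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be positive, got {value!r}")


@dataclass(frozen=True)
class ModelParams:
    """Rate constants of the deterministic dynamics.

    Parameters
    ----------
    f : float
        Intake gain [mg/h per unit of uncontrolled craving].
    r : float
        Nicotine elimination rate [1/h] (half-life ln2/r).
    b : float
        Craving activation rate [1/(mg h)].
    v : float
        Craving decay rate [1/h]; 1/v is of the order of months.
    g : float
        Urge growth rate [1/h^2] of the time-dependent lighting
        intensity; 0 for the constant-urge case used throughout.
    """

    f: float = 0.680
    r: float = 0.385
    b: float = 6.27e-3
    v: float = 5.54e-3
    g: float = 0.0

    def __post_init__(self) -> None:
        for name in ("f", "r", "b", "v"):
            _require_positive(name, getattr(self, name))
        if self.g < 0:
            raise ValueError(f"g must be non-negative, got {self.g!r}")

    @property
    def a(self) -> float:
        """Composite gain b*f/r of the reduced slow dynamics."""
        return self.b * self.f / self.r


@dataclass(frozen=True)
class State:
    """Instantaneous state (N, C, S)."""

    N: float
    C: float
    S: float

    def __post_init__(self) -> None:
        if self.N < 0:
            raise ValueError(f"N must be non-negative, got {self.N!r}")
        if not 0.0 <= self.C <= 1.0:
            raise ValueError(f"C must lie in [0, 1], got {self.C!r}")


@dataclass(frozen=True)
class Equilibrium:
    """A fixed point of the deterministic system at fixed S."""

    N: float
    C: float
    stability: Literal["stable", "unstable"]


def derive_rate_constants(
    nicotine_half_life_h: float = 1.8,
    craving_ref_days: float = 26.0,
    craving_residual_fraction: float = 0.1,
    cigs_per_hour: float = 0.8,
    mg_per_cig: float = 1.7,
    uptake_fraction: float = 0.25,
    reference_C: float = 0.5,
) -> ModelParams:
    """Derive (f, r, b, v) from observable calibration quantities.

    ``r`` follows from the nicotine half-life; ``v`` from the craving
    level having decayed to ``craving_residual_fraction`` after
    ``craving_ref_days`` days of 16 waking hours.  The intake gain is
    calibrated on a moderate smoker: ``Q_ref = cigs_per_hour *
    mg_per_cig * uptake_fraction`` at equilibrium craving
    ``reference_C`` with no control, giving ``f = Q_ref/reference_C``;
    the equilibrium conditions then force ``b = 2*r*v/f`` when
    ``reference_C = 1/2``.

    With the defaults this reproduces f=0.680, r=0.385, b=6.27e-3,
    v=5.54e-3 (3 significant figures).
    """
    for name, value in (
        ("nicotine_half_life_h", nicotine_half_life_h),
        ("craving_ref_days", craving_ref_days),
        ("craving_residual_fraction", craving_residual_fraction),
        ("cigs_per_hour", cigs_per_hour),
        ("mg_per_cig", mg_per_cig),
        ("uptake_fraction", uptake_fraction),
        ("reference_C", reference_C),
    ):
        _require_positive(name, value)
    if craving_residual_fraction >= 1:
        raise ValueError(
            "craving_residual_fraction must be < 1, got "
            f"{craving_residual_fraction!r}"
        )
    if not reference_C < 1:
        raise ValueError(f"reference_C must lie in (0, 1), got {reference_C!r}")

    r = math.log(2.0) / nicotine_half_life_h
    v = -math.log(craving_residual_fraction) / (craving_ref_days * DAY_HOURS)
    q_ref = cigs_per_hour * mg_per_cig * uptake_fraction
    f = q_ref / reference_C
    # equilibrium of dC/dt: N = v*C/(b*(1-C)); of dN/dt: N = f*C/r (S=0)
    b = v * r / (f * (1.0 - reference_C))
    return ModelParams(f=f, r=r, b=b, v=v)


def rhs(state: State, params: ModelParams) -> tuple[float, float]:
    """Right-hand side (dN/dt, dC/dt) of the deterministic system."""
    intake = params.f * max(state.C - state.S, 0.0)
    dN = intake - params.r * state.N
    dC = params.b * (1.0 - state.C) * state.N - params.v * state.C
    return dN, dC


def quasi_steady_N(C: float, S: float, params: ModelParams) -> float:
    """Fast-variable nullcline N = f*max(C-S, 0)/r (dN/dt = 0)."""
    return params.f * max(C - S, 0.0) / params.r


def _slow_reduced(C: float, S: float, params: ModelParams) -> float:
    """dC/dt on the quasi-steady manifold N = quasi_steady_N(C, S)."""
    return (
        params.b * (1.0 - C) * quasi_steady_N(C, S, params)
        - params.v * C
    )


def _jacobian(N: float, C: float, S: float, params: ModelParams) -> np.ndarray:
    """Jacobian on the branch the point lies in (C<=S: no-intake branch)."""
    dintake_dC = params.f if C > S else 0.0
    return np.array(
        [
            [-params.r, dintake_dC],
            [params.b * (1.0 - C), -params.b * N - params.v],
        ]
    )


def _classify(N: float, C: float, S: float, params: ModelParams) -> Equilibrium:
    eig = np.linalg.eigvals(_jacobian(N, C, S, params))
    stability = "stable" if np.all(eig.real < 0) else "unstable"
    return Equilibrium(N=N, C=C, stability=stability)


def find_equilibria(S: float, params: ModelParams) -> list[Equilibrium]:
    """All equilibria of the system at fixed control S, with stability.

    The smoking branch is solved in closed form from the equilibrium
    quadratic; a bisection fallback on the reduced slow equation guards
    against a degenerate leading coefficient.  The no-smoking
    equilibrium (0, 0) exists iff S >= 0 (for negative S the origin has
    positive intake).  Stability comes from the Jacobian eigenvalues of
    the branch each equilibrium lies in.
    """
    a = params.a
    out: list[Equilibrium] = []

    if S >= 0:
        out.append(_classify(0.0, 0.0, S, params))

    roots: list[float] = []
    if a > 1e-12:
        coeffs = [a, -(a * (1.0 + S) - params.v), a * S]
        disc = coeffs[1] * coeffs[1] - 4.0 * coeffs[0] * coeffs[2]
        if disc >= 0.0:
            sq = math.sqrt(disc)
            roots = [(-coeffs[1] - sq) / (2 * a), (-coeffs[1] + sq) / (2 * a)]
    else:
        # degenerate gain: scan the reduced slow equation for sign changes
        grid = np.linspace(max(S, 0.0) + 1e-9, 1.0, 4096)
        vals = np.array([_slow_reduced(c, S, params) for c in grid])
        for i in np.flatnonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0):
            roots.append(
                brentq(_slow_reduced, grid[i], grid[i + 1], args=(S, params))
            )

    for C_eq in sorted(roots):
        if C_eq <= max(S, 0.0) or C_eq > 1.0:
            continue  # off the smoking branch
        N_eq = params.f * (C_eq - S) / params.r
        out.append(_classify(N_eq, C_eq, S, params))
    return out


def bistable_interval(
    params: ModelParams,
) -> tuple[float, float] | None:
    """Control interval (S_low, S_high) with two coexisting stable states.

    S_low is 0: the no-smoking equilibrium exists (and is stable) only
    for S >= 0.  S_high is the fold point where the discriminant of the
    smoking-branch quadratic vanishes, in closed form
    ``(sqrt(a) - sqrt(v))**2 / a`` (smaller root), refined by bisection.
    Returns ``None`` when no bistable interval exists (a <= v).
    """
    a, v = params.a, params.v
    if a <= v:
        return None
    s_high = (math.sqrt(a) - math.sqrt(v)) ** 2 / a

    def disc(S: float) -> float:
        m = a * (1.0 + S) - v
        return m * m - 4.0 * a * a * S

    # refine the closed form against roundoff; disc is decreasing here
    lo, hi = 0.999 * s_high, 1.001 * s_high
    if disc(lo) > 0 > disc(hi):
        s_high = brentq(disc, lo, hi, xtol=1e-10)
    return 0.0, s_high


def equilibrium_craving_from_intake(Q: float, params: ModelParams) -> float:
    """Equilibrium craving as a saturating function of intake rate Q.

    Eliminating N between the two equilibrium conditions yields the
    Michaelis--Menten relation C = Q/(Q + v*r/b): craving saturates at 1
    for large intake, mirroring receptor saturation.
    """
    if Q < 0:
        raise ValueError(f"Q must be non-negative, got {Q!r}")
    if Q == 0.0:
        return 0.0
    return Q / (Q + params.v * params.r / params.b)


@dataclass
class BifurcationDiagram:
    """Equilibrium branches as a function of the control S."""

    S_grid: np.ndarray
    branches: list[list[Equilibrium]]
    S_fold_low: float | None
    S_fold_high: float | None
    params: ModelParams = field(default_factory=ModelParams)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"S": float(s), "N_eq": eq.N, "C_eq": eq.C, "stability": eq.stability}
            for s, eqs in zip(self.S_grid, self.branches)
            for eq in eqs
        ]
        return pd.DataFrame(rows, columns=["S", "N_eq", "C_eq", "stability"])


def bifurcation_diagram(
    params: ModelParams | None = None,
    S_grid: Sequence[float] | None = None,
) -> BifurcationDiagram:
    """Sweep S and collect the equilibrium branches (hysteresis diagram)."""
    params = params or ModelParams()
    if S_grid is None:
        S_grid = np.linspace(-0.05, 0.15, 401)
    S_grid = np.asarray(S_grid, dtype=float)
    branches = [find_equilibria(float(s), params) for s in S_grid]
    interval = bistable_interval(params)
    low, high = interval if interval is not None else (None, None)
    return BifurcationDiagram(
        S_grid=S_grid,
        branches=branches,
        S_fold_low=low,
        S_fold_high=high,
        params=params,
    )


def integrate_deterministic(
    initial: State,
    params: ModelParams,
    duration_h: float,
    t_eval: np.ndarray | None = None,
    rtol: float = 1e-8,
):
    """Integrate the deterministic system at fixed S with a stiff solver.

    The ~100-fold separation between the fast (f, r) and slow (b, v)
    rates makes the system mildly stiff; LSODA switches automatically.
    Returns the scipy solution object (``.t``, ``.y`` with rows N, C).
    """
    S = initial.S

    def fun(_t, y):
        dN, dC = rhs(State(N=max(y[0], 0.0), C=min(max(y[1], 0.0), 1.0), S=S), params)
        return [dN, dC]

    return solve_ivp(
        fun,
        (0.0, duration_h),
        [initial.N, initial.C],
        method="LSODA",
        rtol=rtol,
        atol=1e-10,
        t_eval=t_eval,
        dense_output=t_eval is None,
    )
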