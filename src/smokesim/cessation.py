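"""Cessation schemes and their Monte Carlo evaluation.

A therapy lasts ``T`` days (of 16 waking hours).  During the first
``T_s`` days the prescribed nicotine intake is tapered linearly from
``Q_start`` to zero; during the remaining ``T - T_s`` days it is held
at zero.  The end-points of the family are the two classical schemes:

* abrupt cessation: ``T_s = 0`` (zero intake from day one),
* gradual cessation: ``T_s = T`` (taper only).

Throughout the therapy the control set-point is raised to
``S0_therapy`` (default 0.1, the externally enforced vigilance of a
supervised programme) and nicotine follows the prescribed schedule
instead of the craving-driven intake law; craving itself keeps obeying
its own dynamics, which is what makes longer therapies work: craving
must decay below the separatrix of the post-therapy bistable system
before the prescription is lifted.

A trial starts from the steady-smoking equilibrium, runs the therapy,
then a full year (365 16-hour days) of free dynamics with the set-point
back at its everyday value.  It counts as a success when the mean
intake over that year stays below 5% of the pre-therapy intake (a
strict pointwise variant of the criterion is available).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .model import DAY_HOURS, ModelParams, State, find_equilibria
from .stochastic import ControlParams

__all__ = [
    "TherapyScheme",
    "TrialOutcome",
    "SuccessCurve",
    "MinimalDuration",
    "DurationRegression",
    "scheme_intake_profile",
    "run_trial",
    "success_rate",
    "success_curve",
    "minimal_total_duration",
    "duration_regression",
]

POST_THERAPY_DAYS = 365
SUCCESS_FRACTION = 0.05  # "below 5% of the intake before the therapy"


@dataclass(frozen=True)
class TherapyScheme:
    """A mixed cessation schedule (taper for T_s days, abstain to T)."""

    T_s: float
    T: float
    S0_therapy: float = 0.1
    Q_start: float = 0.262

    def __post_init__(self) -> None:
        if self.T_s < 0:
            raise ValueError(f"T_s must be non-negative, got {self.T_s!r}")
        if self.T < self.T_s:
            raise ValueError(
                f"total length T ({self.T!r}) must be >= taper length "
                f"T_s ({self.T_s!r})"
            )
        if self.Q_start < 0:
            raise ValueError(f"Q_start must be non-negative, got {self.Q_start!r}")

    @classmethod
    def abrupt(cls, T: float, **kw) -> "TherapyScheme":
        return cls(T_s=0.0, T=T, **kw)

    @classmethod
    def gradual(cls, T: float, **kw) -> "TherapyScheme":
        return cls(T_s=T, T=T, **kw)

    @classmethod
    def mixed(cls, T_s: float, T: float, **kw) -> "TherapyScheme":
        return cls(T_s=T_s, T=T, **kw)


def scheme_intake_profile(
    scheme: TherapyScheme, t_days: float
) -> float | None:
    """Prescribed intake [mg/h] at time ``t_days``; None once the
    therapy has ended and intake reverts to the craving-driven law."""
    if t_days < 0:
        raise ValueError(f"t_days must be non-negative, got {t_days!r}")
    if t_days >= scheme.T:
        return None
    if t_days < scheme.T_s:
        return scheme.Q_start * (1.0 - t_days / scheme.T_s)
    return 0.0


def _prescribed_profile(scheme: TherapyScheme, dt: float) -> np.ndarray:
    """Per-step prescribed intake over the therapy phase."""
    n_therapy = int(round(scheme.T * DAY_HOURS / dt))
    t_h = np.arange(n_therapy) * dt
    taper_h = scheme.T_s * DAY_HOURS
    if taper_h > 0:
        q = np.where(t_h < taper_h, scheme.Q_start * (1.0 - t_h / taper_h), 0.0)
    else:
        q = np.zeros(n_therapy)
    return q


@dataclass(frozen=True)
class TrialOutcome:
    """Result of a single simulated cessation attempt."""

    success: bool
    mean_post_intake: float  # mg/h averaged over the post-therapy year
    max_post_intake: float  # largest instantaneous intake in that year
    C_end_of_therapy: float
    seed: int | tuple


def _smoking_start(model: ModelParams, control: ControlParams) -> State:
    """Steady-smoking equilibrium at the everyday set-point."""
    smoking = [
        eq
        for eq in find_equilibria(control.S0, model)
        if eq.stability == "stable" and eq.C > control.S0
    ]
    if not smoking:
        raise ValueError(
            f"no stable smoking equilibrium at S0={control.S0!r}; "
            "cannot start a cessation trial from steady smoking"
        )
    eq = max(smoking, key=lambda e: e.C)
    return State(N=eq.N, C=eq.C, S=control.S0)


def run_trial(
    scheme: TherapyScheme,
    model: ModelParams | None = None,
    control: ControlParams | None = None,
    dt: float = 0.1,
    seed: int | np.random.SeedSequence = 0,
    post_days: int = POST_THERAPY_DAYS,
    criterion: Literal["mean", "pointwise"] = "mean",
    initial: State | None = None,
) -> TrialOutcome:
    """Simulate one cessation attempt and classify it.

    The run starts at the steady-smoking equilibrium for the everyday
    set-point (``control.S0``).  During ``[0, T)`` the control
    set-point is ``scheme.S0_therapy`` and nicotine follows the
    prescribed schedule; afterwards both revert and the system runs
    freely for ``post_days`` days.  Success compares the post-therapy
    intake (mean, or maximum for the pointwise criterion) against 5%
    of the pre-therapy equilibrium intake.
    """
    model = model or ModelParams()
    control = control or ControlParams()
    if not dt > 0:
        raise ValueError(f"dt must be positive, got {dt!r}")
    start = initial if initial is not None else _smoking_start(model, control)
    baseline = model.f * max(start.C - control.S0, 0.0)

    q_presc = _prescribed_profile(scheme, dt)
    n_post = int(round(post_days * DAY_HOURS / dt))
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    rng = np.random.Generator(np.random.PCG64(ss))
    n_total = len(q_presc) + n_post
    if control.epsilon > 0:
        noise = rng.standard_normal(n_total) * math.sqrt(dt)
    else:
        noise = np.zeros(n_total)

    mean_q, max_q, c_end, _s_end, bad = _kernels.therapy_trial(
        start.N,
        start.C,
        start.S,
        dt,
        model.f,
        model.r,
        model.b,
        model.v,
        control.q,
        control.epsilon,
        q_presc,
        scheme.S0_therapy,
        control.S0,
        n_post,
        noise,
    )
    if bad >= 0:
        raise RuntimeError(
            f"non-finite state at step {bad} (t = {bad * dt:.2f} h) of the trial"
        )
    threshold = SUCCESS_FRACTION * baseline
    observed = mean_q if criterion == "mean" else max_q
    return TrialOutcome(
        success=bool(observed < threshold),
        mean_post_intake=float(mean_q),
        max_post_intake=float(max_q),
        C_end_of_therapy=float(c_end),
        seed=ss.entropy if ss.spawn_key == () else (ss.entropy, ss.spawn_key),
    )


@dataclass
class SuccessCurve:
    """Monte Carlo success rates over a grid of therapy lengths."""

    durations: np.ndarray  # T [days]
    success_rate: np.ndarray  # fraction of successful runs
    n_runs: int
    scheme: str  # descriptor, e.g. "abrupt" / "gradual" / "mixed(T_s=21)"
    base_seed: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "T_days": self.durations,
                "success_rate": self.success_rate,
                "n_runs": self.n_runs,
            }
        )


def success_rate(
    scheme: TherapyScheme,
    model: ModelParams | None = None,
    control: ControlParams | None = None,
    n_runs: int = 100,
    base_seed: int = 0,
    dt: float = 0.1,
    criterion: Literal["mean", "pointwise"] = "mean",
) -> tuple[int, int]:
    """Monte Carlo estimate: (number of successes, number of runs).

    Per-run seeds are spawned from ``base_seed`` with a counter-based
    scheme, so batches are reproducible and order-independent: run i
    gives the same outcome whether simulated alone or in a batch.
    """
    if n_runs < 1:
        raise ValueError(f"n_runs must be >= 1, got {n_runs!r}")
    children = np.random.SeedSequence(base_seed).spawn(n_runs)
    n_success = 0
    for child in children:
        outcome = run_trial(
            scheme, model, control, dt=dt, seed=child, criterion=criterion
        )
        n_success += outcome.success
    return n_success, n_runs


def success_curve(
    family: Literal["abrupt", "gradual"] | float,
    durations: Sequence[float],
    model: ModelParams | None = None,
    control: ControlParams | None = None,
    n_runs: int = 100,
    base_seed: int = 0,
    dt: float = 0.1,
    criterion: Literal["mean", "pointwise"] = "mean",
) -> SuccessCurve:
    """Success rate as a function of total therapy length T.

    ``family`` selects the scheme: "abrupt", "gradual", or a number,
    interpreted as a fixed taper length T_s [days] for mixed schemes.
    """
    rates = []
    for T in durations:
        if family == "abrupt":
            scheme = TherapyScheme.abrupt(T)
        elif family == "gradual":
            scheme = TherapyScheme.gradual(T)
        else:
            scheme = TherapyScheme.mixed(float(family), T)
        k, n = success_rate(
            scheme, model, control, n_runs=n_runs, base_seed=base_seed, dt=dt,
            criterion=criterion,
        )
        rates.append(k / n)
    label = family if isinstance(family, str) else f"mixed(T_s={family})"
    return SuccessCurve(
        durations=np.asarray(list(durations), dtype=float),
        success_rate=np.asarray(rates),
        n_runs=n_runs,
        scheme=label,
        base_seed=base_seed,
    )


@dataclass(frozen=True)
class MinimalDuration:
    """First total length T reaching the target success count."""

    T_s: float
    T_min: float | None  # None when not reached by T_max
    target_successes: int
    n_runs: int
    counts: dict = field(default_factory=dict)  # T -> success count

    @property
    def found(self) -> bool:
        return self.T_min is not None


def minimal_total_duration(
    T_s: float,
    model: ModelParams | None = None,
    control: ControlParams | None = None,
    target_successes: int = 30,
    n_runs: int = 100,
    base_seed: int = 0,
    dt: float = 0.1,
    T_max: float = 200.0,
    criterion: Literal["mean", "pointwise"] = "mean",
) -> MinimalDuration:
    """Smallest T in {T_s, T_s+1, ...} days with >= target successes.

    Walks the whole-day grid upward, running an independent n_runs
    Monte Carlo batch at each T, and stops at the first count reaching
    the target; an explicit not-found result is returned if T_max is
    hit first.
    """
    counts: dict[float, int] = {}
    T = float(T_s)
    while T <= T_max:
        k, _ = success_rate(
            TherapyScheme.mixed(T_s, T),
            model,
            control,
            n_runs=n_runs,
            base_seed=base_seed + int(round(T)),
            dt=dt,
            criterion=criterion,
        )
        counts[T] = k
        if k >= target_successes:
            return MinimalDuration(T_s, T, target_successes, n_runs, counts)
        T += 1.0
    return MinimalDuration(T_s, None, target_successes, n_runs, counts)


@dataclass(frozen=True)
class DurationRegression:
    """OLS summary line T_min = intercept + slope * T_s."""

    intercept: float
    slope: float

    def predict_T(self, T_s: float | np.ndarray):
        return self.intercept + self.slope * np.asarray(T_s, dtype=float)

    def taper_for_total(self, T: float | np.ndarray):
        """Inverse lookup: taper length whose minimal total length is T."""
        if self.slope == 0:
            raise ValueError("slope is zero; the line cannot be inverted")
        return (np.asarray(T, dtype=float) - self.intercept) / self.slope


def duration_regression(
    points: Sequence[tuple[float, float]]
) -> DurationRegression:
    """Least-squares line through (T_s, T_min) points (Monte Carlo
    jitter in the individual grid points is what the line smooths)."""
    if len(points) < 2:
        raise ValueError("need at least two (T_s, T_min) points")
    ts = np.asarray([p[0] for p in points], dtype=float)
    tm = np.asarray([p[1] for p in points], dtype=float)
    if np.ptp(ts) == 0:
        raise ValueError("all T_s values are equal; regression is degenerate")
    slope, intercept = np.polyfit(ts, tm, 1)
    return DurationRegression(intercept=float(intercept), slope=float(slope))
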