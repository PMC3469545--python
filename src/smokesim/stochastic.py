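"""Stochastic control and Euler--Maruyama simulation.

Self-control is not constant: attitude shifts, social pressure and
lapses of vigilance move it around.  The control ``S`` therefore
follows an Ornstein--Uhlenbeck process,

    dS = q*(S0 - S)*dt + eps*dW(t),

mean-reverting to a set-point ``S0`` with diffusion amplitude ``eps``.
Its stationary law is Gaussian with mean ``S0`` and variance
``eps**2/(2q)``; choosing the drift ``q = k**2 * eps**2 / 2`` pins the
stationary standard deviation at exactly ``1/k``.  The default
``eps = 1/(30.3*16) = 2.06e-3`` [1/sqrt(h)] places attitude changes on
a monthly time scale (in 16-hour days), and ``k = 75`` keeps typical
control excursions within a few times 0.0133.

Coupled to the nicotine/craving equations this yields a piecewise-
smooth SDE system integrated by the forward Euler(-Maruyama) scheme;
the diffusion is additive so the scheme is strong order 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import _kernels
from .model import ModelParams, State

__all__ = [
    "ControlParams",
    "Trajectory",
    "ou_drift_coefficient",
    "stationary_density_S",
    "simulate_sde",
]


def ou_drift_coefficient(k: float, epsilon: float) -> float:
    """Drift q = k^2 eps^2 / 2 giving stationary sd exactly 1/k.

    The OU stationary variance is eps^2/(2q); this is the unique drift
    for which it equals 1/k^2.
    """
    if not k > 0:
        raise ValueError(f"k must be positive, got {k!r}")
    if not epsilon > 0:
        raise ValueError(f"epsilon must be positive, got {epsilon!r}")
    return 0.5 * k * k * epsilon * epsilon


@dataclass(frozen=True)
class ControlParams:
    """Ornstein--Uhlenbeck control settings.

    ``S0`` is the set-point, ``epsilon`` the diffusion amplitude
    [1/sqrt(h)], ``k`` the inverse stationary standard deviation.  The
    drift ``q`` [1/h] is derived as ``k^2 eps^2/2`` unless explicitly
    overridden.
    """

    S0: float = 0.05
    epsilon: float = 2.06e-3
    k: float = 75.0
    q: float | None = None

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError(f"epsilon must be non-negative, got {self.epsilon!r}")
        if self.q is None:
            # epsilon = 0 freezes the control entirely (deterministic runs)
            derived = (
                ou_drift_coefficient(self.k, self.epsilon)
                if self.epsilon > 0
                else 0.0
            )
            object.__setattr__(self, "q", derived)
        elif self.q < 0:
            raise ValueError(f"q must be non-negative, got {self.q!r}")

    @property
    def stationary_sd(self) -> float:
        """Standard deviation of the stationary control distribution."""
        if self.q <= 0:
            raise ValueError("stationary distribution requires q > 0")
        return self.epsilon / np.sqrt(2.0 * self.q)


def stationary_density_S(
    s: float | np.ndarray, S0: float, k: float
) -> float | np.ndarray:
    """Stationary density of the control: Gaussian(S0, 1/k)."""
    if not k > 0:
        raise ValueError(f"k must be positive, got {k!r}")
    return norm.pdf(s, loc=S0, scale=1.0 / k)


@dataclass
class Trajectory:
    """Time-indexed record of a simulated path on a uniform grid."""

    t: np.ndarray  # hours since start
    N: np.ndarray  # body nicotine [mg]
    C: np.ndarray  # craving
    S: np.ndarray  # control
    Q: np.ndarray  # instantaneous intake f*max(C-S,0) [mg/h]
    metadata: dict[str, Any] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_h": self.t,
                "N_mg": self.N,
                "C": self.C,
                "S": self.S,
                "Q_mg_per_h": self.Q,
            }
        )


def simulate_sde(
    initial: State,
    model: ModelParams | None = None,
    control: ControlParams | None = None,
    duration_h: float = 16000.0,
    dt: float = 0.1,
    seed: int | np.random.SeedSequence = 0,
) -> Trajectory:
    """Integrate the stochastic system by forward Euler--Maruyama.

    After each step the craving is clamped to [0, 1] and the nicotine
    amount to [0, inf); the exact flow preserves both sets, only the
    discretisation can overshoot (clamp count in
    ``metadata["n_clamped"]``).  With ``epsilon = 0`` the scheme
    reduces to deterministic explicit Euler.  The trajectory is a
    deterministic function of (seed, dt, parameters).
    """
    model = model or ModelParams()
    control = control or ControlParams()
    if not dt > 0:
        raise ValueError(f"dt must be positive, got {dt!r}")
    if duration_h < dt:
        raise ValueError("duration_h must be at least one step long")
    n_steps = int(round(duration_h / dt))
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    rng = np.random.Generator(np.random.PCG64(ss))
    if control.epsilon > 0:
        noise = rng.standard_normal(n_steps) * np.sqrt(dt)
    else:
        noise = np.zeros(n_steps)

    N = np.empty(n_steps + 1)
    C = np.empty(n_steps + 1)
    S = np.empty(n_steps + 1)
    Q = np.empty(n_steps + 1)
    n_clamped, bad = _kernels.sde_path(
        initial.N,
        initial.C,
        initial.S,
        dt,
        model.f,
        model.r,
        model.b,
        model.v,
        control.q,
        control.S0,
        control.epsilon if control.epsilon > 0 else 0.0,
        noise,
        N,
        C,
        S,
        Q,
    )
    if bad >= 0:
        raise RuntimeError(
            f"non-finite state at step {bad} (t = {bad * dt:.3f} h); "
            f"last valid state N={N[bad]:.4g} C={C[bad]:.4g} S={S[bad]:.4g}"
        )
    meta = {
        "dt": dt,
        "seed": ss.entropy,
        "n_clamped": int(n_clamped),
        "model": model,
        "control": control,
    }
    t = np.arange(n_steps + 1) * dt
    return Trajectory(t=t, N=N, C=C, S=S, Q=Q, metadata=meta)
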