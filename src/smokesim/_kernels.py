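"""Forward Euler--Maruyama stepping kernels.

The stochastic system couples the deterministic nicotine/craving
dynamics to an Ornstein--Uhlenbeck control::

    N_{i+1} = N_i + (Q_i - r*N_i)*dt                 (clamped at 0)
    C_{i+1} = C_i + (b*(1-C_i)*N_i - v*C_i)*dt       (clamped to [0,1])
    S_{i+1} = S_i + q*(S0 - S_i)*dt + eps*sqrt(dt)*Z_i

with ``Q_i = f*max(C_i - S_i, 0)`` for free smoking, or a prescribed
intake schedule during therapy.  The diffusion is additive, so the
explicit Euler scheme is already of strong order 1.

Kernels are numba-jitted when numba is importable and fall back to the
identical pure-Python code otherwise (correct but slow).
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda fn: fn


@njit(cache=True)
def sde_path(
    N0: float,
    C0: float,
    S_init: float,
    dt: float,
    f: float,
    r: float,
    b: float,
    v: float,
    q: float,
    S0: float,
    eps: float,
    noise: np.ndarray,
    N_out: np.ndarray,
    C_out: np.ndarray,
    S_out: np.ndarray,
    Q_out: np.ndarray,
):
    """Free-running path; ``noise`` is pre-scaled by sqrt(dt).

    Fills the output arrays (length n_steps+1, index 0 = initial state)
    and returns (n_clamped, bad_step): the number of clamped Euler
    overshoots and the first step producing a non-finite state (-1 if
    none; outputs are valid up to that step).
    """
    n = noise.shape[0]
    N, C, S = N0, C0, S_init
    N_out[0], C_out[0], S_out[0] = N, C, S
    Q_out[0] = f * max(C - S, 0.0)
    n_clamped = 0
    for i in range(n):
        Q = f * max(C - S, 0.0)
        N_new = N + (Q - r * N) * dt
        C_new = C + (b * (1.0 - C) * N - v * C) * dt
        S_new = S + q * (S0 - S) * dt + eps * noise[i]
        if N_new < 0.0:
            N_new = 0.0
            n_clamped += 1
        if C_new < 0.0:
            C_new = 0.0
            n_clamped += 1
        elif C_new > 1.0:
            C_new = 1.0
            n_clamped += 1
        if not (
            np.isfinite(N_new) and np.isfinite(C_new) and np.isfinite(S_new)
        ):
            return n_clamped, i
        N, C, S = N_new, C_new, S_new
        N_out[i + 1], C_out[i + 1], S_out[i + 1] = N, C, S
        Q_out[i + 1] = f * max(C - S, 0.0)
    return n_clamped, -1


@njit(cache=True)
def therapy_trial(
    N0: float,
    C0: float,
    S_init: float,
    dt: float,
    f: float,
    r: float,
    b: float,
    v: float,
    q: float,
    eps: float,
    Q_presc: np.ndarray,
    S0_therapy: float,
    S0_post: float,
    n_post: int,
    noise: np.ndarray,
):
    """One cessation trial: therapy phase then a free post-therapy phase.

    During the first ``len(Q_presc)`` steps nicotine intake follows the
    prescribed schedule ``Q_presc`` [mg/h] and the control set-point is
    ``S0_therapy``; afterwards the craving-driven intake law and the
    set-point ``S0_post`` resume for ``n_post`` steps, over which the
    mean and maximum intake are accumulated.

    Returns (mean_post_intake, max_post_intake, C_end_of_therapy,
    S_end_of_therapy, bad_step).
    """
    n_therapy = Q_presc.shape[0]
    N, C, S = N0, C0, S_init
    C_end = C
    S_end = S
    acc = 0.0
    qmax = 0.0
    for i in range(n_therapy + n_post):
        if i < n_therapy:
            Q = Q_presc[i]
            s_target = S0_therapy
        else:
            Q = f * max(C - S, 0.0)
            acc += Q
            if Q > qmax:
                qmax = Q
            s_target = S0_post
        N_new = N + (Q - r * N) * dt
        C_new = C + (b * (1.0 - C) * N - v * C) * dt
        S_new = S + q * (s_target - S) * dt + eps * noise[i]
        if N_new < 0.0:
            N_new = 0.0
        if C_new < 0.0:
            C_new = 0.0
        elif C_new > 1.0:
            C_new = 1.0
        if not (
            np.isfinite(N_new) and np.isfinite(C_new) and np.isfinite(S_new)
        ):
            return np.nan, np.nan, C_end, S_end, i
        N, C, S = N_new, C_new, S_new
        if i == n_therapy - 1:
            C_end = C
            S_end = S
    if n_therapy == 0:
        C_end = C0
        S_end = S_init
    mean_q = acc / n_post if n_post > 0 else 0.0
    return mean_q, qmax, C_end, S_end, -1
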