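# Methods

## Model

The package simulates an individual smoker as a three-variable
stochastic dynamical system: body nicotine `N` [mg], craving `C`
(dimensionless, in [0, 1], proportional to the fraction of activated
nicotinic acetylcholine receptors), and self/societal control `S` (on
the craving scale; negative values model peer pressure *to* smoke).

Deterministic core (fixed `S`):

    dN/dt = f [C - S]+  -  r N
    dC/dt = b (1 - C) N -  v C

`[x]+ = max(x, 0)`: a person whose control exceeds their craving does
not smoke. Craving grows by a second-order-kinetics term in the free
receptor fraction `(1 - C)` and nicotine load, and decays slowly.
Time runs in hours on a 16-hour-day clock: nights are skipped, so one
model "day" is 16 h (`smokesim.DAY_HOURS`).

Default rate constants (derivable with `derive_rate_constants`):

| constant | value | units | origin |
|---|---|---|---|
| `r` | 0.385 | 1/h | nicotine half-life 1.8 h |
| `v` | 5.54e-3 | 1/h | craving down to 10% after 26 x 16 h |
| `f` | 0.680 | mg/h | moderate smoker: intake 0.340 mg/h at C = 0.5, S = 0 |
| `b` | 6.27e-3 | 1/(mg h) | equilibrium conditions => b = 2rv/f |

Because `f, r >> b, v` (two orders of magnitude), `N` relaxes in hours
onto the quasi-steady manifold `N = f[C - S]+ / r`, and the effective
dynamics are one-dimensional in `C` on a time scale of weeks. The
smoking-branch equilibria solve `a C^2 - (a(1+S) - v) C + a S = 0`
with `a = b f / r`; with the no-smoking equilibrium `(0,0)` (which
exists iff `S >= 0`) the system is bistable exactly for
`S` in `(0, (sqrt(a) - sqrt(v))^2 / a)` = (0, 0.0857) at the defaults.
Eliminating `N` at equilibrium also gives the saturating
receptor-activation relation `C = Q / (Q + v r / b)`.

The intake law itself comes from a renewal point process: cigarettes
are lit with intensity `lambda(t) = (alpha + beta t) u`, `u = [C-S]+`,
with the clock reset after each cigarette. The expected waiting time
is the survival integral `E[T] = \int_0^\infty exp(-Lambda(t)) dt` and
its reciprocal is the mean intake rate. Coefficients are expressed in
mg of absorbed nicotine per hour per unit urge, so the constant-urge
case reduces exactly to the deterministic law `Q = f u`; dividing by
`m = 1.7 mg x 25% = 0.425 mg` converts to cigarettes/h. The main
simulations use this fluid-limit intake directly (`beta = 0`);
event-level sampling (`sample_lighting_times`, by inversion of
`Lambda`) exists for validation and exploration.

## Stochastic control

Control fluctuates as an Ornstein-Uhlenbeck process

    dS = q (S0 - S) dt + eps dW,

with diffusion amplitude `eps = 1/(30.3 x 16) = 2.06e-3` per sqrt(h)
(attitude changes on a monthly scale) and drift `q = k^2 eps^2 / 2`,
the unique choice that fixes the stationary sd at `1/k`; `k = 75` by
default, giving sd 0.0133 and a correlation time `1/q ~ 84 h`. The
derivation of `q` from `(k, eps)` is a modelling choice:
`q = k^2 eps^2 / 2` is the unique drift consistent with a stationary
amplitude of `1/k`. `q` can be overridden explicitly.

Integration is by forward Euler(-Maruyama) at `dt = 0.1 h`
(stiffest rate `r dt ~ 0.04`, comfortably stable; the additive noise
makes the scheme strong order 1). After each step `C` is clamped to
[0, 1] and `N` to [0, inf): the exact flow preserves both sets, only
discretisation can overshoot, and clamp events are counted in the
trajectory metadata (zero in all default-parameter runs). With
`eps = 0` the scheme reduces to deterministic explicit Euler, which
the tests verify converges at first order against the closed-form
nicotine decay. Phase-plane work (basin/fast-slow tests) instead uses
an adaptive stiff-capable integrator (LSODA, rtol 1e-8).

Randomness: every Monte Carlo batch derives per-run generators by
spawning `numpy.random.SeedSequence(base_seed)`, so batches are
reproducible and order-independent (run *i* is identical whether run
alone or in the batch), and any result can be regenerated from the
seed recorded in its JSON sidecar.

## Cessation schemes

A therapy of `T` days tapers the prescribed intake linearly from
0.262 mg/h (the steady-smoker baseline at `S0 = 0.05`) to zero over
the first `T_s` days and holds it at zero until `T`; `T_s = 0` is
abrupt cessation, `T_s = T` pure gradual. During therapy the intake
equation is driven by the prescription (`dN/dt = Q_presc(t) - r N`)
while craving and control keep their own dynamics, and the control
set-point is raised to 0.1 in all schemes — the boost is applied
symmetrically so the mixed family is well defined at both end-points;
a trial starts at the steady-smoking equilibrium `(0.68, 0.435)` with
`S = 0.05`. At `t = T` the set-point reverts instantly to 0.05 (S
itself relaxes continuously) and the craving-driven intake law
resumes for a 365-day post-therapy year.

Success: mean intake over the post-therapy year below 5% of the
pre-therapy baseline. The mean criterion is the default because it
separates the two attractors sharply and is robust to infinitesimal
excursions; a strict pointwise variant ("never above 5%") is available
via `criterion="pointwise"`. The minimal-duration scan walks whole
days `T = T_s, T_s + 1, ...` and reports the first `T` with >= 30
successes out of 100 runs; the `(T_s, T_min)` points are summarised by
an ordinary least-squares line (`duration_regression`), which is the
right object to read off scheme trade-offs from, since individual grid
points carry binomial jitter.

## What the default noise level implies (and does not)

At the default calibration the control's stationary sd is 0.0133
around 0.05. Relapse from abstinence requires the control to fall to
~0 (craving is near zero after a successful therapy, and intake needs
`C > S`), a 3.8-sigma excursion with mean first-passage time far
beyond the simulated year; quitting spontaneously requires a sustained
excursion past the fold at 0.086 that the 84-h correlation time almost
never delivers against craving's ~180 h time constant. Consequently,
under the default parameters:

* a steady smoker essentially never quits or relapses in a 1000-day
  free run (the switching tests assert persistence at the default
  amplitude and switching under a few-fold larger, slower control
  noise);
* cessation success is a near-step function of end-of-therapy craving
  relative to the separatrix (~0.115 at S = 0.05): the abrupt scheme
  saturates at ~100% success once `T` exceeds ~16 days, the gradual
  scheme once `T` exceeds ~35 days, and a 21-day taper needs only a
  few further abstinence days (see `scripts/acceptance.py` output).

One-year success rates in the few-tens-of-percent range, as observed
in cessation practice, emerge only when the control-noise amplitude is
several-fold larger (stationary sd ~0.04-0.05, making relapse a
~1-sigma event); `examples/06_noise_amplitude_sensitivity.py` computes
this sensitivity directly. This is a genuine property of the model,
worth knowing before using the defaults to rank therapies:
the *relative* ordering of schemes (abrupt needs the shortest total
time; a taper buys comfort at the cost of total duration) is stable
across noise levels, but the absolute success percentages are
controlled almost entirely by the control-noise amplitude, for which
the calibration evidence is weak.

## Degenerate inputs and numerical guards

* `a = b f / r <= v`: no smoking branch/bistability;
  `bistable_interval` returns an explicit `None`, `find_equilibria`
  falls back to a sign-change scan + Brent refinement of the reduced
  slow equation when the quadratic degenerates (`a ~ 0`).
* Fold location: closed form `(sqrt(a) - sqrt(v))^2 / a`, refined by
  bisection of the discriminant to 1e-10.
* Waiting-time quadrature: adaptive, abs/rel tolerance 1e-10,
  truncated where the survival function falls below 1e-12; zero urge
  returns `inf` ("never"), not a division error.
* Equilibria on the clamp boundary `C = S` are classified on the
  no-intake branch (the bracket is zero for non-positive argument).
* Non-finite states during integration raise with the offending step
  index.

## Problem sizes

Defaults throughout are the reference protocol: `dt = 0.1 h`, 100 runs
per Monte Carlo batch, 365-day post-therapy year, 10^6 steps for the
stationary-sd check. Unit tests use smaller batches (10-400 runs,
shorter horizons) chosen to keep the full suite under a minute while
leaving 3-sigma statistical margins; the acceptance script runs the
full protocol.

## Limitations

* The synthetic world *is* the model: no inter-individual parameter
  variation (the craving decay `v` in particular varies widely between
  people), no pharmacotherapy, substitute rewards, social-network
  effects, or day-night structure beyond the 16-h clock.
* The control process is a single Gaussian OU; real-world "attitude"
  dynamics are unlikely to be stationary or Gaussian, and the success
  percentages are highly sensitive to its amplitude (above).
* Event-level smoking (discrete cigarettes) is not fed back into the
  state equations; the fluid-limit intake is used, which is accurate
  on the multi-hour time scales that matter here.
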