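"""Deterministic core: parameter derivation, equilibria, bifurcation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from smokesim import (
    ModelParams,
    State,
    bistable_interval,
    bifurcation_diagram,
    derive_rate_constants,
    equilibrium_craving_from_intake,
    find_equilibria,
    integrate_deterministic,
    quasi_steady_N,
    rhs,
)

DEFAULTS = ModelParams()


def round_sig(x: float, sig: int = 3) -> float:
    return float(f"%.{sig}g" % x)


class TestDeriveRateConstants:
    def test_moderate_smoker_calibration(self):
        """The standard calibration reproduces the default constants."""
        p = derive_rate_constants(1.8, 26, 0.1, 0.8, 1.7, 0.25, 0.5)
        assert round_sig(p.r) == 0.385
        assert round_sig(p.v) == 5.54e-3
        assert round_sig(p.f) == 0.680
        assert round_sig(p.b) == 6.27e-3

    def test_reference_intake(self):
        """Q_ref = cigs/h * mg/cig * uptake = 0.340 mg/h at C_ref = 0.5."""
        p = derive_rate_constants(1.8, 26, 0.1, 0.8, 1.7, 0.25, 0.5)
        assert p.f * 0.5 == pytest.approx(0.340)

    def test_half_life_identity(self):
        assert derive_rate_constants(nicotine_half_life_h=math.log(2)).r == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "kwargs, name",
        [
            ({"nicotine_half_life_h": -1}, "nicotine_half_life_h"),
            ({"craving_residual_fraction": 1.2}, "craving_residual_fraction"),
            ({"reference_C": 1.0}, "reference_C"),
            ({"cigs_per_hour": 0.0}, "cigs_per_hour"),
        ],
    )
    def test_validation_names_argument(self, kwargs, name):
        with pytest.raises(ValueError, match=name):
            derive_rate_constants(**kwargs)


class TestRhs:
    @pytest.mark.parametrize(
        "state, expected",
        [
            (State(0.0, 0.0, 0.0), (0.0, 0.0)),  # origin fixed point
            (State(0.0, 1.0, 1.0), (0.0, -DEFAULTS.v)),  # only craving decay
        ],
    )
    def test_closed_form_points(self, state, expected):
        dN, dC = rhs(state, DEFAULTS)
        assert dN == pytest.approx(expected[0], abs=1e-15)
        assert dC == pytest.approx(expected[1], abs=1e-15)

    def test_rounded_equilibrium_residual(self):
        """The rounded smoking equilibrium annihilates the vector field."""
        dN, dC = rhs(State(0.68, 0.435, 0.05), DEFAULTS)
        assert abs(dN) < 1e-3 and abs(dC) < 1e-3

    def test_intake_clamped_below_control(self):
        dN, _ = rhs(State(0.0, 0.2, 0.5), DEFAULTS)
        assert dN == 0.0


class TestQuasiSteadyN:
    def test_equilibrium_point(self):
        assert quasi_steady_N(0.435, 0.05, DEFAULTS) == pytest.approx(0.680, rel=2e-3)

    def test_clamped(self):
        assert quasi_steady_N(0.3, 0.4, DEFAULTS) == 0.0

    def test_max_craving(self):
        assert quasi_steady_N(1.0, 0.0, DEFAULTS) == pytest.approx(0.68 / 0.385)


def count_slow_roots(S: float, params: ModelParams, n: int = 100_000) -> int:
    """Brute-force oracle: sign changes of the reduced slow equation."""
    c = np.linspace(0.0, 1.0, n)
    nq = params.f * np.clip(c - S, 0.0, None) / params.r
    g = params.b * (1.0 - c) * nq - params.v * c
    interior = int(np.sum(np.sign(g[:-1]) * np.sign(g[1:]) < 0))
    # the origin is a root of g for S >= 0 but not a sign change
    return interior + (1 if S >= 0 else 0)


class TestFindEquilibria:
    def test_bistable_control(self):
        eqs = find_equilibria(0.05, DEFAULTS)
        assert [e.stability for e in eqs] == ["stable", "unstable", "stable"]
        smoking = eqs[-1]
        assert smoking.N == pytest.approx(0.6795, abs=2e-4)
        assert smoking.C == pytest.approx(0.4347, abs=2e-4)
        assert eqs[1].C == pytest.approx(0.1150, abs=2e-4)

    def test_high_control_only_abstinence(self):
        eqs = find_equilibria(0.1, DEFAULTS)
        assert len(eqs) == 1
        assert eqs[0].N == eqs[0].C == 0.0
        assert eqs[0].stability == "stable"

    def test_negative_control_only_smoking(self):
        eqs = find_equilibria(-0.03, DEFAULTS)
        assert len(eqs) == 1
        assert eqs[0].C > 0.5 and eqs[0].stability == "stable"

    @pytest.mark.parametrize("S", [-0.04, -0.01, 0.0, 0.02, 0.05, 0.08, 0.0857, 0.09, 0.12])
    def test_count_matches_sign_scan_oracle(self, S):
        assert len(find_equilibria(S, DEFAULTS)) == count_slow_roots(S, DEFAULTS)

    @given(
        S=st.floats(-0.05, 0.15),
        f=st.floats(0.1, 2.0),
        v_scale=st.floats(0.2, 5.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_residuals_vanish(self, S, f, v_scale):
        """Every returned equilibrium re-substitutes to ~zero."""
        params = ModelParams(f=f, v=DEFAULTS.v * v_scale)
        for eq in find_equilibria(S, params):
            dN, dC = rhs(State(eq.N, eq.C, S), params)
            assert math.hypot(dN, dC) < 1e-9


class TestBistableInterval:
    def test_default_interval(self):
        low, high = bistable_interval(DEFAULTS)
        assert low == 0.0
        # closed form (sqrt(a)-sqrt(v))^2/a with a = b f / r
        a = DEFAULTS.b * DEFAULTS.f / DEFAULTS.r
        assert high == pytest.approx((math.sqrt(a) - math.sqrt(DEFAULTS.v)) ** 2 / a, abs=1e-9)
        assert high == pytest.approx(0.0857, abs=2e-4)

    def test_matches_equilibrium_count_sweep(self):
        low, high = bistable_interval(DEFAULTS)
        for s in np.linspace(low + 1e-4, high - 1e-4, 7):
            assert len(find_equilibria(float(s), DEFAULTS)) == 3
        assert len(find_equilibria(high + 1e-3, DEFAULTS)) == 1
        assert len(find_equilibria(low - 1e-3, DEFAULTS)) == 1

    def test_widens_with_intake_gain(self):
        _, high = bistable_interval(DEFAULTS)
        _, high2 = bistable_interval(ModelParams(f=2 * DEFAULTS.f))
        assert high2 > high

    def test_no_bistability_for_weak_gain(self):
        # a = b f / r <= v leaves only one equilibrium everywhere
        assert bistable_interval(ModelParams(f=1e-3)) is None


class TestMichaelisMenten:
    def test_moderate_smoker_point(self):
        assert equilibrium_craving_from_intake(0.340, DEFAULTS) == pytest.approx(0.5, abs=2e-4)

    def test_zero_and_saturation(self):
        assert equilibrium_craving_from_intake(0.0, DEFAULTS) == 0.0
        qs = np.linspace(0, 50, 200)
        cs = [equilibrium_craving_from_intake(float(q), DEFAULTS) for q in qs]
        assert all(np.diff(cs) > 0) and cs[-1] < 1.0
        assert equilibrium_craving_from_intake(1e6, DEFAULTS) == pytest.approx(1.0, abs=1e-3)

    @pytest.mark.parametrize("S", [0.0, 0.02, 0.05, 0.08])
    def test_inverse_of_smoking_equilibrium(self, S):
        """Feeding an equilibrium's implied intake back returns its craving."""
        for eq in find_equilibria(S, DEFAULTS):
            if eq.C <= S:
                continue
            Q = DEFAULTS.f * (eq.C - S)
            assert equilibrium_craving_from_intake(Q, DEFAULTS) == pytest.approx(
                eq.C, abs=1e-12
            )


class TestBifurcationDiagram:
    def test_branch_structure_and_export(self):
        diag = bifurcation_diagram(DEFAULTS, np.linspace(-0.02, 0.12, 57))
        assert diag.S_fold_low == 0.0
        assert diag.S_fold_high == pytest.approx(0.0857, abs=2e-4)
        frame = diag.to_frame()
        assert list(frame.columns) == ["S", "N_eq", "C_eq", "stability"]
        inside = (diag.S_grid > 0) & (diag.S_grid < diag.S_fold_high)
        counts = np.array([len(b) for b in diag.branches])
        assert np.all(counts[inside] == 3)
        assert np.all(counts[~inside & (np.abs(diag.S_grid) > 1e-9)] == 1)


class TestDeterministicFlow:
    @pytest.mark.parametrize("N0, C0", [(0.0, 0.9), (2.0, 0.05), (1.0, 0.5), (0.2, 0.2)])
    def test_trajectories_converge_to_a_stable_equilibrium(self, N0, C0):
        sol = integrate_deterministic(State(N0, C0, 0.05), DEFAULTS, 20000.0)
        end = np.array([sol.y[0][-1], sol.y[1][-1]])
        stable = [e for e in find_equilibria(0.05, DEFAULTS) if e.stability == "stable"]
        dists = [np.hypot(end[0] - e.N, end[1] - e.C) for e in stable]
        assert min(dists) < 1e-4

    def test_fast_slow_collapse_onto_nicotine_nullcline(self):
        """After a few 1/r the nicotine level is slaved to craving."""
        t_eval = np.linspace(0, 400, 2001)
        sol = integrate_deterministic(State(1.8, 0.9, 0.05), DEFAULTS, 400.0, t_eval=t_eval)
        mask = t_eval > 5.0 / DEFAULTS.r
        qss = np.array(
            [quasi_steady_N(c, 0.05, DEFAULTS) for c in sol.y[1][mask]]
        )
        assert np.max(np.abs(sol.y[0][mask] - qss)) < 0.02
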