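"""Model core: sigmoid formula, wiring, integrator accuracy, fixed points."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from hpa_pipeline.model_core import (
    BACKGROUND_NAMES,
    PARAM_NAMES,
    NetworkSpec,
    ParameterOverlay,
    ParameterSet,
    StepSignal,
    SystemState,
    Trajectory,
    derivatives,
    find_fixed_points,
    integrate,
    jacobian,
    net_input,
    sigmoid_activity,
)
from tests.conftest import random_parameter_set


def params_from(**values) -> ParameterSet:
    """ParameterSet with given entries, zeros elsewhere, unit timescales."""
    d = {k: 0.0 for k in PARAM_NAMES}
    d.update({k: 1.0 for k in ("ts_CRH", "ts_ACTH", "ts_COR", "ts_GR")})
    d.update(values)
    return ParameterSet.from_dict(d)


class TestSigmoidActivity:
    @pytest.mark.parametrize("sigma", [0.5, 2.0, 10.0, 100.0])
    def test_zero_input_gives_half(self, sigma):
        assert sigmoid_activity(0.0, sigma) == 0.5

    def test_saturation_limits(self):
        assert sigmoid_activity(1e6, 10.0) == pytest.approx(1.0)
        assert sigmoid_activity(-1e6, 10.0) == pytest.approx(0.0)
        # extreme exponents are clamped, not overflowed
        assert np.isfinite(sigmoid_activity(1e300, 10.0))

    def test_closed_form_value(self):
        assert sigmoid_activity(1.0, 2.0) == pytest.approx(
            1.0 / (1.0 + np.exp(-2.0)), abs=1e-12)

    @given(st.floats(-25, 25), st.floats(-25, 25))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing(self, w1, w2):
        # range chosen below float64 saturation of the logistic
        lo, hi = sorted([w1, w2])
        if hi - lo < 1e-9:   # below float64 resolution of the logistic
            return
        assert sigmoid_activity(lo, 1.0) < sigmoid_activity(hi, 1.0)

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            sigmoid_activity(0.0, -1.0)
        with pytest.raises(ValueError):
            sigmoid_activity(np.nan, 1.0)


class TestNetInput:
    def test_all_zero_weights(self):
        w = net_input(SystemState(np.full(4, 0.3)), params_from(), 0.0)
        assert np.allclose(w, 0.0)

    def test_backgrounds_only_at_origin(self):
        p = params_from(RCRH_0=0.4, RACTH_0=-0.2, RCOR_0=0.1, RGR_0=-0.7)
        w = net_input(SystemState(np.zeros(4)), p, 0.0)
        assert np.allclose(w, [0.4, -0.2, 0.1, -0.7])

    def test_hand_summed_unit_weights(self):
        # all activations +1, both GR inhibitions -1, backgrounds 0,
        # state all ones, stress 1
        p = params_from(RCRH_SS=1, RCRH_CRH=1, RCRH_GR=-1, RACTH_CRH=1,
                        RACTH_GR=-1, RCOR_ACTH=1, RGR_COR=1, RGR_GR=1)
        w = net_input(SystemState(np.ones(4)), p, 1.0)
        assert np.allclose(w, [1.0, 0.0, 1.0, 2.0])

    def test_only_wired_edges_contribute(self, basal):
        # COR input depends on ACTH only: perturbing CRH/COR/GR leaves it
        x1 = np.array([0.1, 0.5, 0.2, 0.9])
        x2 = np.array([0.8, 0.5, 0.6, 0.3])
        w1 = net_input(SystemState(x1), basal, 0.0)
        w2 = net_input(SystemState(x2), basal, 0.0)
        assert w1[2] == pytest.approx(w2[2])


class TestDerivatives:
    def test_zero_at_fixed_point(self, spec):
        p = params_from(RCRH_0=0.2, RACTH_0=-0.1, RCOR_0=0.0, RGR_0=0.5)
        xstar = np.array([sigmoid_activity(p[k], spec.sigma)
                          for k in BACKGROUND_NAMES])
        dx = derivatives(SystemState(xstar), p, 0.0, spec)
        assert np.allclose(dx, 0.0, atol=1e-12)

    def test_linear_relaxation_rate(self, spec):
        # frozen input: derivative is ts * (F(b) - x0)
        p = params_from(RCRH_0=0.3, ts_CRH=2.5)
        x0 = np.array([0.9, 0.5, 0.5, 0.5])
        dx = derivatives(SystemState(x0), p, 0.0, spec)
        f = sigmoid_activity(0.3, spec.sigma)
        assert dx[0] == pytest.approx(2.5 * (f - 0.9))

    def test_zero_timescale_freezes_component(self, spec):
        p = params_from(RCRH_0=1.0, ts_CRH=0.0)
        dx = derivatives(SystemState(np.full(4, 0.2)), p, 0.0, spec)
        assert dx[0] == 0.0


class TestIntegrate:
    def test_matches_analytic_relaxation(self, spec):
        """All weights zero: X(t) = F + (X0 - F) exp(-ts t) to 1e-6."""
        rng = np.random.default_rng(99)
        for _ in range(100):
            b = rng.uniform(-1, 1, 4)
            ts = rng.uniform(0.1, 5.0, 4)
            p = params_from(**dict(zip(BACKGROUND_NAMES, b)),
                            **dict(zip(("ts_CRH", "ts_ACTH", "ts_COR",
                                        "ts_GR"), ts)))
            x0 = rng.uniform(0, 1, 4)
            traj = integrate(p, spec, t_span=(0, 10), x0=x0, dt_out=0.5)
            f = np.array([sigmoid_activity(bi, spec.sigma) for bi in b])
            expected = f + (x0 - f) * np.exp(
                -ts[None, :] * traj.times[:, None])
            assert np.abs(traj.states - expected).max() < 1e-6

    def test_constant_at_fixed_point(self, basal, spec):
        root = find_fixed_points(basal, spec)[0]
        traj = integrate(basal, spec, t_span=(0, 50), x0=root.x)
        assert np.abs(traj.states - root.x).max() < 1e-6

    def test_agrees_with_scipy_reference(self, basal, spec):
        """Independent integrator (solve_ivp) agrees along a stressed run."""
        pulse = StepSignal([20.0, 30.0], [2.0, 0.0])
        x0 = np.full(4, 0.1)
        traj = integrate(basal, spec, stress=pulse, t_span=(0, 60), x0=x0)
        vec = basal.as_array()

        def rhs(t, x):
            ss = pulse(t)
            w = np.array([
                vec[8] + vec[0] * ss + vec[1] * x[0] + vec[2] * x[3],
                vec[9] + vec[3] * x[0] + vec[4] * x[3],
                vec[10] + vec[5] * x[1],
                vec[11] + vec[6] * x[2] + vec[7] * x[3]])
            return vec[12:16] * (1 / (1 + np.exp(-spec.sigma * w)) - x)

        ref = []
        x = x0
        for a, b in [(0, 20), (20, 30), (30, 60)]:
            sol = solve_ivp(rhs, (a, b), x, rtol=1e-9, atol=1e-11,
                            t_eval=np.arange(a, b, 0.1), dense_output=True)
            ref.append(sol.y.T)
            x = sol.sol(b)
        ref = np.vstack(ref + [x[None, :]])
        assert np.abs(traj.states - ref).max() < 1e-6

    def test_stress_pulse_transient_cortisol_rise(self, basal, spec):
        """Basal exemplar: cortisol rises under the pulse, then returns."""
        pulse = StepSignal([20.0, 30.0], [2.0, 0.0])
        traj = integrate(basal, spec, stress=pulse, t_span=(0, 100),
                         x0=np.full(4, 0.1))
        cor = traj.component("COR")
        pre = traj.window_mean("COR", 15, 20)
        during = cor[(traj.times >= 20) & (traj.times <= 30)].max()
        post = traj.window_mean("COR", 75, 100)
        assert during > pre + 0.1
        assert abs(post - pre) < 0.05

    def test_boundedness_from_unit_cube(self, basal):
        """[0,1]^4 is forward-invariant for any sampled individual."""
        rng = np.random.default_rng(5)
        for _ in range(25):
            p = random_parameter_set(rng, basal)
            x0 = rng.uniform(0, 1, 4)
            traj = integrate(p, t_span=(0, 50), x0=x0, dt_out=0.5)
            assert traj.states.min() > -1e-6
            assert traj.states.max() < 1 + 1e-6

    def test_rejects_bad_span_and_x0(self, basal):
        with pytest.raises(ValueError):
            integrate(basal, t_span=(10, 10))
        with pytest.raises(ValueError):
            integrate(basal, t_span=(0, 1), x0=np.array([np.nan, 0, 0, 0]))


class TestFixedPoints:
    def test_decoupled_single_root(self, spec):
        p = params_from(RCRH_0=0.25, RACTH_0=-0.5, RCOR_0=0.1, RGR_0=-1.0)
        roots = find_fixed_points(p, spec)
        assert len(roots) == 1
        expected = [sigmoid_activity(p[k], spec.sigma)
                    for k in BACKGROUND_NAMES]
        assert np.allclose(roots[0].x, expected, atol=1e-9)
        assert roots[0].stable

    @pytest.mark.parametrize("r,b", [
        (1.0, -0.5),    # sigma*R = 10 > 4, b inside the bistable window
        (1.0, 0.5),     # outside the window: single root
        (0.3, -0.15),   # sigma*R = 3 < 4: monostable regardless of b
        (2.0, -1.0),    # strong loop, centered
    ])
    def test_gr_self_loop_matches_bisection(self, spec, r, b):
        """1-D reduction: root count equals a dense bisection scan."""
        p = params_from(RGR_GR=r, RGR_0=b)
        roots = find_fixed_points(p, spec, grid_n=8)
        gr_roots = sorted(fp.x[3] for fp in roots)

        def g(x):
            return 1 / (1 + np.exp(-spec.sigma * (b + r * x))) - x

        xs = np.linspace(0, 1, 20001)
        gs = g(xs)
        exact = xs[gs == 0.0]
        strict = xs[np.flatnonzero(gs[:-1] * gs[1:] < 0)]
        oracle = np.sort(np.concatenate([exact, strict]))
        assert len(gr_roots) == len(oracle)
        for expected, root in zip(oracle, gr_roots):
            assert abs(root - expected) < 1e-3

    def test_three_roots_iff_sigma_r_above_4(self, spec):
        # just below the threshold sigma*R = 4 the loop cannot be bistable
        below = find_fixed_points(params_from(RGR_GR=0.39, RGR_0=-0.195),
                                  spec, grid_n=8)
        above = find_fixed_points(params_from(RGR_GR=0.8, RGR_0=-0.4),
                                  spec, grid_n=8)
        assert len(below) == 1
        assert len(above) == 3

    def test_roots_are_equilibria(self, basal, spec):
        for fp in find_fixed_points(basal, spec):
            dx = derivatives(SystemState(fp.x), basal, 0.0, spec)
            assert np.abs(dx).max() < 1e-8

    def test_long_run_endpoints_land_on_roots(self, basal, spec):
        """ODE limits coincide with the root-finder's fixed points."""
        rng = np.random.default_rng(17)
        n_checked = 0
        for _ in range(100):
            p = random_parameter_set(rng, basal)
            x0 = rng.uniform(0, 1, 4)
            traj = integrate(p, spec, t_span=(0, 200), x0=x0, dt_out=0.5)
            if traj.peak_to_peak("COR") > 1e-5:   # oscillatory or slow
                continue
            roots = find_fixed_points(p, spec, grid_n=5)
            dist = min(np.abs(traj.states[-1] - fp.x).max() for fp in roots)
            assert dist < 1e-4
            n_checked += 1
        assert n_checked >= 50   # most draws converge

    def test_monotone_gain_in_cortisol_drive(self, basal, spec):
        """Cooperative reduction: steady cortisol non-decreasing in RCOR_ACTH.

        With the GR-mediated repressions removed every edge is activating,
        the system is monotone, and a stronger ACTH->cortisol weight cannot
        lower the continued fixed point's cortisol.  (The full wiring does
        not obey this: the GR negative feedback can overcompensate.)
        """
        coop = basal.replace(RCRH_GR=0.0, RACTH_GR=0.0)
        values = np.linspace(0.5, 3.0, 8)
        prev_root = min(find_fixed_points(
            coop.replace(RCOR_ACTH=values[0]), spec),
            key=lambda fp: fp.x[2])
        prev_cor = prev_root.x[2]
        for v in values[1:]:
            roots = find_fixed_points(coop.replace(RCOR_ACTH=v), spec)
            cont = min(roots, key=lambda fp: np.abs(fp.x - prev_root.x).max())
            assert cont.x[2] >= prev_cor - 1e-9
            prev_root, prev_cor = cont, cont.x[2]


class TestTrajectoryAndTypes:
    def test_trajectory_csv_round_trip(self, basal, tmp_path):
        traj = integrate(basal, t_span=(0, 5), dt_out=0.5)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        back = Trajectory.from_csv(path)
        assert np.allclose(back.states, traj.states)
        assert np.allclose(back.times, traj.times)

    def test_parameter_set_validation(self):
        with pytest.raises(ValueError, match="sign"):
            params_from(RCRH_GR=0.5)     # inhibition must be <= 0
        with pytest.raises(ValueError, match="missing"):
            ParameterSet(regulatory={}, background={}, timescale={})
        with pytest.raises(ValueError):
            params_from(ts_COR=-1.0)

    def test_network_spec_validation(self):
        with pytest.raises(ValueError):
            NetworkSpec(sigma=-1.0)

    def test_overlay_applies_only_inside_window(self):
        ov = ParameterOverlay([("RGR_GR", -2.0, 10.0, 20.0)])
        base = params_from(RGR_GR=1.0).as_array()
        idx = PARAM_NAMES.index("RGR_GR")
        assert ov.apply(base, 9.9)[idx] == 1.0
        assert ov.apply(base, 10.0)[idx] == -1.0
        assert ov.apply(base, 20.0)[idx] == 1.0

    def test_jacobian_matches_finite_differences(self, basal, spec):
        x = np.array([0.3, 0.4, 0.5, 0.6])
        J = jacobian(x, basal, 0.0, spec)
        eps = 1e-6
        for j in range(4):
            dx = np.zeros(4)
            dx[j] = eps
            fd = (derivatives(SystemState(x + dx), basal, 0.0, spec)
                  - derivatives(SystemState(x - dx), basal, 0.0, spec)) \
                / (2 * eps)
            assert np.allclose(J[:, j], fd, atol=1e-5)
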