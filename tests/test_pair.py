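"""Fixed-point analytics, the inverse designer, and state-dependence metrics."""

import numpy as np
import pytest

from isnkit.dynamics import StimulusSpec
from isnkit.network import ISPParams
from isnkit.pair import (DegenerateSystemError, bistability_check, classify_up,
                         jacobian, solve_isp_from_spec, state_dependence_test,
                         stimulus_sweep, tolerance, trace_determinant,
                         up_fixed_point, up_rotation_period)


def _steady_state_oracle(p: ISPParams, I: float = 0.0):
    """Independent 2x2 linear solve of the steady-state equations."""
    A = np.array([[p.w_ee - 1.0, p.w_ie], [p.w_ei, p.w_ii - 1.0]])
    b = np.array([p.theta_e - I, p.theta_i - I])
    return np.linalg.solve(A, b)


def _design_oracle(trace, det, theta_e, theta_i, r_e, r_i, tau=0.010):
    """Closed-form inverse design: the system is linear in (W_EE-1, W_II-1)."""
    S, P = tau * trace, tau**2 * det
    # theta_I/r_I * a + theta_E/r_E * d = P + theta_E*theta_I/(r_E*r_I); a + d = S
    ci, ce = theta_i / r_i, theta_e / r_e
    a = (P + theta_e * theta_i / (r_e * r_i) - ce * S) / (ci - ce)
    d = S - a
    w_ie = (theta_e - a * r_e) / r_i
    w_ei = (theta_i - d * r_i) / r_e
    return ISPParams(w_ee=1 + a, w_ie=w_ie, w_ei=w_ei, w_ii=1 + d,
                     theta_e=theta_e, theta_i=theta_i, tau=tau)


class TestUpFixedPoint:
    def test_known_location(self):
        p = ISPParams(w_ee=2, w_ie=-1, w_ei=3, w_ii=-0.5, theta_e=1, theta_i=3)
        fp = up_fixed_point(p)
        assert fp.location == pytest.approx((1.0, 0.0))

    def test_zero_system_origin(self):
        p = ISPParams(w_ee=0, w_ie=0, w_ei=0, w_ii=0, theta_e=0, theta_i=0)
        fp = up_fixed_point(p)
        assert fp.location == pytest.approx((0.0, 0.0))

    def test_reference_pair_up_rates(self, ref_pair):
        fp = up_fixed_point(ref_pair)
        assert fp.location == pytest.approx((5.0, 10.0), abs=1e-8)

    def test_matches_linear_solve_oracle(self, ref_pair):
        for I in (0.0, 3.0, 10.0):
            fp = up_fixed_point(ref_pair, I=I)
            np.testing.assert_allclose(fp.location, _steady_state_oracle(ref_pair, I),
                                       atol=1e-10)

    def test_singular_denominator_raises(self):
        # (w_ii-1)(w_ee-1) = w_ei*w_ie: 2*(-2) = ... pick w_ei=4, w_ie=-1
        p = ISPParams(w_ee=3, w_ie=-1, w_ei=4, w_ii=-1, theta_e=1, theta_i=2)
        with pytest.raises(DegenerateSystemError):
            up_fixed_point(p)


class TestClassification:
    def test_spiral_example(self):
        p = ISPParams(w_ee=2, w_ie=-1, w_ei=3, w_ii=-0.5, theta_e=1, theta_i=3)
        tr, det = trace_determinant(p)
        assert tr == pytest.approx(-50.0)
        assert det == pytest.approx(1.5e4)
        assert tr**2 < 4 * det
        assert classify_up(p) == "stable spiral"

    def test_positive_trace_unstable(self):
        p = ISPParams(w_ee=2.6, w_ie=-1, w_ei=3, w_ii=-0.5, theta_e=1, theta_i=3)
        assert up_fixed_point(p).trace > 0
        assert classify_up(p) == "unstable"

    def test_negative_determinant_saddle(self):
        p = ISPParams(w_ee=2, w_ie=-1, w_ei=1, w_ii=-0.5, theta_e=1, theta_i=3)
        # fixed point lies at negative rates here; classify the Jacobian directly
        tr, det = trace_determinant(p)
        assert det < 0
        from isnkit.pair import _classify

        assert _classify(tr, det) == "saddle"

    def test_agrees_with_eigendecomposition(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            p = ISPParams(w_ee=float(rng.uniform(0, 4)),
                          w_ie=-float(rng.uniform(0, 3)),
                          w_ei=float(rng.uniform(0, 25)),
                          w_ii=-float(rng.uniform(0, 3)),
                          theta_e=1.0, theta_i=3.0)
            try:
                kind = classify_up(p)
            except DegenerateSystemError:
                continue
            eig = np.linalg.eigvals(jacobian(p))
            if kind == "saddle":
                assert (eig.real > 0).any() and (eig.real < 0).any()
                assert np.all(eig.imag == 0)
            elif kind == "unstable":
                assert eig.real.max() >= 0
            elif kind == "stable node":
                assert eig.real.max() < 0 and np.all(eig.imag == 0)
            elif kind == "stable spiral":
                assert eig.real.max() < 0 and np.any(eig.imag != 0)


class TestBistability:
    def test_reference_pair_is_bistable(self, ref_pair):
        ok, why = bistability_check(ref_pair)
        assert ok, why

    def test_equal_thresholds_fail_ordering(self, ref_pair):
        p = ISPParams(**{**{f: getattr(ref_pair, f) for f in
                            ("w_ee", "w_ie", "w_ei", "w_ii", "tau")},
                         "theta_e": 5.0, "theta_i": 5.0})
        ok, why = bistability_check(p)
        assert not ok and "threshold" in why

    def test_unstable_up_reported(self):
        # closed-form design with a *positive* trace target: UP at (5, 10) Hz
        # with Tr = +20/s, so only the stability condition fails
        p = _design_oracle(+20.0, 1.5e4, 5.34, 82.43, 5.0, 10.0)
        assert up_fixed_point(p).trace > 0
        ok, why = bistability_check(p)
        assert not ok and "unstable" in why.lower()


class TestInverseDesign:
    @pytest.mark.parametrize("trace,det", [(-50.0, 1.5e4), (-30.0, 1e4),
                                           (-120.0, 2.5e4)])
    def test_round_trip(self, trace, det):
        p = solve_isp_from_spec(trace, det, 5.34, 82.43, 5.0, 10.0)
        fp = up_fixed_point(p)
        assert fp.location == pytest.approx((5.0, 10.0), abs=1e-8)
        assert fp.trace == pytest.approx(trace, abs=1e-7)
        assert fp.determinant == pytest.approx(det, rel=1e-9)

    def test_matches_closed_form_oracle(self):
        got = solve_isp_from_spec(-80.0, 8e3, 5.34, 82.43, 5.0, 10.0)
        want = _design_oracle(-80.0, 8e3, 5.34, 82.43, 5.0, 10.0)
        for f in ("w_ee", "w_ie", "w_ei", "w_ii"):
            assert getattr(got, f) == pytest.approx(getattr(want, f), abs=1e-8)

    def test_dimensionless_targets(self):
        a = solve_isp_from_spec(-50.0, 1.5e4, 5.34, 82.43, 5.0, 10.0)
        b = solve_isp_from_spec(-0.5, 1.5, 5.34, 82.43, 5.0, 10.0,
                                dimensionless=True)
        assert a.w_ee == pytest.approx(b.w_ee, abs=1e-9)

    def test_unstable_target_rejected(self):
        with pytest.raises(ValueError, match="stable"):
            solve_isp_from_spec(+10.0, 1e4, 5.34, 82.43, 5.0, 10.0)

    def test_brute_force_grid_agreement(self):
        # coarse exhaustive search over (w_ee, w_ii) minimizing the residual
        target = (-50.0, 1.5e4)
        sol = solve_isp_from_spec(*target, 5.34, 82.43, 5.0, 10.0)
        tau = 0.010
        best = None
        for w_ee in np.arange(1.0, 4.0, 0.02):
            w_ii = 2.0 + tau * target[0] - w_ee  # trace constraint
            w_ie = (5.34 - (w_ee - 1) * 5.0) / 10.0  # E steady state
            w_ei = (82.43 - (w_ii - 1) * 10.0) / 5.0  # I steady state
            det = ((w_ee - 1) * (w_ii - 1) - w_ei * w_ie) / tau**2
            err = abs(det - target[1])
            if best is None or err < best[0]:
                best = (err, w_ee)
        assert abs(best[1] - sol.w_ee) < 0.02


class TestStateDependence:
    def test_reference_stimulus_flips_both_ways(self, ref_pair):
        res = state_dependence_test(
            ref_pair, StimulusSpec(amplitude=52.15, duration=0.001))
        assert res == {"down_to_up": True, "up_to_down": True,
                       "state_dependent": True, "indeterminate": False}

    def test_subthreshold_cannot_leave_down(self, ref_pair):
        res = state_dependence_test(
            ref_pair, StimulusSpec(amplitude=3.0, duration=0.01))
        assert not res["down_to_up"]
        assert not res["state_dependent"]

    def test_requires_bistable_pair(self):
        p = ISPParams(w_ee=0, w_ie=0, w_ei=0, w_ii=0, theta_e=1, theta_i=3)
        with pytest.raises(ValueError, match="not bistable"):
            state_dependence_test(p, StimulusSpec(amplitude=10, duration=0.01))


class TestToleranceMetric:
    def test_circular_coverage_worked_example(self):
        # quarter-pi coverage of ten-fold axes = an equal-area circle of
        # log-diameter 1 -> fold range 10 -> tolerance 9
        assert tolerance(np.pi / 4, [1.0, 10.0], [1.0, 10.0]) == pytest.approx(9.0)

    def test_zero_fraction_gives_zero(self):
        assert tolerance(0.0, [1.0, 10.0], [1.0, 10.0]) == 0.0

    def test_full_coverage(self):
        want = 10 ** (2 / np.sqrt(np.pi)) - 1  # ~12.44
        assert tolerance(1.0, [1, 10], [1, 10]) == pytest.approx(want)
        assert tolerance(1.0, [1, 10], [1, 10]) == pytest.approx(12.44, abs=0.01)

    def test_monotone_in_fraction(self):
        vals = [tolerance(f, [1, 100], [1, 1000]) for f in np.linspace(0, 1, 11)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            tolerance(1.5, [1, 10], [1, 10])


class TestStimulusSweep:
    def test_subthreshold_grid_all_false(self, ref_pair):
        res = stimulus_sweep(ref_pair, [1.0, 2.0], [0.005, 0.01],
                             settle_time=4.0)
        assert res.f_sd == 0.0
        assert res.tolerance == 0.0

    def test_reference_pair_has_positive_tolerance(self, ref_pair):
        amps = np.geomspace(20, 200, 6)
        durs = np.geomspace(0.0005, 0.01, 6)
        res = stimulus_sweep(ref_pair, amps, durs, settle_time=6.0)
        assert res.f_sd > 0
        assert res.tolerance > 0
        assert res.state_dependent.shape == (6, 6)

    def test_duration_periodicity_matches_rotation_period(self):
        # a weakly damped spiral retains its transient over several
        # rotations, so the state-dependent window recurs one rotation
        # period later along a linear duration grid
        p = solve_isp_from_spec(-5.0, 1.5e4, 5.34, 82.43, 5.0, 10.0)
        period = up_rotation_period(p)
        durs = np.arange(0.002, 0.062, 0.0008)
        res = stimulus_sweep(p, [10.0], durs, settle_time=8.0)
        mask = res.state_dependent[0]
        idx = np.flatnonzero(mask)
        assert idx.size >= 2
        gaps = np.diff(idx)
        recurrence = durs[idx[np.argmax(gaps) + 1]] - durs[idx[np.argmax(gaps)]]
        assert recurrence == pytest.approx(period, rel=0.2)
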