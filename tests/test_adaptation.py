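import math

import numpy as np
import pytest

from hypohop import adaptation as ad


@pytest.fixture(scope="module")
def params():
    return ad.AdaptationParams(tau=100.0, delta=1.0, csa_max=1.4)


def _const_profile(force, duration=0.5, n=80):
    return ad.ForceProfile(time=np.linspace(0, duration, n),
                           force=np.full(n, force))


class TestRate:
    def test_zero_at_threshold(self, params):
        assert ad.csa_rate(1.0, params.f0, params) == 0.0

    def test_zero_below_threshold(self, params):
        assert ad.csa_rate(1.1, 0.05, params) == 0.0

    def test_zero_at_saturation(self, params):
        assert ad.csa_rate(params.csa_max, 0.9, params) == 0.0

    def test_hand_evaluated_value(self):
        # tau=1, delta=1, csa_max=2, csa=1, F=0.5: (2-1)/(2-1) * (0.5-0.2) = 0.3
        p = ad.AdaptationParams(tau=1.0, delta=1.0, csa_max=2.0)
        assert ad.csa_rate(1.0, 0.5, p) == pytest.approx(0.3)

    def test_csa_above_ceiling_rejected(self, params):
        with pytest.raises(ValueError):
            ad.csa_rate(1.5, 0.5, params)


class TestGrowthSimulation:
    def test_subthreshold_profile_never_grows(self, params):
        traj = ad.simulate_growth(_const_profile(0.15), params, 20)
        assert np.all(traj == 1.0)

    def test_matches_closed_form_for_constant_force(self, params):
        """The separable equation has an exact solution; the adaptive ODE
        integration must reproduce it to 1e-6."""
        prof = _const_profile(0.6)
        traj = ad.simulate_growth(prof, params, 40)
        D = ad._drive_per_rep(prof, params)
        exact = np.array([ad.csa_closed_form(1.0, k * D, params)
                          for k in range(41)])
        assert np.abs(traj - exact).max() < 1e-6

    def test_monotone_and_bounded(self, params):
        traj = ad.simulate_growth(_const_profile(0.9), params, 200)
        assert np.all(np.diff(traj) >= -1e-12)
        assert traj.max() <= params.csa_max + 1e-9

    def test_nonfinite_profile_rejected(self):
        with pytest.raises(ValueError):
            ad.ForceProfile(time=np.linspace(0, 1, 5),
                            force=np.array([0.3, np.nan, 0.3, 0.3, 0.3]))


class TestRepsToTarget:
    def test_zero_reps_for_baseline_target(self, params):
        assert ad.reps_to_target(_const_profile(0.5), params, target=1.0) == 0

    def test_subthreshold_infeasible(self, params):
        assert ad.reps_to_target(_const_profile(0.1), params) is None

    def test_target_above_ceiling_infeasible(self, params):
        assert ad.reps_to_target(_const_profile(0.9), params, target=1.5) is None

    def test_comparison_principle(self, params, rng):
        """A pointwise-larger force profile never needs more repetitions."""
        t = np.linspace(0, 0.5, 60)
        for _ in range(10):
            base = 0.25 + 0.4 * rng.uniform(size=60)
            bump = 0.05 * rng.uniform(size=60)
            lo = ad.ForceProfile(t, base)
            hi = ad.ForceProfile(t, base + bump)
            assert ad.reps_to_target(hi, params) <= ad.reps_to_target(lo, params)

    def test_doubling_gain_halves_reps(self, params):
        """For constant supra-threshold force the drive is linear in the
        gain, so doubling delta halves the required repetitions."""
        prof = _const_profile(0.6)
        p2 = ad.AdaptationParams(tau=params.tau, delta=2.0,
                                 csa_max=params.csa_max)
        n1 = ad.reps_to_target(prof, params)
        n2 = ad.reps_to_target(prof, p2)
        assert n2 == pytest.approx(n1 / 2, abs=1.0)

    def test_reps_verified_by_simulation(self, params):
        prof = _const_profile(0.6)
        n = ad.reps_to_target(prof, params)
        target = 1.0 + ad.TARGET_INCREASE
        traj = ad.simulate_growth(prof, params, n)
        assert traj[-1] >= target - 1e-9
        assert traj[-2] < target


class TestSchedule:
    def test_reported_set_counts(self):
        # 252 reps at 12 reps/set over 3 sessions/week -> 7 sets/session;
        # 1,426 reps -> 40 sets/session
        assert ad.reps_to_schedule(252) == 7
        assert ad.reps_to_schedule(1426) == 40

    def test_zero_reps_zero_sets(self):
        assert ad.reps_to_schedule(0) == 0

    def test_infeasible_propagates(self):
        assert ad.reps_to_schedule(None) is None

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ad.reps_to_schedule(-3)


class TestCalibration:
    def test_round_trip_reproduces_reference(self):
        params = ad.calibrate_adaptation()
        ref = ad.DEFAULT_REFERENCE
        prof = _const_profile(ref["force"], duration=ref["rep_duration"])
        got = ad.reps_to_target(prof, params)
        assert abs(got - ref["reps"]) <= 1

    def test_deterministic(self):
        a = ad.calibrate_adaptation()
        b = ad.calibrate_adaptation()
        assert a == b

    def test_tau_scales_with_reference_reps(self):
        """Constant-force closed form: doubling the reference rep count
        doubles the fitted time constant."""
        a = ad.calibrate_adaptation({"reps": 100})
        b = ad.calibrate_adaptation({"reps": 200})
        assert b.tau == pytest.approx(2 * a.tau, rel=1e-6)

    def test_unreachable_reference_rejected(self):
        with pytest.raises(ValueError):
            ad.calibrate_adaptation({"force": 0.1})
        with pytest.raises(ValueError):
            ad.calibrate_adaptation({"target_increase": 0.6}, csa_max=1.4)
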