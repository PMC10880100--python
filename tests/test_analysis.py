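import numpy as np
import pytest

from hypohop import analysis as an
from hypohop import model_core as mc
from hypohop.ocp_tracking import OCPSolution
from hypohop.preprocessing import TrackingData


def _static_solution(model, ft=None, grf_scale=1.0):
    """Fabricate a static-standing 'solution' (no motion, optional tendon
    forces) whose GRF supports the body weight under the COM."""
    T = 11
    t = np.linspace(0, 0.5, T)
    nq, nm = model.n_coordinates, len(model.mtus)
    q = np.zeros((T, nq))
    q[:, 1] = 0.98
    kin = mc.ChainKinematics(model, q)
    masses = np.array([s.mass for s in model.segments])
    com = (masses[:, None] * kin.com[:, 0, :]).sum(0) / model.total_mass
    w = model.total_mass * model.gravity_earth * grf_scale
    states = {
        "q": q, "qd": np.zeros((T, nq)),
        "a": np.zeros((T, nm)),
        "ft": np.zeros((T, nm)) if ft is None else np.tile(ft, (T, 1)),
        "atau": np.zeros((T, 1)),
    }
    # all load on the heel sphere, placed under the whole-body COM
    ankle = kin.origin[model._seg_index["foot"], 0]
    sphere_pos = np.array([[com[0] - ankle[0], -0.08], [0.17, -0.08]])
    ugrf = np.zeros((T, 4))
    ugrf[:, 1] = w
    controls = {
        "qdd": np.zeros((T, nq)), "da": np.zeros((T, nm)),
        "dft": np.zeros((T, nm)), "ugrf": ugrf,
        "etau": np.zeros((T, 1)), "res": np.zeros((T, 3)),
    }
    data = TrackingData(
        time=t, q=q, qd=states["qd"], qdd=controls["qdd"],
        njm_exp=np.zeros((T, 4)), residuals_exp=np.zeros((T, 3)),
        grf_exp=ugrf[:, :2] + ugrf[:, 2:], bwss=np.zeros(T),
        touchdown_times=(np.nan, np.nan), mass=model.total_mass, g_level=1.0,
        coordinate_names=list(model.coordinates),
        joint_names=list(model.coordinates[3:]))
    return OCPSolution(
        model=model, data=data, time=t, states=states, controls=controls,
        parameters={"stiffness": 5e5, "damping": 1.0, "sphere_positions": sphere_pos},
        cost_terms={"total": 0.0}, converged=True, status=1, message="",
        n_iterations=0, constr_violation=0.0, winning_guess="data-informed",
        guess_report=[], xvec=np.zeros(1), solve_time=0.0)


class TestPeakAndImpulse:
    def test_constant_series(self):
        t = np.linspace(0, 0.3, 31)
        peak, imp = an.peak_and_impulse(np.full(31, 2.0), t)
        assert peak == 2.0
        assert imp == pytest.approx(0.6)

    def test_half_sine_analytic_integral(self):
        A, T = 3.0, 0.4
        t = np.linspace(0, T, 2001)
        peak, imp = an.peak_and_impulse(A * np.sin(np.pi * t / T), t)
        assert peak == pytest.approx(A, rel=1e-5)
        assert imp == pytest.approx(2 * A * T / np.pi, rel=1e-5)

    def test_all_zero(self):
        t = np.linspace(0, 1, 5)
        assert an.peak_and_impulse(np.zeros(5), t) == (0.0, 0.0)

    def test_signed_extremum(self):
        t = np.linspace(0, 1, 5)
        peak, _ = an.peak_and_impulse(np.array([1.0, -4.0, 2.0, 0.0, 1.0]), t)
        assert peak == -4.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            an.peak_and_impulse(np.array([]), np.array([]))


class TestJointReactionForces:
    def test_static_ankle_reaction_carries_grf(self, model):
        """Standing still without muscle force, the ankle reaction supports
        the GRF minus the foot's own weight."""
        sol = _static_solution(model)
        jrf = an.joint_reaction_forces(sol, frame="lab")
        w = model.total_mass * model.gravity_earth
        foot_w = model.segment("foot").mass * model.gravity_earth
        assert jrf["ankle"]["compressive"][0] == pytest.approx(w - foot_w, rel=1e-6)

    def test_muscle_force_adds_compression(self, model):
        """Loading the soleus increases the ankle compressive force by about
        the muscle tension (free-body oracle)."""
        base = an.joint_reaction_forces(_static_solution(model), frame="child")
        ft = np.zeros(len(model.mtus))
        j = [m.name for m in model.mtus].index("soleus")
        F = 800.0
        ft[j] = F / model.mtus[j].f_max_iso
        loaded = an.joint_reaction_forces(_static_solution(model, ft=ft),
                                          frame="child")
        rise = loaded["ankle"]["compressive"][0] - base["ankle"]["compressive"][0]
        assert 0.6 * F < rise < 1.1 * F

    def test_knee_reaction_exceeds_grf_with_active_extensors(self, model):
        """Quadriceps tension compresses the knee beyond the external load."""
        ft = np.zeros(len(model.mtus))
        for name in mc.QUADRICEPS:
            j = [m.name for m in model.mtus].index(name)
            ft[j] = 0.3
        sol = _static_solution(model, ft=ft)
        jrf = an.joint_reaction_forces(sol, frame="child")
        w = model.total_mass * model.gravity_earth
        assert jrf["knee"]["compressive"].max() > w


class TestTrackingErrors:
    def test_perfect_tracking_zeros(self, model):
        sol = _static_solution(model)
        sol.data.njm_exp = an._solution_moments(sol, model)
        diag = an.tracking_errors(sol)
        assert diag.max_abs_error["rotations_deg"] == 0.0
        assert diag.max_abs_error["translations_m"] == 0.0
        assert diag.reserve_max == 0.0
        assert diag.accepted

    def test_constant_offset_reported(self, model):
        sol = _static_solution(model)
        sol.data.njm_exp = an._solution_moments(sol, model)
        sol.data.q = sol.data.q.copy()
        sol.data.q[:, 4] += np.deg2rad(1.0)  # one degree on the hip
        diag = an.tracking_errors(sol)
        assert diag.max_abs_error["rotations_deg"] == pytest.approx(1.0, abs=1e-9)
        assert diag.rmse["rotations_deg"] == pytest.approx(
            1.0 / np.sqrt(len(model.coordinates) - 2), rel=1e-6)

    def test_reserve_fraction_flags_violation(self, model):
        # reserve of ~1 N m against a ~5 N m knee moment -> ~20% -> rejected
        ft = np.zeros(len(model.mtus))
        j = [m.name for m in model.mtus].index("vastus_lateralis")
        ft[j] = 4.0 / model.mtus[j].f_max_iso / 0.027  # ~4 N m knee extension
        sol = _static_solution(model, ft=ft)
        sol.controls["res"][:, 1] = 1.0
        njm = an._solution_moments(sol, model)
        assert 2.0 < abs(njm[0, 2]) < 10.0
        sol.data.njm_exp = njm
        diag = an.tracking_errors(sol)
        assert diag.reserve_fraction_max > 0.10
        assert not diag.accepted


class TestQuadricepsProfile:
    def test_normalisation_and_cycle_restriction(self, model):
        ft = np.zeros(len(model.mtus))
        for name in mc.QUADRICEPS:
            ft[[m.name for m in model.mtus].index(name)] = 0.5
        sol = _static_solution(model, ft=ft)
        t, f = an.quadriceps_force_profile(sol)
        assert np.allclose(f, 0.5)
        assert t[0] == 0.0
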