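import math

import numpy as np
import pytest
from scipy.linalg import expm

from hypohop import ocp_tracking as ot
from hypohop.model_core import activation_rate_constraints


@pytest.fixture(scope="module")
def nlp(model, clean_tracking_data):
    return ot.TrackingNLP(model, clean_tracking_data, ot.OCPConfig(),
                          ot.CostWeights(), ot.derive_scale_factors())


class TestScaleFactors:
    def test_moment_scale_from_two_degrees(self):
        s = ot.derive_scale_factors(2.0, 0.02)
        assert s.s_tau == 28.6

    def test_vertical_force_scale_from_two_centimetres(self):
        s = ot.derive_scale_factors(2.0, 0.02)
        assert s.s_grf[1] == 50.0

    def test_horizontal_reduced_by_gravity(self):
        s = ot.derive_scale_factors(2.0, 0.02)
        assert s.s_grf[0] == 5.1

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ot.derive_scale_factors(-1.0, 0.02)


class TestCostTerms:
    def test_effort_hand_integral(self):
        # one muscle, PV = 10, a = 1 for 1 s: integral PV a^2 dt = 10
        t = np.linspace(0, 1, 11)
        a = np.ones((11, 1))
        assert ot.effort_cost(t, a, [10.0]) == pytest.approx(10.0)

    def test_effort_zero_when_inactive(self):
        t = np.linspace(0, 1, 11)
        assert ot.effort_cost(t, np.zeros((11, 3)), [10, 20, 30]) == 0.0

    def test_effort_linear_in_volume_fraction(self):
        t = np.linspace(0, 1, 11)
        a = np.full((11, 1), 0.5)
        j1 = ot.effort_cost(t, a, [10.0])
        j2 = ot.effort_cost(t, a, [20.0])
        assert j2 == pytest.approx(2 * j1)

    def test_tracking_hand_integrals(self):
        t = np.linspace(0, 1, 11)
        z = np.zeros((11, 1))
        s = ot.derive_scale_factors()
        w = ot.CostWeights()
        # constant 2 degree error on one angle for 1 s -> unit scaled error
        rot = np.full((11, 1), math.radians(2.0))
        j = ot.tracking_cost(t, rot, z, z, z, np.zeros((11, 2)),
                             np.zeros((11, 2)), z, z, s, w)
        assert j == pytest.approx(1.0, rel=1e-12)
        # constant 28.6 (mass-normalised) moment error at w3 = 10 -> 10
        njm = np.full((11, 1), 28.6)
        j = ot.tracking_cost(t, z, z, z, z, np.zeros((11, 2)),
                             np.zeros((11, 2)), njm, z, s, w)
        assert j == pytest.approx(10.0, rel=1e-12)

    def test_tracking_zero_when_perfect(self, rng):
        t = np.linspace(0, 1, 11)
        x = rng.normal(size=(11, 2))
        g = rng.normal(size=(11, 2))
        s = ot.derive_scale_factors()
        j = ot.tracking_cost(t, x, x, x[:, :1], x[:, :1], g, g, x, x,
                             s, ot.CostWeights())
        assert j == 0.0

    def test_grid_mismatch_rejected(self):
        t = np.linspace(0, 1, 11)
        s = ot.derive_scale_factors()
        with pytest.raises(ValueError):
            ot.tracking_cost(t, np.zeros((11, 1)), np.zeros((10, 1)),
                             np.zeros((11, 1)), np.zeros((11, 1)),
                             np.zeros((11, 2)), np.zeros((11, 2)),
                             np.zeros((11, 1)), np.zeros((11, 1)),
                             s, ot.CostWeights())

    def test_control_hand_integral(self):
        t = np.linspace(0, 1, 11)
        z = np.zeros((11, 1))
        s = ot.derive_scale_factors()
        w = ot.CostWeights()
        # reserve 2 N m for 1 s at s_res = 2, w2 = 1 -> 1
        res = np.full((11, 1), 2.0)
        j = ot.control_cost(t, z, [1.0], z, 1.0, z, 1.0, res, s, w)
        assert j == pytest.approx(1.0)
        # q_ddot at its bound for 1 s contributes w2 * 1
        qdd = np.full((11, 1), 300.0)
        j = ot.control_cost(t, qdd, [300.0], z, 1.0, z, 1.0, z, s, w)
        assert j == pytest.approx(1.0)


class TestTranscription:
    def test_variable_count_closed_form(self, nlp, model):
        N = nlp.N
        nx = 2 * model.n_coordinates + 2 * len(model.mtus) + len(model.torque_actuators)
        ng = 2 * len(model.contact_spheres)
        nu = (model.n_coordinates + 2 * len(model.mtus) + ng
              + len(model.torque_actuators) + len(model.muscle_coordinates))
        npar = 2 + 2 * len(model.contact_spheres)
        assert nlp.n_var == (N + 1) * nx + (N + 1) * nu + npar

    def test_scaling_round_trip(self, nlp, rng):
        x = nlp.lb + (nlp.ub - nlp.lb) * rng.uniform(0.0, 1.0, nlp.n_var)
        assert np.allclose(nlp.unscale(nlp.scale(x)), x, atol=1e-10)
        z = rng.uniform(-1, 1, nlp.n_var)
        assert np.allclose(nlp.scale(nlp.unscale(z)), z, atol=1e-10)

    def test_radau_differentiation_annihilates_constants(self, nlp):
        # derivative of a constant polynomial is zero at every colloc point
        assert np.abs(nlp.Dmat.sum(axis=0)).max() < 1e-12

    def test_radau_nodes(self):
        nodes = ot.radau_nodes(3)
        r6 = math.sqrt(6)
        assert nodes == pytest.approx([(4 - r6) / 10, (4 + r6) / 10, 1.0])

    def test_collocation_exact_on_integrated_linear_dynamics(self, nlp, rng):
        """Feasibility oracle: a trajectory produced by integrating the
        (linear) state dynamics satisfies the reduced collocation constraints
        to discretisation accuracy."""
        Fx, Fu = nlp._dynamics_matrices()
        X = np.zeros((nlp.N + 1, nlp.nx))
        X[0] = rng.normal(size=nlp.nx) * 0.1
        U = rng.normal(size=(nlp.N + 1, nlp.nu)) * 0.1
        h = nlp.h
        for i in range(nlp.N):
            # exact solution with piecewise-linear controls via augmentation
            nzu = nlp.nu
            A = np.zeros((nlp.nx + 2, nlp.nx + 2))
            A[:nlp.nx, :nlp.nx] = Fx
            # x' = Fx x + Fu ((1-s) u0 + s u1), s = t/h
            b0 = Fu @ U[i]
            b1 = Fu @ (U[i + 1] - U[i]) / h
            A[:nlp.nx, nlp.nx] = b0
            A[:nlp.nx, nlp.nx + 1] = b1
            A[nlp.nx, nlp.nx + 1] = 0
            A[nlp.nx + 1, nlp.nx] = 1.0  # d(t)/dt = 1 carried in slot nx+1...
            # simpler: fine RK4
            xx = X[i].copy()
            nsub = 64
            dt = h / nsub
            for ss in range(nsub):
                def f(x, tl):
                    w = (ss * dt + tl) / h
                    return Fx @ x + Fu @ ((1 - w) * U[i] + w * U[i + 1])
                k1 = f(xx, 0)
                k2 = f(xx + dt / 2 * k1, dt / 2)
                k3 = f(xx + dt / 2 * k2, dt / 2)
                k4 = f(xx + dt * k3, dt)
                xx = xx + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            X[i + 1] = xx
        xvec = np.zeros(nlp.n_var)
        xvec[nlp.iX0:nlp.iU0] = X.ravel()
        xvec[nlp.iU0:nlp.iP0] = U.ravel()
        assert np.abs(nlp.A_colloc @ xvec).max() < 1e-4

    def test_activation_rows_match_rate_envelope(self, nlp, rng):
        """The linear inequality block encodes exactly the Raasch-type
        envelope from model_core."""
        x = nlp.v_centre.copy()
        X, U, P = nlp.unpack(x)
        a = rng.uniform(0, 1, nlp.nm)
        da = rng.uniform(-70, 70, nlp.nm)
        X[0, nlp.sx["a"]] = a
        U[0, nlp.su["da"]] = da
        x[nlp.iX0:nlp.iU0] = X.ravel()
        x[nlp.iU0:nlp.iP0] = U.ravel()
        vals = nlp.A_act @ x
        g_act, g_deact = activation_rate_constraints(a, da)
        ours_act = vals[:2 * nlp.nm:2] - nlp.b_act_hi[:2 * nlp.nm:2]
        ours_deact = vals[1:2 * nlp.nm:2] - nlp.b_act_hi[1:2 * nlp.nm:2]
        assert np.allclose(ours_act, g_act)
        assert np.allclose(ours_deact, g_deact)

    def test_cost_decomposition_sums_exactly(self, nlp, rng):
        x = nlp.unscale(rng.uniform(-0.3, 0.3, nlp.n_var))
        terms = nlp.objective_terms(x)
        assert terms["total"] == pytest.approx(
            terms["effort"] + terms["tracking"] + terms["control"], rel=1e-12)

    def test_gradient_matches_finite_differences(self, nlp, rng):
        z = rng.uniform(-0.2, 0.2, nlp.n_var)
        g = nlp.grad(z)
        f0 = nlp.obj(z)
        for i in rng.choice(nlp.n_var, 10, replace=False):
            zp = z.copy()
            zp[i] += 1e-6
            fd = (nlp.obj(zp) - f0) / 1e-6
            assert fd == pytest.approx(g[i], rel=2e-3, abs=1e-7)

    def test_torque_actuator_step_response(self, nlp, model):
        """First-order excitation-activation dynamics: a step in excitation
        reaches 63.2% of its final value after one delay (35 ms)."""
        Fx, Fu = nlp._dynamics_matrices()
        i = nlp.sx["atau"].start
        j = nlp.su["etau"].start
        delay = model.torque_actuators[0].delay
        A, B = Fx[i, i], Fu[i, j]
        assert A == pytest.approx(-1.0 / delay)
        assert B == pytest.approx(1.0 / delay)
        # closed form of a_dot = A a + B for a unit excitation step from rest
        a_at_delay = (1.0 - expm(np.array([[A]]) * delay)[0, 0]) * (B / -A)
        assert a_at_delay == pytest.approx(1 - math.exp(-1), rel=1e-2)

    def test_inconsistent_mesh_rejected(self, model, clean_tracking_data):
        cfg = ot.OCPConfig(n_mesh_intervals=40)
        with pytest.raises(ValueError, match="mesh"):
            ot.TrackingNLP(model, clean_tracking_data, cfg, ot.CostWeights(),
                           ot.derive_scale_factors())


class TestInitialGuesses:
    def test_data_informed_copies_kinematics(self, nlp, clean_tracking_data):
        warm, cold = ot.make_initial_guesses(nlp)
        X, U, P = nlp.unpack(warm)
        assert np.allclose(X[:, nlp.sx["q"]], clean_tracking_data.q, atol=1e-6)
        assert np.allclose(U[:, nlp.su["qdd"]], clean_tracking_data.qdd, atol=1e-6)

    def test_contact_parameter_starting_values(self, nlp):
        warm, cold = ot.make_initial_guesses(nlp)
        for g in (warm, cold):
            assert g[nlp.iP0] == pytest.approx(1e6)
            assert g[nlp.iP0 + 1] == pytest.approx(2.0)

    def test_guesses_respect_bounds(self, nlp):
        for g in ot.make_initial_guesses(nlp):
            assert (g >= nlp.lb - 1e-12).all()
            assert (g <= nlp.ub + 1e-12).all()

    def test_cold_guess_zero_or_lower_bound(self, nlp):
        _, cold = ot.make_initial_guesses(nlp)
        X, U, P = nlp.unpack(cold)
        # two-sided variables sit at (clipped) zero, one-sided at lower bound
        assert np.abs(X[:, nlp.sx["q"]]).max() <= np.abs(nlp.unpack(nlp.ub)[0][:, nlp.sx["q"]]).max()
        assert (X[:, nlp.sx["a"]] <= 0.05).all()
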