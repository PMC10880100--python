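import math

import numpy as np
import pytest

from hypohop import model_core as mc


# ---------------------------------------------------------------------------
# Muscle curves
# ---------------------------------------------------------------------------


class TestMuscleCurves:
    def test_isometric_normalisation(self, model):
        f_act, f_v, _, _ = mc.eval_muscle_curves(1.0, 0.0, 0.0, model.curves)
        assert f_act == pytest.approx(1.0, abs=1e-12)
        assert f_v == pytest.approx(1.0, abs=1e-12)

    def test_tendon_gradient_at_four_percent_strain(self, model):
        # central finite differences on the calibrated curve
        h = 1e-6
        hi = model.curves.tendon_fl(0.04 + h)
        lo = model.curves.tendon_fl(0.04 - h)
        assert (hi - lo) / (2 * h) == pytest.approx(35.0, rel=1e-6)

    @pytest.mark.parametrize("fun,x0,h", [
        # the passive clamp smoothing has a 1e-4 length scale: steps must
        # resolve it for the finite-difference estimate to converge
        ("passive_fl", 1.0, 1e-6), ("passive_fl", 1.3, 1e-4),
        ("tendon_fl", 0.0, 1e-4), ("tendon_fl", 0.04, 1e-4),
    ])
    def test_second_derivative_continuity(self, model, fun, x0, h):
        """Central-difference second derivatives converge as the step
        shrinks, i.e. the curves are twice continuously differentiable."""
        f = getattr(model.curves, fun)
        estimates = []
        for hh in (h, h / 2):
            estimates.append((f(x0 + hh) - 2 * f(x0) + f(x0 - hh)) / hh**2)
        assert estimates[0] == pytest.approx(estimates[1], rel=2e-2, abs=1e-6)

    def test_force_velocity_limits(self, model):
        c = model.curves
        assert c.force_velocity(-1.0) < 0.05  # maximal shortening: ~no force
        assert c.force_velocity(0.5) > 1.2    # eccentric force enhancement

    def test_rejects_nonfinite_input(self, model):
        with pytest.raises(ValueError):
            mc.eval_muscle_curves(np.nan, 0.0, 0.0, model.curves)
        with pytest.raises(ValueError):
            mc.eval_muscle_curves(-0.5, 0.0, 0.0, model.curves)


class TestTendonCalibration:
    def test_slope_condition_holds(self):
        curves = mc.calibrate_tendon_stiffness(mc.MuscleCurveSet())
        assert curves.tendon_slope(0.04) == pytest.approx(35.0, rel=1e-9)

    def test_monotone_in_target_gradient(self):
        c35 = mc.calibrate_tendon_stiffness(mc.MuscleCurveSet(), 35.0)
        c70 = mc.calibrate_tendon_stiffness(mc.MuscleCurveSet(), 70.0)
        assert c70.k_T > c35.k_T

    def test_degenerate_strain_rejected(self):
        with pytest.raises(ValueError):
            mc.calibrate_tendon_stiffness(mc.MuscleCurveSet(), target_strain=0.0)

    def test_missing_root_reported(self):
        with pytest.raises(ValueError, match="bracket"):
            mc.calibrate_tendon_stiffness(mc.MuscleCurveSet(), 1e9,
                                          bracket=(5.0, 10.0))


# ---------------------------------------------------------------------------
# Hill equilibrium
# ---------------------------------------------------------------------------


class TestHillEquilibrium:
    def test_isometric_balance(self, model):
        mtu = model.mtu("soleus")
        curves = model.curves
        # fibre at optimum, tendon carrying the matching force
        ft = math.cos(mtu.pennation_opt) * (1.0 + float(curves.passive_fl(1.0)))
        strain = float(curves.tendon_strain_from_force(ft))
        lmt = mtu.l_slack * (1 + strain) + mtu.l_opt * math.cos(mtu.pennation_opt)
        r = mc.hill_equilibrium_residual(1.0, lmt, 0.0, ft, 0.0, mtu, curves)
        assert r == pytest.approx(0.0, abs=1e-10)

    def test_passive_slack_state(self, model):
        mtu = model.mtu("soleus")
        curves = model.curves
        # inactive muscle, unloaded tendon, fibre short of optimal
        strain = float(curves.tendon_strain_from_force(0.0))
        lmt = mtu.l_slack * (1 + strain) + 0.9 * mtu.l_opt * math.cos(mtu.pennation_opt)
        r = mc.hill_equilibrium_residual(0.0, lmt, 0.0, 0.0, 0.0, mtu, curves)
        assert abs(r) < 1e-6

    def test_matches_independent_rederivation(self, model, rng):
        """Residual equals an explicit re-derivation from the curve set."""
        mtu = model.mtu("gastrocnemius")
        curves = model.curves
        for _ in range(25):
            a = rng.uniform(0, 1)
            ft = rng.uniform(0.0, 1.5)
            dft = rng.uniform(-50, 50)
            strain = curves.tendon_strain_from_force(ft)
            lmt = mtu.l_slack * (1 + strain) + rng.uniform(0.7, 1.3) * mtu.l_opt
            vmt = rng.uniform(-0.3, 0.3)
            got = mc.hill_equilibrium_residual(a, lmt, vmt, ft, dft, mtu, curves)
            # oracle: textbook three-element balance, written out long-hand
            lt = mtu.l_slack * (1.0 + strain)
            h = mtu.l_opt * math.sin(mtu.pennation_opt)
            l_along = lmt - lt
            lm = math.hypot(l_along, h)
            cosa = l_along / lm
            vt = mtu.l_slack * dft / (curves.k_T * (ft + curves.tendon_c3))
            vm = (vmt - vt) * cosa / (mtu.v_max * mtu.l_opt)
            fibre = (a * curves.active_fl(lm / mtu.l_opt) * curves.force_velocity(vm)
                     + curves.passive_fl(lm / mtu.l_opt) + curves.damping * vm)
            assert got == pytest.approx(cosa * fibre - ft, abs=1e-12)

    def test_nonpositive_fibre_length_rejected(self, model):
        mtu = model.mtu("soleus")
        with pytest.raises(ValueError, match="fibre"):
            mc.hill_equilibrium_residual(0.5, 0.01, 0.0, 1.0, 0.0, mtu, model.curves)


# ---------------------------------------------------------------------------
# Activation rate envelope
# ---------------------------------------------------------------------------


class TestActivationRates:
    def test_holding_is_admissible(self):
        g_act, g_deact = mc.activation_rate_constraints(0.5, 0.0)
        assert g_act <= 0 and g_deact <= 0

    def test_cannot_exceed_full_activation(self):
        g_act, _ = mc.activation_rate_constraints(1.0, 1.0)
        assert g_act > 0

    def test_envelope_matches_first_order_model_sweep(self):
        """Brute-force oracle: a rate is admissible iff some excitation in
        [0, 1] produces it through the first-order dynamics."""
        t_act, t_deact = 0.015, 0.06
        for a in np.linspace(0.05, 0.95, 7):
            for adot in np.linspace(-40, 80, 25):
                feasible_e = []
                for e in np.linspace(0, 1, 201):
                    tau = t_act if e > a else t_deact
                    feasible_e.append(abs((e - a) / tau - adot))
                oracle = min(feasible_e) < 0.5  # within grid resolution
                g_act, g_deact = mc.activation_rate_constraints(a, adot, t_act, t_deact)
                ours = (g_act <= 1e-9) and (g_deact <= 1e-9)
                if oracle != ours:
                    # only allowed to disagree within one grid cell of the edge
                    edge_dist = min(abs(adot - (1 - a) / t_act),
                                    abs(adot + a / t_deact))
                    assert edge_dist < 0.5


# ---------------------------------------------------------------------------
# Contact model
# ---------------------------------------------------------------------------


class TestContact:
    def test_clear_of_ground(self, model):
        s = model.contact_spheres[0]
        f = mc.contact_force(-0.05, 0.0, s)
        assert abs(f[..., 1]) < 1e-3

    def test_linear_in_stiffness(self):
        f1 = mc.contact_normal_force(0.005, 0.0, 1e6, 0.0)
        f2 = mc.contact_normal_force(0.005, 0.0, 2e6, 0.0)
        assert f2 / f1 == pytest.approx(2.0, rel=1e-9)

    def test_monotone_in_penetration(self):
        d = np.linspace(-0.01, 0.02, 200)
        f = mc.contact_normal_force(d, 0.1, 1e6, 2.0)
        assert np.all(np.diff(f) > 0)
        assert np.all(f >= 0)

    def test_second_derivative_finite_at_touch(self):
        # the positive-part smoothing scale is 1e-5 m: finite differences
        # converge once the step resolves it
        f = lambda x: mc.contact_normal_force(x, 0.0, 1e6, 2.0)
        ests = [(f(h) - 2 * f(0.0) + f(-h)) / h**2 for h in (2e-7, 1e-7)]
        assert np.isfinite(ests).all()
        assert ests[1] == pytest.approx(ests[0], rel=5e-2)


# ---------------------------------------------------------------------------
# Rigid-body dynamics
# ---------------------------------------------------------------------------


def _standing_pose(model):
    q = np.zeros((1, model.n_coordinates))
    q[0, 1] = 0.98
    return q


class TestInverseDynamics:
    def test_static_equilibrium(self, model):
        q = _standing_pose(model)
        kin = mc.ChainKinematics(model, q)
        masses = np.array([s.mass for s in model.segments])
        com = (masses[:, None] * kin.com[:, 0, :]).sum(0) / model.total_mass
        ankle = kin.origin[model._seg_index["foot"], 0]
        local = np.array([com[0] - ankle[0], -0.08])
        F = np.array([0.0, model.total_mass * model.gravity_earth])
        tau = mc.inverse_dynamics(q, None, None, [("foot", local, F)], model)
        assert np.abs(tau[0, :3]).max() < 1e-6

    def test_static_equilibrium_with_bwss(self, model):
        q = _standing_pose(model)
        cond = mc.GravityCondition.from_g_level(0.5, model.total_mass)
        kin = mc.ChainKinematics(model, q)
        masses = np.array([s.mass for s in model.segments])
        com = (masses[:, None] * kin.com[:, 0, :]).sum(0) / model.total_mass
        ankle = kin.origin[model._seg_index["foot"], 0]
        pelvis = model.segments[0]
        pelvis_com_x = kin.com[0, 0, 0]
        w = model.total_mass * model.gravity_earth
        bwss = mc.bwss_force(cond, model)
        # support the remaining half weight under the combined line of action
        x_grf = (com[0] * w - pelvis_com_x * bwss) / (w - bwss)
        ext = [("foot", np.array([x_grf - ankle[0], -0.08]),
                np.array([0.0, w - bwss])),
               mc.bwss_external_force(cond, model)]
        tau = mc.inverse_dynamics(q, None, None, ext, model)
        assert np.abs(tau[0, :3]).max() < 1e-6

    def test_energy_rate_oracle(self, model, rng):
        """Power of the generalized forces equals the rate of change of
        mechanical energy (no external forces)."""
        t = np.linspace(0, 1, 4001)
        coef = rng.normal(size=(5, model.n_coordinates)) * 0.25
        q = sum(coef[d] * t[:, None] ** d for d in range(5))
        qd = sum(d * coef[d] * t[:, None] ** (d - 1) for d in range(1, 5))
        qdd = sum(d * (d - 1) * coef[d] * t[:, None] ** (d - 2) for d in range(2, 5))
        q[:, 1] += 1.0
        tau = mc.inverse_dynamics(q, qd, qdd, [], model)
        power = (tau * qd).sum(1)
        kin = mc.ChainKinematics(model, q, qd, qdd)
        masses = np.array([s.mass for s in model.segments])
        inertias = np.array([s.inertia_zz for s in model.segments])
        ke = 0.5 * (masses[:, None] * (kin.com_vel ** 2).sum(-1)).sum(0) \
            + 0.5 * (inertias[:, None] * kin.omega ** 2).sum(0)
        pe = (masses[:, None] * model.gravity_earth * kin.com[:, :, 1]).sum(0)
        dE = np.gradient(ke + pe, t)
        scale = max(np.abs(dE).max(), 1.0)
        assert np.abs(power - dE).max() / scale < 1e-3


class TestBwss:
    def test_removed_at_terrestrial_gravity(self, model):
        cond = mc.GravityCondition.from_g_level(1.0, model.total_mass)
        assert mc.bwss_force(cond, model) == 0.0

    @pytest.mark.parametrize("g,expected", [(0.5, 392.0), (0.17, 651.0)])
    def test_offloading_magnitudes(self, model, g, expected):
        cond = mc.GravityCondition.from_g_level(g, model.total_mass)
        assert mc.bwss_force(cond, model) == pytest.approx(expected, abs=1.0)

    @pytest.mark.parametrize("g", [0.0, -0.2, 1.5])
    def test_invalid_g_level(self, model, g):
        with pytest.raises(ValueError):
            mc.GravityCondition.from_g_level(g, model.total_mass)


class TestModelSpecInvariants:
    def test_total_mass_is_segment_sum(self, model):
        assert model.total_mass == pytest.approx(
            sum(s.mass for s in model.segments))

    def test_every_mtu_spans_a_coordinate(self, model):
        for m in model.mtus:
            assert len(m.spanned_coordinates) >= 1

    def test_quadriceps_volume_budget(self, model):
        pv = sum(m.pv_percent for m in model.mtus
                 if m.name in mc.QUADRICEPS)
        assert 0 < pv <= 100

    def test_invalid_segment_rejected(self):
        with pytest.raises(ValueError):
            mc.SegmentSpec("bad", -1.0, (0, 0), 0.1, 0.3)


# ---------------------------------------------------------------------------
# Property tests
# ---------------------------------------------------------------------------

from hypothesis import given, settings
from hypothesis import strategies as st


class TestProperties:
    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(d=st.floats(-0.02, 0.03), dd=st.floats(0.005, 0.02),
           v=st.floats(-0.5, 0.5))
    def test_contact_force_monotone_in_penetration(self, d, dd, v):
        f1 = mc.contact_normal_force(d, v, 5e5, 1.0)
        f2 = mc.contact_normal_force(d + dd, v, 5e5, 1.0)
        assert f2 > f1 >= 0.0

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(ft=st.floats(1e-4, 2.5))
    def test_tendon_curve_inversion_round_trip(self, ft):
        curves = mc.calibrate_tendon_stiffness(mc.MuscleCurveSet())
        strain = float(curves.tendon_strain_from_force(ft))
        assert float(curves.tendon_fl(strain)) == pytest.approx(ft, rel=1e-10)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(a=st.floats(0.0, 1.0), e=st.floats(0.0, 1.0))
    def test_first_order_rates_always_admissible(self, a, e):
        """Any rate produced by the first-order model with a valid
        excitation satisfies the envelope inequalities."""
        tau = 0.015 if e > a else 0.06
        adot = (e - a) / tau
        g_act, g_deact = mc.activation_rate_constraints(a, adot)
        assert g_act <= 1e-9 and g_deact <= 1e-9
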