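"""Data-tracking optimal control problem via direct collocation.

States ``x = (q, q_dot, a_m, Ft_norm, a_tau)`` are parameterised with
third-order polynomials on 50 equally spaced mesh intervals using
Legendre-Gauss-Radau collocation (four points per interval: the interval
start plus three Radau points).  Controls
``u = (q_ddot, a_m_dot, dFt_norm, u_GRF, e_tau, tau_res)`` live on the mesh
points and are interpolated linearly inside an interval.  Because the
skeletal and muscle dynamics are formulated implicitly, every collocation
equation is *linear* in the decision variables; all nonlinearity sits in
path constraints imposed at the mesh points:

* Hill equilibrium between fibre and tendon forces,
* muscle moments + reserve actuators = inverse-dynamics net joint moments,
* idealised trunk torque = inverse-dynamics lumbar moment,
* zero pelvis residuals (dynamic consistency),
* GRF controls = Hunt-Crossley contact-model forces,
* Raasch-type activation rate inequalities (linear).

Contact sphere stiffness, damping and positions are static optimisation
parameters.  All decision variables are affinely scaled to [-1, 1].  The
NLP is solved with a large-scale interior-point method (scipy
``trust-constr``) with sparse Jacobians obtained by sparsity-grouped finite
differences and a Gauss-Newton Hessian of the tracking objective.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import (Bounds, LinearConstraint, NonlinearConstraint,
                            minimize)

from .model_core import (ChainKinematics, ModelSpec, contact_normal_force,
                         hill_equilibrium_residual, inverse_dynamics)
from .mtu_geometry import GeometrySet, fit_model_geometry
from .preprocessing import TrackingData

# ---------------------------------------------------------------------------
# Weights, scale factors, configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CostWeights:
    """Cost-term weights (kept constant once calibrated)."""

    w1: float = 0.01  # translational tracking (lenient on vertical pelvis)
    w2: float = 1.0   # effort, rotational & GRF tracking, q_ddot & reserve control
    w3: float = 10.0  # moment tracking, muscle-state rate control

    def __post_init__(self):
        if min(self.w1, self.w2, self.w3) <= 0:
            raise ValueError("weights must be positive")


@dataclass(frozen=True)
class ScaleFactors:
    """Tracking scale factors: each equals the error that performs one unit
    of work against the corresponding kinematic scale."""

    s_rot_deg: float = 2.0    # deg
    s_tr: float = 0.02        # m
    s_tau: float = 28.6       # N m (per kg when moments are mass-normalised)
    s_grf: tuple[float, float] = (5.1, 50.0)  # (horizontal, vertical) N
    s_res: float = 2.0        # N m

    @property
    def s_rot(self) -> float:
        return math.radians(self.s_rot_deg)


def _round_sig(x: float, sig: int) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def derive_scale_factors(s_rot_deg: float = 2.0, s_tr: float = 0.02,
                         gravity: float = 9.81) -> ScaleFactors:
    """Derive the moment and force scales from the kinematic scales.

    The moment scale is the moment doing 1 J of work over ``s_rot`` (3
    significant figures); the vertical force scale does 1 J over ``s_tr``;
    the horizontal scale is the vertical one reduced by gravity (2 s.f.).
    """
    if s_rot_deg <= 0 or s_tr <= 0:
        raise ValueError("kinematic scales must be positive")
    s_tau = _round_sig(1.0 / math.radians(s_rot_deg), 3)
    s_vert = _round_sig(1.0 / s_tr, 3)
    s_horiz = _round_sig(s_vert / gravity, 2)
    return ScaleFactors(s_rot_deg=s_rot_deg, s_tr=s_tr, s_tau=s_tau,
                        s_grf=(s_horiz, s_vert))


@dataclass
class OCPConfig:
    n_mesh_intervals: int = 50
    collocation_points: int = 3  # Radau points per interval (+ interval start)
    solver: str = "sqp"  # "sqp" (Gauss-Newton SQP) or "trust-constr"
    solver_feas_tol: float = 1e-6
    solver_opt_tol: float = 1e-4
    max_iterations: int = 200
    max_iterations_cold: int = 200
    sqp_step_cap: float = 0.25  # max scaled step (infinity norm)
    sqp_param_reg: float = 5.0  # extra step regularisation on the static parameters
    sqp_merit_penalty: float = 200.0
    # a data-informed start is already near-optimal: begin the interior-point
    # homotopy with an almost-converged barrier so the start is not destroyed
    initial_barrier_warm: float = 1e-5
    initial_barrier_cold: float = 0.1
    verbose: int = 0
    # variable bounds; control bounds double as the s_Bound cost scales
    q_margin_rot: float = 0.30   # rad beyond the tracked range
    q_margin_tr: float = 0.10    # m
    qd_margin_rot: float = 5.0   # rad/s
    qd_margin_tr: float = 1.5    # m/s
    qd_rot_bound: float = 15.0   # rad/s
    qd_tr_bound: float = 4.0     # m/s
    qdd_rot_bound: float = 300.0
    qdd_tr_bound: float = 60.0
    ft_bound: float = 2.5
    da_bound: float = 70.0
    dft_bound: float = 200.0
    ugrf_x_bound: float = 500.0
    ugrf_y_lo: float = -50.0
    ugrf_y_hi: float = 3000.0
    tau_res_bound: float = 50.0
    muscle_informed_guess: bool = True
    stiffness_bounds: tuple[float, float] = (1e5, 1e7)
    damping_bounds: tuple[float, float] = (0.1, 4.0)
    sphere_pos_halfwidth_x: float = 0.03
    sphere_pos_halfwidth_y: float = 0.005
    t_act: float = 0.015
    t_deact: float = 0.06


@dataclass
class ReserveActuatorSpec:
    coordinate: str
    bound: float = 50.0  # N m
    accept_abs: float = 5.0  # N m
    accept_frac: float = 0.10


# ---------------------------------------------------------------------------
# Radau collocation machinery
# ---------------------------------------------------------------------------


def radau_nodes(d: int = 3) -> np.ndarray:
    """Interior/end collocation nodes of the right-Radau scheme on (0, 1]."""
    if d != 3:  # general case via Jacobi roots
        from scipy.special import roots_jacobi
        x, _ = roots_jacobi(d - 1, 1, 0)
        return np.sort(np.concatenate([(x + 1) / 2, [1.0]]))
    r6 = math.sqrt(6.0)
    return np.array([(4 - r6) / 10, (4 + r6) / 10, 1.0])


def lagrange_diff_matrix(nodes_full: np.ndarray, eval_at: np.ndarray) -> np.ndarray:
    """D[j, k] = dL_j/dtau at eval_at[k] for Lagrange basis on nodes_full."""
    n = len(nodes_full)
    D = np.zeros((n, len(eval_at)))
    for j in range(n):
        for k, tk in enumerate(eval_at):
            s = 0.0
            for l in range(n):
                if l == j:
                    continue
                p = 1.0 / (nodes_full[j] - nodes_full[l])
                for mm in range(n):
                    if mm in (j, l):
                        continue
                    p *= (tk - nodes_full[mm]) / (nodes_full[j] - nodes_full[mm])
                s += p
            D[j, k] = s
    return D


# ---------------------------------------------------------------------------
# Cost-term operations (trajectory-level; also used for reporting)
# ---------------------------------------------------------------------------


def effort_cost(time_grid, activations, pv_percent, w2: float = 1.0) -> float:
    """Muscle-sharing effort: w2 * sum_j integral PV_j a_j^2 dt."""
    a = np.asarray(activations, dtype=float)
    pv = np.asarray(pv_percent, dtype=float)
    return float(w2 * np.trapezoid((a * a) @ pv, np.asarray(time_grid)))


def tracking_cost(time_grid, sim_rot, exp_rot, sim_tr, exp_tr, sim_grf, exp_grf,
                  sim_njm, exp_njm, scales: ScaleFactors,
                  weights: CostWeights) -> float:
    """Sum of squared, scaled tracking errors (rotations, translations, GRF,
    mass-normalised net joint moments)."""
    t = np.asarray(time_grid)
    for sim, exp in ((sim_rot, exp_rot), (sim_tr, exp_tr), (sim_grf, exp_grf),
                     (sim_njm, exp_njm)):
        if np.asarray(sim).shape != np.asarray(exp).shape:
            raise ValueError("simulated and experimental grids do not match")
    j = weights.w2 * np.trapezoid(((np.asarray(sim_rot) - np.asarray(exp_rot))
                                   / scales.s_rot) ** 2, t, axis=0).sum()
    j += weights.w1 * np.trapezoid(((np.asarray(sim_tr) - np.asarray(exp_tr))
                                    / scales.s_tr) ** 2, t, axis=0).sum()
    j += weights.w2 * np.trapezoid(((np.asarray(sim_grf) - np.asarray(exp_grf))
                                    / np.asarray(scales.s_grf)) ** 2, t, axis=0).sum()
    j += weights.w3 * np.trapezoid(((np.asarray(sim_njm) - np.asarray(exp_njm))
                                    / scales.s_tau) ** 2, t, axis=0).sum()
    return float(j)


def control_cost(time_grid, qdd, qdd_bound, dft, dft_bound, da, da_bound,
                 tau_res, scales: ScaleFactors, weights: CostWeights) -> float:
    """Control regularisation: rate controls scaled by their bounds, reserve
    actuators by s_res."""
    t = np.asarray(time_grid)
    j = weights.w2 * np.trapezoid((np.asarray(qdd) / np.asarray(qdd_bound)) ** 2,
                                  t, axis=0).sum()
    j += weights.w3 * np.trapezoid((np.asarray(dft) / dft_bound) ** 2, t, axis=0).sum()
    j += weights.w3 * np.trapezoid((np.asarray(da) / da_bound) ** 2, t, axis=0).sum()
    j += weights.w2 * np.trapezoid((np.asarray(tau_res) / scales.s_res) ** 2,
                                   t, axis=0).sum()
    return float(j)


# ---------------------------------------------------------------------------
# The transcribed NLP
# ---------------------------------------------------------------------------


class TrackingNLP:
    """A transcribed tracking OCP for one trial.

    Variable layout (unscaled, "x-space"):
      states  X[node, :]  for node = 0..N*d (d Radau points per interval),
              columns: q (nq), q_dot (nq), a (nm), Ft (nm), a_tau (nta)
      controls U[mesh, :] for mesh = 0..N,
              columns: q_ddot (nq), a_dot (nm), dFt (nm),
                       u_GRF (2 per sphere), e_tau (nta), tau_res (nres)
      parameters: [stiffness, damping, sphere positions (x, y per sphere)]

    Scaled decision vector z in [-1, 1]^n with x = centre + halfwidth * z.
    """

    def __init__(self, model: ModelSpec, data: TrackingData, config: OCPConfig,
                 weights: CostWeights, scales: ScaleFactors,
                 geometry: GeometrySet | None = None,
                 fix_contact_positions: bool = False,
                 fix_contact_params: bool = False):
        self.model = model
        self.data = data
        self.config = config
        self.weights = weights
        self.scales = scales
        self.geometry = geometry or fit_model_geometry(model)
        self.fix_contact_positions = fix_contact_positions
        self.fix_contact_params = fix_contact_params

        N = config.n_mesh_intervals
        if len(data.time) != N + 1:
            raise ValueError(
                f"tracking data has {len(data.time)} mesh points, expected {N + 1}")
        self.N = N
        self.d = config.collocation_points
        self.nq = model.n_coordinates
        self.nm = len(model.mtus)
        self.nta = len(model.torque_actuators)
        self.nsph = len(model.contact_spheres)
        self.muscle_joints = model.muscle_coordinates  # e.g. hip, knee, ankle
        self.nres = len(self.muscle_joints)
        self.h = float(data.time[-1] - data.time[0]) / N
        self.mesh_time = data.time

        # state/control column layout
        nq, nm, nta = self.nq, self.nm, self.nta
        self.sx = dict(q=slice(0, nq), qd=slice(nq, 2 * nq),
                       a=slice(2 * nq, 2 * nq + nm),
                       ft=slice(2 * nq + nm, 2 * nq + 2 * nm),
                       atau=slice(2 * nq + 2 * nm, 2 * nq + 2 * nm + nta))
        self.nx = 2 * nq + 2 * nm + nta
        ng = 2 * self.nsph
        self.su = dict(qdd=slice(0, nq), da=slice(nq, nq + nm),
                       dft=slice(nq + nm, nq + 2 * nm),
                       ugrf=slice(nq + 2 * nm, nq + 2 * nm + ng),
                       etau=slice(nq + 2 * nm + ng, nq + 2 * nm + ng + nta),
                       res=slice(nq + 2 * nm + ng + nta,
                                 nq + 2 * nm + ng + nta + self.nres))
        self.nu = nq + 2 * nm + ng + nta + self.nres
        self.npar = 2 + 2 * self.nsph

        # the interior Radau states are eliminated analytically (the implicit
        # formulation makes the collocation equations linear), so the decision
        # vector carries states at the mesh points only
        self.n_state_nodes = N + 1
        self.n_var = self.n_state_nodes * self.nx + (N + 1) * self.nu + self.npar
        self.iX0 = 0
        self.iU0 = self.n_state_nodes * self.nx
        self.iP0 = self.iU0 + (N + 1) * self.nu

        self.tau_nodes = radau_nodes(self.d)
        full = np.concatenate([[0.0], self.tau_nodes])
        self.Dmat = lagrange_diff_matrix(full, self.tau_nodes)  # (d+1, d)

        self.node_time = data.time.copy()
        self._mesh_state_nodes = np.arange(self.n_state_nodes)

        self._build_bounds()
        self._build_linear_constraints()
        self._prepare_objective()
        self._prepare_nonlinear()

    # -- indexing helpers ----------------------------------------------------
    def x_index(self, node: int, col) -> np.ndarray:
        return self.iX0 + node * self.nx + np.arange(self.nx)[col]

    def u_index(self, mesh: int, col) -> np.ndarray:
        return self.iU0 + mesh * self.nu + np.arange(self.nu)[col]

    def unpack(self, xvec: np.ndarray):
        X = xvec[self.iX0:self.iU0].reshape(self.n_state_nodes, self.nx)
        U = xvec[self.iU0:self.iP0].reshape(self.N + 1, self.nu)
        P = xvec[self.iP0:]
        return X, U, P

    def scale(self, xvec: np.ndarray) -> np.ndarray:
        return (xvec - self.v_centre) / self.v_half

    def unscale(self, z: np.ndarray) -> np.ndarray:
        return self.v_centre + self.v_half * z

    # -- bounds --------------------------------------------------------------
    def _build_bounds(self):
        cfg, model, data = self.config, self.model, self.data
        nq = self.nq
        lb_x = np.empty(self.nx)
        ub_x = np.empty(self.nx)
        is_tr = np.array([c.endswith(("_tx", "_ty")) for c in model.coordinates])
        # coordinate bounds: the model ROM intersected with a window around
        # the tracked trajectory (tracking solutions stay near the data, and
        # the tighter box improves the scaled geometry of the NLP)
        for k, name in enumerate(model.coordinates):
            lo, hi = model.coordinate_ranges[name]
            margin = cfg.q_margin_tr if is_tr[k] else cfg.q_margin_rot
            lo = max(lo, data.q[:, k].min() - margin)
            hi = min(hi, data.q[:, k].max() + margin)
            lb_x[k], ub_x[k] = lo, hi
        qd_margin = np.where(is_tr, cfg.qd_margin_tr, cfg.qd_margin_rot)
        qd_cap = np.where(is_tr, cfg.qd_tr_bound, cfg.qd_rot_bound)
        lb_x[self.sx["qd"]] = np.maximum(data.qd.min(0) - qd_margin, -qd_cap)
        ub_x[self.sx["qd"]] = np.minimum(data.qd.max(0) + qd_margin, qd_cap)
        lb_x[self.sx["a"]], ub_x[self.sx["a"]] = 0.0, 1.0
        lb_x[self.sx["ft"]], ub_x[self.sx["ft"]] = 0.0, cfg.ft_bound
        lb_x[self.sx["atau"]], ub_x[self.sx["atau"]] = -1.0, 1.0

        lb_u = np.empty(self.nu)
        ub_u = np.empty(self.nu)
        self.qdd_bound = np.where(is_tr, cfg.qdd_tr_bound, cfg.qdd_rot_bound)
        lb_u[self.su["qdd"]], ub_u[self.su["qdd"]] = -self.qdd_bound, self.qdd_bound
        lb_u[self.su["da"]], ub_u[self.su["da"]] = -cfg.da_bound, cfg.da_bound
        lb_u[self.su["dft"]], ub_u[self.su["dft"]] = -cfg.dft_bound, cfg.dft_bound
        g_lo = np.tile([-cfg.ugrf_x_bound, cfg.ugrf_y_lo], self.nsph)
        g_hi = np.tile([cfg.ugrf_x_bound, cfg.ugrf_y_hi], self.nsph)
        lb_u[self.su["ugrf"]], ub_u[self.su["ugrf"]] = g_lo, g_hi
        lb_u[self.su["etau"]], ub_u[self.su["etau"]] = -1.0, 1.0
        lb_u[self.su["res"]], ub_u[self.su["res"]] = -cfg.tau_res_bound, cfg.tau_res_bound

        lb_p = np.empty(self.npar)
        ub_p = np.empty(self.npar)
        if self.fix_contact_params:
            k0 = self.model.contact_spheres[0].stiffness
            c0 = self.model.contact_spheres[0].damping
            lb_p[0] = ub_p[0] = k0
            lb_p[1] = ub_p[1] = c0
        else:
            lb_p[0], ub_p[0] = cfg.stiffness_bounds
            lb_p[1], ub_p[1] = cfg.damping_bounds
        for si, sphere in enumerate(model.contact_spheres):
            px, py = sphere.position
            hwx = 0.0 if self.fix_contact_positions else cfg.sphere_pos_halfwidth_x
            hwy = 0.0 if self.fix_contact_positions else cfg.sphere_pos_halfwidth_y
            lb_p[2 + 2 * si], ub_p[2 + 2 * si] = px - hwx, px + hwx
            lb_p[3 + 2 * si], ub_p[3 + 2 * si] = py - hwy, py + hwy

        lb = np.concatenate([np.tile(lb_x, self.n_state_nodes),
                             np.tile(lb_u, self.N + 1), lb_p])
        ub = np.concatenate([np.tile(ub_x, self.n_state_nodes),
                             np.tile(ub_u, self.N + 1), ub_p])
        self.lb, self.ub = lb, ub
        self.v_centre = 0.5 * (lb + ub)
        self.v_half = np.maximum(0.5 * (ub - lb), 1e-12)

    # -- linear constraints: collocation dynamics + activation rates --------
    def _dynamics_matrices(self):
        """State-space matrices of the (linear) implicit dynamics:
        x_dot = Fx x + Fu u."""
        nx, nu = self.nx, self.nu
        Fx = np.zeros((nx, nx))
        Fu = np.zeros((nx, nu))
        sq, sqd = self.sx["q"], self.sx["qd"]
        sa, sft, sat = self.sx["a"], self.sx["ft"], self.sx["atau"]
        Fx[sq, sqd] = np.eye(self.nq)
        Fu[sqd, self.su["qdd"]] = np.eye(self.nq)
        Fu[sa, self.su["da"]] = np.eye(self.nm)
        Fu[sft, self.su["dft"]] = np.eye(self.nm)
        if self.nta:
            delay = self.model.torque_actuators[0].delay
            Fx[sat, sat] = -np.eye(self.nta) / delay
            Fu[sat, self.su["etau"]] = np.eye(self.nta) / delay
        return Fx, Fu

    def _build_linear_constraints(self):
        """Reduced collocation constraints.

        Per interval the three Radau collocation equations are linear, so the
        two interior states are eliminated exactly, leaving one nx-row block
        linking (x_i, x_{i+1}, u_i, u_{i+1}).  The interval matrices are
        identical (equal spacing), so they are assembled once.
        """
        N, nx, nu, h = self.N, self.nx, self.nu, self.h
        Fx, Fu = self._dynamics_matrices()
        D = self.Dmat
        tau = self.tau_nodes
        I = np.eye(nx)
        # interior unknowns y = [x1; x2] from collocation rows k = 1, 2
        M = np.block([[D[1, 0] * I - h * Fx, D[2, 0] * I],
                      [D[1, 1] * I, D[2, 1] * I - h * Fx]])
        R0 = np.vstack([-D[0, 0] * I, -D[0, 1] * I])
        R3 = np.vstack([-D[3, 0] * I, -D[3, 1] * I])
        S0 = np.vstack([h * (1 - tau[0]) * Fu, h * (1 - tau[1]) * Fu])
        S1 = np.vstack([h * tau[0] * Fu, h * tau[1] * Fu])
        Minv = np.linalg.inv(M)
        W0, W3 = Minv @ R0, Minv @ R3
        V0, V1 = Minv @ S0, Minv @ S1
        # reduced row from collocation point k = 3 (tau = 1)
        G = np.hstack([D[1, 2] * I, D[2, 2] * I])
        C0 = G @ W0 + D[0, 2] * I
        C3 = G @ W3 + D[3, 2] * I - h * Fx
        Cu0 = G @ V0
        Cu1 = G @ V1 - h * Fu
        # keep the interior-state reconstruction for post-processing
        self._interior_maps = (W0, W3, V0, V1)

        rows, cols, vals = [], [], []
        for i in range(N):
            r0 = i * nx
            for name, blk, col0 in (("x0", C0, self.iX0 + i * nx),
                                    ("x3", C3, self.iX0 + (i + 1) * nx),
                                    ("u0", Cu0, self.iU0 + i * nu),
                                    ("u1", Cu1, self.iU0 + (i + 1) * nu)):
                rr, cc = np.nonzero(np.abs(blk) > 1e-14)
                rows.append(r0 + rr)
                cols.append(col0 + cc)
                vals.append(blk[rr, cc])
        A = sp.csr_matrix((np.concatenate(vals),
                           (np.concatenate(rows), np.concatenate(cols))),
                          shape=(N * nx, self.n_var))
        self.A_colloc = A

        # activation-rate inequalities at mesh points (linear):
        #   a_dot - (1 - a)/t_act <= 0   and   -a_dot - a/t_deact <= 0
        sa = self.sx["a"]
        uda = self.su["da"]
        rows2, cols2, vals2 = [], [], []
        rhs_hi = []
        r2 = 0
        for mpt in range(N + 1):
            node = mpt
            for off in range(self.nm):
                ia = self.iX0 + node * nx + sa.start + off
                ida = self.iU0 + mpt * self.nu + uda.start + off
                rows2 += [r2, r2]
                cols2 += [ida, ia]
                vals2 += [1.0, 1.0 / self.config.t_act]
                rhs_hi.append(1.0 / self.config.t_act)
                r2 += 1
                rows2 += [r2, r2]
                cols2 += [ida, ia]
                vals2 += [-1.0, -1.0 / self.config.t_deact]
                rhs_hi.append(0.0)
                r2 += 1
        self.A_act = sp.csr_matrix((np.array(vals2), (np.array(rows2), np.array(cols2))),
                                   shape=(r2, self.n_var))
        self.b_act_hi = np.asarray(rhs_hi)

    # -- objective -----------------------------------------------------------
    def _prepare_objective(self):
        """Precompute targets, weights and the constant (quadratic) Hessian."""
        model, data, w, s = self.model, self.data, self.weights, self.scales
        N = self.N
        # trapezoid quadrature weights on the mesh grid
        wt = np.full(N + 1, self.h)
        wt[0] = wt[-1] = 0.5 * self.h
        self.wt = wt
        self.pv = np.array([m.pv_percent for m in model.mtus])
        self.fmax = np.array([m.f_max_iso for m in model.mtus])
        self.is_tr = np.array([c.endswith(("_tx", "_ty")) for c in model.coordinates])
        self.rot_cols = np.where(~self.is_tr)[0]
        self.tr_cols = np.where(self.is_tr)[0]
        self.mass = data.mass

        # tracked moment channels: all non-root coordinates (mass-normalised)
        self.njm_target = data.njm_exp / self.mass
        self.grf_target = data.grf_exp
        self.q_target = data.q

        # per-channel quadratic weights (used by value/grad/hess)
        self.wq = np.where(self.is_tr, w.w1 / s.s_tr ** 2, w.w2 / s.s_rot ** 2)
        self.wgrf = w.w2 / np.asarray(s.s_grf, dtype=float) ** 2
        self.wnjm = w.w3 / s.s_tau ** 2
        self.weff = w.w2 * self.pv
        self.wctl_qdd = w.w2 / self.qdd_bound ** 2
        self.wctl_da = w.w3 / self.config.da_bound ** 2
        self.wctl_dft = w.w3 / self.config.dft_bound ** 2
        self.wctl_res = w.w2 / s.s_res ** 2

        # constant part of the Hessian (everything except moment tracking)
        Hd = np.zeros(self.n_var)
        mesh_nodes = self._mesh_state_nodes
        for mpt in range(N + 1):
            xq = self.x_index(mesh_nodes[mpt], self.sx["q"])
            Hd[xq] += 2 * self.wt[mpt] * self.wq
            xa = self.x_index(mesh_nodes[mpt], self.sx["a"])
            Hd[xa] += 2 * self.wt[mpt] * self.weff
            uq = self.u_index(mpt, self.su["qdd"])
            Hd[uq] += 2 * self.wt[mpt] * self.wctl_qdd
            Hd[self.u_index(mpt, self.su["da"])] += 2 * self.wt[mpt] * self.wctl_da
            Hd[self.u_index(mpt, self.su["dft"])] += 2 * self.wt[mpt] * self.wctl_dft
            Hd[self.u_index(mpt, self.su["res"])] += 2 * self.wt[mpt] * self.wctl_res
        H = sp.diags(Hd).tolil()
        # GRF tracking couples the spheres' u_GRF components
        for mpt in range(N + 1):
            ug = self.u_index(mpt, self.su["ugrf"])
            for comp in range(2):
                idx = ug[comp::2]
                v = 2 * self.wt[mpt] * self.wgrf[comp]
                for ii in idx:
                    for jj in idx:
                        H[ii, jj] += v
        self.H_quad = H.tocsr()

    def _mesh_states(self, X: np.ndarray):
        return X[self._mesh_state_nodes]

    def muscle_geometry_at(self, q_mesh: np.ndarray, qd_mesh: np.ndarray):
        """Lengths, velocities, moment arms of every MTU at the mesh points.

        Returns (lmt (M, nm), vmt (M, nm), arms dict name->(M, n_spanned)).
        """
        M = q_mesh.shape[0]
        lmt = np.empty((M, self.nm))
        vmt = np.empty((M, self.nm))
        arms = {}
        for j, mtu in enumerate(self.model.mtus):
            poly = self.geometry[mtu.name]
            cols = [self.model.coordinate_index(c) for c in mtu.spanned_coordinates]
            Qs = q_mesh[:, cols]
            Qds = qd_mesh[:, cols]
            L = poly.length(Qs)
            R = poly.moment_arms(Qs)
            lmt[:, j] = L
            vmt[:, j] = -(R * Qds).sum(axis=1)
            arms[mtu.name] = R
        return lmt, vmt, arms

    def muscle_moments(self, q_mesh, ft_mesh):
        """Net muscle moments about each muscle-driven coordinate (M, nres)."""
        M = q_mesh.shape[0]
        out = np.zeros((M, self.nres))
        for j, mtu in enumerate(self.model.mtus):
            poly = self.geometry[mtu.name]
            cols = [self.model.coordinate_index(c) for c in mtu.spanned_coordinates]
            R = poly.moment_arms(q_mesh[:, cols])
            F = ft_mesh[:, j] * self.fmax[j]
            for cc, cname in enumerate(mtu.spanned_coordinates):
                out[:, self.muscle_joints.index(cname)] += R[:, cc] * F
        return out

    def _tracked_moments(self, q_mesh, ft_mesh, res_mesh, atau_mesh):
        """Simulated counterparts of every tracked moment channel
        (mass-normalised), ordered as data.joint_names."""
        mus = self.muscle_moments(q_mesh, ft_mesh)
        M = q_mesh.shape[0]
        out = np.zeros((M, len(self.data.joint_names)))
        for jj, name in enumerate(self.data.joint_names):
            if name in self.muscle_joints:
                out[:, jj] = (mus[:, self.muscle_joints.index(name)]
                              + res_mesh[:, self.muscle_joints.index(name)])
            else:
                for ai, act in enumerate(self.model.torque_actuators):
                    if act.coordinate == name:
                        out[:, jj] = atau_mesh[:, ai] * act.tau_max
        return out / self.mass

    def objective_terms(self, xvec: np.ndarray) -> dict:
        """Cost decomposition J = J_effort + J_tracking + J_control."""
        X, U, P = self.unpack(xvec)
        Xm = self._mesh_states(X)
        q = Xm[:, self.sx["q"]]
        a = Xm[:, self.sx["a"]]
        ft = Xm[:, self.sx["ft"]]
        atau = Xm[:, self.sx["atau"]]
        res = U[:, self.su["res"]]
        ugrf = U[:, self.su["ugrf"]]
        grf_tot = ugrf[:, 0::2].sum(1), ugrf[:, 1::2].sum(1)

        j_eff = float(self.wt @ ((a * a) @ self.weff))
        dq = q - self.q_target
        j_tr = float(self.wt @ ((dq * dq) @ self.wq))
        for comp in range(2):
            e = grf_tot[comp] - self.grf_target[:, comp]
            j_tr += float(self.wgrf[comp] * (self.wt @ (e * e)))
        mom = self._tracked_moments(q, ft, res, atau)
        e = mom - self.njm_target
        j_tr += float(self.wnjm * (self.wt @ (e * e).sum(1)))

        qdd = U[:, self.su["qdd"]]
        da = U[:, self.su["da"]]
        dft = U[:, self.su["dft"]]
        j_ctl = float(self.wt @ ((qdd * qdd) @ self.wctl_qdd))
        j_ctl += float(self.wctl_da * (self.wt @ (da * da).sum(1)))
        j_ctl += float(self.wctl_dft * (self.wt @ (dft * dft).sum(1)))
        j_ctl += float(self.wctl_res * (self.wt @ (res * res).sum(1)))
        return {"effort": j_eff, "tracking": j_tr, "control": j_ctl,
                "total": j_eff + j_tr + j_ctl}

    # objective value / gradient / Gauss-Newton Hessian in z-space ----------
    def obj(self, z: np.ndarray) -> float:
        return self.objective_terms(self.unscale(z))["total"]

    def _moment_residual_and_jac(self, xvec: np.ndarray, need_jac: bool):
        X, U, P = self.unpack(xvec)
        Xm = self._mesh_states(X)
        q = Xm[:, self.sx["q"]]
        ft = Xm[:, self.sx["ft"]]
        atau = Xm[:, self.sx["atau"]]
        res = U[:, self.su["res"]]
        mom = self._tracked_moments(q, ft, res, atau)
        resid = mom - self.njm_target  # (M, nj)
        if not need_jac:
            return resid, None
        M, nj = resid.shape
        # dependencies per mesh point: q (nq) via FD, ft / res / atau analytic
        eps = 1e-6
        dq_jac = np.empty((M, nj, self.nq))
        for c in range(self.nq):
            qp = q.copy()
            qp[:, c] += eps
            mp = self._tracked_moments(qp, ft, res, atau)
            dq_jac[:, :, c] = (mp - mom) / eps
        # analytic parts
        dft_jac = np.zeros((M, nj, self.nm))
        mus_j = {name: jj for jj, name in enumerate(self.data.joint_names)}
        for j, mtu in enumerate(self.model.mtus):
            poly = self.geometry[mtu.name]
            cols = [self.model.coordinate_index(c) for c in mtu.spanned_coordinates]
            R = poly.moment_arms(q[:, cols])
            for cc, cname in enumerate(mtu.spanned_coordinates):
                dft_jac[:, mus_j[cname], j] += R[:, cc] * self.fmax[j] / self.mass
        return resid, (dq_jac, dft_jac)

    def grad(self, z: np.ndarray) -> np.ndarray:
        xvec = self.unscale(z)
        g = np.zeros(self.n_var)
        X, U, P = self.unpack(xvec)
        Xm = self._mesh_states(X)
        q = Xm[:, self.sx["q"]]
        a = Xm[:, self.sx["a"]]
        ugrf = U[:, self.su["ugrf"]]

        mesh_nodes = self._mesh_state_nodes
        wt = self.wt
        for mpt in range(self.N + 1):
            g[self.x_index(mesh_nodes[mpt], self.sx["q"])] += (
                2 * wt[mpt] * self.wq * (q[mpt] - self.q_target[mpt]))
            g[self.x_index(mesh_nodes[mpt], self.sx["a"])] += (
                2 * wt[mpt] * self.weff * a[mpt])
        # GRF tracking
        for comp in range(2):
            e = ugrf[:, comp::2].sum(1) - self.grf_target[:, comp]
            for mpt in range(self.N + 1):
                g[self.u_index(mpt, self.su["ugrf"])[comp::2]] += (
                    2 * wt[mpt] * self.wgrf[comp] * e[mpt])
        # control terms
        for mpt in range(self.N + 1):
            g[self.u_index(mpt, self.su["qdd"])] += (
                2 * wt[mpt] * self.wctl_qdd * U[mpt, self.su["qdd"]])
            g[self.u_index(mpt, self.su["da"])] += (
                2 * wt[mpt] * self.wctl_da * U[mpt, self.su["da"]])
            g[self.u_index(mpt, self.su["dft"])] += (
                2 * wt[mpt] * self.wctl_dft * U[mpt, self.su["dft"]])
            g[self.u_index(mpt, self.su["res"])] += (
                2 * wt[mpt] * self.wctl_res * U[mpt, self.su["res"]])
        # moment tracking (FD over q, analytic over ft/res/atau)
        resid, (dq_jac, dft_jac) = self._moment_residual_and_jac(xvec, True)
        coeff = 2 * self.wnjm * wt[:, None]  # (M, 1)
        cr = coeff * resid
        for mpt in range(self.N + 1):
            node = mesh_nodes[mpt]
            g[self.x_index(node, self.sx["q"])] += cr[mpt] @ dq_jac[mpt]
            g[self.x_index(node, self.sx["ft"])] += cr[mpt] @ dft_jac[mpt]
            for jj, name in enumerate(self.data.joint_names):
                if name in self.muscle_joints:
                    g[self.u_index(mpt, self.su["res"])[self.muscle_joints.index(name)]] += (
                        cr[mpt, jj] / self.mass)
                else:
                    for ai, act in enumerate(self.model.torque_actuators):
                        if act.coordinate == name:
                            g[self.x_index(node, self.sx["atau"])[ai]] += (
                                cr[mpt, jj] * act.tau_max / self.mass)
        return g * self.v_half

    def hess(self, z: np.ndarray) -> sp.csr_matrix:
        """Gauss-Newton Hessian: exact for the quadratic terms, J^T W J for
        the (mildly nonlinear) moment-tracking term."""
        xvec = self.unscale(z)
        resid, (dq_jac, dft_jac) = self._moment_residual_and_jac(xvec, True)
        rows, cols, vals = [], [], []
        mesh_nodes = self._mesh_state_nodes
        for mpt in range(self.N + 1):
            node = mesh_nodes[mpt]
            idx = np.concatenate([
                self.x_index(node, self.sx["q"]),
                self.x_index(node, self.sx["ft"]),
                self.x_index(node, self.sx["atau"]),
                self.u_index(mpt, self.su["res"]),
            ])
            nj = resid.shape[1]
            J = np.zeros((nj, len(idx)))
            J[:, :self.nq] = dq_jac[mpt]
            J[:, self.nq:self.nq + self.nm] = dft_jac[mpt]
            col = self.nq + self.nm
            for jj, name in enumerate(self.data.joint_names):
                if name in self.muscle_joints:
                    J[jj, col + self.nta + self.muscle_joints.index(name)] = 1.0 / self.mass
                else:
                    for ai, act in enumerate(self.model.torque_actuators):
                        if act.coordinate == name:
                            J[jj, col + ai] = act.tau_max / self.mass
            Hloc = 2 * self.wnjm * self.wt[mpt] * (J.T @ J)
            ii, jj2 = np.meshgrid(idx, idx, indexing="ij")
            rows.append(ii.ravel())
            cols.append(jj2.ravel())
            vals.append(Hloc.ravel())
        H_mom = sp.csr_matrix((np.concatenate(vals),
                               (np.concatenate(rows), np.concatenate(cols))),
                              shape=(self.n_var, self.n_var))
        Hx = self.H_quad + H_mom
        S = sp.diags(self.v_half)
        return (S @ Hx @ S).tocsr()

    # -- nonlinear path constraints ------------------------------------------
    def _prepare_nonlinear(self):
        """Row layout, row scales and FD sparsity of the nonlinear path
        constraints (per mesh point: Hill (nm), muscle-moment/ID (nres),
        torque/ID (nta), pelvis residuals (3), u_GRF/contact (2 n_sph))."""
        self.ncon_node = self.nm + self.nres + self.nta + 3 + 2 * self.nsph
        self.n_nonlin = (self.N + 1) * self.ncon_node
        # row scales grow with the condition's load level so the merit
        # function treats light and heavy hopping conditions alike
        peak_f = max(200.0, float(np.abs(self.data.grf_exp).max()))
        peak_m = max(50.0, float(np.abs(self.data.njm_exp).max()))
        scale = np.empty(self.ncon_node)
        o = 0
        scale[o:o + self.nm] = 1.0  # Hill residual (dimensionless)
        o += self.nm
        scale[o:o + self.nres] = peak_m  # N m
        o += self.nres
        scale[o:o + self.nta] = peak_m
        o += self.nta
        scale[o:o + 2] = peak_f  # pelvis residual force (N)
        scale[o + 2] = peak_m  # pelvis residual moment (N m)
        o += 3
        # contact rows are divided by the stiffness at evaluation time;
        # the static scale converts the remainder (units m^{3/2}) to order
        # one at centimetre-scale penetrations
        scale[o:] = 0.01 ** 1.5
        self.con_scale = scale

        S = sp.lil_matrix((self.n_nonlin, self.n_var), dtype=bool)
        for mpt in range(self.N + 1):
            r0 = mpt * self.ncon_node
            node = self._mesh_state_nodes[mpt]
            xcols = self.iX0 + node * self.nx + np.arange(self.nx)
            ucols = self.iU0 + mpt * self.nu + np.arange(self.nu)
            S[r0:r0 + self.ncon_node, xcols] = True
            S[r0:r0 + self.ncon_node, ucols] = True
            S[r0:r0 + self.ncon_node, self.iP0:] = True
        self.con_sparsity = S.tocsr()

    def constraints_fun(self, z: np.ndarray) -> np.ndarray:
        xvec = self.unscale(z)
        X, U, P = self.unpack(xvec)
        Xm = self._mesh_states(X)
        q = Xm[:, self.sx["q"]]
        qd = Xm[:, self.sx["qd"]]
        a = Xm[:, self.sx["a"]]
        ft = Xm[:, self.sx["ft"]]
        atau = Xm[:, self.sx["atau"]]
        qdd = U[:, self.su["qdd"]]
        dft = U[:, self.su["dft"]]
        ugrf = U[:, self.su["ugrf"]]
        res = U[:, self.su["res"]]
        stiff, damp = P[0], P[1]
        M = self.N + 1
        model = self.model

        out = np.empty((M, self.ncon_node))
        o = 0
        # Hill equilibrium
        lmt, vmt, _ = self.muscle_geometry_at(q, qd)
        for j, mtu in enumerate(model.mtus):
            out[:, o + j] = hill_equilibrium_residual(
                a[:, j], lmt[:, j], vmt[:, j], ft[:, j], dft[:, j], mtu,
                model.curves, _guard=False)
        o += self.nm

        # inverse dynamics with u_GRF at the (optimised) sphere positions
        kin = ChainKinematics(model, q, qd, qdd)
        ext = []
        for si in range(self.nsph):
            local = P[2 + 2 * si:4 + 2 * si]
            ext.append(("foot", local, ugrf[:, 2 * si:2 * si + 2]))
        bw = np.zeros((M, 2))
        bw[:, 1] = self.data.bwss
        pelvis = model.segments[0]
        ext.append((pelvis.name, np.asarray(pelvis.com_offset), bw))
        tau_id = inverse_dynamics(q, qd, qdd, ext, model, kin=kin)

        mus = self.muscle_moments(q, ft)
        for jj, cname in enumerate(self.muscle_joints):
            k = model.coordinate_index(cname)
            out[:, o + jj] = mus[:, jj] + res[:, jj] - tau_id[:, k]
        o += self.nres
        for ai, act in enumerate(model.torque_actuators):
            k = model.coordinate_index(act.coordinate)
            out[:, o + ai] = atau[:, ai] * act.tau_max - tau_id[:, k]
        o += self.nta
        out[:, o:o + 3] = tau_id[:, :3]
        o += 3
        # u_GRF vs contact model, in penetration-equivalent units: dividing
        # by the stiffness keeps the scaled violation independent of k, so
        # the merit function cannot shrink violations by softening the
        # contact instead of fitting it
        for si, sphere in enumerate(model.contact_spheres):
            local = P[2 + 2 * si:4 + 2 * si]
            pos, vel, _ = kin.point("foot", np.broadcast_to(local, (M, 2)))
            pen = sphere.radius - pos[:, 1]
            pen_vel = -vel[:, 1]
            fn = contact_normal_force(pen, pen_vel, stiff, damp)
            fx = -model.friction_coefficient * fn * np.tanh(
                vel[:, 0] / model.friction_velocity_scale)
            out[:, o + 2 * si] = (ugrf[:, 2 * si] - fx) / stiff
            out[:, o + 2 * si + 1] = (ugrf[:, 2 * si + 1] - fn) / stiff
        out = np.nan_to_num(out, nan=1e3, posinf=1e3, neginf=-1e3)
        return (out / self.con_scale).ravel()

    # -- assembled scipy problem ---------------------------------------------
    def scipy_constraints(self):
        S = sp.diags(1.0 / self.v_half)  # z = S (x - centre)
        Az = (self.A_colloc @ sp.diags(self.v_half)).tocsr()
        bz = -self.A_colloc @ self.v_centre
        lin_eq = LinearConstraint(Az, bz, bz)
        Az2 = (self.A_act @ sp.diags(self.v_half)).tocsr()
        shift = self.A_act @ self.v_centre
        lin_ineq = LinearConstraint(Az2, -np.inf, self.b_act_hi - shift)
        nl = NonlinearConstraint(
            self.constraints_fun, 0.0, 0.0, jac="2-point",
            finite_diff_jac_sparsity=self.con_sparsity,
            hess=lambda z, v: sp.csr_matrix((self.n_var, self.n_var)))
        return [lin_eq, lin_ineq, nl]


# ---------------------------------------------------------------------------
# Initial guesses and solve
# ---------------------------------------------------------------------------

INITIAL_STIFFNESS_GUESS = 1e6  # N m^-3/2
INITIAL_DAMPING_GUESS = 2.0  # s m^-1


def _static_muscle_warm(nlp: TrackingNLP, ugrf: np.ndarray | None = None):
    """Static-optimisation seed for the muscle variables of the
    data-informed guess: per mesh point, distribute the inverse-dynamics
    joint moments over the muscles by minimising the volume-weighted sum of
    squared activations (fibre velocity neglected), then recover consistent
    tendon forces.  Keeps the warm start near-feasible in the Hill and
    moment-consistency constraints."""
    model, data = nlp.model, nlp.data
    M = nlp.N + 1
    curves = model.curves

    # inverse-dynamics moments as the NLP will see them at the warm start
    kin = ChainKinematics(model, data.q, data.qd, data.qdd)
    ext = []
    for si, sphere in enumerate(model.contact_spheres):
        f = (data.grf_exp / nlp.nsph if ugrf is None
             else ugrf[:, 2 * si:2 * si + 2])
        ext.append(("foot", np.asarray(sphere.position), f))
    bw = np.zeros((M, 2))
    bw[:, 1] = data.bwss
    pelvis = model.segments[0]
    ext.append((pelvis.name, np.asarray(pelvis.com_offset), bw))
    tau_id = inverse_dynamics(data.q, data.qd, data.qdd, ext, model, kin=kin)

    lmt, vmt, _ = nlp.muscle_geometry_at(data.q, data.qd)
    arms = np.zeros((M, nlp.nm, nlp.nres))  # moment arm of muscle j about joint k
    for j, mtu in enumerate(model.mtus):
        poly = nlp.geometry[mtu.name]
        cols = [model.coordinate_index(c) for c in mtu.spanned_coordinates]
        R = poly.moment_arms(data.q[:, cols])
        for cc, cname in enumerate(mtu.spanned_coordinates):
            arms[:, j, nlp.muscle_joints.index(cname)] = R[:, cc]
    tau_req = np.stack([tau_id[:, model.coordinate_index(c)]
                        for c in nlp.muscle_joints], axis=1)

    fmax = nlp.fmax
    lopt = np.array([mtu.l_opt for mtu in model.mtus])
    lslack = np.array([mtu.l_slack for mtu in model.mtus])
    height = lopt * np.sin([mtu.pennation_opt for mtu in model.mtus])
    W_inv = 1.0 / (2.0 * nlp.pv)

    ft = np.full((M, nlp.nm), 0.05)
    a = np.full((M, nlp.nm), 0.05)
    for _ in range(6):
        strain = curves.tendon_strain_from_force(ft)
        l_along = np.clip(lmt - lslack * (1.0 + strain), 0.05 * lopt, None)
        l_fib = np.sqrt(l_along ** 2 + height ** 2)
        cosa = l_along / l_fib
        f_act = curves.active_fl(l_fib / lopt)
        f_pas = curves.passive_fl(l_fib / lopt)
        gain = cosa * f_act * fmax  # dF/da
        passive_mom = np.einsum("mj,mjk->mk", cosa * f_pas * fmax, arms)
        b = tau_req - passive_mom
        lo_a, hi_a = 0.01, 0.95
        for t in range(M):
            A = (arms[t] * gain[t][:, None]).T  # (nres, nm)
            at = np.full(nlp.nm, lo_a)
            free = np.ones(nlp.nm, dtype=bool)
            for _ in range(6):  # active-set iteration on the box bounds
                bf = b[t] - A[:, ~free] @ at[~free]
                Af = A[:, free]
                AWA = Af * W_inv[free] @ Af.T + 1e-9 * np.eye(nlp.nres)
                lam = np.linalg.solve(AWA, bf)
                cand = W_inv[free] * (Af.T @ lam)
                viol = (cand < lo_a) | (cand > hi_a)
                at[free] = np.clip(cand, lo_a, hi_a)
                if not viol.any():
                    break
                idx = np.where(free)[0][viol]
                free[idx] = False
                if free.sum() < nlp.nres:
                    break
            a[t] = at
        ft = np.clip(cosa * (a * f_act + f_pas), 1e-3, 0.9 * nlp.config.ft_bound)
    # light temporal smoothing: the per-node static solves are independent
    # and their active-set switches would otherwise seed jumpy rate controls
    kernel = np.array([0.25, 0.5, 0.25])
    for arr in (a, ft):
        padded = np.vstack([arr[:1], arr, arr[-1:]])
        arr[:] = (kernel[0] * padded[:-2] + kernel[1] * padded[1:-1]
                  + kernel[2] * padded[2:])
    np.clip(a, 0.01, 0.95, out=a)
    np.clip(ft, 1e-3, 0.9 * nlp.config.ft_bound, out=ft)
    mus = nlp.muscle_moments(data.q, ft)
    res = np.clip(tau_req - mus, -0.9 * nlp.config.tau_res_bound,
                  0.9 * nlp.config.tau_res_bound)
    atau = np.zeros((M, nlp.nta))
    for ai, act in enumerate(model.torque_actuators):
        atau[:, ai] = np.clip(tau_id[:, model.coordinate_index(act.coordinate)]
                              / act.tau_max, -0.95, 0.95)
    return a, ft, res, atau


def make_initial_guesses(nlp: TrackingNLP):
    """The two initial guesses: data-informed and cold.

    Guess 1 copies the experimental kinematics (q, q_dot, q_ddot) and GRFs
    (split equally over the spheres); guess 2 sets every variable to zero.
    In both, variables whose bounds exclude zero sit at their lower bound,
    and the contact parameters take the stated stiffness/damping starting
    values with the spheres at their anatomical positions.
    """
    data, model = nlp.data, nlp.model

    def base_vector():
        x = np.zeros(nlp.n_var)
        lb, ub = nlp.lb, nlp.ub
        one_sided = lb > 0
        x[one_sided] = lb[one_sided]
        neg = ub < 0
        x[neg] = ub[neg]
        return x

    def set_params(x):
        i0 = nlp.iP0
        x[i0] = min(max(INITIAL_STIFFNESS_GUESS, nlp.lb[i0]), nlp.ub[i0])
        x[i0 + 1] = min(max(INITIAL_DAMPING_GUESS, nlp.lb[i0 + 1]), nlp.ub[i0 + 1])
        for si, sphere in enumerate(model.contact_spheres):
            x[i0 + 2 + 2 * si] = sphere.position[0]
            x[i0 + 3 + 2 * si] = sphere.position[1]

    # guess 2: cold
    cold = base_vector()
    set_params(cold)

    # guess 1: data-informed
    warm = base_vector()
    Xn = np.zeros((nlp.n_state_nodes, nlp.nx))
    # interpolate experimental kinematics onto the collocation node times
    for k in range(nlp.nq):
        Xn[:, nlp.sx["q"].start + k] = np.interp(nlp.node_time, data.time, data.q[:, k])
        Xn[:, nlp.sx["qd"].start + k] = np.interp(nlp.node_time, data.time, data.qd[:, k])
    Xb = base_vector()[nlp.iX0:nlp.iU0].reshape(nlp.n_state_nodes, nlp.nx)
    Xn[:, nlp.sx["a"]] = Xb[:, nlp.sx["a"]]
    Xn[:, nlp.sx["ft"]] = Xb[:, nlp.sx["ft"]]
    Xn[:, nlp.sx["atau"]] = Xb[:, nlp.sx["atau"]]
    warm[nlp.iX0:nlp.iU0] = Xn.ravel()
    U = warm[nlp.iU0:nlp.iP0].reshape(nlp.N + 1, nlp.nu)
    U[:, nlp.su["qdd"]] = data.qdd
    g = nlp.su["ugrf"]
    # u_GRF guess: the measured GRF, split between the spheres according to
    # the contact model's relative load share along the experimental motion.
    # Totals then match both the tracking targets and the inverse-dynamics
    # moments, and the only violated rows are the per-sphere contact
    # consistencies, which the stiffness parameter repairs.
    kin = ChainKinematics(model, data.q, data.qd)
    fn_model = np.empty((nlp.N + 1, nlp.nsph))
    for si, sphere in enumerate(model.contact_spheres):
        pos, vel, _ = kin.point("foot", np.asarray(sphere.position))
        pen = sphere.radius - pos[:, 1]
        fn_model[:, si] = contact_normal_force(pen, -vel[:, 1],
                                               INITIAL_STIFFNESS_GUESS,
                                               INITIAL_DAMPING_GUESS)
    share = fn_model / np.maximum(fn_model.sum(axis=1, keepdims=True), 1e-9)
    for si in range(nlp.nsph):
        U[:, g.start + 2 * si] = data.grf_exp[:, 0] * share[:, si]
        U[:, g.start + 2 * si + 1] = data.grf_exp[:, 1] * share[:, si]
    if nlp.config.muscle_informed_guess:
        a_w, ft_w, res_w, atau_w = _static_muscle_warm(nlp, U[:, nlp.su["ugrf"]])
        Xn2 = warm[nlp.iX0:nlp.iU0].reshape(nlp.n_state_nodes, nlp.nx)
        for j in range(nlp.nm):
            Xn2[:, nlp.sx["a"].start + j] = np.interp(
                nlp.node_time, data.time, a_w[:, j])
            Xn2[:, nlp.sx["ft"].start + j] = np.interp(
                nlp.node_time, data.time, ft_w[:, j])
        for ai in range(nlp.nta):
            Xn2[:, nlp.sx["atau"].start + ai] = np.interp(
                nlp.node_time, data.time, atau_w[:, ai])
        warm[nlp.iX0:nlp.iU0] = Xn2.ravel()
        U[:, nlp.su["res"]] = res_w
        dt = float(data.time[1] - data.time[0])
        da = np.gradient(a_w, dt, axis=0)
        da = np.minimum(da, (1.0 - a_w) / nlp.config.t_act)
        da = np.maximum(da, -a_w / nlp.config.t_deact)
        U[:, nlp.su["da"]] = np.clip(da, -0.9 * nlp.config.da_bound,
                                     0.9 * nlp.config.da_bound)
        U[:, nlp.su["dft"]] = np.clip(np.gradient(ft_w, dt, axis=0),
                                      -0.9 * nlp.config.dft_bound,
                                      0.9 * nlp.config.dft_bound)
        delay = (model.torque_actuators[0].delay if nlp.nta else 0.035)
        etau = atau_w + delay * np.gradient(atau_w, dt, axis=0)
        U[:, nlp.su["etau"]] = np.clip(etau, -0.95, 0.95)
    warm[nlp.iU0:nlp.iP0] = U.ravel()
    set_params(warm)
    # keep strictly inside the box for the interior-point method
    margin = 0.02
    for x in (warm, cold):
        np.clip(x, nlp.lb + margin * nlp.v_half, nlp.ub - margin * nlp.v_half, out=x)
    return warm, cold


@dataclass
class OCPSolution:
    """A converged (or attempted) tracking solution."""

    model: ModelSpec
    data: TrackingData
    time: np.ndarray          # mesh grid
    states: dict              # q, qd, a, ft, atau at mesh points
    controls: dict            # qdd, da, dft, ugrf, etau, res at mesh points
    parameters: dict          # stiffness, damping, sphere positions
    cost_terms: dict          # effort / tracking / control / total
    converged: bool
    status: int
    message: str
    n_iterations: int
    constr_violation: float
    winning_guess: str        # "data-informed" | "cold"
    guess_report: list        # per-guess (name, converged, cost, status)
    xvec: np.ndarray          # full unscaled decision vector
    solve_time: float

    @property
    def muscle_forces(self) -> np.ndarray:
        """Tendon forces (N) per MTU at the mesh points."""
        fmax = np.array([m.f_max_iso for m in self.model.mtus])
        return self.states["ft"] * fmax

    @property
    def grf_total(self) -> np.ndarray:
        u = self.controls["ugrf"]
        return np.stack([u[:, 0::2].sum(1), u[:, 1::2].sum(1)], axis=1)


def _extract_solution(nlp: TrackingNLP, res, winner, reports, t0) -> OCPSolution:
    xvec = nlp.unscale(res.x)
    X, U, P = nlp.unpack(xvec)
    Xm = X[nlp._mesh_state_nodes]
    states = {k: Xm[:, nlp.sx[k]] for k in nlp.sx}
    controls = {k: U[:, nlp.su[k]] for k in nlp.su}
    params = {
        "stiffness": float(P[0]), "damping": float(P[1]),
        "sphere_positions": P[2:].reshape(nlp.nsph, 2).copy(),
    }
    terms = nlp.objective_terms(xvec)
    converged = res.status in (1, 2, 3, 5) and res.constr_violation < 5e-3
    return OCPSolution(
        model=nlp.model, data=nlp.data, time=nlp.mesh_time,
        states=states, controls=controls, parameters=params,
        cost_terms=terms, converged=converged, status=res.status,
        message=res.message, n_iterations=res.niter,
        constr_violation=float(res.constr_violation),
        winning_guess=winner, guess_report=reports, xvec=xvec,
        solve_time=time.time() - t0)


def solve_tracking(nlp: TrackingNLP, guesses=None, single_guess: bool = False) -> OCPSolution:
    """Solve the NLP from both initial guesses and keep the lower-cost
    converged solution (ties favour the data-informed guess)."""
    t0 = time.time()
    if guesses is None:
        guesses = make_initial_guesses(nlp)
    names = ["data-informed", "cold"]
    if single_guess:
        guesses, names = guesses[:1], names[:1]
    constraints = nlp.scipy_constraints()
    bounds = Bounds(-1.0, 1.0, keep_feasible=False)
    results, reports = [], []
    for name, guess in zip(names, guesses):
        z0 = nlp.scale(guess)
        warm_start = name == "data-informed"
        maxit = (nlp.config.max_iterations if warm_start
                 else nlp.config.max_iterations_cold)
        if nlp.config.solver == "sqp":
            res = sqp_solve(nlp, z0, max_iter=maxit,
                            feas_tol=nlp.config.solver_feas_tol,
                            verbose=nlp.config.verbose)
            ok = res.status in (1, 2, 3, 5) and res.constr_violation < 5e-3
            results.append((name, res, ok))
            reports.append({"guess": name, "converged": bool(ok),
                            "cost": float(res.fun), "status": int(res.status),
                            "iterations": int(res.niter)})
            continue
        res = minimize(
            nlp.obj, z0, jac=nlp.grad, hess=nlp.hess, method="trust-constr",
            bounds=bounds, constraints=constraints,
            options={"gtol": nlp.config.solver_opt_tol,
                     "xtol": 1e-10,
                     "maxiter": maxit,
                     "initial_tr_radius": 1.0,
                     "initial_barrier_parameter": (
                         nlp.config.initial_barrier_warm if warm_start
                         else nlp.config.initial_barrier_cold),
                     "sparse_jacobian": True,
                     "verbose": nlp.config.verbose})
        ok = res.status in (1, 2, 3, 5) and res.constr_violation < 5e-3
        results.append((name, res, ok))
        reports.append({"guess": name, "converged": bool(ok),
                        "cost": float(res.fun), "status": int(res.status),
                        "iterations": int(res.niter)})
    ok_results = [(n, r) for n, r, ok in results if ok]
    if not ok_results:
        # fall back to the best feasible attempt (reported as unconverged)
        feasible = [(n, r) for n, r, _ in results if r.constr_violation < 5e-3]
        if feasible:
            winner, best = min(feasible, key=lambda nr: nr[1].fun)
            return _extract_solution(nlp, best, winner, reports, t0)
        diag = "; ".join(f"{n}: status={r.status} viol={r.constr_violation:.2e}"
                         for n, r, _ in results)
        raise RuntimeError(f"tracking NLP failed from every initial guess ({diag})")
    winner, best = min(ok_results, key=lambda nr: (nr[1].fun, names.index(nr[0])))
    return _extract_solution(nlp, best, winner, reports, t0)


def track_trial(model: ModelSpec, data: TrackingData,
                config: OCPConfig | None = None,
                weights: CostWeights | None = None,
                scales: ScaleFactors | None = None,
                geometry: GeometrySet | None = None,
                **nlp_kwargs) -> OCPSolution:
    """Convenience wrapper: transcribe and solve one preprocessed trial."""
    config = config or OCPConfig()
    weights = weights or CostWeights()
    scales = scales or derive_scale_factors()
    nlp = TrackingNLP(model, data, config, weights, scales, geometry=geometry,
                      **nlp_kwargs)
    return solve_tracking(nlp)


def transcribe(model: ModelSpec, data: TrackingData, config: OCPConfig,
               weights: CostWeights, scales: ScaleFactors,
               geometry: GeometrySet | None = None, **kwargs) -> TrackingNLP:
    """Build the NLP for one trial (alias constructor)."""
    return TrackingNLP(model, data, config, weights, scales, geometry=geometry,
                       **kwargs)


# ---------------------------------------------------------------------------
# Gauss-Newton SQP (the default solver)
# ---------------------------------------------------------------------------


class _SQPResult:
    def __init__(self, x, fun, status, niter, constr_violation, message):
        self.x = x
        self.fun = fun
        self.status = status
        self.niter = niter
        self.constr_violation = constr_violation
        self.message = message


def _grouped_jacobian(nlp: TrackingNLP, z: np.ndarray, c0: np.ndarray):
    from scipy.optimize._numdiff import approx_derivative, group_columns
    if not hasattr(nlp, "_fd_groups"):
        nlp._fd_groups = group_columns(nlp.con_sparsity)
    J = approx_derivative(nlp.constraints_fun, z, method="2-point", f0=c0,
                          sparsity=(nlp.con_sparsity, nlp._fd_groups))
    return sp.csr_matrix(J)


def sqp_solve(nlp: TrackingNLP, z0: np.ndarray, max_iter: int = 200,
              feas_tol: float = 1e-6, step_tol: float = 1e-7,
              verbose: int = 0) -> _SQPResult:
    """Equality-driven sequential Gauss-Newton solver.

    Each iteration linearises the path constraints, forms the Gauss-Newton
    Hessian of the tracking objective, and solves one sparse KKT system for
    the step; a backtracking line search on an l1 merit function and an
    infinity-norm step cap provide globalisation.  The activation-rate
    inequalities are handled by an active set; box bounds by projection.
    Built for the warm, near-feasible starts this tracking problem provides
    (the interior-point alternative wanders far from the data before
    converging).
    """
    from scipy.sparse.linalg import splu
    cfg = nlp.config
    rho = cfg.sqp_merit_penalty
    cap = cfg.sqp_step_cap
    z = np.clip(z0.copy(), -1.0, 1.0)
    A_eq = (nlp.A_colloc @ sp.diags(nlp.v_half)).tocsr()
    b_eq = -nlp.A_colloc @ nlp.v_centre
    A_act = (nlp.A_act @ sp.diags(nlp.v_half)).tocsr()
    b_act = nlp.b_act_hi - nlp.A_act @ nlp.v_centre
    # scale the collocation rows to O(1)
    row_norm = np.sqrt(np.asarray(A_eq.multiply(A_eq).sum(axis=1)).ravel()) + 1e-12
    Rs = sp.diags(1.0 / row_norm)
    A_eq = (Rs @ A_eq).tocsr()
    b_eq = b_eq / row_norm

    lam = 1e-6
    f = nlp.obj(z)
    c = nlp.constraints_fun(z)
    r_eq = A_eq @ z - b_eq
    act_viol = np.maximum(A_act @ z - b_act, 0.0)

    def merit(fv, cv, rv, av):
        return fv + rho * (np.abs(cv).sum() + np.abs(rv).sum() + av.sum())

    phi = merit(f, c, r_eq, act_viol)
    n = nlp.n_var
    status, msg = 0, "max iterations"
    f_hist = []
    phi_hist = []
    bound_fix_prev = np.zeros(nlp.n_var, dtype=bool)
    failure_streak = 0
    it = 0
    for it in range(1, max_iter + 1):
        J = _grouped_jacobian(nlp, z, c)
        g = nlp.grad(z)
        H = nlp.hess(z)
        if nlp.npar:
            # damp the static-parameter directions: they couple every mesh
            # point and large early swings drive the contact identification
            # into degenerate corners
            reg = np.zeros(n)
            reg[nlp.iP0:] = cfg.sqp_param_reg
            H = H + sp.diags(reg)
        feas = max(np.abs(c).max(), np.abs(r_eq).max(), act_viol.max())

        # active-set rows of the rate inequalities
        act_idx = np.where(A_act @ z - b_act > -1e-8)[0]
        blocks = [A_eq, J]
        rhs_c = [-r_eq, -c]
        if len(act_idx):
            blocks.append(A_act[act_idx])
            rhs_c.append(-(A_act[act_idx] @ z - b_act[act_idx]))
        A_base = sp.vstack(blocks).tocsc()
        r_base = np.concatenate(rhs_c)

        # warm-start the bound active set from the previous iteration,
        # dropping entries that have left their bound
        bound_fix = bound_fix_prev & (((z <= -1 + 1e-9)) | (z >= 1 - 1e-9))
        for _ in range(8):  # Levenberg loop (with bound active-set rounds)
            d = None
            n_bound_rows = 0
            for _round in range(2):
                if bound_fix.any():
                    idx = np.where(bound_fix)[0]
                    E = sp.csr_matrix((np.ones(len(idx)),
                                       (np.arange(len(idx)), idx)), shape=(len(idx), n))
                    A_all = sp.vstack([A_base, E]).tocsc()
                    r_all = np.concatenate([r_base, np.zeros(len(idx))])
                    n_bound_rows = len(idx)
                else:
                    A_all, r_all = A_base, r_base
                    n_bound_rows = 0
                m = A_all.shape[0]
                K = sp.bmat([[H + lam * sp.eye(n), A_all.T],
                             [A_all, -1e-10 * sp.eye(m)]], format="csc")
                try:
                    lu = splu(K, permc_spec="MMD_ATA")
                except RuntimeError:
                    d = None
                    break
                sol = lu.solve(np.concatenate([-g, r_all]))
                d = sol[:n]
                if not np.isfinite(d).all():
                    d = None
                    break
                # freeze variables whose step exits the box at an active bound
                new_fix = (((z <= -1 + 1e-9) & (d < 0))
                           | ((z >= 1 - 1e-9) & (d > 0))) & ~bound_fix
                if not new_fix.any():
                    break
                bound_fix |= new_fix
            if d is None:
                lam = max(lam * 10, 1e-5)
                continue
            step_inf = np.abs(d).max()
            if step_inf > cap:
                d *= cap / step_inf
            # backtracking on the merit function with box projection; a
            # second-order correction cures rejections caused by constraint
            # curvature, and a short nonmonotone (watchdog) reference avoids
            # creeping along the contact manifold
            accepted = False
            alpha = 1.0
            phi_ref = max([phi] + phi_hist[-3:])
            soc_budget = 2
            for _ in range(9):
                z_new = np.clip(z + alpha * d, -1.0, 1.0)
                f_new = nlp.obj(z_new)
                c_new = nlp.constraints_fun(z_new)
                r_new = A_eq @ z_new - b_eq
                a_new = np.maximum(A_act @ z_new - b_act, 0.0)
                phi_new = merit(f_new, c_new, r_new, a_new)
                ref = phi_ref if alpha == 1.0 else phi
                if phi_new < ref - 1e-12 * abs(ref):
                    accepted = True
                    break
                if soc_budget > 0:
                    soc_budget -= 1
                    viol_new = [r_new, c_new]
                    if len(act_idx):
                        viol_new.append(A_act[act_idx] @ z_new - b_act[act_idx])
                    if n_bound_rows:
                        viol_new.append(np.zeros(n_bound_rows))
                    soc = lu.solve(np.concatenate(
                        [np.zeros(n), -np.concatenate(viol_new)]))[:n]
                    if np.isfinite(soc).all() and np.abs(soc).max() <= cap:
                        z_soc = np.clip(z_new + alpha * soc, -1.0, 1.0)
                        f_soc = nlp.obj(z_soc)
                        c_soc = nlp.constraints_fun(z_soc)
                        r_soc = A_eq @ z_soc - b_eq
                        a_soc = np.maximum(A_act @ z_soc - b_act, 0.0)
                        phi_soc = merit(f_soc, c_soc, r_soc, a_soc)
                        if phi_soc < ref - 1e-12 * abs(ref):
                            z_new, f_new, c_new = z_soc, f_soc, c_soc
                            r_new, a_new, phi_new = r_soc, a_soc, phi_soc
                            accepted = True
                            break
                alpha *= 0.5
            if accepted:
                break
            lam = max(lam * 10, 1e-5)
        if not accepted:
            feas = max(np.abs(c).max(), np.abs(r_eq).max(), act_viol.max())
            if feas < 5e-3:
                # feasible and the merit function cannot be improved further
                status, msg = 3, "converged (feasible, no further merit progress)"
                break
            # restoration phase: ignore the objective and take a damped
            # least-norm step onto the linearised constraint manifold,
            # judged on feasibility alone
            d_rest = lu.solve(np.concatenate([np.zeros(n), r_all]))[:n]
            restored = False
            if np.isfinite(d_rest).all():
                step_inf = np.abs(d_rest).max()
                if step_inf > cap:
                    d_rest *= cap / step_inf
                viol0 = np.abs(c).sum() + np.abs(r_eq).sum() + act_viol.sum()
                alpha = 1.0
                for _ in range(7):
                    z_new = np.clip(z + alpha * d_rest, -1.0, 1.0)
                    c_new = nlp.constraints_fun(z_new)
                    r_new = A_eq @ z_new - b_eq
                    a_new = np.maximum(A_act @ z_new - b_act, 0.0)
                    viol1 = np.abs(c_new).sum() + np.abs(r_new).sum() + a_new.sum()
                    if viol1 < viol0 * (1 - 1e-8):
                        f_new = nlp.obj(z_new)
                        phi_new = merit(f_new, c_new, r_new, a_new)
                        restored = True
                        break
                    alpha *= 0.5
            if not restored:
                # re-linearise with heavier damping before giving up: a stale
                # Jacobian direction is the usual culprit
                failure_streak += 1
                if failure_streak >= 3:
                    status, msg = 4, "line search failed"
                    break
                lam = max(lam * 30, 1.0)
                continue
            accepted = True
            failure_streak = 0
        step_taken = np.abs(z_new - z).max()
        failure_streak = 0
        bound_fix_prev = bound_fix
        phi_hist.append(phi)
        z, f, c, r_eq, act_viol, phi = z_new, f_new, c_new, r_new, a_new, phi_new
        lam = max(lam / 3, 1e-8)
        feas = max(np.abs(c).max(), np.abs(r_eq).max(), act_viol.max())
        if verbose:
            pinfo = ""
            if nlp.npar:
                pv = nlp.unscale(z)[nlp.iP0:nlp.iP0 + 2]
                pinfo = f" k={pv[0]:8.3g} c={pv[1]:5.2f}"
            print(f"  sqp it {it:3d}  f={f:12.6g}  feas={feas:9.3e} "
                  f"step={step_taken:9.3e} lam={lam:8.1e} alpha={alpha:5.3f}{pinfo}")
        f_hist.append(f)
        if feas < feas_tol and step_taken < step_tol:
            status, msg = 1, "converged (feasible, step tolerance)"
            break
        if (feas < 5e-3 and len(f_hist) > 6
                and abs(f_hist[-7] - f) < 1e-6 * max(1.0, abs(f))):
            status, msg = 2, "converged (feasible, objective stagnant)"
            break
    final_feas = float(max(np.abs(c).max(), np.abs(r_eq).max(), act_viol.max()))
    if status == 0 and final_feas < 5e-3:
        # iteration budget exhausted at a feasible point: optimality is not
        # proven, but the trajectory satisfies the dynamics and path
        # constraints and is usable (acceptable-level exit)
        status, msg = 5, "acceptable (feasible at iteration limit)"
    return _SQPResult(z, f, status, it, final_feas, msg)
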