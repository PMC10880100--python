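"""Outcome measures from converged tracking solutions.

Joint reaction forces (JRF) come from a free-body analysis of the segments
distal to each joint: the bone-on-bone force equals the inertial-minus-
gravitational wrench of the distal segments, minus the external forces
acting on them, minus the pull of every muscle crossing the joint.  Peaks
and time-integrals (impulses) are reported body-weight normalised, and
tracking diagnostics implement the reserve-actuator acceptance rule
(<= 5 N m and <= 10% of the net joint moment).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import ChainKinematics, ModelSpec, mtu_path_points
from .ocp_tracking import OCPSolution
from .preprocessing import TrackingData

RESERVE_ABS_LIMIT = 5.0  # N m
RESERVE_FRACTION_LIMIT = 0.10


@dataclass
class JointLoadSummary:
    joint: str
    peak_njm: float       # N m / kg (signed extremum, largest magnitude)
    njm_impulse: float    # N m s / kg (integral of |moment|)
    peak_jrf: float       # BW (compressive positive)
    jrf_impulse: float    # BW s


@dataclass
class TrackingDiagnostics:
    max_abs_error: dict   # per channel group
    rmse: dict
    reserve_max: float            # N m
    reserve_fraction_max: float   # dimensionless
    accepted: bool


# ---------------------------------------------------------------------------
# Joint reaction forces
# ---------------------------------------------------------------------------


def _distal_segments(model: ModelSpec, joint: str) -> list[int]:
    """Indices of the segments distal to (moved by) a joint coordinate."""
    k = model.coordinate_index(joint)
    return [i for i in range(len(model.segments)) if model._affected[k, i]]


def _muscle_pull_on_distal(model: ModelSpec, kin: ChainKinematics, joint: str,
                           muscle_forces: np.ndarray) -> np.ndarray:
    """Sum of muscle force vectors acting on the distal side of a joint.

    For each MTU whose path crosses the joint, the force pulls the first
    path point on the distal side towards its neighbour on the proximal
    side, along the straight path segment joining them.
    """
    distal = set(_distal_segments(model, joint))
    T = kin.q.shape[0]
    total = np.zeros((T, 2))
    for j, mtu in enumerate(model.mtus):
        sides = [model._seg_index[seg] in distal for seg, _ in mtu.path]
        if all(sides) or not any(sides):
            continue  # does not cross this joint
        pts = mtu_path_points(model, mtu, kin)  # (n_pts, T, 2)
        # first transition between proximal- and distal-side path points
        for a in range(len(sides) - 1):
            if sides[a] != sides[a + 1]:
                i_dist, i_prox = (a, a + 1) if sides[a] else (a + 1, a)
                vec = pts[i_prox] - pts[i_dist]
                unit = vec / np.linalg.norm(vec, axis=1, keepdims=True)
                total += unit * muscle_forces[:, j][:, None]
                break
    return total


def joint_reaction_forces(solution: OCPSolution, model: ModelSpec | None = None,
                          frame: str = "child", residual_tolerance: float = 20.0):
    """Per-joint reaction force time series (N, on the child segment).

    ``frame="child"`` resolves the force in the distal segment frame with
    the compressive (long-axis) component positive; ``frame="lab"`` returns
    the laboratory vertical component instead.
    """
    model = model or solution.model
    res_force = np.abs(solution.cost_terms.get("pelvis_residual_max", 0.0))
    q = solution.states["q"]
    qd = solution.states["qd"]
    qdd = solution.controls["qdd"]
    kin = ChainKinematics(model, q, qd, qdd)
    T = q.shape[0]
    g_vec = np.array([0.0, -model.gravity_earth])
    masses = np.array([s.mass for s in model.segments])

    # external forces per segment: u_GRF at the optimised sphere positions
    ugrf = solution.controls["ugrf"]
    sphere_pos = solution.parameters["sphere_positions"]
    foot_i = model._seg_index["foot"]
    ext_force_on = {foot_i: np.zeros((T, 2))}
    for si in range(len(model.contact_spheres)):
        ext_force_on[foot_i] = ext_force_on[foot_i] + ugrf[:, 2 * si:2 * si + 2]

    forces = solution.muscle_forces
    out = {}
    for joint in [c for c in model.coordinates[3:]]:
        distal = _distal_segments(model, joint)
        inertial = np.zeros((T, 2))
        for i in distal:
            inertial += masses[i] * (kin.com_acc[i] - g_vec)
        ext = np.zeros((T, 2))
        for i in distal:
            if i in ext_force_on:
                ext += ext_force_on[i]
        pull = _muscle_pull_on_distal(model, kin, joint, forces)
        f_bone = inertial - ext - pull  # world frame, on the child segment
        child = next(i for i in distal
                     if model._joint_coord[i] == model.coordinate_index(joint))
        if frame == "child":
            c, s = np.cos(kin.phi[child]), np.sin(kin.phi[child])
            # child long axis points distally (-y local); compression positive
            comp = -(-s * f_bone[:, 0] + c * f_bone[:, 1])
        elif frame == "lab":
            comp = -f_bone[:, 1]
        else:
            raise ValueError(f"unknown frame {frame!r}")
        out[joint] = {"force_world": f_bone, "compressive": comp}
    return out


# ---------------------------------------------------------------------------
# Scalar summaries
# ---------------------------------------------------------------------------


def peak_and_impulse(series, time) -> tuple[float, float]:
    """Signed extremum (largest magnitude) and trapezoidal time-integral."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty series")
    if not np.isfinite(series).all():
        raise ValueError("non-finite series")
    peak = series[np.argmax(np.abs(series))]
    impulse = float(np.trapezoid(series, np.asarray(time)))
    return float(peak), impulse


def summarise_joint_loads(solution: OCPSolution, model: ModelSpec | None = None,
                          frame: str = "child") -> list[JointLoadSummary]:
    """Table-style per-joint summary: peak/impulse of the mass-normalised net
    joint moment and of the body-weight-normalised compressive JRF."""
    model = model or solution.model
    data = solution.data
    bw = data.mass * model.gravity_earth
    jrf = joint_reaction_forces(solution, model, frame=frame)
    nlp_moments = _solution_moments(solution, model)
    out = []
    for jj, joint in enumerate(data.joint_names):
        pk_m, imp_m = peak_and_impulse(nlp_moments[:, jj] / data.mass, solution.time)
        comp = jrf[joint]["compressive"] / bw
        pk_f, imp_f = peak_and_impulse(comp, solution.time)
        out.append(JointLoadSummary(joint=joint, peak_njm=pk_m,
                                    njm_impulse=float(np.trapezoid(
                                        np.abs(nlp_moments[:, jj]) / data.mass,
                                        solution.time)),
                                    peak_jrf=pk_f, jrf_impulse=imp_f))
    return out


def _solution_moments(solution: OCPSolution, model: ModelSpec) -> np.ndarray:
    """Simulated moments of the tracked joints (muscle + reserve, or torque
    actuator), N m, ordered as data.joint_names."""
    from .mtu_geometry import fit_model_geometry
    geometry = fit_model_geometry(model)
    q = solution.states["q"]
    ft = solution.states["ft"]
    res = solution.controls["res"]
    atau = solution.states["atau"]
    fmax = np.array([m.f_max_iso for m in model.mtus])
    joints = solution.data.joint_names
    muscle_joints = model.muscle_coordinates
    out = np.zeros((q.shape[0], len(joints)))
    for j, mtu in enumerate(model.mtus):
        poly = geometry[mtu.name]
        cols = [model.coordinate_index(c) for c in mtu.spanned_coordinates]
        R = poly.moment_arms(q[:, cols])
        F = ft[:, j] * fmax[j]
        for cc, cname in enumerate(mtu.spanned_coordinates):
            out[:, joints.index(cname)] += R[:, cc] * F
    for jj, name in enumerate(joints):
        if name in muscle_joints:
            out[:, jj] += res[:, muscle_joints.index(name)]
        else:
            for ai, act in enumerate(model.torque_actuators):
                if act.coordinate == name:
                    out[:, jj] += atau[:, ai] * act.tau_max
    return out


def tracking_errors(solution: OCPSolution, data: TrackingData | None = None) -> TrackingDiagnostics:
    """Per-channel-group maximum and RMS errors plus reserve acceptance."""
    data = data or solution.data
    model = solution.model
    is_tr = np.array([c.endswith(("_tx", "_ty")) for c in model.coordinates])
    q_err = solution.states["q"] - data.q
    rot_err = np.rad2deg(q_err[:, ~is_tr])
    tr_err = q_err[:, is_tr]
    bw = data.mass * model.gravity_earth
    grf_err = (solution.grf_total - data.grf_exp) / bw
    njm_sim = _solution_moments(solution, model)
    njm_err = (njm_sim - data.njm_exp) / data.mass

    def _summary(e):
        return float(np.abs(e).max()), float(np.sqrt(np.mean(e ** 2)))

    groups = {"rotations_deg": rot_err, "translations_m": tr_err,
              "grf_bw": grf_err, "njm_nm_per_kg": njm_err}
    max_abs = {k: _summary(v)[0] for k, v in groups.items()}
    rmse = {k: _summary(v)[1] for k, v in groups.items()}

    res = solution.controls["res"]
    reserve_max = float(np.abs(res).max())
    muscle_joints = model.muscle_coordinates
    frac = 0.0
    for jj, name in enumerate(data.joint_names):
        if name not in muscle_joints:
            continue
        r = np.abs(res[:, muscle_joints.index(name)])
        njm = np.abs(njm_sim[:, jj])
        mask = njm > 1.0  # ignore near-zero moments for the fraction rule
        if mask.any():
            frac = max(frac, float((r[mask] / njm[mask]).max()))
    accepted = (reserve_max <= RESERVE_ABS_LIMIT) and (frac <= RESERVE_FRACTION_LIMIT)
    return TrackingDiagnostics(max_abs_error=max_abs, rmse=rmse,
                               reserve_max=reserve_max,
                               reserve_fraction_max=frac, accepted=accepted)


def quadriceps_force_profile(solution: OCPSolution, model: ModelSpec | None = None):
    """Cumulative quadriceps (RF + three vasti) active plus parallel-passive
    force, normalised to their summed maximum isometric force.

    Returns ``(time, profile)`` restricted to the first full hopping cycle
    (touchdown to touchdown) when touchdown times are available.
    """
    from .model_core import QUADRICEPS
    model = model or solution.model
    quad_idx = [j for j, m in enumerate(model.mtus) if m.name in QUADRICEPS]
    if not quad_idx:
        raise ValueError("model has no quadriceps MTUs")
    fmax = np.array([m.f_max_iso for m in model.mtus])
    total_fmax = fmax[quad_idx].sum()
    # tendon force = transmitted fibre force (active + parallel passive),
    # so the normalised profile is the summed tendon forces over Fmax
    force = solution.muscle_forces[:, quad_idx].sum(axis=1)
    t = solution.time
    td1, td2 = solution.data.touchdown_times
    if np.isfinite(td1) and np.isfinite(td2):
        mask = (t >= td1) & (t <= td2)
        t, force = t[mask], force[mask]
    return t - t[0], force / total_fmax
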