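"""Reduced planar musculoskeletal model for single-leg hopping.

The model is a five-segment planar chain (pelvis root with two translations
and a tilt, plus torso, thigh, shank and foot) driven by Hill-type
muscle-tendon units (MTUs) at the hip, knee and ankle and an idealised
torque actuator at the lumbar joint.  Foot-ground interaction uses a
smoothed Hunt-Crossley sphere contact model, and hypogravity is emulated
by a constant vertical body-weight-support (BWSS) force at the pelvis
centre of mass.

Everything here is written to be evaluated vectorised over time frames so
the same code serves preprocessing, the tracking optimal control problem
and post-hoc analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

GRAVITY_EARTH = 9.81  # m s^-2

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SegmentSpec:
    """A rigid planar segment.

    The segment frame origin sits at its proximal joint.  ``com_offset`` and
    ``joint_location_in_parent`` are expressed in the local frames of the
    segment and its parent respectively.  ``parent_joint`` names the
    generalized coordinate that rotates this segment relative to its parent
    (``"root"`` for the floating pelvis) and ``joint_sign`` fixes the
    rotation convention (e.g. knee flexion positive).
    """

    name: str
    mass: float  # kg
    com_offset: tuple[float, float]  # m, segment frame
    inertia_zz: float  # kg m^2 about the COM
    length: float  # m
    parent_joint: str = "root"
    parent_segment: str | None = None
    joint_location_in_parent: tuple[float, float] = (0.0, 0.0)
    joint_sign: float = 1.0

    def __post_init__(self):
        if self.mass <= 0:
            raise ValueError(f"segment {self.name}: mass must be > 0")
        if self.inertia_zz <= 0:
            raise ValueError(f"segment {self.name}: inertia_zz must be > 0")
        if self.length <= 0:
            raise ValueError(f"segment {self.name}: length must be > 0")


@dataclass(frozen=True)
class MuscleCurveSet:
    """Dimensionless Hill-model curves (Gaussian active force-length,
    log-type force-velocity, exponential passive and tendon curves).

    The tendon curve ``f_t(strain) = c1 exp(k_T (1 + strain - c2)) - c3`` is
    monotone in the stiffness parameter ``k_T``; :func:`calibrate_tendon_stiffness`
    adjusts ``k_T`` so the normalised slope at 4% strain equals 35.
    """

    # active force-length: sum of Gaussians b1*exp(-0.5*(l-b2)^2/(b3+b4*l)^2)
    afl_b1: tuple[float, ...] = (0.815, 0.433, 0.100)
    afl_b2: tuple[float, ...] = (1.055, 0.717, 1.000)
    afl_b3: tuple[float, ...] = (0.162, -0.030, 0.354)
    afl_b4: tuple[float, ...] = (0.063, 0.200, 0.000)
    # force-velocity: d1*log(d2*v + d3 + sqrt((d2*v + d3)^2 + 1)) + d4
    fv_d: tuple[float, ...] = (-0.318, -8.149, -0.374, 0.886)
    # passive force-length: (exp(kpe*(l-1)/e0) - 1)/(exp(kpe) - 1), smooth-clamped >= 0
    kpe: float = 4.0
    e0: float = 0.6
    passive_clamp_eps: float = 1e-4
    # tendon force-length
    k_T: float = 35.0
    tendon_c1: float = 0.200
    tendon_c2: float = 0.995
    tendon_c3: float = 0.250
    # fibre damping (normalised force per normalised velocity)
    damping: float = 0.1

    # -- individual curves (vectorised) -------------------------------------
    def active_fl(self, lm_norm):
        lm_norm = np.asarray(lm_norm, dtype=float)
        out = 0.0
        for b1, b2, b3, b4 in zip(self.afl_b1, self.afl_b2, self.afl_b3, self.afl_b4):
            out = out + b1 * np.exp(-0.5 * (lm_norm - b2) ** 2 / (b3 + b4 * lm_norm) ** 2)
        return out / self._afl_norm()

    def _afl_norm(self) -> float:
        out = 0.0
        for b1, b2, b3, b4 in zip(self.afl_b1, self.afl_b2, self.afl_b3, self.afl_b4):
            out += b1 * math.exp(-0.5 * (1.0 - b2) ** 2 / (b3 + b4) ** 2)
        return out

    def force_velocity(self, vm_norm):
        vm_norm = np.asarray(vm_norm, dtype=float)
        d1, d2, d3, d4 = self.fv_d
        z = d2 * vm_norm + d3
        raw = d1 * np.log(z + np.sqrt(z * z + 1.0)) + d4
        z0 = d3
        norm = d1 * math.log(z0 + math.sqrt(z0 * z0 + 1.0)) + d4
        return raw / norm

    def passive_fl(self, lm_norm):
        lm_norm = np.asarray(lm_norm, dtype=float)
        raw = (np.exp(self.kpe * (lm_norm - 1.0) / self.e0) - 1.0) / (math.exp(self.kpe) - 1.0)
        return _smooth_pos(raw, self.passive_clamp_eps)

    def tendon_fl(self, strain):
        """Normalised tendon force as a function of tendon strain."""
        strain = np.asarray(strain, dtype=float)
        return self.tendon_c1 * np.exp(self.k_T * (1.0 + strain - self.tendon_c2)) - self.tendon_c3

    def tendon_slope(self, strain):
        return self.k_T * self.tendon_c1 * np.exp(self.k_T * (1.0 + strain - self.tendon_c2))

    def tendon_strain_from_force(self, ft_norm):
        """Invert the tendon curve: strain at which f_t equals ``ft_norm``."""
        ft_norm = np.asarray(ft_norm, dtype=float)
        return self.tendon_c2 - 1.0 + np.log((ft_norm + self.tendon_c3) / self.tendon_c1) / self.k_T


@dataclass(frozen=True)
class MTUParams:
    """Hill-type muscle-tendon unit parameters plus its planar path.

    ``path`` is a sequence of (segment name, local point) pairs from origin
    to insertion; straight lines join consecutive points.  ``pv_percent`` is
    the muscle volume as a percentage of the modelled musculature, used to
    penalise large muscles in the effort cost.
    """

    name: str
    f_max_iso: float  # N
    l_opt: float  # m
    pennation_opt: float  # rad
    l_slack: float  # m
    spanned_coordinates: tuple[str, ...]
    pv_percent: float
    path: tuple[tuple[str, tuple[float, float]], ...]
    v_max: float = 10.0  # optimal fibre lengths per second

    def __post_init__(self):
        if self.f_max_iso <= 0:
            raise ValueError(f"MTU {self.name}: f_max_iso must be > 0")
        if not (0 < self.pv_percent <= 100):
            raise ValueError(f"MTU {self.name}: pv_percent must be in (0, 100]")
        if self.l_opt <= 0 or self.l_slack <= 0:
            raise ValueError(f"MTU {self.name}: lengths must be > 0")


@dataclass(frozen=True)
class TorqueActuatorSpec:
    """Idealised torque actuator: torque = activation * tau_max, with
    first-order excitation-activation dynamics of time constant ``delay``."""

    name: str
    coordinate: str
    tau_max: float  # N m
    delay: float = 0.035  # s (electromechanical delay)

    def __post_init__(self):
        if self.tau_max <= 0:
            raise ValueError(f"actuator {self.name}: tau_max must be > 0")


@dataclass(frozen=True)
class ContactSphere:
    """Foot-ground contact sphere.  Radius is fixed; stiffness, damping and
    position are optimised in the tracking problem (stiffness/damping shared
    across the spheres of a model)."""

    name: str
    attached_segment: str
    position: tuple[float, float]  # m, segment frame (optimisable)
    radius: float = 0.02
    stiffness: float = 1e6  # N m^-3/2 (Hertz-type d^{3/2} law)
    damping: float = 2.0  # s m^-1

    def __post_init__(self):
        if self.stiffness <= 0:
            raise ValueError(f"sphere {self.name}: stiffness must be > 0")
        if self.damping < 0:
            raise ValueError(f"sphere {self.name}: damping must be >= 0")


@dataclass(frozen=True)
class GravityCondition:
    """A hypogravity condition emulated by body-weight support.

    ``bwss_force`` is the vertical offloading force (N) applied at the pelvis
    centre of mass: (1 - g_level) * total mass * 9.81.
    """

    g_level: float
    bwss_force: float

    @classmethod
    def from_g_level(cls, g_level: float, total_mass: float) -> "GravityCondition":
        if not (0 < g_level <= 1):
            raise ValueError(f"g_level must be in (0, 1], got {g_level}")
        return cls(g_level=g_level, bwss_force=(1.0 - g_level) * total_mass * GRAVITY_EARTH)


@dataclass
class ModelSpec:
    """Full description of the planar hopping model."""

    segments: list[SegmentSpec]
    coordinates: list[str]
    mtus: list[MTUParams]
    torque_actuators: list[TorqueActuatorSpec]
    contact_spheres: list[ContactSphere]
    curves: MuscleCurveSet
    coordinate_ranges: dict[str, tuple[float, float]]
    gravity_earth: float = GRAVITY_EARTH
    friction_coefficient: float = 0.8
    friction_velocity_scale: float = 1.0  # m/s, tanh regularisation (near-viscous)

    def __post_init__(self):
        if len(self.coordinates) < 6:
            raise ValueError("model needs at least 6 coordinates")
        if self.coordinates[:3] != ["pelvis_tx", "pelvis_ty", "pelvis_tilt"]:
            raise ValueError("first three coordinates must be the pelvis root")
        for m in self.mtus:
            if len(m.spanned_coordinates) < 1:
                raise ValueError(f"MTU {m.name} spans no coordinate")
        self._build_topology()

    # -- derived ------------------------------------------------------------
    @property
    def total_mass(self) -> float:
        return sum(s.mass for s in self.segments)

    @property
    def n_coordinates(self) -> int:
        return len(self.coordinates)

    def coordinate_index(self, name: str) -> int:
        return self.coordinates.index(name)

    def segment(self, name: str) -> SegmentSpec:
        return self.segments[self._seg_index[name]]

    def mtu(self, name: str) -> MTUParams:
        for m in self.mtus:
            if m.name == name:
                return m
        raise KeyError(name)

    @property
    def muscle_coordinates(self) -> list[str]:
        """Coordinates actuated by at least one MTU."""
        out = []
        for c in self.coordinates[3:]:
            if any(c in m.spanned_coordinates for m in self.mtus):
                out.append(c)
        return out

    @property
    def actuator_coordinates(self) -> list[str]:
        return [a.coordinate for a in self.torque_actuators]

    def _build_topology(self):
        self._seg_index = {s.name: i for i, s in enumerate(self.segments)}
        n_seg = len(self.segments)
        # parent index per segment (-1 for root)
        self._parent = np.full(n_seg, -1, dtype=int)
        self._joint_coord = np.full(n_seg, -1, dtype=int)  # coordinate index rotating the segment
        for i, s in enumerate(self.segments):
            if s.parent_segment is not None:
                if self._seg_index[s.parent_segment] >= i:
                    raise ValueError("segments must be ordered parent before child")
                self._parent[i] = self._seg_index[s.parent_segment]
                self._joint_coord[i] = self.coordinate_index(s.parent_joint)
        # affected[k, i]: does angular coordinate k move segment i?
        nq = self.n_coordinates
        aff = np.zeros((nq, n_seg), dtype=bool)
        aff[2, :] = True  # pelvis tilt rotates everything about the root origin
        for i, s in enumerate(self.segments):
            j = i
            while j >= 0:
                if self._joint_coord[j] >= 0:
                    aff[self._joint_coord[j], i] = True
                j = self._parent[j]
        self._affected = aff


# ---------------------------------------------------------------------------
# Smoothing helpers
# ---------------------------------------------------------------------------


def _smooth_pos(x, eps):
    """Twice continuously differentiable positive part: -> max(x, 0)."""
    x = np.asarray(x, dtype=float)
    return 0.5 * (x + np.sqrt(x * x + eps * eps))


# ---------------------------------------------------------------------------
# Muscle curve operations
# ---------------------------------------------------------------------------


def eval_muscle_curves(lm_norm, vm_norm, tendon_strain, curves: MuscleCurveSet):
    """Evaluate the four dimensionless Hill-model curves.

    Returns ``(f_act_fl, f_v, f_pas, f_tendon)``.  All curves are smooth
    (C-infinity) over their operating range.
    """
    lm_norm = np.asarray(lm_norm, dtype=float)
    if np.any(~np.isfinite(lm_norm)) or np.any(lm_norm <= 0):
        raise ValueError("lm_norm must be finite and > 0")
    for x, label in ((vm_norm, "vm_norm"), (tendon_strain, "tendon_strain")):
        if np.any(~np.isfinite(np.asarray(x, dtype=float))):
            raise ValueError(f"{label} must be finite")
    return (
        curves.active_fl(lm_norm),
        curves.force_velocity(vm_norm),
        curves.passive_fl(lm_norm),
        curves.tendon_fl(tendon_strain),
    )


def calibrate_tendon_stiffness(
    curves: MuscleCurveSet, target_gradient: float = 35.0, target_strain: float = 0.04,
    bracket: tuple[float, float] = (5.0, 200.0),
) -> MuscleCurveSet:
    """Return a curve set whose tendon slope at ``target_strain`` equals
    ``target_gradient`` (root-found on the stiffness parameter k_T)."""
    if target_strain <= 0:
        raise ValueError("target_strain must be > 0: the slack point has no prescribed slope")

    def slope_err(k):
        return k * curves.tendon_c1 * math.exp(k * (1.0 + target_strain - curves.tendon_c2)) - target_gradient

    lo, hi = bracket
    if slope_err(lo) * slope_err(hi) > 0:
        raise ValueError(f"no tendon stiffness root in bracket {bracket}")
    k_T = brentq(slope_err, lo, hi, xtol=1e-12, rtol=1e-12)
    return replace(curves, k_T=k_T)


def hill_equilibrium_residual(a_m, lmt, vmt, ft_norm, dft_norm, mtu: MTUParams,
                              curves: MuscleCurveSet, _guard: bool = True):
    """Implicit Hill-equilibrium residual of the three-element muscle model.

    States are the activation ``a_m`` and normalised tendon force ``ft_norm``
    with its time derivative ``dft_norm`` as control.  The tendon length is
    recovered by inverting the tendon curve; the fibre is a fixed-height
    (constant thickness) pennation model.  The residual is zero iff the
    pennation-projected fibre force balances the tendon force.
    """
    a_m = np.asarray(a_m, dtype=float)
    ft_norm = np.asarray(ft_norm, dtype=float)
    # the strain inversion is only defined for ft > -c3; clamp smoothly so
    # transient out-of-bound solver iterates stay finite
    ft_safe = ft_norm if _guard else _smooth_pos(ft_norm, 1e-3)
    strain = curves.tendon_strain_from_force(ft_safe)
    l_tendon = mtu.l_slack * (1.0 + strain)
    # tendon lengthening rate from the force rate (chain rule through f_t)
    strain_rate = np.asarray(dft_norm, dtype=float) / (curves.k_T * (ft_safe + curves.tendon_c3))
    v_tendon = mtu.l_slack * strain_rate

    height = mtu.l_opt * math.sin(mtu.pennation_opt)
    l_along = np.asarray(lmt, dtype=float) - l_tendon
    if _guard:
        if np.any(l_along <= 0):
            raise ValueError(f"MTU {mtu.name}: non-positive fibre projection length")
    else:
        l_along = _smooth_pos(l_along - 0.01 * mtu.l_opt, 1e-4) + 0.01 * mtu.l_opt
    l_fibre = np.sqrt(l_along * l_along + height * height)
    cos_penn = l_along / l_fibre
    lm_norm = l_fibre / mtu.l_opt
    v_fibre = (np.asarray(vmt, dtype=float) - v_tendon) * cos_penn
    vm_norm = v_fibre / (mtu.v_max * mtu.l_opt)

    f_act = curves.active_fl(lm_norm)
    f_v = curves.force_velocity(vm_norm)
    f_pas = curves.passive_fl(lm_norm)
    fibre_force = a_m * f_act * f_v + f_pas + curves.damping * vm_norm
    return cos_penn * fibre_force - ft_norm


def activation_rate_constraints(a_m, a_m_dot, t_act: float = 0.015, t_deact: float = 0.06):
    """Admissible activation-rate envelope of first-order excitation-activation
    dynamics with excitation bounded in [0, 1] (Raasch-type model).

    Returns ``(g_act, g_deact)``; both are <= 0 iff the rate is admissible:
    ``a_dot <= (1 - a)/t_act`` and ``a_dot >= -a/t_deact``.
    """
    a_m = np.asarray(a_m, dtype=float)
    a_m_dot = np.asarray(a_m_dot, dtype=float)
    g_act = a_m_dot - (1.0 - a_m) / t_act
    g_deact = -a_m_dot - a_m / t_deact
    return g_act, g_deact


# ---------------------------------------------------------------------------
# Contact model
# ---------------------------------------------------------------------------

_PEN_EPS = 1e-5  # m, smoothing of the penetration positive part
_DAMP_EPS = 1e-2  # smoothing of the Hunt-Crossley damping factor


def contact_normal_force(penetration, penetration_velocity, stiffness, damping):
    """Smoothed Hunt-Crossley normal force (vectorised).

    ``F = k * <d>^{3/2} * <1 + 1.5 c d_dot>`` where ``<.>`` is a C-infinity
    softplus-type positive part, so the force vanishes smoothly out of
    contact and the whole law is twice continuously differentiable.
    """
    d = _smooth_pos(penetration, _PEN_EPS)
    damp = _smooth_pos(1.0 + 1.5 * np.asarray(damping) * np.asarray(penetration_velocity), _DAMP_EPS)
    return np.asarray(stiffness) * d ** 1.5 * damp


def contact_force(penetration, penetration_velocity, sphere: ContactSphere,
                  slip_velocity=0.0, mu: float = 0.8, v_scale: float = 1.0):
    """Planar contact force ``(tangential, normal)`` for one sphere.

    Friction is a smooth Coulomb model: ``-mu * F_n * tanh(v_slip / v_scale)``.
    """
    fn = contact_normal_force(penetration, penetration_velocity, sphere.stiffness, sphere.damping)
    fx = -mu * fn * np.tanh(np.asarray(slip_velocity) / v_scale)
    return np.stack(np.broadcast_arrays(fx, fn), axis=-1)


# ---------------------------------------------------------------------------
# Chain kinematics and rigid-body dynamics
# ---------------------------------------------------------------------------


def _rot(phi):
    c, s = np.cos(phi), np.sin(phi)
    return c, s


def _rotate(c, s, p):
    """Rotate local 2-vector p by angle with cos c / sin s.  c, s: (T,); p: (2,) or (T,2)."""
    px, py = (p[..., 0], p[..., 1]) if np.ndim(p) > 1 else (p[0], p[1])
    return np.stack([c * px - s * py, s * px + c * py], axis=-1)


def _perp(v):
    """90-degree CCW rotation of (..., 2) vectors."""
    return np.stack([-v[..., 1], v[..., 0]], axis=-1)


class ChainKinematics:
    """World-frame positions/velocities/accelerations of every segment
    origin and COM, for a trajectory of generalized coordinates."""

    def __init__(self, model: ModelSpec, q, qd=None, qdd=None):
        q = np.atleast_2d(np.asarray(q, dtype=float))
        T, nq = q.shape
        if nq != model.n_coordinates:
            raise ValueError(f"expected {model.n_coordinates} coordinates, got {nq}")
        zeros = np.zeros_like(q)
        qd = zeros if qd is None else np.atleast_2d(np.asarray(qd, dtype=float))
        qdd = zeros if qdd is None else np.atleast_2d(np.asarray(qdd, dtype=float))
        self.model = model
        self.q, self.qd, self.qdd = q, qd, qdd
        n_seg = len(model.segments)
        self.phi = np.empty((n_seg, T))
        self.omega = np.empty((n_seg, T))
        self.alpha = np.empty((n_seg, T))
        self.origin = np.empty((n_seg, T, 2))
        self.origin_vel = np.empty((n_seg, T, 2))
        self.origin_acc = np.empty((n_seg, T, 2))
        self.com = np.empty((n_seg, T, 2))
        self.com_vel = np.empty((n_seg, T, 2))
        self.com_acc = np.empty((n_seg, T, 2))
        # pivot point of each angular coordinate in world frame
        self.pivot = np.zeros((model.n_coordinates, T, 2))

        for i, seg in enumerate(model.segments):
            p = model._parent[i]
            if p < 0:  # pelvis root
                self.phi[i] = q[:, 2]
                self.omega[i] = qd[:, 2]
                self.alpha[i] = qdd[:, 2]
                self.origin[i] = q[:, :2]
                self.origin_vel[i] = qd[:, :2]
                self.origin_acc[i] = qdd[:, :2]
                self.pivot[2] = q[:, :2]
            else:
                ci = model._joint_coord[i]
                sgn = seg.joint_sign
                self.phi[i] = self.phi[p] + sgn * q[:, ci]
                self.omega[i] = self.omega[p] + sgn * qd[:, ci]
                self.alpha[i] = self.alpha[p] + sgn * qdd[:, ci]
                c, s = _rot(self.phi[p])
                r = _rotate(c, s, np.asarray(seg.joint_location_in_parent))
                self.origin[i] = self.origin[p] + r
                wp = self.omega[p][:, None]
                ap = self.alpha[p][:, None]
                self.origin_vel[i] = self.origin_vel[p] + wp * _perp(r)
                self.origin_acc[i] = self.origin_acc[p] + ap * _perp(r) - wp**2 * r
                self.pivot[ci] = self.origin[i]
            c, s = _rot(self.phi[i])
            rc = _rotate(c, s, np.asarray(seg.com_offset))
            w = self.omega[i][:, None]
            al = self.alpha[i][:, None]
            self.com[i] = self.origin[i] + rc
            self.com_vel[i] = self.origin_vel[i] + w * _perp(rc)
            self.com_acc[i] = self.origin_acc[i] + al * _perp(rc) - w**2 * rc

    def point(self, segment: str, local):
        """World position, velocity, acceleration of a material point."""
        i = self.model._seg_index[segment]
        c, s = _rot(self.phi[i])
        r = _rotate(c, s, np.asarray(local, dtype=float))
        w = self.omega[i][:, None]
        al = self.alpha[i][:, None]
        pos = self.origin[i] + r
        vel = self.origin_vel[i] + w * _perp(r)
        acc = self.origin_acc[i] + al * _perp(r) - w**2 * r
        return pos, vel, acc


def inverse_dynamics(q, qd, qdd, external_forces, model: ModelSpec, kin: ChainKinematics | None = None):
    """Generalized forces of the planar chain for a given motion.

    ``external_forces`` is a list of ``(segment_name, local_point, force)``
    with force of shape (T, 2) (or (2,)) in world frame.  The returned array
    has one column per coordinate: hip/knee/ankle/lumbar columns are the net
    joint moments; the three pelvis columns are the residual force (N) and
    moment (N m) at the floating base.
    """
    kin = kin or ChainKinematics(model, q, qd, qdd)
    T = kin.q.shape[0]
    nq = model.n_coordinates
    g_vec = np.array([0.0, -model.gravity_earth])
    tau = np.zeros((T, nq))

    masses = np.array([s.mass for s in model.segments])
    inertias = np.array([s.inertia_zz for s in model.segments])
    # inertial minus gravitational wrench per segment
    f_seg = masses[None, :, None] * (np.transpose(kin.com_acc, (1, 0, 2)) - g_vec)  # (T, S, 2)
    com = np.transpose(kin.com, (1, 0, 2))

    ext = []
    for seg_name, local, force in external_forces:
        pos, _, _ = kin.point(seg_name, local)
        f = np.broadcast_to(np.asarray(force, dtype=float), (T, 2))
        ext.append((model._seg_index[seg_name], pos, f))

    # translations
    tau[:, 0] = f_seg[:, :, 0].sum(axis=1) - sum(f[:, 0] for _, _, f in ext)
    tau[:, 1] = f_seg[:, :, 1].sum(axis=1) - sum(f[:, 1] for _, _, f in ext)

    # angular coordinates
    for k in range(2, nq):
        mask = model._affected[k]
        if not mask.any():
            continue
        if k == 2:
            sgn_per_seg = np.ones(len(model.segments))
        else:
            sgn = None
            for i, s in enumerate(model.segments):
                if model._joint_coord[i] == k:
                    sgn = s.joint_sign
            sgn_per_seg = np.full(len(model.segments), sgn)
        pivot = kin.pivot[k]  # (T,2)
        lever = com[:, mask, :] - pivot[:, None, :]
        mom = (f_seg[:, mask, 0] * -lever[:, :, 1] + f_seg[:, mask, 1] * lever[:, :, 0])
        mom = (mom * sgn_per_seg[mask][None, :]).sum(axis=1)
        mom += (inertias[mask] * sgn_per_seg[mask] * np.transpose(kin.alpha, (1, 0))[:, mask]).sum(axis=1)
        for si, pos, f in ext:
            if mask[si]:
                lev = pos - pivot
                mom -= sgn_per_seg[si] * (f[:, 0] * -lev[:, 1] + f[:, 1] * lev[:, 0])
        tau[:, k] = mom
    return tau


def bwss_force(condition: GravityCondition, model: ModelSpec) -> float:
    """Vertical body-weight-support force (N) applied at the pelvis COM."""
    if not (0 < condition.g_level <= 1):
        raise ValueError(f"g_level must be in (0, 1], got {condition.g_level}")
    expected = (1.0 - condition.g_level) * model.total_mass * model.gravity_earth
    return expected


def bwss_external_force(condition: GravityCondition, model: ModelSpec):
    """The BWSS force as an ``inverse_dynamics`` external-force entry."""
    f = bwss_force(condition, model)
    pelvis = model.segments[0]
    return (pelvis.name, np.asarray(pelvis.com_offset), np.array([0.0, f]))


# ---------------------------------------------------------------------------
# Muscle path geometry (exact reference for the polynomial fits)
# ---------------------------------------------------------------------------


def mtu_path_points(model: ModelSpec, mtu: MTUParams, kin: ChainKinematics):
    """World positions of every path point, shape (n_points, T, 2)."""
    return np.stack([kin.point(seg, np.asarray(local))[0] for seg, local in mtu.path])


def mtu_length(model: ModelSpec, mtu: MTUParams, q) -> np.ndarray:
    """Exact MTU length (straight lines between via points) vs time."""
    kin = ChainKinematics(model, q)
    pts = mtu_path_points(model, mtu, kin)
    seglen = np.linalg.norm(np.diff(pts, axis=0), axis=-1)
    return seglen.sum(axis=0)


def mtu_moment_arm(model: ModelSpec, mtu: MTUParams, q, coordinate: str, h: float = 1e-6) -> np.ndarray:
    """Reference moment arm about a coordinate: r = -dL/dq (central differences)."""
    q = np.atleast_2d(np.asarray(q, dtype=float))
    k = model.coordinate_index(coordinate)
    qp, qm = q.copy(), q.copy()
    qp[:, k] += h
    qm[:, k] -= h
    return -(mtu_length(model, mtu, qp) - mtu_length(model, mtu, qm)) / (2 * h)


# ---------------------------------------------------------------------------
# Default planar hopping model
# ---------------------------------------------------------------------------

_DEFAULT_ROM = {
    "pelvis_tx": (-0.5, 0.5),
    "pelvis_ty": (0.55, 1.45),
    "pelvis_tilt": (-0.5, 0.5),
    "lumbar": (-0.35, 0.35),
    "hip": (-0.4, 1.4),
    "knee": (-0.1, 1.6),
    "ankle": (-0.9, 0.5),
}

# name: (f_max [N], pennation [rad], pv_percent, spanned, path)
_DEFAULT_MUSCLES = {
    "iliopsoas": (2500.0, 0.14, 9.0, ("hip",),
                  (("pelvis", (0.05, 0.03)), ("thigh", (0.015, -0.12)))),
    "glutei": (4000.0, 0.30, 24.0, ("hip",),
               (("pelvis", (-0.07, 0.03)), ("pelvis", (-0.09, -0.05)),
                ("thigh", (-0.02, -0.15)))),
    "hamstrings": (3500.0, 0.20, 16.0, ("hip", "knee"),
                   (("pelvis", (-0.06, -0.03)), ("shank", (-0.028, -0.05)))),
    "rectus_femoris": (2600.0, 0.12, 5.0, ("hip", "knee"),
                       (("pelvis", (0.04, 0.02)), ("thigh", (0.055, -0.45)), ("shank", (0.045, -0.07)))),
    "vastus_lateralis": (6600.0, 0.16, 12.0, ("knee",),
                         (("thigh", (0.030, -0.12)), ("thigh", (0.055, -0.45)), ("shank", (0.045, -0.07)))),
    "vastus_intermedius": (5300.0, 0.08, 9.0, ("knee",),
                           (("thigh", (0.028, -0.15)), ("thigh", (0.055, -0.45)), ("shank", (0.045, -0.07)))),
    "vastus_medialis": (5000.0, 0.10, 8.0, ("knee",),
                        (("thigh", (0.026, -0.18)), ("thigh", (0.055, -0.45)), ("shank", (0.045, -0.07)))),
    "gastrocnemius": (3200.0, 0.30, 9.0, ("knee", "ankle"),
                      (("thigh", (-0.025, -0.40)), ("foot", (-0.065, -0.05)))),
    "soleus": (5500.0, 0.44, 6.0, ("ankle",),
               (("shank", (-0.03, -0.13)), ("foot", (-0.065, -0.05)))),
    "tibialis_anterior": (1500.0, 0.10, 2.0, ("ankle",),
                          (("shank", (0.025, -0.15)), ("shank", (0.04, -0.41)), ("foot", (0.09, -0.025)))),
}


def reference_pose(model: ModelSpec) -> np.ndarray:
    """Mid-range pose used for deriving fibre/tendon lengths."""
    q = np.zeros(model.n_coordinates)
    for k, name in enumerate(model.coordinates):
        lo, hi = model.coordinate_ranges[name]
        q[k] = 0.5 * (lo + hi)
    q[0] = 0.0
    q[2] = 0.0
    return q


def _derive_fibre_params(model: ModelSpec, name: str, f_max, penn, pv, spanned, path,
                         operating_range: float = 0.6):
    """Pick l_opt and l_slack from the path excursion over the ROM so the
    fibre covers roughly [1 - r/2, 1 + r/2] optimal lengths."""
    mtu = MTUParams(name=name, f_max_iso=f_max, l_opt=0.1, pennation_opt=penn,
                    l_slack=0.1, spanned_coordinates=spanned, pv_percent=pv, path=path)
    qref = reference_pose(model)
    grids = []
    for c in spanned:
        lo, hi = model.coordinate_ranges[c]
        grids.append(np.linspace(lo, hi, 9))
    mesh = np.meshgrid(*grids, indexing="ij")
    Q = np.tile(qref, (mesh[0].size, 1))
    for c, g in zip(spanned, mesh):
        Q[:, model.coordinate_index(c)] = g.ravel()
    L = mtu_length(model, mtu, Q)
    l_ref = float(mtu_length(model, mtu, qref[None, :])[0])
    excursion = float(L.max() - L.min())
    l_opt = max(0.06, excursion / operating_range)
    l_slack = l_ref - l_opt * math.cos(penn)
    if l_slack < 0.02:
        # shift work to the tendon for short paths
        l_opt = max(0.05, l_ref - 0.02) / math.cos(penn) if l_ref > 0.07 else l_opt
        l_slack = max(0.02, l_ref - l_opt * math.cos(penn))
    return replace(mtu, l_opt=l_opt, l_slack=l_slack)


def build_default_model(total_mass: float = 79.9, height: float = 1.82,
                        calibrate_tendon: bool = True) -> ModelSpec:
    """The default planar single-leg hopper (masses/lengths from standard
    anthropometry scaled to the stated body mass and stature).

    The contralateral leg, trunk, head and arms are lumped into the torso
    segment; the pelvis is the floating base.
    """
    scale_l = height / 1.82
    scale_m = total_mass / 79.9
    foot_m, shank_m, thigh_m, pelvis_m = 1.10 * scale_m, 3.46 * scale_m, 8.00 * scale_m, 8.90 * scale_m
    torso_m = total_mass - (foot_m + shank_m + thigh_m + pelvis_m)
    s = scale_l
    segments = [
        SegmentSpec("pelvis", pelvis_m, (0.0, 0.05 * s), 0.08 * scale_m * s**2, 0.12 * s),
        SegmentSpec("torso", torso_m, (0.0, 0.30 * s), 2.6 * scale_m * s**2, 0.60 * s,
                    parent_joint="lumbar", parent_segment="pelvis",
                    joint_location_in_parent=(0.0, 0.10 * s), joint_sign=1.0),
        SegmentSpec("thigh", thigh_m, (0.0, -0.20 * s), 0.15 * scale_m * s**2, 0.45 * s,
                    parent_joint="hip", parent_segment="pelvis",
                    joint_location_in_parent=(0.0, 0.0), joint_sign=1.0),
        SegmentSpec("shank", shank_m, (0.0, -0.19 * s), 0.055 * scale_m * s**2, 0.43 * s,
                    parent_joint="knee", parent_segment="thigh",
                    joint_location_in_parent=(0.0, -0.45 * s), joint_sign=-1.0),
        SegmentSpec("foot", foot_m, (0.05 * s, -0.04 * s), 0.005 * scale_m * s**2, 0.26 * s,
                    parent_joint="ankle", parent_segment="shank",
                    joint_location_in_parent=(0.0, -0.43 * s), joint_sign=1.0),
    ]
    coordinates = ["pelvis_tx", "pelvis_ty", "pelvis_tilt", "lumbar", "hip", "knee", "ankle"]
    curves = MuscleCurveSet()
    if calibrate_tendon:
        curves = calibrate_tendon_stiffness(curves)
    spheres = [
        ContactSphere("heel", "foot", (-0.05 * s, -0.08 * s)),
        ContactSphere("toe", "foot", (0.17 * s, -0.08 * s)),
    ]
    actuators = [TorqueActuatorSpec("trunk", "lumbar", tau_max=300.0 * scale_m)]
    model = ModelSpec(
        segments=segments, coordinates=coordinates, mtus=[],
        torque_actuators=actuators, contact_spheres=spheres, curves=curves,
        coordinate_ranges=dict(_DEFAULT_ROM),
    )
    mtus = []
    for name, (fmax, penn, pv, spanned, path) in _DEFAULT_MUSCLES.items():
        path_s = tuple((seg, (x * s, y * s)) for seg, (x, y) in path)
        mtus.append(_derive_fibre_params(model, name, fmax * scale_m, penn, pv, spanned, path_s))
    model.mtus = mtus
    return model


QUADRICEPS = ("rectus_femoris", "vastus_lateralis", "vastus_intermedius", "vastus_medialis")
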