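"""Synthetic hopping trials with the mechanical structure of the study.

No motion-capture data ships with the package, so trials are synthesised:
periodic single-leg hopping at a metronome-like frequency, with contact and
flight phases, for five gravity conditions emulated by a constant vertical
body-weight-support force.

The generator works "ground up" so the kinematics are close to dynamically
consistent with the ground reaction forces it reports:

1. a smooth squared-half-sine ground-penetration pulse is prescribed over
   the contact time and the recorded GRF *is* the Hunt-Crossley contact
   force along it, with the depth scaled so the vertical impulse balances
   the effective weight over one cycle;
3. the whole-body COM trajectory is obtained by integrating
   m a = GRF + BWSS - m g with periodic boundary conditions;
4. stance hip/knee/ankle angles come from closed-form two-link inverse
   kinematics (foot flat, pelvis placed so the COM follows step 3), flight
   angles are Hermite blends between lift-off and touchdown postures;
5. a fixed-point pass adds a torso (lumbar) counter-rotation that absorbs
   the residual root moment (translational root residuals are zero by
   construction of step 4), leaving only a few N m of inconsistency.

Measurement noise is added at the end.  Everything is deterministic for a
given seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .model_core import (ChainKinematics, GravityCondition, ModelSpec,
                         contact_normal_force, inverse_dynamics, _smooth_pos)
from .preprocessing import RawTrial

#: mean contact times per gravity level reported for the hopping task (s)
DEFAULT_CONTACT_TIMES = {0.17: 0.29, 0.25: 0.27, 0.37: 0.28, 0.50: 0.32, 1.0: 0.34}


@dataclass
class SynthConfig:
    """Study conditions for the synthetic experiment."""

    g_levels: tuple[float, ...] = (0.17, 0.25, 0.37, 0.50, 1.0)
    hop_frequency: float = 2.0  # Hz
    contact_times: dict = field(default_factory=lambda: dict(DEFAULT_CONTACT_TIMES))
    n_trials: int = 5
    noise_kin_deg: float = 0.5  # SD of angular coordinate noise
    noise_trans_m: float = 0.002  # SD of pelvis translation noise
    noise_grf_N: float = 5.0  # SD of GRF noise
    seed: int = 0
    mass: float = 79.9  # kg
    height: float = 1.82  # m
    contact_stiffness: float = 5.0e5  # generating stiffness (compliant shoe-ground interface)
    contact_damping: float = 1.0  # generating damping (s/m)
    kinematics_rate: float = 200.0  # Hz
    force_rate: float = 2000.0  # Hz
    trunk_lean_gain: float = 2.8  # rad of forward lean per metre of crouch depth
    pulse_plateau: float = 0.18  # plateau parameter of the penetration pulse
    knee_touchdown_base: float = 0.35  # rad, knee flexion at touchdown (0 g limit)
    knee_touchdown_gain: float = 0.55  # rad per g: deeper crouch at higher gravity
    cycle_grid: int = 2000  # samples per cycle for the internal solution

    def __post_init__(self):
        for g in self.g_levels:
            tc = self.contact_times.get(g, 0.30)
            if tc >= 1.0 / self.hop_frequency:
                raise ValueError(f"contact time {tc} s >= hop period at g={g}")
        if min(self.noise_kin_deg, self.noise_trans_m, self.noise_grf_N) < 0:
            raise ValueError("noise SDs must be >= 0")


@dataclass
class ReferenceMotion:
    """One noise-free periodic hopping cycle (touchdown at t = 0)."""

    period: float
    contact_time: float
    t: np.ndarray  # (N,) cycle grid
    q: np.ndarray  # (N, nq)
    sphere_forces: np.ndarray  # (N, n_spheres, 2) world frame
    grf: np.ndarray  # (N, 2) total
    cop_x: np.ndarray  # (N,)
    bwss: float
    g_level: float
    residual_moment_max: float  # N m, remaining root-moment inconsistency

    def sample(self, times: np.ndarray, arr: np.ndarray) -> np.ndarray:
        """Periodically interpolate a cycle-grid array at arbitrary times."""
        times = np.asarray(times, dtype=float)
        if arr.ndim == 1:
            return np.interp(times, self.t, arr, period=self.period)
        return np.stack([np.interp(times, self.t, arr[:, j], period=self.period)
                         for j in range(arr.shape[1])], axis=1)


# ---------------------------------------------------------------------------
# internal construction helpers
# ---------------------------------------------------------------------------


def _com_offset(model: ModelSpec, q_angles: np.ndarray) -> np.ndarray:
    """Whole-body COM position relative to the pelvis origin for given
    angles (pelvis translation set to zero)."""
    q = q_angles.copy()
    q[:, 0] = 0.0
    q[:, 1] = 0.0
    kin = ChainKinematics(model, q)
    masses = np.array([s.mass for s in model.segments])
    return (masses[:, None, None] * kin.com).sum(axis=0) / model.total_mass


def _leg_ik(model: ModelSpec, pelvis: np.ndarray, tilt: np.ndarray,
            ankle_target: np.ndarray):
    """Closed-form planar two-link IK: hip and knee angles placing the ankle,
    plus the ankle angle that keeps the foot flat (sole parallel to ground)."""
    # distal joint offsets give the functional segment lengths
    l1 = float(np.linalg.norm(model.segment("shank").joint_location_in_parent))
    l2 = float(np.linalg.norm(model.segment("foot").joint_location_in_parent))
    v = ankle_target - pelvis  # hip sits at the pelvis origin
    d2 = (v ** 2).sum(axis=1)
    cos_k = np.clip((d2 - l1 * l1 - l2 * l2) / (2 * l1 * l2), -1.0, 1.0)
    knee = np.arccos(cos_k)  # flexion-positive branch
    b = np.stack([-l2 * np.sin(knee), -l1 - l2 * np.cos(knee)], axis=1)
    phi_thigh = np.arctan2(v[:, 1], v[:, 0]) - np.arctan2(b[:, 1], b[:, 0])
    phi_thigh = (phi_thigh + np.pi) % (2 * np.pi) - np.pi
    hip = phi_thigh - tilt
    phi_shank = phi_thigh - knee  # knee joint sign is -1 (flexion positive)
    ankle = -phi_shank  # foot flat: phi_foot = phi_shank + ankle = 0
    return hip, knee, ankle


def _hermite(t, t0, t1, y0, y1, v0, v1, a0=0.0, a1=0.0):
    """Quintic Hermite interpolation on [t0, t1] matching position, velocity
    and acceleration at both ends (vectorised in t)."""
    h = t1 - t0
    s = (t - t0) / h
    s2, s3, s4, s5 = s**2, s**3, s**4, s**5
    h00 = 1 - 10 * s3 + 15 * s4 - 6 * s5
    h10 = s - 6 * s3 + 8 * s4 - 3 * s5
    h20 = 0.5 * s2 - 1.5 * s3 + 1.5 * s4 - 0.5 * s5
    h01 = 10 * s3 - 15 * s4 + 6 * s5
    h11 = -4 * s3 + 7 * s4 - 3 * s5
    h21 = 0.5 * s3 - s4 + 0.5 * s5
    return (h00 * y0 + h10 * h * v0 + h20 * h * h * a0
            + h01 * y1 + h11 * h * v1 + h21 * h * h * a1)


def _periodic_gradient(y: np.ndarray, dt: float) -> np.ndarray:
    pad = np.concatenate([y[-3:], y, y[:3]], axis=0)
    g = np.gradient(pad, dt, axis=0)
    return g[3:-3]


def _periodic_double_integral(a: np.ndarray, period: float, n_harmonics: int = 60) -> np.ndarray:
    """Exactly periodic second antiderivative of the low-harmonic content of
    a periodic signal (the mean, which has no periodic antiderivative, is
    dropped; high harmonics are truncated to avoid grid-scale ringing)."""
    N = len(a)
    A = np.fft.rfft(a)
    k = np.arange(len(A))
    omega = 2 * np.pi * k / period
    out = np.zeros_like(A)
    sel = (k >= 1) & (k <= n_harmonics)
    out[sel] = -A[sel] / omega[sel] ** 2
    return np.fft.irfft(out, n=N)


def generate_reference_motion(model: ModelSpec, config: SynthConfig,
                              g_level: float, contact_time: float | None = None,
                              period: float | None = None,
                              n_tilt_iters: int = 12) -> ReferenceMotion:
    """Build one periodic, near-dynamically-consistent hopping cycle."""
    if g_level not in config.g_levels:
        raise ValueError(f"g_level {g_level} not in configured conditions")
    P = period if period is not None else 1.0 / config.hop_frequency
    tc = contact_time if contact_time is not None else config.contact_times.get(g_level, 0.30)
    if tc >= P:
        raise ValueError(f"infeasible timing: contact {tc} s >= period {P} s")
    m = model.total_mass
    g_earth = model.gravity_earth
    g_eff = g_level * g_earth
    bwss = (1.0 - g_level) * m * g_earth
    k = config.contact_stiffness
    c = config.contact_damping
    n_spheres = len(model.contact_spheres)

    N = config.cycle_grid
    t = np.linspace(0.0, P, N, endpoint=False)
    dt = P / N
    stance = t < tc

    # --- penetration waveform and contact force (foot flat: equal
    # penetration under both spheres).  The penetration is prescribed as a
    # smooth pulse and the recorded GRF *is* the contact-model output along
    # it; the depth is scaled so the vertical impulse balances the effective
    # weight over one cycle.
    # squared-half-sine pulse with a smooth plateau: the flattened top
    # spreads the braking impulse (spring-like hopping) so the centre of
    # mass dips realistically instead of collapsing into a deep squat
    shape = np.zeros(N)
    s2 = np.sin(np.pi * t[stance] / tc) ** 2
    a_pl = config.pulse_plateau
    shape[stance] = s2 * (1.0 + a_pl) / (s2 + a_pl)
    amp = m * g_eff * P / (tc * 4.0 / (3.0 * np.pi))  # target peak force
    d_max = (amp / (n_spheres * k)) ** (2.0 / 3.0)
    target_impulse = m * g_eff * P
    for _ in range(20):
        delta = d_max * shape
        ddot = _periodic_gradient(delta, dt)
        fn_sphere = contact_normal_force(delta, ddot, k, c)
        f_contact = n_spheres * fn_sphere
        impulse = np.trapezoid(f_contact, dx=dt)
        ratio = target_impulse / impulse
        d_max *= ratio ** (2.0 / 3.0)
        if abs(ratio - 1.0) < 1e-10:
            break

    # --- COM trajectory (periodic) -----------------------------------------
    a_y = (f_contact + bwss) / m - g_earth
    a_y -= a_y.mean()  # enforce exact velocity periodicity at grid level
    v_y = np.concatenate([[0.0], np.cumsum(0.5 * (a_y[1:] + a_y[:-1])) * dt])
    v_y -= v_y.mean()
    y_rel = np.concatenate([[0.0], np.cumsum(0.5 * (v_y[1:] + v_y[:-1])) * dt])

    # anchor the COM height to the touchdown leg posture
    foot = model.segment("foot")
    l1 = float(np.linalg.norm(model.segment("shank").joint_location_in_parent))
    l2 = float(np.linalg.norm(foot.joint_location_in_parent))
    sphere_local_y = model.contact_spheres[0].position[1]
    radius = model.contact_spheres[0].radius
    ankle_h0 = radius - sphere_local_y  # ankle height with the foot flat on the ground
    knee_td = config.knee_touchdown_base + config.knee_touchdown_gain * g_level
    d_td = math.sqrt(l1 * l1 + l2 * l2 + 2 * l1 * l2 * math.cos(knee_td))
    q_guess = np.zeros((1, model.n_coordinates))
    q_guess[0, model.coordinate_index("knee")] = knee_td
    off = _com_offset(model, q_guess)[0]
    com_y = (ankle_h0 + d_td + off[1]) + (y_rel - y_rel[0])
    cop_mid = 0.5 * (model.contact_spheres[0].position[0] + model.contact_spheres[1].position[0])
    com_x = np.full(N, cop_mid)  # COM above the centre of the contact patch

    # --- assemble coordinates ----------------------------------------------
    nq = model.n_coordinates
    iq = {name: model.coordinate_index(name) for name in model.coordinates}
    # hip-hinge strategy: the trunk leans forward in proportion to the
    # crouch depth, moving the torso mass forward and the pelvis/knee back,
    # which keeps the knee extension demand physiological in deep crouches
    dip = com_y.max() - com_y
    tilt = -config.trunk_lean_gain * dip
    lumbar = np.zeros(N)
    q = np.zeros((N, nq))
    ankle_target = np.stack([np.zeros(N), ankle_h0 - delta], axis=1)
    residual_max = np.inf

    for it in range(n_tilt_iters):
        # stance: fixed-point between pelvis placement and leg IK
        q[:, iq["pelvis_tilt"]] = tilt
        q[:, iq["lumbar"]] = lumbar
        pelvis = np.stack([com_x, com_y], axis=1) - _com_offset(model, q)
        for _ in range(10):
            hip_s, knee_s, ankle_s = _leg_ik(model, pelvis[stance], tilt[stance],
                                             ankle_target[stance])
            q[stance, iq["hip"]] = hip_s
            q[stance, iq["knee"]] = knee_s
            q[stance, iq["ankle"]] = ankle_s
            pelvis = np.stack([com_x, com_y], axis=1) - _com_offset(model, q)
        # flight: Hermite blend of the three leg angles between lift-off
        # and (next) touchdown postures
        i_lo = int(np.sum(stance)) - 1
        fl = ~stance
        for name in ("hip", "knee", "ankle"):
            j = iq[name]
            # one-sided boundary rates/curvatures from within the stance phase
            v_lo = (q[i_lo, j] - q[i_lo - 2, j]) / (2 * dt)
            v_td = (-3 * q[0, j] + 4 * q[1, j] - q[2, j]) / (2 * dt)
            a_lo = (q[i_lo, j] - 2 * q[i_lo - 1, j] + q[i_lo - 2, j]) / dt**2
            a_td = (q[0, j] - 2 * q[1, j] + q[2, j]) / dt**2
            q[fl, j] = _hermite(t[fl], t[i_lo], P, q[i_lo, j], q[0, j],
                                v_lo, v_td, a_lo, a_td)
        # extra knee flexion in flight guarantees foot-ground clearance
        # (sin^3 bump: zero value/rate/curvature at both boundaries); the
        # ankle counter-rotates so the sole stays parallel to the ground
        s_fl = (t[fl] - t[i_lo]) / (P - t[i_lo])
        bump = 0.12 * np.sin(np.pi * s_fl) ** 3
        q[fl, iq["knee"]] += bump
        q[fl, iq["ankle"]] += bump
        pelvis = np.stack([com_x, com_y], axis=1) - _com_offset(model, q)
        q[:, iq["pelvis_tx"]] = pelvis[:, 0]
        q[:, iq["pelvis_ty"]] = pelvis[:, 1]

        # root-moment residual -> tilt correction
        qd = _periodic_gradient(q, dt)
        qdd = _periodic_gradient(qd, dt)
        kin = ChainKinematics(model, q, qd, qdd)
        ext = _external_forces(model, kin, fn_sphere, bwss)
        tau = inverse_dynamics(q, qd, qdd, ext, model, kin=kin)
        residual_max = float(np.abs(tau[:, 2]).max())
        if it == n_tilt_iters - 1:
            break
        # absorb the residual with a torso (lumbar) counter-rotation: the
        # torso holds most of the inertia and does not disturb the leg IK
        ti = model._seg_index["torso"]
        torso = model.segments[ti]
        lever2 = ((kin.com[ti] - kin.origin[0]) ** 2).sum(axis=-1)
        i_eff = torso.inertia_zz + torso.mass * lever2
        lumbar = lumbar + 0.8 * _periodic_double_integral(-tau[:, 2] / i_eff, P)

    sphere_forces = np.zeros((N, n_spheres, 2))
    for si in range(n_spheres):
        sphere_forces[:, si, 1] = fn_sphere
    grf = sphere_forces.sum(axis=1)
    # centre of pressure (world x); mid-foot when unloaded
    sphere_x = np.stack([kin.point("foot", np.asarray(s.position))[0][:, 0]
                         for s in model.contact_spheres], axis=1)
    w = sphere_forces[:, :, 1]
    cop_x = np.where(w.sum(1) > 1.0, (sphere_x * w).sum(1) / np.maximum(w.sum(1), 1e-9),
                     sphere_x.mean(1))
    return ReferenceMotion(period=P, contact_time=tc, t=t, q=q,
                           sphere_forces=sphere_forces, grf=grf, cop_x=cop_x,
                           bwss=bwss, g_level=g_level,
                           residual_moment_max=residual_max)


def _external_forces(model: ModelSpec, kin: ChainKinematics, fn_sphere: np.ndarray,
                     bwss: float):
    T = len(fn_sphere)
    ext = []
    for s in model.contact_spheres:
        f = np.zeros((T, 2))
        f[:, 1] = fn_sphere
        ext.append(("foot", np.asarray(s.position), f))
    fb = np.zeros((T, 2))
    fb[:, 1] = bwss
    pelvis = model.segments[0]
    ext.append((pelvis.name, np.asarray(pelvis.com_offset), fb))
    return ext


# ---------------------------------------------------------------------------
# trial generation
# ---------------------------------------------------------------------------


def generate_condition_trial(model: ModelSpec, config: SynthConfig, g_level: float,
                             trial_index: int = 0, noise: bool = True) -> RawTrial:
    """One synthetic trial: ~2 hopping cycles plus margins, sampled at the
    recording rates, with additive measurement noise."""
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, int(round(g_level * 100)), trial_index]))
    tc0 = config.contact_times.get(g_level, 0.30)
    tc = float(np.clip(tc0 + rng.normal(0.0, 0.005), 0.05, None))
    motion = generate_reference_motion(model, config, g_level, contact_time=tc)
    P = motion.period

    margin = 0.30
    t0, t1 = -margin, 2 * P + margin
    t_kin = np.arange(t0, t1, 1.0 / config.kinematics_rate)
    t_grf = np.arange(t0, t1, 1.0 / config.force_rate)

    q = motion.sample(t_kin, motion.q)
    grf = motion.sample(t_grf, motion.grf)
    cop = motion.sample(t_grf, motion.cop_x)
    bwss = np.full(len(t_grf), motion.bwss)

    if noise:
        ang = np.deg2rad(config.noise_kin_deg)
        q = q + rng.normal(0.0, ang, q.shape)
        # translations carry translation-scale, not angular-scale, noise
        q[:, :2] = motion.sample(t_kin, motion.q)[:, :2] + rng.normal(
            0.0, config.noise_trans_m, (len(t_kin), 2))
        grf = grf + rng.normal(0.0, config.noise_grf_N, grf.shape)

    meta = {
        "g_level": g_level, "trial_index": trial_index,
        "contact_time": tc, "period": P,
        "true_stiffness": config.contact_stiffness,
        "true_damping": config.contact_damping,
        "residual_moment_max": motion.residual_moment_max,
    }
    return RawTrial(time=t_kin - t0, q_raw=q, coordinate_names=list(model.coordinates),
                    grf_time=t_grf - t0, grf_raw=grf, bwss_raw=bwss,
                    mass=model.total_mass, g_level=g_level, cop_raw=cop, meta=meta)
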