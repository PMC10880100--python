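"""Raw trial time series -> tracking-ready data.

Pipeline: crop a window around two consecutive touchdowns, low-pass filter
(6 Hz, second-order Butterworth, applied zero-phase), resample everything
onto the collocation mesh with third-order B-splines (which also supply
velocities and accelerations), and run inverse dynamics to obtain the
experimental net joint moments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import make_interp_spline
from scipy.signal import butter, filtfilt

from .model_core import (GravityCondition, ModelSpec, bwss_external_force,
                         inverse_dynamics)

TOUCHDOWN_THRESHOLD = 10.0  # N, vertical GRF rising-edge threshold


@dataclass
class RawTrial:
    """One experimental (or synthetic) hopping trial as recorded.

    ``q_raw`` holds the generalized coordinates (rad / m) on the kinematics
    time grid; GRF and BWSS force streams may be sampled at a higher rate on
    their own grid.
    """

    time: np.ndarray  # s, kinematics grid
    q_raw: np.ndarray  # (T, n_coordinates)
    coordinate_names: list[str]
    grf_time: np.ndarray  # s
    grf_raw: np.ndarray  # (Tg, 2): horizontal, vertical (N)
    bwss_raw: np.ndarray  # (Tg,) vertical support force (N)
    mass: float
    g_level: float
    cop_raw: np.ndarray | None = None  # (Tg,) world-frame x of the centre of pressure
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        for t, label in ((self.time, "time"), (self.grf_time, "grf_time")):
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"{label} must be strictly increasing")


@dataclass
class TrackingData:
    """Preprocessed experimental data on the collocation mesh grid."""

    time: np.ndarray  # (N+1,)
    q: np.ndarray  # (N+1, nq)
    qd: np.ndarray
    qdd: np.ndarray
    njm_exp: np.ndarray  # (N+1, n_joints): moments of the non-root coordinates (N m)
    residuals_exp: np.ndarray  # (N+1, 3): pelvis residual force/moment from the data
    grf_exp: np.ndarray  # (N+1, 2) N
    bwss: np.ndarray  # (N+1,) N
    touchdown_times: tuple[float, float]
    mass: float
    g_level: float
    coordinate_names: list[str]
    joint_names: list[str]


def detect_touchdowns(grf_time: np.ndarray, grf_vertical: np.ndarray,
                      threshold: float = TOUCHDOWN_THRESHOLD,
                      min_duration: float = 0.05) -> np.ndarray:
    """Times at which the vertical GRF rises through the threshold and stays
    above it for at least ``min_duration`` (rejects sensor-noise crossings)."""
    dt = float(np.median(np.diff(grf_time)))
    n_hold = max(1, int(round(min_duration / dt)))
    above = grf_vertical >= threshold
    rising = np.where(~above[:-1] & above[1:])[0]
    out = []
    for i in rising:
        if not above[i + 1:i + 1 + n_hold].all():
            continue
        f0, f1 = grf_vertical[i], grf_vertical[i + 1]
        t0, t1 = grf_time[i], grf_time[i + 1]
        out.append(t0 + (threshold - f0) / (f1 - f0) * (t1 - t0))
    return np.asarray(out)


def crop_trial(raw: RawTrial, pre_window: float = 0.15,
               threshold: float = TOUCHDOWN_THRESHOLD, guard: float = 0.0) -> RawTrial:
    """Crop to [first touchdown - pre_window, second touchdown + pre_window]
    (intersected with the recorded time range).

    ``guard`` keeps extra samples on both sides as support for filtering and
    spline fitting; downstream resampling still targets the exact window.
    """
    tds = detect_touchdowns(raw.grf_time, raw.grf_raw[:, 1], threshold)
    if len(tds) < 2:
        raise ValueError(
            f"need two touchdowns to crop (found {len(tds)} with threshold {threshold} N)")
    td1, td2 = tds[0], tds[1]
    t_lo = max(td1 - pre_window - guard, raw.time[0], raw.grf_time[0])
    t_hi = min(td2 + pre_window + guard, raw.time[-1], raw.grf_time[-1])
    mk = (raw.time >= t_lo - 1e-12) & (raw.time <= t_hi + 1e-12)
    mg = (raw.grf_time >= t_lo - 1e-12) & (raw.grf_time <= t_hi + 1e-12)
    meta = dict(raw.meta)
    meta["touchdown_times"] = (float(td1), float(td2))
    return replace(raw, time=raw.time[mk], q_raw=raw.q_raw[mk],
                   grf_time=raw.grf_time[mg], grf_raw=raw.grf_raw[mg],
                   bwss_raw=raw.bwss_raw[mg],
                   cop_raw=None if raw.cop_raw is None else raw.cop_raw[mg],
                   meta=meta)


def lowpass_filter(signal: np.ndarray, fs: float, cutoff: float = 6.0,
                   order: int = 2) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter along axis 0.

    Forward-backward application doubles the effective order and squares the
    magnitude response; the -3 dB point of the single pass sits at
    ``cutoff``.
    """
    if fs <= 2 * cutoff:
        raise ValueError(f"sampling rate {fs} Hz too low for cutoff {cutoff} Hz")
    signal = np.asarray(signal, dtype=float)
    b, a = butter(order, cutoff, fs=fs)
    # pad over ~3 filter time constants so edge transients decay
    padlen = min(signal.shape[0] - 2, int(round(3 * fs / cutoff)))
    if padlen < 3 * (max(len(a), len(b)) - 1):
        raise ValueError(f"signal too short ({signal.shape[0]} samples) for stable filtering")
    return filtfilt(b, a, signal, axis=0, padlen=padlen)


def spline_resample(time: np.ndarray, signal: np.ndarray, time_out: np.ndarray):
    """Cubic B-spline resampling with first and second derivatives.

    Returns ``(value, d1, d2)`` evaluated at ``time_out``; derivatives are
    the exact derivatives of the fitted interpolating spline.
    """
    time = np.asarray(time, dtype=float)
    if np.any(np.diff(time) <= 0):
        raise ValueError("time must be strictly increasing")
    if len(time) < 4:
        raise ValueError("need at least 4 samples for a cubic spline")
    spl = make_interp_spline(time, np.asarray(signal, dtype=float), k=3, axis=0)
    return spl(time_out), spl.derivative(1)(time_out), spl.derivative(2)(time_out)


def compute_net_joint_moments(q, qd, qdd, grf, grf_point_world, bwss,
                              model: ModelSpec):
    """Inverse-dynamics generalized forces given total GRF applied at a
    world-frame point path (centre of pressure) and the BWSS force.

    Returns ``(njm, residuals)`` where ``njm`` covers the non-root
    coordinates and ``residuals`` the pelvis force/moment.
    """
    from .model_core import ChainKinematics
    T = np.atleast_2d(q).shape[0]
    kin = ChainKinematics(model, q, qd, qdd)
    # express the CoP as a foot-fixed material point per frame so the lever
    # arms are exact (the CoP travels along the foot during contact)
    foot_i = model._seg_index["foot"]
    c, s = np.cos(kin.phi[foot_i]), np.sin(kin.phi[foot_i])
    d = np.asarray(grf_point_world, dtype=float) - kin.origin[foot_i]
    local = np.stack([c * d[:, 0] + s * d[:, 1], -s * d[:, 0] + c * d[:, 1]], axis=1)
    pelvis = model.segments[0]
    bw = np.zeros((T, 2))
    bw[:, 1] = bwss
    ext = [("foot", local, np.asarray(grf, dtype=float)),
           (pelvis.name, np.asarray(pelvis.com_offset), bw)]
    tau = inverse_dynamics(q, qd, qdd, ext, model, kin=kin)
    return tau[:, 3:], tau[:, :3]


def preprocess_trial(raw: RawTrial, model: ModelSpec, n_mesh_intervals: int = 50,
                     cutoff: float = 6.0, pre_window: float = 0.15,
                     guard: float = 0.12) -> TrackingData:
    """Full preprocessing pipeline for one trial."""
    cropped = crop_trial(raw, pre_window, guard=guard)
    fs_kin = 1.0 / np.median(np.diff(cropped.time))
    fs_grf = 1.0 / np.median(np.diff(cropped.grf_time))
    q_f = lowpass_filter(cropped.q_raw, fs_kin, cutoff)
    grf_f = lowpass_filter(cropped.grf_raw, fs_grf, cutoff)
    bwss_f = lowpass_filter(cropped.bwss_raw, fs_grf, cutoff)

    td1, td2 = cropped.meta["touchdown_times"]
    t_lo = max(td1 - pre_window, cropped.time[0], cropped.grf_time[0])
    t_hi = min(td2 + pre_window, cropped.time[-1], cropped.grf_time[-1])
    t_out = np.linspace(t_lo, t_hi, n_mesh_intervals + 1)
    q, qd, qdd = spline_resample(cropped.time, q_f, t_out)
    grf, _, _ = spline_resample(cropped.grf_time, grf_f, t_out)
    bwss, _, _ = spline_resample(cropped.grf_time, bwss_f, t_out)

    if cropped.cop_raw is not None:
        cop_x = np.interp(t_out, cropped.grf_time, cropped.cop_raw)
    else:
        # force-weighted sphere positions are unknown for external data:
        # assume mid-foot.  Flight frames carry no moment anyway (GRF ~ 0).
        cop_x = np.full_like(t_out, 0.06)
    cop = np.stack([cop_x, np.zeros_like(cop_x)], axis=1)
    njm, residuals = compute_net_joint_moments(q, qd, qdd, grf, cop, bwss, model)
    return TrackingData(
        time=t_out, q=q, qd=qd, qdd=qdd, njm_exp=njm, residuals_exp=residuals,
        grf_exp=grf, bwss=bwss,
        touchdown_times=cropped.meta.get("touchdown_times", (np.nan, np.nan)),
        mass=raw.mass, g_level=raw.g_level,
        coordinate_names=list(raw.coordinate_names),
        joint_names=list(model.coordinates[3:]),
    )
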