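"""Muscle-adaptation model: normalised quadriceps force -> training volume.

The cross-sectional area (CSA, normalised to baseline = 1) grows according
to

    dCSA/dt = (1/tau) * (CSA_max - CSA)/(CSA_max - 1) * delta * max(F - F0, 0)

where F is the normalised quadriceps force and F0 the loading threshold
(0.2, i.e. 20% of summed maximum isometric force).  Growth-only: the drive
is clamped at zero below the threshold.  Because the right-hand side is
separable (a function of CSA times a function of time), the equation has a
closed-form solution for any force profile, which doubles as the oracle
for the numerical integrator used in :func:`simulate_growth`.

Repetitions are modelled as back-to-back repeats of one hopping cycle's
force profile; ``reps_to_target`` finds the smallest number reaching a
minimal worthwhile CSA increase (default +3.37%), and ``reps_to_schedule``
converts it to sets per session at 12 repetitions per set and 3 sessions
per week.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

TARGET_INCREASE = 0.0337  # minimal worthwhile CSA increase
REPS_PER_SET = 12
SESSIONS_PER_WEEK = 3


@dataclass(frozen=True)
class AdaptationParams:
    """Parameters of the CSA growth equation."""

    tau: float          # time-like rate constant (s of loading per unit drive)
    delta: float        # dimensionless gain
    csa_max: float      # normalised ceiling (> 1)
    csa0: float = 1.0   # baseline (normalised)
    f0: float = 0.2     # loading threshold (fraction of summed Fmax)

    def __post_init__(self):
        if not (self.csa_max > self.csa0 == 1.0):
            raise ValueError("need csa_max > csa0 = 1")
        if not (0 < self.f0 < 1):
            raise ValueError("f0 must be in (0, 1)")
        if self.tau <= 0 or self.delta <= 0:
            raise ValueError("tau and delta must be positive")


@dataclass(frozen=True)
class ForceProfile:
    """Normalised quadriceps force over one hopping cycle."""

    time: np.ndarray
    force: np.ndarray  # dimensionless, >= 0

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        f = np.asarray(self.force, dtype=float)
        if not (np.isfinite(t).all() and np.isfinite(f).all()):
            raise ValueError("non-finite force profile")
        if np.any(np.diff(t) <= 0):
            raise ValueError("profile time must be strictly increasing")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "force", f)

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])


@dataclass(frozen=True)
class TrainingVolume:
    reps_required: int | None  # None when the target is unreachable
    sets_per_session: int | None
    reps_per_set: int = REPS_PER_SET
    sessions_per_week: int = SESSIONS_PER_WEEK
    target_increase: float = TARGET_INCREASE

    @property
    def feasible(self) -> bool:
        return self.reps_required is not None


# ---------------------------------------------------------------------------
# Core rate equation
# ---------------------------------------------------------------------------


def csa_rate(csa, force, params: AdaptationParams):
    """Instantaneous CSA growth rate (clamped drive, growth only)."""
    csa = np.asarray(csa, dtype=float)
    if np.any(csa > params.csa_max * (1 + 1e-12)):
        raise ValueError("csa exceeds csa_max")
    drive = np.maximum(np.asarray(force, dtype=float) - params.f0, 0.0)
    return (1.0 / params.tau) * (params.csa_max - csa) / (params.csa_max - 1.0) \
        * params.delta * drive


def _drive_per_rep(profile: ForceProfile, params: AdaptationParams) -> float:
    """Integral of the clamped, scaled drive over one repetition."""
    u = params.delta / (params.tau * (params.csa_max - 1.0)) \
        * np.maximum(profile.force - params.f0, 0.0)
    return float(np.trapezoid(u, profile.time))


def csa_closed_form(csa0: float, drive_integral: float, params: AdaptationParams) -> float:
    """Exact solution of the separable growth equation after accumulating a
    given drive integral."""
    return params.csa_max - (params.csa_max - csa0) * math.exp(-drive_integral)


def simulate_growth(profile: ForceProfile, params: AdaptationParams,
                    n_reps: int) -> np.ndarray:
    """CSA after each of ``n_reps`` concatenated repetitions (adaptive ODE
    integration of the rate equation; monotone non-decreasing)."""
    if n_reps < 0:
        raise ValueError("n_reps must be >= 0")
    t = profile.time - profile.time[0]
    dur = profile.duration
    csa = params.csa0
    out = np.empty(n_reps + 1)
    out[0] = csa

    def rhs(tt, y):
        f = np.interp(tt, t, profile.force)
        return csa_rate(min(y[0], params.csa_max), f, params)

    for r in range(n_reps):
        sol = solve_ivp(rhs, (0.0, dur), [csa], rtol=1e-10, atol=1e-12,
                        dense_output=False)
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        csa = min(float(sol.y[0, -1]), params.csa_max)
        out[r + 1] = csa
    return out


def reps_to_target(profile: ForceProfile, params: AdaptationParams,
                   target: float | None = None) -> int | None:
    """Smallest repetition count whose end-state CSA reaches ``target``
    (default baseline + 3.37%); ``None`` when unreachable."""
    target = (1.0 + TARGET_INCREASE) * params.csa0 if target is None else target
    if target <= params.csa0:
        return 0
    if target > params.csa_max:
        return None
    D = _drive_per_rep(profile, params)
    if D <= 0:
        return None
    # closed form of the separable equation: CSA_n = max - (max - 1) e^{-nD}
    n_exact = math.log((params.csa_max - params.csa0)
                       / (params.csa_max - target)) / D
    return int(math.ceil(n_exact - 1e-9))


def reps_to_schedule(reps_required: int | None,
                     reps_per_set: int = REPS_PER_SET,
                     sessions_per_week: int = SESSIONS_PER_WEEK) -> int | None:
    """Sets per session under a week-normalised convention:
    ceil(reps / reps_per_set / sessions_per_week)."""
    if reps_required is None:
        return None
    if reps_required < 0:
        raise ValueError("reps_required must be >= 0")
    return math.ceil(reps_required / reps_per_set / sessions_per_week)


def training_volume(profile: ForceProfile, params: AdaptationParams,
                    target_increase: float = TARGET_INCREASE) -> TrainingVolume:
    reps = reps_to_target(profile, params, (1.0 + target_increase) * params.csa0)
    return TrainingVolume(reps_required=reps,
                          sets_per_session=reps_to_schedule(reps),
                          target_increase=target_increase)


# ---------------------------------------------------------------------------
# Calibration of the default parameters
# ---------------------------------------------------------------------------

#: Reference condition for the shipped defaults: a resistance-training
#: programme in untrained young men reaches the minimal worthwhile increase
#: after roughly two weeks, i.e. ~6 sets x 12 reps x 3 sessions = 216
#: repetitions at a high relative load (70% of maximum), each repetition
#: loading the muscle for about 3 s.
DEFAULT_REFERENCE = {"reps": 216, "force": 0.70, "rep_duration": 3.0,
                     "target_increase": TARGET_INCREASE}
DEFAULT_CSA_MAX = 1.40


def calibrate_adaptation(reference: dict | None = None,
                         csa_max: float = DEFAULT_CSA_MAX) -> AdaptationParams:
    """Fit tau (with delta fixed at 1) so that the reference constant-force
    schedule reproduces the reference repetition count within one rep."""
    ref = dict(DEFAULT_REFERENCE)
    if reference:
        ref.update(reference)
    target = 1.0 + ref["target_increase"]
    if target > csa_max:
        raise ValueError("reference target exceeds csa_max")
    if ref["force"] <= 0.2:
        raise ValueError("reference force must exceed the threshold F0")

    def reps_for_tau(tau):
        params = AdaptationParams(tau=tau, delta=1.0, csa_max=csa_max)
        D = (ref["force"] - params.f0) * ref["rep_duration"] * params.delta \
            / (params.tau * (csa_max - 1.0))
        return math.log((csa_max - 1.0) / (csa_max - target)) / D

    tau = brentq(lambda x: reps_for_tau(x) - ref["reps"], 1e-3, 1e6,
                 xtol=1e-12, rtol=1e-12)
    params = AdaptationParams(tau=tau, delta=1.0, csa_max=csa_max)
    # verify the round trip on the actual simulator
    prof = ForceProfile(time=np.linspace(0, ref["rep_duration"], 50),
                        force=np.full(50, ref["force"]))
    got = reps_to_target(prof, params, target)
    if got is None or abs(got - ref["reps"]) > 1:
        raise RuntimeError(f"calibration failed: {got} vs {ref['reps']} reps")
    return params


def default_adaptation_params() -> AdaptationParams:
    return calibrate_adaptation()
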