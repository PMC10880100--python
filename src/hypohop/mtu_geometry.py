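"""Polynomial parameterisation of MTU lengths, velocities and moment arms.

Inside the tracking problem, muscle geometry is evaluated thousands of
times, so exact path-point geometry is replaced by multivariate polynomials
of the spanned joint coordinates, fitted once per model by least squares on
randomly sampled poses.  Moment arms are the analytic derivatives of the
fitted length polynomial (r_k = -dL/dq_k), which makes length, velocity and
moment arms mutually consistent by construction.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field

import numpy as np

from .model_core import ModelSpec, MTUParams, mtu_length, mtu_moment_arm, reference_pose


@dataclass
class MTUPolynomial:
    """Fitted length polynomial for one MTU.

    ``coefficients[i]`` multiplies the monomial with exponent tuple
    ``exponents[i]`` over ``spanned_coordinates``.  ``fit_domain`` records the
    per-coordinate ranges the fit covers; evaluation outside is allowed but a
    soft warning is attached to the result object at fit time.
    """

    mtu_name: str
    spanned_coordinates: tuple[str, ...]
    exponents: np.ndarray  # (n_terms, n_coords) integer
    coefficients: np.ndarray  # (n_terms,)
    degree: int
    fit_domain: dict[str, tuple[float, float]]
    fit_error: float  # max |length residual| over training poses (m)

    def _power_table(self, Q: np.ndarray) -> np.ndarray:
        """P[c, e, :] = Q[:, c]**e for e = 0..degree (shared by value/grad)."""
        n, nc = Q.shape
        P = np.ones((nc, self.degree + 1, n))
        for c in range(nc):
            for e in range(1, self.degree + 1):
                P[c, e] = P[c, e - 1] * Q[:, c]
        return P

    def _vander(self, Q: np.ndarray) -> np.ndarray:
        """Monomial design matrix for poses Q of shape (n, n_coords)."""
        P = self._power_table(Q)
        V = np.ones((Q.shape[0], len(self.exponents)))
        for c in range(Q.shape[1]):
            V *= P[c, self.exponents[:, c]].T
        return V

    def _vander_grad(self, Q: np.ndarray, c: int) -> np.ndarray:
        P = self._power_table(Q)
        e_c = self.exponents[:, c]
        V = np.where(e_c > 0, e_c, 0).astype(float) * np.ones((Q.shape[0], 1))
        ed = np.maximum(e_c - 1, 0)
        for cc in range(Q.shape[1]):
            exps = ed if cc == c else self.exponents[:, cc]
            V *= P[cc, exps].T
        return V

    def length(self, Q: np.ndarray) -> np.ndarray:
        return self._vander(np.atleast_2d(Q)) @ self.coefficients

    def moment_arms(self, Q: np.ndarray) -> np.ndarray:
        """(n, n_coords): r_k = -dL/dq_k for each spanned coordinate."""
        Q = np.atleast_2d(Q)
        out = np.empty((Q.shape[0], len(self.spanned_coordinates)))
        for c in range(len(self.spanned_coordinates)):
            out[:, c] = -(self._vander_grad(Q, c) @ self.coefficients)
        return out


def _monomial_exponents(n_coords: int, degree: int) -> np.ndarray:
    exps = [e for e in itertools.product(range(degree + 1), repeat=n_coords)
            if sum(e) <= degree]
    exps.sort(key=lambda e: (sum(e), e))
    return np.array(exps, dtype=int)


def sample_training_poses(ranges: dict[str, tuple[float, float]], n: int, seed: int,
                          degree: int = 4) -> dict[str, np.ndarray]:
    """Uniform random poses over the per-coordinate intervals (deterministic
    for a given seed)."""
    n_coords = len(ranges)
    n_terms = len(_monomial_exponents(n_coords, degree))
    if n < 2 * n_terms:
        raise ValueError(
            f"n={n} poses insufficient for degree {degree} in {n_coords} coordinates; "
            f"need at least {2 * n_terms}")
    rng = np.random.default_rng(seed)
    out = {}
    for name, (lo, hi) in ranges.items():
        out[name] = rng.uniform(lo, hi, size=n)
    return out


def fit_mtu_polynomials(model: ModelSpec, mtu: MTUParams, degree: int = 4,
                        n_poses: int = 2000, seed: int = 0,
                        rom_margin: float = 0.2, tol: float = 2e-3) -> MTUPolynomial:
    """Fit the length polynomial of one MTU against the exact via-point path
    geometry, sampling poses over the ROM extended by ``rom_margin``."""
    spanned = tuple(mtu.spanned_coordinates)
    ranges = {}
    for c in spanned:
        lo, hi = model.coordinate_ranges[c]
        half = 0.5 * (hi - lo) * rom_margin
        ranges[c] = (lo - half, hi + half)
    poses = sample_training_poses(ranges, n_poses, seed, degree)
    qref = reference_pose(model)
    Qfull = np.tile(qref, (n_poses, 1))
    Qs = np.empty((n_poses, len(spanned)))
    for j, c in enumerate(spanned):
        Qfull[:, model.coordinate_index(c)] = poses[c]
        Qs[:, j] = poses[c]
    L = mtu_length(model, mtu, Qfull)

    poly = MTUPolynomial(
        mtu_name=mtu.name, spanned_coordinates=spanned,
        exponents=_monomial_exponents(len(spanned), degree),
        coefficients=np.zeros(0), degree=degree, fit_domain=ranges, fit_error=np.nan)
    V = poly._vander(Qs)
    cond = np.linalg.cond(V)
    if cond > 1e10:
        raise np.linalg.LinAlgError(
            f"ill-conditioned normal equations for {mtu.name} (cond={cond:.1e}); "
            "reduce the polynomial degree")
    coef, *_ = np.linalg.lstsq(V, L, rcond=None)
    poly.coefficients = coef
    poly.fit_error = float(np.abs(V @ coef - L).max())
    if poly.fit_error > tol:
        raise ValueError(
            f"{mtu.name}: polynomial fit error {poly.fit_error:.2e} m exceeds {tol:.0e}; "
            "increase the degree or sample count")
    return poly


def eval_mtu(poly: MTUPolynomial, q, qd=None):
    """Length, lengthening velocity and moment arms at poses ``q`` (values of
    the spanned coordinates only, shape (n, n_spanned)).

    The velocity is the chain-rule contraction v = -sum_k r_k qd_k.
    """
    q = np.atleast_2d(np.asarray(q, dtype=float))
    length = poly.length(q)
    arms = poly.moment_arms(q)
    if qd is None:
        vel = np.zeros_like(length)
    else:
        qd = np.atleast_2d(np.asarray(qd, dtype=float))
        vel = -(arms * qd).sum(axis=1)
    return length, vel, arms


@dataclass
class GeometrySet:
    """Fitted polynomials for every MTU of a model, with a content hash for
    caching alongside the model configuration."""

    polynomials: dict[str, MTUPolynomial]
    cache_key: str

    def __getitem__(self, name: str) -> MTUPolynomial:
        return self.polynomials[name]


_GEOMETRY_CACHE: dict[str, GeometrySet] = {}


def fit_model_geometry(model: ModelSpec, degree: int = 4, n_poses: int = 2000,
                       seed: int = 0, rom_margin: float = 0.2) -> GeometrySet:
    """Fit polynomials for all MTUs of a model (memoised on a hash of the
    geometry, ranges, seed and degree)."""
    key_src = json.dumps([
        [[m.name, m.path, list(m.spanned_coordinates)] for m in model.mtus],
        {c: model.coordinate_ranges[c] for c in sorted(model.coordinate_ranges)},
        degree, n_poses, seed, rom_margin,
    ], default=str)
    key = hashlib.sha256(key_src.encode()).hexdigest()[:16]
    if key in _GEOMETRY_CACHE:
        return _GEOMETRY_CACHE[key]
    polys = {m.name: fit_mtu_polynomials(model, m, degree, n_poses, seed, rom_margin)
             for m in model.mtus}
    gs = GeometrySet(polynomials=polys, cache_key=key)
    _GEOMETRY_CACHE[key] = gs
    return gs
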