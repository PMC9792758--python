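"""Dipole forward model, moment inversion, lead fields, and inverse solvers.

The forward model is a current dipole in an infinite homogeneous medium.  Two
conventions coexist deliberately:

* The *field* operations (:func:`dipole_field`, :func:`moment_from_field`)
  implement the electrostatic dipole equations with the vacuum permittivity
  eps0, exactly as the guiding transfer-matrix algebra is usually written:
  ``E = M(e) P0 / (4 pi eps0 r^3)`` with ``M = 3 e e^T - I``.
* The *scalp potential* operation uses the volume-conductor form with tissue
  conductivity sigma, ``V = p . d / (4 pi sigma |d|^3)``, average-referenced
  over the montage.  The constant choice rescales recovered moments but never
  source positions.

Inverse solvers: a guided single-dipole fit (coarse grid + Nelder-Mead
refinement, moment solved in closed form), and an eLORETA distributed inverse
(standard fixed-point weight iteration, zero localization error for noiseless
point sources at grid nodes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .errors import (
    ConvergenceError,
    DegenerateInputError,
    GeometryError,
    SingularityError,
)
from .montage import Montage

EPSILON0 = 8.8541878128e-12  # vacuum permittivity, F/m


@dataclass(frozen=True)
class PhysicalConstants:
    epsilon0: float = EPSILON0     # F/m, used by the field/moment equations
    sigma: float = 0.33            # S/m, brain conductivity for potentials

    def __post_init__(self) -> None:
        if self.epsilon0 <= 0 or self.sigma <= 0:
            raise ValueError("physical constants must be positive")


@dataclass(frozen=True)
class Dipole:
    """Current dipole: position r0 (m, head coordinates) and moment p (A*m)."""

    r0: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "r0", np.asarray(self.r0, dtype=float))
        object.__setattr__(self, "p", np.asarray(self.p, dtype=float))
        if self.r0.shape != (3,) or self.p.shape != (3,):
            raise ValueError("r0 and p must be 3-vectors")
        if not (np.isfinite(self.r0).all() and np.isfinite(self.p).all()):
            raise ValueError("r0 and p must be finite")


@dataclass(frozen=True)
class TargetRegion:
    """Spherical target region, e.g. the calcarine ball."""

    center: np.ndarray = field(
        default_factory=lambda: np.array([0.0, -0.065, 0.0]))
    radius: float = 0.015
    name: str = "calcarine"

    def __post_init__(self) -> None:
        object.__setattr__(self, "center",
                           np.asarray(self.center, dtype=float))
        if self.radius <= 0:
            raise ValueError("region radius must be positive")


@dataclass
class LeadField:
    """Gain matrix A (n_channels x 3*n_grid) with its source grid."""

    A: np.ndarray
    grid: np.ndarray              # (n_grid, 3) source positions, m
    reference: str = "average"

    @property
    def n_grid(self) -> int:
        return self.grid.shape[0]


@dataclass
class SourceEstimate:
    """Distributed-inverse output: moment magnitude per grid point."""

    grid: np.ndarray
    magnitude: np.ndarray
    alpha: float

    def argmax_position(self) -> np.ndarray:
        return self.grid[int(np.argmax(self.magnitude))]


def transfer_matrix(e_hat: np.ndarray) -> np.ndarray:
    """M = 3 e e^T - I for a unit observation direction e.

    Symmetric with eigenvalues {2, -1, -1}; the closed-form inverse is
    ``M^-1 = (1/2) e e^T - (I - e e^T)``.
    """
    e = np.asarray(e_hat, dtype=float)
    if e.shape != (3,) or abs(np.linalg.norm(e) - 1.0) > 1e-9:
        raise ValueError("e_hat must be a unit 3-vector")
    return 3.0 * np.outer(e, e) - np.eye(3)


def transfer_matrix_inverse(e_hat: np.ndarray) -> np.ndarray:
    """Closed-form inverse of the transfer matrix."""
    e = np.asarray(e_hat, dtype=float)
    if e.shape != (3,) or abs(np.linalg.norm(e) - 1.0) > 1e-9:
        raise ValueError("e_hat must be a unit 3-vector")
    ee = np.outer(e, e)
    return 0.5 * ee - (np.eye(3) - ee)


def dipole_field(p0: np.ndarray, r: np.ndarray,
                 constants: PhysicalConstants = PhysicalConstants(),
                 r0: np.ndarray | None = None) -> np.ndarray:
    """Electric field of a dipole with moment ``p0`` observed at ``r``.

    ``E = M(e) p0 / (4 pi eps0 |r - r0|^3)`` with e the unit vector from the
    dipole (default: the origin) to the observation point.
    """
    p0 = np.asarray(p0, dtype=float)
    d = np.asarray(r, dtype=float) - (0.0 if r0 is None else np.asarray(r0))
    dist = float(np.linalg.norm(d))
    if dist == 0.0:
        raise SingularityError("observation point coincides with the dipole")
    e = d / dist
    M = 3.0 * np.outer(e, e) - np.eye(3)
    return M @ p0 / (4.0 * np.pi * constants.epsilon0 * dist ** 3)


def dipole_field_polar(p0_mag: float, r_dist: float, theta: float,
                       constants: PhysicalConstants = PhysicalConstants()
                       ) -> tuple[float, float]:
    """Polar dipole field: components along (e_r, e_phi).

    ``E = p0 / (4 pi eps0 r^3) * (2 cos(theta) e_r + sin(theta) e_phi)``
    where theta is the angle between the moment and the observation direction.
    Returns the (radial, tangential) components.
    """
    if r_dist <= 0:
        raise SingularityError("r must be positive")
    k = p0_mag / (4.0 * np.pi * constants.epsilon0 * r_dist ** 3)
    return 2.0 * k * np.cos(theta), k * np.sin(theta)


def moment_from_field(E: np.ndarray, r: np.ndarray, r0: np.ndarray,
                      constants: PhysicalConstants = PhysicalConstants()
                      ) -> np.ndarray:
    """Invert the dipole field: ``P0 = 4 pi eps0 |r-r0|^3 M(e)^-1 E``."""
    d = np.asarray(r, dtype=float) - np.asarray(r0, dtype=float)
    dist = float(np.linalg.norm(d))
    if dist == 0.0:
        raise SingularityError("observation point coincides with the dipole")
    e = d / dist
    Minv = transfer_matrix_inverse(e)
    return 4.0 * np.pi * constants.epsilon0 * dist ** 3 * (Minv @ np.asarray(E))


def _potential_gain(r0: np.ndarray, positions: np.ndarray,
                    sigma: float) -> np.ndarray:
    """(n_sensors, 3) gain: V = G @ p for a dipole at r0 (no re-reference)."""
    d = positions - r0[None, :]
    dist = np.linalg.norm(d, axis=1)
    if np.any(dist == 0.0):
        raise SingularityError("dipole coincides with a sensor")
    return d / (4.0 * np.pi * sigma * dist ** 3)[:, None]


def scalp_potentials(dipole: Dipole, montage: Montage,
                     constants: PhysicalConstants = PhysicalConstants()
                     ) -> np.ndarray:
    """Average-referenced scalp potentials (V) of a dipole on the montage."""
    if np.linalg.norm(dipole.r0) >= montage.sphere_radius:
        raise GeometryError("dipole must lie strictly inside the head sphere")
    G = _potential_gain(dipole.r0, montage.positions, constants.sigma)
    v = G @ dipole.p
    return v - v.mean()


def build_lead_field(montage: Montage, spacing: float = 0.01,
                     head_radius: float | None = None,
                     interior_fraction: float = 0.85,
                     constants: PhysicalConstants = PhysicalConstants()
                     ) -> LeadField:
    """Regular interior grid (|r| <= interior_fraction * radius) lead field.

    Three columns per grid point: average-referenced potentials of unit
    moments along x, y, z.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    R = montage.sphere_radius if head_radius is None else head_radius
    rmax = interior_fraction * R
    ax = np.arange(-rmax, rmax + spacing / 2, spacing)
    # center the lattice on the origin
    ax = ax - (ax[0] + ax[-1]) / 2.0
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    grid = pts[np.linalg.norm(pts, axis=1) <= rmax]
    if grid.shape[0] == 0:
        raise ValueError("grid spec produced no interior points")
    pos = montage.positions
    n_ch = pos.shape[0]
    A = np.empty((n_ch, 3 * grid.shape[0]))
    for i, r0 in enumerate(grid):
        G = _potential_gain(r0, pos, constants.sigma)     # (n_ch, 3)
        G = G - G.mean(axis=0, keepdims=True)             # average reference
        A[:, 3 * i:3 * i + 3] = G
    return LeadField(A=A, grid=grid)


def accuracy_weights(accuracy: np.ndarray) -> tuple[np.ndarray, bool]:
    """Per-channel weights from one subject's accuracy row.

    ``w_c = max(accuracy_c - 0.5, 0)`` normalized to sum 1.  If every channel
    is at or below chance the weights fall back to uniform and the returned
    flag is True.
    """
    acc = np.asarray(accuracy, dtype=float)
    w = np.clip(acc - 0.5, 0.0, None)
    total = w.sum()
    if total <= 0.0:
        n = acc.size
        return np.full(n, 1.0 / n), True
    return w / total, False


def _solve_moment(r0: np.ndarray, y: np.ndarray, positions: np.ndarray,
                  w: np.ndarray, sigma: float) -> tuple[np.ndarray, float]:
    """Weighted least-squares moment at a candidate position; returns
    (moment, weighted residual sum of squares)."""
    G = _potential_gain(r0, positions, sigma)
    G = G - G.mean(axis=0, keepdims=True)
    sw = np.sqrt(w)
    p, *_ = np.linalg.lstsq(G * sw[:, None], y * sw, rcond=None)
    resid = y - G @ p
    return p, float(np.sum(w * resid ** 2))


def fit_single_dipole(y: np.ndarray, montage: Montage,
                      weights: np.ndarray | None = None,
                      constants: PhysicalConstants = PhysicalConstants(),
                      grid_spacing: float = 0.01,
                      interior_fraction: float = 0.85,
                      xatol: float = 1e-4) -> tuple[Dipole, float]:
    """Guided single-dipole fit.

    Minimizes the weighted squared misfit between ``y`` and the forward
    potentials over the dipole position (coarse interior grid search followed
    by Nelder-Mead refinement to ``xatol`` meters), solving the moment in
    closed form at every candidate position.  Returns the fitted dipole and
    the weighted residual fraction (0 = perfect fit).
    """
    y = np.asarray(y, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("y must be finite")
    if not np.any(y):
        raise DegenerateInputError("y is identically zero")
    n_ch = y.size
    if weights is None:
        w = np.full(n_ch, 1.0 / n_ch)
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be non-negative, not all zero")
        w = w / w.sum()
    pos = montage.positions
    sigma = constants.sigma
    rmax = interior_fraction * montage.sphere_radius

    ax = np.arange(-rmax, rmax + grid_spacing / 2, grid_spacing)
    ax = ax - (ax[0] + ax[-1]) / 2.0
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    pts = pts[np.linalg.norm(pts, axis=1) <= rmax]

    scores = np.array([_solve_moment(r0, y, pos, w, sigma)[1]
                       for r0 in pts])

    def objective(r0: np.ndarray) -> float:
        if np.linalg.norm(r0) >= 0.98 * montage.sphere_radius:
            return np.inf
        return _solve_moment(r0, y, pos, w, sigma)[1]

    # multi-start local refinement: deep or inferior sources can leave
    # shallow local minima, so refine from several coarse candidates
    best_r0, best_rss = None, np.inf
    for idx in np.argsort(scores)[:4]:
        res = minimize(objective, pts[idx], method="Nelder-Mead",
                       options={"xatol": xatol, "fatol": 0.0,
                                "maxiter": 2000})
        rss = objective(res.x)
        if rss < best_rss:
            best_r0, best_rss = res.x, rss
    r0 = best_r0
    p, rss = _solve_moment(r0, y, pos, w, sigma)
    total = float(np.sum(w * y ** 2))
    return Dipole(r0=r0, p=p), rss / total


def eloreta_inverse(y: np.ndarray, lead_field: LeadField,
                    alpha: float = 1e-6, tol: float = 1e-6,
                    max_iter: int = 500) -> SourceEstimate:
    """eLORETA distributed inverse.

    Standard fixed-point iteration on 3x3 per-source weight blocks
    ``W_i = [A_i^T (A W^-1 A^T + alpha H)^+ A_i]^(1/2)`` until the relative
    weight change drops below ``tol``, then the weighted minimum-norm
    estimate ``x = W^-1 A^T (A W^-1 A^T + alpha H)^+ y``.  ``alpha`` scales
    the average-reference-centered regularizer relative to the mean sensor
    variance of the weighted gain.  Returns per-point moment magnitudes.
    """
    y = np.asarray(y, dtype=float)
    A = lead_field.A
    n_ch = A.shape[0]
    n_src = lead_field.n_grid
    if not np.isfinite(y).all() or y.shape != (n_ch,):
        raise ValueError("y must be a finite vector matching the lead field")
    H = np.eye(n_ch) - np.ones((n_ch, n_ch)) / n_ch  # avg-ref centering
    A3 = A.reshape(n_ch, n_src, 3)

    Winv = np.tile(np.eye(3), (n_src, 1, 1))
    for _ in range(max_iter):
        # K = A W^-1 A^T, accumulated per source block
        AW = np.einsum("csk,skl->csl", A3, Winv)
        K = np.einsum("csl,dsl->cd", AW, A3)
        lam = alpha * np.trace(K) / n_ch
        Kinv = np.linalg.pinv(K + lam * H, hermitian=True)
        # N_i = A_i^T Kinv A_i, stacked (n_src, 3, 3)
        KA = np.einsum("cd,dsk->csk", Kinv, A3)
        N = np.einsum("csk,csl->skl", A3, KA)
        N = (N + N.transpose(0, 2, 1)) / 2.0
        evals, evecs = np.linalg.eigh(N)
        evals = np.clip(evals, 0.0, None)
        sq = np.sqrt(evals)
        W_new = evecs @ (sq[..., None] * evecs.transpose(0, 2, 1))
        inv_sq = np.where(sq > 0, 1.0 / np.where(sq > 0, sq, 1.0), 0.0)
        Winv_new = evecs @ (inv_sq[..., None] * evecs.transpose(0, 2, 1))
        delta = np.linalg.norm(W_new - _W_from_inv(Winv)) / max(
            np.linalg.norm(W_new), 1e-300)
        Winv = Winv_new
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            f"eLORETA weights did not converge in {max_iter} iterations")

    AW = np.einsum("csk,skl->csl", A3, Winv)
    K = np.einsum("csl,dsl->cd", AW, A3)
    lam = alpha * np.trace(K) / n_ch
    Kinv = np.linalg.pinv(K + lam * H, hermitian=True)
    x = np.einsum("skl,csl,c->sk", Winv, A3, Kinv @ y)
    mag = np.linalg.norm(x, axis=1)
    return SourceEstimate(grid=lead_field.grid, magnitude=mag, alpha=alpha)


def _W_from_inv(Winv: np.ndarray) -> np.ndarray:
    """Invert a stack of symmetric PSD 3x3 blocks (pseudo-inverse)."""
    evals, evecs = np.linalg.eigh(Winv)
    inv = np.where(evals > 0, 1.0 / np.where(evals > 0, evals, 1.0), 0.0)
    return evecs @ (inv[..., None] * evecs.transpose(0, 2, 1))


def line_region_test(dipole: Dipole, region: TargetRegion
                     ) -> tuple[bool, float]:
    """Does the dipole's orientation line pass through the target ball?

    The line is ``r0 + t * p_hat`` for t in R.  Returns (hit, minimum
    distance from the line to the region center in meters).
    """
    p_norm = float(np.linalg.norm(dipole.p))
    if p_norm == 0.0:
        raise DegenerateInputError("dipole moment is zero")
    p_hat = dipole.p / p_norm
    delta = region.center - dipole.r0
    perp = delta - np.dot(delta, p_hat) * p_hat
    dist = float(np.linalg.norm(perp))
    return dist <= region.radius, dist
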