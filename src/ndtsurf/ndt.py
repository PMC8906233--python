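"""3D normal-distributions-transform (NDT) registration.

The reference surface is voxelised into a regular grid; each occupied cell
is summarised by the sample mean and covariance of its points.  A current
point falling in a cell is scored under a Gaussian-inlier / uniform-outlier
mixture whose negative log is approximated by a single exponential term
(the classic point-to-distribution NDT construction), so each point
contributes

    s_i = -d1 * exp(-d2/2 * (x_i' - mu)^T Sigma^{-1} (x_i' - mu))

where ``x_i'`` is the transformed point and the constants ``d1 > 0`` and
``d2 > 0`` follow from the assumed outlier mass and the cell volume.  Points
in unoccupied cells sit at the uniform-outlier baseline, which is the zero
level of the score.  The total score is minimised over the 6 pose
parameters by Newton's method with analytic gradient and Hessian,
positive-definiteness damping, and step halving.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .base import (MAX_ITERATIONS, MIN_ROTATION_STEP, MIN_TRANSLATION_STEP,
                   BaseSurfaceRegistration, RegistrationResult)
from .geometry import RigidTransform, _axis_rotations, as_cloud

__all__ = ["NDTCell", "NDTGrid", "NDTRegistration", "build_ndt_grid",
           "ndt_score", "ndt_register", "mixture_constants"]

# so(3) generators: d/da exp(a G_k) at 0
_GX = np.array([[0., 0, 0], [0, 0, -1], [0, 1, 0]])
_GY = np.array([[0., 0, 1], [0, 0, 0], [-1, 0, 0]])
_GZ = np.array([[0., -1, 0], [1, 0, 0], [0, 0, 0]])
_DEG = np.pi / 180.0


@dataclass
class NDTCell:
    """Sufficient statistics of one occupied grid cell."""

    count: int
    mu: np.ndarray          # mean, mm
    sigma: np.ndarray       # regularised covariance, mm^2
    sigma_inv: np.ndarray


def mixture_constants(outlier_mass: float, cell_volume: float):
    """Exponential-approximation constants (d1, d2) of the per-cell mixture.

    The cell likelihood is modelled as ``c1 * exp(-q/2) + c2`` with the
    uniform component ``c2 = outlier_mass / cell_volume`` and Gaussian
    amplitude ``c1 = 10 * (1 - outlier_mass)``.  Fitting
    ``d3 - d1 * exp(-d2 q / 2)`` to the negative log-mixture at q = 0, 1 and
    infinity gives the constants below; the additive d3 is dropped as a
    constant offset.
    """
    if not 0.0 < outlier_mass < 1.0:
        raise ValueError("outlier_mass must lie in (0, 1)")
    c1 = 10.0 * (1.0 - outlier_mass)
    c2 = outlier_mass / cell_volume
    d1 = np.log((c1 + c2) / c2)
    d2 = -2.0 * np.log(np.log((c1 * np.exp(-0.5) + c2) / c2) / d1)
    return float(d1), float(d2)


class NDTGrid:
    """Voxel grid of per-cell normal distributions over a reference surface.

    Attributes
    ----------
    cell_size : float
        Cubic cell edge length, mm.
    origin : ndarray (3,)
        Grid origin (minimum corner of the reference bounding box).
    cells : dict[tuple, NDTCell]
        Occupied cells with at least ``min_points_per_cell`` points.
    d1, d2 : float
        Mixture score constants.
    """

    def __init__(self, cell_size: float, origin: np.ndarray,
                 cells: dict, shape: tuple, d1: float, d2: float):
        self.cell_size = cell_size
        self.origin = origin
        self.cells = cells
        self.shape = shape
        self.d1 = d1
        self.d2 = d2
        # dense index -> cell id lookup for vectorised scoring
        self._ids = np.full(shape, -1, dtype=np.int32)
        self._mus = np.empty((len(cells), 3))
        self._sinvs = np.empty((len(cells), 3, 3))
        for cid, (key, cell) in enumerate(cells.items()):
            self._ids[key] = cid
            self._mus[cid] = cell.mu
            self._sinvs[cid] = cell.sigma_inv

    @property
    def n_active_cells(self) -> int:
        return len(self.cells)

    def cell_ids(self, points: np.ndarray) -> np.ndarray:
        """Active-cell id per point (-1 for points outside any active cell)."""
        idx = np.floor((points - self.origin) / self.cell_size).astype(int)
        inside = np.all((idx >= 0) & (idx < np.array(self.shape)), axis=1)
        out = np.full(len(points), -1, dtype=np.int32)
        if inside.any():
            ii = idx[inside]
            out[inside] = self._ids[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out


def build_ndt_grid(reference, cell_size: float = 100.0,
                   min_points_per_cell: int = 5,
                   eig_floor_ratio: float = 1e-3,
                   outlier_mass: float = 0.55) -> NDTGrid:
    """Bin a reference surface into an :class:`NDTGrid`.

    Per occupied cell the sample mean and covariance (n-1 denominator) are
    computed; covariance eigenvalues are floored at ``eig_floor_ratio``
    times the largest eigenvalue (with a small absolute floor for fully
    degenerate cells) so that planar surface patches — the norm for skin
    surfaces — keep an invertible Sigma.
    """
    pts = as_cloud(reference, name="reference")
    if not len(pts):
        raise ValueError("reference must be non-empty")
    if cell_size <= 0 or min_points_per_cell < 1 or eig_floor_ratio <= 0:
        raise ValueError("grid parameters must be positive")

    origin = pts.min(axis=0)
    idx = np.floor((pts - origin) / cell_size).astype(int)
    shape = tuple(idx.max(axis=0) + 1)
    abs_floor = (1e-3 * cell_size) ** 2
    cells: dict[tuple, NDTCell] = {}
    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0]))
    idx_sorted, pts_sorted = idx[order], pts[order]
    keys, starts = np.unique(idx_sorted, axis=0, return_index=True)
    bounds = np.append(starts, len(pts_sorted))
    for key, lo, hi in zip(keys, bounds[:-1], bounds[1:]):
        members = pts_sorted[lo:hi]
        if len(members) < min_points_per_cell:
            continue
        mu = members.mean(axis=0)
        dev = members - mu
        sigma = dev.T @ dev / max(len(members) - 1, 1)
        w, v = np.linalg.eigh(sigma)
        floor = max(eig_floor_ratio * w[-1], abs_floor)
        w = np.maximum(w, floor)
        sigma = (v * w) @ v.T
        sigma_inv = (v / w) @ v.T
        cells[tuple(key)] = NDTCell(len(members), mu, sigma, sigma_inv)
    if not cells:
        raise ValueError(
            f"no grid cell collected {min_points_per_cell} points at "
            f"cell_size={cell_size} mm; use smaller cells or a denser cloud")
    d1, d2 = mixture_constants(outlier_mass, cell_size ** 3)
    return NDTGrid(cell_size, origin, cells, shape, d1, d2)


def _rotation_derivatives(angles_deg: np.ndarray):
    """R, dR/dp_k and d2R/dp_k dp_l for Z-Y-X Euler angles in degrees."""
    rad = np.deg2rad(angles_deg)
    rx, ry, rz = _axis_rotations(rad)
    r = rz @ ry @ rx
    dx, dy, dz = _GX @ rx, _GY @ ry, _GZ @ rz  # per-factor first derivatives
    d1 = np.stack([rz @ ry @ dx, rz @ dy @ rx, dz @ ry @ rx]) * _DEG
    d2 = np.empty((3, 3, 3, 3))
    d2[0, 0] = rz @ ry @ (_GX @ dx)
    d2[1, 1] = rz @ (_GY @ dy) @ rx
    d2[2, 2] = (_GZ @ dz) @ ry @ rx
    d2[0, 1] = d2[1, 0] = rz @ dy @ dx
    d2[0, 2] = d2[2, 0] = dz @ ry @ dx
    d2[1, 2] = d2[2, 1] = dz @ dy @ rx
    d2 *= _DEG ** 2
    return r, d1, d2


def ndt_score(grid: NDTGrid, current, pose: RigidTransform,
              *, derivatives: bool = True):
    """Score a current surface under the grid at a given pose.

    Returns ``(score, gradient, hessian)`` — the gradient (6,) and Hessian
    (6, 6) are the analytic derivatives of the score with respect to the
    pose vector (tx, ty, tz in mm, rx, ry, rz in degrees); both are ``None``
    when ``derivatives=False``.  Lower scores are better; the score is
    bounded below by ``-d1 * n_points`` and the uniform-outlier baseline is
    zero.
    """
    if grid.n_active_cells == 0:
        raise ValueError("grid has no active cells")
    pts = as_cloud(current, name="current")
    p = pose.as_vector()
    r, dr, d2r = _rotation_derivatives(p[3:])
    xt = pts @ r.T + p[:3]
    cid = grid.cell_ids(xt)
    active = cid >= 0
    if not active.any():
        z = np.zeros(6), np.zeros((6, 6))
        return 0.0, (z[0] if derivatives else None), (z[1] if derivatives else None)
    x = pts[active]
    cids = cid[active]
    mu = grid._mus[cids]
    sinv = grid._sinvs[cids]
    d1c, d2c = grid.d1, grid.d2

    q = xt[active] - mu
    a = np.einsum("nij,nj->ni", sinv, q)
    u = np.einsum("ni,ni->n", q, a)
    e = np.exp(-0.5 * d2c * u)
    score = float(-(d1c * e).sum())
    if not derivatives:
        return score, None, None

    # Jacobian of the transformed point wrt the 6 pose parameters
    n = len(x)
    jac = np.zeros((n, 3, 6))
    jac[:, :, :3] = np.eye(3)
    for k in range(3):
        jac[:, :, 3 + k] = x @ dr[k].T
    aj = np.einsum("ni,nik->nk", a, jac)
    grad = d1c * d2c * (e[:, None] * aj).sum(axis=0)

    sj = np.einsum("nij,njk->nik", sinv, jac)
    t_quad = np.einsum("nik,nil->nkl", jac, sj)
    t_outer = np.einsum("nk,nl->nkl", aj, aj)
    w = np.einsum("klij,nj->nkli", d2r, x)
    t_second = np.zeros((n, 6, 6))
    t_second[:, 3:, 3:] = np.einsum("ni,nkli->nkl", a, w)
    hess = d1c * d2c * np.einsum(
        "n,nkl->kl", e, t_quad + t_second - d2c * t_outer)
    return score, grad, hess


class NDTRegistration(BaseSurfaceRegistration):
    """Rigid registration by the 3D normal-distributions transform.

    Parameters
    ----------
    cell_size : float, default 100
        Cubic grid-cell edge, mm.  100 mm suits torso-scale surfaces;
        bench-scale fixtures want 20-50 mm.
    min_points_per_cell : int, default 5
        Cells with fewer reference points stay inactive.
    eig_floor_ratio : float, default 1e-3
        Covariance eigenvalue floor, relative to the largest eigenvalue.
    outlier_mass : float, default 0.55
        Assumed probability mass of the uniform outlier component.
    max_iterations : int, default 100
    min_translation_step, min_rotation_step : float, defaults 0.1 mm / 0.1 deg
        Stopping thresholds on the Newton increment.
    min_step_fraction : float, default 1/64
        Smallest step-halving factor tried before declaring divergence.

    Attributes
    ----------
    reference_ : ndarray (n, 3)
    grid_ : NDTGrid
    pose_, result_ : set by :meth:`transform`.

    The optimiser is fully deterministic: Newton steps ``-H^{-1} g`` with
    the Hessian shifted by ``lambda * I`` whenever it is not positive
    definite, and the step halved until the score does not worsen.
    """

    def __init__(self, cell_size: float = 100.0, min_points_per_cell: int = 5,
                 eig_floor_ratio: float = 1e-3, outlier_mass: float = 0.55,
                 max_iterations: int = MAX_ITERATIONS,
                 min_translation_step: float = MIN_TRANSLATION_STEP,
                 min_rotation_step: float = MIN_ROTATION_STEP,
                 min_step_fraction: float = 1.0 / 64.0):
        self.cell_size = cell_size
        self.min_points_per_cell = min_points_per_cell
        self.eig_floor_ratio = eig_floor_ratio
        self.outlier_mass = outlier_mass
        self.max_iterations = max_iterations
        self.min_translation_step = min_translation_step
        self.min_rotation_step = min_rotation_step
        self.min_step_fraction = min_step_fraction

    def fit(self, X, y=None):
        """Build the NDT grid from the reference surface."""
        self.reference_ = self._validate(X, "reference")
        self.grid_ = build_ndt_grid(
            self.reference_, cell_size=self.cell_size,
            min_points_per_cell=self.min_points_per_cell,
            eig_floor_ratio=self.eig_floor_ratio,
            outlier_mass=self.outlier_mass)
        self.n_features_in_ = 3
        return self

    def register(self, X) -> RegistrationResult:
        self._check_fitted_reference()
        current = self._validate(X, "current")

        vec = np.zeros(6)  # zero transform and rotation as initial estimate
        score, grad, hess = ndt_score(self.grid_, current,
                                      RigidTransform.from_vector(vec))
        trace = []
        converged = False
        iterations = 0
        max_t_step = 0.5 * self.cell_size  # trust-region caps per iteration
        max_r_step = 5.0
        for iterations in range(1, self.max_iterations + 1):
            w = np.linalg.eigvalsh(hess)
            if w[0] <= 0:  # damp to positive definite
                hess = hess + (-w[0] + 1e-6 * max(1.0, abs(w[-1]))) * np.eye(6)
            delta = -np.linalg.solve(hess, grad)
            t_norm = np.linalg.norm(delta[:3])
            r_norm = np.abs(delta[3:]).max(initial=0.0)
            cap = min(max_t_step / t_norm if t_norm > max_t_step else 1.0,
                      max_r_step / r_norm if r_norm > max_r_step else 1.0)
            delta = delta * cap
            # backtracking line search keeping the best scored candidate
            best_alpha, best_score = 0.0, score
            alpha = 1.0
            while alpha >= self.min_step_fraction:
                trial_score, _, _ = ndt_score(
                    self.grid_, current,
                    RigidTransform.from_vector(vec + alpha * delta),
                    derivatives=False)
                if trial_score < best_score:
                    best_alpha, best_score = alpha, trial_score
                alpha *= 0.5
            if best_alpha == 0.0:
                # no candidate improves the score, down to steps of
                # min_step_fraction * |delta|: convergence if even that
                # probe is below the stopping thresholds, divergence if the
                # pose is still unresolved at threshold scale
                converged = self._step_converged(
                    self.min_step_fraction * delta,
                    self.min_translation_step, self.min_rotation_step)
                break
            step = best_alpha * delta
            vec = vec + step
            trace.append((vec.copy(), best_score))
            # convergence requires a small increment on a full Newton step;
            # a capped or backtracked step can be small far from stationarity
            if (best_alpha == 1.0 and cap == 1.0
                    and self._step_converged(step, self.min_translation_step,
                                             self.min_rotation_step)):
                score = best_score
                converged = True
                break
            score, grad, hess = ndt_score(self.grid_, current,
                                          RigidTransform.from_vector(vec))
        pose = RigidTransform.from_vector(vec)
        return RegistrationResult(pose=pose, iterations=iterations,
                                  converged=converged, residual=float(score),
                                  trace=trace,
                                  transformed_cloud=pose.apply(current))


def ndt_register(reference, current, **params) -> RegistrationResult:
    """Functional one-shot NDT; keyword arguments as in :class:`NDTRegistration`."""
    return NDTRegistration(**params).fit(reference).register(current)
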