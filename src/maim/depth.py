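"""Axial inversion of the multi-angle evanescent decay.

Each in-mask pixel carries a K-vector b of background-subtracted
intensities across incidence angles.  With A the K x M system matrix of
evanescent excitation weights, the axial fluorophore distribution f over
the depth bins solves

    minimize  1/2 ||A f - b||^2 + mu ||f||_1    subject to  f >= 0,

a convex problem solved by ADMM (operator splitting f = g, g >= 0
soft-thresholded).  Pixels are independent sub-problems and are solved
as one vectorized batch; the system matrix is column-normalized
internally (with compensation on output) to improve conditioning, which
makes ``mu`` act on the normalized variables.  A projected-gradient
solver and a non-negative-least-squares oracle (mu = 0) are provided for
cross-validation.

The per-pixel mean depth is the intensity-weighted average
h = sum(z_m f_m) / sum(f_m).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.optimize import nnls as _scipy_nnls

from .optics import AxialGrid, SystemMatrix
from .segment import SegmentedStack

__all__ = [
    "SolverParams",
    "AxialProfile",
    "DepthMap",
    "solve_pixel",
    "solve_batch",
    "solve_volume",
    "solve_gradient_descent",
    "nnls_oracle",
    "depth_from_profile",
    "assemble_volume",
]


@dataclass(frozen=True)
class SolverParams:
    """Hyperparameters of the axial inverse solver.

    ``mu`` is the l1 weight; in the default ``mu_mode='relative'`` it is
    multiplied per pixel by ||A^T b||_inf (column-normalized system), so
    a given value means the same thing across pixel brightnesses.  Set
    ``mu=0`` for pure non-negative least squares.
    """

    mu: float = 0.01
    mu_mode: str = "relative"
    rho: float = 1.0
    max_iter: int = 500
    tol: float = 1e-6
    solver: str = "admm"

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.mu_mode not in ("relative", "absolute"):
            raise ValueError("mu_mode must be 'relative' or 'absolute'")
        if self.solver not in ("admm", "grad", "nnls"):
            raise ValueError("solver must be one of admm, grad, nnls")


@dataclass(frozen=True)
class AxialProfile:
    """Non-negative axial weights over the depth bins for one pixel."""

    f: np.ndarray
    residual_norm: float
    converged: bool = True
    iterations: int = 0

    def __post_init__(self) -> None:
        f = np.asarray(self.f, dtype=float)
        if not np.all(np.isfinite(f)):
            raise ValueError("axial profile must be finite")
        object.__setattr__(self, "f", f)


@dataclass(frozen=True)
class DepthMap:
    """Per-pixel mean depth and integrated intensity over the mask.

    ``h`` is NaN outside the mask and on flagged pixels (zero recovered
    intensity); ``profiles`` optionally holds the full axial profile per
    in-mask pixel for volume assembly.
    """

    h: np.ndarray
    intensity: np.ndarray
    mask: np.ndarray
    axial_grid: AxialGrid
    profiles: np.ndarray | None = None  # (P, M) over in-mask pixels
    pixel_index: np.ndarray | None = None  # (P, 2) row/col of profiles
    qc: dict[str, Any] = field(default_factory=dict)

    def pooled_profile(self, region: np.ndarray | None = None) -> np.ndarray:
        """Sum of per-pixel profiles over the mask (or a sub-region),
        the ROI-level axial distribution."""
        if self.profiles is None:
            raise ValueError("profiles were not stored")
        if region is None:
            return self.profiles.sum(axis=0)
        sel = region[self.pixel_index[:, 0], self.pixel_index[:, 1]]
        return self.profiles[sel].sum(axis=0)


def _as_matrix(a: SystemMatrix | np.ndarray) -> np.ndarray:
    return a.a if isinstance(a, SystemMatrix) else np.asarray(a, dtype=float)


def _normalize_columns(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scale = np.linalg.norm(a, axis=0)
    if np.any(scale <= 0):
        raise ValueError("system matrix has a zero column")
    return a / scale, scale


def _thresholds(
    an: np.ndarray, scale: np.ndarray, b: np.ndarray, params: SolverParams
) -> np.ndarray:
    """(M, P) soft-threshold weights in the column-normalized system.

    Relative mode: mu scaled per pixel by ||An^T b||_inf, uniform across
    bins.  Absolute mode: mu applies to the original (un-normalized)
    coefficients, so the normalized-domain threshold is mu / column_norm.
    """
    m = an.shape[1]
    p = b.shape[1]
    if params.mu == 0:
        return np.zeros((1, p))
    if params.mu_mode == "relative":
        per_pixel = params.mu * np.max(np.abs(an.T @ b), axis=0)
        return np.broadcast_to(per_pixel[None, :], (1, p)).copy()
    return np.broadcast_to((params.mu / scale)[:, None], (m, p)).copy()


def solve_batch(
    b: np.ndarray,
    a: SystemMatrix | np.ndarray,
    params: SolverParams | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized ADMM over a batch of pixels.

    Parameters
    ----------
    b : (K, P) array of per-pixel intensity vectors.
    a : system matrix (K x M).

    Returns
    -------
    f : (M, P) non-negative profiles (original, un-normalized scale)
    residual : (P,) data residual norms ||A f - b||
    converged : (P,) bool
    iterations : (P,) iteration counts at convergence
    """
    if params is None:
        params = SolverParams()
    amat = _as_matrix(a)
    b = np.asarray(b, dtype=float)
    if b.ndim != 2 or b.shape[0] != amat.shape[0]:
        raise ValueError("b must be (K, P) matching the system matrix")
    if not np.all(np.isfinite(b)):
        raise ValueError("intensity vectors must be finite")
    k, m = amat.shape
    p = b.shape[1]
    an, scale = _normalize_columns(amat)
    thr = _thresholds(an, scale, b, params)  # (M or 1, P)

    gram = an.T @ an
    eigval, eigvec = np.linalg.eigh(gram)
    eigval = np.clip(eigval, 0.0, None)
    atb = an.T @ b  # (M, P)
    atb_eig = eigvec.T @ atb

    rho = np.full(p, params.rho)
    x = np.zeros((m, p))
    g = np.zeros((m, p))
    u = np.zeros((m, p))
    converged = np.zeros(p, dtype=bool)
    iterations = np.zeros(p, dtype=int)
    for it in range(1, params.max_iter + 1):
        rhs_eig = atb_eig + eigvec.T @ (rho * (g - u))
        x = eigvec @ (rhs_eig / (eigval[:, None] + rho[None, :]))
        g_prev = g
        g = np.maximum(x + u - thr / rho[None, :], 0.0)
        u = u + x - g
        r_norm = np.linalg.norm(x - g, axis=0)
        s_norm = rho * np.linalg.norm(g - g_prev, axis=0)
        ref = np.maximum.reduce(
            [np.linalg.norm(x, axis=0), np.linalg.norm(g, axis=0)]
        )
        ref = np.maximum(ref, 1e-12)
        dual_ref = np.maximum(rho * np.linalg.norm(u, axis=0), 1e-12)
        ok = (r_norm <= params.tol * ref) & (s_norm <= params.tol * dual_ref)
        newly = ok & ~converged
        iterations[newly] = it
        converged |= ok
        if np.all(converged):
            break
        # residual balancing keeps primal and dual progress comparable
        if it % 10 == 0:
            up = r_norm > 10.0 * s_norm
            dn = s_norm > 10.0 * r_norm
            rho = np.where(up, rho * 2.0, rho)
            u = np.where(up[None, :], u / 2.0, u)
            rho = np.where(dn, rho / 2.0, rho)
            u = np.where(dn[None, :], u * 2.0, u)
    iterations[~converged] = params.max_iter
    if not np.all(converged):
        warnings.warn(
            f"{int((~converged).sum())} of {p} pixels did not reach "
            f"tol={params.tol} within {params.max_iter} ADMM iterations"
        )
    f = g / scale[:, None]
    residual = np.linalg.norm(amat @ f - b, axis=0)
    return f, residual, converged, iterations


def solve_pixel(
    b: np.ndarray,
    a: SystemMatrix | np.ndarray,
    params: SolverParams | None = None,
) -> AxialProfile:
    """Solve the axial inverse problem for one pixel's K-vector."""
    if params is None:
        params = SolverParams()
    b = np.asarray(b, dtype=float).ravel()
    if not np.all(np.isfinite(b)):
        raise ValueError("intensity vector must be finite")
    amat = _as_matrix(a)
    if np.all(b == 0):
        return AxialProfile(
            f=np.zeros(amat.shape[1]), residual_norm=0.0, converged=True
        )
    if params.solver == "grad":
        return solve_gradient_descent(b, a, params)
    if params.solver == "nnls":
        return nnls_oracle(b, a, params)
    f, res, conv, iters = solve_batch(b[:, None], amat, params)
    return AxialProfile(
        f=f[:, 0],
        residual_norm=float(res[0]),
        converged=bool(conv[0]),
        iterations=int(iters[0]),
    )


def _objective(
    amat: np.ndarray, b: np.ndarray, f: np.ndarray, w: np.ndarray
) -> float:
    r = amat @ f - b
    return float(0.5 * r @ r + np.sum(w * np.abs(f)))


def solve_gradient_descent(
    b: np.ndarray,
    a: SystemMatrix | np.ndarray,
    params: SolverParams | None = None,
) -> AxialProfile:
    """Accelerated projected gradient (FISTA with restart) on the same
    objective; the comparison solver."""
    if params is None:
        params = SolverParams(solver="grad")
    b = np.asarray(b, dtype=float).ravel()
    amat = _as_matrix(a)
    an, scale = _normalize_columns(amat)
    thr = _thresholds(an, scale, b[:, None], params)
    m = an.shape[1]
    lip = float(np.linalg.eigvalsh(an.T @ an)[-1])
    if lip <= 0:
        return AxialProfile(f=np.zeros(m), residual_norm=float(np.linalg.norm(b)))
    step = 1.0 / lip
    atb = an.T @ b
    gram = an.T @ an
    x = np.zeros(m)
    y = x.copy()
    t = 1.0
    w = np.broadcast_to(thr[..., 0], (m,)) if thr.shape[0] == m else np.full(m, thr[0, 0])
    obj = _objective(an, b, x, w)
    bad_steps = 0
    converged = False
    n_iter = max(params.max_iter, 2000)
    it = 0
    for it in range(1, n_iter + 1):
        grad = gram @ y - atb
        # proximal step for the l1 term on the non-negative orthant
        x_new = np.maximum(y - step * grad - step * w, 0.0)
        obj_new = _objective(an, b, x_new, w)
        if obj_new > obj + 1e-15:
            bad_steps += 1
            if bad_steps >= 10:
                step *= 0.5
                bad_steps = 0
                if step < 1e-8 / lip:
                    raise RuntimeError("projected gradient diverged")
            # restart momentum on non-monotone step
            y = x
            t = 1.0
            continue
        t_new = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
        y = x_new + ((t - 1.0) / t_new) * (x_new - x)
        if abs(obj - obj_new) <= params.tol * 1e-2 * max(abs(obj), 1e-12):
            x = x_new
            converged = True
            break
        x, t, obj = x_new, t_new, obj_new
    f = x / scale
    return AxialProfile(
        f=f,
        residual_norm=float(np.linalg.norm(amat @ f - b)),
        converged=converged,
        iterations=it,
    )


def nnls_oracle(
    b: np.ndarray,
    a: SystemMatrix | np.ndarray,
    params: SolverParams | None = None,
) -> AxialProfile:
    """Exact non-negative least squares (active-set), valid for mu = 0.

    Serves as the independent oracle the iterative solvers are checked
    against.
    """
    if params is not None and params.mu != 0:
        raise ValueError("the NNLS oracle solves the mu = 0 problem only")
    b = np.asarray(b, dtype=float).ravel()
    amat = _as_matrix(a)
    f, rnorm = _scipy_nnls(amat, b)
    return AxialProfile(f=f, residual_norm=float(rnorm), converged=True)


def depth_from_profile(
    profile: AxialProfile | np.ndarray, axial_grid: AxialGrid
) -> float:
    """Intensity-weighted mean depth h = sum(z f) / sum(f), NaN if the
    profile is empty."""
    f = profile.f if isinstance(profile, AxialProfile) else np.asarray(profile)
    total = f.sum()
    if total <= 0:
        return float("nan")
    return float((axial_grid.z_nm * f).sum() / total)


def solve_volume(
    segmented: SegmentedStack,
    a: SystemMatrix,
    params: SolverParams | None = None,
    store_profiles: bool = True,
) -> DepthMap:
    """Solve every in-mask pixel of a segmented stack independently.

    Pixels are embarrassingly parallel sub-problems sharing one system
    matrix; the result is independent of pixel ordering.
    """
    if params is None:
        params = SolverParams()
    bmat, idx = segmented.pixel_vectors()
    ny, nx = segmented.frames.shape[1:]
    h = np.full((ny, nx), np.nan)
    intensity = np.zeros((ny, nx))
    if bmat.shape[1] == 0:
        return DepthMap(
            h=h,
            intensity=intensity,
            mask=segmented.mask.mask,
            axial_grid=a.axial_grid,
            profiles=np.zeros((0, a.axial_grid.m)) if store_profiles else None,
            pixel_index=idx,
            qc={"n_pixels": 0},
        )
    if params.solver == "admm":
        f, res, conv, iters = solve_batch(bmat, a, params)
    else:
        profs = [
            solve_pixel(bmat[:, j], a, params) for j in range(bmat.shape[1])
        ]
        f = np.stack([pr.f for pr in profs], axis=1)
        res = np.array([pr.residual_norm for pr in profs])
        conv = np.array([pr.converged for pr in profs])
        iters = np.array([pr.iterations for pr in profs])
    totals = f.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        depths = (a.axial_grid.z_nm @ f) / totals
    depths = np.where(totals > 0, depths, np.nan)
    h[idx[:, 0], idx[:, 1]] = depths
    intensity[idx[:, 0], idx[:, 1]] = totals
    qc = {
        "n_pixels": int(bmat.shape[1]),
        "n_converged": int(conv.sum()),
        "mean_iterations": float(iters.mean()),
        "max_residual": float(res.max()),
        "solver": params.solver,
    }
    return DepthMap(
        h=h,
        intensity=intensity,
        mask=segmented.mask.mask,
        axial_grid=a.axial_grid,
        profiles=f.T if store_profiles else None,
        pixel_index=idx,
        qc=qc,
    )


def assemble_volume(depth_map: DepthMap) -> np.ndarray:
    """Stack the per-pixel axial profiles into an (M, ny, nx) volume whose
    z-sum equals the intensity map exactly."""
    if depth_map.profiles is None:
        raise ValueError("depth map was built without stored profiles")
    m = depth_map.axial_grid.m
    ny, nx = depth_map.h.shape
    vol = np.zeros((m, ny, nx))
    idx = depth_map.pixel_index
    vol[:, idx[:, 0], idx[:, 1]] = depth_map.profiles.T
    return vol
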