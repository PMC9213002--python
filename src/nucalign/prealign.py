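"""Spatial pre-alignment: landmark-based affine / thin-plate-spline fits and
correspondence-free coherent point drift (CPD) refinement.

The anonymous cloud is warped into each labeled cloud's frame: first a global
fit from a handful of manually identified correspondences, then a nonrigid
CPD refinement that treats the moving cloud as Gaussian-mixture centroids and
regularizes the displacement field so nearby points move coherently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .landmarks_io import CpdParams, LandmarkCloud

logger = logging.getLogger("nucalign")


class DegenerateFitError(ValueError):
    """Raised when the correspondence geometry cannot determine the transform."""


@dataclass(frozen=True)
class SpatialTransform:
    """An affine map, a 3D thin-plate spline, or a fitted displacement field."""

    kind: str  # "affine" | "tps" | "displacement_field"
    matrix: np.ndarray | None = None          # affine: (3, 3)
    offset: np.ndarray | None = None          # affine: (3,)
    control_points: np.ndarray | None = None  # tps: (m, 3)
    tps_weights: np.ndarray | None = None     # tps: (m, 3) kernel coefficients
    tps_affine: np.ndarray | None = None      # tps: (4, 3) [offset; matrix rows]
    regularization: float = 0.0
    source_points: np.ndarray | None = None   # displacement_field: fitted source
    displacements: np.ndarray | None = None   # displacement_field: (n, 3)
    converged: bool = True
    residual: float = 0.0

    def __call__(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        if self.kind == "affine":
            return points @ self.matrix.T + self.offset
        if self.kind == "tps":
            k = _tps_kernel(points, self.control_points)
            return (np.hstack([np.ones((len(points), 1)), points]) @ self.tps_affine
                    + k @ self.tps_weights)
        if self.kind == "displacement_field":
            if (self.source_points.shape != points.shape
                    or not np.allclose(self.source_points, points)):
                raise ValueError(
                    "displacement field applied to a cloud it was not fitted on")
            return points + self.displacements
        raise ValueError(f"unknown transform kind {self.kind!r}")


def apply_transform(t: SpatialTransform, cloud: LandmarkCloud) -> LandmarkCloud:
    """Map a cloud's positions through a transform; names/metadata untouched."""
    return cloud.with_points(t(cloud.points))


# ---------------------------------------------------------------------------
# Affine
# ---------------------------------------------------------------------------

def affine_fit(src: np.ndarray, dst: np.ndarray) -> SpatialTransform:
    """Least-squares affine fit ``dst ~ A @ src + t`` from >= 4 correspondences."""
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("src and dst must be matching (n, 3) arrays")
    if len(src) < 4:
        raise ValueError(f"affine fit needs >= 4 correspondences; got {len(src)}")
    centered = src - src.mean(axis=0)
    rank = np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(centered).max()))
    if rank < 3:
        raise DegenerateFitError(
            f"source correspondences span only {rank} dimensions (coplanar or worse)")
    design = np.hstack([src, np.ones((len(src), 1))])
    coef, _, _, _ = np.linalg.lstsq(design, dst, rcond=None)
    matrix = coef[:3].T
    offset = coef[3]
    residual = float(np.sqrt(((design @ coef - dst) ** 2).sum()))
    return SpatialTransform(kind="affine", matrix=matrix, offset=offset,
                            residual=residual)


# ---------------------------------------------------------------------------
# Thin-plate spline (3D biharmonic kernel |r|)
# ---------------------------------------------------------------------------

def _tps_kernel(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    # -r is the conditionally positive definite form of the 3D biharmonic
    # kernel (same sign convention as scipy's RBFInterpolator 'linear')
    diff = a[:, None, :] - b[None, :, :]
    return -np.sqrt((diff ** 2).sum(axis=2))


def tps_fit(src: np.ndarray, dst: np.ndarray,
            regularization: float = 0.0) -> SpatialTransform:
    """3D thin-plate-spline (biharmonic) fit with kernel ``U(r) = -r``.

    With ``regularization == 0`` the spline interpolates every control point
    exactly; positive values trade interpolation accuracy for smoothness and,
    in the large-lambda limit, approach the affine least-squares fit.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("src and dst must be matching (n, 3) arrays")
    m = len(src)
    if m < 5:
        raise ValueError(f"TPS fit needs >= 5 correspondences; got {m}")
    if regularization < 0:
        raise ValueError("regularization must be >= 0")
    tree = cKDTree(src)
    if tree.query_pairs(r=0.0):
        raise DegenerateFitError("coincident source control points make the TPS kernel singular")

    K = _tps_kernel(src, src) + regularization * np.eye(m)
    P = np.hstack([np.ones((m, 1)), src])  # (m, 4)
    A = np.zeros((m + 4, m + 4))
    A[:m, :m] = K
    A[:m, m:] = P
    A[m:, :m] = P.T
    rhs = np.zeros((m + 4, 3))
    rhs[:m] = dst
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        raise DegenerateFitError(f"TPS system singular: {exc}") from exc
    weights, affine = sol[:m], sol[m:]
    fitted = P @ affine + (K - regularization * np.eye(m)) @ weights
    residual = float(np.sqrt(((fitted - dst) ** 2).sum()))
    return SpatialTransform(kind="tps", control_points=src.copy(),
                            tps_weights=weights, tps_affine=affine,
                            regularization=regularization, residual=residual)


# ---------------------------------------------------------------------------
# Coherent point drift (nonrigid, Gaussian-mixture EM)
# ---------------------------------------------------------------------------

def cpd_refine(src: LandmarkCloud | np.ndarray, dst: LandmarkCloud | np.ndarray,
               params: CpdParams | None = None) -> SpatialTransform:
    """Nonrigid CPD registration of ``src`` onto ``dst``.

    The moving points are GMM centroids fitted to the target by EM; the
    displacement field is ``G @ W`` with a Gaussian kernel G of width ``beta``,
    so nearby points move coherently (motion-coherence weight ``lam``).  Both
    clouds are normalized internally to zero mean and unit RMS; ``beta``,
    ``tol`` apply in that frame.  Returns a displacement field evaluated at the
    source points; on non-convergence the best iterate is returned with
    ``converged=False``.
    """
    params = params or CpdParams()
    Y0 = src.points if isinstance(src, LandmarkCloud) else np.asarray(src, dtype=float)
    X0 = dst.points if isinstance(dst, LandmarkCloud) else np.asarray(dst, dtype=float)
    M, N, D = len(Y0), len(X0), 3

    # normalize each cloud to zero mean, unit RMS
    y_mu, x_mu = Y0.mean(axis=0), X0.mean(axis=0)
    y_scale = float(np.sqrt(((Y0 - y_mu) ** 2).sum() / M)) or 1.0
    x_scale = float(np.sqrt(((X0 - x_mu) ** 2).sum() / N)) or 1.0
    Y = (Y0 - y_mu) / y_scale
    X = (X0 - x_mu) / x_scale

    G = np.exp(-_sq_dists(Y, Y) / (2.0 * params.beta ** 2))
    W = np.zeros((M, D))
    sigma2 = _sq_dists(Y, X).sum() / (D * M * N)
    w = min(max(params.outlier_weight, 0.0), 0.999)

    prev_q = np.inf
    converged = False
    T = Y.copy()
    for _ in range(params.max_iters):
        # E-step: posteriors with uniform outlier component
        sq = _sq_dists(T, X)
        num = np.exp(-sq / (2.0 * sigma2))
        c = (2.0 * np.pi * sigma2) ** (D / 2.0) * w / (1.0 - w) * M / N
        den = num.sum(axis=0) + c
        den[den == 0] = np.finfo(float).tiny
        P = num / den
        Np = P.sum()
        if Np < 1e-12:
            break
        P1 = P.sum(axis=1)
        # M-step: solve (diag(P1) G + lam sigma2 I) W = P X - diag(P1) Y
        A = G * P1[:, None] + params.lam * sigma2 * np.eye(M)
        B = P @ X - P1[:, None] * Y
        W = np.linalg.solve(A, B)
        T = Y + G @ W
        # update sigma2 and objective proxy
        xPx = (P.sum(axis=0) * (X ** 2).sum(axis=1)).sum()
        tPt = (P1 * (T ** 2).sum(axis=1)).sum()
        trPXT = (P @ X * T).sum()
        sigma2 = max((xPx - 2.0 * trPXT + tPt) / (Np * D), 1e-10)
        q = (xPx - 2.0 * trPXT + tPt) / (2.0 * sigma2) + Np * D / 2.0 * np.log(sigma2)
        if abs(prev_q - q) < params.tol * (1.0 + abs(q)):
            converged = True
            break
        prev_q = q

    if not converged:
        logger.warning("CPD did not converge in %d iterations", params.max_iters)
    # back to the original frame: target frame scale/offset
    warped = T * x_scale + x_mu
    return SpatialTransform(kind="displacement_field", source_points=Y0.copy(),
                            displacements=warped - Y0, converged=converged)


def _sq_dists(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
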