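"""Thin-plate-spline interpolation in 3D, bending energy, and TPS-based
estimation of missing (semi)landmarks.

The 3D radial kernel is U(r) = r, the convention used throughout landmark
morphometrics. A TPS fitted on k control points decomposes into an affine
part (4 coefficients per output coordinate) and a non-affine warp whose
roughness is the bending energy, the quadratic form of the target
coordinates against Bookstein's bending-energy matrix. In 3D the upper-left
k x k block of the inverted TPS system is negative semidefinite (the
biharmonic fundamental solution carries a negative constant), so the
bending-energy matrix returned here is that block negated: symmetric, PSD,
with a 4-dimensional null space spanned by the constant vector and the
three coordinate columns of the reference (affine maps bend nothing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .errors import DegenerateGeometryError, MissingPointsError
from .geometry import similarity_fit

__all__ = [
    "TPSModel",
    "fit_tps",
    "apply_tps",
    "bending_energy",
    "bending_energy_matrix",
    "estimate_missing",
]


@dataclass(frozen=True)
class TPSModel:
    """Fitted 3D thin-plate spline x -> affine(x) + sum_i w_i U(|x - s_i|)."""

    source: np.ndarray        # (k, 3) control points
    target: np.ndarray        # (k, 3) fitted values at the control points
    affine: np.ndarray        # (4, 3): rows = [1, x, y, z] coefficients
    weights: np.ndarray       # (k, 3) warp coefficients
    kernel: str = "r"

    @property
    def n_points(self) -> int:
        return len(self.source)


def _kernel_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)


def _check_source(source: np.ndarray) -> None:
    k = len(source)
    if k < 5:
        raise DegenerateGeometryError(f"TPS needs >= 5 source points, got {k}")
    d = _kernel_matrix(source, source)
    np.fill_diagonal(d, np.inf)
    if d.min() <= 0.0:
        raise DegenerateGeometryError("duplicate source points in TPS fit")
    centered = source - source.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[2] <= 1e-9 * s[0]:
        raise DegenerateGeometryError(
            "source points are (near) coplanar; the TPS system is singular "
            "-- add out-of-plane points or use a regularized 2D method"
        )


def _system(source: np.ndarray, ridge: float | None = None) -> np.ndarray:
    k = len(source)
    kmat = _kernel_matrix(source, source)
    if ridge is None:
        # small ridge keeps tight landmark clusters from blowing up the solve
        cond = np.linalg.cond(kmat)
        if cond > 1e12:
            warnings.warn(
                f"ill-conditioned TPS kernel (cond={cond:.2e}); adding ridge",
                RuntimeWarning,
                stacklevel=3,
            )
            kmat = kmat + (1e-10 * np.trace(kmat)) * np.eye(k)
    else:
        kmat = kmat + ridge * np.eye(k)
    p = np.hstack([np.ones((k, 1)), source])
    l = np.zeros((k + 4, k + 4))
    l[:k, :k] = kmat
    l[:k, k:] = p
    l[k:, :k] = p.T
    return l


def fit_tps(source: np.ndarray, target: np.ndarray) -> TPSModel:
    """Fit the exact-interpolation TPS carrying ``source`` onto ``target``.

    Requires k >= 5 non-coplanar, duplicate-free source points; the fitted
    model reproduces ``target`` exactly at the control points and decomposes
    into affine + non-affine parts (affine maps yield zero warp weights).
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.shape != target.shape or source.ndim != 2 or source.shape[1] != 3:
        raise DegenerateGeometryError(
            f"source/target must both be (k, 3); got {source.shape}, {target.shape}"
        )
    _check_source(source)
    k = len(source)
    l = _system(source)
    rhs = np.vstack([target, np.zeros((4, 3))])
    sol = scipy.linalg.solve(l, rhs)
    return TPSModel(
        source=source, target=target, weights=sol[:k], affine=sol[k:]
    )


def apply_tps(model: TPSModel, points: np.ndarray) -> np.ndarray:
    """Evaluate the fitted spline at arbitrary points (m, 3)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != 3:
        raise DegenerateGeometryError(f"points must be (m, 3), got {pts.shape}")
    u = _kernel_matrix(pts, model.source)
    p = np.hstack([np.ones((len(pts), 1)), pts])
    return u @ model.weights + p @ model.affine


def bending_energy_matrix(reference: np.ndarray) -> np.ndarray:
    """Bookstein's bending-energy matrix B for a reference configuration.

    B is symmetric PSD; its null space contains the constant vector and the
    three coordinate columns of the reference, so affine displacement fields
    carry zero energy. The energy of a target Y relative to the reference is
    trace(Y' B Y).
    """
    reference = np.asarray(reference, dtype=float)
    _check_source(reference)
    k = len(reference)
    l = _system(reference)
    li = scipy.linalg.inv(l)
    b = -li[:k, :k]          # negated: U(r)=r makes the raw block NSD in 3D
    return 0.5 * (b + b.T)


def bending_energy(model: TPSModel) -> float:
    """Bending energy of a fitted TPS: zero iff the map is affine; invariant
    to rotating/translating the target as a whole."""
    b = bending_energy_matrix(model.source)
    e = float(np.trace(model.target.T @ b @ model.target))
    return max(e, 0.0)


def estimate_missing(
    reference: np.ndarray,
    partial_target: np.ndarray,
    missing_idx: np.ndarray,
) -> np.ndarray:
    """Estimate missing points of a partial configuration from a complete
    reference (typically a Procrustes mean shape).

    The reference is first fitted onto the target's present points by an
    ordinary Procrustes superimposition *with scaling* (so the completed
    specimen keeps the target's natural pose and size, and its centroid
    size stays meaningful); a TPS is then fitted from the aligned reference
    to the target on the present points and evaluated at the reference's
    missing positions. Present target points are returned unchanged.
    """
    reference = np.asarray(reference, dtype=float)
    target = np.asarray(partial_target, dtype=float)
    if reference.shape != target.shape:
        raise DegenerateGeometryError(
            f"reference {reference.shape} and target {target.shape} differ"
        )
    k = len(reference)
    missing = np.zeros(k, dtype=bool)
    missing[np.asarray(missing_idx, dtype=int)] = True
    present = ~missing
    if missing.all():
        raise MissingPointsError("all points are missing; nothing to anchor on")
    if not missing.any():
        return target.copy()
    if present.sum() < 5:
        raise MissingPointsError(
            f"only {int(present.sum())} shared points; TPS estimation needs >= 5"
        )
    s, r, t = similarity_fit(reference[present], target[present], scale=True)
    ref_aligned = s * reference @ r + t
    model = fit_tps(ref_aligned[present], target[present])
    completed = target.copy()
    completed[missing] = apply_tps(model, ref_aligned[missing])
    return completed
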