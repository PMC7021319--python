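"""Low-level point-set geometry: centroid size, optimal rotations and
similarity (partial Procrustes) fits shared by the alignment, TPS and
reconstruction layers.

Conventions: configurations are (k, 3) float arrays in mm, right-handed
axes; "centered" means the centroid sits at the origin.
"""

from __future__ import annotations

import numpy as np

from .errors import DegenerateGeometryError

__all__ = ["centroid", "centroid_size", "optimal_rotation", "similarity_fit"]


def centroid(coords: np.ndarray) -> np.ndarray:
    return np.asarray(coords, dtype=float).mean(axis=0)


def centroid_size(coords: np.ndarray) -> float:
    """Centroid size: the square root of the summed squared distances of
    every (semi)landmark from the configuration centroid.

    This is the standard geometric-morphometric size measure; its natural
    log (lnCS) is the size variable used in form space and allometric
    regressions.
    """
    x = np.asarray(coords, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise DegenerateGeometryError(f"expected a (k, 3) configuration, got {x.shape}")
    if x.shape[0] < 2:
        raise DegenerateGeometryError("centroid size needs at least 2 points")
    cs = float(np.sqrt(((x - x.mean(axis=0)) ** 2).sum()))
    if cs <= 0.0:
        raise DegenerateGeometryError("all points coincide: centroid size is zero")
    return cs


def optimal_rotation(
    moving: np.ndarray,
    fixed: np.ndarray,
    allow_reflection: bool = False,
) -> np.ndarray:
    """Rotation R minimizing ||moving @ R - fixed||_F for centered inputs.

    Kabsch solution via SVD of the cross-covariance. With
    ``allow_reflection=False`` (default, the morphometric convention) the
    result is a proper rotation, det(R) = +1, obtained by flipping the
    singular direction with the smallest singular value when needed.
    """
    a = np.asarray(moving, dtype=float)
    b = np.asarray(fixed, dtype=float)
    if a.shape != b.shape:
        raise DegenerateGeometryError(f"shape mismatch {a.shape} vs {b.shape}")
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    if s[1] <= 1e-12 * max(s[0], 1e-300):
        raise DegenerateGeometryError(
            "configuration has rank < 2; rotation is not identifiable"
        )
    r = u @ vt
    if not allow_reflection and np.linalg.det(r) < 0:
        u = u.copy()
        u[:, -1] *= -1.0
        r = u @ vt
    return r


def similarity_fit(
    moving: np.ndarray,
    fixed: np.ndarray,
    scale: bool = True,
    allow_reflection: bool = False,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Least-squares similarity fit of ``moving`` onto ``fixed``.

    Returns ``(s, R, t)`` such that ``s * moving @ R + t`` best matches
    ``fixed`` (ordinary Procrustes superimposition with optional scaling).
    """
    a = np.asarray(moving, dtype=float)
    b = np.asarray(fixed, dtype=float)
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    r = optimal_rotation(a0, b0, allow_reflection=allow_reflection)
    if scale:
        denom = (a0 * a0).sum()
        s = float((a0 @ r * b0).sum() / denom)
        if s <= 0:
            raise DegenerateGeometryError("non-positive optimal scale")
    else:
        s = 1.0
    t = cb - s * (ca @ r)
    return s, r, t
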