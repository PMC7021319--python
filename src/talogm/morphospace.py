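"""Shape-space and form-space principal component analysis.

Shape space is the PCA of the flattened Procrustes shape coordinates; form
space augments those coordinates with one extra column, the natural log of
centroid size (lnCS), so the leading axis can absorb size and size-related
(allometric) shape change together. PCA is covariance-based (the variables
share units) and computed by SVD of the centered data matrix; each
eigenvector is oriented so its largest-magnitude loading is positive,
which pins down the otherwise arbitrary axis signs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import AlignedSample
from .errors import DegenerateGeometryError
from .geometry import centroid_size, optimal_rotation

__all__ = [
    "MorphospaceModel",
    "shape_space_pca",
    "form_space_pca",
    "project",
    "shape_at_score",
    "align_to_consensus",
]


@dataclass
class MorphospaceModel:
    space: str                      # "shape" | "form"
    mean_vector: np.ndarray         # (d,)
    eigenvectors: np.ndarray        # (d, m) orthonormal columns
    variance_fraction: np.ndarray   # (m,)
    eigenvalues: np.ndarray         # (m,)
    scores: np.ndarray              # (n, m)
    consensus: np.ndarray           # (k, 3) reference for projecting new specimens
    lncs_index: int | None = None   # column position of lnCS (form space)

    @property
    def n_components(self) -> int:
        return self.eigenvectors.shape[1]

    @property
    def n_points(self) -> int:
        return len(self.consensus)


def _pca(data: np.ndarray):
    n = len(data)
    mean = data.mean(axis=0)
    centered = data - mean
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    eigvals = s**2 / (n - 1)
    keep = eigvals > max(eigvals[0], 1e-300) * 1e-12
    eigvals = eigvals[keep]
    vecs = vt[keep].T
    # deterministic sign: largest-|loading| entry positive per axis
    for j in range(vecs.shape[1]):
        col = vecs[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            vecs[:, j] = -col
    scores = centered @ vecs
    frac = eigvals / eigvals.sum()
    return mean, vecs, eigvals, scores, frac


def _pca_model(data, space, consensus, lncs_index=None) -> MorphospaceModel:
    if len(data) < 3:
        raise DegenerateGeometryError("PCA needs at least 3 specimens")
    mean, vecs, eigvals, scores, frac = _pca(np.asarray(data, dtype=float))
    return MorphospaceModel(
        space=space,
        mean_vector=mean,
        eigenvectors=vecs,
        eigenvalues=eigvals,
        variance_fraction=frac,
        scores=scores,
        consensus=np.asarray(consensus, dtype=float),
        lncs_index=lncs_index,
    )


def shape_space_pca(aligned: AlignedSample) -> MorphospaceModel:
    """Covariance PCA of the Procrustes shape coordinates."""
    return _pca_model(aligned.flattened(), "shape", aligned.consensus)


def form_space_pca(aligned: AlignedSample) -> MorphospaceModel:
    """Covariance PCA of [shape coordinates | lnCS]; the lnCS column is
    centered with the rest but never re-scaled, so the leading axis retains
    the size information."""
    x = aligned.flattened()
    data = np.hstack([x, aligned.ln_centroid_sizes[:, None]])
    return _pca_model(data, "form", aligned.consensus, lncs_index=x.shape[1])


def align_to_consensus(coordinates: np.ndarray, consensus: np.ndarray) -> np.ndarray:
    """Ordinary Procrustes fit of one configuration onto the consensus:
    center, scale to unit centroid size, optimal rotation."""
    x = np.asarray(coordinates, dtype=float)
    x = x - x.mean(axis=0)
    x = x / centroid_size(x)
    return x @ optimal_rotation(x, consensus)


def project(
    model: MorphospaceModel,
    coordinates: np.ndarray,
    lncs: float | None = None,
    pre_aligned: bool = False,
) -> np.ndarray:
    """Project a specimen into the morphospace.

    Unless ``pre_aligned``, the configuration is first superimposed on the
    model consensus (ordinary Procrustes fit with unit scaling), matching
    how the training rows were built. Form-space projection additionally
    requires the specimen's lnCS.
    """
    x = np.asarray(coordinates, dtype=float)
    if x.shape != model.consensus.shape:
        raise DegenerateGeometryError(
            f"expected {model.consensus.shape} coordinates, got {x.shape}"
        )
    if not pre_aligned:
        x = align_to_consensus(x, model.consensus)
    vec = x.reshape(-1)
    if model.space == "form":
        if lncs is None:
            raise ValueError("form-space projection requires lnCS")
        vec = np.concatenate([vec, [float(lncs)]])
    if vec.shape != model.mean_vector.shape:
        raise DegenerateGeometryError("dimension mismatch with the model mean")
    return (vec - model.mean_vector) @ model.eigenvectors


def shape_at_score(
    model: MorphospaceModel, axis: int, score: float
) -> tuple[np.ndarray, float | None]:
    """Configuration at ``mean + score * eigenvector[axis]``.

    Returns ``(points, implied_lncs)``; the lnCS component (form space) is
    reported separately and dropped from the geometry. Used to visualize
    shape change along principal axes by warping the grand mean.
    """
    if not (0 <= axis < model.n_components):
        raise IndexError(f"axis {axis} out of range (0..{model.n_components - 1})")
    vec = model.mean_vector + score * model.eigenvectors[:, axis]
    if model.space == "form":
        lncs = float(vec[model.lncs_index])
        geom = np.delete(vec, model.lncs_index)
        return geom.reshape(-1, 3), lncs
    return vec.reshape(-1, 3), None
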