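"""Generalized Procrustes Analysis with recursive sliding of curve and
surface semilandmarks against the consensus.

The superimposition follows the standard GM recipe: every configuration is
centered, scaled to unit centroid size, and rotated onto the running
consensus; the consensus is the arithmetic mean of the aligned specimens,
itself rescaled to unit size, and the loop repeats until it stops moving.
Size is carried separately as centroid size (CS, from the raw mm
coordinates) and its natural log lnCS.

With ``sliding="bending_energy"`` the semilandmarks are additionally
allowed to slide within their tangent spaces (one direction along a curve,
a tangent plane on a surface) so as to minimize the thin-plate-spline
bending energy between each specimen and the consensus. Per specimen this
is a single linear solve: with B the consensus bending-energy matrix,
tangent displacement amplitudes t minimize

    E(t) = vec(Y + U t - C)' (I3 x B) vec(Y + U t - C),

whose normal equations reduce -- because each column of U touches exactly
one landmark -- to (G .* B_sub) t = -rhs, with G the Gram matrix of the
tangent directions and B_sub the corresponding block of B. Sliding is a
tangent-space displacement without re-projection onto an underlying
surface: this coordinates-only variant is the main source of small numeric
divergence from digitizer-based pipelines that re-project on the mesh.

Fixed anatomical landmarks never move during sliding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError, MissingPointsError
from .geometry import centroid_size, optimal_rotation
from .io import LandmarkDataset
from .template import Template
from .tps import bending_energy_matrix

__all__ = [
    "AlignedSample",
    "gpa",
    "tangent_vectors",
    "slide_semilandmarks",
    "centroid_size",
    "optimal_rotation",
]


@dataclass
class AlignedSample:
    """Output of GPA: unit-size, consensus-oriented shape coordinates with
    the size variables and a per-iteration sliding audit trail."""

    shape_coordinates: np.ndarray          # (n, k, 3)
    centroid_sizes: np.ndarray             # (n,) mm
    consensus: np.ndarray                  # (k, 3), unit CS
    template: Template | None = None
    specimen_ids: list[str] = field(default_factory=list)
    sexes: np.ndarray | None = None
    populations: np.ndarray | None = None
    sliding_log: list[dict] = field(default_factory=list)
    residual_log: list[float] = field(default_factory=list)

    @property
    def ln_centroid_sizes(self) -> np.ndarray:
        return np.log(self.centroid_sizes)

    @property
    def n_specimens(self) -> int:
        return len(self.shape_coordinates)

    @property
    def n_points(self) -> int:
        return self.shape_coordinates.shape[1]

    def flattened(self) -> np.ndarray:
        """(n, 3k) row-per-specimen matrix, point-major (x1,y1,z1,x2,...)."""
        n = self.n_specimens
        return self.shape_coordinates.reshape(n, -1)


def _center_scale(x: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=0)
    return x / centroid_size(x)


def tangent_vectors(
    coordinates: np.ndarray,
    template: Template,
    k_neighbors: int = 8,
) -> dict[int, np.ndarray]:
    """Orthonormal sliding directions per semilandmark.

    Curve points get the normalized central-difference direction of their
    curve neighbours (one-sided at curve ends, using the anchoring fixed
    landmark when declared); surface points get the two leading principal
    directions of the local covariance of their ``k_neighbors`` nearest
    neighbours. Returns {point index: (d, 3) row-orthonormal basis} with
    d = 1 for curve points and d = 2 for surface points.
    """
    x = np.asarray(coordinates, dtype=float)
    out: dict[int, np.ndarray] = {}
    for curve in template.curves:
        pts = list(curve.points)
        chain = (
            ([curve.anchor_start] if curve.anchor_start is not None else [])
            + pts
            + ([curve.anchor_end] if curve.anchor_end is not None else [])
        )
        pos = {p: i for i, p in enumerate(chain)}
        for p in pts:
            i = pos[p]
            prev_p = chain[i - 1] if i > 0 else p
            next_p = chain[i + 1] if i < len(chain) - 1 else p
            d = x[next_p] - x[prev_p]
            nrm = np.linalg.norm(d)
            if nrm <= 1e-12:
                raise DegenerateGeometryError(
                    f"zero-length tangent at curve point {p}"
                )
            out[p] = (d / nrm)[None, :]

    surface = template.surface_idx
    if len(surface):
        if len(x) - 1 < k_neighbors:
            raise DegenerateGeometryError(
                f"{k_neighbors} neighbours requested but only {len(x) - 1} "
                "other points exist"
            )
        d2 = ((x[surface, None, :] - x[None, :, :]) ** 2).sum(axis=-1)
        for row, p in enumerate(surface):
            d2[row, p] = np.inf
            nbr = np.argpartition(d2[row], k_neighbors)[:k_neighbors]
            local = x[nbr] - x[nbr].mean(axis=0)
            # leading two right-singular vectors span the local tangent plane
            _, s, vt = np.linalg.svd(local, full_matrices=False)
            if s[1] <= 1e-12 * max(s[0], 1e-300):
                raise DegenerateGeometryError(
                    f"degenerate neighbourhood at surface point {p}"
                )
            out[p] = vt[:2]
    return out


def slide_semilandmarks(
    configurations: np.ndarray,
    consensus: np.ndarray,
    template: Template,
    k_neighbors: int = 8,
    bem: np.ndarray | None = None,
) -> np.ndarray:
    """One bending-energy sliding pass of every specimen against the
    consensus. Returns updated configurations; fixed landmarks are
    bit-identical to their inputs.
    """
    configs = np.asarray(configurations, dtype=float)
    if bem is None:
        bem = bending_energy_matrix(consensus)
    k = consensus.shape[0]

    out = configs.copy()
    for si in range(len(configs)):
        y = configs[si]
        tangents = tangent_vectors(y, template, k_neighbors=k_neighbors)
        idx_list: list[int] = []   # landmark index per tangent column
        dirs: list[np.ndarray] = []
        for p in sorted(tangents):
            for row in tangents[p]:
                idx_list.append(p)
                dirs.append(row)
        if not idx_list:
            continue
        idx = np.array(idx_list, dtype=int)
        t_dirs = np.array(dirs)                      # (q, 3)
        gram = t_dirs @ t_dirs.T                     # (q, q)
        m = gram * bem[np.ix_(idx, idx)]             # (G .* B_sub)
        v = bem @ (y - consensus)                    # (k, 3)
        rhs = (t_dirs * v[idx]).sum(axis=1)          # (q,)
        ridge = 1e-10 * max(np.trace(m), 1e-30)
        amp = np.linalg.solve(m + ridge * np.eye(len(m)), -rhs)
        disp = np.zeros((k, 3))
        np.add.at(disp, idx, amp[:, None] * t_dirs)
        disp[template.fixed_idx] = 0.0               # fixed landmarks pinned
        out[si] = y + disp
    return out


def total_bending_energy(
    configurations: np.ndarray, consensus: np.ndarray, bem: np.ndarray | None = None
) -> float:
    if bem is None:
        bem = bending_energy_matrix(consensus)
    diff = configurations - consensus[None]
    return float(
        sum(np.trace(d.T @ bem @ d) for d in diff)
    )


def _canonical_rotation(consensus: np.ndarray) -> np.ndarray:
    """Proper rotation carrying the consensus onto its principal axes with a
    deterministic sign convention (largest-|loading| positive on the first
    two axes; the third axis sign is forced so det = +1, i.e. the map is a
    rotation, never a reflection)."""
    c = consensus - consensus.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    r = vt.T
    signs = np.ones(3)
    for j in range(2):
        load = c @ r[:, j]
        if load[np.argmax(np.abs(load))] < 0:
            signs[j] = -1.0
    signs[2] = np.linalg.det(r) * signs[0] * signs[1]
    return r * signs[None, :]


def gpa(
    dataset: LandmarkDataset | np.ndarray,
    sliding: str = "none",
    max_iter: int = 100,
    tol: float = 1e-10,
    n_sliding_cycles: int = 5,
    k_neighbors: int = 8,
) -> AlignedSample:
    """Generalized Procrustes Analysis, optionally with bending-energy
    sliding of the semilandmarks interleaved with re-superimposition.

    ``sliding`` is ``"none"`` or ``"bending_energy"``; sliding requires the
    dataset's template topology, so a bare coordinate stack can only be
    aligned rigidly. Specimens with missing points are rejected: reconstruct
    them first (:mod:`talogm.reconstruct`).
    """
    if isinstance(dataset, LandmarkDataset):
        incomplete = [s.specimen_id for s in dataset.specimens if not s.is_complete]
        if incomplete:
            raise MissingPointsError(
                f"specimens {incomplete} have missing points; run "
                "reconstruction before GPA"
            )
        raw = dataset.coordinate_array()
        template = dataset.template
        ids = dataset.ids
        sexes = dataset.sexes
        pops = dataset.populations
    else:
        raw = np.asarray(dataset, dtype=float)
        template = None
        ids, sexes, pops = [], None, None
    if raw.ndim != 3 or len(raw) < 2:
        raise DegenerateGeometryError("GPA needs at least 2 complete specimens")
    if sliding not in ("none", "bending_energy"):
        raise ValueError(f"unknown sliding mode {sliding!r}")
    if sliding == "bending_energy" and template is None:
        raise ValueError("bending-energy sliding needs a LandmarkDataset with template")

    cs = np.array([centroid_size(x) for x in raw])
    configs = np.stack([_center_scale(x) for x in raw])

    residual_log: list[float] = []

    def superimpose(configs: np.ndarray, consensus: np.ndarray):
        """Iterate rotate-to-consensus / update-consensus to convergence."""
        for _ in range(max_iter):
            for i in range(len(configs)):
                r = optimal_rotation(configs[i], consensus)
                configs[i] = configs[i] @ r
            new_cons = _center_scale(configs.mean(axis=0))
            residual_log.append(float(((configs - new_cons[None]) ** 2).sum()))
            change = np.linalg.norm(new_cons - consensus)
            consensus = new_cons
            if change < tol:
                break
        return configs, consensus

    consensus = _center_scale(configs[0].copy())
    configs, consensus = superimpose(configs, consensus)

    log: list[dict] = []
    if sliding == "bending_energy":
        for cycle in range(n_sliding_cycles):
            bem = bending_energy_matrix(consensus)
            be_before = total_bending_energy(configs, consensus, bem)
            slid = slide_semilandmarks(
                configs, consensus, template, k_neighbors=k_neighbors, bem=bem
            )
            be_after = total_bending_energy(slid, consensus, bem)
            configs = np.stack([_center_scale(x) for x in slid])
            configs, new_consensus = superimpose(configs, consensus)
            cons_change = float(np.linalg.norm(new_consensus - consensus))
            consensus = new_consensus
            log.append(
                {
                    "cycle": cycle,
                    "bending_energy_before": be_before,
                    "bending_energy_after": be_after,
                    "consensus_change": cons_change,
                }
            )
            if cons_change < 1e-8:
                break

    # canonical orientation, then one clean-up pass so every specimen is
    # optimally rotated onto the final consensus (projection consistency)
    rot = _canonical_rotation(consensus)
    consensus = consensus @ rot
    configs = configs @ rot
    # final consensus is the plain arithmetic mean of the aligned specimens
    # (CS marginally < 1); rotation targets are scale-free so this is safe
    for _ in range(3):
        for i in range(len(configs)):
            configs[i] = configs[i] @ optimal_rotation(configs[i], consensus)
        consensus = configs.mean(axis=0)

    return AlignedSample(
        shape_coordinates=configs,
        centroid_sizes=cs,
        consensus=consensus,
        template=template,
        specimen_ids=list(ids),
        sexes=sexes,
        populations=pops,
        sliding_log=log,
        residual_log=residual_log,
    )
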