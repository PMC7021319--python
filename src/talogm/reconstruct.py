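"""Fragmentary-specimen workflow: virtual resection with a cutting plane,
TPS estimation of the missing (semi)landmarks from a reference mean shape,
and end-to-end sex assessment of the reconstructed specimen.

The reference mean (a Procrustes consensus, e.g. of the fragment's own
population or of the pooled sample) is Procrustes-fitted with scaling onto
the fragment's surviving points, so the completed specimen keeps the
fragment's natural pose and size; the TPS fitted on the surviving points
then extends smoothly over the missing region. The completed specimen is
not re-slid against the consensus: sliding assumes trustworthy surface
geometry that an estimated region does not have.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .classify import LDAModel, posterior
from .errors import MissingPointsError, TalogmError
from .geometry import centroid_size
from .io import SpecimenRecord
from .morphospace import MorphospaceModel, project
from .tps import estimate_missing

__all__ = [
    "CuttingPlane",
    "FragmentarySpecimen",
    "FragmentReport",
    "resect",
    "reconstruct_missing",
    "assess_fragment",
]

_BOUNDARY_TOL = 1e-9


@dataclass(frozen=True)
class CuttingPlane:
    """Oriented plane used for virtual resection; points strictly on the
    discard side of the plane are removed."""

    point: np.ndarray
    normal: np.ndarray
    keep_side: str = "positive"     # side (sign of signed distance) kept

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        n = np.asarray(self.normal, dtype=float)
        nrm = np.linalg.norm(n)
        if nrm <= 0:
            raise TalogmError("cutting plane normal has zero length")
        object.__setattr__(self, "normal", n / nrm)
        if self.keep_side not in ("positive", "negative"):
            raise TalogmError(f"keep_side must be positive|negative, got {self.keep_side!r}")

    def signed_distance(self, coords: np.ndarray) -> np.ndarray:
        return (np.asarray(coords, dtype=float) - self.point) @ self.normal


@dataclass
class FragmentarySpecimen:
    record: SpecimenRecord
    missing_idx: np.ndarray
    provenance: str = "observed_damage"   # or "virtual_resection"

    def __post_init__(self) -> None:
        self.missing_idx = np.asarray(self.missing_idx, dtype=int)
        n = len(self.record.coordinates)
        n_present = n - len(self.missing_idx)
        if n_present < 5:
            raise MissingPointsError(
                f"fragment retains only {n_present} points; need >= 5"
            )

    @property
    def present_idx(self) -> np.ndarray:
        mask = np.ones(len(self.record.coordinates), dtype=bool)
        mask[self.missing_idx] = False
        return np.flatnonzero(mask)


@dataclass
class FragmentReport:
    """Audit trail of a fragment sex assessment."""

    completed: SpecimenRecord
    n_missing: int
    centroid_size: float
    lncs: float
    scores: np.ndarray
    label_proportional: str
    posterior_proportional: np.ndarray
    label_equal: str
    posterior_equal: np.ndarray

    @property
    def label(self) -> str:
        return self.label_equal

    @property
    def p_post(self) -> float:
        return float(self.posterior_equal.max())


def resect(record: SpecimenRecord, plane: CuttingPlane) -> FragmentarySpecimen:
    """Flag every point strictly on the plane's discard side as missing
    (boundary points within 1e-9 are kept). Emulates taphonomic damage."""
    if not record.is_complete:
        raise MissingPointsError(
            f"specimen {record.specimen_id!r} already has missing points"
        )
    d = plane.signed_distance(record.coordinates)
    if plane.keep_side == "positive":
        remove = d < -_BOUNDARY_TOL
    else:
        remove = d > _BOUNDARY_TOL
    n_keep = int((~remove).sum())
    if n_keep < 5:
        raise MissingPointsError(
            f"plane leaves only {n_keep} points; resection rejected"
        )
    missing_idx = np.flatnonzero(remove)
    rec = replace(
        record,
        coordinates=record.coordinates.copy(),
        missing=remove.copy(),
    )
    return FragmentarySpecimen(
        record=rec, missing_idx=missing_idx, provenance="virtual_resection"
    )


def reconstruct_missing(
    fragment: FragmentarySpecimen, reference_mean: np.ndarray
) -> SpecimenRecord:
    """Complete a fragment from a reference mean configuration via
    Procrustes fit + TPS extension. Present points are never modified."""
    rec = fragment.record
    if len(fragment.missing_idx) == 0:
        return replace(rec, coordinates=rec.coordinates.copy())
    completed = estimate_missing(
        np.asarray(reference_mean, dtype=float),
        rec.coordinates,
        fragment.missing_idx,
    )
    return replace(
        rec,
        coordinates=completed,
        missing=np.zeros(len(completed), dtype=bool),
        reconstructed=True,
    )


def assess_fragment(
    fragment: FragmentarySpecimen,
    form_model: MorphospaceModel,
    lda_model: LDAModel,
    reference_mean: np.ndarray,
) -> FragmentReport:
    """Reconstruct, superimpose on the trained consensus, project into the
    stored form space and call sex with the discriminant model.

    Posteriors are reported under both frequency-proportional and equal
    priors (the forensic single-specimen convention); ``report.label`` is
    the equal-prior call.
    """
    completed = reconstruct_missing(fragment, reference_mean)
    cs = centroid_size(completed.coordinates)
    lncs = float(np.log(cs))
    scores = project(form_model, completed.coordinates, lncs=lncs)
    x = scores[: lda_model.dims]

    post_prop = posterior(lda_model, x)
    lab_prop = lda_model.class_labels[int(post_prop.argmax())]
    eq_model = LDAModel(
        class_labels=lda_model.class_labels,
        class_means=lda_model.class_means,
        pooled_covariance=lda_model.pooled_covariance,
        priors=np.array([0.5, 0.5]),
        variable_set=lda_model.variable_set,
        n_components=lda_model.n_components,
    )
    post_eq = posterior(eq_model, x)
    lab_eq = eq_model.class_labels[int(post_eq.argmax())]

    return FragmentReport(
        completed=completed,
        n_missing=len(fragment.missing_idx),
        centroid_size=cs,
        lncs=lncs,
        scores=scores,
        label_proportional=lab_prop,
        posterior_proportional=post_prop,
        label_equal=lab_eq,
        posterior_equal=post_eq,
    )
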