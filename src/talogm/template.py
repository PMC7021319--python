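"""Template topology of a (semi)landmark scheme.

A template fixes, once per study, which of the digitized points are true
anatomical landmarks, which are semilandmarks ordered along curves, and
which are semilandmarks spread over surface patches. The study scheme has
251 points: 15 anatomical landmarks, 105 curve semilandmarks on ordered
curves, and 131 surface semilandmarks.

Point indices are 0-based internally; report/label numbering (e.g. the
anatomical landmark labels 1-15) is 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import TemplateError

FIXED = "fixed"
CURVE = "curve"
SURFACE = "surface"


@dataclass(frozen=True)
class Curve:
    """An ordered run of curve semilandmarks, optionally anchored by a fixed
    anatomical landmark at either end (anchors are not members of ``points``,
    so curves stay disjoint even when they share anchors)."""

    points: tuple[int, ...]
    anchor_start: int | None = None
    anchor_end: int | None = None


@dataclass(frozen=True)
class Template:
    n_points: int
    point_type: tuple[str, ...]
    landmark_names: tuple[str, ...]
    curves: tuple[Curve, ...]
    surface_patches: tuple[frozenset[int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.validate()

    # -- derived index sets -------------------------------------------------
    @property
    def fixed_idx(self) -> np.ndarray:
        return np.array([i for i, t in enumerate(self.point_type) if t == FIXED], int)

    @property
    def curve_idx(self) -> np.ndarray:
        return np.array([i for i, t in enumerate(self.point_type) if t == CURVE], int)

    @property
    def surface_idx(self) -> np.ndarray:
        return np.array([i for i, t in enumerate(self.point_type) if t == SURFACE], int)

    @property
    def semilandmark_idx(self) -> np.ndarray:
        return np.array(
            [i for i, t in enumerate(self.point_type) if t != FIXED], int
        )

    def validate(self) -> None:
        n = self.n_points
        if len(self.point_type) != n:
            raise TemplateError(
                f"point_type has {len(self.point_type)} entries for n_points={n}"
            )
        bad = {t for t in self.point_type} - {FIXED, CURVE, SURFACE}
        if bad:
            raise TemplateError(f"unknown point types: {sorted(bad)}")
        n_fixed = sum(t == FIXED for t in self.point_type)
        n_curve = sum(t == CURVE for t in self.point_type)
        n_surface = sum(t == SURFACE for t in self.point_type)
        if n_fixed + n_curve + n_surface != n:
            raise TemplateError("point type counts do not partition n_points")
        if len(self.landmark_names) != n_fixed:
            raise TemplateError(
                f"{len(self.landmark_names)} landmark names for {n_fixed} fixed points"
            )
        seen: set[int] = set()
        curve_members: set[int] = set()
        for ci, c in enumerate(self.curves):
            if len(c.points) < 3:
                raise TemplateError(f"curve {ci} has {len(c.points)} points (< 3)")
            for p in c.points:
                if not (0 <= p < n):
                    raise TemplateError(f"curve {ci} point index {p} out of range")
                if self.point_type[p] != CURVE:
                    raise TemplateError(
                        f"curve {ci} contains point {p} of type {self.point_type[p]}"
                    )
                if p in seen:
                    raise TemplateError(f"point {p} appears in two curves")
                seen.add(p)
            curve_members.update(c.points)
            for anchor in (c.anchor_start, c.anchor_end):
                if anchor is not None:
                    if not (0 <= anchor < n) or self.point_type[anchor] != FIXED:
                        raise TemplateError(
                            f"curve {ci} anchor {anchor} is not a fixed landmark"
                        )
        missing = set(int(i) for i in self.curve_idx) - curve_members
        if missing:
            raise TemplateError(
                f"curve points {sorted(missing)} belong to no curve"
            )
        for pi, patch in enumerate(self.surface_patches):
            for p in patch:
                if not (0 <= p < n) or self.point_type[p] != SURFACE:
                    raise TemplateError(
                        f"surface patch {pi} contains non-surface point {p}"
                    )

    @property
    def counts(self) -> tuple[int, int, int]:
        """(n_fixed, n_curve, n_surface)."""
        return (len(self.fixed_idx), len(self.curve_idx), len(self.surface_idx))

    # -- (de)serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_points": self.n_points,
            "point_type": list(self.point_type),
            "landmark_names": list(self.landmark_names),
            "curves": [
                {
                    "points": list(c.points),
                    "anchor_start": c.anchor_start,
                    "anchor_end": c.anchor_end,
                }
                for c in self.curves
            ],
            "surface_patches": [sorted(p) for p in self.surface_patches],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Template":
        return cls(
            n_points=int(d["n_points"]),
            point_type=tuple(d["point_type"]),
            landmark_names=tuple(d.get("landmark_names", ())),
            curves=tuple(
                Curve(
                    points=tuple(int(p) for p in c["points"]),
                    anchor_start=c.get("anchor_start"),
                    anchor_end=c.get("anchor_end"),
                )
                for c in d.get("curves", ())
            ),
            surface_patches=tuple(
                frozenset(int(p) for p in patch)
                for patch in d.get("surface_patches", ())
            ),
        )
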