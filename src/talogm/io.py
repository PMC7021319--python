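"""Reading and writing landmark datasets and template topology.

Coordinate tables come in two layouts:

* ``wide``  -- one row per specimen; coordinate columns ``p1_x, p1_y, p1_z,
  p2_x, ...`` plus metadata columns (id, sex, population, side);
* ``long``  -- one row per point with columns (id, point, x, y, z) and the
  metadata repeated per row; ``point`` is 1-based.

Column names are supplied through a :class:`TableSchema` rather than
guessed, because deposited spreadsheets rarely document their layout.
CSV/TSV and XLSX are supported via pandas. Units are millimetres and are
passed through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import DatasetError
from .template import Template

SEXES = ("F", "M", "unknown")
SIDES = ("left", "right")


@dataclass
class SpecimenRecord:
    """One specimen: metadata plus its (n_points, 3) coordinates in mm.

    ``missing`` is a boolean mask over points (True = not observed, e.g. a
    fragmentary region); complete specimens carry an all-False mask.
    Missing points are flagged, never silently zero-filled.
    """

    specimen_id: str
    sex: str
    population: str
    side: str
    coordinates: np.ndarray
    missing: np.ndarray | None = None
    reconstructed: bool = False

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise DatasetError(
                f"specimen {self.specimen_id!r}: coordinates must be (n, 3), "
                f"got {self.coordinates.shape}"
            )
        if self.sex not in SEXES:
            raise DatasetError(
                f"specimen {self.specimen_id!r}: sex {self.sex!r} not in {SEXES}"
            )
        if self.side not in SIDES:
            raise DatasetError(
                f"specimen {self.specimen_id!r}: side {self.side!r} not in {SIDES}"
            )
        if self.missing is None:
            self.missing = np.zeros(len(self.coordinates), dtype=bool)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != (len(self.coordinates),):
                raise DatasetError(
                    f"specimen {self.specimen_id!r}: missing mask shape mismatch"
                )
        present = self.coordinates[~self.missing]
        if not np.all(np.isfinite(present)):
            raise DatasetError(
                f"specimen {self.specimen_id!r}: non-finite coordinates at "
                "points not flagged missing"
            )

    @property
    def is_complete(self) -> bool:
        return not bool(self.missing.any())

    def validate_against(self, template: Template) -> None:
        if len(self.coordinates) != template.n_points:
            raise DatasetError(
                f"specimen {self.specimen_id!r} has {len(self.coordinates)} "
                f"points; template requires {template.n_points}"
            )


@dataclass
class LandmarkDataset:
    template: Template
    specimens: list[SpecimenRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [s.specimen_id for s in self.specimens]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise DatasetError(f"duplicate specimen ids: {sorted(dup)}")
        for s in self.specimens:
            s.validate_against(self.template)

    def __len__(self) -> int:
        return len(self.specimens)

    @property
    def ids(self) -> list[str]:
        return [s.specimen_id for s in self.specimens]

    @property
    def sexes(self) -> np.ndarray:
        return np.array([s.sex for s in self.specimens])

    @property
    def populations(self) -> np.ndarray:
        return np.array([s.population for s in self.specimens])

    def coordinate_array(self) -> np.ndarray:
        """(n_specimens, n_points, 3) stack; requires complete specimens."""
        bad = [s.specimen_id for s in self.specimens if not s.is_complete]
        if bad:
            raise DatasetError(
                f"specimens with missing points: {bad}; reconstruct them first"
            )
        return np.stack([s.coordinates for s in self.specimens])

    def subset(self, keep: Sequence[bool] | np.ndarray) -> "LandmarkDataset":
        keep = np.asarray(keep, dtype=bool)
        return LandmarkDataset(
            template=self.template,
            specimens=[s for s, k in zip(self.specimens, keep) if k],
            provenance=self.provenance,
        )


@dataclass(frozen=True)
class TableSchema:
    """Column mapping for landmark tables."""

    layout: str = "wide"  # "wide" | "long"
    id_col: str = "specimen_id"
    sex_col: str = "sex"
    population_col: str = "population"
    side_col: str = "side"
    point_col: str = "point"  # long layout only, 1-based
    coord_cols: tuple[str, str, str] = ("x", "y", "z")  # long layout only


def _coord_columns(n_points: int) -> list[str]:
    return [f"p{i + 1}_{ax}" for i in range(n_points) for ax in "xyz"]


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xlsm"}:
        return pd.read_excel(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def read_landmark_table(
    path: str | Path,
    template: Template,
    schema: TableSchema = TableSchema(),
) -> LandmarkDataset:
    """Parse a delimited-text or XLSX landmark table into a dataset.

    Raises :class:`DatasetError` naming the offending specimen for wrong
    point counts, the row/column for non-numeric coordinates, and listing
    duplicated specimen ids.
    """
    df = _read_table(path)
    n = template.n_points
    meta_cols = [schema.id_col, schema.sex_col, schema.population_col, schema.side_col]
    for c in meta_cols:
        if c not in df.columns:
            raise DatasetError(f"missing metadata column {c!r} in {path}")

    specimens: list[SpecimenRecord] = []
    if schema.layout == "wide":
        cols = _coord_columns(n)
        absent = [c for c in cols if c not in df.columns]
        if absent:
            raise DatasetError(
                f"table lacks {len(absent)} coordinate columns for a "
                f"{n}-point template (first missing: {absent[0]!r}); a "
                "specimen with the wrong point count cannot be read"
            )
        for ridx, row in df.iterrows():
            sid = str(row[schema.id_col])
            vals = row[cols]
            try:
                coords = vals.to_numpy(dtype=float).reshape(n, 3)
            except (TypeError, ValueError):
                bad = next(
                    c for c in cols if not _is_number(row[c])
                )
                raise DatasetError(
                    f"non-numeric coordinate at row {ridx}, column {bad!r} "
                    f"(specimen {sid!r})"
                ) from None
            specimens.append(
                SpecimenRecord(
                    specimen_id=sid,
                    sex=str(row[schema.sex_col]),
                    population=str(row[schema.population_col]),
                    side=str(row[schema.side_col]),
                    coordinates=coords,
                    missing=np.isnan(coords).any(axis=1),
                )
            )
    elif schema.layout == "long":
        needed = [schema.point_col, *schema.coord_cols]
        for c in needed:
            if c not in df.columns:
                raise DatasetError(f"missing column {c!r} for long layout")
        for sid, grp in df.groupby(schema.id_col, sort=False):
            if len(grp) != n:
                raise DatasetError(
                    f"specimen {sid!r} has {len(grp)} points; template "
                    f"requires {n}"
                )
            grp = grp.sort_values(schema.point_col)
            pts = grp[schema.point_col].to_numpy()
            if not np.array_equal(pts, np.arange(1, n + 1)):
                raise DatasetError(
                    f"specimen {sid!r}: point numbering must be 1..{n}"
                )
            try:
                coords = grp[list(schema.coord_cols)].to_numpy(dtype=float)
            except (TypeError, ValueError):
                raise DatasetError(
                    f"non-numeric coordinate for specimen {sid!r}"
                ) from None
            first = grp.iloc[0]
            specimens.append(
                SpecimenRecord(
                    specimen_id=str(sid),
                    sex=str(first[schema.sex_col]),
                    population=str(first[schema.population_col]),
                    side=str(first[schema.side_col]),
                    coordinates=coords,
                    missing=np.isnan(coords).any(axis=1),
                )
            )
    else:
        raise DatasetError(f"unknown layout {schema.layout!r}")

    return LandmarkDataset(
        template=template, specimens=specimens, provenance=str(path)
    )


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def write_landmark_table(
    dataset: LandmarkDataset,
    path: str | Path,
    layout: str = "wide",
    schema: TableSchema = TableSchema(),
) -> Path:
    """Write a dataset as CSV/TSV/XLSX; text formats round-trip bit-exactly
    (coordinates serialized with repr precision)."""
    if len(dataset) == 0:
        raise DatasetError("refusing to write an empty dataset")
    path = Path(path)
    n = dataset.template.n_points
    rows = []
    if layout == "wide":
        cols = _coord_columns(n)
        for s in dataset.specimens:
            coords = s.coordinates.copy()
            coords[s.missing] = np.nan
            row = {
                schema.id_col: s.specimen_id,
                schema.sex_col: s.sex,
                schema.population_col: s.population,
                schema.side_col: s.side,
            }
            row.update(dict(zip(cols, coords.ravel())))
            rows.append(row)
    elif layout == "long":
        for s in dataset.specimens:
            coords = s.coordinates.copy()
            coords[s.missing] = np.nan
            for i in range(n):
                rows.append(
                    {
                        schema.id_col: s.specimen_id,
                        schema.sex_col: s.sex,
                        schema.population_col: s.population,
                        schema.side_col: s.side,
                        schema.point_col: i + 1,
                        schema.coord_cols[0]: coords[i, 0],
                        schema.coord_cols[1]: coords[i, 1],
                        schema.coord_cols[2]: coords[i, 2],
                    }
                )
    else:
        raise DatasetError(f"unknown layout {layout!r}")
    df = pd.DataFrame(rows)
    if path.suffix.lower() in {".xlsx", ".xlsm"}:
        df.to_excel(path, index=False)
    else:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
        # 17 significant digits: doubles round-trip bit-exactly through text
        df.to_csv(path, index=False, sep=sep, float_format="%.17g")
    return path


def mirror_configuration(record: SpecimenRecord) -> SpecimenRecord:
    """Reflect a right-side specimen into a left-side one.

    Reflection is across the plane normal to the first coordinate axis
    (x -> -x); the choice of plane is immaterial after Procrustes
    superimposition but is fixed here for reproducibility. The map has
    determinant -1, preserves all inter-point distances and centroid size,
    and applying it twice restores the input exactly.
    """
    if record.side == "left":
        raise DatasetError(
            f"specimen {record.specimen_id!r} is already left-sided; "
            "refusing to mirror twice"
        )
    coords = record.coordinates.copy()
    coords[:, 0] *= -1.0
    return replace(record, coordinates=coords, side="left")


def standardize_sides(dataset: LandmarkDataset) -> LandmarkDataset:
    """Mirror every right-side specimen so the whole dataset is left-sided."""
    specimens = [
        mirror_configuration(s) if s.side == "right" else s
        for s in dataset.specimens
    ]
    return LandmarkDataset(
        template=dataset.template, specimens=specimens, provenance=dataset.provenance
    )


# -- template config I/O ----------------------------------------------------

def write_template(template: Template, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(template.to_dict(), fh, sort_keys=False)
    return path


def read_template(path: str | Path) -> Template:
    with open(path) as fh:
        return Template.from_dict(yaml.safe_load(fh))
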