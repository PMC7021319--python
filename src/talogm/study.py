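"""Optional regression suite against the study's deposited coordinates.

The original sample (98 left tali, three populations) is deposited as a
spreadsheet of 251-point configurations. When a copy of that file is
available locally, :func:`run_study_regression` re-runs the full pipeline
on it and tabulates the computed quantities next to the values printed in
the study report, so sliding-implementation differences can be audited.
Nothing here downloads anything, and no printed value is ever substituted
for a computed one.
"""

from __future__ import annotations

from pathlib import Path


import pandas as pd

from .align import gpa
from .classify import loo_cv, select_pc_count
from .dimorphism import pearson_r, sex_dimorphism_stats
from .io import LandmarkDataset, TableSchema, read_landmark_table, standardize_sides
from .morphospace import form_space_pca, shape_space_pca
from .template import Template

# Values printed in the study report (pooled sample), used only as the
# comparison column of the regression table -- never as computed output.
PRINTED_POOLED = {
    "shape_pc1_plus_pc2_variance_pct": 24.9,
    "form_pc1_variance_pct": 48.7,
    "form_pc1_lncs_r_abs": 0.99,
    "cs_cohens_d": -2.501,
    "cs_anova_F": 151.7,
    "form_anova_F": 147.5,
    "shape_pc1_lncs_r": 0.25,
    "loo_accuracy_shape_pct": 66.3,
    "loo_accuracy_cs_pct": 87.7,
    "loo_accuracy_form_pct": 91.8,
}


def load_study_coordinates(
    path: str | Path,
    template: Template,
    schema: TableSchema = TableSchema(),
) -> LandmarkDataset:
    """Read a study-layout coordinate spreadsheet (XLSX or CSV)."""
    return standardize_sides(read_landmark_table(path, template, schema))


def compute_pooled_quantities(dataset: LandmarkDataset, max_pcs: int = 10) -> dict:
    """Recompute the pooled-sample quantities the study report prints."""
    aligned = gpa(dataset, sliding="bending_energy")
    shape_m = shape_space_pca(aligned)
    form_m = form_space_pca(aligned)
    sex = aligned.sexes
    lncs = aligned.ln_centroid_sizes
    cs_stats = sex_dimorphism_stats(aligned.centroid_sizes, sex, variable="CS")
    form_stats = sex_dimorphism_stats(form_m.scores[:, 0], sex, variable="form PC1")
    r_form, _ = pearson_r(form_m.scores[:, 0], lncs)
    r_shape, _ = pearson_r(shape_m.scores[:, 0], lncs)
    _, res_shape = select_pc_count(shape_m.scores, sex, max_pcs=max_pcs)
    _, res_form = select_pc_count(form_m.scores, sex, max_pcs=max_pcs)
    res_cs = loo_cv(aligned.centroid_sizes[:, None], sex)
    return {
        "shape_pc1_plus_pc2_variance_pct": 100
        * float(shape_m.variance_fraction[:2].sum()),
        "form_pc1_variance_pct": 100 * float(form_m.variance_fraction[0]),
        "form_pc1_lncs_r_abs": abs(r_form),
        "cs_cohens_d": cs_stats.cohens_d,
        "cs_anova_F": cs_stats.F_statistic,
        "form_anova_F": form_stats.F_statistic,
        "shape_pc1_lncs_r": r_shape,
        "loo_accuracy_shape_pct": res_shape.overall_accuracy,
        "loo_accuracy_cs_pct": res_cs.overall_accuracy,
        "loo_accuracy_form_pct": res_form.overall_accuracy,
    }


def run_study_regression(
    path: str | Path,
    template: Template,
    schema: TableSchema = TableSchema(),
) -> pd.DataFrame:
    """Full regression table: computed vs printed pooled-sample values."""
    dataset = load_study_coordinates(path, template, schema)
    computed = compute_pooled_quantities(dataset)
    rows = [
        {
            "quantity": key,
            "computed": computed[key],
            "printed": PRINTED_POOLED[key],
            "difference": computed[key] - PRINTED_POOLED[key],
        }
        for key in PRINTED_POOLED
    ]
    return pd.DataFrame(rows)
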