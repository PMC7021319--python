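"""End-to-end analysis: alignment -> morphospaces -> dimorphism statistics
-> trajectory permutation tests -> cross-validated classification, with
report tables written per population block and for the pooled sample.

Population-specific blocks re-run GPA (and PCA) on the population subset by
default, which is the natural reading of per-population morphospaces; a
``pooled_subspaces`` switch instead reuses the pooled superimposition and
scores for every block, which keeps all populations in one shared space.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .align import AlignedSample, gpa
from .classify import loo_cv, select_pc_count
from .dimorphism import permutation_trajectory_test, sex_dimorphism_stats
from .errors import TalogmError
from .io import LandmarkDataset, TableSchema, read_landmark_table, read_template, standardize_sides
from .morphospace import form_space_pca, shape_space_pca

log = logging.getLogger("talogm")

__all__ = ["AnalysisConfig", "run_analysis", "analyze_dataset"]


@dataclass
class AnalysisConfig:
    landmark_table: str | None = None
    template_file: str | None = None
    layout: str = "wide"
    output_dir: str = "talogm_out"
    sliding: str = "bending_energy"
    max_iter: int = 100
    tol: float = 1e-10
    k_neighbors: int = 8
    spaces: tuple[str, ...] = ("shape", "form", "cs")
    n_perm: int = 1000
    seed: int = 0
    max_pcs: int = 10
    variance_cutoff: float = 0.70
    lda_priors: str = "proportional"
    per_population: bool = True
    pooled_subspaces: bool = False

    def validate(self) -> None:
        if self.n_perm < 1:
            raise TalogmError("n_perm must be >= 1")
        if not (0 < self.variance_cutoff <= 1):
            raise TalogmError("variance cutoff must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def _block_tables(aligned: AlignedSample, cfg: AnalysisConfig, block: str):
    """Stats + classification for one specimen block (population or pooled)."""
    sex = aligned.sexes
    lncs = aligned.ln_centroid_sizes
    cs = aligned.centroid_sizes
    shape_m = shape_space_pca(aligned)
    form_m = form_space_pca(aligned)

    stats_rows = []
    for space, model in (("shape", shape_m), ("form", form_m)):
        for pc in (0, 1):
            if pc >= model.n_components:
                continue
            s = sex_dimorphism_stats(
                model.scores[:, pc], sex, lncs=lncs, variable=f"{space} PC{pc + 1}"
            )
            stats_rows.append(
                {
                    "block": block,
                    "variable": s.variable,
                    "variance_pct": 100 * model.variance_fraction[pc],
                    "F": s.F_statistic,
                    "df1": s.df[0],
                    "df2": s.df[1],
                    "p": s.p_value,
                    "cohens_d": s.cohens_d,
                    "power": s.achieved_power,
                    "r_lnCS": s.pearson_r_vs_lncs,
                    "r_lnCS_p": s.pearson_p_vs_lncs,
                }
            )
    s = sex_dimorphism_stats(cs, sex, lncs=None, variable="CS")
    stats_rows.append(
        {
            "block": block,
            "variable": "CS",
            "variance_pct": np.nan,
            "F": s.F_statistic,
            "df1": s.df[0],
            "df2": s.df[1],
            "p": s.p_value,
            "cohens_d": s.cohens_d,
            "power": s.achieved_power,
            "r_lnCS": np.nan,
            "r_lnCS_p": np.nan,
        }
    )

    class_rows = []
    for space, model in (("shape", shape_m), ("form", form_m)):
        if space not in cfg.spaces:
            continue
        m, res = select_pc_count(
            model.scores, sex, max_pcs=cfg.max_pcs, priors=cfg.lda_priors,
            variable_set=f"{space}_pcs",
        )
        class_rows.append(_class_row(block, f"{m} {space}-space PCs", res))
    if "cs" in cfg.spaces:
        res = loo_cv(cs[:, None], sex, priors=cfg.lda_priors, variable_set="cs")
        class_rows.append(_class_row(block, "Centroid size", res))

    return stats_rows, class_rows, shape_m, form_m


def _class_row(block: str, variables: str, res) -> dict:
    row = {"block": block, "variables": variables}
    for lab in res.class_labels:
        ok, tot = res.per_class_correct[lab]
        row[f"{lab}_correct"] = f"{ok}/{tot}"
        row[f"{lab}_pct"] = res.per_class_pct[lab]
    row["total_pct"] = res.overall_accuracy
    return row


def analyze_dataset(dataset: LandmarkDataset, cfg: AnalysisConfig) -> dict:
    """Run the full analysis on an in-memory dataset; returns the report
    bundle as DataFrames plus fitted models, without touching disk."""
    cfg.validate()
    dataset = standardize_sides(dataset)
    pooled_aligned = gpa(
        dataset,
        sliding=cfg.sliding,
        max_iter=cfg.max_iter,
        tol=cfg.tol,
        k_neighbors=cfg.k_neighbors,
    )

    stats_rows: list[dict] = []
    class_rows: list[dict] = []
    blocks: dict[str, dict] = {}

    pops = sorted(set(dataset.populations.tolist()))
    if cfg.per_population:
        for pop in pops:
            if cfg.pooled_subspaces:
                keep = pooled_aligned.populations == pop
                sub = AlignedSample(
                    shape_coordinates=pooled_aligned.shape_coordinates[keep],
                    centroid_sizes=pooled_aligned.centroid_sizes[keep],
                    consensus=pooled_aligned.consensus,
                    template=pooled_aligned.template,
                    specimen_ids=[
                        i for i, k in zip(pooled_aligned.specimen_ids, keep) if k
                    ],
                    sexes=pooled_aligned.sexes[keep],
                    populations=pooled_aligned.populations[keep],
                )
            else:
                sub = gpa(
                    dataset.subset(dataset.populations == pop),
                    sliding=cfg.sliding,
                    max_iter=cfg.max_iter,
                    tol=cfg.tol,
                    k_neighbors=cfg.k_neighbors,
                )
            srows, crows, sm, fm = _block_tables(sub, cfg, pop)
            stats_rows += srows
            class_rows += crows
            blocks[pop] = {"aligned": sub, "shape": sm, "form": fm}

    srows, crows, shape_m, form_m = _block_tables(pooled_aligned, cfg, "Pooled sample")
    stats_rows += srows
    class_rows += crows
    blocks["Pooled sample"] = {
        "aligned": pooled_aligned, "shape": shape_m, "form": form_m,
    }

    traj_rows: list[dict] = []
    if len(pops) >= 2:
        for space, model in (("shape", shape_m), ("form", form_m)):
            comps = permutation_trajectory_test(
                model.scores,
                pooled_aligned.ln_centroid_sizes,
                pooled_aligned.populations,
                n_perm=cfg.n_perm,
                seed=cfg.seed,
            )
            for c in comps:
                traj_rows.append(
                    {
                        "space": space,
                        "group_a": c.group_pair[0],
                        "group_b": c.group_pair[1],
                        "angle_deg": c.angle_deg,
                        "angle_p": c.angle_p,
                        "length_diff": c.length_diff,
                        "length_p": c.length_p,
                        "n_permutations": c.n_permutations,
                    }
                )

    pca_rows = []
    for block, b in blocks.items():
        for space in ("shape", "form"):
            vf = b[space].variance_fraction
            for j in range(min(10, len(vf))):
                pca_rows.append(
                    {
                        "block": block,
                        "space": space,
                        "pc": j + 1,
                        "variance_pct": 100 * vf[j],
                    }
                )

    return {
        "stats": pd.DataFrame(stats_rows),
        "classification": pd.DataFrame(class_rows),
        "trajectories": pd.DataFrame(traj_rows),
        "pca_summary": pd.DataFrame(pca_rows),
        "blocks": blocks,
        "aligned": pooled_aligned,
        "config": cfg,
    }


def run_analysis(cfg: AnalysisConfig, dataset: LandmarkDataset | None = None) -> dict:
    """File-level entry point: read inputs per config, analyze, and write
    the report bundle (CSV tables + a JSON log with version and seed)."""
    cfg.validate()
    if dataset is None:
        if cfg.landmark_table is None or cfg.template_file is None:
            raise TalogmError("config must give landmark_table and template_file")
        template = read_template(cfg.template_file)
        dataset = read_landmark_table(
            cfg.landmark_table, template, TableSchema(layout=cfg.layout)
        )
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        bundle = analyze_dataset(dataset, cfg)
    except TalogmError as e:
        raise TalogmError(f"analysis failed: {e}") from e
    for name in ("stats", "classification", "trajectories", "pca_summary"):
        bundle[name].to_csv(out / f"{name}.csv", index=False)
    sliding_log = bundle["aligned"].sliding_log
    with open(out / "run_log.json", "w") as fh:
        json.dump(
            {
                "talogm_version": __version__,
                "seed": cfg.seed,
                "n_specimens": len(dataset),
                "n_points": dataset.template.n_points,
                "sliding": cfg.sliding,
                "n_perm": cfg.n_perm,
                "sliding_log": sliding_log,
            },
            fh,
            indent=2,
        )
    log.info("analysis written to %s", out)
    return bundle
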