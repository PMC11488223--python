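"""End-to-end pipeline: simulate -> features -> qc -> score -> omics.

`RunConfig` collects every stage's parameters; `run_pipeline` executes the
selected stages into one artifact directory with a manifest, so a full run
is reproducible from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as eio
from . import morphometry, omics, proteomics, scoring
from .gsva import gsva_scores
from .synthetic import (
    CANONICAL_FEATURES,
    NEG_CTL,
    POS_CTL,
    POS_EV,
    SyntheticOmicsConfig,
    SyntheticPlateConfig,
    gen_feature_table,
    gen_omics_tables,
    gen_plate_layout,
)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

STAGES = ("simulate", "features", "qc", "score", "secretome", "lipidome", "proteome")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Parameters of a pipeline run; unknown keys are rejected."""

    stages: tuple[str, ...] = STAGES
    out_dir: str = "evmorph_run"
    seed: int = 0
    # simulate
    n_wells_per_group: int = 8
    cells_per_well_range: tuple[int, int] = (700, 1000)
    ev_effect: float = 0.5
    # inputs (used when `simulate` is not among the stages)
    features_path: str | None = None
    layout_path: str | None = None
    secretion_path: str | None = None
    secretion_groups_path: str | None = None
    lipids_path: str | None = None
    lipid_groups_path: str | None = None
    proteins_path: str | None = None
    protein_groups_path: str | None = None
    gene_sets_path: str | None = None
    # qc / scoring
    min_cells: int = 50
    solidity_rule: bool = True
    nucleus_ratio_rule: bool = True
    normalize: bool = True
    # omics statistics
    alpha: float = 0.05
    fc_threshold: float = 2.0
    bh_correct: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        d = dict(d)
        for tup_key in ("stages", "cells_per_well_range"):
            if tup_key in d and isinstance(d[tup_key], list):
                d[tup_key] = tuple(d[tup_key])
        return cls(**d)

    def __post_init__(self):
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stage(s): {sorted(bad)}")


def _load_or(path, what):
    if path is None:
        raise FileNotFoundError(f"{what} input required but no path configured")
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"{what} file not found: {p}")
    return eio.read_table(p)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the artifact directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    eio.write_manifest(out / "manifest.json", dataclasses.asdict(config),
                       seed=config.seed)
    stages = config.stages
    features = layout = None
    try:
        if "simulate" in stages:
            stage = "simulate"
            plate_cfg = SyntheticPlateConfig(
                n_wells_per_group=config.n_wells_per_group,
                cells_per_well_range=config.cells_per_well_range,
                ev_effect=config.ev_effect,
                seed=config.seed,
            )
            layout = gen_plate_layout(plate_cfg)
            features = gen_feature_table(plate_cfg, layout)
            eio.write_table(layout, out / "layout.csv")
            eio.write_table(features, out / "features.csv")
            om = gen_omics_tables(SyntheticOmicsConfig(seed=config.seed))
            eio.write_table(om["secretion"].reset_index(), out / "secretion.csv")
            eio.write_table(
                om["secretion_groups"].rename_axis("sample").reset_index(),
                out / "secretion_groups.csv",
            )
            eio.write_table(om["lipids"], out / "lipids.csv")
            eio.write_table(
                om["lipid_groups"].rename_axis("sample").reset_index(),
                out / "lipid_groups.csv",
            )
            eio.write_table(om["proteins"].reset_index(), out / "proteins.csv")
            eio.write_table(
                om["protein_groups"].rename_axis("sample").reset_index(),
                out / "protein_groups.csv",
            )
            eio.write_gmt(om["gene_sets"], out / "gene_sets.gmt")

        if features is None and (set(stages) & {"features", "qc", "score"}):
            stage = "features"
            features = _load_or(config.features_path, "feature table")
            layout = _load_or(config.layout_path, "plate layout")

        if "qc" in stages:
            stage = "qc"
            kept, rejected = morphometry.qc_filter(
                features,
                solidity_rule=config.solidity_rule,
                nucleus_ratio_rule=config.nucleus_ratio_rule,
            )
            eio.write_table(kept, out / "features_qc.csv")
            eio.write_table(rejected, out / "features_rejected.csv")
            features = kept

        if "score" in stages:
            stage = "score"
            profiles = scoring.aggregate_well_medians(
                features, layout, min_cells=config.min_cells
            )
            feats = [f for f in CANONICAL_FEATURES if f in profiles.columns]
            if config.normalize:
                profiles_n = scoring.minmax_normalize(profiles, feats)
                res = scoring.composite_pca_score(profiles_n, feats, standardize=False)
            else:
                profiles_n = profiles
                res = scoring.composite_pca_score(profiles, feats, standardize=True)
            scores = profiles_n[["group"]].copy()
            scores["PC1"] = res.pc1
            scores["PC1_normalized"] = scoring.normalize_scores(
                res.pc1, profiles_n["group"]
            )
            eio.write_table(scores.reset_index(), out / "scores.csv")
            zres = scoring.z_factor(res.pc1, profiles_n["group"])
            (out / "score_summary.json").write_text(json.dumps({
                "variance_explained_pct": res.variance_explained[:2].tolist(),
                "z_factor": zres.z_factor,
                "quality_label": zres.quality_label,
                "loadings_pc1": res.loadings["PC1"].to_dict(),
            }, indent=2))

        if "secretome" in stages:
            stage = "secretome"
            sec = (
                om["secretion"] if "simulate" in stages
                else _load_or(config.secretion_path, "secretion table").set_index(
                    "analyte")
            )
            sgroups = (
                om["secretion_groups"] if "simulate" in stages
                else _load_or(config.secretion_groups_path,
                              "secretion groups").set_index("sample")["group"]
            )
            de = omics.differential_panel(
                sec, sgroups, NEG_CTL, POS_CTL,
                alpha=config.alpha, correct=config.bh_correct,
            )
            eio.write_table(de.reset_index(), out / "secretome_differential.csv")

        if "lipidome" in stages:
            stage = "lipidome"
            lip = (
                om["lipids"] if "simulate" in stages
                else _load_or(config.lipids_path, "lipid table")
            )
            totals = omics.lipid_class_totals(lip)
            for mode, tbl in totals.items():
                eio.write_table(tbl.reset_index(), out / f"lipid_totals_{mode}.csv")

        if "proteome" in stages:
            stage = "proteome"
            prot = (
                om["proteins"] if "simulate" in stages
                else _load_or(config.proteins_path, "protein matrix").set_index(
                    "protein")
            )
            pgroups = (
                om["protein_groups"] if "simulate" in stages
                else _load_or(config.protein_groups_path,
                              "protein groups").set_index("sample")["group"]
            )
            de = proteomics.moderated_de(
                prot, pgroups, (POS_EV, POS_CTL),
                fc_threshold=config.fc_threshold, alpha=config.alpha,
            )
            eio.write_table(de.reset_index(), out / "proteome_differential.csv")
            counts = proteomics.volcano_classify(de)
            gene_sets = (
                om["gene_sets"] if "simulate" in stages
                else eio.read_gmt(config.gene_sets_path)
            )
            es = gsva_scores(prot, gene_sets)
            eio.write_table(es.reset_index(names="set"), out / "gsva_scores.csv")
            anova = proteomics.gene_set_anova(es, pgroups)
            eio.write_table(anova.reset_index(), out / "gsva_anova.csv")
            (out / "proteome_summary.json").write_text(json.dumps(counts, indent=2))
    except Exception as exc:
        if isinstance(exc, (PipelineError, FileNotFoundError)):
            raise
        raise PipelineError(stage, str(exc)) from exc
    return out
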