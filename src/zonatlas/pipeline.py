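"""Configuration-driven orchestration: simulate → QC → cluster → axis →
zonation → DE → ssGSEA, with a machine-readable run report.

The run is driven by a YAML config validated against a pydantic schema;
every parameter has a default, and the resolved values of all of them are
echoed into ``run_report.json`` so a run is fully reproducible from its
report.  One global seed is fanned out to per-stage seeds by hashing the
stage name (CRC-32 mixed with the global seed), which keeps stages
independent without seed collisions.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, ValidationError as PydanticValidationError

from . import axis_inference, de_enrichment, preprocessing, synthetic_data, zonation
from .errors import ValidationError
from .io_visium import SpotDataset, merge_conditions, read_visium, write_visium

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# config schema
# ---------------------------------------------------------------------------

class SimulateConfig(BaseModel):
    enabled: bool = True
    n_lobules: int = 2
    spots_per_lobule: int = 500
    n_per_family: int = 120
    conditions: list[str] = list(synthetic_data.CONDITIONS)
    lib_size_mean: float = synthetic_data.DEFAULT_LIB_SIZE
    dispersion: float = synthetic_data.DEFAULT_DISPERSION
    mito_boost: dict[str, float] = dict(synthetic_data.DEFAULT_MITO_BOOST)
    erythroid_fraction: float = synthetic_data.DEFAULT_ERYTHROID_FRACTION


class PreprocessingConfig(BaseModel):
    mito_prefix: str = preprocessing.DEFAULT_MITO_PREFIX
    hemoglobin_genes: list[str] = list(preprocessing.DEFAULT_HEMOGLOBIN_GENES)
    scale: float = 1e4
    n_pcs: int = 30
    k_neighbors: int = 15
    resolution: float = 0.8
    n_top_genes: int = 2000
    hb_threshold: float = 0.1


class AxisConfig(BaseModel):
    n_dc: int = 10
    kernel_width: str | float = "auto"
    n_bins: int = 20
    portal_markers: list[str] = list(synthetic_data.DEFAULT_PORTAL_MARKERS)
    central_markers: list[str] = list(synthetic_data.DEFAULT_CENTRAL_MARKERS)
    root_cluster: Optional[int] = None  # default: most portal-marker-high cluster


class ZonationConfig(BaseModel):
    threshold: float = 0.1
    min_count: int = 10
    min_spots: int = 200
    n_bins: int = 20
    pole_boundaries: tuple[float, float] = (0.25, 0.75)


class DEConfig(BaseModel):
    lfc_threshold: float = 0.25
    fdr_threshold: float = 0.05
    comparisons: list[tuple[str, str]] = [("fasted", "ctrl"), ("refed", "fasted")]


class SSGSEAConfig(BaseModel):
    alpha: float = 0.25
    min_overlap: int = 5
    normalize: bool = False
    gmt: Optional[str] = None  # path to a GMT file; default sets are empty


class RunConfig(BaseModel):
    """Top-level pipeline configuration; every field has a default."""

    seed: int = 0
    outdir: str
    input_bundles: dict[str, str] = Field(default_factory=dict)
    simulate: SimulateConfig = SimulateConfig()
    preprocessing: PreprocessingConfig = PreprocessingConfig()
    axis: AxisConfig = AxisConfig()
    zonation: ZonationConfig = ZonationConfig()
    de: DEConfig = DEConfig()
    ssgsea: SSGSEAConfig = SSGSEAConfig()


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return validate_config(raw)


def validate_config(raw: dict) -> RunConfig:
    try:
        return RunConfig(**raw)
    except PydanticValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(x) for x in first["loc"])
        raise ValidationError(f"config field {loc!r}: {first['msg']}") from exc


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed: CRC-32 of the stage name mixed with the global seed."""
    return (zlib.crc32(stage.encode()) ^ (global_seed * 2654435761)) % (2**31)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def analyze_dataset(ds: SpotDataset, config: RunConfig) -> dict:
    """In-memory QC → clustering → axis → zonation on a merged dataset.

    Returns a dict with the intermediate objects (qc, norm, embedding,
    axis, labels); used by callers that do not need on-disk artifacts.
    """
    pp = config.preprocessing
    qc = preprocessing.compute_qc(ds, pp.mito_prefix, pp.hemoglobin_genes)
    keep = ~qc["flag_remove"].to_numpy()
    ds = ds.subset_spots(keep)
    qc = preprocessing.QCMetrics(qc.table.loc[keep].reset_index(drop=True))
    norm = preprocessing.normalize_log(ds, pp.scale)
    emb = preprocessing.reduce_and_cluster(
        norm, n_pcs=pp.n_pcs, k_neighbors=pp.k_neighbors,
        resolution=pp.resolution, seed=stage_seed(config.seed, "cluster"),
        n_top_genes=pp.n_top_genes,
    )
    emb = preprocessing.flag_erythroid_clusters(emb, qc, pp.hb_threshold)
    major_idx = np.flatnonzero(emb.major_spot_mask())
    ax_cfg = config.axis
    sub_emb = preprocessing.reduce_and_cluster(
        norm[:, major_idx], n_pcs=pp.n_pcs, k_neighbors=pp.k_neighbors,
        resolution=pp.resolution, seed=stage_seed(config.seed, "axis"),
        n_top_genes=pp.n_top_genes,
    )
    dc = axis_inference.diffusion_map(
        sub_emb, n_dc=ax_cfg.n_dc, kernel_width=ax_cfg.kernel_width
    )
    root = (
        ax_cfg.root_cluster
        if ax_cfg.root_cluster is not None
        else axis_inference.default_root_cluster(
            norm[:, major_idx], ds.gene_ids, sub_emb.cluster_labels,
            ax_cfg.portal_markers,
        )
    )
    axis = axis_inference.pseudotime(
        dc, sub_emb.cluster_labels, root,
        spots=major_idx, barcodes=ds.barcodes[major_idx],
    )
    axis = axis_inference.orient_axis(
        axis, norm, ds.gene_ids, ax_cfg.portal_markers, ax_cfg.central_markers
    )
    z = config.zonation
    labels = zonation.classify_all(
        ds, axis, norm=norm, n_bins=z.n_bins, threshold=z.threshold,
        min_count=z.min_count, min_spots=z.min_spots,
        pole_boundaries=tuple(z.pole_boundaries),
    )
    return {
        "ds": ds, "qc": qc, "norm": norm, "embedding": emb,
        "axis": axis, "labels": labels,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the pipeline and return the run report dict.

    Artifacts are written under ``config.outdir``; identical config + seed
    produce identical artifacts.  On stage failure a ``FAILED`` marker file
    naming the stage is left next to the partial artifacts and the
    exception propagates.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": json.loads(config.model_dump_json()),
        "stages": {},
        "artifacts": {},
    }
    stage = "init"

    def done(name: str, **info):
        report["stages"][name] = {"status": "ok", **info}

    try:
        # ----- input: simulate or read bundles ---------------------------
        stage = "simulate"
        truths = None
        if config.simulate.enabled and not config.input_bundles:
            sim = config.simulate
            panel = synthetic_data.default_gene_panel(
                sim.n_per_family, seed=stage_seed(config.seed, "panel")
            )
            samples, truths = synthetic_data.simulate_study(
                gene_specs=panel,
                n_lobules=sim.n_lobules,
                spots_per_lobule=sim.spots_per_lobule,
                conditions=sim.conditions,
                seed=stage_seed(config.seed, "simulate"),
                lib_size_mean=sim.lib_size_mean,
                dispersion=sim.dispersion,
                mito_boost=sim.mito_boost,
                erythroid_fraction=sim.erythroid_fraction,
            )
            for ds_c, cond in samples:
                write_visium(ds_c, out / f"bundle_{cond}")
            synthetic_data.write_truth(truths, out / "truth")
            done(stage, conditions=list(sim.conditions))
        else:
            samples = [
                (read_visium(path), cond)
                for cond, path in config.input_bundles.items()
            ]
            done(stage, skipped=True)

        ds = merge_conditions(samples)

        # ----- QC + normalization + clustering ---------------------------
        stage = "qc"
        pp = config.preprocessing
        qc = preprocessing.compute_qc(ds, pp.mito_prefix, pp.hemoglobin_genes)
        qc.table.to_csv(out / "qc.tsv", sep="\t", index=False)
        keep = ~qc["flag_remove"].to_numpy()
        ds = ds.subset_spots(keep)
        qc = preprocessing.QCMetrics(qc.table.loc[keep].reset_index(drop=True))
        done(stage, n_spots=ds.n_spots)

        stage = "cluster"
        norm = preprocessing.normalize_log(ds, pp.scale)
        emb = preprocessing.reduce_and_cluster(
            norm,
            n_pcs=pp.n_pcs,
            k_neighbors=pp.k_neighbors,
            resolution=pp.resolution,
            seed=stage_seed(config.seed, "cluster"),
            n_top_genes=pp.n_top_genes,
        )
        emb = preprocessing.flag_erythroid_clusters(emb, qc, pp.hb_threshold)
        pd.DataFrame(
            {
                "barcode": ds.barcodes,
                "cluster": emb.cluster_labels,
                "major_flag": emb.major_flag[emb.cluster_labels],
            }
        ).to_csv(out / "clusters.tsv", sep="\t", index=False)
        done(stage, n_clusters=emb.n_clusters,
             n_major=int(emb.major_flag.sum()))

        # ----- axis -------------------------------------------------------
        stage = "axis"
        ax_cfg = config.axis
        major = emb.major_spot_mask()
        major_idx = np.flatnonzero(major)
        sub_norm = norm[:, major_idx]
        sub_emb = preprocessing.reduce_and_cluster(
            sub_norm,
            n_pcs=pp.n_pcs,
            k_neighbors=pp.k_neighbors,
            resolution=pp.resolution,
            seed=stage_seed(config.seed, "axis"),
            n_top_genes=pp.n_top_genes,
        )
        dc = axis_inference.diffusion_map(
            sub_emb, n_dc=ax_cfg.n_dc, kernel_width=ax_cfg.kernel_width
        )
        root = (
            ax_cfg.root_cluster
            if ax_cfg.root_cluster is not None
            else axis_inference.default_root_cluster(
                sub_norm, ds.gene_ids, sub_emb.cluster_labels, ax_cfg.portal_markers
            )
        )
        axis = axis_inference.pseudotime(
            dc, sub_emb.cluster_labels, root,
            spots=major_idx, barcodes=ds.barcodes[major_idx],
        )
        axis = axis_inference.orient_axis(
            axis, norm, ds.gene_ids, ax_cfg.portal_markers, ax_cfg.central_markers
        )
        pd.DataFrame(
            {
                "barcode": axis.barcodes,
                "t": axis.t,
                "condition": ds.condition[axis.spots],
            }
        ).to_csv(out / "axis.tsv", sep="\t", index=False)
        done(stage, root_cluster=int(root), root_spot=axis.root_spot)

        # ----- zonation ---------------------------------------------------
        stage = "zonation"
        z = config.zonation
        labels = zonation.classify_all(
            ds,
            axis,
            norm=norm,
            n_bins=z.n_bins,
            threshold=z.threshold,
            min_count=z.min_count,
            min_spots=z.min_spots,
            pole_boundaries=tuple(z.pole_boundaries),
        )
        labels.to_csv(out / "zonation_labels.tsv", sep="\t", index=False)
        conds = list(pd.unique(labels["condition"]))
        transitions = {}
        for ca, cb in zip(conds[:-1], conds[1:]):
            tt = zonation.transition_table(
                zonation.labels_as_series(labels, ca),
                zonation.labels_as_series(labels, cb),
            )
            tt.matrix.to_csv(out / f"transitions_{ca}_to_{cb}.tsv", sep="\t")
            sankey = {
                "source_condition": ca,
                "target_condition": cb,
                "flows": [
                    {"source": la, "target": lb,
                     "value": int(tt.matrix.loc[la, lb]),
                     "genes": tt.genes.get((la, lb), [])}
                    for la in zonation.LABELS
                    for lb in zonation.LABELS
                    if tt.matrix.loc[la, lb] > 0
                ],
            }
            (out / f"sankey_{ca}_to_{cb}.json").write_text(
                json.dumps(sankey, indent=1)
            )
            transitions[f"{ca}->{cb}"] = tt
        done(stage, n_labeled=int(len(labels)))

        # ----- differential expression ------------------------------------
        stage = "de"
        de_cfg = config.de
        for cond_a, cond_b in de_cfg.comparisons:
            in_a = np.flatnonzero((ds.condition == cond_a) & major)
            in_b = np.flatnonzero((ds.condition == cond_b) & major)
            if len(in_a) < 3 or len(in_b) < 3:
                continue
            de = de_enrichment.wilcoxon_de(
                norm, ds.gene_ids, in_a, in_b,
                lfc_threshold=de_cfg.lfc_threshold,
                fdr_threshold=de_cfg.fdr_threshold,
            )
            de.table.to_csv(
                out / f"de_{cond_a}_vs_{cond_b}.tsv", sep="\t", index=False
            )
        done(stage)

        # ----- ssGSEA ------------------------------------------------------
        stage = "ssgsea"
        ss = config.ssgsea
        gene_sets = (
            de_enrichment.read_gmt(ss.gmt)
            if ss.gmt
            else de_enrichment.DEFAULT_GENE_SETS
        )
        usable = {
            k: v for k, v in gene_sets.items()
            if len(set(v) & set(ds.gene_ids)) >= ss.min_overlap
        }
        if usable:
            scores = de_enrichment.ssgsea_scores(
                norm, ds.gene_ids, usable,
                alpha=ss.alpha, min_overlap=ss.min_overlap,
                normalize=ss.normalize,
            )
            scores.scores.to_csv(out / "ssgsea_scores.tsv", sep="\t")
            prof = de_enrichment.pathway_axis_profile(
                scores, axis, n_bins=ax_cfg.n_bins, condition=ds.condition
            )
            prof.table.to_csv(out / "ssgsea_axis_profile.tsv", sep="\t", index=False)
            done(stage, n_sets=len(usable))
        else:
            logger.warning("no gene set overlaps the data; ssGSEA skipped")
            done(stage, skipped=True)

    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise

    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "run_report.json":
            report["artifacts"][str(p.relative_to(out))] = _sha256(p)
    (out / "run_report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


__all__ = [
    "RunConfig",
    "SimulateConfig",
    "PreprocessingConfig",
    "AxisConfig",
    "ZonationConfig",
    "DEConfig",
    "SSGSEAConfig",
    "load_config",
    "validate_config",
    "stage_seed",
    "analyze_dataset",
    "run_pipeline",
]
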