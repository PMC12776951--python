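"""Configuration-driven orchestration of the full analysis.

A pipeline run consumes a dataset directory (one sub-directory per sample
with the standard file set, as written by :func:`spikemap.synthetic.generate_dataset`
or exported from MERSCOPE-style processing) and executes: QC → filtering →
normalization → integration → Leiden clustering → prevalence accounting →
marker ranking and enrichment → the requested axis analyses.  Outputs are a
versioned JSON report of all headline statistics, per-stage CSV/TSV tables
and a log of every seed and threshold actually used.  Re-running an
identical config reproduces identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, axis, domains, io as _io, qc
from .errors import ConfigError, StageError

log = logging.getLogger("spikemap")

REPORT_SCHEMA = 1

_DEFAULTS = {
    "thresholds": {"min_counts": 25.0, "min_volume": 500.0},
    "clustering": {"resolution": 1.0, "k": 15, "d": 30},
    "analysis": {
        "n_bins": 30,
        "gene_pairs": [["VRT2", "SEP1-4"]],
        "gradient_gene": "VRT2",
        "transect_samples": [],
        "groups_samples": [],
        "crosshyb_probe": None,
        "pseudobulk": True,
    },
}


@dataclass
class PipelineConfig:
    dataset_dir: str
    out_dir: str
    seed: int
    samples: list[str] = field(default_factory=list)  # empty = all in manifest
    thresholds: dict = field(default_factory=lambda: dict(_DEFAULTS["thresholds"]))
    clustering: dict = field(default_factory=lambda: dict(_DEFAULTS["clustering"]))
    analysis: dict = field(default_factory=lambda: dict(_DEFAULTS["analysis"]))


def _merge_section(name: str, given: dict) -> dict:
    out = dict(_DEFAULTS[name])
    for key, val in given.items():
        if key not in out:
            raise ConfigError(f"unknown key '{name}.{key}'")
        out[key] = val
    return out


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and strictly validate a YAML pipeline config, filling defaults."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    allowed = {"dataset_dir", "out_dir", "seed", "samples", "thresholds", "clustering", "analysis"}
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    for req in ("dataset_dir", "out_dir", "seed"):
        if req not in raw:
            raise ConfigError(f"missing required config key '{req}'")
    cfg = PipelineConfig(
        dataset_dir=str(raw["dataset_dir"]),
        out_dir=str(raw["out_dir"]),
        seed=int(raw["seed"]),
        samples=[str(s) for s in raw.get("samples", [])],
        thresholds=_merge_section("thresholds", raw.get("thresholds", {})),
        clustering=_merge_section("clustering", raw.get("clustering", {})),
        analysis=_merge_section("analysis", raw.get("analysis", {})),
    )
    dataset = Path(cfg.dataset_dir)
    if not dataset.exists():
        raise ConfigError(f"dataset directory not found: {dataset}")
    for sid in cfg.samples:
        if not (dataset / sid).exists():
            raise ConfigError(f"sample directory not found: {dataset / sid}")
    return cfg


def dump_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)


def stage_seed(base_seed: int, stage_index: int) -> int:
    """Expand the global seed into independent per-stage seeds by a fixed
    counter scheme, so inserting a stage does not perturb earlier ones."""
    return int((base_seed * 10007 + 97 * stage_index + 13) % 2**31)


def _discover_samples(dataset: Path, requested: list[str]) -> list[str]:
    if requested:
        return requested
    manifest = dataset / "manifest.json"
    if manifest.exists():
        with open(manifest) as fh:
            return sorted(json.load(fh)["samples"])
    return sorted(p.name for p in dataset.iterdir() if (p / "cells.csv").exists())


def load_sample(sample_dir: str | Path):
    """Read one sample's cells and counts (and ROI/groups when present)."""
    sample_dir = Path(sample_dir)
    cells = _io.read_cell_metadata(sample_dir / "cells.csv")
    counts = _io.read_count_matrix(sample_dir / "counts.csv")
    extras = {}
    if (sample_dir / "roi.geojson").exists():
        extras["rois"] = _io.read_rois(sample_dir / "roi.geojson")
    if (sample_dir / "groups.csv").exists():
        extras["groups"] = _io.read_groups(sample_dir / "groups.csv")
    if (sample_dir / "bulk_reference.csv").exists():
        extras["bulk_reference"] = _io.read_bulk_reference(sample_dir / "bulk_reference.csv")
    return cells, counts, extras


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the report dict."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema": REPORT_SCHEMA,
        "spikemap_version": __version__,
        "seed": cfg.seed,
        "thresholds": cfg.thresholds,
        "clustering": cfg.clustering,
        "stages": {},
    }
    dataset = Path(cfg.dataset_dir)
    sample_ids = _discover_samples(dataset, cfg.samples)
    if not sample_ids:
        raise StageError("load", f"no samples found under {dataset}")

    # ---- QC and filtering (per sample)
    thresholds = qc.QcThresholds(**cfg.thresholds)
    per_sample = {}
    qc_stage: dict = {"per_sample": {}}
    try:
        for sid in sample_ids:
            cells, counts, extras = load_sample(dataset / sid)
            rate, _ = qc.blank_rate(counts)
            filt, cells_f, flog = qc.filter_cells(counts, cells, thresholds)
            entry = {"blank_pct": rate, **flog}
            if cfg.analysis.get("crosshyb_probe"):
                ratio, probe_mean = qc.crosshyb_ratio(counts, cfg.analysis["crosshyb_probe"])
                entry["crosshyb_fold"] = ratio
                entry["crosshyb_mean_counts"] = probe_mean
            qc_stage["per_sample"][sid] = entry
            per_sample[sid] = {
                "cells": cells_f,
                "counts": qc.strip_blanks(filt),
                "extras": extras,
            }
        qc_stage["mean_blank_pct"] = float(
            np.mean([v["blank_pct"] for v in qc_stage["per_sample"].values()])
        )
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise StageError("qc", str(e)) from e
    report["stages"]["qc"] = qc_stage
    log.info("qc: %d samples, mean blank %.3f%%", len(sample_ids), qc_stage["mean_blank_pct"])

    # ---- normalization (per sample) and integration
    try:
        normed = []
        for sid in sample_ids:
            s = per_sample[sid]
            m = domains.normalize_counts(s["counts"])
            m.obs["sample_id"] = s["cells"]["sample_id"].loc[m.obs_names].to_numpy()
            s["normalized"] = m
            normed.append(m)
        embedding, stacked = domains.integrate_and_embed(normed, n_comps=cfg.clustering["d"])
    except Exception as e:  # noqa: BLE001
        raise StageError("integrate", str(e)) from e
    report["stages"]["integrate"] = {
        "n_cells": int(stacked.n_obs),
        "n_genes": int(stacked.n_vars),
        "embedding_dim": int(embedding.shape[1]),
    }

    # ---- clustering and prevalence
    try:
        labeling = domains.cluster_domains(
            stacked,
            resolution=cfg.clustering["resolution"],
            seed=stage_seed(cfg.seed, 3),
            n_neighbors=cfg.clustering["k"],
        )
        all_cells = pd.concat([per_sample[sid]["cells"] for sid in sample_ids])
        prevalence = domains.domain_prevalence(labeling, all_cells)
        per_sample_domains = domains.count_domains_per_sample(prevalence)
    except Exception as e:  # noqa: BLE001
        raise StageError("cluster", str(e)) from e
    labeling.labels.rename("ed").to_csv(out_dir / "labels.csv")
    prevalence.to_csv(out_dir / "prevalence.csv", index=False)
    report["stages"]["cluster"] = {
        "n_domains": labeling.n_domains,
        "domains_per_sample": {str(k): int(v) for k, v in per_sample_domains.items()},
    }

    # ---- marker ranking and enrichment
    try:
        table = domains.rank_domain_markers(stacked, labeling)
        enriched, summary = domains.call_enriched(table)
    except Exception as e:  # noqa: BLE001
        raise StageError("enrich", str(e)) from e
    tidy = (
        table.scores.stack()
        .rename("score")
        .reset_index()
        .rename(columns={"level_1": "gene"})
    )
    tidy["mean_expr"] = [
        table.mean_expr.at[ed, g] for ed, g in zip(tidy["ed"], tidy["gene"])
    ]
    tidy["enriched"] = [enriched.at[ed, g] for ed, g in zip(tidy["ed"], tidy["gene"])]
    tidy.to_csv(out_dir / "enrichment.tsv", sep="\t", index=False)
    report["stages"]["enrich"] = summary

    # ---- axis analyses
    ana = cfg.analysis
    axis_stage: dict = {}
    try:
        for sid in ana.get("transect_samples", []):
            s = per_sample[sid]
            cells_t = s["cells"]
            rois = s["extras"].get("rois")
            if rois:
                from .geometry import roi_filter

                cells_t = roi_filter(cells_t, rois[0])
            m = s["normalized"][cells_t.index.to_list()].copy()
            entry: dict = {}
            gene = ana.get("gradient_gene")
            if gene and gene in m.var_names:
                entry["basal_central_ratio"] = axis.basal_central_ratio(
                    m, cells_t, gene, n_bins=ana["n_bins"]
                )
            sub_labels = domains.DomainLabeling(labels=labeling.labels.loc[m.obs_names])
            for pair in ana.get("gene_pairs", []):
                ga, gb = pair
                cx = axis.coexpression_summary(m, sub_labels, ga, gb)
                entry[f"coexpression_{ga}_{gb}"] = cx.table.loc["all"].to_dict()
                cx.table.to_csv(out_dir / f"coexpression_{sid}_{ga}_{gb}.csv")
            axis_stage[sid] = entry

        for sid in ana.get("groups_samples", []):
            s = per_sample[sid]
            groups = s["extras"].get("groups")
            if groups is None:
                raise StageError("axis", f"sample {sid} has no group annotation file")
            groups = groups[groups["cell_id"].isin(s["normalized"].obs_names)]
            entry = {}
            for tissue in ("AM", "LR"):
                sub = groups[groups["tissue_class"] == tissue]
                if sub.empty:
                    continue
                gm = axis.group_means(s["normalized"], sub)
                gmf = axis.filter_group_genes(gm)
                positions = sub.drop_duplicates("group_id").set_index("group_id")["position"]
                res = axis.axis_pca(gmf, positions)
                entry[tissue] = {
                    "n_groups": int(gmf.shape[0]),
                    "n_genes": int(gmf.shape[1]),
                    "spearman_rho": res.spearman_rho,
                    "spearman_p": res.spearman_p,
                }
                res.scores.to_csv(out_dir / f"pca_scores_{sid}_{tissue}.csv")
                res.loadings.to_csv(out_dir / f"pca_loadings_{sid}_{tissue}.csv")
            entry["ridge_sizes"] = axis.ridge_size_stats(groups)
            axis_stage[sid] = {**axis_stage.get(sid, {}), **entry}

        if ana.get("pseudobulk", True):
            pb = {}
            for sid in sample_ids:
                s = per_sample[sid]
                ref = s["extras"].get("bulk_reference")
                if ref is None:
                    continue
                vec = axis.pseudobulk(s["normalized"], list(s["normalized"].obs_names))
                pb[sid] = axis.pseudobulk_correlation(vec, ref)
            if pb:
                axis_stage["pseudobulk_spearman"] = pb
                axis_stage["pseudobulk_spearman_mean"] = float(np.mean(list(pb.values())))
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("axis", str(e)) from e
    report["stages"]["axis"] = axis_stage

    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
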