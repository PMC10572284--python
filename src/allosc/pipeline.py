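"""End-to-end orchestration: QC -> normalize -> cluster -> DE -> GO -> TCR -> diversity.

All stage parameters live in :class:`PipelineConfig` with defaults matching
the analysis conventions this pipeline implements (QC at 500/5000 expressed
genes and 5% mitochondrial signal, scale factor 10,000, 2000 HVGs, 16 PCA
dimensions, clustering resolution 0.4, marker ranking at adjusted p < 1e-5,
GO DE thresholds 0.01 for cluster markers and 0.1 for the pre/post contrast,
chain filters at 25 reads, top > 0.8 and flocus > 0.1).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import cluster as cluster_mod
from . import de as de_mod
from . import go as go_mod
from . import io as io_mod
from . import preprocess, synth, tcr
from .containers import DIVERSITY_LEVELS
from .errors import ConfigurationError

logger = logging.getLogger(__name__)

DEFAULT_MARKER_MAP = {
    "CD4-like": ["CD4"],
    "CD8-like": ["CD8A", "CD8B"],
    "non-T contaminant": ["CD14", "CD19", "NCAM1"],
}
DEFAULT_CONTAMINANT_MARKERS = ["CD14", "CD19", "NCAM1"]


@dataclass
class PipelineConfig:
    """All stage parameters, paths and the master seed."""

    # QC
    min_genes: int = 500
    max_genes: int = 5000
    max_pct_mito: float = 5.0
    mito_prefix: str = "MT-"
    # normalization / reduction
    scale_factor: float = 10_000.0
    n_hvg: int = 2000
    hvg_method: str = "vst"
    protein_coding_only: bool = True
    n_dims: int = 16
    per_chip_centering: bool = False
    # clustering
    knn_k: int = 20
    resolution: float = 0.4
    # differential expression / GO
    de_method: str = "wilcoxon"
    de_adjust: str = "bonferroni"
    min_pct: float = 0.05
    de_alpha: float = 1e-5
    go_alpha_cluster: float = 0.01
    go_alpha_prepost: float = 0.1
    # TCR
    min_reads: int = 25
    top_threshold: float = 0.8
    flocus_threshold: float = 0.1
    # orchestration
    seed: int = 0
    counts_dir: Optional[str] = None
    chains_path: Optional[str] = None
    gene_sets_path: Optional[str] = None
    gene_lengths_path: Optional[str] = None
    out_dir: str = "allosc_out"
    simulate: bool = False
    synth: Dict = field(default_factory=dict)
    marker_map: Dict[str, List[str]] = field(default_factory=lambda: dict(DEFAULT_MARKER_MAP))
    contaminant_markers: List[str] = field(default_factory=lambda: list(DEFAULT_CONTAMINANT_MARKERS))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class RunReport:
    """Per-stage bookkeeping plus the analysis tables of a pipeline run."""

    config_hash: str = ""
    seed: int = 0
    stage_counts: Dict[str, Dict[str, int]] = field(default_factory=dict)
    cluster_table: Optional[pd.DataFrame] = None
    marker_tables: Dict[int, pd.DataFrame] = field(default_factory=dict)
    prepost_tables: Dict[str, pd.DataFrame] = field(default_factory=dict)
    go_tables: Dict[str, pd.DataFrame] = field(default_factory=dict)
    diversity: Optional[pd.DataFrame] = None
    vdj: Optional[pd.DataFrame] = None
    overlap: Optional[pd.DataFrame] = None

    def to_json_dict(self) -> dict:
        def tab(df):
            return None if df is None else json.loads(df.to_json(orient="split"))

        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "stage_counts": self.stage_counts,
            "cluster_table": tab(self.cluster_table),
            "marker_tables": {str(k): tab(v) for k, v in self.marker_tables.items()},
            "prepost_tables": {k: tab(v) for k, v in self.prepost_tables.items()},
            "go_tables": {k: tab(v) for k, v in self.go_tables.items()},
            "diversity": tab(self.diversity),
            "vdj": tab(self.vdj),
            "overlap": tab(self.overlap),
        }


def _log_stage(report: RunReport, stage: str, n_in: int, n_out: int, t0: float) -> None:
    report.stage_counts[stage] = {"input": int(n_in), "output": int(n_out)}
    logger.info("stage=%s input=%d output=%d elapsed=%.2fs", stage, n_in, n_out, time.time() - t0)


def run_pipeline(cfg: PipelineConfig, write_outputs: bool = True) -> RunReport:
    """Run the full analysis; returns a RunReport and writes stage tables."""
    report = RunReport(config_hash=cfg.config_hash(), seed=cfg.seed)
    out = cfg.out_dir
    if write_outputs:
        os.makedirs(out, exist_ok=True)

    # ------------------------------------------------------------------ input
    t0 = time.time()
    if cfg.simulate or cfg.counts_dir is None:
        scfg = synth.SynthConfig(**{"rng_seed": cfg.seed, **cfg.synth})
        study = synth.simulate_study(scfg)
        counts, chains = study.counts, study.chains
        gene_lengths, categories = study.gene_lengths, study.go_categories
        if write_outputs:
            io_mod.write_counts(counts, os.path.join(out, "counts"))
            io_mod.write_chains(chains, os.path.join(out, "chains.tsv"))
    else:
        counts = io_mod.read_counts(cfg.counts_dir)
        chains = io_mod.read_chains(cfg.chains_path) if cfg.chains_path else None
        gene_lengths = (
            io_mod.read_gene_lengths(cfg.gene_lengths_path)
            if cfg.gene_lengths_path
            else pd.Series(counts.genes.get("length"), index=counts.gene_ids)
        )
        categories = (
            io_mod.read_gene_sets(cfg.gene_sets_path) if cfg.gene_sets_path else {}
        )
    _log_stage(report, "input", counts.n_cells, counts.n_cells, t0)

    # --------------------------------------------------------------------- QC
    t0 = time.time()
    qc = preprocess.compute_qc_metrics(counts, mito_prefix=cfg.mito_prefix)
    filtered = preprocess.filter_cells(
        counts, qc, min_genes=cfg.min_genes, max_genes=cfg.max_genes,
        max_pct_mito=cfg.max_pct_mito,
    )
    _log_stage(report, "qc", counts.n_cells, filtered.n_cells, t0)
    if write_outputs:
        qc.to_csv(os.path.join(out, "qc_metrics.tsv"), sep="\t")

    # ---------------------------------------------------- normalize / reduce
    t0 = time.time()
    nm = preprocess.normalize(filtered, scale_factor=cfg.scale_factor)
    hvg = preprocess.select_hvg(
        nm, n_top=cfg.n_hvg, protein_coding_only=cfg.protein_coding_only,
        method=cfg.hvg_method,
    )
    nm_for_pca = preprocess.center_per_chip(nm) if cfg.per_chip_centering else nm
    n_dims = min(cfg.n_dims, len(hvg), nm.values.shape[1] - 1)
    emb = preprocess.pca(nm_for_pca, hvg, n_dims=n_dims)
    _log_stage(report, "normalize_pca", filtered.n_cells, filtered.n_cells, t0)

    # ---------------------------------------------------------------- cluster
    t0 = time.time()
    graph = cluster_mod.build_knn_graph(emb, k=min(cfg.knn_k, filtered.n_cells - 1))
    assign = cluster_mod.louvain_cluster(graph, resolution=cfg.resolution, seed=cfg.seed)
    annotations = cluster_mod.label_clusters(
        assign, nm, cfg.marker_map, contaminant_markers=cfg.contaminant_markers
    )
    report.cluster_table = annotations
    _log_stage(report, "cluster", filtered.n_cells, int(assign.nunique()), t0)
    if write_outputs:
        assign.rename("cluster").to_csv(os.path.join(out, "clusters.tsv"), sep="\t")
        annotations.to_csv(os.path.join(out, "cluster_annotations.tsv"), sep="\t")

    retained_clusters = [
        c for c in sorted(assign.unique())
        if not annotations.loc[c, "excluded"] and (assign == c).sum() >= 3
    ]

    # --------------------------------------------------------------------- DE
    t0 = time.time()
    universe = list(nm.gene_ids)
    for c in retained_clusters:
        if (assign != c).sum() < 3:
            continue
        markers = de_mod.cluster_markers(
            nm, assign, c, min_pct=cfg.min_pct, method=cfg.de_method,
            adjust=cfg.de_adjust,
        )
        report.marker_tables[c] = de_mod.rank_de(markers, alpha=cfg.de_alpha)
        if categories is not None and len(categories):
            report.go_tables[f"cluster{c}"] = go_mod.go_analysis(
                markers, categories, gene_lengths, universe, alpha=cfg.go_alpha_cluster
            )
        for stim in ("don", "thirdP"):
            contrast = de_mod.prepost_contrast(
                nm, assign, c, stimulus=stim, min_pct=cfg.min_pct,
                method=cfg.de_method, adjust=cfg.de_adjust,
            )
            if contrast is not None:
                key = f"cluster{c}_{stim}"
                report.prepost_tables[key] = contrast
                if categories is not None and len(categories):
                    report.go_tables[f"prepost_{key}"] = go_mod.go_analysis(
                        contrast, categories, gene_lengths, universe,
                        alpha=cfg.go_alpha_prepost,
                    )
    _log_stage(report, "de_go", len(retained_clusters), len(report.marker_tables), t0)
    if write_outputs:
        for c, table in report.marker_tables.items():
            table.to_csv(os.path.join(out, f"markers_cluster{c}.tsv"), sep="\t", index=False)
        for key, table in report.prepost_tables.items():
            table.to_csv(os.path.join(out, f"prepost_{key}.tsv"), sep="\t", index=False)
        for key, table in report.go_tables.items():
            table.to_csv(os.path.join(out, f"go_{key}.tsv"), sep="\t", index=False)

    # -------------------------------------------------------------------- TCR
    if chains is not None and len(chains):
        t0 = time.time()
        selected, trace = tcr.apply_filter_cascade(
            chains, min_reads=cfg.min_reads, top_threshold=cfg.top_threshold,
            flocus_threshold=cfg.flocus_threshold,
        )
        clonotypes = tcr.build_clonotypes(selected)
        sample_of = dict(counts.cell_meta["sample_id"]) if "sample_id" in counts.cell_meta else {}
        by_sample: Dict[str, list] = {}
        for ct in clonotypes:
            sample = sample_of.get(ct.cell_id, "sample")
            by_sample.setdefault(sample, []).append(ct)
        report.diversity = tcr.diversity_table(by_sample, DIVERSITY_LEVELS)
        report.vdj = tcr.vdj_table(selected)
        if len(by_sample) >= 2:
            report.overlap = tcr.clonotype_overlap(by_sample)
        _log_stage(report, "tcr", len(chains), len(selected), t0)
        if write_outputs:
            trace.to_csv(os.path.join(out, "chain_filter_trace.tsv"), sep="\t", index=False)
            selected.to_csv(os.path.join(out, "chains_filtered.tsv"), sep="\t", index=False)
            pd.DataFrame(
                [
                    {"cell_id": c.cell_id, "tra": c.tra, "trb": c.trb,
                     "paired_key": c.paired_key}
                    for c in clonotypes
                ]
            ).to_csv(os.path.join(out, "clonotypes.tsv"), sep="\t", index=False)
            report.diversity.to_csv(os.path.join(out, "diversity.tsv"), sep="\t", index=False)
            report.vdj.to_csv(os.path.join(out, "vdj_table.tsv"), sep="\t", index=False)
            if report.overlap is not None:
                report.overlap.to_csv(os.path.join(out, "clonotype_overlap.tsv"), sep="\t")

    if write_outputs:
        with open(os.path.join(out, "report.json"), "w") as fh:
            json.dump(report.to_json_dict(), fh, indent=1, default=float, sort_keys=True)
        _write_markdown_report(report, os.path.join(out, "report.md"))
    return report


def _write_markdown_report(report: RunReport, path: str) -> None:
    lines = ["# Pipeline run report", "", f"seed: {report.seed}",
             f"config: {report.config_hash}", "", "## Stage counts", ""]
    for stage, c in report.stage_counts.items():
        lines.append(f"- {stage}: {c['input']} -> {c['output']}")
    if report.cluster_table is not None:
        lines += ["", "## Clusters", "", report.cluster_table.to_markdown()]
    if report.diversity is not None and len(report.diversity):
        lines += ["", "## Repertoire diversity", "", report.diversity.round(3).to_markdown()]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
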