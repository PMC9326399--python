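"""End-to-end orchestration: files in, artifact bundle out.

Stage order is fixed: read -> align -> probe filter -> z-score
(expression) -> per-modality adaptive kernel (optionally tuned) ->
kernel addition -> tensor-product-graph diffusion -> spectral clustering
(K via the configured selector) -> diffusion-potential embedding of the
integrated similarity (t = 200 by default in this mode) -> marker
composite scores -> pairwise differential tests -> per-cluster
Kaplan-Meier / log-rank.  Artifacts are stamped with a hash of the
resolved configuration and the seed; byte-for-byte reproducibility under
a fixed seed is part of the contract (timestamps only ever appear in the
run log).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import omics_io
from .cluster import (ClusterAssignment, cluster_eigenvectors, select_k_eigengap,
                      select_k_multimodality, spectral_eigen)
from .downstream import (MarkerPanel, composite_score, emt_score, pairwise_de,
                         survival_by_cluster, write_survival)
from .embed import Embedding, PhateConfig, phate, write_embedding
from .integrate import DiffusionConfig, combine_kernels, tpg_diffuse
from .kernel import (KernelConfig, SimilarityMatrix, adaptive_kernel,
                     pairwise_distance, read_similarity, tune_kernel,
                     write_similarity)
from .omics_io import OmicsMatrix

logger = logging.getLogger("omicsfuse")

MODALITY_KEYS = ("expression", "methylation", "microbiome")


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    expression_path: str | None = None
    methylation_path: str | None = None
    microbiome_path: str | None = None
    clinical_path: str | None = None
    probe_annotation_path: str | None = None
    precomputed_similarity_path: str | None = None
    modalities: tuple[str, ...] = MODALITY_KEYS
    orientation: str = "features_by_samples"
    kernel: KernelConfig = field(default_factory=KernelConfig)
    tune: bool = False
    diffusion: DiffusionConfig = field(default_factory=DiffusionConfig)
    phate: PhateConfig = field(default_factory=lambda: PhateConfig(t=200))
    k_method: str = "multimodality_gap"  # or eigengap / fixed
    k_min: int = 2
    k_max: int = 12
    k_fixed: int | None = None
    de_features: tuple[str, ...] | None = None
    max_de_features: int = 50
    out_dir: str = "omicsfuse_out"
    seed: int = 0

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)  # analysis identity, not output location
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    similarity: SimilarityMatrix
    clusters: ClusterAssignment
    embedding: Embedding
    scores: pd.DataFrame
    de_table: pd.DataFrame
    logrank: tuple[float, int, float]
    config: RunConfig


def _load_inputs(cfg: RunConfig):
    matrices = []
    paths = {
        "expression": cfg.expression_path,
        "methylation": cfg.methylation_path,
        "microbiome": cfg.microbiome_path,
    }
    for mod in cfg.modalities:
        path = paths[mod]
        if path is None:
            raise ValueError(f"modality {mod!r} requested but no path given")
        matrices.append(omics_io.read_matrix(path, cfg.orientation, mod))
    clinical = omics_io.read_clinical(cfg.clinical_path) if cfg.clinical_path else None
    return matrices, clinical


def integrate_modalities(
    matrices: Sequence[OmicsMatrix],
    kernel_cfg: KernelConfig,
    diffusion_cfg: DiffusionConfig,
    tune: bool = False,
) -> SimilarityMatrix:
    """Kernels per modality, kernel addition, TPG diffusion (the in-memory
    core of the pipeline; expression should already be z-scored)."""
    views = []
    for m in matrices:
        d = pairwise_distance(m)
        if tune:
            _, w = tune_kernel(d, kernel_cfg)
        else:
            w = adaptive_kernel(d, kernel_cfg)
        views.append(w)
    combined = views[0] if len(views) == 1 else combine_kernels(views)
    return tpg_diffuse(combined, diffusion_cfg)


def cluster_similarity(
    w: SimilarityMatrix,
    k_method: str = "multimodality_gap",
    k_min: int = 2,
    k_max: int = 12,
    k_fixed: int | None = None,
    seed: int = 0,
) -> ClusterAssignment:
    """K selection plus k-means on the leading eigenvectors."""
    m = min(w.n, k_max + 1)
    es = spectral_eigen(w, m)
    if k_method == "fixed":
        if k_fixed is None:
            raise ValueError("k_method='fixed' requires k_fixed")
        k = k_fixed
    elif k_method == "eigengap":
        k = select_k_eigengap(es, k_min, k_max)
    elif k_method == "multimodality_gap":
        k = select_k_multimodality(es, k_min, k_max)
    else:
        raise ValueError(f"unknown k_method {k_method!r}")
    assignment = cluster_eigenvectors(es, k, seed=seed)
    assignment.method_k = k_method  # type: ignore[assignment]
    return assignment


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute the full analysis and write the artifact bundle."""
    t0 = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = f"# config_hash={cfg.config_hash()}\tseed={cfg.seed}\n"
    log_lines = [f"config_hash={cfg.config_hash()} seed={cfg.seed}"]

    def stage(name):
        log_lines.append(f"[{time.time() - t0:8.2f}s] {name}")
        logger.info("pipeline stage: %s", name)

    try:
        stage("read")
        matrices, clinical = _load_inputs(cfg)
        if clinical is None:
            raise ValueError("a clinical table is required")

        stage("align")
        matrices, clinical = omics_io.align_samples(matrices, clinical)

        stage("filter+scale")
        processed = []
        expr_z = None
        for m in matrices:
            if m.modality == "methylation" and cfg.probe_annotation_path:
                ann = omics_io.read_probe_annotation(cfg.probe_annotation_path)
                m = omics_io.filter_probes(m, ann)
            if m.modality == "expression":
                m = omics_io.zscore_features(m)
                expr_z = m
            processed.append(m)

        if cfg.precomputed_similarity_path:
            stage("precomputed similarity")
            diffused = read_similarity(cfg.precomputed_similarity_path)
            keep = [s for s in diffused.sample_ids if s in set(clinical.sample_ids)]
            if keep != diffused.sample_ids:
                raise ValueError("precomputed similarity samples must match inputs")
        else:
            stage("kernels+integration")
            diffused = integrate_modalities(processed, cfg.kernel, cfg.diffusion, cfg.tune)

        stage("spectral clustering")
        clusters = cluster_similarity(
            diffused, cfg.k_method, cfg.k_min, cfg.k_max, cfg.k_fixed, cfg.seed
        )

        stage("embedding")
        embedding = phate(diffused, cfg.phate)

        stage("scores")
        if expr_z is not None:
            panel = MarkerPanel()
            scores = pd.DataFrame(
                {
                    "sample_id": expr_z.sample_ids,
                    "basal_composite": composite_score(expr_z, panel),
                    "emt_score": emt_score(expr_z, panel),
                    "cluster": clusters.labels,
                }
            )
        else:
            scores = pd.DataFrame(
                {"sample_id": clusters.sample_ids, "cluster": clusters.labels}
            )

        stage("differential expression")
        if expr_z is not None:
            feats = list(cfg.de_features) if cfg.de_features else _top_variable(
                expr_z, cfg.max_de_features
            )
            de_table = pairwise_de(expr_z, clusters, feats)
        else:
            de_table = pd.DataFrame(
                columns=["feature_id", "group_a", "group_b", "statistic", "p_raw", "p_adj_holm"]
            )

        stage("survival")
        curves, logrank = survival_by_cluster(clinical, clusters)
    except Exception as err:
        log_lines.append(f"FAILED: {err}")
        (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
        raise

    stage("write artifacts")
    with open(out / "similarity.tsv", "w") as fh:
        fh.write(stamp)
        write_similarity(diffused, fh)
    with open(out / "embedding.tsv", "w") as fh:
        fh.write(stamp)
        write_embedding(embedding, fh)
    with open(out / "clusters.tsv", "w") as fh:
        fh.write(stamp)
        pd.DataFrame(
            {
                "sample_id": clusters.sample_ids,
                "cluster_label": clusters.labels,
                "K": clusters.K,
                "method_k": clusters.method_k,
            }
        ).to_csv(fh, sep="\t", index=False)
    with open(out / "scores.tsv", "w") as fh:
        fh.write(stamp)
        scores.to_csv(fh, sep="\t", index=False, float_format="%.10g")
    with open(out / "de.tsv", "w") as fh:
        fh.write(stamp)
        de_table.to_csv(fh, sep="\t", index=False, float_format="%.10g")
    with open(out / "survival.tsv", "w") as fh:
        fh.write(stamp)
    with open(out / "survival.tsv", "a") as fh:
        write_survival(curves, logrank, fh)
    (out / "config.json").write_text(
        json.dumps(dataclasses.asdict(cfg), sort_keys=True, indent=2, default=str) + "\n"
    )
    stage("done")
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return PipelineResult(diffused, clusters, embedding, scores, de_table, logrank, cfg)


def _top_variable(expr: OmicsMatrix, k: int) -> list[str]:
    var = expr.values.var(axis=0)
    order = np.argsort(-var, kind="stable")[:k]
    return [expr.feature_ids[j] for j in sorted(order)]
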