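"""End-to-end orchestration: read -> standardize -> threshold -> metrics -> maps.

Each stage writes a plain-format artifact (edge list, metrics CSV, NIfTI
maps) and the run produces a JSON manifest listing every artifact with its
SHA-256 checksum plus the graph summary (N, E, K, S), so reruns with the
same configuration are verifiably identical and cached intermediates can
be reused.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._util import config_hash, sha256_file
from .connectivity import plan_tiles, standardize, threshold_stream, write_edge_list
from .errors import StatisticUndefinedError, ValidationError, VoxelGraphError
from .graph import (
    GraphSummary,
    compute_vertex_metrics,
    edge_density_statistic,
    from_weighted_edges,
    select_threshold,
)
from .group import group_stack, truncated_svd
from .nifti_io import BrainMask, MetricMap, load_mask, read_masked, write_metric_map

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_subject_pipeline", "run_group_pipeline"]

DEFAULT_THRESHOLD_GRID = np.round(np.arange(0.95, 0.04, -0.05), 2)


@dataclass
class PipelineConfig:
    """Configuration for a single-subject run.

    Exactly one of ``threshold`` / ``target_S`` must be set: either the
    correlation threshold is fixed, or it is selected automatically to
    reach the requested edge-density statistic S.
    """

    image: str
    mask: str
    out_prefix: str
    threshold: float | None = 0.6
    target_S: float | None = None
    tile_budget_bytes: int = 512 * 2**20
    chunk_volumes: int = 32
    pagerank_damping: float = 0.85
    pagerank_tol: float = 1e-8
    pagerank_max_iter: int = 200
    seed: int = 0
    metric_dtype: str = "float32"
    threshold_grid: tuple[float, ...] = tuple(DEFAULT_THRESHOLD_GRID)

    def __post_init__(self):
        if (self.threshold is None) == (self.target_S is None):
            raise ValidationError(
                "exactly one of threshold / target_S must be set"
            )

    def to_dict(self) -> dict:
        return asdict(self)


def _provenance(cfg: PipelineConfig) -> dict:
    # out_prefix is excluded: where results are written must not change
    # what is written, so reruns to a different directory stay bit-identical
    params = {k: v for k, v in cfg.to_dict().items() if k != "out_prefix"}
    return {
        "tool": "voxelgraph",
        "version": __version__,
        "config_hash": config_hash(params),
        "seed": cfg.seed,
    }


def run_subject_pipeline(cfg: PipelineConfig) -> dict:
    """Run the whole single-subject pipeline and return the manifest dict.

    Stages: masked read, columnwise standardization, tiled thresholded
    correlation streaming, per-vertex graph metrics, NIfTI metric maps.
    Any stage failure aborts with the stage name attached.
    """
    out_prefix = Path(cfg.out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    stage = "read"
    try:
        table = read_masked(cfg.image, cfg.mask, chunk_volumes=cfg.chunk_volumes)
        mask = load_mask(cfg.mask)

        stage = "standardize"
        z = standardize(table)

        stage = "threshold"
        if cfg.target_S is not None:
            threshold, _ = select_threshold(
                z, cfg.target_S, np.asarray(cfg.threshold_grid)
            )
            logger.info("selected threshold %.3f for target S %.3f", threshold, cfg.target_S)
        else:
            threshold = float(cfg.threshold)
        plan = plan_tiles(z.n_voxels, 8, max(cfg.tile_budget_bytes, z.n_voxels * 8))
        edges = threshold_stream(z, plan, threshold)
        edge_path = Path(f"{out_prefix}edges.txt.gz")
        write_edge_list(
            edges, edge_path, source=str(cfg.image), extra_header=_provenance(cfg)
        )
        artifacts["edges"] = str(edge_path)

        stage = "metrics"
        g = from_weighted_edges(edges)
        metrics = compute_vertex_metrics(
            g,
            damping=cfg.pagerank_damping,
            tol=cfg.pagerank_tol,
            max_iter=cfg.pagerank_max_iter,
        )
        csv_path = Path(f"{out_prefix}metrics.csv")
        pd.DataFrame(
            {
                "vertex": table.index_map,
                "degree": metrics.d,
                "tc": metrics.tc,
                "cc": metrics.cc,
                "pagerank": metrics.pr,
                "component": table.index_map[metrics.comp],
            }
        ).to_csv(csv_path, index=False)
        artifacts["metrics_csv"] = str(csv_path)

        stage = "maps"
        dtype = np.float32 if cfg.metric_dtype == "float32" else np.float64
        for name, values in [
            ("degree", metrics.d),
            ("cc", metrics.cc),
            ("pagerank", metrics.pr),
            ("component", table.index_map[metrics.comp]),
        ]:
            map_path = Path(f"{out_prefix}{name}.nii.gz")
            write_metric_map(MetricMap(values=np.asarray(values, dtype=np.float64)),
                             mask, map_path, dtype=dtype)
            artifacts[f"map_{name}"] = str(map_path)
    except VoxelGraphError as exc:
        raise VoxelGraphError(f"stage {stage!r} failed: {exc}") from exc

    comp_sizes = np.bincount(metrics.comp, minlength=g.n_vertices)
    comp_sizes = comp_sizes[comp_sizes > 0]
    try:
        summary = edge_density_statistic(g.n_edges, g.n_vertices)
        S = summary.S
        K = summary.K
    except StatisticUndefinedError:
        S = None
        K = 2.0 * g.n_edges / g.n_vertices if g.n_vertices else 0.0

    manifest = {
        "provenance": _provenance(cfg),
        "config": cfg.to_dict(),
        "graph_summary": {
            "N": g.n_vertices,
            "E": g.n_edges,
            "K": K,
            "S": S,
            "threshold": threshold,
        },
        "components": {
            "n_components": int(comp_sizes.size),
            "n_nonsingleton": int((comp_sizes > 1).sum()),
            "largest": int(comp_sizes.max()) if comp_sizes.size else 0,
        },
        "artifacts": {
            name: {"path": path, "sha256": sha256_file(path)}
            for name, path in artifacts.items()
        },
    }
    manifest_path = Path(f"{out_prefix}manifest.json")
    manifest_path.write_text(json.dumps(manifest, indent=2))
    manifest["manifest_path"] = str(manifest_path)
    return manifest


def run_group_pipeline(
    cfg: PipelineConfig,
    subjects: list[tuple[str, str]],
    svd_k: int | None = None,
    center: bool = False,
) -> dict:
    """Per-subject pipelines plus an optional group stack + truncated SVD.

    ``subjects`` is a list of (image_path, subject_label) pairs; every
    subject shares ``cfg.mask``.  Per-subject outputs are identical to what
    individual :func:`run_subject_pipeline` calls would produce.
    """
    if not subjects:
        raise ValidationError("no subjects given")
    manifests = {}
    tables = []
    for image, label in subjects:
        if not Path(image).exists():
            raise ValidationError(f"missing input for subject {label!r}: {image}")
        sub_cfg = PipelineConfig(
            **{**cfg.to_dict(), "image": str(image),
               "out_prefix": f"{cfg.out_prefix}{label}_"}
        )
        manifests[label] = run_subject_pipeline(sub_cfg)
        if svd_k is not None:
            tables.append(read_masked(image, cfg.mask, chunk_volumes=cfg.chunk_volumes))

    group_manifest: dict = {"subjects": manifests}
    if svd_k is not None:
        gm = group_stack(tables)
        s, _, right = truncated_svd(gm, svd_k, center=center, seed=cfg.seed)
        sv_path = Path(f"{cfg.out_prefix}singular_values.csv")
        pd.DataFrame({"component": np.arange(1, svd_k + 1), "singular_value": s}).to_csv(
            sv_path, index=False
        )
        group_manifest["svd"] = {
            "k": svd_k,
            "center": center,
            "singular_values_csv": str(sv_path),
            "sha256": sha256_file(sv_path),
        }
    manifest_path = Path(f"{cfg.out_prefix}group_manifest.json")
    manifest_path.write_text(json.dumps(group_manifest, indent=2, default=str))
    group_manifest["manifest_path"] = str(manifest_path)
    return group_manifest
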