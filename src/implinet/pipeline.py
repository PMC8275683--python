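"""End-to-end pipeline: binarize -> pairs -> network -> paths -> score -> evaluate."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import core_io, implication, network_builder, path_engine, stepminer

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All tunable parameters of a pipeline run, serializable to JSON."""

    margin: float = stepminer.DEFAULT_MARGIN
    sthr: float = implication.DEFAULT_STHR
    pthr: float = implication.DEFAULT_PTHR
    min_frac: float = 0.05
    min_count: int = 3
    min_cluster_size: int = network_builder.DEFAULT_MIN_CLUSTER_SIZE
    edge_support_min: float = network_builder.DEFAULT_EDGE_SUPPORT_MIN
    max_len: int = path_engine.DEFAULT_MAX_LEN
    healthy_label: str = "healthy"
    disease_label: str = "disease"
    missing_policy: str = "drop_gene"
    log2: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as handle:
            return cls.from_dict(json.load(handle))


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise StageError(f"stage {name!r} failed: {exc}") from exc

    return wrap


def run_pipeline(
    config: PipelineConfig,
    expr_path: str | Path,
    ann_path: str | Path,
    out_dir: str | Path,
) -> dict:
    """Run every stage on one cohort and write all artifacts to ``out_dir``.

    Writes network.json, selection.json, scores.tsv, report.json and the
    resolved config.json.  Returns the report dict.  Deterministic for a
    fixed config and inputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    matrix = _stage("read_expression")(
        core_io.read_expression, expr_path, config.missing_policy, config.log2
    )
    annotation = _stage("read_annotation")(core_io.read_annotation, ann_path)
    annotation.check_against(matrix)

    ternary, fits = _stage("binarize")(stepminer.binarize_matrix, matrix, config.margin)
    genes = _stage("dynamic_range_filter")(
        stepminer.dynamic_range_filter, ternary, config.min_frac, config.min_count
    )
    logger.info("%d/%d genes pass the dynamic-range filter", len(genes), matrix.n_genes)
    if len(genes) < 2:
        raise StageError("stage 'dynamic_range_filter' failed: fewer than 2 bimodal genes")

    results = _stage("all_pairs")(
        implication.all_pairs_network, ternary, genes, config.sthr, config.pthr
    )
    logger.info("%d gene pairs carry a Boolean implication", len(results))

    graph = _stage("equivalence_graph")(network_builder.build_equivalence_graph, results)
    clusters = _stage("cluster_genes")(
        network_builder.cluster_genes, graph, config.min_cluster_size
    )
    clusters = _stage("orient_clusters")(
        network_builder.orient_clusters,
        clusters, matrix, annotation, fits, config.healthy_label, config.disease_label,
    )
    network = _stage("cluster_network")(
        network_builder.build_cluster_network, clusters, results, config.edge_support_min
    )
    logger.info("network: %d clusters, %d edges", len(network.clusters), len(network.edges))
    core_io.write_network(network, out / "network.json", "json")

    paths = _stage("enumerate_paths")(path_engine.enumerate_paths, network, config.max_len)
    if not paths:
        raise StageError("stage 'enumerate_paths' failed: no admissible paths in network")
    normalized = _stage("normalize")(path_engine.normalize_expression, matrix, fits)
    selection = _stage("select_best_path")(
        path_engine.select_best_path,
        paths, normalized, clusters, annotation, config.healthy_label,
    )
    chosen = selection.chosen
    scores = _stage("score")(path_engine.score_samples, chosen.path, normalized, clusters)
    labels = [1 if l == config.healthy_label else 0 for l in annotation.labels_for(matrix.sample_ids)]
    auc = _stage("evaluate")(path_engine.roc_auc, scores.to_numpy(), labels)
    pred_healthy = scores.to_numpy() > 0
    table = [
        [int(sum(p and l for p, l in zip(pred_healthy, labels))),
         int(sum(p and not l for p, l in zip(pred_healthy, labels)))],
        [int(sum((not p) and l for p, l in zip(pred_healthy, labels))),
         int(sum((not p) and (not l) for p, l in zip(pred_healthy, labels)))],
    ]
    fisher_p = path_engine.fisher_exact_2x2(table)

    selection_payload = {
        "chosen": _fit_to_dict(chosen),
        "candidates": [_fit_to_dict(f) for f in selection.fits],
    }
    with open(out / "selection.json", "w", encoding="utf-8") as handle:
        json.dump(selection_payload, handle, indent=2)
    scores.rename_axis("sample_id").to_frame().to_csv(out / "scores.tsv", sep="\t")

    report = {
        "n_genes": matrix.n_genes,
        "n_samples": matrix.n_samples,
        "n_bimodal_genes": len(genes),
        "n_pairs": len(results),
        "n_clusters": len(network.clusters),
        "n_edges": len(network.edges),
        "n_paths": len(paths),
        "chosen_path": list(chosen.path.clusters),
        "auc": auc,
        "fisher_p": fisher_p,
    }
    with open(out / "report.json", "w", encoding="utf-8") as handle:
        json.dump(report, handle, indent=2)
    with open(out / "config.json", "w", encoding="utf-8") as handle:
        json.dump(config.to_dict(), handle, indent=2)
    return report


def _fit_to_dict(fit: path_engine.PathFit) -> dict:
    return {
        "clusters": list(fit.path.clusters),
        "relations": list(fit.path.relations),
        "weights": list(fit.path.weights),
        "coefficient": fit.coefficient,
        "ci95": [fit.ci_low, fit.ci_high],
        "pvalue": fit.pvalue,
    }
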