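"""Continuum paths over the cluster network and per-sample scoring.

A path is an ordered chain of clusters connected by admissible relations.
Each sample receives a composite score: the weighted sum over path clusters
of the mean normalized expression of the cluster's genes.  Paths are ranked
by ordinary least squares of the binary class label on the score, and
signatures are evaluated by ROC-AUC and Fisher exact tests.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .core_io import ExpressionMatrix, GeneSet, SampleAnnotation
from .implication import Relation
from .network_builder import ClusterNetwork, GeneCluster
from .stepminer import StepFit

logger = logging.getLogger(__name__)

DEFAULT_MAX_LEN = 5
MAX_ENUMERATED_PATHS = 100_000

#: Relations an edge may carry inside a path.  EQUIVALENT is admissible only
#: between clusters on the same side.
DEFAULT_ADMISSIBLE = frozenset(
    {Relation.OPPOSITE.value, Relation.LOW_HIGH.value, Relation.HIGH_LOW.value}
)

__all__ = [
    "BooleanPath",
    "PathFit",
    "PathSelection",
    "enumerate_paths",
    "normalize_expression",
    "score_samples",
    "select_best_path",
    "roc_auc",
    "fisher_exact_2x2",
    "evaluate_signature",
    "DEFAULT_MAX_LEN",
    "DEFAULT_ADMISSIBLE",
]


@dataclass(frozen=True)
class BooleanPath:
    """Ordered cluster chain with per-cluster score weights."""

    clusters: tuple[str, ...]
    relations: tuple[str, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.clusters) < 1:
            raise ValueError("path needs at least one cluster")
        if len(self.relations) != max(len(self.clusters) - 1, 0):
            raise ValueError("need one relation per consecutive cluster pair")
        if len(self.weights) != len(self.clusters):
            raise ValueError("need one weight per cluster")


@dataclass(frozen=True)
class PathFit:
    path: BooleanPath
    coefficient: float
    ci_low: float
    ci_high: float
    pvalue: float


@dataclass
class PathSelection:
    fits: list[PathFit]
    chosen: PathFit


def _side_weight(cluster: GeneCluster) -> float:
    return {"healthy": 1.0, "disease": -1.0}.get(cluster.side, 0.0)


def enumerate_paths(
    network: ClusterNetwork,
    max_len: int = DEFAULT_MAX_LEN,
    admissible_relations: Iterable[str] | None = None,
    max_paths: int = MAX_ENUMERATED_PATHS,
) -> list[BooleanPath]:
    """All simple directed paths of 2..max_len clusters over admissible edges.

    ``max_len`` counts clusters.  EQUIVALENT edges are admissible only when
    both endpoints share a side.  Output order is deterministic
    (lexicographic by cluster-id tuple); enumeration past ``max_paths`` is
    truncated with a warning.
    """
    if max_len < 2:
        raise ValueError("max_len must be >= 2")
    admissible = (
        set(DEFAULT_ADMISSIBLE) | {Relation.EQUIVALENT.value}
        if admissible_relations is None
        else set(admissible_relations)
    )
    by_id = {c.cluster_id: c for c in network.clusters}
    graph = nx.DiGraph()
    graph.add_nodes_from(by_id)
    for e in network.edges:
        if e.relation not in admissible:
            continue
        if e.relation == Relation.EQUIVALENT.value and admissible_relations is None:
            a, b = by_id[e.source], by_id[e.target]
            if a.side != b.side or a.side == "unassigned":
                continue
        graph.add_edge(e.source, e.target, relation=e.relation)

    paths: list[tuple[str, ...]] = []
    truncated = False

    def extend(chain: list[str]) -> bool:
        if len(chain) >= 2:
            if len(paths) >= max_paths:
                return False
            paths.append(tuple(chain))
        if len(chain) == max_len:
            return True
        for nxt in sorted(graph.successors(chain[-1])):
            if nxt not in chain:
                if not extend(chain + [nxt]):
                    return False
        return True

    for start in sorted(graph.nodes):
        if not extend([start]):
            truncated = True
            break
    if truncated:
        logger.warning("path enumeration truncated at %d paths", max_paths)
    paths.sort()
    result = []
    for chain in paths:
        relations = tuple(graph.edges[u, v]["relation"] for u, v in itertools.pairwise(chain))
        weights = tuple(_side_weight(by_id[c]) for c in chain)
        result.append(BooleanPath(chain, relations, weights))
    return result


def normalize_expression(
    matrix: ExpressionMatrix, fits: Mapping[str, StepFit]
) -> ExpressionMatrix:
    """Threshold-center and scale each gene: (x - t) / sd (sd=1 if zero)."""
    missing = [g for g in matrix.gene_ids if g not in fits]
    if missing:
        raise ValueError(f"no step fit for genes: {missing[:10]}")
    thresholds = np.array([fits[g].threshold for g in matrix.gene_ids])
    sd = matrix.values.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    values = (matrix.values - thresholds[:, None]) / sd[:, None]
    return ExpressionMatrix(matrix.gene_ids, matrix.sample_ids, values)


def score_samples(
    path: BooleanPath,
    normalized: ExpressionMatrix,
    clusters: Sequence[GeneCluster],
) -> pd.Series:
    """Composite continuum score per sample.

    score(s) = sum_i w_i * mean over genes of cluster i of normalized value.
    """
    by_id = {c.cluster_id: c for c in clusters}
    scores = np.zeros(normalized.n_samples)
    for cid, weight in zip(path.clusters, path.weights):
        if cid not in by_id:
            raise KeyError(f"path cluster {cid} not found")
        genes = sorted(by_id[cid].members & set(normalized.gene_ids))
        if not genes:
            raise ValueError(f"cluster {cid} has no genes in the matrix")
        rows = np.stack([normalized.row(g) for g in genes])
        scores += weight * rows.mean(axis=0)
    return pd.Series(scores, index=normalized.sample_ids, name="score")


def _binary_labels(
    annotation: SampleAnnotation, sample_ids: Sequence[str], positive_label: str | None
) -> tuple[np.ndarray, str]:
    labels = annotation.labels_for(sample_ids)
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError(f"need two classes, got {classes}")
    if len(classes) > 2:
        raise ValueError(f"binary labels required, got {classes}")
    if positive_label is None:
        positive_label = classes[-1]
    if positive_label not in classes:
        raise ValueError(f"positive label {positive_label!r} not in {classes}")
    return np.array([1.0 if l == positive_label else 0.0 for l in labels]), positive_label


def _ols_fit(path: BooleanPath, scores: pd.Series, y: np.ndarray) -> PathFit:
    x = sm.add_constant(scores.to_numpy())
    model = sm.OLS(y, x).fit()
    coef = float(model.params[1])
    pvalue = float(model.pvalues[1])
    ci = model.conf_int(alpha=0.05)
    lo, hi = float(ci[1][0]), float(ci[1][1])
    if np.isnan(pvalue) and model.ssr <= 1e-12 and abs(coef) > 0:
        pvalue, lo, hi = 0.0, coef, coef  # perfect fit: zero residual variance
    return PathFit(path, coef, lo, hi, pvalue)


def select_best_path(
    paths: Sequence[BooleanPath],
    normalized: ExpressionMatrix,
    clusters: Sequence[GeneCluster],
    annotation: SampleAnnotation,
    positive_label: str | None = None,
) -> PathSelection:
    """Rank candidate paths by OLS of the binary label on the path score.

    The chosen path minimizes the slope p-value; ties break toward larger
    absolute coefficient, then lexicographic cluster order.
    """
    if not paths:
        raise ValueError("no candidate paths")
    y, _ = _binary_labels(annotation, normalized.sample_ids, positive_label)
    fits = [
        _ols_fit(path, score_samples(path, normalized, clusters), y) for path in paths
    ]
    chosen = min(fits, key=lambda f: (f.pvalue, -abs(f.coefficient), f.path.clusters))
    return PathSelection(fits, chosen)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Probability that a random positive outranks a random negative.

    Ties count 0.5 (Mann-Whitney convention).  Labels are 0/1 and both
    classes must be present.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape:
        raise ValueError("scores and labels differ in length")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = scipy.stats.rankdata(s)
    u = float(np.sum(ranks[y == 1])) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p-value for a 2x2 count table."""
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if not np.issubdtype(arr.dtype, np.integer) or (arr < 0).any():
        raise ValueError("table entries must be non-negative integers")
    if arr.sum() == 0:
        raise ValueError("all-zero table")
    return float(scipy.stats.fisher_exact(arr, alternative="two-sided")[1])


def evaluate_signature(
    matrix: ExpressionMatrix,
    annotation: SampleAnnotation,
    signature,
    clusters: Sequence[GeneCluster] | None = None,
    fits: Mapping[str, StepFit] | None = None,
    positive_label: str | None = None,
    threshold: float = 0.0,
) -> dict:
    """Score a labeled cohort with a signature and report AUC and Fisher p.

    ``signature`` is either a :class:`BooleanPath` (requires ``clusters``)
    or an (up, down) pair of gene sets; gene-set scores are the mean
    normalized value of the up set minus that of the down set.  Samples
    with score > ``threshold`` are predicted positive for the Fisher table.
    """
    from .stepminer import binarize_matrix

    if fits is None:
        _, fits = binarize_matrix(matrix)
    normalized = normalize_expression(matrix, fits)
    if isinstance(signature, BooleanPath):
        if clusters is None:
            raise ValueError("path signatures require clusters")
        scores = score_samples(signature, normalized, clusters)
    else:
        up, down = signature
        up = set(up.genes if isinstance(up, GeneSet) else up)
        down = set(down.genes if isinstance(down, GeneSet) else down)
        present = set(normalized.gene_ids)
        up_found = sorted(up & present)
        down_found = sorted(down & present)
        if len(up_found) + len(down_found) < 2:
            missing = sorted((up | down) - present)
            raise ValueError(f"fewer than 2 signature genes in matrix; missing: {missing}")
        values = np.zeros(normalized.n_samples)
        if up_found:
            values += np.stack([normalized.row(g) for g in up_found]).mean(axis=0)
        if down_found:
            values -= np.stack([normalized.row(g) for g in down_found]).mean(axis=0)
        scores = pd.Series(values, index=normalized.sample_ids, name="score")

    y, positive = _binary_labels(annotation, normalized.sample_ids, positive_label)
    auc = roc_auc(scores.to_numpy(), y.astype(int))
    pred = scores.to_numpy() > threshold
    table = [
        [int(np.sum(pred & (y == 1))), int(np.sum(pred & (y == 0)))],
        [int(np.sum(~pred & (y == 1))), int(np.sum(~pred & (y == 0)))],
    ]
    fisher_p = fisher_exact_2x2(table)
    return {
        "auc": auc,
        "fisher_p": fisher_p,
        "scores": scores,
        "positive_label": positive,
        "contingency": table,
    }
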