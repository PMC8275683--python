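"""Equivalence clustering of genes and the directed cluster-level network.

Genes mutually related by the EQUIVALENT relation are agglomerated into
clusters; cluster pairs whose cross-gene relations overwhelmingly agree on
one relation class become directed labeled edges.  Clusters are oriented
healthy- or disease-side by comparing threshold-centered mean expression
between the two sample classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

from .core_io import ExpressionMatrix, SampleAnnotation
from .implication import CONVERSE, ImplicationResult, Relation
from .stepminer import StepFit

logger = logging.getLogger(__name__)

DEFAULT_EDGE_SUPPORT_MIN = 0.5
DEFAULT_MIN_CLUSTER_SIZE = 3

__all__ = [
    "GeneCluster",
    "ClusterEdge",
    "ClusterNetwork",
    "build_equivalence_graph",
    "cluster_genes",
    "build_cluster_network",
    "orient_clusters",
    "DEFAULT_EDGE_SUPPORT_MIN",
    "DEFAULT_MIN_CLUSTER_SIZE",
]


@dataclass(frozen=True)
class GeneCluster:
    cluster_id: str
    members: frozenset[str]
    side: str = "unassigned"  # healthy | disease | unassigned
    healthy_mean: float = float("nan")
    disease_mean: float = float("nan")

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"cluster {self.cluster_id} has no members")
        if self.side not in ("healthy", "disease", "unassigned"):
            raise ValueError(f"invalid side {self.side!r}")


@dataclass(frozen=True)
class ClusterEdge:
    source: str
    target: str
    relation: str
    support: float  # fraction of cross-cluster gene pairs carrying this relation
    mean_s: float


@dataclass
class ClusterNetwork:
    clusters: list[GeneCluster]
    edges: list[ClusterEdge]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c in self.clusters:
            overlap = seen & c.members
            if overlap:
                raise ValueError(f"gene(s) in multiple clusters: {sorted(overlap)}")
            seen |= c.members
        ids = {c.cluster_id for c in self.clusters}
        for e in self.edges:
            if e.source not in ids or e.target not in ids:
                raise ValueError(f"edge references unknown cluster: {e}")

    def cluster(self, cluster_id: str) -> GeneCluster:
        for c in self.clusters:
            if c.cluster_id == cluster_id:
                return c
        raise KeyError(cluster_id)

    def members_of(self, cluster_id: str) -> frozenset[str]:
        return self.cluster(cluster_id).members

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ClusterNetwork):
            return NotImplemented

        def key(net: "ClusterNetwork"):
            clusters = sorted(
                (c.cluster_id, tuple(sorted(c.members)), c.side) for c in net.clusters
            )
            edges = sorted((e.source, e.target, e.relation, round(e.support, 9)) for e in net.edges)
            return clusters, edges

        return key(self) == key(other)


def build_equivalence_graph(results: Iterable[ImplicationResult]) -> nx.Graph:
    """Undirected graph with one edge per EQUIVALENT gene pair."""
    graph = nx.Graph()
    for r in results:
        graph.add_node(r.gene_a)
        graph.add_node(r.gene_b)
        if r.relation is Relation.EQUIVALENT:
            graph.add_edge(r.gene_a, r.gene_b, mean_s=r.mean_sparse_statistic)
    return graph


def cluster_genes(
    equiv_graph: nx.Graph, min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE
) -> list[GeneCluster]:
    """Greedy agglomeration over genes in descending-degree order.

    A gene joins the first existing cluster (in creation order) to which it
    has equivalence edges covering at least half of the current members;
    otherwise it seeds a new cluster.  Clusters below ``min_cluster_size``
    are discarded.  The procedure is deterministic: ties in degree break by
    gene id, and final ids C1, C2, ... are assigned by descending size then
    smallest member id.
    """
    order = sorted(equiv_graph.nodes, key=lambda g: (-equiv_graph.degree(g), g))
    protoclusters: list[set[str]] = []
    for gene in order:
        neighbors = set(equiv_graph.neighbors(gene))
        for members in protoclusters:
            if len(neighbors & members) * 2 >= len(members):
                members.add(gene)
                break
        else:
            protoclusters.append({gene})
    kept = [m for m in protoclusters if len(m) >= min_cluster_size]
    kept.sort(key=lambda m: (-len(m), min(m)))
    return [GeneCluster(f"C{i + 1}", frozenset(m)) for i, m in enumerate(kept)]


def _relation_lookup(
    results: Iterable[ImplicationResult],
) -> dict[tuple[str, str], tuple[Relation, float]]:
    """(gene_a, gene_b) -> (relation read a->b, mean sparse S), both orders."""
    lookup: dict[tuple[str, str], tuple[Relation, float]] = {}
    for r in results:
        s = r.mean_sparse_statistic
        lookup[(r.gene_a, r.gene_b)] = (r.relation, s)
        lookup[(r.gene_b, r.gene_a)] = (CONVERSE[r.relation], s)
    return lookup


def build_cluster_network(
    clusters: list[GeneCluster],
    results: Iterable[ImplicationResult],
    edge_support_min: float = DEFAULT_EDGE_SUPPORT_MIN,
) -> ClusterNetwork:
    """Directed cluster network from majority cross-cluster relations.

    For each cluster pair all cross gene-pair relations are tallied (pairs
    with no relation count toward the denominator).  The single majority
    relation becomes an edge iff its support is >= ``edge_support_min``;
    ties between relation classes break toward the higher mean S.  Edge
    direction: healthy side -> disease side when sides differ, otherwise
    the lexicographically smaller cluster id first; the stored relation is
    read in that direction.
    """
    lookup = _relation_lookup(results)
    edges: list[ClusterEdge] = []
    by_id = {c.cluster_id: c for c in clusters}
    ids = sorted(by_id)
    for idx, cid_a in enumerate(ids):
        for cid_b in ids[idx + 1:]:
            a, b = by_id[cid_a], by_id[cid_b]
            if a.side == "disease" and b.side == "healthy":
                a, b = b, a
            tallies: dict[Relation, list[float]] = {}
            total = len(a.members) * len(b.members)
            for ga in a.members:
                for gb in b.members:
                    rel, s = lookup.get((ga, gb), (Relation.NONE, 0.0))
                    if rel is not Relation.NONE:
                        tallies.setdefault(rel, []).append(s)
            if not tallies:
                continue
            best = max(
                tallies.items(),
                key=lambda kv: (len(kv[1]), float(np.mean(kv[1])), kv[0].value),
            )
            relation, stats = best
            support = len(stats) / total
            if support >= edge_support_min:
                edges.append(
                    ClusterEdge(a.cluster_id, b.cluster_id, relation.value, support,
                                float(np.mean(stats)))
                )
    return ClusterNetwork(list(clusters), edges)


def orient_clusters(
    clusters: list[GeneCluster],
    matrix: ExpressionMatrix,
    annotation: SampleAnnotation,
    fits: Mapping[str, StepFit],
    healthy_label: str = "healthy",
    disease_label: str = "disease",
) -> list[GeneCluster]:
    """Assign each cluster to the healthy or disease side.

    A cluster is healthy-side iff the mean threshold-centered expression
    (x - t, per gene) over its members is higher in healthy samples than in
    disease samples.  Missing classes or exact ties leave the cluster
    unassigned.
    """
    sample_idx = {s: i for i, s in enumerate(matrix.sample_ids)}
    healthy_cols = [sample_idx[s] for s in annotation.samples_with(healthy_label) if s in sample_idx]
    disease_cols = [sample_idx[s] for s in annotation.samples_with(disease_label) if s in sample_idx]
    oriented: list[GeneCluster] = []
    for cluster in clusters:
        genes = sorted(cluster.members)
        missing = [g for g in genes if g not in fits]
        if missing or not healthy_cols or not disease_cols:
            oriented.append(replace(cluster, side="unassigned"))
            continue
        centered = np.stack([matrix.row(g) - fits[g].threshold for g in genes])
        h_mean = float(centered[:, healthy_cols].mean())
        d_mean = float(centered[:, disease_cols].mean())
        if h_mean > d_mean:
            side = "healthy"
        elif d_mean > h_mean:
            side = "disease"
        else:
            side = "unassigned"
        oriented.append(replace(cluster, side=side, healthy_mean=h_mean, disease_mean=d_mean))
    return oriented
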