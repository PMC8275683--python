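"""Shared data model and readers/writers for all on-disk artifacts.

Formats are deliberately plain: expression and annotation tables are
tab-separated text, gene sets are GMT, networks are JSON (documented schema
below) or GraphML, scores and reports are TSV/JSON.  Every writer has a
matching reader and the pair round-trips exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "ExpressionMatrix",
    "SampleAnnotation",
    "GeneSet",
    "read_expression",
    "write_expression",
    "read_annotation",
    "write_annotation",
    "read_gmt",
    "write_gmt",
    "read_ternary",
    "write_ternary",
    "read_network",
    "write_network",
]


class ParseError(ValueError):
    """Raised when an input file violates its declared dialect."""


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of log2-scale expression values.

    Invariants: identifiers are unique, the value array matches the
    identifier lengths, and no value is missing (missing-data policy is
    applied at read time).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dupes = _duplicates(ids)
            if dupes:
                raise ValueError(f"duplicate {name} ids: {sorted(dupes)}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self._index[gene_id]
        except AttributeError:
            self._index = {g: i for i, g in enumerate(self.gene_ids)}
            return self._index[gene_id]

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_index(gene_id)]

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        keep = [g for g in self.gene_ids if g in set(genes)]
        idx = [self.gene_index(g) for g in keep]
        return ExpressionMatrix(keep, self.sample_ids, self.values[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            [str(g) for g in frame.index],
            [str(s) for s in frame.columns],
            frame.to_numpy(dtype=float),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.allclose(self.values, other.values, rtol=0, atol=1e-9)
        )


@dataclass
class SampleAnnotation:
    """Per-sample class labels plus free-form covariates.

    Backed by a DataFrame indexed by sample id with a mandatory
    ``class_label`` column; any further columns are covariates.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "class_label" not in self.table.columns:
            raise ValueError("annotation table requires a 'class_label' column")
        if self.table.index.has_duplicates:
            dupes = self.table.index[self.table.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        if (self.table["class_label"].astype(str).str.len() == 0).any():
            raise ValueError("empty class_label encountered")

    @classmethod
    def from_labels(
        cls,
        sample_ids: Iterable[str],
        labels: Iterable[str],
        covariates: Mapping[str, Iterable] | None = None,
    ) -> "SampleAnnotation":
        data = {"class_label": list(labels)}
        if covariates:
            data.update({k: list(v) for k, v in covariates.items()})
        frame = pd.DataFrame(data, index=pd.Index(list(sample_ids), name="sample_id"))
        return cls(frame)

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.table.index]

    def class_of(self, sample_id: str) -> str:
        return str(self.table.loc[sample_id, "class_label"])

    def classes(self) -> list[str]:
        return sorted(self.table["class_label"].astype(str).unique())

    def samples_with(self, label: str) -> list[str]:
        mask = self.table["class_label"].astype(str) == label
        return [str(s) for s in self.table.index[mask]]

    def labels_for(self, sample_ids: Iterable[str]) -> list[str]:
        return [self.class_of(s) for s in sample_ids]

    def check_against(self, matrix: ExpressionMatrix) -> None:
        missing = set(self.sample_ids) - set(matrix.sample_ids)
        if missing:
            raise ValueError(f"annotated samples absent from matrix: {sorted(missing)}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SampleAnnotation):
            return NotImplemented
        return self.table.equals(other.table)


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene ids (one GMT line)."""

    name: str
    description: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        object.__setattr__(self, "genes", frozenset(self.genes))


def _duplicates(ids: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for i in ids:
        if i in seen:
            dupes.add(i)
        seen.add(i)
    return dupes


# ---------------------------------------------------------------------------
# expression tables


def read_expression(
    path: str | Path,
    missing_policy: str = "drop_gene",
    log2: bool = False,
) -> ExpressionMatrix:
    """Read a genes x samples TSV (first row sample ids, first column gene ids).

    ``missing_policy`` is one of ``drop_gene`` (default; remove genes with
    any missing cell) or ``impute_row_mean``.  ``log2`` applies log2(x+1)
    for raw-count input.
    """
    if missing_policy not in ("drop_gene", "impute_row_mean"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, header=0)
    except Exception as exc:  # pandas raises several flavors on bad input
        raise ParseError(f"{path}: cannot parse expression table: {exc}") from exc
    if frame.shape[1] == 0:
        raise ParseError(f"{path}: malformed header at line 1 (no sample columns)")
    non_numeric = [c for c in frame.columns if not pd.api.types.is_numeric_dtype(frame[c])]
    if non_numeric:
        try:
            frame = frame.apply(pd.to_numeric)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: non-numeric expression values: {exc}") from exc
    dupes = _duplicates(str(g) for g in frame.index)
    if dupes:
        raise ParseError(f"{path}: duplicate gene ids: {sorted(dupes)}")
    n_missing_genes = int(frame.isna().any(axis=1).sum())
    if n_missing_genes:
        if missing_policy == "drop_gene":
            frame = frame.dropna(axis=0)
            logger.info("dropped %d genes with missing values", n_missing_genes)
        else:
            means = frame.mean(axis=1)
            frame = frame.apply(lambda col: col.fillna(means))
            logger.info("imputed row means for %d genes", n_missing_genes)
    if log2:
        frame = np.log2(frame + 1.0)
    return ExpressionMatrix.from_frame(frame)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def read_annotation(path: str | Path) -> SampleAnnotation:
    """Read a TSV with header ``sample_id<TAB>class_label[<TAB>covariate...]``."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype=str)
    if "class_label" not in frame.columns:
        raise ParseError(f"{path}: header must contain a 'class_label' column")
    return SampleAnnotation(frame)


def write_annotation(annotation: SampleAnnotation, path: str | Path) -> None:
    annotation.table.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT file: ``name<TAB>description<TAB>gene...`` per line."""
    sets: list[GeneSet] = []
    names: set[str] = set()
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >=3 tab-separated fields")
            name, description, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ParseError(f"{path}: line {lineno}: gene set {name!r} has no genes")
            if name in names:
                raise ParseError(f"{path}: line {lineno}: duplicate gene set name {name!r}")
            names.add(name)
            sets.append(GeneSet(name, description, frozenset(genes)))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for gs in sets:
            handle.write("\t".join([gs.name, gs.description, *sorted(gs.genes)]) + "\n")


# ---------------------------------------------------------------------------
# ternary label matrices


def write_ternary(ternary, path: str | Path) -> None:
    frame = pd.DataFrame(ternary.labels, index=ternary.gene_ids, columns=ternary.sample_ids)
    frame.to_csv(path, sep="\t", index_label="gene_id")


def read_ternary(path: str | Path):
    from .stepminer import TernaryMatrix

    frame = pd.read_csv(path, sep="\t", index_col=0, header=0)
    labels = frame.to_numpy(dtype=np.int8)
    if not np.isin(labels, (0, 1, 2)).all():
        raise ParseError(f"{path}: ternary labels must be 0, 1 or 2")
    return TernaryMatrix(
        [str(g) for g in frame.index], [str(s) for s in frame.columns], labels
    )


# ---------------------------------------------------------------------------
# cluster networks
#
# JSON schema:
# {
#   "clusters": [{"cluster_id": str, "members": [str], "side": str,
#                 "healthy_mean": float|null, "disease_mean": float|null}],
#   "edges": [{"from": str, "to": str, "relation": str,
#              "support": float, "mean_S": float}]
# }


def write_network(network, path: str | Path, format: str = "json") -> None:
    """Serialize a ClusterNetwork to JSON (default) or GraphML."""
    if format == "json":
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(_network_to_dict(network), handle, indent=2, sort_keys=True)
            handle.write("\n")
    elif format == "graphml":
        nx.write_graphml(_network_to_graph(network), path)
    else:
        raise ValueError(f"unsupported network format {format!r}")


def read_network(path: str | Path, format: str = "json"):
    from .network_builder import ClusterEdge, ClusterNetwork, GeneCluster

    if format == "json":
        with open(path, encoding="utf-8") as handle:
            payload = json.load(handle)
        clusters = [
            GeneCluster(
                cluster_id=c["cluster_id"],
                members=frozenset(c["members"]),
                side=c["side"],
                healthy_mean=c["healthy_mean"] if c["healthy_mean"] is not None else float("nan"),
                disease_mean=c["disease_mean"] if c["disease_mean"] is not None else float("nan"),
            )
            for c in payload["clusters"]
        ]
        edges = [
            ClusterEdge(e["from"], e["to"], e["relation"], e["support"], e["mean_S"])
            for e in payload["edges"]
        ]
        return ClusterNetwork(clusters, edges)
    if format == "graphml":
        graph = nx.read_graphml(path)
        clusters = [
            GeneCluster(
                cluster_id=node,
                members=frozenset(data["members"].split(",")),
                side=data.get("side", "unassigned"),
                healthy_mean=float(data.get("healthy_mean", "nan")),
                disease_mean=float(data.get("disease_mean", "nan")),
            )
            for node, data in sorted(graph.nodes(data=True))
        ]
        edges = [
            ClusterEdge(u, v, data["relation"], float(data["support"]), float(data["mean_S"]))
            for u, v, data in sorted(graph.edges(data=True))
        ]
        return ClusterNetwork(clusters, edges)
    raise ValueError(f"unsupported network format {format!r}")


def _network_to_dict(network) -> dict:
    return {
        "clusters": [
            {
                "cluster_id": c.cluster_id,
                "members": sorted(c.members),
                "side": c.side,
                "healthy_mean": None if np.isnan(c.healthy_mean) else float(c.healthy_mean),
                "disease_mean": None if np.isnan(c.disease_mean) else float(c.disease_mean),
            }
            for c in network.clusters
        ],
        "edges": [
            {
                "from": e.source,
                "to": e.target,
                "relation": e.relation,
                "support": float(e.support),
                "mean_S": float(e.mean_s),
            }
            for e in network.edges
        ],
    }


def _network_to_graph(network) -> nx.DiGraph:
    graph = nx.DiGraph()
    for c in network.clusters:
        graph.add_node(
            c.cluster_id,
            members=",".join(sorted(c.members)),
            side=c.side,
            healthy_mean=float(c.healthy_mean),
            disease_mean=float(c.disease_mean),
        )
    for e in network.edges:
        graph.add_edge(
            e.source, e.target, relation=e.relation, support=float(e.support), mean_S=float(e.mean_s)
        )
    return graph
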