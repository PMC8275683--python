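"""Target prioritization rules and organoid barrier-response classification.

A candidate target is predicted to succeed only when it sits on both
disease-continuum paths (epithelial-mesenchymal and inflammation-fibrosis)
AND carries a strong "anchor high => target low" implication against the
anchor gene (sparse high/high-adjacent quadrant with S > SThr, p < pThr).
An "anchor high => target high" implication marks genes that should not be
antagonized (contraindicated).  Organoid lines are binned by percent TEER
increase after treatment: <=25 nonresponder, >25-75 responder, >75 high
responder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib.resources import files
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .implication import (
    DEFAULT_PTHR,
    DEFAULT_STHR,
    ImplicationResult,
    Relation,
    classify_pair,
)
from .stepminer import TernaryMatrix

logger = logging.getLogger(__name__)

RESPONSE_CUTOFF_LOW = 25.0  # percent TEER increase
RESPONSE_CUTOFF_HIGH = 75.0

__all__ = [
    "TargetRecord",
    "OrganoidRecord",
    "filter_druggable",
    "vet_target",
    "target_association",
    "classify_response",
    "summarize_cohort",
    "load_organoid_table",
    "RESPONSE_CUTOFF_LOW",
    "RESPONSE_CUTOFF_HIGH",
]


@dataclass(frozen=True)
class TargetRecord:
    gene_id: str
    on_path_emt: bool
    on_path_fibrosis: bool
    anchor_relation: ImplicationResult
    verdict: str  # predicted_success | predicted_failure | contraindicated


@dataclass(frozen=True)
class OrganoidRecord:
    line_id: str
    disease: str  # healthy | UC | CD
    teer_increase_pct: float
    category: str  # nonresponder | responder | high_responder


def filter_druggable(
    genes: Iterable[str],
    annotation_table: Mapping[str, Iterable[str]] | pd.DataFrame,
    required_tags: Iterable[str],
) -> set[str]:
    """Genes carrying all ``required_tags`` in the annotation table.

    The table maps gene id -> set of molecular-function tags (a DataFrame
    with 'gene_id' and 'tags' columns, comma-separated, also works).  Genes
    absent from the table are excluded with a warning.
    """
    if isinstance(annotation_table, pd.DataFrame):
        annotation_table = {
            str(row["gene_id"]): {t for t in str(row["tags"]).split(",") if t}
            for _, row in annotation_table.iterrows()
        }
    required = set(required_tags)
    genes = set(genes)
    missing = sorted(g for g in genes if g not in annotation_table)
    if missing:
        logger.warning("genes absent from annotation table, excluded: %s", missing)
    return {
        g
        for g in genes
        if g in annotation_table and required <= set(annotation_table[g])
    }


def _anchor_implies_target_low(result: ImplicationResult) -> bool:
    # "anchor high => target low" holds when the (high, high) quadrant is sparse
    return result.relation in (Relation.HIGH_LOW, Relation.OPPOSITE)


def _anchor_implies_target_high(result: ImplicationResult) -> bool:
    # "anchor high => target high" holds when the (high, low) quadrant is sparse
    return result.relation in (Relation.HIGH_HIGH, Relation.EQUIVALENT)


def vet_target(
    target: str,
    anchor: str,
    paths: Mapping[str, Iterable[str]],
    ternary: TernaryMatrix,
    sthr: float = DEFAULT_STHR,
    pthr: float = DEFAULT_PTHR,
    rule: str = "conjunctive",
) -> TargetRecord:
    """Apply the vetting rules to one candidate target.

    ``paths`` maps "emt" and "fibrosis" to the gene lists of the two
    continuum paths.  With the default conjunctive rule a success verdict
    requires membership in both paths and the anchor-high => target-low
    implication; the disjunctive variant accepts any single criterion.
    An anchor-high => target-high implication is contraindicated regardless
    of path membership.
    """
    if rule not in ("conjunctive", "disjunctive"):
        raise ValueError(f"unknown rule {rule!r}")
    for gene in (target, anchor):
        if gene not in ternary.gene_ids:
            raise ValueError(f"gene {gene!r} not in ternary matrix")
    result = classify_pair(
        ternary.row(anchor), ternary.row(target), sthr, pthr, gene_a=anchor, gene_b=target
    )
    on_emt = target in set(paths.get("emt", ()))
    on_fibrosis = target in set(paths.get("fibrosis", ()))
    if _anchor_implies_target_high(result):
        verdict = "contraindicated"
    else:
        implied_low = _anchor_implies_target_low(result)
        if rule == "conjunctive":
            success = on_emt and on_fibrosis and implied_low
        else:
            success = on_emt or on_fibrosis or implied_low
        verdict = "predicted_success" if success else "predicted_failure"
    return TargetRecord(target, on_emt, on_fibrosis, result, verdict)


def target_association(
    targets: Sequence[str],
    ternary: TernaryMatrix,
    sthr: float = DEFAULT_STHR,
    pthr: float = DEFAULT_PTHR,
    approved: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Pairwise EQUIVALENT flags among targets, plus approved-set counts.

    Returns a symmetric boolean matrix (diagonal True by convention of
    self-equivalence excluded from counts) and, per target, the number of
    equivalences with the designated approved set (the full target list
    when ``approved`` is None).
    """
    missing = [t for t in targets if t not in ternary.gene_ids]
    if missing:
        raise ValueError(f"targets not in ternary matrix: {missing}")
    k = len(targets)
    flags = np.zeros((k, k), dtype=bool)
    for i in range(k):
        flags[i, i] = True
        for j in range(i + 1, k):
            rel = classify_pair(
                ternary.row(targets[i]), ternary.row(targets[j]), sthr, pthr
            ).relation
            flags[i, j] = flags[j, i] = rel is Relation.EQUIVALENT
    matrix = pd.DataFrame(flags, index=list(targets), columns=list(targets))
    approved_set = set(approved) if approved is not None else set(targets)
    counts = pd.Series(
        {
            t: int(sum(matrix.loc[t, a] for a in approved_set if a != t))
            for t in targets
        },
        name="n_equivalent_approved",
    )
    return matrix, counts


def classify_response(
    line_id: str, teer_increase_pct: float, disease: str = "unknown"
) -> OrganoidRecord:
    """Bin one organoid line by its percent TEER increase after treatment."""
    pct = float(teer_increase_pct)
    if not np.isfinite(pct):
        raise ValueError(f"{line_id}: TEER change must be finite")
    if pct <= RESPONSE_CUTOFF_LOW:
        category = "nonresponder"
    elif pct <= RESPONSE_CUTOFF_HIGH:
        category = "responder"
    else:
        category = "high_responder"
    return OrganoidRecord(line_id, disease, pct, category)


def summarize_cohort(records: Sequence[OrganoidRecord]) -> dict:
    """Counts, percentages (2 decimals) and disease breakdown per category."""
    if not records:
        raise ValueError("empty cohort")
    total = len(records)
    summary: dict = {"n": total, "categories": {}}
    for category in ("nonresponder", "responder", "high_responder"):
        subset = [r for r in records if r.category == category]
        by_disease: dict[str, int] = {}
        for r in subset:
            by_disease[r.disease] = by_disease.get(r.disease, 0) + 1
        summary["categories"][category] = {
            "count": len(subset),
            "percent": round(100.0 * len(subset) / total, 2),
            "by_disease": dict(sorted(by_disease.items())),
        }
    return summary


def load_organoid_table(path=None) -> pd.DataFrame:
    """Load the bundled patient-derived organoid TEER table (or one like it).

    Columns: line_id, disease (healthy/UC/CD), teer_increase_pct.
    """
    if path is None:
        path = files("implinet").joinpath("data/organoid_teer.tsv")
        with path.open("r", encoding="utf-8") as handle:
            return pd.read_csv(handle, sep="\t")
    return pd.read_csv(path, sep="\t")
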