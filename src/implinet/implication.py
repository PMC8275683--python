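"""Boolean implication relations between binarized gene pairs.

For a gene pair (A, B) the samples where both genes are decisively low or
high form a 2x2 contingency table.  A quadrant is *sparse* when its count
falls far below the independence expectation:

    e_ij = row_i * col_j / n
    S_ij = (e_ij - a_ij) / sqrt(e_ij)
    p_ij = 0.5 * (a_ij / row_i + a_ij / col_j)

and sparse <=> S_ij > SThr and p_ij < pThr (defaults 3.0 / 0.1).  The sparse
pattern maps to one of six relations: four asymmetric single-quadrant
implications and the two symmetric patterns (EQUIVALENT: a01 & a10 sparse;
OPPOSITE: a00 & a11 sparse).  Every other pattern is NONE.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .stepminer import TernaryMatrix

logger = logging.getLogger(__name__)

DEFAULT_STHR = 3.0
DEFAULT_PTHR = 0.1

QUADRANTS = ((0, 0), (0, 1), (1, 0), (1, 1))

__all__ = [
    "Relation",
    "QuadrantTable",
    "QuadrantTest",
    "ImplicationResult",
    "count_quadrants",
    "quadrant_statistic",
    "relation_from_sparse_pattern",
    "classify_table",
    "classify_pair",
    "all_pairs_network",
    "CONVERSE",
    "DEFAULT_STHR",
    "DEFAULT_PTHR",
    "QUADRANTS",
]


class Relation(str, Enum):
    """The six Boolean implication relation classes plus NONE."""

    LOW_LOW = "LOW_LOW"  # A low => B low
    LOW_HIGH = "LOW_HIGH"  # A low => B high
    HIGH_LOW = "HIGH_LOW"  # A high => B low
    HIGH_HIGH = "HIGH_HIGH"  # A high => B high
    EQUIVALENT = "EQUIVALENT"
    OPPOSITE = "OPPOSITE"
    NONE = "NONE"

    def __str__(self) -> str:  # plain value in files and reports
        return self.value


#: Relation of (B, A) given the relation of (A, B).
CONVERSE: dict[Relation, Relation] = {
    Relation.LOW_LOW: Relation.HIGH_HIGH,
    Relation.HIGH_HIGH: Relation.LOW_LOW,
    Relation.LOW_HIGH: Relation.LOW_HIGH,
    Relation.HIGH_LOW: Relation.HIGH_LOW,
    Relation.EQUIVALENT: Relation.EQUIVALENT,
    Relation.OPPOSITE: Relation.OPPOSITE,
    Relation.NONE: Relation.NONE,
}

#: Sparse-quadrant pattern -> relation.  First index is A's state, second B's.
_PATTERN_TO_RELATION: dict[frozenset, Relation] = {
    frozenset({(0, 1)}): Relation.LOW_LOW,
    frozenset({(0, 0)}): Relation.LOW_HIGH,
    frozenset({(1, 1)}): Relation.HIGH_LOW,
    frozenset({(1, 0)}): Relation.HIGH_HIGH,
    frozenset({(0, 1), (1, 0)}): Relation.EQUIVALENT,
    frozenset({(0, 0), (1, 1)}): Relation.OPPOSITE,
}


@dataclass(frozen=True)
class QuadrantTable:
    """2x2 counts over samples where both genes are low (0) or high (1)."""

    a00: int
    a01: int
    a10: int
    a11: int

    def __post_init__(self) -> None:
        for q in (self.a00, self.a01, self.a10, self.a11):
            if q < 0:
                raise ValueError("quadrant counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a00 + self.a01 + self.a10 + self.a11

    def count(self, i: int, j: int) -> int:
        return (self.a00, self.a01, self.a10, self.a11)[i * 2 + j]

    def row(self, i: int) -> int:
        return self.count(i, 0) + self.count(i, 1)

    def col(self, j: int) -> int:
        return self.count(0, j) + self.count(1, j)

    def transpose(self) -> "QuadrantTable":
        return QuadrantTable(self.a00, self.a10, self.a01, self.a11)


@dataclass(frozen=True)
class QuadrantTest:
    """Sparse-quadrant test for one cell of a QuadrantTable."""

    quadrant: tuple[int, int]
    expected: float
    statistic: float  # NaN when not evaluable (empty row or column)
    error_rate: float
    sparse: bool
    evaluable: bool


@dataclass(frozen=True)
class ImplicationResult:
    """Classified relation for an ordered gene pair."""

    gene_a: str
    gene_b: str
    table: QuadrantTable
    tests: tuple[QuadrantTest, QuadrantTest, QuadrantTest, QuadrantTest]
    relation: Relation

    def test(self, i: int, j: int) -> QuadrantTest:
        return self.tests[i * 2 + j]

    @property
    def mean_sparse_statistic(self) -> float:
        """Mean S over the sparse quadrants (0.0 when none is sparse)."""
        stats = [t.statistic for t in self.tests if t.sparse]
        return float(np.mean(stats)) if stats else 0.0

    def converse(self) -> "ImplicationResult":
        """The result read in the (B, A) direction."""
        tests = tuple(
            QuadrantTest((t.quadrant[1], t.quadrant[0]), t.expected, t.statistic,
                         t.error_rate, t.sparse, t.evaluable)
            for t in (self.tests[0], self.tests[2], self.tests[1], self.tests[3])
        )
        return ImplicationResult(
            self.gene_b, self.gene_a, self.table.transpose(), tests, CONVERSE[self.relation]
        )


def count_quadrants(ternary_a: Sequence[int], ternary_b: Sequence[int]) -> QuadrantTable:
    """Tally the 2x2 low/high table, excluding intermediate samples."""
    a = np.asarray(ternary_a)
    b = np.asarray(ternary_b)
    if a.shape != b.shape:
        raise ValueError(f"label vectors differ in length: {a.shape} vs {b.shape}")
    both = (a != 1) & (b != 1)
    ah = a[both] == 2
    bh = b[both] == 2
    return QuadrantTable(
        a00=int(np.sum(~ah & ~bh)),
        a01=int(np.sum(~ah & bh)),
        a10=int(np.sum(ah & ~bh)),
        a11=int(np.sum(ah & bh)),
    )


def quadrant_statistic(
    table: QuadrantTable,
    quadrant: tuple[int, int],
    sthr: float = DEFAULT_STHR,
    pthr: float = DEFAULT_PTHR,
) -> QuadrantTest:
    """Evaluate sparseness of one quadrant of ``table``.

    An empty row or column margin makes the quadrant non-evaluable
    (statistic NaN, sparse False).
    """
    i, j = quadrant
    if quadrant not in QUADRANTS:
        raise ValueError(f"invalid quadrant {quadrant}")
    n = table.n
    row = table.row(i)
    col = table.col(j)
    a = table.count(i, j)
    if n == 0 or row == 0 or col == 0:
        return QuadrantTest(quadrant, 0.0, math.nan, math.nan, False, False)
    e = row * col / n
    s = (e - a) / math.sqrt(e)
    p = 0.5 * (a / row + a / col)
    return QuadrantTest(quadrant, e, s, p, bool(s > sthr and p < pthr), True)


def relation_from_sparse_pattern(pattern: Iterable[tuple[int, int]]) -> Relation:
    """Map a set of sparse quadrants to a relation class.

    Only six patterns are admissible: the four single quadrants and the two
    disjoint diagonal pairs.  Everything else (adjacent pairs, 3-4 sparse
    quadrants, empty) is NONE.
    """
    return _PATTERN_TO_RELATION.get(frozenset(pattern), Relation.NONE)


def classify_table(
    gene_a: str,
    gene_b: str,
    table: QuadrantTable,
    sthr: float = DEFAULT_STHR,
    pthr: float = DEFAULT_PTHR,
) -> ImplicationResult:
    tests = tuple(quadrant_statistic(table, q, sthr, pthr) for q in QUADRANTS)
    pattern = frozenset(t.quadrant for t in tests if t.sparse)
    relation = relation_from_sparse_pattern(pattern)
    if relation is Relation.NONE and len(pattern) >= 2:
        logger.debug(
            "pair (%s, %s): inadmissible sparse pattern %s -> NONE", gene_a, gene_b, sorted(pattern)
        )
    return ImplicationResult(gene_a, gene_b, table, tests, relation)


def classify_pair(
    ternary_a: Sequence[int],
    ternary_b: Sequence[int],
    sthr: float = DEFAULT_STHR,
    pthr: float = DEFAULT_PTHR,
    gene_a: str = "A",
    gene_b: str = "B",
) -> ImplicationResult:
    """Classify one gene pair from its ternary label vectors."""
    return classify_table(gene_a, gene_b, count_quadrants(ternary_a, ternary_b), sthr, pthr)


def all_pairs_network(
    ternary: TernaryMatrix,
    genes: Iterable[str] | None = None,
    sthr: float = DEFAULT_STHR,
    pthr: float = DEFAULT_PTHR,
) -> list[ImplicationResult]:
    """Classify every unordered gene pair; return the non-NONE results.

    Counts are accumulated with matrix products over low/high indicator
    matrices, so the pass is O(G^2) with exact integer counts.  Each result
    is stored once for the lexicographically smaller (gene_a, gene_b)
    ordering; use :meth:`ImplicationResult.converse` for the other reading.
    """
    if genes is None:
        gene_list = sorted(ternary.gene_ids)
    else:
        gene_set = set(genes)
        missing = gene_set - set(ternary.gene_ids)
        if missing:
            raise ValueError(f"genes absent from ternary matrix: {sorted(missing)}")
        gene_list = sorted(gene_set)
    if len(gene_list) < 2:
        return []
    rows = np.stack([ternary.row(g) for g in gene_list])
    low = (rows == 0).astype(np.int64)
    high = (rows == 2).astype(np.int64)

    counts = {
        (0, 0): low @ low.T,
        (0, 1): low @ high.T,
        (1, 0): high @ low.T,
        (1, 1): high @ high.T,
    }
    n = counts[0, 0] + counts[0, 1] + counts[1, 0] + counts[1, 1]
    row0 = counts[0, 0] + counts[0, 1]
    row1 = counts[1, 0] + counts[1, 1]
    col0 = counts[0, 0] + counts[1, 0]
    col1 = counts[0, 1] + counts[1, 1]
    margins = {(0, 0): (row0, col0), (0, 1): (row0, col1), (1, 0): (row1, col0), (1, 1): (row1, col1)}

    code = np.zeros(n.shape, dtype=np.int8)
    bit = {(0, 0): 1, (0, 1): 2, (1, 0): 4, (1, 1): 8}
    with np.errstate(divide="ignore", invalid="ignore"):
        for q, a in counts.items():
            row, col = margins[q]
            e = row * col / np.where(n > 0, n, 1)
            s = (e - a) / np.sqrt(np.where(e > 0, e, 1.0))
            p = 0.5 * (a / np.where(row > 0, row, 1) + a / np.where(col > 0, col, 1))
            sparse = (row > 0) & (col > 0) & (n > 0) & (s > sthr) & (p < pthr)
            code += bit[q] * sparse.astype(np.int8)

    code_to_relation = {2: True, 1: True, 8: True, 4: True, 6: True, 9: True}
    results: list[ImplicationResult] = []
    g = len(gene_list)
    iu, ju = np.triu_indices(g, k=1)
    hits = [(i, j) for i, j in zip(iu, ju) if code_to_relation.get(int(code[i, j]), False)]
    for i, j in hits:
        table = QuadrantTable(
            int(counts[0, 0][i, j]), int(counts[0, 1][i, j]),
            int(counts[1, 0][i, j]), int(counts[1, 1][i, j]),
        )
        result = classify_table(gene_list[i], gene_list[j], table, sthr, pthr)
        if result.relation is not Relation.NONE:
            results.append(result)
    return results
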