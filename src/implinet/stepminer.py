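"""One-step fits for per-gene expression binarization.

Each gene's values are sorted and a step function with a single jump is
fitted by least squares; the midpoint between the two level means is the
binarization threshold.  Values within a noise margin of the threshold are
labeled intermediate and excluded from downstream pair counting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .core_io import ExpressionMatrix

DEFAULT_MARGIN = 0.5  # log2 units

__all__ = [
    "StepFit",
    "TernaryMatrix",
    "fit_step",
    "binarize_matrix",
    "dynamic_range_filter",
    "DEFAULT_MARGIN",
]


@dataclass(frozen=True)
class StepFit:
    """Result of fitting a one-step function to a gene's sorted values."""

    gene_id: str
    threshold: float
    sse: float
    low_mean: float
    high_mean: float
    margin: float
    n_low: int
    n_high: int
    bimodal: bool

    def label(self, x: float) -> int:
        """Ternary label for a single value: 0 low, 1 intermediate, 2 high."""
        if x < self.threshold - self.margin:
            return 0
        if x > self.threshold + self.margin:
            return 2
        return 1

    def label_values(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        labels = np.ones(values.shape, dtype=np.int8)
        labels[values < self.threshold - self.margin] = 0
        labels[values > self.threshold + self.margin] = 2
        return labels


@dataclass
class TernaryMatrix:
    """Genes x samples matrix of ternary labels (0 low, 1 intermediate, 2 high)."""

    gene_ids: list[str]
    sample_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("label shape does not match identifier lengths")
        if self.labels.size and not np.isin(self.labels, (0, 1, 2)).all():
            raise ValueError("ternary labels must be in {0, 1, 2}")
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, gene_id: str) -> np.ndarray:
        return self.labels[self._index[gene_id]]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TernaryMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.labels, other.labels)
        )


def fit_step(
    values: Iterable[float],
    margin: float = DEFAULT_MARGIN,
    gene_id: str = "",
) -> StepFit:
    """Fit a one-step function to ``values`` and derive the threshold.

    Over all split points k in 1..n-1 of the ascending-sorted values, the k
    minimizing the pooled within-level sum of squares is chosen (ties go to
    the smaller k); the threshold is the midpoint of the two level means.
    Constant input yields a degenerate non-bimodal fit.  Requires n >= 4.
    """
    x = np.asarray(list(values) if not isinstance(values, np.ndarray) else values, dtype=float)
    if x.ndim != 1:
        raise ValueError("fit_step expects a 1-D vector")
    if not np.isfinite(x).all():
        raise ValueError("fit_step requires finite values")
    n = x.size
    if n < 4:
        raise ValueError(f"fit_step requires >=4 values, got {n}")

    xs = np.sort(x)
    if xs[-1] == xs[0]:
        t = float(xs[0])
        return StepFit(gene_id, t, 0.0, t, t, margin, 0, 0, False)

    # Vectorized SSE for every split: SSE(k) = ssq_total - sum_l^2/k - sum_r^2/(n-k)
    csum = np.cumsum(xs)
    total = csum[-1]
    ssq_total = float(np.dot(xs, xs))
    k = np.arange(1, n)
    left = csum[:-1]
    right = total - left
    sse = ssq_total - left**2 / k - right**2 / (n - k)
    best = int(np.argmin(sse))  # argmin takes the first minimum: smaller k on ties
    k_best = best + 1
    low_mean = float(left[best] / k_best)
    high_mean = float(right[best] / (n - k_best))
    t = (low_mean + high_mean) / 2.0
    n_low = int(np.sum(x < t - margin))
    n_high = int(np.sum(x > t + margin))
    bimodal = n_low > 0 and n_high > 0
    return StepFit(
        gene_id=gene_id,
        threshold=t,
        sse=float(max(sse[best], 0.0)),
        low_mean=low_mean,
        high_mean=high_mean,
        margin=margin,
        n_low=n_low,
        n_high=n_high,
        bimodal=bimodal,
    )


def binarize_matrix(
    matrix: ExpressionMatrix, margin: float = DEFAULT_MARGIN
) -> tuple[TernaryMatrix, dict[str, StepFit]]:
    """Fit every gene and produce the ternary label matrix.

    Degenerate genes (constant, or lacking low/high samples) are flagged
    ``bimodal=False`` in their fit but kept in the output.
    """
    fits: dict[str, StepFit] = {}
    labels = np.empty((matrix.n_genes, matrix.n_samples), dtype=np.int8)
    for i, gene in enumerate(matrix.gene_ids):
        fit = fit_step(matrix.values[i], margin=margin, gene_id=gene)
        fits[gene] = fit
        labels[i] = fit.label_values(matrix.values[i])
    return TernaryMatrix(matrix.gene_ids, matrix.sample_ids, labels), fits


def dynamic_range_filter(
    ternary: TernaryMatrix, min_frac: float = 0.05, min_count: int = 3
) -> set[str]:
    """Genes with enough samples in both the low and the high state.

    The bound is max(min_count, ceil(min_frac * n_samples)) and must be met
    by the low count AND the high count.
    """
    bound = max(min_count, math.ceil(min_frac * ternary.n_samples))
    n_low = (ternary.labels == 0).sum(axis=1)
    n_high = (ternary.labels == 2).sum(axis=1)
    keep = (n_low >= bound) & (n_high >= bound)
    return {g for g, ok in zip(ternary.gene_ids, keep) if ok}
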