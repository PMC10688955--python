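"""BIC-based clustering of the Gaussian condition-cell means.

After the network search has identified which factors drive a subjective
indicator, the remaining question is which of the factor-level cells
actually produce *distinct* levels of perceived risk.  Every set partition
of the cells is scored: within each block the cells share one pooled mean,
a single variance is shared across all blocks, and the partition's
BIC = -2 log L + (#blocks + 1) ln n is computed on the underlying
observations.  Because the partitions are non-nested, BIC (rather than a
likelihood-ratio path) is the comparison currency, exactly as in the
network stage, and differences are graded on the Raftery scale.

Enumeration is exact (restricted-growth strings, Bell(#cells) partitions)
and guarded to at most 10 cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import comb, log, pi

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .network import raftery_grade

__all__ = [
    "MAX_CELLS",
    "bell_number",
    "enumerate_partitions",
    "PartitionScore",
    "score_partition",
    "best_partition",
    "MeanPartitionCluster",
]

MAX_CELLS = 10


@lru_cache(maxsize=None)
def bell_number(n: int) -> int:
    """Number of set partitions of n items (via the binomial recurrence)."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    if n == 0:
        return 1
    return sum(comb(n - 1, i) * bell_number(i) for i in range(n))


def enumerate_partitions(cells):
    """All set partitions of ``cells``, canonically ordered.

    Partitions are generated as restricted-growth strings, so each comes
    out exactly once with blocks ordered by their smallest member.  Each
    partition is a tuple of blocks; each block a tuple of cells.
    """
    cells = list(cells)
    n = len(cells)
    if n < 1:
        raise ValueError("need at least one cell")
    if n > MAX_CELLS:
        raise ValueError(
            f"refusing to enumerate partitions of {n} > {MAX_CELLS} cells "
            f"(Bell({n}) = {bell_number(n)})"
        )
    out = []

    def grow(i, rgs, n_blocks):
        if i == n:
            blocks = [[] for _ in range(n_blocks)]
            for item, b in zip(cells, rgs):
                blocks[b].append(item)
            out.append(tuple(tuple(b) for b in blocks))
            return
        for b in range(n_blocks + 1):
            rgs.append(b)
            grow(i + 1, rgs, max(n_blocks, b + 1))
            rgs.pop()

    grow(0, [], 0)
    return out


@dataclass
class PartitionScore:
    """One scored partition of the condition cells."""

    partition: tuple[tuple, ...]
    block_means: tuple[float, ...]
    sigma2: float
    loglik: float
    k: int
    bic: float

    @property
    def n_blocks(self) -> int:
        return len(self.partition)


def _cell_suffstats(values, cells):
    values = np.asarray(values, dtype=float)
    cells = np.asarray(cells)
    labels = list(pd.unique(cells))
    stats = {}
    for lab in labels:
        v = values[cells == lab]
        if v.size == 0:
            raise ValueError(f"cell {lab!r} is empty")
        stats[lab] = (v.size, float(v.sum()), float(np.sum(v * v)))
    return labels, stats


def score_partition(partition, stats: dict, n_total: int) -> PartitionScore:
    """Score one partition from per-cell sufficient statistics.

    ``stats`` maps cell label -> (n, sum, sum of squares).  The Gaussian
    profile likelihood has a closed form: block means are pooled averages
    and the shared variance is the MLE SSE / n.
    """
    sse = 0.0
    means = []
    for block in partition:
        bn = sum(stats[c][0] for c in block)
        if bn == 0:
            raise ValueError(f"empty block {block!r}")
        bs = sum(stats[c][1] for c in block)
        bq = sum(stats[c][2] for c in block)
        m = bs / bn
        means.append(m)
        sse += bq - bn * m * m
    sigma2 = max(sse / n_total, 1e-300)
    loglik = -0.5 * n_total * (log(2.0 * pi * sigma2) + 1.0)
    k = len(partition) + 1
    return PartitionScore(
        partition=tuple(tuple(b) for b in partition),
        block_means=tuple(means),
        sigma2=sigma2,
        loglik=loglik,
        k=k,
        bic=-2.0 * loglik + k * log(n_total),
    )


class MeanPartitionCluster(BaseEstimator):
    """Exhaustive BIC selection over set partitions of condition cells.

    ``fit(X, y)`` takes the observation values ``X`` (1-D) and their cell
    labels ``y``.  Attributes after fitting:

    results_ : DataFrame ranked ascending by BIC (partition, n_blocks,
        loglik, k, bic, delta_bic, grade)
    best_partition_ : tuple of blocks (tuples of cell labels)
    block_means_ : pooled means of the best partition
    labels_ : dict cell label -> block index in the best partition
    """

    def __init__(self, max_cells: int = MAX_CELLS):
        self.max_cells = max_cells

    def fit(self, X, y):
        values = np.asarray(X, dtype=float).ravel()
        cells = np.asarray(y)
        if values.shape[0] != cells.shape[0]:
            raise ValueError("values and cell labels must align")
        labels, stats = _cell_suffstats(values, cells)
        if len(labels) > self.max_cells:
            raise ValueError(
                f"{len(labels)} cells exceed the max_cells={self.max_cells} guard"
            )
        n_total = values.shape[0]
        scored = [
            score_partition(p, stats, n_total)
            for p in enumerate_partitions(labels)
        ]
        order = np.argsort([s.bic for s in scored], kind="stable")
        scored = [scored[i] for i in order]
        best = scored[0].bic
        self.results_ = pd.DataFrame(
            {
                "partition": [s.partition for s in scored],
                "n_blocks": [s.n_blocks for s in scored],
                "loglik": [s.loglik for s in scored],
                "k": [s.k for s in scored],
                "bic": [s.bic for s in scored],
                "delta_bic": [s.bic - best for s in scored],
                "grade": [raftery_grade(s.bic - best) for s in scored],
            }
        )
        self.scores_ = scored
        self.best_partition_ = scored[0].partition
        self.block_means_ = scored[0].block_means
        self.labels_ = {
            cell: b
            for b, block in enumerate(self.best_partition_)
            for cell in block
        }
        self.n_cells_ = len(labels)
        return self


def best_partition(
    df: pd.DataFrame,
    value_col: str,
    cell_cols,
    max_cells: int = MAX_CELLS,
) -> MeanPartitionCluster:
    """Cluster the cells defined by ``cell_cols`` on the values in ``value_col``.

    Cell labels are human-readable "Factor=level & ..." strings, matching
    how conditions are reported.
    """
    cell_cols = list(cell_cols)
    labels = df[cell_cols].apply(
        lambda r: " & ".join(f"{c}={r[c]}" for c in cell_cols), axis=1
    )
    return MeanPartitionCluster(max_cells=max_cells).fit(
        df[value_col].to_numpy(dtype=float), labels.to_numpy()
    )
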