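"""Edge-weight estimation from expression profiles.

The default weight is mutual information estimated by adaptive
partitioning (Darbellay–Vajda style) on rank-transformed profiles: the
unit square is recursively quadri-sected at the conditional medians of
each cell while a chi-squared uniformity test on the four sub-cell
counts rejects.  Cells holding more than four times the minimum
occupancy are always refined: the quadrant test has little power
against smooth density gradients in heavily populated cells (the
conditional-median split re-balances the marginals, masking the
departure), so the test is only trusted where it has local resolution.
MI is accumulated over the final cells as

    MI = Σ_cells (n_c / n) · ln( n · n_c / (n_x · n_y) )

where ``n_c`` is the cell count and ``n_x``, ``n_y`` the marginal counts
of the cell's x- and y-intervals.  Because ranks are a strictly monotone
transform of each profile and the recursion depends on the data only
through order statistics, the estimate is invariant under monotone
rescaling of either input and symmetric in its arguments.

A magnitude-of-Pearson alternative is provided for comparison.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from .datatypes import ExpressionMatrix, ValidationError, WeightMatrix

__all__ = [
    "RankedProfiles",
    "rank_transform",
    "mi_pair",
    "mi_matrix",
    "pearson_matrix",
    "DEFAULT_SIGNIFICANCE",
    "MIN_CELL_OCCUPANCY",
]

#: significance level of the chi-squared split test (3 degrees of freedom)
DEFAULT_SIGNIFICANCE = 1e-4
#: cells with fewer points than this are never split further
MIN_CELL_OCCUPANCY = 8
#: cells with more than 4x the minimum occupancy are always split
FORCED_SPLIT_FACTOR = 4


class RankedProfiles:
    """Per-gene rank-transformed profiles mapped into (0, 1)."""

    def __init__(self, gene_ids, ranks: np.ndarray):
        self.gene_ids = list(gene_ids)
        self.ranks = np.asarray(ranks, dtype=float)

    def row(self, gene_id: str) -> np.ndarray:
        return self.ranks[self.gene_ids.index(gene_id)]


def _rank_rows(values: np.ndarray) -> np.ndarray:
    n = values.shape[1]
    ranks = stats.rankdata(values, axis=1, method="average")
    return (ranks - 0.5) / n


def rank_transform(expr: ExpressionMatrix) -> RankedProfiles:
    """Within-gene rank transform: sample rank k of n maps to (k−0.5)/n.

    Ties receive the average rank.  Any strictly increasing rescaling of
    a profile leaves its transformed row unchanged.
    """
    if expr.n_samples < 2:
        raise ValidationError("rank transform requires at least 2 samples")
    return RankedProfiles(expr.gene_ids, _rank_rows(expr.values))


def _adaptive_partition_mi(
    x: np.ndarray, y: np.ndarray, chi2_crit: float, min_cell: int
) -> float:
    n = x.size
    sx = np.sort(x)
    sy = np.sort(y)
    mi = 0.0
    # cells as (point-index array, x_lo, x_hi, y_lo, y_hi]; half-open below
    stack = [(np.arange(n), -np.inf, np.inf, -np.inf, np.inf)]
    while stack:
        idx, x_lo, x_hi, y_lo, y_hi = stack.pop()
        n_c = idx.size
        if n_c == 0:
            continue
        split = False
        if n_c >= min_cell:
            cx = x[idx]
            cy = y[idx]
            x_med = np.median(cx)
            y_med = np.median(cy)
            left = cx <= x_med
            below = cy <= y_med
            counts = np.array(
                [
                    np.count_nonzero(left & below),
                    np.count_nonzero(left & ~below),
                    np.count_nonzero(~left & below),
                    np.count_nonzero(~left & ~below),
                ]
            )
            # all-in-one-quadrant splits make no progress (degenerate ties)
            if counts.max() < n_c:
                if n_c > FORCED_SPLIT_FACTOR * min_cell:
                    split = True
                else:
                    expected = n_c / 4.0
                    stat = float(np.sum((counts - expected) ** 2) / expected)
                    split = stat > chi2_crit
                if split:
                    stack.append((idx[left & below], x_lo, x_med, y_lo, y_med))
                    stack.append((idx[left & ~below], x_lo, x_med, y_med, y_hi))
                    stack.append((idx[~left & below], x_med, x_hi, y_lo, y_med))
                    stack.append((idx[~left & ~below], x_med, x_hi, y_med, y_hi))
        if not split:
            n_x = np.searchsorted(sx, x_hi, side="right") - np.searchsorted(
                sx, x_lo, side="right"
            )
            n_y = np.searchsorted(sy, y_hi, side="right") - np.searchsorted(
                sy, y_lo, side="right"
            )
            mi += (n_c / n) * np.log(n * n_c / (n_x * n_y))
    return max(mi, 0.0)


def mi_pair(
    x,
    y,
    significance: float = DEFAULT_SIGNIFICANCE,
    min_cell: int = MIN_CELL_OCCUPANCY,
) -> float:
    """Adaptive-partitioning MI (nats) between two profiles.

    Inputs are rank-transformed internally (idempotent for profiles that
    are already ranks without ties), making the estimate symmetric and
    invariant under strictly monotone transforms of either input.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValidationError(f"profile lengths differ: {x.size} vs {y.size}")
    if x.size < 8:
        raise ValidationError("mi_pair requires at least 8 samples")
    if not (0 < significance < 1):
        raise ValidationError("significance must lie in (0, 1)")
    xr = _rank_rows(x[None, :])[0]
    yr = _rank_rows(y[None, :])[0]
    if yr.tobytes() < xr.tobytes():
        xr, yr = yr, xr  # canonical argument order => exact symmetry
    chi2_crit = float(stats.chi2.isf(significance, df=3))
    return _adaptive_partition_mi(xr, yr, chi2_crit, min_cell)


def mi_matrix(
    expr: ExpressionMatrix,
    significance: float = DEFAULT_SIGNIFICANCE,
    tf_ids=None,
    min_cell: int = MIN_CELL_OCCUPANCY,
) -> WeightMatrix:
    """Pairwise adaptive-partitioning MI as a weight matrix.

    Without ``tf_ids`` the result is a symmetric zero-diagonal GCN
    matrix over all genes; with ``tf_ids`` rows are restricted to the
    TFs (a GRN regulators × targets matrix) and TF–self entries are 0.
    """
    ranked = rank_transform(expr)
    chi2_crit = float(stats.chi2.isf(significance, df=3))
    ranks = ranked.ranks
    gene_ids = expr.gene_ids
    if tf_ids is None:
        n = len(gene_ids)
        values = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                values[i, j] = values[j, i] = _adaptive_partition_mi(
                    ranks[i], ranks[j], chi2_crit, min_cell
                )
        return WeightMatrix.gcn(gene_ids, values)
    tf_ids = list(tf_ids)
    missing = sorted(set(tf_ids) - set(gene_ids))
    if missing:
        raise ValidationError(f"tf_ids not found among gene_ids: {missing}")
    gidx = {g: i for i, g in enumerate(gene_ids)}
    values = np.zeros((len(tf_ids), len(gene_ids)))
    cache: dict[tuple[int, int], float] = {}
    for a, tf in enumerate(tf_ids):
        i = gidx[tf]
        for b, gene in enumerate(gene_ids):
            j = gidx[gene]
            if i == j:
                continue
            key = (min(i, j), max(i, j))
            if key not in cache:
                cache[key] = _adaptive_partition_mi(
                    ranks[i], ranks[j], chi2_crit, min_cell
                )
            values[a, b] = cache[key]
    return WeightMatrix.grn(tf_ids, gene_ids, values)


def pearson_matrix(expr: ExpressionMatrix) -> WeightMatrix:
    """Magnitude of Pearson correlation per gene pair.

    Zero-variance profiles yield weight 0 for every pair they touch (and
    a warning); the diagonal is 0.
    """
    if expr.n_samples < 3:
        raise ValidationError("pearson_matrix requires at least 3 samples")
    values = expr.values
    sd = values.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        flagged = [g for g, d in zip(expr.gene_ids, degenerate) if d]
        warnings.warn(
            f"zero-variance profile(s) scored 0 for all pairs: {flagged}",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    corr = np.abs(corr)
    corr[~np.isfinite(corr)] = 0.0
    corr[degenerate, :] = 0.0
    corr[:, degenerate] = 0.0
    np.fill_diagonal(corr, 0.0)
    corr = np.minimum(corr, 1.0)
    return WeightMatrix.gcn(expr.gene_ids, corr)
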