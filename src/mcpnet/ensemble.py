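"""Ensemble multipath scores, AUPRC evaluation and groundtruth handling.

The single-length MCP score ρ^L only sees indirect routes of one
length.  The ensemble score replaces the denominator with a convex
combination of path capacities,

    M_st = W_st / (a_1·η¹_st + a_2·η²_st + ... + a_L·η^L_st),
    Σ a_k = 1,  a_k ≥ 0,

(η¹ = W, so the direct term is optional), and the coefficients are
chosen by exhaustive search on a lattice (default spacing 0.1) to
maximize AUPRC against partial groundtruth — experimentally supported
positive pairs plus asserted non-interactions.  A Stouffer-style
row/column z-transform of the ensemble matrix suppresses background
signal, as in CLR-style post-processing.

AUPRC here is average precision with tie grouping: pairs are ranked by
score descending (+∞ first), one precision–recall point per distinct
score, and AP = Σ_positives precision(tie group of that positive)/n_pos.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GroundTruth, ValidationError, WeightMatrix
from .mcp import PathCapacityMatrix, ScoreMatrix, _score_values, _zero_matching_diagonal

__all__ = [
    "EnsembleCoefficients",
    "PRResult",
    "ensemble_score",
    "coefficient_grid",
    "auprc",
    "optimize_ensemble",
    "stouffer_transform",
    "split_groundtruth",
    "robustness_experiment",
    "summarize_robustness",
    "complete_pair_count",
    "partial_groundtruth_census",
]

DEFAULT_LENGTHS = (1, 2, 3, 4)


@dataclass
class EnsembleCoefficients:
    """Convex weights over path lengths for the ensemble denominator."""

    lengths: tuple = DEFAULT_LENGTHS
    weights: tuple = ()

    def __post_init__(self) -> None:
        self.lengths = tuple(int(l) for l in self.lengths)
        self.weights = tuple(float(w) for w in self.weights)
        if len(self.lengths) != len(self.weights):
            raise ValidationError("lengths and weights must have equal cardinality")
        if any(w < 0 or w > 1 for w in self.weights):
            raise ValidationError("weights must lie in [0, 1]")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValidationError("weights must sum to 1")
        if any(l < 1 for l in self.lengths):
            raise ValidationError("lengths must be >= 1")


@dataclass
class PRResult:
    """Precision-recall curve and its area (average precision)."""

    auprc: float
    curve: list = field(default_factory=list)  # (recall, precision) per tie group
    n_pos: int = 0
    n_neg: int = 0


def _collect_etas(W: WeightMatrix, etas, lengths) -> list[np.ndarray]:
    """Denominator terms per requested length; length 1 is W itself."""
    etas = dict(etas or {})
    arrays = []
    for L in lengths:
        if L == 1 and L not in etas:
            arrays.append(W.values)
            continue
        if L not in etas:
            raise ValidationError(f"no capacity matrix supplied for length {L}")
        m = etas[L]
        values = m.values if hasattr(m, "values") else np.asarray(m, dtype=float)
        if values.shape != W.values.shape:
            raise ValidationError(f"capacity matrix for length {L} has wrong shape")
        arrays.append(values)
    return arrays


def ensemble_score(
    W: WeightMatrix, etas, coeffs: EnsembleCoefficients
) -> ScoreMatrix:
    """Ensemble multipath score M = W / Σ_k a_k · η^{L_k}.

    Conventions match the MCP score: 0/0 → 0, positive/0 → +∞,
    self-pairs 0.  A one-hot coefficient vector reduces M to the
    single-length score R^L.
    """
    arrays = _collect_etas(W, etas, coeffs.lengths)
    denom = np.zeros_like(W.values)
    for w_k, arr in zip(coeffs.weights, arrays):
        if w_k:
            denom = denom + w_k * arr
    values = _score_values(W.values, denom)
    _zero_matching_diagonal(values, W.row_ids, W.col_ids)
    return ScoreMatrix(list(W.row_ids), list(W.col_ids), values, score_kind="ensemble")


def coefficient_grid(n_terms: int, interval: float = 0.1) -> list[tuple]:
    """All compositions of 1.0 into ``n_terms`` weights on the lattice.

    ``interval`` must divide 1; the grid is ordered lexicographically and
    contains every one-hot vector.  Size is C(k+n−1, n−1) for k = 1/interval.
    """
    if n_terms < 1:
        raise ValidationError("n_terms must be >= 1")
    k = round(1.0 / interval)
    if abs(k - 1.0 / interval) > 1e-9:
        raise ValidationError("1/interval must be an integer")
    grid = []
    for parts in itertools.product(range(k + 1), repeat=n_terms - 1):
        if sum(parts) <= k:
            last = k - sum(parts)
            grid.append(tuple(p / k for p in parts) + (last / k,))
    grid.sort()
    return grid


def _pair_values(matrix, pairs, directed: bool) -> np.ndarray:
    row_idx = {g: i for i, g in enumerate(matrix.row_ids)}
    col_idx = {g: j for j, g in enumerate(matrix.col_ids)}
    values = matrix.values
    out = np.empty(len(pairs))
    for k, (a, b) in enumerate(pairs):
        if a in row_idx and b in col_idx:
            out[k] = values[row_idx[a], col_idx[b]]
        elif not directed and b in row_idx and a in col_idx:
            out[k] = values[row_idx[b], col_idx[a]]
        else:
            raise ValidationError(f"groundtruth pair ({a}, {b}) not addressable in matrix")
    return out


def _average_precision(scores: np.ndarray, labels: np.ndarray):
    """AP with tie grouping; +∞ ranks first. Returns (ap, curve)."""
    n_pos = int(labels.sum())
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    # tie-group boundaries: one PR point per distinct score
    # (direct comparison, not diff: inf - inf would be nan)
    boundary = np.nonzero(s[1:] != s[:-1])[0]
    ends = np.append(boundary, s.size - 1)
    cum_tp = np.cumsum(y)
    tp_at_end = cum_tp[ends]
    prec = tp_at_end / (ends + 1.0)
    rec = tp_at_end / n_pos
    tp_per_group = np.diff(np.concatenate([[0], tp_at_end]))
    ap = float(np.sum(tp_per_group * prec) / n_pos)
    curve = list(zip(rec.tolist(), prec.tolist()))
    return ap, curve


def auprc(scores, gt: GroundTruth) -> PRResult:
    """Area under the precision-recall curve over the labelled pairs.

    Only positives ∪ negatives are ranked; all labelled pairs must be
    addressable in the score matrix.
    """
    if gt.n_pos < 1 or gt.n_neg < 1:
        raise ValidationError("groundtruth needs at least one positive and one negative")
    pairs = gt.pairs()
    values = _pair_values(scores, pairs, gt.directed)
    ap, curve = _average_precision(values, gt.labels())
    return PRResult(auprc=ap, curve=curve, n_pos=gt.n_pos, n_neg=gt.n_neg)


def optimize_ensemble(
    W: WeightMatrix,
    etas,
    gt: GroundTruth,
    interval: float = 0.1,
    lengths=DEFAULT_LENGTHS,
) -> tuple[EnsembleCoefficients, PRResult]:
    """Exhaustive lattice search for the AUPRC-maximizing coefficients.

    Every grid point is evaluated; ties are broken toward the
    lexicographically smallest weight vector.  Scores only need to be
    ranked at labelled pairs, so the search evaluates the ensemble on
    the groundtruth pairs directly; the returned optimum is identical to
    a full-matrix re-evaluation.
    """
    if gt.n_pos < 1 or gt.n_neg < 1:
        raise ValidationError("groundtruth needs at least one positive and one negative")
    lengths = tuple(int(l) for l in lengths)
    pairs = gt.pairs()
    labels = gt.labels()
    w_pairs = _pair_values(W, pairs, gt.directed)
    arrays = _collect_etas(W, etas, lengths)

    class _View:
        def __init__(self, vals):
            self.row_ids = W.row_ids
            self.col_ids = W.col_ids
            self.values = vals

    eta_pairs = [_pair_values(_View(arr), pairs, gt.directed) for arr in arrays]

    best_weights = None
    best_ap = -1.0
    best_curve = None
    for weights in coefficient_grid(len(lengths), interval):
        denom = np.zeros_like(w_pairs)
        for w_k, ep in zip(weights, eta_pairs):
            if w_k:
                denom = denom + w_k * ep
        with np.errstate(divide="ignore", invalid="ignore"):
            scores = np.where(denom > 0, w_pairs / np.where(denom > 0, denom, 1.0), 0.0)
        scores[(denom == 0) & (w_pairs > 0)] = np.inf
        ap, curve = _average_precision(scores, labels)
        if ap > best_ap:  # lexicographic grid order breaks ties
            best_ap, best_weights, best_curve = ap, weights, curve
    coeffs = EnsembleCoefficients(lengths=lengths, weights=best_weights)
    return coeffs, PRResult(best_ap, best_curve, gt.n_pos, gt.n_neg)


def stouffer_transform(M: ScoreMatrix) -> ScoreMatrix:
    """Row/column z-standardization of a score matrix (CLR-style).

    Infinite entries are clipped to the largest finite entry; per-row
    and per-column z-scores (population σ, self-pairs excluded, σ=0→0)
    are clamped at 0 and combined as (z_row + z_col)/√2.
    """
    values = M.values.copy().astype(float)
    self_mask = np.zeros(values.shape, dtype=bool)
    cidx = {g: j for j, g in enumerate(M.col_ids)}
    for i, g in enumerate(M.row_ids):
        if g in cidx:
            self_mask[i, cidx[g]] = True
    finite = np.isfinite(values)
    if not finite.all():
        fmax = values[finite].max(initial=0.0)
        values[~finite] = fmax

    def clamped_z(vals, mask, axis):
        counts = np.sum(mask, axis=axis, keepdims=True)
        counts = np.maximum(counts, 1)
        mean = np.sum(np.where(mask, vals, 0.0), axis=axis, keepdims=True) / counts
        var = np.sum(np.where(mask, (vals - mean) ** 2, 0.0), axis=axis, keepdims=True) / counts
        sd = np.sqrt(var)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(sd > 0, (vals - mean) / np.where(sd > 0, sd, 1.0), 0.0)
        return np.maximum(z, 0.0)

    mask = ~self_mask
    z_row = clamped_z(values, mask, axis=1)
    z_col = clamped_z(values, mask, axis=0)
    out = (z_row + z_col) / math.sqrt(2.0)
    out[self_mask] = 0.0
    return ScoreMatrix(list(M.row_ids), list(M.col_ids), out, score_kind="stouffer")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_groundtruth(
    gt: GroundTruth, train_frac: float, seed: int
) -> tuple[GroundTruth, GroundTruth]:
    """Random stratified split of the groundtruth into train and test.

    Positives and negatives are split independently at ``train_frac``
    (rounded half-up, clamped so both sides keep at least one pair of
    each label); the two halves partition the input exactly and the
    split is reproducible per seed.
    """
    if not (0 < train_frac < 1):
        raise ValidationError("train_frac must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    halves = {"train": {}, "test": {}}
    for label, pairs in (("pos", gt.positives), ("neg", gt.negatives)):
        pairs = sorted(pairs)
        if len(pairs) < 2:
            raise ValidationError(f"stratum {label!r} has fewer than 2 pairs")
        n_train = _round_half_up(train_frac * len(pairs))
        n_train = min(max(n_train, 1), len(pairs) - 1)
        perm = rng.permutation(len(pairs))
        train_idx = set(perm[:n_train].tolist())
        halves["train"][label] = {p for k, p in enumerate(pairs) if k in train_idx}
        halves["test"][label] = {p for k, p in enumerate(pairs) if k not in train_idx}
    train = GroundTruth(
        frozenset(halves["train"]["pos"]), frozenset(halves["train"]["neg"]), gt.directed
    )
    test = GroundTruth(
        frozenset(halves["test"]["pos"]), frozenset(halves["test"]["neg"]), gt.directed
    )
    return train, test


def robustness_experiment(
    W: WeightMatrix,
    etas,
    gt: GroundTruth,
    fracs,
    n_reps: int,
    interval: float = 0.1,
    lengths=DEFAULT_LENGTHS,
    seed: int = 0,
) -> pd.DataFrame:
    """Train/test robustness of the ensemble optimization.

    For every training fraction and repetition: split the groundtruth,
    optimize coefficients on the training half, then evaluate the
    resulting ensemble on the held-out half and on the full groundtruth.
    Returns a long-format table (frac, rep, auprc_train, auprc_test,
    auprc_full, one column per coefficient).
    """
    lengths = tuple(int(l) for l in lengths)
    rows = []
    for fi, frac in enumerate(fracs):
        for rep in range(n_reps):
            split_seed = int(
                np.random.SeedSequence([int(seed), fi, rep]).generate_state(1)[0]
                % (2**31)
            )
            train, test = split_groundtruth(gt, frac, split_seed)
            coeffs, train_pr = optimize_ensemble(W, etas, train, interval, lengths)
            scores = ensemble_score(W, etas, coeffs)
            row = {
                "frac": frac,
                "rep": rep,
                "auprc_train": train_pr.auprc,
                "auprc_test": auprc(scores, test).auprc,
                "auprc_full": auprc(scores, gt).auprc,
            }
            for L, w_k in zip(coeffs.lengths, coeffs.weights):
                row[f"a{L}"] = w_k
            rows.append(row)
    return pd.DataFrame(rows)


def summarize_robustness(table: pd.DataFrame) -> pd.DataFrame:
    """Mean/sd of test and full-groundtruth AUPRC per training fraction."""
    return (
        table.groupby("frac")[["auprc_test", "auprc_full"]]
        .agg(["mean", "std"])
        .reset_index()
    )


def complete_pair_count(n_genes: int, directed: bool = False) -> int:
    """Number of distinct gene pairs among ``n_genes``."""
    if n_genes < 2:
        raise ValidationError("need at least 2 genes")
    return n_genes * (n_genes - 1) // (1 if directed else 2)


def partial_groundtruth_census(
    n_positives: int,
    n_genes: int | None = None,
    n_regulators: int | None = None,
    n_targets: int | None = None,
) -> dict:
    """Bookkeeping for partial groundtruth built from a known-interaction list.

    Either ``n_genes`` (undirected: all unordered gene pairs) or
    ``n_regulators`` × ``n_targets`` (a regulator–target matrix) defines
    the universe; everything not listed positive counts as negative.
    Returns total pair count, negative count and the positive fraction.
    """
    if n_genes is not None:
        total = complete_pair_count(n_genes)
    elif n_regulators is not None and n_targets is not None:
        total = n_regulators * n_targets
    else:
        raise ValidationError("supply n_genes or both n_regulators and n_targets")
    if not (0 <= n_positives <= total):
        raise ValidationError("n_positives out of range for the pair universe")
    return {
        "total_pairs": total,
        "n_positives": n_positives,
        "n_negatives": total - n_positives,
        "positive_fraction": n_positives / total,
    }
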