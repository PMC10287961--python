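"""Maximum-capacity-path (MCP) scores.

The capacity of a length-L walk between genes s and t is the minimum
edge weight along the walk; the L-path capacity

    η^L_st = max over all walks (v_s, v_{i1}, ..., v_{i(L-1)}, v_t)
             of min(W_{s,i1}, ..., W_{i(L-1),t})

takes the best such walk.  Walks may revisit vertices (closed loops are
legitimate, modelling e.g. regulatory feedback), which is exactly what
makes the recursive bisection

    η^L = η^h ⊗ η^(L−h),   h = ⌊L/2⌋

valid, where ⊗ is the max-min matrix product.  The MCP score is the
ratio ρ^L_st = W_st / η^L_st: values above 1 flag a direct interaction
stronger than any length-L indirect route.

The ARACNe-style data-processing-inequality filter is the L = 2
special case: an edge is removed when its weight falls below the
capacity of some two-edge detour (up to a multiplicative tolerance).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .datatypes import ValidationError, WeightMatrix, canonical_pair
from .parallel import parallel_map_tiles

__all__ = [
    "PathCapacityMatrix",
    "ScoreMatrix",
    "maxmin_product",
    "eta",
    "brute_force_eta",
    "mcp_score",
    "dpi_filter",
    "grn_eta",
    "DEFAULT_TILE_SIZE",
]

DEFAULT_TILE_SIZE = 64


@dataclass
class PathCapacityMatrix:
    """η^L values for all pairs at one path length L."""

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray
    length: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValidationError("capacity matrix shape does not match labels")
        if self.length < 1:
            raise ValidationError("path length must be >= 1")
        if np.any(self.values < 0):
            raise ValidationError("capacities must be non-negative")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        s, t = pair
        return float(self.values[self.row_ids.index(s), self.col_ids.index(t)])


@dataclass
class ScoreMatrix:
    """MCP score ρ^L, ensemble score M^L, or Stouffer-transformed scores."""

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray
    score_kind: str = "mcp"

    def __post_init__(self) -> None:
        if self.score_kind not in ("mcp", "ensemble", "stouffer"):
            raise ValidationError(f"unknown score_kind {self.score_kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValidationError("score matrix shape does not match labels")
        if np.any(self.values < 0):
            raise ValidationError("scores must be non-negative")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        s, t = pair
        return float(self.values[self.row_ids.index(s), self.col_ids.index(t)])


def _as_capacity(m) -> PathCapacityMatrix:
    if isinstance(m, PathCapacityMatrix):
        return m
    if isinstance(m, WeightMatrix):
        return PathCapacityMatrix(list(m.row_ids), list(m.col_ids), m.values, length=1)
    raise ValidationError(f"expected a weight or capacity matrix, got {type(m).__name__}")


def _maxmin_values(
    a: np.ndarray, b: np.ndarray, tile_size: int, n_workers: int
) -> np.ndarray:
    def kernel(rs: slice, cs: slice) -> np.ndarray:
        block_b = b[:, cs]
        rows = a[rs]
        out = np.empty((rows.shape[0], block_b.shape[1]))
        for k in range(rows.shape[0]):
            # capacity of the best 2-segment walk s -> i -> t for each t
            out[k] = np.minimum(rows[k][:, None], block_b).max(axis=0)
        return out

    return parallel_map_tiles(
        (a.shape[0], b.shape[1]), tile_size, n_workers, kernel
    )


def maxmin_product(
    A,
    B,
    tile_size: int = DEFAULT_TILE_SIZE,
    n_workers: int = 1,
) -> PathCapacityMatrix:
    """Max-min matrix product: out[s,t] = max_i min(A[s,i], B[i,t]).

    Composes an A.length-walk with a B.length-walk, so the result has
    length ``A.length + B.length``.  Evaluated tile by tile; because max
    and min are order-independent the result is bit-identical for any
    tile size and worker count.
    """
    A = _as_capacity(A)
    B = _as_capacity(B)
    if A.col_ids != B.row_ids:
        raise ValidationError("inner identifiers of A and B do not match")
    values = _maxmin_values(A.values, B.values, tile_size, n_workers)
    return PathCapacityMatrix(
        list(A.row_ids), list(B.col_ids), values, length=A.length + B.length
    )


def eta(
    W,
    L: int,
    tile_size: int = DEFAULT_TILE_SIZE,
    n_workers: int = 1,
) -> PathCapacityMatrix:
    """L-path capacities by recursive path bisection with memoization.

    η^1 = W; η^L = η^⌊L/2⌋ ⊗ η^⌈L/2⌉.  Equals the brute-force maximum
    over all length-L walks (vertex repeats permitted).
    """
    if L < 1:
        raise ValidationError("path length L must be >= 1")
    base = _as_capacity(W)
    if base.row_ids != base.col_ids:
        raise ValidationError("eta requires a square matrix over one gene set")
    cache: dict[int, PathCapacityMatrix] = {1: base}

    def power(length: int) -> PathCapacityMatrix:
        if length not in cache:
            h = length // 2
            cache[length] = maxmin_product(
                power(h), power(length - h), tile_size=tile_size, n_workers=n_workers
            )
        return cache[length]

    result = power(L)
    return PathCapacityMatrix(
        list(result.row_ids), list(result.col_ids), result.values.copy(), length=L
    )


def brute_force_eta(W, L: int, s: str, t: str) -> float:
    """Direct enumeration oracle for η^L_st, O(|V|^(L−1)).

    Guarded to |V| ≤ 12 and L ≤ 6; intended for testing only.
    """
    cap = _as_capacity(W)
    if cap.row_ids != cap.col_ids:
        raise ValidationError("brute_force_eta requires a square matrix")
    n = len(cap.row_ids)
    if n > 12 or L > 6:
        raise ValidationError("brute-force guard exceeded (|V| <= 12, L <= 6)")
    if L < 1:
        raise ValidationError("path length L must be >= 1")
    values = cap.values
    si = cap.row_ids.index(s)
    ti = cap.col_ids.index(t)
    best = 0.0
    for inner in itertools.product(range(n), repeat=L - 1):
        walk = (si, *inner, ti)
        capacity = min(values[a, b] for a, b in zip(walk[:-1], walk[1:]))
        best = max(best, capacity)
    return best


def _score_values(w: np.ndarray, e: np.ndarray) -> np.ndarray:
    out = np.zeros_like(w, dtype=float)
    pos_eta = e > 0
    out[pos_eta] = w[pos_eta] / e[pos_eta]
    out[(~pos_eta) & (w > 0)] = np.inf  # direct edge with no indirect route
    return out


def _zero_matching_diagonal(values: np.ndarray, row_ids, col_ids) -> None:
    cidx = {g: j for j, g in enumerate(col_ids)}
    for i, g in enumerate(row_ids):
        j = cidx.get(g)
        if j is not None:
            values[i, j] = 0.0


def mcp_score(W, etaL: PathCapacityMatrix) -> ScoreMatrix:
    """MCP score ρ^L = W / η^L elementwise.

    Conventions: 0/0 → 0; positive/0 → +∞; self-pairs are unscored
    (set to 0).
    """
    wcap = _as_capacity(W)
    if (wcap.row_ids, wcap.col_ids) != (etaL.row_ids, etaL.col_ids):
        raise ValidationError("weight and capacity matrices are not aligned")
    values = _score_values(wcap.values, etaL.values)
    _zero_matching_diagonal(values, wcap.row_ids, wcap.col_ids)
    return ScoreMatrix(list(wcap.row_ids), list(wcap.col_ids), values, score_kind="mcp")


def dpi_filter(W: WeightMatrix, tolerance: float = 0.0) -> set:
    """Data-processing-inequality filter as the 2-path MCP special case.

    Returns the set of removed (canonical) edges:
    ``{(s,t) : 0 < W[s,t] < (1−tolerance)·η²[s,t]}``.  At tolerance 0
    this is exactly the edge set with ρ² < 1.
    """
    if not (0 <= tolerance < 1):
        raise ValidationError("tolerance must lie in [0, 1)")
    if W.kind != "gcn":
        raise ValidationError("dpi_filter expects a gcn weight matrix")
    eta2 = eta(W, 2)
    w = W.values
    removed_mask = (w > 0) & (w < (1.0 - tolerance) * eta2.values)
    removed = set()
    for i, j in zip(*np.nonzero(removed_mask)):
        removed.add(canonical_pair(W.row_ids[i], W.col_ids[j], directed=False))
    return removed


def grn_eta(
    W_tt: WeightMatrix,
    W_tg: WeightMatrix,
    L: int,
    tile_size: int = DEFAULT_TILE_SIZE,
    n_workers: int = 1,
) -> PathCapacityMatrix:
    """TF–target L-path capacities under the regulatory path model.

    The indirect route is L−1 TF–TF hops followed by a single TF–target
    edge: η_grn(L) = η_tt(L−1) ⊗ W_tg.  Targets never serve as
    intermediaries.  The GRN MCP score is ``mcp_score(W_tg, grn_eta(...))``.
    """
    if L < 2:
        raise ValidationError("grn_eta requires L >= 2")
    if W_tt.row_ids != W_tt.col_ids:
        raise ValidationError("W_tt must be square over the TF identifiers")
    if W_tt.col_ids != W_tg.row_ids:
        raise ValidationError("W_tt TF identifiers must match W_tg rows")
    eta_tt = eta(W_tt, L - 1, tile_size=tile_size, n_workers=n_workers)
    out = maxmin_product(eta_tt, _as_capacity(W_tg), tile_size=tile_size, n_workers=n_workers)
    return PathCapacityMatrix(list(out.row_ids), list(out.col_ids), out.values, length=L)
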