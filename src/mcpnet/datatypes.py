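"""Core data containers for network reconstruction.

The containers are thin, validated wrappers around numpy arrays plus
identifier lists.  Conventions used throughout the package:

* An expression matrix ``P`` has one row per gene and one column per
  sample.
* An edge-weight matrix ``W`` is non-negative.  In co-expression (GCN)
  mode it is square and symmetric with a zero diagonal; in regulatory
  (GRN) mode it is rectangular, rows indexed by regulators (TFs) and
  columns by target genes.
* Ground truth is a pair of disjoint labelled gene-pair sets
  (positives / negatives); in undirected mode pairs are stored
  canonically with the lexicographically smaller identifier first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ValidationError",
    "ExpressionMatrix",
    "WeightMatrix",
    "GroundTruth",
    "RunConfig",
    "SYMMETRY_TOL",
]

#: tolerance used when checking symmetry of GCN weight matrices
SYMMETRY_TOL = 1e-12


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


def _check_unique(ids, what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise ValidationError(f"duplicate {what} identifier(s): {sorted(set(dups))}")
    return ids


@dataclass
class ExpressionMatrix:
    """Genes × samples expression matrix with labels."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"expression values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite expression value for gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]


@dataclass
class WeightMatrix:
    """Non-negative edge-weight matrix W.

    ``kind='gcn'`` requires a square symmetric matrix with zero diagonal
    over a single gene set; ``kind='grn'`` permits a rectangular
    regulators × targets matrix.
    """

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray
    kind: str = "gcn"

    def __post_init__(self) -> None:
        if self.kind not in ("gcn", "grn"):
            raise ValidationError(f"kind must be 'gcn' or 'grn', got {self.kind!r}")
        self.row_ids = _check_unique(self.row_ids, "row")
        self.col_ids = _check_unique(self.col_ids, "column")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValidationError(
                f"weight matrix shape {self.values.shape} does not match labels"
            )
        if np.any(self.values < 0):
            raise ValidationError("weight matrix contains negative entries")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("weight matrix contains non-finite entries")
        if self.kind == "gcn":
            if self.row_ids != self.col_ids:
                raise ValidationError("gcn weight matrix requires row_ids == col_ids")
            if np.abs(self.values - self.values.T).max(initial=0.0) > SYMMETRY_TOL:
                raise ValidationError("gcn weight matrix is not symmetric")
            if np.abs(np.diag(self.values)).max(initial=0.0) != 0.0:
                raise ValidationError("gcn weight matrix must have a zero diagonal")

    @classmethod
    def gcn(cls, gene_ids, values) -> "WeightMatrix":
        """Build a GCN matrix, sanitizing raw values.

        Negative entries are replaced by their magnitude, asymmetry is
        resolved conservatively by the elementwise maximum of W and Wᵀ,
        and the diagonal is forced to zero.
        """
        values = np.abs(np.asarray(values, dtype=float))
        if values.shape[0] != values.shape[1]:
            raise ValidationError("gcn weight matrix must be square")
        values = np.maximum(values, values.T)
        np.fill_diagonal(values, 0.0)
        gene_ids = list(gene_ids)
        return cls(gene_ids, list(gene_ids), values, kind="gcn")

    @classmethod
    def grn(cls, tf_ids, gene_ids, values) -> "WeightMatrix":
        """Build a GRN (regulators × targets) matrix from raw values."""
        values = np.abs(np.asarray(values, dtype=float))
        return cls(list(tf_ids), list(gene_ids), values, kind="grn")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def __getitem__(self, pair: tuple[str, str]) -> float:
        s, t = pair
        return float(self.values[self.row_ids.index(s), self.col_ids.index(t)])


def canonical_pair(a: str, b: str, directed: bool) -> tuple[str, str]:
    """Canonical form of a gene pair: ordered as given if directed,
    lexicographically sorted otherwise."""
    if directed or a <= b:
        return (a, b)
    return (b, a)


@dataclass
class GroundTruth:
    """Partial groundtruth: labelled positive and negative gene pairs."""

    positives: frozenset
    negatives: frozenset
    directed: bool = False

    def __post_init__(self) -> None:
        self.positives = frozenset(
            canonical_pair(a, b, self.directed) for a, b in self.positives
        )
        self.negatives = frozenset(
            canonical_pair(a, b, self.directed) for a, b in self.negatives
        )
        for a, b in self.positives | self.negatives:
            if a == b:
                raise ValidationError(f"self-pair ({a}, {b}) in groundtruth")
        overlap = self.positives & self.negatives
        if overlap:
            raise ValidationError(
                f"{len(overlap)} pair(s) labelled both positive and negative, "
                f"e.g. {sorted(overlap)[0]}"
            )

    @property
    def n_pos(self) -> int:
        return len(self.positives)

    @property
    def n_neg(self) -> int:
        return len(self.negatives)

    def pairs(self) -> list[tuple[str, str]]:
        """All labelled pairs, positives first, deterministic order."""
        return sorted(self.positives) + sorted(self.negatives)

    def labels(self) -> np.ndarray:
        return np.concatenate(
            [np.ones(self.n_pos, dtype=bool), np.zeros(self.n_neg, dtype=bool)]
        )


@dataclass
class RunConfig:
    """Configuration for a full reconstruction run."""

    path_lengths: list[int] = field(default_factory=lambda: [2, 3, 4])
    ensemble_interval: float = 0.1
    include_direct_term: bool = True
    mi_significance: float = 1e-4
    seed: int = 0
    n_workers: int = 1
    tile_size: int = 64

    def __post_init__(self) -> None:
        self.path_lengths = sorted(int(x) for x in self.path_lengths)
        if any(l < 2 for l in self.path_lengths):
            raise ValidationError("path_lengths must all be >= 2")
        if not (0 < self.ensemble_interval <= 1):
            raise ValidationError("ensemble_interval must lie in (0, 1]")
        if abs(round(1 / self.ensemble_interval) - 1 / self.ensemble_interval) > 1e-9:
            raise ValidationError("1/ensemble_interval must be an integer")
        if self.tile_size < 1 or self.n_workers < 1:
            raise ValidationError("tile_size and n_workers must be positive")

    @property
    def ensemble_lengths(self) -> list[int]:
        lengths = list(self.path_lengths)
        if self.include_direct_term:
            lengths = [1] + lengths
        return lengths
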