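"""Readers and writers for expression matrices, weight/score matrices,
groundtruth pair lists and run configuration.

All on-disk formats are plain text: tab-separated, UTF-8, ``.`` decimal
separator.  Dense matrices carry a header row of column identifiers whose
first cell is empty, and one row label per line.  Edge lists are
three-column ``src<TAB>dst<TAB>weight`` files without a header.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    ExpressionMatrix,
    GroundTruth,
    RunConfig,
    SYMMETRY_TOL,
    ValidationError,
    WeightMatrix,
    canonical_pair,
)

__all__ = [
    "read_expression",
    "write_expression",
    "read_weight_matrix",
    "write_weight_matrix",
    "write_scores",
    "read_scores",
    "read_groundtruth",
    "write_groundtruth",
    "read_id_list",
    "read_config",
    "write_config",
]

logger = logging.getLogger(__name__)


def _read_dense(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype=str)
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna() & (df[col].str.lower() != "nan")
        if bad.any():
            row = df.index[bad.argmax()]
            raise ValidationError(
                f"{path}: non-numeric value {df.loc[row, col]!r} "
                f"at row {row!r}, column {col!r}"
            )
        numeric[col] = converted
    return numeric


def read_expression(path) -> ExpressionMatrix:
    """Read a genes × samples expression TSV (samples in the header row).

    Rows containing missing values are rejected; gene and sample
    identifiers must be unique.
    """
    df = _read_dense(path)
    if df.isna().any(axis=None):
        bad_rows = df.index[df.isna().any(axis=1)].tolist()
        raise ValidationError(f"{path}: missing values in gene row(s) {bad_rows}")
    return ExpressionMatrix(df.index.tolist(), df.columns.tolist(), df.to_numpy())


def write_expression(expr: ExpressionMatrix, path) -> None:
    df = pd.DataFrame(expr.values, index=expr.gene_ids, columns=expr.sample_ids)
    df.to_csv(path, sep="\t", float_format="%.17g")


def _looks_dense(path) -> bool:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n")
    fields = first.split("\t")
    if fields and fields[0] == "":
        return True  # dense header: empty first cell
    if len(fields) == 3:
        try:
            float(fields[2])
            return False
        except ValueError:
            return False  # 3-column header of an edge list
    return True


def read_weight_matrix(path, kind: str = "gcn") -> WeightMatrix:
    """Read an edge-weight matrix from a dense TSV or a 3-column edge list.

    Negative weights are converted to their magnitude.  In GCN mode the
    matrix is symmetrized by the elementwise maximum (with a warning when
    the asymmetry exceeds tolerance) and the diagonal is zeroed; pairs
    absent from an edge list default to weight 0.
    """
    if kind not in ("gcn", "grn"):
        raise ValidationError(f"kind must be 'gcn' or 'grn', got {kind!r}")
    if _looks_dense(path):
        df = _read_dense(path)
        if df.isna().any(axis=None):
            raise ValidationError(f"{path}: missing values in weight matrix")
        row_ids, col_ids = df.index.tolist(), df.columns.tolist()
        values = df.to_numpy()
    else:
        edges = pd.read_csv(
            path, sep="\t", header=None, names=["src", "dst", "w"],
            dtype={"src": str, "dst": str, "w": float},
        )
        if kind == "gcn":
            ids = sorted(set(edges["src"]) | set(edges["dst"]))
            row_ids = col_ids = ids
        else:
            row_ids = sorted(set(edges["src"]))
            col_ids = sorted(set(edges["dst"]))
        ridx = {g: i for i, g in enumerate(row_ids)}
        cidx = {g: i for i, g in enumerate(col_ids)}
        values = np.zeros((len(row_ids), len(col_ids)))
        for src, dst, w in edges.itertuples(index=False):
            w = abs(w)
            values[ridx[src], cidx[dst]] = max(values[ridx[src], cidx[dst]], w)
            if kind == "gcn":
                # an undirected edge listed once implies its mirror
                values[ridx[dst], cidx[src]] = max(values[ridx[dst], cidx[src]], w)
    if kind == "gcn":
        if values.shape[0] != values.shape[1] or row_ids != col_ids:
            raise ValidationError(
                f"{path}: gcn weight matrix must be square with matching labels, "
                f"got shape {values.shape}"
            )
        asym = np.abs(values - values.T).max(initial=0.0)
        if asym > SYMMETRY_TOL:
            warnings.warn(
                f"{path}: asymmetric gcn input (max |W - W^T| = {asym:.3g}); "
                "symmetrized by elementwise max",
                stacklevel=2,
            )
        return WeightMatrix.gcn(row_ids, values)
    return WeightMatrix.grn(row_ids, col_ids, values)


def write_weight_matrix(w: WeightMatrix, path) -> None:
    df = pd.DataFrame(w.values, index=w.row_ids, columns=w.col_ids)
    df.to_csv(path, sep="\t", float_format="%.17g")


def write_scores(matrix, path, format: str = "dense-tsv") -> None:
    """Write a score or capacity matrix.

    ``dense-tsv`` writes the full labelled matrix (infinities as ``inf``).
    ``edge-list`` writes one ``src dst score`` row per pair with a score
    that is positive (including +inf); for square symmetric matrices each
    unordered pair is emitted once.
    """
    values = np.asarray(matrix.values, dtype=float)
    row_ids, col_ids = list(matrix.row_ids), list(matrix.col_ids)
    if format == "dense-tsv":
        df = pd.DataFrame(values, index=row_ids, columns=col_ids)
        df.to_csv(path, sep="\t", float_format="%.17g")
        return
    if format != "edge-list":
        raise ValidationError(f"unknown score format {format!r}")
    symmetric = (
        row_ids == col_ids
        and np.array_equal(values, values.T)
    )
    with open(path, "w", encoding="utf-8") as fh:
        for i, s in enumerate(row_ids):
            for j, t in enumerate(col_ids):
                if symmetric and j <= i:
                    continue
                if s == t:
                    continue
                v = values[i, j]
                if v > 0:
                    tok = "inf" if np.isinf(v) else format_float(v)
                    fh.write(f"{s}\t{t}\t{tok}\n")


def format_float(v: float) -> str:
    return np.format_float_scientific(v, trim="-") if 0 < abs(v) < 1e-4 else repr(float(v))


def read_scores(path) -> pd.DataFrame:
    """Read back a dense score TSV as a labelled DataFrame."""
    return pd.read_csv(path, sep="\t", index_col=0, header=0)


def _read_pairs(path) -> list[tuple[str, str]]:
    pairs = []
    with open(path, "r", encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValidationError(f"{path}:{ln}: expected 2 columns, got {len(fields)}")
            pairs.append((fields[0], fields[1]))
    return pairs


def read_groundtruth(pos_path, neg_path, directed: bool = False) -> GroundTruth:
    """Read positive and negative gene-pair lists (2-column TSVs).

    Pairs are canonicalized (undirected mode sorts each pair); a pair
    appearing in both files, or a self-pair, is a validation error.
    """
    pos = {canonical_pair(a, b, directed) for a, b in _read_pairs(pos_path)}
    neg = {canonical_pair(a, b, directed) for a, b in _read_pairs(neg_path)}
    return GroundTruth(frozenset(pos), frozenset(neg), directed=directed)


def write_groundtruth(gt: GroundTruth, pos_path, neg_path) -> None:
    for pairs, path in ((gt.positives, pos_path), (gt.negatives, neg_path)):
        with open(path, "w", encoding="utf-8") as fh:
            for a, b in sorted(pairs):
                fh.write(f"{a}\t{b}\n")


def read_id_list(path) -> list[str]:
    """Read one identifier per line (e.g. a TF list)."""
    with open(path, "r", encoding="utf-8") as fh:
        ids = [line.strip() for line in fh if line.strip()]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate identifiers in list")
    return ids


def read_config(path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def write_config(config: RunConfig, path) -> None:
    data = {
        "path_lengths": list(config.path_lengths),
        "ensemble_interval": float(config.ensemble_interval),
        "include_direct_term": bool(config.include_direct_term),
        "mi_significance": float(config.mi_significance),
        "seed": int(config.seed),
        "n_workers": int(config.n_workers),
        "tile_size": int(config.tile_size),
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")
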