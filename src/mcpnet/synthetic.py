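"""Planted-network and expression simulators for end-to-end testing.

The generator plants a random undirected network whose weight matrix
mimics what an MI estimate of a real co-expression study looks like:

* true (direct) edges carry strong weights, Uniform(0.6, 1.0);
* "indirect decoy" pairs — non-edges joined by a two-edge chain of true
  edges — carry a weight equal to the chain's bottleneck scaled by
  Uniform(0.5, 0.95).  This models data-processing-inequality leakage:
  dependence transmitted through a chain is bounded by its weakest
  link, so a decoy's weight overlaps the true-edge range (fooling a
  raw-weight ranking) yet always stays below its own chain capacity
  (so its 2-path MCP score is below 1);
* all remaining non-edges carry |Normal(0, noise_sd)| background noise.

Groundtruth labels the true edges positive and the decoys plus an
equally sized sample of noise pairs negative.  A companion
linear-Gaussian simulator produces expression profiles whose
dependence structure follows the true edges only, so indirect
correlation arises mechanistically rather than by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import ExpressionMatrix, GroundTruth, ValidationError, WeightMatrix

__all__ = ["PlantedNetwork", "make_planted_weights", "simulate_expression"]

TRUE_WEIGHT_LOW, TRUE_WEIGHT_HIGH = 0.6, 1.0
DECOY_LEAK_LOW, DECOY_LEAK_HIGH = 0.7, 0.95


@dataclass
class PlantedNetwork:
    """A planted weight matrix with known direct/indirect structure."""

    gene_ids: list[str]
    true_edges: list  # insertion-ordered (a, b) pairs
    weight_matrix: WeightMatrix
    groundtruth: GroundTruth
    decoys: list = field(default_factory=list)
    tf_ids: list | None = None


def make_planted_weights(
    n_genes: int = 40,
    n_true: int = 60,
    chain_frac: float = 0.5,
    noise_sd: float = 0.05,
    seed: int = 0,
    n_tfs: int | None = None,
) -> PlantedNetwork:
    """Plant a random network with direct edges and indirect decoys.

    ``chain_frac`` of the chain-connected non-edges become decoys.  The
    decoy negative set is matched in size by a random sample of pure
    noise pairs.  Deterministic per seed.
    """
    if n_genes < 3:
        raise ValidationError("need at least 3 genes")
    if not (0 <= chain_frac <= 1):
        raise ValidationError("chain_frac must lie in [0, 1]")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    width = len(str(n_genes))
    gene_ids = [f"g{i:0{width}d}" for i in range(1, n_genes + 1)]
    all_pairs = [
        (gene_ids[i], gene_ids[j])
        for i in range(n_genes)
        for j in range(i + 1, n_genes)
    ]
    if n_true > len(all_pairs):
        raise ValidationError(
            f"n_true={n_true} exceeds the {len(all_pairs)} available pairs"
        )
    rng = np.random.default_rng(seed)
    idx = {g: i for i, g in enumerate(gene_ids)}
    chosen = rng.choice(len(all_pairs), size=n_true, replace=False)
    true_edges = [all_pairs[k] for k in chosen]
    values = np.zeros((n_genes, n_genes))
    for a, b in true_edges:
        w = rng.uniform(TRUE_WEIGHT_LOW, TRUE_WEIGHT_HIGH)
        values[idx[a], idx[b]] = values[idx[b], idx[a]] = w

    true_set = set(true_edges)
    adj = values.copy()  # currently true edges only
    # chain-connected non-edges and their best two-edge bottleneck
    candidates = []
    for a, b in all_pairs:
        if (a, b) in true_set:
            continue
        bottleneck = np.minimum(adj[idx[a]], adj[idx[b]]).max()
        if bottleneck > 0:
            candidates.append(((a, b), float(bottleneck)))
    n_decoys = int(round(chain_frac * len(candidates)))
    decoy_pick = rng.choice(len(candidates), size=n_decoys, replace=False) if n_decoys else []
    decoys = []
    for k in sorted(decoy_pick):
        (a, b), bottleneck = candidates[k]
        # DPI-style leakage: strictly below the chain capacity
        w = bottleneck * rng.uniform(DECOY_LEAK_LOW, DECOY_LEAK_HIGH)
        values[idx[a], idx[b]] = values[idx[b], idx[a]] = w
        decoys.append((a, b))

    decoy_set = set(decoys)
    noise_pairs = [
        p for p in all_pairs if p not in true_set and p not in decoy_set
    ]
    for a, b in noise_pairs:
        if noise_sd > 0:
            w = abs(rng.normal(0.0, noise_sd))
            values[idx[a], idx[b]] = values[idx[b], idx[a]] = w
    n_noise_neg = min(len(decoys), len(noise_pairs)) if decoys else min(
        len(true_edges), len(noise_pairs)
    )
    noise_neg_pick = (
        rng.choice(len(noise_pairs), size=n_noise_neg, replace=False)
        if n_noise_neg
        else []
    )
    negatives = decoy_set | {noise_pairs[k] for k in sorted(noise_neg_pick)}
    gt = GroundTruth(frozenset(true_set), frozenset(negatives), directed=False)
    tf_ids = None
    if n_tfs is not None:
        if not (0 < n_tfs <= n_genes):
            raise ValidationError("n_tfs out of range")
        tf_ids = sorted(
            gene_ids[k] for k in rng.choice(n_genes, size=n_tfs, replace=False)
        )
    return PlantedNetwork(
        gene_ids=gene_ids,
        true_edges=true_edges,
        weight_matrix=WeightMatrix.gcn(gene_ids, values),
        groundtruth=gt,
        decoys=decoys,
        tf_ids=tf_ids,
    )


def simulate_expression(
    net: PlantedNetwork,
    n_samples: int = 200,
    noise_sd: float = 0.25,
    seed: int = 0,
) -> ExpressionMatrix:
    """Linear-Gaussian expression profiles over the planted true edges.

    Each true edge is oriented by insertion order (the endpoint seen
    first becomes the parent, which also breaks cycles); root genes are
    N(0, 1) and every other gene is the weighted sum of its parents
    plus N(0, noise_sd).  Only true edges propagate signal — decoy
    pairs become dependent solely through shared chain neighbours.
    """
    if n_samples < 10:
        raise ValidationError("n_samples must be >= 10")
    rng = np.random.default_rng(seed)
    idx = {g: i for i, g in enumerate(net.gene_ids)}
    wvals = net.weight_matrix.values
    order: list[str] = []
    seen = set()
    parents: dict[str, list[str]] = {g: [] for g in net.gene_ids}
    for a, b in net.true_edges:
        for g in (a, b):
            if g not in seen:
                seen.add(g)
                order.append(g)
        # orient from the earlier-seen endpoint; cycles cannot arise
        if order.index(a) < order.index(b):
            parents[b].append(a)
        else:
            parents[a].append(b)
    for g in net.gene_ids:  # isolated genes
        if g not in seen:
            order.append(g)
    n = len(net.gene_ids)
    values = np.zeros((n, n_samples))
    for g in order:
        gi = idx[g]
        if parents[g]:
            acc = np.zeros(n_samples)
            for p in parents[g]:
                acc += wvals[gi, idx[p]] * values[idx[p]]
            if noise_sd > 0:
                acc = acc + rng.normal(0.0, noise_sd, size=n_samples)
            values[gi] = acc
        else:
            values[gi] = rng.normal(0.0, 1.0, size=n_samples)
    return ExpressionMatrix(net.gene_ids, [f"s{k+1}" for k in range(n_samples)], values)
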