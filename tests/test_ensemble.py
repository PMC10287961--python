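import math

import numpy as np
import pytest

from mcpnet import (
    EnsembleCoefficients,
    GroundTruth,
    ValidationError,
    WeightMatrix,
    auprc,
    coefficient_grid,
    complete_pair_count,
    ensemble_score,
    eta,
    mcp_score,
    optimize_ensemble,
    partial_groundtruth_census,
    robustness_experiment,
    split_groundtruth,
    stouffer_transform,
)
from mcpnet.mcp import ScoreMatrix

from conftest import random_gcn


def score_matrix_from_pairs(pair_scores):
    """Build a symmetric ScoreMatrix over the genes mentioned in pair_scores."""
    ids = sorted({g for pair in pair_scores for g in pair})
    idx = {g: i for i, g in enumerate(ids)}
    vals = np.zeros((len(ids), len(ids)))
    for (a, b), s in pair_scores.items():
        vals[idx[a], idx[b]] = vals[idx[b], idx[a]] = s
    return ScoreMatrix(ids, ids, vals)


def brute_force_average_precision(scores, labels):
    """Independent AP oracle: explicit sort + cumulative counts with tie groups."""
    items = sorted(zip(scores, labels), key=lambda p: -p[0])
    n_pos = sum(1 for _, y in items if y)
    ap = 0.0
    i = 0
    tp = fp = 0
    while i < len(items):
        j = i
        group_tp = 0
        while j < len(items) and items[j][0] == items[i][0]:
            if items[j][1]:
                group_tp += 1
            j += 1
        tp += group_tp
        fp += (j - i) - group_tp
        if group_tp:
            ap += group_tp * tp / (tp + fp)
        i = j
    return ap / n_pos


class TestEnsembleScore:
    def test_one_hot_on_length_two_reduces_to_r2(self, w3):
        etas = {2: eta(w3, 2)}
        coeffs = EnsembleCoefficients(lengths=(1, 2), weights=(0.0, 1.0))
        m = ensemble_score(w3, etas, coeffs)
        np.testing.assert_array_equal(m.values, mcp_score(w3, etas[2]).values)

    def test_toy_mixed_weights(self, w3):
        etas = {2: eta(w3, 2), 3: eta(w3, 3), 4: eta(w3, 4)}
        coeffs = EnsembleCoefficients(lengths=(1, 2, 3, 4), weights=(0, 0.5, 0.5, 0))
        m = ensemble_score(w3, etas, coeffs)
        # denominator 0.5*eta2 + 0.5*eta3 = 0.5*0.8 + 0.5*0.1 = 0.45
        assert m["g1", "g3"] == pytest.approx(0.1 / 0.45)

    def test_one_hot_on_direct_term_scores_one_where_positive(self, w3):
        coeffs = EnsembleCoefficients(lengths=(1, 2), weights=(1.0, 0.0))
        m = ensemble_score(w3, {2: eta(w3, 2)}, coeffs)
        positive = w3.values > 0
        assert np.all(m.values[positive] == 1.0)

    def test_missing_length_rejected(self, w3):
        coeffs = EnsembleCoefficients(lengths=(1, 2, 3), weights=(0.5, 0.25, 0.25))
        with pytest.raises(ValidationError, match="length 3"):
            ensemble_score(w3, {2: eta(w3, 2)}, coeffs)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            EnsembleCoefficients(lengths=(1, 2), weights=(0.5, 0.6))


class TestCoefficientGrid:
    def test_small_grid_enumerated(self):
        assert coefficient_grid(2, 0.5) == [(0.0, 1.0), (0.5, 0.5), (1.0, 0.0)]

    @pytest.mark.parametrize(
        "n_terms,expected", [(3, 66), (4, 286)]
    )  # stars and bars: C(k+n-1, n-1), k=10
    def test_grid_sizes_match_stars_and_bars(self, n_terms, expected):
        grid = coefficient_grid(n_terms, 0.1)
        assert len(grid) == expected
        assert len(set(grid)) == expected
        for weights in grid:
            assert abs(sum(weights) - 1.0) < 1e-9
        for i in range(n_terms):  # all one-hots present
            onehot = tuple(1.0 if j == i else 0.0 for j in range(n_terms))
            assert onehot in grid

    def test_non_integral_interval_rejected(self):
        with pytest.raises(ValidationError):
            coefficient_grid(3, 0.3)


class TestAuprc:
    def test_hand_enumerated_ranking(self):
        m = score_matrix_from_pairs(
            {("a", "b"): 0.9, ("c", "d"): 0.1, ("e", "f"): 0.5}
        )
        gt = GroundTruth(
            frozenset({("a", "b"), ("c", "d")}), frozenset({("e", "f")})
        )
        assert auprc(m, gt).auprc == pytest.approx((1 + 2 / 3) / 2)

    def test_perfect_ranking_scores_one(self):
        m = score_matrix_from_pairs(
            {("a", "b"): 3.0, ("c", "d"): 2.0, ("e", "f"): 1.0, ("g", "h"): 0.5}
        )
        gt = GroundTruth(
            frozenset({("a", "b"), ("c", "d")}),
            frozenset({("e", "f"), ("g", "h")}),
        )
        assert auprc(m, gt).auprc == 1.0

    def test_constant_scores_give_prevalence(self):
        m = score_matrix_from_pairs(
            {("a", "b"): 2.0, ("c", "d"): 2.0, ("e", "f"): 2.0, ("g", "h"): 2.0}
        )
        gt = GroundTruth(
            frozenset({("a", "b")}),
            frozenset({("c", "d"), ("e", "f"), ("g", "h")}),
        )
        assert auprc(m, gt).auprc == pytest.approx(1 / 4)

    def test_matches_brute_force_oracle_with_ties_and_infinities(self):
        rng = np.random.default_rng(0)
        for trial in range(50):
            n = int(rng.integers(4, 40))
            scores = rng.choice([0.0, 0.25, 0.5, 1.0, 2.0, np.inf], size=n)
            labels = rng.integers(0, 2, size=n).astype(bool)
            if not labels.any() or labels.all():
                continue
            pair_scores = {(f"a{i}", f"b{i}"): scores[i] for i in range(n)}
            m = score_matrix_from_pairs(pair_scores)
            pos = frozenset((f"a{i}", f"b{i}") for i in range(n) if labels[i])
            neg = frozenset((f"a{i}", f"b{i}") for i in range(n) if not labels[i])
            gt = GroundTruth(pos, neg)
            expected = brute_force_average_precision(
                [pair_scores[p] for p in gt.pairs()], gt.labels()
            )
            assert auprc(m, gt).auprc == pytest.approx(expected, abs=1e-12)

    def test_curve_reproduces_area(self):
        m = score_matrix_from_pairs(
            {("a", "b"): 0.9, ("c", "d"): 0.1, ("e", "f"): 0.5, ("g", "h"): 0.5}
        )
        gt = GroundTruth(
            frozenset({("a", "b"), ("c", "d")}),
            frozenset({("e", "f"), ("g", "h")}),
        )
        pr = auprc(m, gt)
        recalls = [0.0] + [r for r, _ in pr.curve]
        area = sum(
            (r1 - r0) * p
            for (r0, (r1, p)) in zip(recalls[:-1], pr.curve)
        )
        assert pr.auprc == pytest.approx(area, abs=1e-12)

    def test_missing_pair_rejected(self):
        m = score_matrix_from_pairs({("a", "b"): 1.0, ("c", "d"): 0.5})
        gt = GroundTruth(frozenset({("a", "b")}), frozenset({("x", "y")}))
        with pytest.raises(ValidationError, match="not addressable"):
            auprc(m, gt)


class TestOptimizeEnsemble:
    def test_dominates_single_length_networks(self, planted):
        W = planted.weight_matrix
        gt = planted.groundtruth
        etas = {L: eta(W, L) for L in (2, 3, 4)}
        coeffs, pr = optimize_ensemble(W, etas, gt, interval=0.1, lengths=(1, 2, 3, 4))
        singles = [auprc(W, gt).auprc]
        singles += [auprc(mcp_score(W, etas[L]), gt).auprc for L in (2, 3, 4)]
        assert pr.auprc >= max(singles)
        assert abs(sum(coeffs.weights) - 1.0) < 1e-9

    def test_argmax_matches_independent_full_reevaluation(self, planted):
        W = planted.weight_matrix
        gt = planted.groundtruth
        etas = {L: eta(W, L) for L in (2, 3)}
        lengths = (1, 2, 3)
        coeffs, pr = optimize_ensemble(W, etas, gt, interval=0.5, lengths=lengths)
        best = (-1.0, None)
        for weights in coefficient_grid(3, 0.5):
            c = EnsembleCoefficients(lengths=lengths, weights=weights)
            ap = auprc(ensemble_score(W, etas, c), gt).auprc
            if ap > best[0]:
                best = (ap, weights)
        assert pr.auprc == pytest.approx(best[0], abs=1e-12)
        assert coeffs.weights == best[1]

    def test_empty_groundtruth_rejected(self, w3):
        gt = GroundTruth(frozenset(), frozenset({("g1", "g2")}))
        with pytest.raises(ValidationError):
            optimize_ensemble(w3, {2: eta(w3, 2)}, gt)


class TestStoufferTransform:
    def test_constant_matrix_maps_to_zero(self):
        ids = ["a", "b", "c"]
        m = ScoreMatrix(ids, ids, np.full((3, 3), 2.0) - 2 * np.eye(3))
        out = stouffer_transform(m)
        np.testing.assert_array_equal(out.values, np.zeros((3, 3)))

    def test_symmetric_input_gives_symmetric_output(self):
        w = random_gcn(6, seed=8)
        m = mcp_score(w, eta(w, 2))
        out = stouffer_transform(m).values
        np.testing.assert_allclose(out, out.T, atol=1e-12)

    def test_matches_direct_mean_sd_oracle(self):
        ids = ["a", "b", "c"]
        vals = np.array([[0.0, 1.0, 4.0], [1.0, 0.0, 2.0], [4.0, 2.0, 0.0]])
        out = stouffer_transform(ScoreMatrix(ids, ids, vals)).values
        for i in range(3):
            for j in range(3):
                if i == j:
                    assert out[i, j] == 0.0
                    continue
                row = np.delete(vals[i], i)
                col = np.delete(vals[:, j], j)
                zr = max((vals[i, j] - row.mean()) / row.std(), 0.0)
                zc = max((vals[i, j] - col.mean()) / col.std(), 0.0)
                assert out[i, j] == pytest.approx((zr + zc) / math.sqrt(2), abs=1e-12)

    def test_invariant_under_affine_rescaling(self):
        w = random_gcn(5, seed=12)
        m = mcp_score(w, eta(w, 2))
        finite = m.values.copy()
        finite[~np.isfinite(finite)] = finite[np.isfinite(finite)].max()
        base = stouffer_transform(ScoreMatrix(m.row_ids, m.col_ids, finite)).values
        rescaled = stouffer_transform(
            ScoreMatrix(m.row_ids, m.col_ids, 3.0 * finite + 1.0)
        ).values
        np.testing.assert_allclose(base, rescaled, atol=1e-10)

    def test_infinities_clipped_to_finite_max(self):
        ids = ["a", "b", "c"]
        vals = np.array([[0.0, np.inf, 1.0], [np.inf, 0.0, 2.0], [1.0, 2.0, 0.0]])
        out = stouffer_transform(ScoreMatrix(ids, ids, vals))
        assert np.all(np.isfinite(out.values))


class TestSplitGroundtruth:
    @staticmethod
    def _gt(n_pos, n_neg):
        pos = frozenset((f"p{i}", f"q{i}") for i in range(n_pos))
        neg = frozenset((f"r{i}", f"s{i}") for i in range(n_neg))
        return GroundTruth(pos, neg)

    def test_counts_at_ten_percent(self):
        train, test = split_groundtruth(self._gt(100, 100), 0.1, seed=0)
        assert (train.n_pos, train.n_neg) == (10, 10)
        assert (test.n_pos, test.n_neg) == (90, 90)

    def test_same_seed_reproduces_split(self):
        gt = self._gt(30, 50)
        a = split_groundtruth(gt, 0.3, seed=5)
        b = split_groundtruth(gt, 0.3, seed=5)
        assert a[0].positives == b[0].positives
        assert a[1].negatives == b[1].negatives

    def test_exact_partition_over_many_seeds(self):
        gt = self._gt(17, 23)
        for seed in range(50):
            train, test = split_groundtruth(gt, 0.4, seed=seed)
            assert train.positives | test.positives == gt.positives
            assert train.negatives | test.negatives == gt.negatives
            assert not (train.positives & test.positives)
            assert not (train.negatives & test.negatives)

    def test_tiny_stratum_rejected(self):
        with pytest.raises(ValidationError):
            split_groundtruth(self._gt(1, 10), 0.5, seed=0)


class TestRobustness:
    def test_table_shape_and_reproducibility(self, planted):
        W = planted.weight_matrix
        gt = planted.groundtruth
        etas = {L: eta(W, L) for L in (2, 3)}
        kwargs = dict(
            fracs=[0.5], n_reps=4, interval=0.5, lengths=(1, 2, 3), seed=3
        )
        t1 = robustness_experiment(W, etas, gt, **kwargs)
        t2 = robustness_experiment(W, etas, gt, **kwargs)
        assert len(t1) == 4
        assert t1.equals(t2)

    def test_mean_full_auprc_bounded_by_full_optimum(self, planted):
        W = planted.weight_matrix
        gt = planted.groundtruth
        etas = {L: eta(W, L) for L in (2, 3)}
        table = robustness_experiment(
            W, etas, gt, fracs=[0.5], n_reps=5, interval=0.5, lengths=(1, 2, 3), seed=1
        )
        _, full_pr = optimize_ensemble(W, etas, gt, interval=0.5, lengths=(1, 2, 3))
        assert table["auprc_full"].mean() <= full_pr.auprc + 1e-12


class TestCensus:
    def test_pair_counts(self):
        assert complete_pair_count(2000) == 1_999_000
        assert complete_pair_count(3, directed=True) == 6

    def test_regulator_target_census(self):
        census = partial_groundtruth_census(1360, n_regulators=97, n_targets=956)
        assert census["total_pairs"] == 92_732
        assert census["n_negatives"] == 91_372
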