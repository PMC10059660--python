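"""Classification metrics, AUC, top-k accuracy, dataset diagnostics."""

import math
from fractions import Fraction

import numpy as np
import pytest

import aoxsom as ax
from aoxsom.errors import NumericError, ReferenceMismatchError, UndefinedMetricError
from aoxsom.metrics import (
    ConfusionCounts,
    auc_score,
    chemical_space_pca,
    classification_metrics,
    confusion_from_predictions,
    coverage_ceiling,
    tanimoto_statistics,
    topk_accuracy,
)
from aoxsom.model import RankedPrediction


def make_prediction(std, ordered_indices):
    """A ranking with strictly decreasing synthetic scores."""
    n = len(ordered_indices)
    sites = [(idx, (n - i) / (n + 1)) for i, idx in enumerate(ordered_indices)]
    return RankedPrediction(std, sites, is_predicted_substrate=bool(sites))


class TestConfusion:
    def test_simple_split(self):
        c = confusion_from_predictions([0.9, 0.1], [1, 0], 0.5)
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 1, 0, 0)

    def test_all_below_threshold_all_positive(self):
        c = confusion_from_predictions([0.2] * 7, [1] * 7, 0.5)
        assert c.fn == 7 and c.tp == c.fp == c.tn == 0

    def test_matches_per_site_loop(self, rng):
        scores = rng.random(1000)
        labels = (rng.random(1000) < 0.3).astype(int)
        c = confusion_from_predictions(scores, labels, 0.5)
        tp = sum(1 for s, l in zip(scores, labels) if s >= 0.5 and l == 1)
        fp = sum(1 for s, l in zip(scores, labels) if s >= 0.5 and l == 0)
        tn = sum(1 for s, l in zip(scores, labels) if s < 0.5 and l == 0)
        fn = sum(1 for s, l in zip(scores, labels) if s < 0.5 and l == 1)
        assert (c.tp, c.fp, c.tn, c.fn) == (tp, fp, tn, fn)
        assert c.total == 1000

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_from_predictions([0.5], [1, 0], 0.5)


class TestClassificationMetrics:
    def test_hand_worked_counts(self):
        m = classification_metrics(ConfusionCounts(tp=3, fp=1, tn=5, fn=1))
        assert m.se == pytest.approx(0.75)
        assert m.sp == pytest.approx(5 / 6)
        assert m.acc == pytest.approx(0.8)
        assert m.f1 == pytest.approx(0.75)
        assert m.mcc == pytest.approx(14 / math.sqrt(4 * 4 * 6 * 6))

    def test_perfect_counts(self):
        m = classification_metrics(ConfusionCounts(10, 0, 10, 0))
        assert (m.se, m.sp, m.acc, m.f1, m.mcc) == (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_balanced_noise(self):
        m = classification_metrics(ConfusionCounts(5, 5, 5, 5))
        assert m.mcc == pytest.approx(0.0)
        assert m.acc == pytest.approx(0.5)

    def test_zero_denominators_are_flagged_not_zero(self):
        m = classification_metrics(ConfusionCounts(0, 0, 4, 0))
        assert m.se is None and "SE" in m.undefined
        assert m.mcc is None and "MCC" in m.undefined
        assert m.sp == 1.0

    def test_exact_rational_agreement_on_random_tables(self, rng):
        """Float implementation vs exact Fraction arithmetic."""
        for _ in range(500):
            tp, fp, tn, fn = (int(x) for x in rng.integers(0, 15, size=4))
            if tp + fp + tn + fn == 0:
                continue
            m = classification_metrics(ConfusionCounts(tp, fp, tn, fn))
            if tp + fn:
                assert m.se == pytest.approx(float(Fraction(tp, tp + fn)), abs=1e-12)
            if tn + fp:
                assert m.sp == pytest.approx(float(Fraction(tn, tn + fp)), abs=1e-12)
            assert m.acc == pytest.approx(float(Fraction(tp + tn, tp + fp + tn + fn)), abs=1e-12)


class TestAuc:
    def test_scores_equal_labels(self):
        assert auc_score([0, 1, 0, 1], [0, 1, 0, 1]) == 1.0

    def test_anticorrelated(self):
        assert auc_score([1, 0, 1, 0], [0, 1, 0, 1]) == 0.0

    def test_null_scores_near_half(self):
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            scores = rng.random(2000)
            labels = (rng.random(2000) < 0.5).astype(int)
            aucs.append(auc_score(scores, labels))
        assert abs(np.mean(aucs) - 0.5) < 0.03

    def test_equals_pairwise_comparison_with_midranks(self, rng):
        """Brute-force Mann-Whitney with 0.5 credit for ties."""
        for _ in range(10):
            n = int(rng.integers(20, 200))
            scores = rng.integers(0, 10, size=n) / 10.0  # force ties
            labels = (rng.random(n) < 0.4).astype(int)
            if labels.min() == labels.max():
                continue
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            brute = wins / (len(pos) * len(neg))
            assert auc_score(scores, labels) == pytest.approx(brute, abs=1e-12)

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            auc_score([0.1, 0.9], [1, 1])


class TestTopK:
    def test_true_som_ranked_second(self, pyridine):
        sites = [s.atom_index for s in ax.enumerate_candidate_sites(pyridine)]
        pred = make_prediction(pyridine, sites)
        truth = [ax.SomLabelSet(pyridine, frozenset({sites[1]}))]
        assert topk_accuracy([pred], truth, 1) == 0.0
        assert topk_accuracy([pred], truth, 2) == 1.0

    def test_three_molecules_ranks_1_2_4(self, synthetic_batch):
        mols = [std for std, _ in synthetic_batch[:3]]
        preds, truths = [], []
        for rank, std in zip((1, 2, 4), mols):
            ordered = list(range(5))  # every azaheteroaromatic here has >= 5 atoms
            preds.append(make_prediction(std, ordered))
            truths.append(ax.SomLabelSet(std, frozenset({ordered[rank - 1]})))
        assert topk_accuracy(preds, truths, 1) == pytest.approx(1 / 3)
        assert topk_accuracy(preds, truths, 2) == pytest.approx(2 / 3)
        assert topk_accuracy(preds, truths, 3) == pytest.approx(2 / 3)

    def test_all_first_every_k_perfect(self, synthetic_batch):
        preds, truths = [], []
        for std, _ in synthetic_batch[:5]:
            sites = [s.atom_index for s in ax.enumerate_candidate_sites(std)]
            preds.append(make_prediction(std, sites))
            truths.append(ax.SomLabelSet(std, frozenset({sites[0]})))
        for k in (1, 2, 3):
            assert topk_accuracy(preds, truths, k) == 1.0

    def test_empty_ranking_counts_as_failure(self, benzene):
        pred = RankedPrediction(benzene, [], is_predicted_substrate=False)
        truth = [ax.SomLabelSet(benzene, frozenset({0}))]
        assert topk_accuracy([pred], truth, 3) == 0.0
        assert coverage_ceiling([pred], truth) == 0.0

    def test_alignment_mismatch(self, pyridine, benzene):
        pred = make_prediction(pyridine, [0])
        with pytest.raises(ReferenceMismatchError):
            topk_accuracy([pred], [ax.SomLabelSet(benzene, frozenset())], 1)

    def test_large_k_hits_coverage_ceiling(self, synthetic_batch):
        preds, truths = [], []
        for std, labels in synthetic_batch:
            sites = [s.atom_index for s in ax.enumerate_candidate_sites(std)]
            preds.append(make_prediction(std, sites))
            truths.append(labels)
        big_k = max(len(p.ranked_sites) for p in preds) + 1
        assert topk_accuracy(preds, truths, big_k) == coverage_ceiling(preds, truths)


class TestTanimoto:
    def test_identical_molecules_similarity_one(self):
        mols = [ax.standardize_molecule("c1ccncc1") for _ in range(3)]
        mat, mean, _ = tanimoto_statistics(mols)
        assert mean == pytest.approx(1.0)
        assert np.allclose(mat, 1.0)

    def test_matrix_symmetric_unit_diagonal(self, fixture_molecules):
        mat, mean, (hist, edges) = tanimoto_statistics(fixture_molecules)
        assert np.allclose(mat, mat.T)
        assert np.allclose(np.diag(mat), 1.0)
        assert 0.0 <= mean <= 1.0
        n = len(fixture_molecules)
        assert hist.sum() == n * (n - 1) // 2
        assert len(edges) == 21  # 0.05-wide bins over [0, 1]

    def test_requires_two_molecules(self, pyridine):
        with pytest.raises(NumericError):
            tanimoto_statistics([pyridine])


class TestChemicalSpacePca:
    def test_identical_sets_coincide(self, fixture_molecules):
        df, ratios = chemical_space_pca(
            {"a": fixture_molecules, "b": fixture_molecules}
        )
        a = df[df["set"] == "a"][["pc1", "pc2"]].to_numpy()
        b = df[df["set"] == "b"][["pc1", "pc2"]].to_numpy()
        assert np.allclose(a, b)
        assert ratios[0] >= ratios[1]

    def test_duplicated_molecule_coincident_points(self, fixture_molecules, pyridine):
        df, _ = chemical_space_pca({"x": list(fixture_molecules) + [pyridine, pyridine]})
        pts = df.tail(2)[["pc1", "pc2"]].to_numpy()
        assert np.allclose(pts[0], pts[1])

    def test_too_few_molecules(self, pyridine):
        with pytest.raises(NumericError):
            chemical_space_pca({"x": [pyridine]})
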