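"""Precision-recall curves, AUPRC, precision-at-recall, fold over random."""

import numpy as np
import pytest

from phenonet.evaluation import (
    auprc,
    fold_over_random,
    precision_at_recall,
    precision_recall_curve,
    summarize,
)
from phenonet.ontology import GoldStandard
from phenonet.predict import ScoreVector


def _fixture(scores_by_gene, positives):
    genes = list(scores_by_gene)
    sv = ScoreVector(scores=dict(scores_by_gene), provenance="summed_weight")
    gold = GoldStandard(term="t", positives=frozenset(positives),
                        negatives=frozenset(genes) - frozenset(positives))
    return sv, gold


def brute_force_curve(scores, labels):
    """Independent oracle: one confusion matrix per distinct threshold."""
    n_p = sum(labels)
    points = []
    for thr in sorted(set(scores), reverse=True):
        called = [s >= thr for s in scores]
        tp = sum(1 for c, y in zip(called, labels) if c and y)
        fp = sum(1 for c, y in zip(called, labels) if c and not y)
        points.append((thr, tp, fp, n_p - tp, tp / n_p, tp / (tp + fp)))
    return points


class TestCurve:
    def test_alternating_ranking(self):
        sv, gold = _fixture({"a": 4.0, "b": 3.0, "c": 2.0, "d": 1.0}, {"a", "c"})
        curve = precision_recall_curve(sv, gold)
        pts = set(zip(curve.recall.tolist(), curve.precision.tolist()))
        assert (0.5, 1.0) in pts
        assert (1.0, 2 / 3) in pts

    def test_perfect_ranking_all_precision_one(self):
        sv, gold = _fixture({"a": 5.0, "b": 4.0, "c": 1.0, "d": 0.5}, {"a", "b"})
        curve = precision_recall_curve(sv, gold)
        # precision 1 at every recall level (achieved-point convention)
        for r in (0.01, 0.25, 0.5, 0.75, 1.0):
            assert precision_at_recall(curve, r) == 1.0
        assert auprc(curve) == 1.0

    def test_tied_scores_form_single_group(self):
        sv, gold = _fixture({"a": 1.0, "b": 1.0, "c": 1.0, "d": 1.0}, {"a", "b"})
        curve = precision_recall_curve(sv, gold)
        assert len(curve) == 1
        assert curve.precision[0] == gold.prevalence
        assert auprc(curve) == pytest.approx(gold.prevalence)

    def test_unscored_gene_is_error(self):
        sv = ScoreVector(scores={"a": 1.0}, provenance="summed_weight")
        gold = GoldStandard(term="t", positives=frozenset({"a"}),
                            negatives=frozenset({"b"}))
        with pytest.raises(ValueError, match="unscored"):
            precision_recall_curve(sv, gold)

    def test_invariants_and_oracle_on_random_instances(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 200))
            genes = [f"g{i}" for i in range(n)]
            # coarse grid makes ties likely
            scores = {g: float(rng.integers(0, 8)) for g in genes}
            pos = set(rng.choice(genes, size=int(rng.integers(1, n)), replace=False))
            sv, gold = _fixture(scores, pos)
            curve = precision_recall_curve(sv, gold)
            expected = brute_force_curve(
                [scores[g] for g in genes], [g in pos for g in genes]
            )
            assert len(curve) == len(expected)
            for i, (thr, tp, fp, fn, rec, prec) in enumerate(expected):
                assert curve.threshold[i] == thr
                assert curve.tp[i] == tp and curve.fp[i] == fp and curve.fn[i] == fn
                assert curve.recall[i] == pytest.approx(rec, abs=1e-15)
                assert curve.precision[i] == pytest.approx(prec, abs=1e-15)
            assert np.all(curve.tp + curve.fn == gold.n_p)
            assert curve.recall[-1] == 1.0


class TestAuprc:
    def test_matches_step_sum_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 200))
            genes = [f"g{i}" for i in range(n)]
            scores = {g: float(rng.integers(0, 10)) for g in genes}
            pos = set(rng.choice(genes, size=int(rng.integers(1, n)), replace=False))
            sv, gold = _fixture(scores, pos)
            curve = precision_recall_curve(sv, gold)
            expected = 0.0
            prev_r = 0.0
            for _, _, _, _, rec, prec in brute_force_curve(
                [scores[g] for g in genes], [g in pos for g in genes]
            ):
                expected += (rec - prev_r) * prec
                prev_r = rec
            assert auprc(curve) == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_sklearn_average_precision(self, rng):
        from sklearn.metrics import average_precision_score

        for _ in range(5):
            n = 120
            y = rng.random(n) < 0.2
            if not y.any():
                y[0] = True
            s = rng.normal(size=n) + y.astype(float)
            sv, gold = _fixture(
                {f"g{i}": float(s[i]) for i in range(n)},
                {f"g{i}" for i in range(n) if y[i]},
            )
            ours = auprc(precision_recall_curve(sv, gold))
            assert ours == pytest.approx(average_precision_score(y, s), abs=1e-10)

    def test_swapping_adjacent_pn_to_np_never_increases(self, rng):
        n = 40
        labels = [True] * 8 + [False] * 32
        rng.shuffle(labels)
        scores = list(np.linspace(10, 1, n))
        def area(lbls):
            sv, gold = _fixture(
                {f"g{i}": scores[i] for i in range(n)},
                {f"g{i}" for i in range(n) if lbls[i]},
            )
            return auprc(precision_recall_curve(sv, gold))
        for i in range(n - 1):
            if labels[i] and not labels[i + 1]:
                worse = labels.copy()
                worse[i], worse[i + 1] = worse[i + 1], worse[i]
                assert area(worse) <= area(labels) + 1e-12

    def test_random_scores_approach_prevalence(self, rng):
        n, prev = 2000, 0.05
        areas = []
        for _ in range(10):
            y = np.zeros(n, dtype=bool)
            y[: int(n * prev)] = True
            s = rng.normal(size=n)
            sv, gold = _fixture(
                {f"g{i}": float(s[i]) for i in range(n)},
                {f"g{i}" for i in range(n) if y[i]},
            )
            areas.append(auprc(precision_recall_curve(sv, gold)))
        se = np.std(areas, ddof=1) / np.sqrt(len(areas))
        assert abs(np.mean(areas) - prev) < 3 * se + 1e-9


class TestPrecisionAtRecall:
    def test_alternating_ranking_at_half(self):
        sv, gold = _fixture({"a": 4.0, "b": 3.0, "c": 2.0, "d": 1.0}, {"a", "c"})
        curve = precision_recall_curve(sv, gold)
        assert precision_at_recall(curve, 0.5) == 1.0
        assert precision_at_recall(curve, 1.0) == 2 / 3

    def test_between_achieved_recalls_takes_next_point(self):
        # 6 genes, 3 positives: achieved recalls 1/3, 2/3, 1
        sv, gold = _fixture(
            {"a": 6.0, "b": 5.0, "c": 4.0, "d": 3.0, "e": 2.0, "f": 1.0},
            {"a", "c", "f"},
        )
        curve = precision_recall_curve(sv, gold)
        # r=0.5 falls between 1/3 and 2/3; next achieved point is c at rank 3
        assert precision_at_recall(curve, 0.5) == pytest.approx(2 / 3)

    @pytest.mark.parametrize("bad_r", [0.0, -0.2, 1.5])
    def test_invalid_recall_level(self, bad_r):
        sv, gold = _fixture({"a": 1.0, "b": 0.5}, {"a"})
        curve = precision_recall_curve(sv, gold)
        with pytest.raises(ValueError):
            precision_at_recall(curve, bad_r)


class TestFoldOverRandom:
    def test_examples(self):
        assert fold_over_random(0.4, 0.1) == pytest.approx(4.0)
        assert fold_over_random(0.1, 0.1) == pytest.approx(1.0)

    def test_perfect_low_recall_equals_inverse_prevalence(self):
        sv, gold = _fixture({"a": 5.0, "b": 4.0, "c": 1.0, "d": 0.5}, {"a", "b"})
        curve = precision_recall_curve(sv, gold)
        p = precision_at_recall(curve, 0.01)
        assert fold_over_random(p, gold.prevalence) == pytest.approx(1 / gold.prevalence)

    def test_summarize_keys(self):
        sv, gold = _fixture({"a": 5.0, "b": 4.0, "c": 1.0, "d": 0.5}, {"a", "b"})
        stats = summarize(precision_recall_curve(sv, gold))
        assert stats["auprc"] == 1.0
        assert stats["p_at_50pct"] == 1.0
        assert stats["p_at_50pct_fold"] == pytest.approx(2.0)
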