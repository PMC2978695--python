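"""Precision-recall evaluation of ranked gene predictions.

Genes are ranked by score; at each threshold, precision = TP / (TP + FP)
and recall = TP / n_p. Tied scores are collapsed into a single threshold
group, so no ordering credit is taken inside a tie. The area under the
precision-recall curve (AUPRC) is computed by step-wise summation of
precision over recall increments, consistent with the achieved-point
convention used for precision at a fixed recall. The random baseline for
both precision and AUPRC is the class prevalence n_p / (n_p + n_n), which
motivates reporting precision as fold change over random.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, TextIO

import numpy as np

from .ontology import GoldStandard
from .predict import ScoreVector


@dataclass
class PRCurve:
    """Ranked-evaluation points, one per distinct score threshold.

    Arrays are aligned; recall is non-decreasing and reaches 1 at the last
    point, and TP + FN = n_p everywhere.
    """

    threshold: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    recall: np.ndarray
    precision: np.ndarray
    prevalence: float

    def __post_init__(self) -> None:
        n = len(self.threshold)
        for arr in (self.tp, self.fp, self.fn, self.recall, self.precision):
            if len(arr) != n:
                raise ValueError("curve arrays misaligned")
        if n and not np.all(np.diff(self.recall) >= 0):
            raise ValueError("recall must be non-decreasing")

    def __len__(self) -> int:
        return len(self.threshold)


def precision_recall_curve(scores: ScoreVector, gold: GoldStandard) -> PRCurve:
    """Compute the PR curve of a score vector against a gold standard.

    Every universe gene must be scored. Points are emitted at each distinct
    score value, best-first, with cumulative TP/FP counted over the whole
    tie group.
    """
    universe = sorted(gold.universe)
    missing = [g for g in universe if g not in scores.scores]
    if missing:
        raise ValueError(f"unscored gold-standard gene(s): {missing[:5]}")
    if gold.n_p == 0:
        raise ValueError("gold standard has no positives")
    s = scores.array(universe)
    y = np.array([1 if g in gold.positives else 0 for g in universe])
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    cum_tp = np.cumsum(y_sorted)
    cum_fp = np.cumsum(1 - y_sorted)
    # last index of each tie group = positions where the next score differs
    last_of_group = np.nonzero(np.append(np.diff(s_sorted) != 0, True))[0]
    tp = cum_tp[last_of_group]
    fp = cum_fp[last_of_group]
    fn = gold.n_p - tp
    with np.errstate(invalid="ignore"):
        precision = tp / (tp + fp)
    recall = tp / gold.n_p
    return PRCurve(
        threshold=s_sorted[last_of_group],
        tp=tp,
        fp=fp,
        fn=fn,
        recall=recall,
        precision=precision,
        prevalence=gold.prevalence,
    )


def auprc(curve: PRCurve) -> float:
    """Area under the PR curve by step summation over recall increments.

    Each point contributes (recall_i - recall_{i-1}) * precision_i; a
    perfect ranking scores exactly 1 and an all-tied ranking scores the
    prevalence.
    """
    prev_recall = np.concatenate(([0.0], curve.recall[:-1]))
    return float(np.sum((curve.recall - prev_recall) * curve.precision))


def precision_at_recall(curve: PRCurve, r: float) -> float:
    """Precision of the first curve point achieving recall >= r."""
    if not 0.0 < r <= 1.0:
        raise ValueError("recall level must be in (0, 1]")
    idx = np.nonzero(curve.recall >= r)[0]
    if len(idx) == 0:
        raise ValueError(f"no curve point reaches recall {r}")
    return float(curve.precision[idx[0]])


def fold_over_random(p: float, prevalence: float) -> float:
    """Precision as fold change over the random baseline (the prevalence)."""
    if prevalence <= 0:
        raise ValueError("prevalence must be positive")
    return p / prevalence


def summarize(
    curve: PRCurve,
    recall_levels: Sequence[float] = (0.01, 0.10, 0.20, 0.50),
) -> dict[str, float]:
    """Summary statistics: AUPRC and precision at fixed recall levels,
    each also expressed as fold over random."""
    out: dict[str, float] = {
        "auprc": auprc(curve),
        "prevalence": curve.prevalence,
    }
    out["auprc_fold"] = fold_over_random(out["auprc"], curve.prevalence)
    for r in recall_levels:
        p = precision_at_recall(curve, r)
        key = f"p_at_{int(round(r * 100))}pct"
        out[key] = p
        out[key + "_fold"] = fold_over_random(p, curve.prevalence)
    return out


def write_curve(curve: PRCurve, stream: TextIO) -> None:
    """Write curve points as TSV: threshold, TP, FP, FN, recall, precision."""
    stream.write("#threshold\tTP\tFP\tFN\trecall\tprecision\n")
    for i in range(len(curve)):
        stream.write(
            f"{curve.threshold[i]:.17g}\t{int(curve.tp[i])}\t{int(curve.fp[i])}\t"
            f"{int(curve.fn[i])}\t{curve.recall[i]:.17g}\t{curve.precision[i]:.17g}\n"
        )
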