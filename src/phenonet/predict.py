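"""Per-phenotype gene scoring: summed weight and network-feature SVM.

Two rankers share the same guilt-by-association premise. The summed-weight
baseline scores a candidate gene by the sum of its network weights to all
known (positive) genes of the phenotype. The SVM approach instead builds,
for each phenotype, a feature space of dimension n_p — a gene's vector of
connection weights to each positive example — and trains a class-weighted
soft-margin linear SVM to separate annotated from unannotated genes in that
space. Generalization error is estimated by bootstrap aggregation: in each
round genes are sampled with replacement to form the training set, a model
is fitted, and decision values are recorded only for out-of-bag genes; a
gene's final score is the median of its recorded out-of-bag values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.svm import LinearSVC

from .network import FunctionalNetwork
from .ontology import GoldStandard

logger = logging.getLogger(__name__)


@dataclass
class FeatureMatrix:
    """Connection-weight features: rows = example genes, columns = positives."""

    rows: list[str]
    columns: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.rows), len(self.columns)):
            raise ValueError("feature matrix shape mismatch")


@dataclass
class LinearSVMModel:
    """Fitted soft-margin linear SVM: decision value = w . x + b."""

    w: np.ndarray
    b: float
    C: float
    class_weight: str | None

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        return X @ self.w + self.b


@dataclass
class ScoreVector:
    """Raw per-gene scores with provenance.

    ``flags`` marks genes whose score did not come from the standard path
    (e.g. never out-of-bag across all bootstrap rounds, scored by a model
    trained on all genes instead).
    """

    scores: dict[str, float]
    provenance: str
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        bad = [g for g, s in self.scores.items() if not np.isfinite(s)]
        if bad:
            raise ValueError(f"non-finite scores for {bad[:5]}")

    def __getitem__(self, gene: str) -> float:
        return self.scores[gene]

    def __len__(self) -> int:
        return len(self.scores)

    def genes(self) -> list[str]:
        return list(self.scores)

    def array(self, genes: Sequence[str]) -> np.ndarray:
        return np.array([self.scores[g] for g in genes], dtype=float)

    def ranked(self) -> list[tuple[str, float]]:
        """Genes best-first; ties broken by gene id for determinism."""
        return sorted(self.scores.items(), key=lambda kv: (-kv[1], kv[0]))


def summed_weight_score(
    net: FunctionalNetwork,
    positives: Sequence[str] | set[str],
    universe: Sequence[str],
) -> ScoreVector:
    """Summed-weight baseline: f(x) = sum over positives x_i of K(x_i, x).

    The self term is excluded when x is itself a positive (connection
    weight of a gene to itself is 0 by policy).
    """
    pos = sorted(set(positives))
    if not pos:
        raise ValueError("no positive examples")
    m = net.subweights(list(universe), pos)
    # fsum: exactly rounded, so the result is independent of addend order
    return ScoreVector(
        scores={g: math.fsum(row) for g, row in zip(universe, m)},
        provenance="summed_weight",
    )


def build_feature_matrix(
    net: FunctionalNetwork,
    examples: Sequence[str],
    feature_positives: Sequence[str],
) -> FeatureMatrix:
    """Feature matrix entry (i, j) = K(examples[i], feature_positives[j]).

    A gene appearing among its own feature columns gets 0 in that column
    (self-weight policy); genes absent from the network get the network's
    default weight everywhere.
    """
    if not len(examples) or not len(feature_positives):
        raise ValueError("examples and feature_positives must be non-empty")
    vals = net.subweights(list(examples), list(feature_positives))
    return FeatureMatrix(rows=list(examples), columns=list(feature_positives), values=vals)


def train_linear_svm(
    features: FeatureMatrix | np.ndarray,
    labels: Sequence[int],
    C: float = 1.0,
    class_weighting: str | None = "balanced",
) -> LinearSVMModel:
    """Fit a soft-margin (hinge-loss) linear SVM.

    ``class_weighting="balanced"`` weights classes inversely to their
    frequencies, which matters here because n_n >> n_p for most phenotype
    terms. Requires both classes present.
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    y = np.asarray(labels)
    if C <= 0:
        raise ValueError("C must be positive")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    clf = LinearSVC(
        C=C,
        loss="hinge",
        dual=True,
        class_weight=class_weighting,
        random_state=0,
        max_iter=50_000,
        tol=1e-5,
    )
    import warnings
    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, y)
    return LinearSVMModel(
        w=clf.coef_.ravel().copy(),
        b=float(clf.intercept_[0]),
        C=C,
        class_weight=class_weighting,
    )


def bootstrap_aggregate(
    net: FunctionalNetwork,
    gold: GoldStandard,
    rounds: int = 25,
    seed: int = 0,
    C: float = 1.0,
    class_weighting: str | None = "balanced",
    feature_space: str = "fixed",
    max_redraws: int = 10,
    instrument: bool = False,
) -> ScoreVector | tuple[ScoreVector, dict[str, list[float]]]:
    """Bootstrap-aggregated SVM scores for every universe gene.

    Per round, ``|universe|`` genes are drawn with replacement as the
    training multiset; genes never drawn are out-of-bag and receive a
    recorded decision value from the round's model. A round whose training
    draw lacks one of the two classes is redrawn (at most ``max_redraws``
    times). The final score is the per-gene median of recorded out-of-bag
    values; genes that were never out-of-bag are scored by a model trained
    on all genes and flagged.

    ``feature_space="fixed"`` uses all n_p positives as feature columns in
    every round; ``"strict"`` restricts columns to in-bag positives,
    removing any test-identity leakage at the cost of a varying feature
    space. ``instrument=True`` additionally returns the per-gene lists of
    recorded out-of-bag values.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    if feature_space not in ("fixed", "strict"):
        raise ValueError("feature_space must be 'fixed' or 'strict'")
    universe = sorted(gold.universe)
    n = len(universe)
    labels = np.array([gold.label(g) for g in universe])
    all_positives = sorted(gold.positives)
    full_features = build_feature_matrix(net, universe, all_positives).values

    recorded: dict[str, list[float]] = {g: [] for g in universe}
    for r in range(rounds):
        rng = np.random.default_rng(seed + r)  # per-round substream
        for attempt in range(max_redraws + 1):
            idx = rng.integers(0, n, size=n)
            y_train = labels[idx]
            if len(np.unique(y_train)) == 2:
                break
            logger.warning("round %d draw %d lacked a class; redrawing", r, attempt)
        else:
            raise RuntimeError(
                f"round {r}: no two-class training draw in {max_redraws} redraws"
            )
        oob_mask = np.ones(n, dtype=bool)
        oob_mask[idx] = False
        if not oob_mask.any():
            continue
        if feature_space == "fixed":
            X_train = full_features[idx]
            X_oob = full_features[oob_mask]
        else:
            in_bag_pos = sorted({universe[i] for i in idx} & gold.positives)
            fm = build_feature_matrix(net, universe, in_bag_pos).values
            X_train = fm[idx]
            X_oob = fm[oob_mask]
        model = train_linear_svm(X_train, y_train, C=C, class_weighting=class_weighting)
        dv = model.decision_values(X_oob)
        for g, v in zip(np.array(universe)[oob_mask], dv):
            recorded[str(g)].append(float(v))

    never_oob = [g for g in universe if not recorded[g]]
    scores: dict[str, float] = {
        g: float(np.median(vals)) for g, vals in recorded.items() if vals
    }
    if never_oob:
        logger.info("%d gene(s) never out-of-bag; scoring with full-data model", len(never_oob))
        full_model = train_linear_svm(
            full_features, labels, C=C, class_weighting=class_weighting
        )
        fb = build_feature_matrix(net, never_oob, all_positives).values
        for g, v in zip(never_oob, full_model.decision_values(fb)):
            scores[g] = float(v)
    sv = ScoreVector(
        scores=scores, provenance="svm_oob_median", flags=frozenset(never_oob)
    )
    if instrument:
        return sv, recorded
    return sv
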