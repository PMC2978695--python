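"""Planted-module recovery benchmark comparing SVM and summed weight.

For each synthetic module: the annotated (observed) members define the
training gold standard; the held-out members are the evaluation truth.
Both rankers score every gene, and performance is measured as AUPRC over
the genes that were *not* observed positives — held-out members count as
positives, everything else (background, hubs) as negatives. The random
baseline is the held-out prevalence, so any AUPRC above it reflects signal
recovered from the network.
"""

from __future__ import annotations

from dataclasses import replace

import pandas as pd

from .evaluation import auprc, precision_recall_curve
from .ontology import (
    GoldStandard,
    build_gold_standard,
    collapse_alleles,
    propagate_annotations,
)
from .predict import ScoreVector, bootstrap_aggregate, summed_weight_score
from .synthetic import (
    SyntheticConfig,
    generate_annotations,
    generate_ontology,
    generate_planted_network,
)


def heldout_gold(
    term: str,
    observed_positives: frozenset[str],
    held_out: frozenset[str],
    universe,
) -> GoldStandard:
    """Evaluation gold standard over genes not used as training positives."""
    eval_genes = frozenset(universe) - observed_positives
    return GoldStandard(
        term=term,
        positives=held_out & eval_genes,
        negatives=eval_genes - held_out,
    )


def heldout_auprc(scores: ScoreVector, gold: GoldStandard) -> float:
    restricted = ScoreVector(
        scores={g: scores[g] for g in gold.universe},
        provenance=scores.provenance,
    )
    return auprc(precision_recall_curve(restricted, gold))


def run_planted_benchmark(
    cfg: SyntheticConfig,
    rounds: int = 25,
    C: float = 1.0,
    depth: int = 2,
    branching: int = 3,
) -> pd.DataFrame:
    """Score all planted modules with both methods on one synthetic draw.

    Returns one row per (term, method) with the held-out AUPRC and the
    held-out prevalence. Fully deterministic given ``cfg.seed``.
    """
    dag = generate_ontology(depth, branching)
    planted = generate_planted_network(cfg)
    net = planted.network
    universe = list(net.genes)
    annots, held_out = generate_annotations(
        planted.membership, dag, cfg.annotation_holdout_fraction, cfg.seed + 1
    )
    propagated = propagate_annotations(collapse_alleles(annots), dag)

    rows = []
    for i, term in enumerate(sorted(held_out)):
        train_gold = build_gold_standard(term, propagated, universe)
        egold = heldout_gold(term, train_gold.positives, held_out[term], universe)

        summed = summed_weight_score(net, train_gold.positives, universe)
        svm = bootstrap_aggregate(
            net, train_gold, rounds=rounds, seed=cfg.seed * 1009 + i * 101, C=C
        )
        for method, sv in (("summed_weight", summed), ("svm", svm)):
            rows.append(
                {
                    "term": term,
                    "method": method,
                    "auprc": heldout_auprc(sv, egold),
                    "prevalence": egold.prevalence,
                    "n_train_pos": train_gold.n_p,
                    "n_heldout": egold.n_p,
                }
            )
    return pd.DataFrame(rows)


def benchmark_over_seeds(
    cfg: SyntheticConfig, seeds, rounds: int = 25, **kwargs
) -> pd.DataFrame:
    """Run the planted benchmark for several seeds; concatenated rows."""
    frames = []
    for s in seeds:
        df = run_planted_benchmark(replace(cfg, seed=int(s)), rounds=rounds, **kwargs)
        df.insert(0, "seed", int(s))
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
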