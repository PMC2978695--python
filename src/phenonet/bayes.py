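"""Naive-Bayes integration of discretized pairwise evidence into a network.

Heterogeneous evidence sources (expression correlation, physical
interaction, phylogenetic profiles, ...) are discretized per gene pair into
a small number of bins. Against a gold standard of functionally related /
unrelated gene pairs, each source contributes a conditional probability
table p(bin | related) and p(bin | unrelated); treating sources as
conditionally independent given the relationship status, the posterior
probability of a functional relationship for a pair is

    P(FR | bins) = prior * prod_d p(bin_d | FR)
                   / (prior * prod_d p(bin_d | FR)
                      + (1 - prior) * prod_d p(bin_d | not FR))

Laplace pseudocounts keep every table entry positive. Phenotype-derived
evidence must not enter the integration (the resulting network is used to
predict phenotypes, so including it would be circular); dataset names
containing "phenotype" are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .network import FunctionalNetwork

Pair = frozenset


def _pair(a: str, b: str) -> frozenset[str]:
    if a == b:
        raise ValueError(f"self-pair ({a}, {a}) not allowed")
    return frozenset((a, b))


_RESERVED = "phenotype"


@dataclass
class EvidenceDataset:
    """One discretized pairwise evidence source.

    ``bins`` counts all discrete levels including, if present, the
    designated ``missing_bin`` used for pairs the source does not cover.
    """

    name: str
    bins: int
    values: dict[frozenset[str], int]
    missing_bin: int | None = None

    def __post_init__(self) -> None:
        if _RESERVED in self.name.lower():
            raise ValueError(
                f"dataset name {self.name!r} looks phenotype-derived; "
                "phenotype data must not enter network integration"
            )
        if self.missing_bin is not None and not 0 <= self.missing_bin < self.bins:
            raise ValueError("missing_bin outside [0, bins)")
        bad = {b for b in self.values.values() if not 0 <= b < self.bins}
        if bad:
            raise ValueError(f"bin indices {sorted(bad)} outside [0, {self.bins})")

    def with_missing_bin(self) -> "EvidenceDataset":
        """Return a copy with one extra bin reserved for missing pairs."""
        if self.missing_bin is not None:
            return self
        return EvidenceDataset(
            name=self.name,
            bins=self.bins + 1,
            values=dict(self.values),
            missing_bin=self.bins,
        )

    def bin_of(self, a: str, b: str) -> int:
        p = _pair(a, b)
        if p in self.values:
            return self.values[p]
        if self.missing_bin is None:
            raise KeyError(
                f"pair ({a}, {b}) absent from dataset {self.name!r} "
                "and no missing bin is designated"
            )
        return self.missing_bin


@dataclass
class ConditionalProbabilityTable:
    """Per-source likelihoods p(bin | FR) and p(bin | not FR)."""

    name: str
    p_bin_given_fr: np.ndarray
    p_bin_given_not_fr: np.ndarray

    def __post_init__(self) -> None:
        for v in (self.p_bin_given_fr, self.p_bin_given_not_fr):
            if abs(v.sum() - 1.0) > 1e-9:
                raise ValueError("CPT row does not sum to 1")
            if (v <= 0).any():
                raise ValueError("CPT entries must be positive (use pseudocounts)")

    def likelihood_ratio(self, b: int) -> float:
        return float(self.p_bin_given_fr[b] / self.p_bin_given_not_fr[b])


@dataclass
class PairGoldStandard:
    """Functionally related (positive) / unrelated (negative) gene pairs."""

    positives: set[frozenset[str]]
    negatives: set[frozenset[str]]
    prior: float = 0.5

    def __post_init__(self) -> None:
        if self.positives & self.negatives:
            raise ValueError("positive and negative pair sets overlap")
        if not 0.0 < self.prior < 1.0:
            raise ValueError("prior must be in (0, 1)")

    @classmethod
    def from_labeled(
        cls, labeled: Iterable[tuple[str, str, int]], prior: float = 0.5
    ) -> "PairGoldStandard":
        pos, neg = set(), set()
        for a, b, y in labeled:
            (pos if y == 1 else neg).add(_pair(a, b))
        return cls(positives=pos, negatives=neg, prior=prior)


def learn_cpt(
    data: EvidenceDataset,
    gold: PairGoldStandard,
    pseudocount: float = 1.0,
) -> ConditionalProbabilityTable:
    """Estimate a source's CPT from the pair gold standard.

    p(bin b | FR) = (#positive pairs in b + pseudocount) / (n_pos + B * pseudocount),
    and analogously for negatives. Gold pairs the source does not cover
    fall into its missing bin (an error if none is designated).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if not gold.positives:
        raise ValueError("pair gold standard has no positive pairs")
    B = data.bins
    counts = {True: np.zeros(B), False: np.zeros(B)}
    for is_pos, pairs in ((True, gold.positives), (False, gold.negatives)):
        for p in pairs:
            a, b = sorted(p)
            counts[is_pos][data.bin_of(a, b)] += 1
    p_fr = (counts[True] + pseudocount) / (len(gold.positives) + B * pseudocount)
    p_not = (counts[False] + pseudocount) / (len(gold.negatives) + B * pseudocount)
    return ConditionalProbabilityTable(
        name=data.name, p_bin_given_fr=p_fr, p_bin_given_not_fr=p_not
    )


def posterior_edge(
    pair_bins: Mapping[str, int],
    cpts: Sequence[ConditionalProbabilityTable],
    prior: float,
) -> float:
    """Naive-Bayes posterior probability of a functional relationship.

    ``pair_bins`` maps dataset name -> observed bin for one gene pair;
    every named dataset must have a CPT. Result is strictly inside (0, 1)
    because pseudocounts preclude zero likelihoods.
    """
    if not 0.0 < prior < 1.0:
        raise ValueError("prior must be in (0, 1)")
    by_name = {c.name: c for c in cpts}
    log_fr = np.log(prior)
    log_not = np.log1p(-prior)
    for name, b in pair_bins.items():
        if name not in by_name:
            raise KeyError(f"no CPT for dataset {name!r}")
        cpt = by_name[name]
        log_fr += np.log(cpt.p_bin_given_fr[b])
        log_not += np.log(cpt.p_bin_given_not_fr[b])
    # stable logistic of the log odds
    return float(1.0 / (1.0 + np.exp(log_not - log_fr)))


def integrate(
    datasets: Sequence[EvidenceDataset],
    gold: PairGoldStandard,
    pair_universe: Iterable[tuple[str, str]],
    pseudocount: float = 1.0,
) -> FunctionalNetwork:
    """Build a posterior functional network over ``pair_universe``.

    Each dataset is extended with a missing bin if it does not cover every
    pair it will be asked about; CPTs are learned from the pair gold
    standard, then every universe pair receives its naive-Bayes posterior
    as edge weight.
    """
    pairs = [(a, b) for a, b in pair_universe]
    if not pairs:
        raise ValueError("pair universe is empty")
    needed = {_pair(a, b) for a, b in pairs}
    needed |= gold.positives | gold.negatives
    prepared: list[EvidenceDataset] = []
    for d in datasets:
        if d.missing_bin is None and not needed <= set(d.values):
            d = d.with_missing_bin()
        prepared.append(d)
    cpts = [learn_cpt(d, gold, pseudocount) for d in prepared]
    edges = []
    for a, b in pairs:
        bins = {d.name: d.bin_of(a, b) for d in prepared}
        edges.append((a, b, posterior_edge(bins, cpts, gold.prior)))
    return FunctionalNetwork.from_edges(edges)
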