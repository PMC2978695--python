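"""Phenotype ontology handling and per-term gold standards.

A phenotype ontology (e.g. the Mammalian Phenotype ontology) is a DAG of
terms linked by ``is_a`` edges, with annotations recorded at the most
specific term that applies. Because an annotation to a child term implies
annotation to every ancestor, gold standards are built after propagating
annotations up the hierarchy: positives for a term are all genes annotated
to it or any descendant, negatives are every other gene in the universe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import obonet
import pandas as pd

#: Term-size bins (number of annotated genes) used for grouped performance
#: reporting. Half-open [lo, hi) so every count maps to exactly one bin.
PAPER_SIZE_BINS: tuple[tuple[int, int], ...] = (
    (30, 50),
    (50, 100),
    (100, 200),
    (200, 300),
)


@dataclass(frozen=True)
class OntologyDAG:
    """Acyclic is_a hierarchy of phenotype terms.

    Parameters
    ----------
    terms:
        All non-obsolete term identifiers.
    parents:
        Mapping term -> set of direct is_a parents. Roots map to the
        empty set.
    """

    terms: frozenset[str]
    parents: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        unknown = {
            p for ps in self.parents.values() for p in ps if p not in self.terms
        }
        if unknown:
            raise ValueError(
                f"parent term(s) not defined in ontology: {sorted(unknown)}"
            )
        g = nx.DiGraph(
            (child, parent) for child, ps in self.parents.items() for parent in ps
        )
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"ontology contains a cycle through {cycle[0][0]!r}")

    @property
    def roots(self) -> frozenset[str]:
        return frozenset(t for t in self.terms if not self.parents.get(t))

    def ancestors(self, term: str) -> frozenset[str]:
        """All terms reachable from ``term`` by following is_a links
        (excluding ``term`` itself)."""
        if term not in self.terms:
            raise KeyError(f"unknown term {term!r}")
        out: set[str] = set()
        stack = list(self.parents.get(term, ()))
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(self.parents.get(t, ()))
        return frozenset(out)

    def descendants(self, term: str) -> frozenset[str]:
        """All terms from which ``term`` is reachable (excluding itself)."""
        if term not in self.terms:
            raise KeyError(f"unknown term {term!r}")
        children: dict[str, set[str]] = {t: set() for t in self.terms}
        for child, ps in self.parents.items():
            for p in ps:
                children[p].add(child)
        out: set[str] = set()
        stack = list(children[term])
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(children[t])
        return frozenset(out)


@dataclass(frozen=True)
class AnnotationSet:
    """Gene/allele-to-term annotation records.

    ``records`` are (gene, term, allele) triples; ``allele`` is None once
    alleles have been collapsed to the gene level.
    """

    records: tuple[tuple[str, str, str | None], ...]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "AnnotationSet":
        return cls(tuple((g, t, None) for g, t in pairs))

    def gene_term_pairs(self) -> frozenset[tuple[str, str]]:
        return frozenset((g, t) for g, t, _ in self.records)

    def genes(self) -> frozenset[str]:
        return frozenset(g for g, _, _ in self.records)

    def genes_for_term(self, term: str) -> frozenset[str]:
        return frozenset(g for g, t, _ in self.records if t == term)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class GoldStandard:
    """Labeled gene sets for one phenotype term.

    Positives are genes annotated to the term (after propagation, so
    descendant annotations count); negatives are all other universe genes.
    """

    term: str
    positives: frozenset[str]
    negatives: frozenset[str]

    def __post_init__(self) -> None:
        if self.positives & self.negatives:
            raise ValueError("positives and negatives overlap")
        if not self.positives:
            raise ValueError(f"term {self.term!r} has no positive examples")

    @property
    def n_p(self) -> int:
        return len(self.positives)

    @property
    def n_n(self) -> int:
        return len(self.negatives)

    @property
    def universe(self) -> frozenset[str]:
        return self.positives | self.negatives

    @property
    def prevalence(self) -> float:
        return self.n_p / (self.n_p + self.n_n)

    def label(self, gene: str) -> int:
        return 1 if gene in self.positives else -1


def parse_obo(stream) -> OntologyDAG:
    """Parse an OBO 1.2 ontology into an :class:`OntologyDAG`.

    Only ``is_a`` relationships define parentage; other relationship types
    are ignored. Obsolete terms are dropped. Raises ``ValueError`` on cycles
    or references to undefined parent terms.
    """
    graph = obonet.read_obo(stream, ignore_obsolete=True)
    # obonet creates bare nodes for ids that are referenced but never
    # defined by a [Term] stanza; those are undefined parents.
    defined = {n for n, data in graph.nodes(data=True) if data}
    parents: dict[str, frozenset[str]] = {}
    for term in defined:
        ps = {
            v
            for _, v, key in graph.out_edges(term, keys=True)
            if key == "is_a"
        }
        parents[term] = frozenset(ps)
    undefined = {
        p for ps in parents.values() for p in ps if p not in defined
    }
    if undefined:
        raise ValueError(
            f"is_a parent(s) not defined in ontology: {sorted(undefined)}"
        )
    return OntologyDAG(terms=frozenset(defined), parents=parents)


def read_annotations(stream) -> AnnotationSet:
    """Read an annotation TSV with columns gene_id, term_id[, allele_id].

    Lines starting with '#' are skipped. No header row is expected.
    """
    df = pd.read_csv(
        stream,
        sep="\t",
        comment="#",
        header=None,
        names=["gene_id", "term_id", "allele_id"],
        dtype=str,
    )
    records = tuple(
        (row.gene_id, row.term_id, None if pd.isna(row.allele_id) else row.allele_id)
        for row in df.itertuples()
    )
    return AnnotationSet(records)


def collapse_alleles(annots: AnnotationSet) -> AnnotationSet:
    """Collapse allele-level records to the gene level.

    If any allele of a gene is annotated to a phenotype, the gene is
    associated with that phenotype; one record per distinct (gene, term).
    """
    pairs = sorted({(g, t) for g, t, _ in annots.records})
    return AnnotationSet.from_pairs(pairs)


def propagate_annotations(annots: AnnotationSet, dag: OntologyDAG) -> AnnotationSet:
    """Propagate gene-term annotations to all ancestor terms.

    Every annotation to a term implies annotation to each of its is_a
    ancestors. Input should already be collapsed to gene-term level.
    Raises ``ValueError`` if any annotation references an unknown term.
    """
    unknown = sorted({t for _, t, _ in annots.records if t not in dag.terms})
    if unknown:
        raise ValueError(f"annotations reference unknown term(s): {unknown}")
    anc_cache: dict[str, frozenset[str]] = {}
    pairs: set[tuple[str, str]] = set()
    for g, t, _ in annots.records:
        pairs.add((g, t))
        if t not in anc_cache:
            anc_cache[t] = dag.ancestors(t)
        for a in anc_cache[t]:
            pairs.add((g, a))
    return AnnotationSet.from_pairs(sorted(pairs))


def build_gold_standard(
    term: str,
    propagated: AnnotationSet,
    universe: Iterable[str],
) -> GoldStandard:
    """Partition the gene universe into positives and negatives for a term.

    ``propagated`` must already reflect annotation propagation, so genes
    annotated only to descendants appear at ``term``. Positives are
    restricted to the universe; all remaining universe genes are negatives.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("gene universe is empty")
    positives = propagated.genes_for_term(term) & universe
    if not positives:
        raise ValueError(f"term {term!r} has no positive examples")
    return GoldStandard(
        term=term, positives=positives, negatives=universe - positives
    )


def group_terms_by_size(
    standards: Sequence[GoldStandard],
    bins: Sequence[tuple[int, int]] = PAPER_SIZE_BINS,
) -> dict[tuple[int, int], list[str]]:
    """Group terms by positive-set size into half-open bins [lo, hi).

    Terms whose n_p falls outside every bin are omitted. Bins must not
    overlap (under the half-open convention).
    """
    for i, (lo, hi) in enumerate(bins):
        if hi <= lo:
            raise ValueError(f"empty bin ({lo}, {hi})")
        for lo2, hi2 in bins[i + 1 :]:
            if lo < hi2 and lo2 < hi:
                raise ValueError("bins overlap")
    out: dict[tuple[int, int], list[str]] = {tuple(b): [] for b in bins}
    for gs in standards:
        for lo, hi in bins:
            if lo <= gs.n_p < hi:
                out[(lo, hi)].append(gs.term)
                break
    return out


def write_gold_standard(gs: GoldStandard, stream) -> None:
    """Export a gold standard as TSV rows gene_id<TAB>label with label ±1."""
    stream.write("#gene_id\tlabel\n")
    for g in sorted(gs.positives):
        stream.write(f"{g}\t1\n")
    for g in sorted(gs.negatives):
        stream.write(f"{g}\t-1\n")
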