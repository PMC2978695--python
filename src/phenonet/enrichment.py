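"""Overlap between top predictions and QTL/GWAS genomic intervals.

Quantitative-genetics loci (QTL confidence intervals, GWAS regions) can
span hundreds of genes, so a large fraction of the genome may lie under at
least one locus. The question is whether the top-k network-based
predictions fall under loci more often than a random draw of k genes
would: with N universe genes of which K lie under loci, the probability of
seeing at least x of k top predictions under loci is the upper tail of the
hypergeometric distribution.

Coordinates are 1-based and intervals closed; overlap with a shared
endpoint counts. Units (bp or cM) are tagged and must agree between gene
positions and loci.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, TextIO

import pandas as pd
from scipy.stats import hypergeom


@dataclass(frozen=True)
class GenomicInterval:
    """A locus: closed interval [start, end] on a chromosome."""

    chrom: str
    start: float
    end: float
    source: str = ""
    unit: str = "bp"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")


@dataclass(frozen=True)
class GenePosition:
    """Genomic extent of a gene, in the same unit system as the loci."""

    gene: str
    chrom: str
    start: float
    end: float
    unit: str = "bp"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene}: start > end")


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric locus-overlap test for a top-k prediction list.

    x of the k top predictions lie under loci; K of the N universe genes
    do; p is the inclusive upper-tail probability P(X >= x).
    """

    k: int
    x: int
    K: int
    N: int
    p: float

    def __post_init__(self) -> None:
        if self.x > min(self.k, self.K):
            raise ValueError("overlap count exceeds min(k, K)")
        if not 0.0 < self.p <= 1.0:
            raise ValueError("p must be in (0, 1]")


def genes_in_loci(
    positions: Sequence[GenePosition],
    loci: Sequence[GenomicInterval],
    expand: float = 0.0,
) -> frozenset[str]:
    """Genes whose interval overlaps any locus expanded by ``expand``.

    ``expand`` widens every locus by the given amount on both sides (e.g.
    a 5 cM window around QTL peaks). Overlap is closed-interval: touching
    endpoints count. Mixing units between genes and loci is an error.
    """
    if expand < 0:
        raise ValueError("expand must be >= 0")
    units = {p.unit for p in positions} | {l.unit for l in loci}
    if len(units) > 1:
        raise ValueError(f"mixed coordinate units: {sorted(units)}")
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for loc in loci:
        by_chrom.setdefault(loc.chrom, []).append(loc)
    hit = set()
    for gp in positions:
        for loc in by_chrom.get(gp.chrom, ()):
            if gp.start <= loc.end + expand and loc.start - expand <= gp.end:
                hit.add(gp.gene)
                break
    return frozenset(hit)


def hypergeometric_overlap(
    top: Sequence[str],
    in_loci: Iterable[str],
    universe: Iterable[str],
) -> EnrichmentResult:
    """Upper-tail hypergeometric test of top-k overlap with locus genes.

    ``top`` is the prefix of the ranking (size k, must lie within the
    universe); ``in_loci`` the universe genes covered by loci. The p-value
    is inclusive of the observed overlap: P(X >= x).
    """
    universe = frozenset(universe)
    top = list(top)
    if not top:
        raise ValueError("top list is empty")
    if not set(top) <= universe:
        raise ValueError("top predictions must be a subset of the universe")
    in_loci = frozenset(in_loci) & universe
    k = len(top)
    K = len(in_loci)
    N = len(universe)
    x = len(set(top) & in_loci)
    if K == 0 and x > 0:
        raise ValueError("overlap observed but no universe gene lies in loci")
    # P(X >= x) = sf(x - 1); sf(-1) = 1 covers x = 0
    p = float(hypergeom.sf(x - 1, N, K, k))
    return EnrichmentResult(k=k, x=x, K=K, N=N, p=min(p, 1.0))


def read_positions(stream: TextIO, unit: str = "bp") -> list[GenePosition]:
    """Read gene positions TSV: gene_id, chrom, start, end ('#' comments)."""
    df = pd.read_csv(
        stream, sep="\t", comment="#", header=None,
        names=["gene_id", "chrom", "start", "end"],
        dtype={"gene_id": str, "chrom": str},
    )
    return [
        GenePosition(r.gene_id, r.chrom, float(r.start), float(r.end), unit=unit)
        for r in df.itertuples()
    ]


def read_loci(stream: TextIO, unit: str = "bp") -> list[GenomicInterval]:
    """Read loci TSV: chrom, start, end, source ('#' comments)."""
    df = pd.read_csv(
        stream, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "source"],
        dtype={"chrom": str, "source": str},
    )
    return [
        GenomicInterval(
            r.chrom, float(r.start), float(r.end),
            source="" if pd.isna(r.source) else r.source, unit=unit,
        )
        for r in df.itertuples()
    ]
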