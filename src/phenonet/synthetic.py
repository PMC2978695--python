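"""Seeded synthetic data with the statistical structure the method assumes.

The generator emulates the inputs of the real pipeline at desk scale:

* a small rooted phenotype ontology (optionally with one diamond);
* a functional network with planted gene modules — within-module pair
  weights drawn from a high Beta distribution over a sparse low-weight
  background, matching the semantics of posterior relationship
  probabilities in [0, 1];
* per-module annotations to one ontology leaf each, with a held-out
  fraction of members recorded as evaluation truth (emulating annotation
  incompleteness);
* optional hub genes: promiscuous connectors wired to every gene. Hubs
  share a common per-gene affinity profile (gene x receives weight
  ~ s_h * a_x from every hub h, with a_x drawn once per gene and a per-hub
  strength s_h). Their summed connection weight to a module's genes is
  then comparable to a genuine member's, so the summed-weight baseline
  ranks them among held-out positives, while their near-collinear feature
  vectors are linearly separable from the member cloud — the failure mode
  that motivates the SVM;
* genomic gene positions on a small set of chromosomes plus random locus
  intervals grown until they cover a configurable fraction of genes.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

from .network import FunctionalNetwork
from .ontology import AnnotationSet, OntologyDAG
from .enrichment import GenePosition, GenomicInterval, genes_in_loci


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters.

    Weight distributions are Beta(alpha, beta); defaults give mean ~0.8
    within modules and ~0.1 on the background, separable but noisy.
    """

    n_genes: int = 1000
    module_count: int = 5
    module_size: int = 50
    within_weight_dist: tuple[float, float] = (8.0, 2.0)
    background_weight_dist: tuple[float, float] = (1.0, 9.0)
    background_edge_density: float = 0.05
    hub_count: int = 0
    hub_weight_dist: tuple[float, float] = (8.0, 2.0)
    hub_strength_range: tuple[float, float] = (0.85, 1.15)
    annotation_holdout_fraction: float = 0.4
    locus_coverage_fraction: float = 0.83
    seed: int = 0

    def __post_init__(self) -> None:
        if self.module_count * self.module_size + self.hub_count > self.n_genes:
            raise ValueError("modules plus hubs exceed the gene count")
        if not 0.0 <= self.annotation_holdout_fraction <= 1.0:
            raise ValueError("holdout fraction must be in [0, 1]")
        if not 0.0 < self.background_edge_density <= 1.0:
            raise ValueError("background density must be in (0, 1]")
        if not 0.0 < self.locus_coverage_fraction < 1.0:
            raise ValueError("locus coverage must be in (0, 1)")


class PlantedNetwork(NamedTuple):
    network: FunctionalNetwork
    membership: dict[str, list[str]]  # module term label -> member genes
    hubs: list[str]


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"G{i:0{width}d}" for i in range(n)]


def generate_ontology(
    depth: int, branching: int, diamond: bool = False
) -> OntologyDAG:
    """Rooted tree ontology of sum_{d<=depth} branching^d terms.

    Term ids are SYN:0000001, SYN:0000002, ... breadth-first from the
    root. With ``diamond=True`` one extra term with two parents (the first
    two children of the root) is appended, making the DAG non-tree.
    """
    if depth < 1 or branching < 1:
        raise ValueError("depth and branching must be >= 1")
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"SYN:{counter:07d}"

    root = next_id()
    parents: dict[str, frozenset[str]] = {root: frozenset()}
    level = [root]
    for _ in range(depth):
        nxt = []
        for t in level:
            for _ in range(branching):
                c = next_id()
                parents[c] = frozenset({t})
                nxt.append(c)
        level = nxt
    if diamond:
        if branching < 2:
            raise ValueError("diamond requires branching >= 2")
        first_children = sorted(t for t, ps in parents.items() if root in ps)[:2]
        d = next_id()
        parents[d] = frozenset(first_children)
    return OntologyDAG(terms=frozenset(parents), parents=parents)


def ontology_leaves(dag: OntologyDAG) -> list[str]:
    """Terms with no children, sorted."""
    has_child = {p for ps in dag.parents.values() for p in ps}
    return sorted(dag.terms - has_child)


def generate_planted_network(cfg: SyntheticConfig) -> PlantedNetwork:
    """Planted-module weighted network (plus optional hub genes).

    Module pairs get within-distribution weights; background pairs exist
    with ``background_edge_density`` and low weights; each hub gene is
    connected to every other gene with weight clip(s_h * a_x) where a_x is
    the target gene's hub-affinity (drawn from ``hub_weight_dist``) and
    s_h ~ U(hub_strength_range) the hub's strength.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    genes = _gene_names(n)
    aw, bw = cfg.within_weight_dist
    ab, bb = cfg.background_weight_dist

    w = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    mask = rng.random(len(iu)) < cfg.background_edge_density
    w[iu[mask], ju[mask]] = rng.beta(ab, bb, size=int(mask.sum()))

    membership: dict[str, list[str]] = {}
    for m in range(cfg.module_count):
        lo = m * cfg.module_size
        hi = lo + cfg.module_size
        members = list(range(lo, hi))
        mi, mj = np.triu_indices(cfg.module_size, k=1)
        w[lo + mi, lo + mj] = rng.beta(aw, bw, size=len(mi))
        membership[f"module_{m}"] = [genes[i] for i in members]

    n_mod = cfg.module_count * cfg.module_size
    hubs_idx = list(range(n_mod, n_mod + cfg.hub_count))
    if cfg.hub_count:
        ah, bh = cfg.hub_weight_dist
        affinity = rng.beta(ah, bh, size=n)  # per-gene receptivity to hubs
        s_lo, s_hi = cfg.hub_strength_range
        strength = rng.uniform(s_lo, s_hi, size=cfg.hub_count)
        for h, s in zip(hubs_idx, strength):
            row = np.clip(s * affinity, 0.0, 1.0)
            w[h, :] = np.maximum(w[h, :], row)
            w[:, h] = np.maximum(w[:, h], row)
            w[h, h] = 0.0

    w = np.triu(w, k=1)
    w = w + w.T
    net = FunctionalNetwork.from_matrix(genes, w, stored=w > 0)
    return PlantedNetwork(network=net, membership=membership, hubs=[genes[i] for i in hubs_idx])


def generate_annotations(
    membership: dict[str, Sequence[str]],
    dag: OntologyDAG,
    holdout: float,
    seed: int,
) -> tuple[AnnotationSet, dict[str, frozenset[str]]]:
    """Annotate module members to one ontology leaf per module.

    Each member is annotated to its module's leaf with probability
    1 - holdout; the rest are recorded as held-out evaluation truth. A
    module that would end up with zero annotated members gets one forced
    annotation. Returns (annotations keyed by leaf term, held-out truth
    keyed by leaf term).
    """
    if not 0.0 <= holdout < 1.0:
        raise ValueError("holdout must be in [0, 1); 1 would leave no positives")
    leaves = ontology_leaves(dag)
    if len(leaves) < len(membership):
        raise ValueError(
            f"ontology has {len(leaves)} leaves but {len(membership)} modules"
        )
    rng = np.random.default_rng(seed)
    pairs: list[tuple[str, str]] = []
    held_out: dict[str, frozenset[str]] = {}
    for leaf, (module, members) in zip(leaves, sorted(membership.items())):
        members = list(members)
        keep = rng.random(len(members)) >= holdout
        if not keep.any():
            keep[rng.integers(len(members))] = True
        annotated = [g for g, k in zip(members, keep) if k]
        pairs.extend((g, leaf) for g in annotated)
        held_out[leaf] = frozenset(members) - frozenset(annotated)
    return AnnotationSet.from_pairs(pairs), held_out


def generate_gene_positions(
    genes: Sequence[str],
    n_chromosomes: int = 5,
    spacing: float = 100_000.0,
    gene_length: float = 20_000.0,
    unit: str = "bp",
) -> list[GenePosition]:
    """Deterministic layout: genes in equal blocks along each chromosome."""
    n = len(genes)
    per_chrom = -(-n // n_chromosomes)  # ceil
    out = []
    for i, g in enumerate(genes):
        c = i // per_chrom
        j = i % per_chrom
        start = 1.0 + j * spacing
        out.append(GenePosition(g, f"chr{c + 1}", start, start + gene_length, unit=unit))
    return out


def generate_loci(
    positions: Sequence[GenePosition],
    coverage: float,
    seed: int,
    tol: float = 0.02,
    locus_fraction: float = 0.02,
    max_iter: int = 100_000,
) -> list[GenomicInterval]:
    """Random locus intervals covering ~``coverage`` of genes (±``tol``).

    Intervals of length ``locus_fraction`` of a chromosome are proposed at
    random positions and accepted while they do not overshoot
    coverage + tol; generation stops once the covered gene fraction
    reaches coverage - tol. ``coverage`` close to 1 degenerates to
    whole-chromosome loci.
    """
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must be in (0, 1]")
    chrom_extent: dict[str, tuple[float, float]] = {}
    for p in positions:
        lo, hi = chrom_extent.get(p.chrom, (p.start, p.end))
        chrom_extent[p.chrom] = (min(lo, p.start), max(hi, p.end))
    unit = positions[0].unit
    chroms = sorted(chrom_extent)
    if coverage >= 1.0 - tol:
        return [
            GenomicInterval(c, *chrom_extent[c], source="synthetic", unit=unit)
            for c in chroms
        ]
    rng = np.random.default_rng(seed)
    n = len(positions)
    loci: list[GenomicInterval] = []
    covered: set[str] = set()
    for _ in range(max_iter):
        if len(covered) / n >= coverage - tol:
            break
        c = chroms[rng.integers(len(chroms))]
        lo, hi = chrom_extent[c]
        length = (hi - lo) * locus_fraction
        start = rng.uniform(lo, max(lo, hi - length))
        cand = GenomicInterval(c, start, start + length, source="synthetic", unit=unit)
        gained = genes_in_loci(positions, [cand])
        if len(covered | gained) / n <= coverage + tol:
            loci.append(cand)
            covered |= gained
    else:
        raise RuntimeError("could not reach target locus coverage")
    return loci


# -- fixture directory ------------------------------------------------------


def _write_obo(dag: OntologyDAG, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic-phenotype\n\n")
        for t in sorted(dag.terms):
            fh.write(f"[Term]\nid: {t}\nname: synthetic term {t}\n")
            for p in sorted(dag.parents.get(t, ())):
                fh.write(f"is_a: {p}\n")
            fh.write("\n")


def write_fixture_dir(cfg: SyntheticConfig, outdir: str | Path, depth: int = 2, branching: int = 3) -> Path:
    """Write a complete synthetic input set (the formats the readers consume).

    Produces ontology.obo, annotations.tsv, network.tsv, positions.tsv,
    loci.tsv, and truth.tsv (held-out gene-term pairs) under ``outdir``.
    """
    from .network import write_network

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dag = generate_ontology(depth, branching)
    planted = generate_planted_network(cfg)
    annots, held_out = generate_annotations(
        planted.membership, dag, cfg.annotation_holdout_fraction, cfg.seed + 1
    )
    positions = generate_gene_positions(planted.network.genes)
    loci = generate_loci(positions, cfg.locus_coverage_fraction, cfg.seed + 2)

    _write_obo(dag, outdir / "ontology.obo")
    with open(outdir / "network.tsv", "w") as fh:
        write_network(planted.network, fh)
    with open(outdir / "annotations.tsv", "w") as fh:
        fh.write("#gene_id\tterm_id\n")
        for g, t, _ in annots.records:
            fh.write(f"{g}\t{t}\n")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("#term_id\tgene_id\n")
        for t in sorted(held_out):
            for g in sorted(held_out[t]):
                fh.write(f"{t}\t{g}\n")
    with open(outdir / "positions.tsv", "w") as fh:
        fh.write("#gene_id\tchrom\tstart\tend\n")
        for p in positions:
            fh.write(f"{p.gene}\t{p.chrom}\t{p.start:g}\t{p.end:g}\n")
    with open(outdir / "loci.tsv", "w") as fh:
        fh.write("#chrom\tstart\tend\tsource\n")
        for l in loci:
            fh.write(f"{l.chrom}\t{l.start:g}\t{l.end:g}\t{l.source}\n")
    return outdir
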