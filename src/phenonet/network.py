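"""Probabilistic functional relationship network.

The network is an undirected weighted gene graph; the weight K(a, b) in
[0, 1] is interpreted as the posterior probability that genes a and b
participate in the same biological process. Pairs absent from the input are
assigned ``default_weight`` (0 by default: released edge lists are usually
thresholded, and 0 is the conservative reading). No self-edges are stored;
a gene's connection weight to itself is taken as 0 so that a positive
example never sees a trivially separating identity feature.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence, TextIO

import numpy as np

logger = logging.getLogger(__name__)

_HEADER = "#gene_a\tgene_b\tweight\n"


class FunctionalNetwork:
    """Symmetric gene-gene weight map backed by a dense matrix.

    Parameters
    ----------
    genes:
        Ordered gene identifiers (node set).
    default_weight:
        Weight returned for pairs with no stored edge, in [0, 1].
    """

    def __init__(self, genes: Iterable[str], default_weight: float = 0.0):
        if not 0.0 <= default_weight <= 1.0:
            raise ValueError("default_weight must be in [0, 1]")
        self.genes: list[str] = list(dict.fromkeys(genes))
        self.index: dict[str, int] = {g: i for i, g in enumerate(self.genes)}
        self.default_weight = float(default_weight)
        n = len(self.genes)
        self._w = np.full((n, n), self.default_weight, dtype=float)
        np.fill_diagonal(self._w, 0.0)
        self._stored = np.zeros((n, n), dtype=bool)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, float]],
        default_weight: float = 0.0,
        genes: Iterable[str] | None = None,
    ) -> "FunctionalNetwork":
        """Build from (gene_a, gene_b, weight) triples.

        Duplicate pairs keep the maximum weight; self-loops are dropped with
        a warning. ``genes`` may add isolated nodes beyond edge endpoints.
        """
        edges = list(edges)
        node_order: list[str] = list(genes) if genes is not None else []
        for a, b, _ in edges:
            node_order.append(a)
            node_order.append(b)
        net = cls(node_order, default_weight=default_weight)
        for a, b, w in edges:
            net.add_edge(a, b, w)
        return net

    @classmethod
    def from_matrix(
        cls,
        genes: Sequence[str],
        weights: np.ndarray,
        stored: np.ndarray | None = None,
        default_weight: float = 0.0,
    ) -> "FunctionalNetwork":
        """Wrap a dense symmetric weight matrix (diagonal forced to 0).

        ``stored`` marks which entries are real edges (for serialization);
        by default every off-diagonal entry differing from ``default_weight``
        counts as stored.
        """
        weights = np.asarray(weights, dtype=float)
        n = len(genes)
        if weights.shape != (n, n):
            raise ValueError("weight matrix shape does not match gene list")
        if not np.allclose(weights, weights.T):
            raise ValueError("weight matrix must be symmetric")
        if weights.min() < 0.0 or weights.max() > 1.0:
            raise ValueError("weights must lie in [0, 1]")
        net = cls(genes, default_weight=default_weight)
        net._w = weights.copy()
        np.fill_diagonal(net._w, 0.0)
        if stored is None:
            stored = net._w != default_weight
            np.fill_diagonal(stored, False)
        net._stored = stored | stored.T
        np.fill_diagonal(net._stored, False)
        return net

    def add_edge(self, a: str, b: str, w: float) -> None:
        if a == b:
            logger.warning("dropping self-loop on gene %r", a)
            return
        if not 0.0 <= w <= 1.0:
            raise ValueError(f"weight {w} for pair ({a}, {b}) outside [0, 1]")
        i, j = self.index[a], self.index[b]
        if self._stored[i, j]:
            w = max(w, self._w[i, j])  # duplicate rows resolved by max
        self._w[i, j] = self._w[j, i] = w
        self._stored[i, j] = self._stored[j, i] = True

    # -- queries -----------------------------------------------------------

    def __contains__(self, gene: str) -> bool:
        return gene in self.index

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return int(self._stored.sum()) // 2

    def weight(self, a: str, b: str) -> float:
        """K(a, b); default_weight for unstored pairs, 0 for a == b."""
        if a == b:
            return 0.0
        ia = self.index.get(a)
        ib = self.index.get(b)
        if ia is None or ib is None:
            return self.default_weight
        return float(self._w[ia, ib])

    def edges(self) -> Iterable[tuple[str, str, float]]:
        """Stored edges with gene_a < gene_b lexicographically."""
        ii, jj = np.nonzero(np.triu(self._stored, k=1))
        out = []
        for i, j in zip(ii.tolist(), jj.tolist()):
            a, b = self.genes[i], self.genes[j]
            if b < a:
                a, b = b, a
            out.append((a, b, float(self._w[i, j])))
        out.sort()
        return out

    def connection_weights(
        self,
        gene: str,
        reference: Sequence[str],
        self_weight: float = 0.0,
    ) -> np.ndarray:
        """Vector of K(gene, r) for each r in ``reference`` (positional).

        A gene appearing in its own reference list contributes
        ``self_weight`` (0 by default). A gene absent from the network gets
        the default weight against every reference gene, with a warning.
        """
        v = np.empty(len(reference), dtype=float)
        gi = self.index.get(gene)
        if gi is None:
            logger.warning("gene %r absent from network; scoring with defaults", gene)
            v.fill(self.default_weight)
            for j, r in enumerate(reference):
                if r == gene:
                    v[j] = self_weight
            return v
        for j, r in enumerate(reference):
            if r == gene:
                v[j] = self_weight
                continue
            ri = self.index.get(r)
            v[j] = self.default_weight if ri is None else self._w[gi, ri]
        return v

    def subweights(self, rows: Sequence[str], cols: Sequence[str]) -> np.ndarray:
        """Dense block of weights for ``rows`` x ``cols`` gene lists.

        Row gene equal to column gene yields 0 (self-weight policy). Genes
        absent from the network yield default_weight.
        """
        m = np.full((len(rows), len(cols)), self.default_weight, dtype=float)
        col_idx = [(j, self.index[c]) for j, c in enumerate(cols) if c in self.index]
        if col_idx:
            jj = [j for j, _ in col_idx]
            cc = [c for _, c in col_idx]
            for i, g in enumerate(rows):
                gi = self.index.get(g)
                if gi is not None:
                    m[i, jj] = self._w[gi, cc]
        for i, g in enumerate(rows):
            for j, c in enumerate(cols):
                if g == c:
                    m[i, j] = 0.0
        return m


def read_network(stream: TextIO, default_weight: float = 0.0) -> FunctionalNetwork:
    """Read an edge-list TSV: gene_a<TAB>gene_b<TAB>weight.

    '#' lines are comments. Duplicate pairs keep the max weight; self-loops
    are dropped with a warning; a weight outside [0, 1] is a hard error
    reported with its line number.
    """
    edges: list[tuple[str, str, float]] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"line {lineno}: expected 3 tab-separated fields")
        a, b, w_str = parts
        try:
            w = float(w_str)
        except ValueError as exc:
            raise ValueError(f"line {lineno}: unparseable weight {w_str!r}") from exc
        if not 0.0 <= w <= 1.0:
            raise ValueError(f"line {lineno}: weight {w} outside [0, 1]")
        edges.append((a, b, w))
    return FunctionalNetwork.from_edges(edges, default_weight=default_weight)


def write_network(net: FunctionalNetwork, stream: TextIO) -> None:
    """Write stored edges as TSV with gene_a < gene_b.

    Weights are printed with 17 significant digits so a read/write round
    trip reproduces every stored value exactly.
    """
    stream.write(_HEADER)
    for a, b, w in net.edges():
        stream.write(f"{a}\t{b}\t{w:.17g}\n")
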