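"""Outcome-stratified co-expression networks and the cohesion statistic.

A network is built per outcome group by thresholding the absolute Pearson
correlation matrix of the selected (highly variable) genes at |r| > 0.6 and
keeping an unweighted, unsigned simple graph. Every selected gene becomes a
node even if isolated, so a knockout is defined for each of them.

Cohesion — the global statistic that virtual knockout perturbs — is the
arithmetic mean of edge density and the global (transitivity-style)
clustering coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .io_preprocess import ExpressionMatrix

__all__ = ["CoexprNetwork", "build_network", "cohesion", "write_edgelist", "write_graphml"]


@dataclass
class CoexprNetwork:
    """Thresholded correlation network with construction provenance."""

    graph: nx.Graph
    threshold: float = 0.6
    source: str = ""

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list:
        return list(self.graph.edges)

    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()


def build_network(
    matrix: ExpressionMatrix,
    genes: Sequence[str] | None = None,
    threshold: float = 0.6,
    source: str = "",
) -> CoexprNetwork:
    """Build the |Pearson r| > threshold co-expression graph.

    Parameters
    ----------
    matrix
        Expression values (any space; correlations are scale-location
        invariant per gene). Needs at least 3 samples.
    genes
        Node set; defaults to all genes in the matrix. Constant genes are an
        error — correlation is undefined for them — and should be excluded
        upstream (variable-gene selection does this).
    threshold
        Strict cutoff on |r|; edge (i, j) exists iff |r(x_i, x_j)| > threshold.
    """
    if genes is None:
        genes = list(matrix.genes)
    else:
        genes = list(genes)
    if len(genes) == 0:
        raise ValueError("empty gene list")
    sub = matrix.subset_genes(genes)
    if sub.shape[1] < 3:
        raise ValueError(f"need >= 3 samples to estimate correlations, got {sub.shape[1]}")
    vals = sub.values.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    if (sd == 0).any():
        bad = [g for g, s in zip(genes, sd) if s == 0]
        raise ValueError(f"constant gene(s) in network input: {bad[:5]}")
    r = np.corrcoef(vals)
    adj = np.abs(r) > threshold
    np.fill_diagonal(adj, False)
    g = nx.Graph()
    g.add_nodes_from(genes)
    ii, jj = np.nonzero(np.triu(adj, k=1))
    g.add_edges_from((genes[i], genes[j]) for i, j in zip(ii, jj))
    return CoexprNetwork(g, threshold=threshold, source=source)


def _density(n: int, m: int) -> float:
    return 2.0 * m / (n * (n - 1)) if n >= 2 else 0.0


def cohesion(net: CoexprNetwork | nx.Graph) -> float:
    """Mean of edge density and global clustering coefficient, in [0, 1].

    Global clustering is 3 x triangles / connected triplets (transitivity),
    defined as 0 when the graph has no connected triplets; density is
    2m / n(n-1), defined as 0 for n < 2.
    """
    g = net.graph if isinstance(net, CoexprNetwork) else net
    n, m = g.number_of_nodes(), g.number_of_edges()
    clustering = nx.transitivity(g) if n >= 3 else 0.0
    return 0.5 * (_density(n, m) + clustering)


def write_edgelist(net: CoexprNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in net.graph.edges:
            fh.write(f"{a}\t{b}\n")


def write_graphml(net: CoexprNetwork, path: str | Path) -> None:
    nx.write_graphml(net.graph, str(path))
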