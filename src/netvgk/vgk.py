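"""Virtual gene knockout (VGK) and related network-perturbation measures.

A knockout deletes a gene's node (and incident edges) from a co-expression
network; its *impact* is baseline cohesion minus post-knockout cohesion.
Ranking genes by the *differential impact* (DI = impact in the non-healed
network minus impact in the healed network) screens for genes on which the
non-healing network preferentially depends — including hubs whose mean
expression barely changes and which standard differential expression misses.

Also here: PageRank redistribution after node removal (which downstream
genes lose the most centrality when the hub disappears) and a single-sample
neighborhood disruption score that stratifies patients by how far a hub's
neighborhood has drifted from a reference group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse

from .coexpression import CoexprNetwork, cohesion, _density

__all__ = [
    "knockout_impact",
    "all_knockout_impacts",
    "differential_impact",
    "pagerank_perturbation",
    "sample_disruption",
    "DisruptionResult",
]


def _as_graph(net: CoexprNetwork | nx.Graph) -> nx.Graph:
    return net.graph if isinstance(net, CoexprNetwork) else net


def knockout_impact(net: CoexprNetwork | nx.Graph, gene) -> float:
    """Cohesion change from deleting ``gene``: cohesion(G) - cohesion(G - gene).

    Computed by full recomputation on the deleted graph. Negative values are
    legal (removing a pendant node can raise density/clustering).
    """
    g = _as_graph(net)
    if gene not in g:
        raise KeyError(f"gene {gene!r} not in network")
    base = cohesion(g)
    h = g.copy()
    h.remove_node(gene)
    return base - cohesion(h)


def all_knockout_impacts(net: CoexprNetwork | nx.Graph, genes: Sequence | None = None) -> pd.Series:
    """Knockout impact for every requested node, via incremental updates.

    Removing node v changes the triangle count by the triangles through v
    and the connected-triplet count by C(d_v, 2) plus (d_u - 1) for each
    neighbor u, so all n impacts cost one sparse A@A instead of n cohesion
    recomputations. Agreement with :func:`knockout_impact` is enforced by the
    test suite's brute-force oracle.
    """
    g = _as_graph(net)
    nodes = list(g.nodes)
    if genes is None:
        genes = nodes
    missing = [x for x in genes if x not in g]
    if missing:
        raise KeyError(f"genes not in network: {missing[:5]}")
    n = len(nodes)
    a = nx.to_scipy_sparse_array(g, nodelist=nodes, format="csr", dtype=np.float64)
    deg = np.asarray(a.sum(axis=1)).ravel()
    m = g.number_of_edges()
    # triangles through each node: diag(A^3)/2
    a2 = a @ a
    tri_v = np.asarray(a2.multiply(a).sum(axis=1)).ravel() / 2.0
    tri_total = tri_v.sum() / 3.0
    p2_total = float(np.sum(deg * (deg - 1) / 2.0))
    clustering = 3.0 * tri_total / p2_total if p2_total > 0 else 0.0
    base = 0.5 * (_density(n, m) + clustering)

    nbr_deg_sum = np.asarray(a @ deg.reshape(-1, 1)).ravel()  # sum of d_u over u in N(v)
    m_after = m - deg
    tri_after = tri_total - tri_v
    p2_after = p2_total - deg * (deg - 1) / 2.0 - (nbr_deg_sum - deg)
    n_after = n - 1
    dens_after = np.where(n_after >= 2, 2.0 * m_after / max(n_after * (n_after - 1), 1), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        clus_after = np.where(p2_after > 0, 3.0 * tri_after / np.where(p2_after > 0, p2_after, 1.0), 0.0)
    impact = base - 0.5 * (dens_after + clus_after)
    ser = pd.Series(impact, index=nodes)
    return ser.loc[list(genes)]


def differential_impact(
    net_healed: CoexprNetwork | nx.Graph,
    net_nonhealed: CoexprNetwork | nx.Graph,
    genes: Sequence | None = None,
) -> pd.DataFrame:
    """Per-gene VGK table with DI = impact_nonhealed - impact_healed.

    ``genes`` defaults to the intersection of the two node sets; genes
    present in only one network are excluded from the table and listed in
    ``result.attrs["excluded_genes"]`` (imputing a zero impact for them
    would silently distort the ranking).

    Returns a DataFrame indexed by gene with columns ``impact_healed``,
    ``impact_nonhealed``, ``di`` and 1-based ``rank_di`` (descending DI,
    ties broken by gene ID).
    """
    ga, gb = _as_graph(net_healed), _as_graph(net_nonhealed)
    shared = set(ga.nodes) & set(gb.nodes)
    if genes is None:
        genes = sorted(shared)
        excluded = sorted((set(ga.nodes) | set(gb.nodes)) - shared)
    else:
        genes = list(genes)
        excluded = sorted(g for g in genes if g not in shared)
        genes = [g for g in genes if g in shared]
    if len(genes) == 0:
        raise ValueError("no genes shared by both networks")
    imp_a = all_knockout_impacts(ga, genes)
    imp_b = all_knockout_impacts(gb, genes)
    df = pd.DataFrame({"impact_healed": imp_a, "impact_nonhealed": imp_b})
    df["di"] = df["impact_nonhealed"] - df["impact_healed"]
    df = df.sort_index().sort_values("di", ascending=False, kind="stable")
    df["rank_di"] = np.arange(1, len(df) + 1)
    df.attrs["excluded_genes"] = excluded
    return df


def _power_iteration_pagerank(g: nx.Graph, damping: float, tol: float = 1e-12) -> pd.Series:
    """PageRank by plain power iteration; dangling mass teleports uniformly."""
    nodes = list(g.nodes)
    n = len(nodes)
    if n == 0:
        raise ValueError("empty graph")
    a = nx.to_scipy_sparse_array(g, nodelist=nodes, format="csr", dtype=np.float64)
    deg = np.asarray(a.sum(axis=1)).ravel()
    dangling = deg == 0
    inv_deg = np.where(dangling, 0.0, 1.0 / np.where(dangling, 1.0, deg))
    x = np.full(n, 1.0 / n)
    for _ in range(100_000):
        contrib = a.T @ (x * inv_deg)
        dangling_mass = x[dangling].sum()
        x_new = (1 - damping) / n + damping * (contrib + dangling_mass / n)
        if np.abs(x_new - x).sum() < tol:
            x = x_new
            break
        x = x_new
    return pd.Series(x / x.sum(), index=nodes)


def pagerank_perturbation(
    net: CoexprNetwork | nx.Graph, gene, damping: float = 0.85
) -> pd.DataFrame:
    """PageRank redistribution after removing one node.

    The undirected graph is treated as bidirected for the walk; isolated
    (dangling) nodes teleport uniformly. Returns a DataFrame over the
    remaining genes with ``pagerank_before``, ``pagerank_after`` and
    ``centrality_loss`` (before - after), ranked by descending loss with
    gene-ID tie-break. Both PageRank vectors sum to 1 (+-1e-9).
    """
    g = _as_graph(net)
    if gene not in g:
        raise KeyError(f"gene {gene!r} not in network")
    before = _power_iteration_pagerank(g, damping)
    h = g.copy()
    h.remove_node(gene)
    if h.number_of_nodes() == 0:
        raise ValueError("cannot remove the only node")
    after = _power_iteration_pagerank(h, damping)
    df = pd.DataFrame({"pagerank_before": before.drop(gene), "pagerank_after": after})
    df["centrality_loss"] = df["pagerank_before"] - df["pagerank_after"]
    df = df.sort_index().sort_values("centrality_loss", ascending=False, kind="stable")
    df["rank"] = np.arange(1, len(df) + 1)
    return df


@dataclass
class DisruptionResult:
    """Per-sample neighborhood disruption scores with a two-way split."""

    scores: pd.Series  # indexed by sample
    labels: pd.Series  # "high" / "low"
    genes_used: list
    genes_dropped: list

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"disruption_score": self.scores, "subtype": self.labels})


def _kmeans_1d_two(scores: np.ndarray, max_iter: int = 200) -> np.ndarray:
    """Deterministic 2-class 1-D k-means initialized at the min and max."""
    lo, hi = float(scores.min()), float(scores.max())
    if lo == hi:
        return np.zeros(len(scores), dtype=int)
    centers = np.array([lo, hi])
    assign = np.zeros(len(scores), dtype=int)
    for _ in range(max_iter):
        new_assign = (np.abs(scores - centers[1]) < np.abs(scores - centers[0])).astype(int)
        if (new_assign == assign).all():
            break
        assign = new_assign
        for k in (0, 1):
            if (assign == k).any():
                centers[k] = scores[assign == k].mean()
    return assign


def sample_disruption(
    cohort,
    neighborhood: Sequence[str],
    reference_group: str = "healed",
) -> DisruptionResult:
    """Single-sample perturbation of a hub's neighborhood.

    For each sample outside the reference group, the score is the mean over
    neighborhood genes of |x_gs - mu_g(ref)| / sd_g(ref), i.e. the average
    absolute z-deviation from the reference group's expression. Samples are
    split into ``high``/``low`` disruption subtypes by deterministic 1-D
    2-means (centers initialized at the score min and max).

    Parameters
    ----------
    cohort
        A :class:`~netvgk.synthetic_data.BulkCohort` (or any object with
        ``expression`` gene x sample DataFrame and ``metadata`` with an
        ``outcome`` column indexed by sample).
    neighborhood
        Gene list (e.g. the hub's top network neighbors).
    reference_group
        Outcome label defining the reference distribution (>= 3 samples).
    """
    expr: pd.DataFrame = cohort.expression
    meta: pd.DataFrame = cohort.metadata
    missing = [g for g in neighborhood if g not in expr.index]
    if missing:
        raise KeyError(f"neighborhood genes not in cohort: {missing[:5]}")
    ref_samples = meta.index[meta["outcome"] == reference_group]
    if len(ref_samples) < 3:
        raise ValueError(f"reference group {reference_group!r} has < 3 samples")
    other = meta.index[meta["outcome"] != reference_group]
    ref = expr.loc[list(neighborhood), ref_samples]
    mu = ref.mean(axis=1)
    sd = ref.std(axis=1, ddof=1)
    keep = sd > 0
    dropped = sd.index[~keep].tolist()
    if dropped:
        warnings.warn(f"dropping zero-variance reference genes: {dropped[:5]}")
    if not keep.any():
        raise ValueError("all neighborhood genes have zero reference variance")
    used = sd.index[keep].tolist()
    dev = expr.loc[used, other].sub(mu[used], axis=0).abs().div(sd[used], axis=0)
    scores = dev.mean(axis=0)
    assign = _kmeans_1d_two(scores.to_numpy(dtype=float))
    # class with the higher mean score is "high"
    if assign.any() and (~assign.astype(bool)).any():
        high_class = int(scores.to_numpy()[assign == 1].mean() > scores.to_numpy()[assign == 0].mean())
    else:
        high_class = 1  # degenerate: everything in class 0 -> all "low"
    labels = pd.Series(np.where(assign == high_class, "high", "low"), index=scores.index)
    return DisruptionResult(scores=scores, labels=labels, genes_used=used, genes_dropped=dropped)
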