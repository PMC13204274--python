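"""Per-sample/cell gene-module scoring and TF panel correlation.

Two scoring methods:

* ``module_zscore`` — the mean over module genes of the gene's z-standardized
  (across samples, n-1 divisor) log-normalized expression. The inflammation
  score, migration phenotype score and growth-factor pathway activation
  scores are all instances of this with different gene lists.
* ``ssgsea`` — a rank-based single-sample enrichment score: per sample the
  genes are ordered by expression and the score is the accumulated gap
  between the weighted in-set ECDF (weights rank^alpha, top gene heaviest)
  and the unweighted out-of-set ECDF.

``tf_correlation`` screens a transcription-factor panel for monotone
association with a target gene (Spearman, BH-adjusted).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_preprocess import ExpressionMatrix, GeneSetLibrary
from .inference_stats import bh_adjust

__all__ = ["ScoreVector", "module_zscore", "ssgsea", "tf_correlation"]


@dataclass
class ScoreVector:
    """Per-sample/cell module scores."""

    scores: pd.Series
    module_name: str
    n_genes_used: int


def module_zscore(
    matrix: ExpressionMatrix,
    module: Sequence[str],
    name: str = "module",
    *,
    center: pd.Series | None = None,
    scale: pd.Series | None = None,
) -> ScoreVector:
    """Mean of per-gene z-standardized expression over module genes.

    Genes absent from the matrix or with zero variance are dropped (counted
    in ``n_genes_used``); having none usable is an error. ``center``/``scale``
    allow freezing the standardization constants from another matrix (used by
    the reversal-subtraction comparison so the intervention is not partially
    cancelled by re-standardization).
    """
    if matrix.space not in ("lognorm", "log2"):
        raise ValueError(f"module_zscore expects log-scale expression, got space={matrix.space!r}")
    present = [g for g in module if g in matrix.genes]
    if not present:
        raise ValueError("no module gene present in the matrix")
    sub = matrix.values.loc[present]
    mu = sub.mean(axis=1) if center is None else center.loc[present]
    sd = sub.std(axis=1, ddof=1) if scale is None else scale.loc[present]
    keep = sd > 0
    if not keep.any():
        raise ValueError("all module genes are constant")
    used = keep.index[keep]
    z = sub.loc[used].sub(mu[used], axis=0).div(sd[used], axis=0)
    return ScoreVector(scores=z.mean(axis=0), module_name=name, n_genes_used=int(keep.sum()))


def _ssgsea_sample(order: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """Running-sum enrichment for one sample.

    ``order`` lists gene indices by descending expression; the gene at list
    position j (0-based) carries rank weight (N - j)^alpha if in the set.
    Score = sum over positions of (weighted in-set ECDF - out-set ECDF).
    """
    n = len(order)
    flags = in_set[order]
    k = int(flags.sum())
    if k == 0 or k == n:
        raise ValueError("set must be a proper, non-empty subset of the ranked genes")
    weights = np.where(flags, (n - np.arange(n)).astype(float) ** alpha, 0.0)
    p_in = np.cumsum(weights) / weights.sum()
    p_out = np.cumsum(~flags) / (n - k)
    return float(np.sum(p_in - p_out))


def ssgsea(
    matrix: ExpressionMatrix,
    sets: GeneSetLibrary,
    alpha: float = 0.25,
) -> dict[str, ScoreVector]:
    """Single-sample enrichment scores for every set in the library.

    Scores depend only on each sample's expression *ranking* (descending,
    ties broken deterministically by gene ID), so they are invariant under
    any strictly monotone per-sample transform. Sets with no gene in the
    matrix are skipped with a warning.
    """
    genes = matrix.genes.to_numpy()
    gene_pos = {g: i for i, g in enumerate(genes)}
    vals = matrix.values.to_numpy(dtype=float)
    # stable sort on gene ID first, then descending value => deterministic ties
    id_order = np.argsort(genes, kind="stable")
    out: dict[str, ScoreVector] = {}
    orders = []
    for s in range(vals.shape[1]):
        col = vals[:, s][id_order]
        order = id_order[np.argsort(-col, kind="stable")]
        orders.append(order)
    for name in sets.names():
        members = [g for g in sets.genes(name) if g in gene_pos]
        if not members:
            warnings.warn(f"set {name!r} shares no gene with the matrix; skipped")
            continue
        in_set = np.zeros(len(genes), dtype=bool)
        in_set[[gene_pos[g] for g in members]] = True
        scores = np.array([_ssgsea_sample(order, in_set, alpha) for order in orders])
        out[name] = ScoreVector(
            scores=pd.Series(scores, index=matrix.samples),
            module_name=name,
            n_genes_used=len(members),
        )
    return out


def tf_correlation(
    matrix: ExpressionMatrix,
    target_gene: str,
    tf_list: Sequence[str],
) -> pd.DataFrame:
    """Spearman correlation of a target gene against a TF panel.

    Returns a DataFrame indexed by TF with ``spearman_rho``, ``p_value`` and
    ``bh_q`` (BH across the panel), sorted by descending rho. Requires >= 10
    samples/cells and a non-constant target; constant TFs are dropped with a
    warning.
    """
    if matrix.shape[1] < 10:
        raise ValueError("need >= 10 samples/cells for the TF screen")
    if target_gene not in matrix.genes:
        raise KeyError(f"target gene {target_gene!r} not in matrix")
    target = matrix.values.loc[target_gene].to_numpy(dtype=float)
    if np.ptp(target) == 0:
        raise ValueError("target gene is constant")
    present = [t for t in tf_list if t in matrix.genes and t != target_gene]
    if not present:
        raise ValueError("no TF from the panel present in the matrix")
    rows = {}
    for tf in present:
        x = matrix.values.loc[tf].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            warnings.warn(f"TF {tf!r} is constant; dropped")
            continue
        rho, p = stats.spearmanr(target, x)
        rows[tf] = (float(rho), float(p))
    if not rows:
        raise ValueError("every panel TF was constant")
    df = pd.DataFrame.from_dict(rows, orient="index", columns=["spearman_rho", "p_value"])
    df["bh_q"] = bh_adjust(df["p_value"].to_numpy())
    return df.sort_index().sort_values("spearman_rho", ascending=False, kind="stable")
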