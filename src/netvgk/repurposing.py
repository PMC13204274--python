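"""Disease-signature construction, drug-set enrichment, and the
reversal-signature subtraction simulation.

The disease signature is the top-N up- and down-regulated genes of a
case-vs-control differential expression ranking (by t-statistic). Each drug
gene set is tested against both lists with the one-sided Fisher exact
(hypergeometric upper-tail) test; DOWN rows test the disease *down* list, so
a significant DOWN hit is a drug signature that opposes the disease profile
(candidate therapeutic). The subtraction simulation shifts the expression of
reversal-signature genes against their disease direction and re-scores a
phenotype module with frozen standardization constants; its output is
labeled hypothesis-generating.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .inference_stats import bh_adjust, rank_sum_test
from .io_preprocess import ExpressionMatrix, GeneSetLibrary
from .module_scoring import ScoreVector, module_zscore

__all__ = ["Signature", "build_signature", "enrich", "reversal_subtraction", "recurrent_genes", "ReversalResult"]


@dataclass
class Signature:
    """Up/down disease gene lists with the ranking statistic's name."""

    up: list[str]
    down: list[str]
    ranking_stat: str = "t_stat"

    def __post_init__(self) -> None:
        overlap = set(self.up) & set(self.down)
        if overlap:
            raise ValueError(f"up and down lists overlap: {sorted(overlap)[:5]}")


def build_signature(de: pd.DataFrame, n_up: int = 200, n_down: int = 200) -> Signature:
    """Top-N up and down genes from a DE table, ranked by t-statistic.

    Up = the ``n_up`` largest positive t among genes with positive fold
    change; down = the ``n_down`` most negative t among negative-fold genes;
    exact ties break by gene ID.
    """
    pos = de[de["t_stat"] > 0].sort_index().sort_values("t_stat", ascending=False, kind="stable")
    neg = de[de["t_stat"] < 0].sort_index().sort_values("t_stat", ascending=True, kind="stable")
    if len(pos) < n_up or len(neg) < n_down:
        raise ValueError(
            f"need {n_up} up / {n_down} down genes; have {len(pos)} positive and {len(neg)} negative t"
        )
    return Signature(up=pos.index[:n_up].tolist(), down=neg.index[:n_down].tolist())


def enrich(sig: Signature, lib: GeneSetLibrary, background: Sequence[str]) -> pd.DataFrame:
    """One-sided Fisher exact enrichment of each drug set against both lists.

    For a drug set of size K (after intersecting with the ``background``
    universe of size N) and a signature list of size n, the p-value is the
    hypergeometric upper tail P(X >= k) for the observed overlap k. BH
    adjustment runs across all (set x direction) tests. DOWN rows test the
    disease down-list (drug reverses disease), UP rows the up-list.
    """
    background = list(dict.fromkeys(background))
    if not background:
        raise ValueError("empty background universe")
    bg = set(background)
    for lst, nm in ((sig.up, "up"), (sig.down, "down")):
        stray = [g for g in lst if g not in bg]
        if stray:
            raise ValueError(f"signature {nm} genes missing from background: {stray[:5]}")
    n_bg = len(bg)
    rows = []
    for name in lib.names():
        members = set(lib.genes(name)) & bg
        K = len(members)
        for direction, lst in (("UP", sig.up), ("DOWN", sig.down)):
            k = len(members & set(lst))
            n_sig = len(lst)
            p = float(stats.hypergeom.sf(k - 1, n_bg, K, n_sig)) if K else 1.0
            rows.append((name, direction, k, K, n_sig, n_bg, p))
    df = pd.DataFrame(
        rows,
        columns=["drug_set", "direction", "overlap", "set_size", "signature_size", "background", "fisher_p"],
    )
    df["bh_q"] = bh_adjust(df["fisher_p"].to_numpy())
    df = df.sort_values(["fisher_p", "drug_set", "direction"], kind="stable").reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


@dataclass
class ReversalResult:
    """Before/after phenotype scores under the subtraction simulation."""

    before: ScoreVector
    after: ScoreVector
    rank_sum_p: float
    weight: float
    note: str = "exploratory, hypothesis-generating simulation; not a predicted treatment outcome"


def reversal_subtraction(
    matrix: ExpressionMatrix,
    reversal: Sequence[str],
    signature: Signature,
    weight: float,
    migration_module: Sequence[str],
) -> ReversalResult:
    """Re-score a phenotype module after subtracting a drug-reversal signature.

    Each reversal gene g present in the disease signature is shifted by
    ``-weight * s_g`` where s_g = +1 for disease-up genes and -1 for
    disease-down genes (the adjustment opposes the disease direction); other
    genes are untouched. Both score vectors use standardization constants
    frozen from the *unadjusted* matrix, so the comparison isolates the
    expression shift; the two score distributions are compared with the
    two-sided rank-sum test.
    """
    if weight < 0:
        raise ValueError("weight must be >= 0")
    reversal = list(reversal)
    missing = [g for g in reversal if g not in matrix.genes]
    if missing:
        raise KeyError(f"reversal genes not in matrix: {missing[:5]}")
    up, down = set(signature.up), set(signature.down)
    s = {g: (1.0 if g in up else -1.0 if g in down else 0.0) for g in reversal}
    center = matrix.values.mean(axis=1)
    scale = matrix.values.std(axis=1, ddof=1)
    before = module_zscore(matrix, migration_module, name="migration", center=center, scale=scale)
    adjusted = matrix.values.copy()
    for g in reversal:
        if s[g] != 0.0:
            adjusted.loc[g] = adjusted.loc[g] - weight * s[g]
    adj = ExpressionMatrix(adjusted, space=matrix.space)
    after = module_zscore(adj, migration_module, name="migration", center=center, scale=scale)
    p = rank_sum_test(before.scores.to_numpy(), after.scores.to_numpy())
    return ReversalResult(before=before, after=after, rank_sum_p=p, weight=weight)


def recurrent_genes(
    table: pd.DataFrame, lib: GeneSetLibrary, sig: Signature, q_max: float = 0.05
) -> pd.Series:
    """Descriptive per-gene membership count across significant drug sets.

    Counts, for each signature gene, how many distinct drug sets with
    bh_q < ``q_max`` contain it — a simple recurrence screen for pathway
    nominations (e.g. a gene appearing across many reversal signatures).
    """
    sig_sets = table.loc[table["bh_q"] < q_max, "drug_set"].unique()
    sig_genes = set(sig.up) | set(sig.down)
    counts: dict[str, int] = {}
    for name in sig_sets:
        for g in set(lib.genes(name)) & sig_genes:
            counts[g] = counts.get(g, 0) + 1
    return pd.Series(counts, dtype=int).sort_values(ascending=False)
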