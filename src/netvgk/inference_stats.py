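"""Differential expression, rank tests, permutation and resampling
validation, and the three-variable path (mediation) model.

The moderated t follows the empirical-Bayes variance-shrinkage scheme used
throughout transcriptomics: per-gene sample variances are shrunk toward a
prior scale s0^2 with prior degrees of freedom d0, both estimated by
matching moments of the log sample variances (trigamma inversion); the
fold-change column is estimator-free and identical between methods.

The path model regresses, on z-scored variables, inflammation on transport
(path a) and outcome on transport + inflammation (paths c' and b); the
indirect effect a*b gets a percentile bootstrap CI. The binary outcome is
kept numeric (linear-probability treatment), mirroring covariance-based
path fitting.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "DETable",
    "PathResult",
    "CoherenceResult",
    "LopoResult",
    "differential_expression",
    "rank_sum_test",
    "module_coherence_test",
    "lopo_stability",
    "path_analysis",
    "bh_adjust",
]

DETable = pd.DataFrame  # per-gene: log2fc, fold_change, t_stat, p_raw, p_bh, direction


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending order, capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be 1-D")
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# differential expression


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate prior df d0 and scale s0^2 from sample variances.

    Moment-matching on z = log s^2: E[z] = log s0^2 + psi(df/2) - log(df/2)
    + psi(d0/2)-ish decomposition; Var[z] = trigamma(df/2) + trigamma(d0/2).
    Returns (d0, s0_squared); d0 = inf when the observed spread is no larger
    than the chi-square sampling spread (complete shrinkage).
    """
    z = np.log(np.maximum(s2, 1e-300))
    e = z - special.digamma(df / 2) + math.log(df / 2)
    ebar = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2))
    if evar <= 0:
        return np.inf, float(np.exp(ebar))
    # invert trigamma(d0/2) = evar by Newton iteration
    x = 0.5 + 1.0 / evar  # good starting point
    for _ in range(100):
        tri = float(special.polygamma(1, x))
        diff = tri - evar
        if abs(diff) < 1e-12:
            break
        x -= diff / float(special.polygamma(2, x))
        x = max(x, 1e-8)
    d0 = 2 * x
    s0_sq = float(np.exp(ebar + special.digamma(x) - math.log(x)))
    return d0, s0_sq


def differential_expression(
    matrix,
    labels: pd.Series,
    case: str,
    control: str,
    method: str = "welch",
) -> DETable:
    """Two-group differential expression on log2-scale values.

    Parameters
    ----------
    matrix
        :class:`~netvgk.io_preprocess.ExpressionMatrix` in ``log2`` or
        ``lognorm`` space (log-scale values; the fold change is the mean
        difference on this scale).
    labels
        Per-sample group labels indexed by sample ID.
    case, control
        Labels defining the contrast; log2fc = mean(case) - mean(control).
    method
        ``"welch"`` (two-sided Welch t) or ``"moderated"`` (empirical-Bayes
        shrunken pooled variance with augmented df).

    Returns a DataFrame indexed by gene with ``log2fc``, ``fold_change``,
    ``t_stat``, ``p_raw``, ``p_bh`` and ``direction`` (Up/Down by fold-change
    sign), sorted by ascending raw p (ties by gene ID).
    """
    if matrix.space not in ("log2", "lognorm"):
        raise ValueError(f"differential_expression expects log-scale values, got {matrix.space!r}")
    labels = labels.reindex(matrix.samples)
    idx_case = labels.index[labels == case]
    idx_ctrl = labels.index[labels == control]
    if len(idx_case) < 2 or len(idx_ctrl) < 2:
        raise ValueError(f"each group needs >= 2 samples (case={len(idx_case)}, control={len(idx_ctrl)})")
    a = matrix.values[idx_case].to_numpy(dtype=float)
    b = matrix.values[idx_ctrl].to_numpy(dtype=float)
    n1, n2 = a.shape[1], b.shape[1]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    log2fc = m1 - m2
    v1, v2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    if method == "welch":
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(v1 / n1 + v2 / n2)
            t = log2fc / se
            dfw = (v1 / n1 + v2 / n2) ** 2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
        p = 2 * stats.t.sf(np.abs(t), dfw)
        p = np.where(np.isnan(p), 1.0, p)
    elif method == "moderated":
        df_resid = n1 + n2 - 2
        s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df_resid
        d0, s0_sq = _fit_f_dist(s2[s2 > 0], df_resid)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_sq)
            df_total = np.inf
        else:
            s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
            df_total = d0 + df_resid
        with np.errstate(divide="ignore", invalid="ignore"):
            t = log2fc / np.sqrt(s2_post * (1 / n1 + 1 / n2))
        p = (
            2 * stats.norm.sf(np.abs(t))
            if np.isinf(df_total)
            else 2 * stats.t.sf(np.abs(t), df_total)
        )
        p = np.where(np.isnan(p), 1.0, p)
    else:
        raise ValueError(f"unknown method {method!r}")
    df = pd.DataFrame(
        {
            "log2fc": log2fc,
            "fold_change": 2.0**log2fc,
            "t_stat": t,
            "p_raw": p,
            "p_bh": bh_adjust(p),
            "direction": np.where(log2fc >= 0, "Up", "Down"),
        },
        index=matrix.genes,
    )
    return df.sort_index().sort_values("p_raw", kind="stable")


# ---------------------------------------------------------------------------
# rank-sum test


def rank_sum_test(a, b) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact by full enumeration of the C(n_a+n_b, n_a) label assignments
    (average ranks, hence tie-safe) when n_a + n_b <= 12; otherwise the
    normal approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)
    ranks = stats.rankdata(pooled)
    w_obs = ranks[:na].sum()
    expect = na * (n + 1) / 2.0
    if n <= 12:
        dev = abs(w_obs - expect)
        count = total = 0
        for combo in itertools.combinations(range(n), na):
            w = ranks[list(combo)].sum()
            total += 1
            if abs(w - expect) >= dev - 1e-9:
                count += 1
        return count / total
    # normal approximation with tie correction
    _, tie_counts = np.unique(pooled, return_counts=True)
    nb = n - na
    tie_term = ((tie_counts**3 - tie_counts).sum()) / ((n) * (n - 1))
    var = na * nb / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return 1.0
    z = (w_obs - expect) / math.sqrt(var)
    return float(min(1.0, 2 * stats.norm.sf(abs(z))))


# ---------------------------------------------------------------------------
# permutation coherence test


@dataclass
class CoherenceResult:
    """Observed module coherence against a random-module null."""

    observed_coherence: float
    null_samples: np.ndarray
    p_perm: float
    module_size: int


def _mean_pairwise_r(vals: np.ndarray) -> float:
    r = np.corrcoef(vals)
    iu = np.triu_indices_from(r, k=1)
    return float(r[iu].mean())


def module_coherence_test(
    matrix,
    module: Sequence[str],
    B: int = 1000,
    seed: int | None = None,
    absolute: bool = False,
) -> CoherenceResult:
    """Permutation test of a module's internal co-expression coherence.

    Coherence is the mean pairwise Pearson correlation (signed by default;
    ``absolute=True`` uses mean |r|) among module genes; the null draws B
    same-size gene sets without replacement from all non-constant genes of
    the matrix. p = (1 + #{null >= observed}) / (B + 1).
    """
    module = list(module)
    if len(module) < 2:
        raise ValueError("module must have >= 2 genes")
    missing = [g for g in module if g not in matrix.genes]
    if missing:
        raise KeyError(f"module genes not in matrix: {missing[:5]}")
    vals = matrix.values.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    eligible = matrix.genes[sd > 0]
    if len(eligible) < len(module):
        raise ValueError("not enough non-constant genes to sample null modules")
    stat = (lambda v: float(np.abs(np.corrcoef(v)[np.triu_indices(len(v), k=1)]).mean())) if absolute else _mean_pairwise_r
    obs = stat(matrix.values.loc[module].to_numpy(dtype=float))
    rng = np.random.default_rng(seed)
    elig_vals = matrix.values.loc[eligible].to_numpy(dtype=float)
    null = np.empty(B)
    for i in range(B):
        pick = rng.choice(len(eligible), size=len(module), replace=False)
        null[i] = stat(elig_vals[pick])
    p = (1 + int((null >= obs).sum())) / (B + 1)
    return CoherenceResult(observed_coherence=obs, null_samples=null, p_perm=p, module_size=len(module))


# ---------------------------------------------------------------------------
# leave-one-patient-out stability


@dataclass
class LopoResult:
    """Coefficient of variation of the group effect size across LOPO folds."""

    cv: float
    effects: pd.Series  # per excluded patient
    skipped: list = field(default_factory=list)


def _cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    nx_, ny = len(x), len(y)
    pooled = ((nx_ - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx_ + ny - 2)
    return float((x.mean() - y.mean()) / math.sqrt(pooled))


def lopo_stability(cohort, module: Sequence[str]) -> LopoResult:
    """Leave-one-patient-out stability of the module's outcome effect size.

    For every patient, all their samples are dropped and Cohen's d (pooled
    SD) of the module z-score between healed and non-healed samples is
    recomputed; the CV is sd/|mean| over folds. Folds that empty a group are
    skipped with a warning.
    """
    from .io_preprocess import ExpressionMatrix
    from .module_scoring import module_zscore

    meta = cohort.metadata
    patients = meta["patient"].unique()
    if len(patients) < 3:
        raise ValueError("need >= 3 patients")
    effects, skipped = {}, []
    for pat in patients:
        keep = meta.index[meta["patient"] != pat]
        sub_meta = meta.loc[keep]
        healed = sub_meta.index[sub_meta["outcome"] == "healed"]
        nonhealed = sub_meta.index[sub_meta["outcome"] == "nonhealed"]
        if len(healed) < 2 or len(nonhealed) < 2:
            warnings.warn(f"excluding patient {pat!r} empties a group; fold skipped")
            skipped.append(pat)
            continue
        em = ExpressionMatrix(cohort.expression[keep], space="lognorm")
        sv = module_zscore(em, module, name="lopo")
        effects[pat] = _cohens_d(
            sv.scores[healed].to_numpy(), sv.scores[nonhealed].to_numpy()
        )
    eff = pd.Series(effects)
    if len(eff) < 2:
        raise ValueError("fewer than 2 usable folds")
    cv = float(eff.std(ddof=1) / abs(eff.mean()))
    return LopoResult(cv=cv, effects=eff, skipped=skipped)


# ---------------------------------------------------------------------------
# path (mediation) analysis


@dataclass
class PathResult:
    """Standardized three-variable path model T -> I -> H with direct path."""

    a: float  # transport -> inflammation
    b: float  # inflammation -> outcome, adjusted for transport
    c_prime: float  # direct transport -> outcome
    indirect: float  # a * b
    indirect_ci: tuple[float, float]
    p_a: float
    p_b: float
    p_c_prime: float
    n: int
    n_boot: int


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot z-score a constant variable")
    return (x - x.mean()) / sd


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Coefficients and two-sided p-values for least squares with intercept."""
    import statsmodels.api as sm

    model = sm.OLS(y, sm.add_constant(X)).fit()
    return model.params[1:], model.pvalues[1:]


def path_analysis(
    T,
    I,
    H,
    n_boot: int = 1000,
    seed: int | None = None,
) -> PathResult:
    """Three-variable path model with bootstrap CI for the indirect effect.

    All variables are z-scored (the binary outcome H as 0/1 first); a is the
    slope of I ~ T, (c', b) are the slopes of H ~ T + I, and the indirect
    effect a*b gets a percentile bootstrap CI over samples.
    """
    T = np.asarray(T, dtype=float)
    I = np.asarray(I, dtype=float)
    H = np.asarray(H, dtype=float)
    if not (len(T) == len(I) == len(H)):
        raise ValueError("T, I, H must have equal length")
    r_ti = np.corrcoef(T, I)[0, 1]
    if abs(r_ti) > 0.999:
        raise ValueError("T and I are collinear (|r| > 0.999)")
    zT, zI, zH = _zscore(T), _zscore(I), _zscore(H)
    (a,), (p_a,) = _ols(zI, zT[:, None])
    (c_prime, b), (p_c, p_b) = _ols(zH, np.column_stack([zT, zI]))
    rng = np.random.default_rng(seed)
    n = len(T)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        t_, i_, h_ = T[idx], I[idx], H[idx]
        if t_.std() == 0 or i_.std() == 0 or h_.std() == 0:
            boots[i] = np.nan
            continue
        zt, zi, zh = _zscore(t_), _zscore(i_), _zscore(h_)
        a_b = np.linalg.lstsq(np.column_stack([np.ones(n), zt]), zi, rcond=None)[0][1]
        bcoef = np.linalg.lstsq(np.column_stack([np.ones(n), zt, zi]), zh, rcond=None)[0][2]
        boots[i] = a_b * bcoef
    boots = boots[~np.isnan(boots)]
    lo, hi = (np.percentile(boots, [2.5, 97.5]) if len(boots) else (np.nan, np.nan))
    return PathResult(
        a=float(a),
        b=float(b),
        c_prime=float(c_prime),
        indirect=float(a * b),
        indirect_ci=(float(lo), float(hi)),
        p_a=float(p_a),
        p_b=float(p_b),
        p_c_prime=float(p_c),
        n=n,
        n_boot=n_boot,
    )
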