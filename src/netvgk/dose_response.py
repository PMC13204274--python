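"""Dose-response profiling of pathway activity against a driver gene.

Cells are split into expression deciles (equal-count bins; ties at zero —
ubiquitous in single-cell data — are broken by stable input order so the
bins never collapse), per-bin means form the dose-response profile, and a
grid search over bin boundaries fits a flat-below / linear-above
("hockey-stick") model to locate the activation threshold. A Hill-equation
response with a transport-capacity factor tau provides the conceptual
sigmoid the threshold pattern is compared against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["HillParams", "ThresholdFit", "decile_profile", "detect_threshold", "hill_response"]


@dataclass
class HillParams:
    """Parameters of the transport-modulated Hill response.

    R(C) = R0 + tau * (Emax - R0) * C^h / (K^h + C^h); tau in [0, 1] encodes
    transport capacity (tau = 0: transport-deficient, response pinned at
    baseline; tau = 1: fully competent sigmoid).
    """

    R0: float = 0.0
    Emax: float = 1.0
    K: float = 1.0
    h: float = 2.0
    tau: float = 1.0

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError("K must be > 0")
        if self.h <= 0:
            raise ValueError("h must be > 0")
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError("tau must be in [0, 1]")


@dataclass
class ThresholdFit:
    """Hockey-stick fit of a dose-response profile.

    ``breakpoint_percentile`` is the bin boundary (in percent of cells)
    below which the profile is modeled as flat; ``degenerate`` flags an
    all-equal profile for which the breakpoint is undefined.
    """

    breakpoint_percentile: float
    sse_piecewise: float
    sse_linear: float
    bins_below_flat: int
    degenerate: bool = False


def decile_profile(driver, pathway_score, n_bins: int = 10) -> pd.DataFrame:
    """Equal-count binning of cells by driver expression with per-bin means.

    Cells are sorted by (driver value, stable input index) and split into
    ``n_bins`` contiguous bins whose sizes differ by at most one. Returns a
    DataFrame with one row per bin: ``bin`` (1-based), ``mean_driver``,
    ``mean_score``, ``n_cells``.
    """
    driver = np.asarray(driver, dtype=float)
    score = np.asarray(pathway_score, dtype=float)
    if driver.shape != score.shape or driver.ndim != 1:
        raise ValueError("driver and pathway_score must be 1-D arrays of equal length")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if len(driver) < 2 * n_bins:
        raise ValueError(f"need >= {2 * n_bins} cells for {n_bins} bins")
    order = np.argsort(driver, kind="stable")
    chunks = np.array_split(order, n_bins)
    rows = [
        (i + 1, driver[idx].mean(), score[idx].mean(), len(idx))
        for i, idx in enumerate(chunks)
    ]
    return pd.DataFrame(rows, columns=["bin", "mean_driver", "mean_score", "n_cells"])


def _line_sse(x: np.ndarray, y: np.ndarray) -> float:
    """Least-squares straight-line SSE (exact for <= 2 points: 0)."""
    if len(x) < 2:
        return 0.0
    coef = np.polyfit(x, y, 1)
    resid = y - np.polyval(coef, x)
    return float(resid @ resid)


def detect_threshold(profile: pd.DataFrame) -> ThresholdFit:
    """Grid-search breakpoint of a flat-below / linear-above profile.

    For each candidate boundary b (after bin b, b = 1..n_bins-2) the model
    is: bins 1..b at a free constant (their mean), bins b+1..n on a free
    straight line in bin-center percentile; the breakpoint minimizing total
    SSE wins, ties going to the smallest percentile. The straight-line
    (no-breakpoint) SSE is reported alongside; the piecewise SSE never
    exceeds it because the b = 1 model can reproduce any straight line.
    """
    if len(profile) < 4:
        raise ValueError("need >= 4 bins to detect a threshold")
    y = profile["mean_score"].to_numpy(dtype=float)
    n = len(y)
    counts = profile["n_cells"].to_numpy(dtype=float)
    edges = np.concatenate([[0.0], np.cumsum(counts)]) / counts.sum() * 100.0
    centers = 0.5 * (edges[:-1] + edges[1:])  # bin centers in percentile units
    sse_linear = _line_sse(centers, y)
    if np.ptp(y) == 0:
        return ThresholdFit(float("nan"), 0.0, sse_linear, 0, degenerate=True)
    best_b, best_sse = None, np.inf
    for b in range(1, n - 1):
        flat = y[:b] - y[:b].mean()
        sse = float(flat @ flat) + _line_sse(centers[b:], y[b:])
        if sse < best_sse - 1e-12:
            best_sse, best_b = sse, b
    return ThresholdFit(
        breakpoint_percentile=float(edges[best_b]),
        sse_piecewise=best_sse,
        sse_linear=sse_linear,
        bins_below_flat=int(best_b),
    )


def hill_response(C, p: HillParams):
    """Transport-modulated Hill curve R(C); scalar or array concentration.

    Non-decreasing in C and tau; bounded in [R0, R0 + tau*(Emax - R0)].
    With h = 1 this reduces to the Michaelis-Menten form.
    """
    arr = np.asarray(C, dtype=float)
    if (arr < 0).any():
        raise ValueError("concentration must be >= 0")
    ch = arr**p.h
    resp = p.R0 + p.tau * (p.Emax - p.R0) * ch / (p.K**p.h + ch)
    return resp if isinstance(C, np.ndarray) else float(resp) if np.isscalar(C) else resp
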