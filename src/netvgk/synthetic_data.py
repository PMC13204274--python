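"""Synthetic cohorts with planted network, mediation and threshold structure.

Three generators make the whole analysis testable without any download:

* :func:`generate_bulk_cohort` — a longitudinal two-outcome bulk cohort.
  A transport module shares a per-sample latent factor whose loading is set
  so the expected within-module correlation equals the group's ``rho`` (the
  factor model x = lambda*f + sqrt(1-lambda^2)*eps with lambda = sqrt(rho)
  gives a closed-form expected correlation). The module's hub gene loads on
  the factor with loading 1 and additionally drives a set of spoke genes,
  while carrying only a small mean shift between outcomes — a
  high-centrality, low-fold-change gene by construction. The rest of the
  transcriptome is organized into background co-expression modules (real
  transcriptomes are modular; this also stabilizes global clustering). An
  inflammation latent is negatively coupled to the transport factor and the
  (Bernoulli) healing outcome depends on inflammation only, planting a full
  transport -> inflammation -> outcome mediation chain.
* :func:`generate_sc_dataset` — single-cell counts with dropout, a
  zero-inflated driver gene, pathway modules whose activity is flat below a
  planted driver-expression percentile and rises linearly above it, and a
  migration module elevated in driver-high cells.
* :func:`generate_drug_library` — random drug gene sets plus one planted
  set with an exact overlap with a disease signature's down list.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io_preprocess import ExpressionMatrix, GeneSetLibrary, write_expression, write_gmt, write_mtx
from .repurposing import Signature

__all__ = [
    "BulkSimParams",
    "SCSimParams",
    "BulkCohort",
    "SingleCellDataset",
    "generate_bulk_cohort",
    "generate_sc_dataset",
    "generate_drug_library",
    "write_bulk_cohort",
    "write_sc_dataset",
]

# Fixed structural constants (not exposed as knobs; see docs/methods.md):
_PATIENT_SD_FRAC = 0.1  # per-patient, per-gene random intercept, x noise_sd
_INFLAM_MODULE_SIZE = 20  # genes loading on the inflammation latent
_INFLAM_LOADING = 0.6  # kept below the 0.6 network threshold after products
_SPOKE_COUPLING = 0.7  # spoke-hub correlation (group-independent)
_BG_MODULE_SIZE = 13  # background co-expression module size
_BG_RHO = 0.72  # within-background-module correlation
_DRIVER_ZERO_MASS = 0.15  # zero-inflation of the SC driver before dropout
_DRIVER_RATE_SCALE = 3.0  # Poisson rate per unit of driver latent
_ACTIVATION_MAX = 1.5  # saturation of the planted log-rate response
_MIGRATION_MODULE_SIZE = 30
_SC_HOUSEKEEPING = 5  # high-expression genes guaranteeing non-zero cell totals


@dataclass
class BulkSimParams:
    """Study-condition parameters of the longitudinal bulk cohort.

    Defaults emulate the discovery cohort scale: 9 healed + 8 non-healed
    patients with a handful of serial biopsies each (~117 samples), a
    40-gene transport module whose cohesion differs between outcomes
    (rho 0.5 vs 0.8 across the |r| > 0.6 network threshold), a hub with a
    small (non-significant) log2 shift, and a strong negative
    transport -> inflammation coupling (implied standardized slope
    beta/sqrt(beta^2 + noise_sd^2) = -0.92 at the defaults).
    """

    n_patients_healed: int = 9
    n_patients_nonhealed: int = 8
    samples_per_patient_range: tuple[int, int] = (3, 10)
    n_genes: int = 2000
    module_size: int = 40
    hub_gene_extra_links: int = 15
    rho_module_healed: float = 0.5
    rho_module_nonhealed: float = 0.8
    hub_log2_shift: float = 0.1
    beta_transport_inflammation: float = -2.3
    beta_inflammation_outcome: float = -0.3
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_patients_healed", "n_patients_nonhealed", "n_genes", "module_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.hub_gene_extra_links < 0:
            raise ValueError("hub_gene_extra_links must be >= 0")
        lo, hi = self.samples_per_patient_range
        if not (1 <= lo <= hi):
            raise ValueError("samples_per_patient_range must satisfy 1 <= min <= max")
        for name in ("rho_module_healed", "rho_module_nonhealed"):
            rho = getattr(self, name)
            if not (0.0 <= rho < 1.0):
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.module_size >= self.n_genes:
            raise ValueError("module_size must be < n_genes")
        reserved = self.module_size + self.hub_gene_extra_links + _INFLAM_MODULE_SIZE
        if reserved > self.n_genes:
            raise ValueError(f"n_genes={self.n_genes} too small for the planted structure ({reserved})")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")

    @property
    def implied_module_correlation(self) -> dict[str, float]:
        """Expected within-module Pearson r per group (patient-intercept attenuated)."""
        atten = 1.0 / (1.0 + _PATIENT_SD_FRAC**2)
        return {
            "healed": self.rho_module_healed * atten,
            "nonhealed": self.rho_module_nonhealed * atten,
        }

    @property
    def implied_standardized_a(self) -> float:
        """Standardized transport -> inflammation slope implied by the chain."""
        b = self.beta_transport_inflammation
        return b / np.sqrt(b**2 + self.noise_sd**2)


@dataclass
class SCSimParams:
    """Study-condition parameters of the synthetic single-cell dataset."""

    n_cells: int = 3000
    n_genes: int = 1000
    driver_gene: str = "KIF13A"
    dropout_rate: float = 0.1
    threshold_percentile: float = 30.0
    slope_above: float = 0.5
    pathway_module_sizes: tuple[int, ...] = (30, 30, 30)
    migration_shift: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0 or self.n_genes <= 0:
            raise ValueError("n_cells and n_genes must be positive")
        if not (0.0 < self.threshold_percentile < 100.0):
            raise ValueError("threshold_percentile must lie in (0, 100)")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")
        if any(s <= 0 for s in self.pathway_module_sizes):
            raise ValueError("pathway module sizes must be positive")
        reserved = sum(self.pathway_module_sizes) + _MIGRATION_MODULE_SIZE + 1 + _SC_HOUSEKEEPING
        if reserved > self.n_genes:
            raise ValueError(f"n_genes={self.n_genes} too small for the planted modules ({reserved})")


@dataclass
class BulkCohort:
    """Gene x sample log-scale expression with metadata and planted truth."""

    expression: pd.DataFrame  # genes x samples, log scale
    metadata: pd.DataFrame  # per sample: patient, outcome, week
    truth: dict

    def __post_init__(self) -> None:
        if not self.expression.columns.equals(self.metadata.index):
            raise ValueError("metadata rows must match expression columns 1:1")
        outcomes = set(self.metadata["outcome"].unique())
        if not outcomes <= {"healed", "nonhealed"}:
            raise ValueError(f"outcome labels must be healed/nonhealed, got {outcomes}")

    @property
    def genes(self) -> pd.Index:
        return self.expression.index

    @property
    def samples(self) -> pd.Index:
        return self.expression.columns

    def to_expression_matrix(self) -> ExpressionMatrix:
        return ExpressionMatrix(self.expression, space="lognorm")

    def samples_of(self, outcome: str) -> pd.Index:
        return self.metadata.index[self.metadata["outcome"] == outcome]


@dataclass
class SingleCellDataset:
    """Sparse-friendly single-cell counts with planted per-cell truth."""

    counts: pd.DataFrame  # genes x cells, non-negative integers
    cell_truth: pd.DataFrame  # per cell: transport_latent, activation, groups
    gene_sets_truth: dict[str, list[str]]
    lognorm: ExpressionMatrix | None = None

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def cells(self) -> pd.Index:
        return self.counts.columns

    def counts_matrix(self) -> ExpressionMatrix:
        return ExpressionMatrix(self.counts, space="raw_counts")

    def normalize(self, scale: float = 10_000) -> ExpressionMatrix:
        from .io_preprocess import lognormalize

        self.lognorm = lognormalize(self.counts_matrix(), scale=scale)
        return self.lognorm

    def to_anndata(self):
        """Cells x genes AnnData view (lazy import; optional dependency)."""
        import anndata as ad
        from scipy import sparse

        adata = ad.AnnData(
            X=sparse.csr_matrix(self.counts.to_numpy().T),
            obs=self.cell_truth.copy(),
        )
        adata.var_names = [str(g) for g in self.genes]
        adata.obs_names = [str(c) for c in self.cells]
        return adata


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def generate_bulk_cohort(params: BulkSimParams) -> BulkCohort:
    """Simulate the longitudinal two-outcome cohort with planted structure.

    Patients are drawn one at a time: each gets a sample count, biopsy
    weeks, per-sample transport latents f ~ N(0,1) and inflammation latents
    I = beta_TI*f + noise_sd*eps, and a healing outcome drawn
    Bernoulli(logistic(alpha + beta_IH * mean(I))) with alpha centering the
    expected split on the requested group sizes; patients are accepted until
    both group quotas are filled (rejection keeps the outcome genuinely
    stochastic while the cohort composition stays fixed).
    """
    rng = np.random.default_rng(params.seed)
    lo, hi = params.samples_per_patient_range
    n_h, n_n = params.n_patients_healed, params.n_patients_nonhealed
    alpha = float(logit(n_h / (n_h + n_n)))
    patients: list[dict] = []
    quota = {"healed": n_h, "nonhealed": n_n}
    attempts = 0
    while quota["healed"] > 0 or quota["nonhealed"] > 0:
        attempts += 1
        if attempts > 200 * (n_h + n_n):
            raise RuntimeError("patient rejection sampling failed to fill group quotas")
        n_s = int(rng.integers(lo, hi + 1))
        weeks = np.sort(rng.integers(1, 13, size=n_s))
        f = rng.normal(size=n_s)
        infl = params.beta_transport_inflammation * f + params.noise_sd * rng.normal(size=n_s)
        p_heal = float(expit(alpha + params.beta_inflammation_outcome * infl.mean()))
        outcome = "healed" if rng.random() < p_heal else "nonhealed"
        if quota[outcome] == 0:
            continue
        quota[outcome] -= 1
        patients.append({"weeks": weeks, "f": f, "infl": infl, "outcome": outcome})

    pat_ids, sample_ids, outcomes, weeks_all, f_all, infl_all = [], [], [], [], [], []
    for i, pat in enumerate(patients):
        pid = f"P{i + 1:02d}"
        for j in range(len(pat["f"])):
            pat_ids.append(pid)
            sample_ids.append(f"{pid}_S{j + 1:02d}")
            outcomes.append(pat["outcome"])
            weeks_all.append(int(pat["weeks"][j]))
            f_all.append(pat["f"][j])
            infl_all.append(pat["infl"][j])
    n_samples = len(sample_ids)
    f_arr = np.array(f_all)
    infl_arr = np.array(infl_all)
    nonhealed_mask = np.array([o == "nonhealed" for o in outcomes])
    rho_arr = np.where(nonhealed_mask, params.rho_module_nonhealed, params.rho_module_healed)
    lam = np.sqrt(rho_arr)

    genes = _gene_names(params.n_genes)
    idx = np.arange(params.n_genes)
    module_idx = idx[: params.module_size]
    hub_idx = int(module_idx[0])
    extra_idx = idx[params.module_size : params.module_size + params.hub_gene_extra_links]
    infl_start = params.module_size + params.hub_gene_extra_links
    inflam_idx = idx[infl_start : infl_start + _INFLAM_MODULE_SIZE]

    baseline = rng.normal(3.0, 1.0, size=params.n_genes)
    patient_codes = pd.Categorical(pat_ids).codes
    pat_eff = rng.normal(
        0.0, _PATIENT_SD_FRAC * params.noise_sd, size=(params.n_genes, len(patients))
    )
    # standardized per-gene fluctuation; blocks below overwrite their rows
    signal = rng.normal(size=(params.n_genes, n_samples))

    # transport module: shared latent factor, group-specific loading
    # lambda = sqrt(rho) => expected pairwise r = rho
    eps_mod = rng.normal(size=(params.module_size, n_samples))
    signal[module_idx] = lam[None, :] * f_arr[None, :] + np.sqrt(1 - rho_arr)[None, :] * eps_mod
    # the hub loads on the factor with loading 1: its edges to module members
    # (corr sqrt(rho)) clear the 0.6 threshold even in the low-rho group,
    # where member-member pairs do not — a star whose removal destabilizes
    # the healed network's clustering, while in the high-rho group the hub
    # sits inside the module near-clique
    signal[hub_idx] = f_arr

    # hub spokes: non-module genes coupled to the hub at a fixed 0.7
    if len(extra_idx):
        eps_ext = rng.normal(size=(len(extra_idx), n_samples))
        signal[extra_idx] = _SPOKE_COUPLING * f_arr[None, :] + np.sqrt(
            1 - _SPOKE_COUPLING**2
        ) * eps_ext

    # inflammation module: loads on the standardized inflammation latent;
    # the 0.6 loading keeps all its pairwise and cross-module correlations
    # below the network threshold
    infl_sd = np.sqrt(params.beta_transport_inflammation**2 + params.noise_sd**2)
    infl_std = infl_arr / infl_sd
    eps_inf = rng.normal(size=(_INFLAM_MODULE_SIZE, n_samples))
    signal[inflam_idx] = _INFLAM_LOADING * infl_std[None, :] + np.sqrt(
        1 - _INFLAM_LOADING**2
    ) * eps_inf

    # background co-expression modules: real transcriptomes are modular, and
    # this stable triangle/triplet mass keeps the clustering coefficient away
    # from degenerate values so knockout impacts reflect planted topology
    bg_modules: list[list[int]] = []
    bg_start = infl_start + _INFLAM_MODULE_SIZE
    lam_bg = np.sqrt(_BG_RHO)
    i = bg_start
    while i < params.n_genes:
        size = min(_BG_MODULE_SIZE, params.n_genes - i)
        if size < 3:
            break  # leave a remainder of independent genes
        g_lat = rng.normal(size=n_samples)
        eps_bg = rng.normal(size=(size, n_samples))
        signal[i : i + size] = lam_bg * g_lat[None, :] + np.sqrt(1 - _BG_RHO) * eps_bg
        bg_modules.append(list(range(i, i + size)))
        i += size

    expr = baseline[:, None] + pat_eff[:, patient_codes] + params.noise_sd * signal
    expr[hub_idx] += params.hub_log2_shift * nonhealed_mask

    expression = pd.DataFrame(expr, index=genes, columns=sample_ids)
    metadata = pd.DataFrame(
        {"patient": pat_ids, "outcome": outcomes, "week": weeks_all},
        index=pd.Index(sample_ids, name="sample"),
    )
    truth = {
        "module_genes": [genes[i] for i in module_idx],
        "hub_gene": genes[hub_idx],
        "extra_link_genes": [genes[i] for i in extra_idx],
        "inflammation_genes": [genes[i] for i in inflam_idx],
        "transport_latent": pd.Series(f_arr, index=sample_ids),
        "inflammation_latent": pd.Series(infl_arr, index=sample_ids),
        "background_modules": [[genes[i] for i in mod] for mod in bg_modules],
        "implied_module_correlation": params.implied_module_correlation,
        "implied_standardized_a": float(params.implied_standardized_a),
        "params": asdict(params),
    }
    return BulkCohort(expression=expression, metadata=metadata, truth=truth)


def generate_sc_dataset(params: SCSimParams) -> SingleCellDataset:
    """Simulate single-cell counts with a planted activation threshold.

    The driver gene's latent abundance is zero-inflated (point mass 0.25,
    Gamma(2, 1) otherwise); pathway modules stay at baseline for cells whose
    driver latent is below the planted percentile and rise linearly (in
    log-rate, slope ``slope_above`` per latent unit, saturating at a fixed
    cap) above it; the migration
    module is shifted up by ``migration_shift`` in driver-high (top-quartile
    latent) cells. Counts are Poisson draws, then independent per-entry
    dropout at ``dropout_rate``.
    """
    rng = np.random.default_rng(params.seed)
    n_c, n_g = params.n_cells, params.n_genes

    zero = rng.random(n_c) < _DRIVER_ZERO_MASS
    latent = np.where(zero, 0.0, rng.gamma(2.0, 1.0, size=n_c))
    q_thr = np.percentile(latent, params.threshold_percentile)
    # flat below the planted percentile, linear above, saturating (receptor
    # signaling saturates; an uncapped log-rate response would also let hot
    # cells' library sizes swamp normalization)
    activation = np.minimum(
        params.slope_above * np.maximum(0.0, latent - q_thr), _ACTIVATION_MAX
    )
    high_cut = np.percentile(latent, 75.0)
    driver_high = latent > high_cut

    genes = _gene_names(n_g)
    genes[0] = params.driver_gene
    sizes = list(params.pathway_module_sizes)
    cursor = 1
    pathway_names = ["EGF_pathway", "PDGF_pathway", "FGF_pathway"]
    gene_sets: dict[str, list[str]] = {}
    pathway_idx: list[np.ndarray] = []
    for i, size in enumerate(sizes):
        name = pathway_names[i] if i < len(pathway_names) else f"pathway_{i + 1}"
        ids = np.arange(cursor, cursor + size)
        cursor += size
        pathway_idx.append(ids)
        gene_sets[name] = [genes[j] for j in ids]
    mig_idx = np.arange(cursor, cursor + _MIGRATION_MODULE_SIZE)
    cursor += _MIGRATION_MODULE_SIZE
    gene_sets["migration"] = [genes[j] for j in mig_idx]
    hk_idx = np.arange(cursor, cursor + _SC_HOUSEKEEPING)
    cursor += _SC_HOUSEKEEPING

    base = rng.normal(0.0, 0.6, size=n_g)
    # planted modules get moderate marker-like expression so per-cell scores
    # are informative at realistic depth
    for ids in pathway_idx:
        base[ids] = rng.normal(0.3, 0.3, size=len(ids))
    base[mig_idx] = rng.normal(0.3, 0.3, size=len(mig_idx))
    depth = rng.normal(0.0, 0.15, size=n_c)
    log_rate = base[:, None] + depth[None, :]
    for ids in pathway_idx:
        log_rate[ids] += activation[None, :]
    log_rate[mig_idx] += params.migration_shift * driver_high[None, :]
    log_rate[hk_idx] = 3.5 + depth[None, :]

    rate = np.exp(log_rate)
    # driver: Poisson around scale * latent, sharing the cell depth factor;
    # the zero-latent class stays at exactly zero counts
    rate[0] = _DRIVER_RATE_SCALE * latent * np.exp(depth)
    counts = rng.poisson(rate)
    if params.dropout_rate > 0:
        keep = rng.random(size=counts.shape) >= params.dropout_rate
        counts = counts * keep
    cells = [f"C{i:05d}" for i in range(n_c)]
    counts_df = pd.DataFrame(counts.astype(np.int64), index=genes, columns=cells)
    cell_truth = pd.DataFrame(
        {
            "transport_latent": latent,
            "zero_class": zero,
            "activation": activation,
            "driver_high": driver_high,
        },
        index=pd.Index(cells, name="cell"),
    )
    return SingleCellDataset(counts=counts_df, cell_truth=cell_truth, gene_sets_truth=gene_sets)


def generate_drug_library(
    n_sets: int,
    set_size_range: tuple[int, int],
    planted_reversal_overlap: int,
    signature: Signature,
    seed: int,
    background: Sequence[str],
    planted_name: str = "PLANTED_REVERSAL",
) -> GeneSetLibrary:
    """Random drug gene sets plus one planted reversal set.

    The planted set shares exactly ``planted_reversal_overlap`` genes with
    the signature's down list; its remaining members (and all random sets)
    are drawn uniformly from the background universe. GMT-writable.
    """
    if planted_reversal_overlap > len(signature.down):
        raise ValueError(
            f"planted overlap {planted_reversal_overlap} exceeds down-list size {len(signature.down)}"
        )
    lo, hi = set_size_range
    if not (1 <= lo <= hi):
        raise ValueError("set_size_range must satisfy 1 <= min <= max")
    if planted_reversal_overlap > lo:
        lo = planted_reversal_overlap
        if lo > hi:
            raise ValueError("planted overlap exceeds the maximum set size")
    background = list(dict.fromkeys(background))
    rng = np.random.default_rng(seed)
    sets: dict[str, tuple[str, list[str]]] = {}
    for i in range(n_sets):
        size = int(rng.integers(set_size_range[0], set_size_range[1] + 1))
        members = rng.choice(background, size=min(size, len(background)), replace=False)
        sets[f"DRUG_{i + 1:03d}"] = ("random drug signature", sorted(members.tolist()))
    size = int(rng.integers(lo, hi + 1))
    down = list(signature.down)
    shared = rng.choice(down, size=planted_reversal_overlap, replace=False).tolist()
    pool = [g for g in background if g not in set(down)]
    filler = rng.choice(pool, size=size - planted_reversal_overlap, replace=False).tolist()
    sets[planted_name] = ("planted reversal signature", sorted(shared + filler))
    return GeneSetLibrary(sets)


# ---------------------------------------------------------------------------
# writers


def write_bulk_cohort(cohort: BulkCohort, outdir: str | Path) -> None:
    """Expression TSV + metadata TSV + JSON truth file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression(cohort.to_expression_matrix(), outdir / "expression.tsv")
    cohort.metadata.to_csv(outdir / "metadata.tsv", sep="\t")
    truth = {
        k: (v.to_dict() if isinstance(v, pd.Series) else v)
        for k, v in cohort.truth.items()
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1, default=str))


def write_sc_dataset(ds: SingleCellDataset, outdir: str | Path) -> None:
    """MTX + genes.tsv + barcodes.tsv + cell truth TSV + module GMT."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_mtx(ds.counts_matrix(), outdir)
    ds.cell_truth.to_csv(outdir / "cell_truth.tsv", sep="\t")
    lib = GeneSetLibrary({k: ("planted module", v) for k, v in ds.gene_sets_truth.items()})
    write_gmt(lib, outdir / "modules.gmt")
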