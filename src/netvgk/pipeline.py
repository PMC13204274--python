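"""End-to-end orchestration: simulate -> preprocess -> network -> VGK ->
score -> threshold -> validate -> repurpose, with one reproducible report.

The pipeline runs entirely on the synthetic generators (or on user-supplied
tables via the same entry points) and writes every stage's table plus a
single JSON report mirroring the analysis result structure: the
DEG-vs-DI dissociation table, the VGK ranking, coherence/LOPO/path
validation, the decile dose-response profile with its fitted threshold, the
drug-enrichment table, and the reversal simulation. Re-running with the same
config is bit-identical; per-stage seeds derive from the master seed via
``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coexpression import build_network, cohesion
from .dose_response import decile_profile, detect_threshold
from .inference_stats import (
    differential_expression,
    lopo_stability,
    module_coherence_test,
    path_analysis,
    rank_sum_test,
)
from .io_preprocess import select_variable_genes
from .module_scoring import module_zscore
from .repurposing import build_signature, enrich, reversal_subtraction
from .synthetic_data import (
    BulkSimParams,
    SCSimParams,
    generate_bulk_cohort,
    generate_drug_library,
    generate_sc_dataset,
)
from .vgk import differential_impact

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of a full synthetic-cohort analysis run."""

    seed: int = 0
    hvg_bulk: int = 2000
    hvg_sc: int = 1000
    correlation_threshold: float = 0.6
    n_bins: int = 10
    coherence_B: int = 1000
    n_boot: int = 500
    signature_up: int = 200
    signature_down: int = 200
    n_drug_sets: int = 50
    drug_set_size: tuple[int, int] = (50, 150)
    planted_reversal_overlap: int = 30
    reversal_weight: float = 1.0
    bulk: dict = field(default_factory=dict)
    sc: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "drug_set_size" in raw:
            raw["drug_set_size"] = tuple(raw["drug_set_size"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["drug_set_size"] = list(self.drug_set_size)
        return d


def _stage_seeds(master: int, n: int) -> list[int]:
    seqs = np.random.SeedSequence(master).spawn(n)
    return [int(s.generate_state(1)[0] % (2**31)) for s in seqs]


def _round_floats(obj: Any, ndigits: int = 10) -> Any:
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run every stage on a synthetic cohort and write the report bundle.

    Returns the report dict (also written to ``report.json`` along with the
    per-stage TSV tables). Raises with the failing stage named; tables from
    completed stages remain on disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed, 6)
    report: dict[str, Any] = {"version": __version__, "config": config.to_dict()}
    stage = "simulate_bulk"
    try:
        bulk_params = BulkSimParams(**{"seed": seeds[0], **config.bulk})
        cohort = generate_bulk_cohort(bulk_params)
        matrix = cohort.to_expression_matrix()

        stage = "preprocess"
        n_hvg = min(config.hvg_bulk, matrix.shape[0])
        hvg = select_variable_genes(matrix, n_hvg)

        stage = "networks"
        healed = cohort.samples_of("healed")
        nonhealed = cohort.samples_of("nonhealed")
        net_h = build_network(
            matrix.subset_samples(healed), hvg, config.correlation_threshold, source="healed"
        )
        net_n = build_network(
            matrix.subset_samples(nonhealed), hvg, config.correlation_threshold, source="nonhealed"
        )
        report["networks"] = {
            "healed": {
                "n_nodes": net_h.number_of_nodes(),
                "n_edges": net_h.number_of_edges(),
                "cohesion": cohesion(net_h),
            },
            "nonhealed": {
                "n_nodes": net_n.number_of_nodes(),
                "n_edges": net_n.number_of_edges(),
                "cohesion": cohesion(net_n),
            },
        }

        stage = "vgk"
        vgk_table = differential_impact(net_h, net_n)
        vgk_table.to_csv(outdir / "vgk_table.tsv", sep="\t")
        de = differential_expression(matrix, cohort.metadata["outcome"], "nonhealed", "healed")
        de.to_csv(outdir / "de_table.tsv", sep="\t")
        hub = cohort.truth["hub_gene"]
        top10_di = vgk_table.head(10)
        top10_de = de.head(10)
        # two-block comparison table: top drivers by DE significance vs by
        # VGK differential impact, with each gene's stats from both methods
        dissociation = pd.concat(
            [
                pd.DataFrame(
                    {
                        "method": "DEG",
                        "rank": np.arange(1, 11),
                        "log2fc": top10_de["log2fc"],
                        "de_p": top10_de["p_raw"],
                        "di": vgk_table["di"].reindex(top10_de.index),
                        "rank_di": vgk_table["rank_di"].reindex(top10_de.index),
                    }
                ),
                pd.DataFrame(
                    {
                        "method": "VGK",
                        "rank": np.arange(1, 11),
                        "log2fc": de["log2fc"].reindex(top10_di.index),
                        "de_p": de["p_raw"].reindex(top10_di.index),
                        "di": top10_di["di"],
                        "rank_di": top10_di["rank_di"],
                    }
                ),
            ]
        )
        dissociation.to_csv(outdir / "dissociation_table.tsv", sep="\t")
        report["vgk"] = {
            "hub_gene": hub,
            "hub_rank_di": int(vgk_table.loc[hub, "rank_di"]),
            "hub_di": float(vgk_table.loc[hub, "di"]),
            "hub_de_p": float(de.loc[hub, "p_raw"]),
            "hub_de_log2fc": float(de.loc[hub, "log2fc"]),
            "top10_di_genes": top10_di.index.tolist(),
        }

        stage = "validation"
        module = cohort.truth["module_genes"]
        coh = module_coherence_test(matrix, module, B=config.coherence_B, seed=seeds[1])
        lopo = lopo_stability(cohort, module)
        t_score = module_zscore(matrix, module, name="transport").scores
        i_score = module_zscore(matrix, cohort.truth["inflammation_genes"], name="inflammation").scores
        h_bin = (cohort.metadata["outcome"] == "healed").astype(float)
        path = path_analysis(
            t_score.to_numpy(), i_score.to_numpy(), h_bin.to_numpy(),
            n_boot=config.n_boot, seed=seeds[2],
        )
        report["validation"] = {
            "coherence_observed": coh.observed_coherence,
            "coherence_p": coh.p_perm,
            "lopo_cv": lopo.cv,
            "path_a": path.a,
            "path_b": path.b,
            "path_c_prime": path.c_prime,
            "path_indirect": path.indirect,
            "path_indirect_ci": list(path.indirect_ci),
        }

        stage = "single_cell"
        sc_params = SCSimParams(**{"seed": seeds[3], **config.sc})
        ds = generate_sc_dataset(sc_params)
        lognorm = ds.normalize()
        driver = lognorm.values.loc[sc_params.driver_gene]
        egf = module_zscore(lognorm, ds.gene_sets_truth["EGF_pathway"], name="EGF").scores
        profile = decile_profile(driver.to_numpy(), egf.to_numpy(), n_bins=config.n_bins)
        profile.to_csv(outdir / "dose_response_profile.tsv", sep="\t", index=False)
        fit = detect_threshold(profile)
        migration = module_zscore(lognorm, ds.gene_sets_truth["migration"], name="migration").scores
        zero_cells = driver.index[driver == 0]
        hi_cells = driver.index[driver >= driver.quantile(0.75)]
        mig_p = rank_sum_test(migration[hi_cells].to_numpy(), migration[zero_cells].to_numpy())
        report["single_cell"] = {
            "threshold_percentile": fit.breakpoint_percentile,
            "sse_piecewise": fit.sse_piecewise,
            "sse_linear": fit.sse_linear,
            "migration_rank_sum_p": mig_p,
            "n_zero_detection_cells": int(len(zero_cells)),
            "n_high_cells": int(len(hi_cells)),
        }

        stage = "repurposing"
        n_up = min(config.signature_up, int((de["t_stat"] > 0).sum()))
        n_down = min(config.signature_down, int((de["t_stat"] < 0).sum()))
        sig = build_signature(de, n_up=n_up, n_down=n_down)
        lib = generate_drug_library(
            config.n_drug_sets,
            config.drug_set_size,
            min(config.planted_reversal_overlap, n_down),
            sig,
            seed=seeds[4],
            background=list(matrix.genes),
        )
        table = enrich(sig, lib, background=list(matrix.genes))
        table.to_csv(outdir / "enrichment_table.tsv", sep="\t", index=False)
        planted = table[table["drug_set"] == "PLANTED_REVERSAL"]
        rev = reversal_subtraction(
            matrix,
            lib.genes("PLANTED_REVERSAL"),
            sig,
            weight=config.reversal_weight,
            migration_module=module,
        )
        report["repurposing"] = {
            "planted_set_best_rank": int(planted["rank"].min()),
            "planted_set_best_p": float(planted["fisher_p"].min()),
            "n_tests": int(len(table)),
            "reversal_rank_sum_p": rev.rank_sum_p,
            "reversal_score_shift": float(
                rev.after.scores.mean() - rev.before.scores.mean()
            ),
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report = _round_floats(report)
    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    (outdir / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    return report
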