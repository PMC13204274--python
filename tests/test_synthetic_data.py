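import numpy as np
import pandas as pd
import pytest
from scipy import stats

import netvgk as nv
from netvgk.repurposing import Signature


class TestBulkCohort:
    def test_determinism(self):
        p = nv.BulkSimParams(n_genes=120, seed=3)
        a = nv.generate_bulk_cohort(p)
        b = nv.generate_bulk_cohort(p)
        pd.testing.assert_frame_equal(a.expression, b.expression)
        pd.testing.assert_frame_equal(a.metadata, b.metadata)

    def test_group_sizes_and_metadata_alignment(self, small_cohort):
        meta = small_cohort.metadata
        assert meta["patient"].nunique() == 17
        assert (meta.groupby("patient")["outcome"].nunique() == 1).all()
        assert meta.index.equals(small_cohort.expression.columns)
        counts = meta.drop_duplicates("patient")["outcome"].value_counts()
        assert counts["healed"] == 9 and counts["nonhealed"] == 8
        assert set(small_cohort.truth["module_genes"]) <= set(small_cohort.genes)

    def test_module_correlation_recovery_monte_carlo(self):
        # factor-model closed form: expected pairwise r = rho (attenuated by
        # the patient intercept); Monte-Carlo average over 20 seeds
        means = []
        for seed in range(20):
            c = nv.generate_bulk_cohort(
                nv.BulkSimParams(n_genes=120, rho_module_nonhealed=0.8, seed=seed)
            )
            sub = c.expression.loc[
                c.truth["module_genes"], c.samples_of("nonhealed")
            ].to_numpy()
            r = np.corrcoef(sub)
            means.append(r[np.triu_indices_from(r, k=1)].mean())
        assert np.mean(means) == pytest.approx(0.8, abs=0.1)

    def test_null_hub_type_one_error(self):
        # with no planted shift and no outcome coupling the hub's two-sample
        # t-test p (on per-patient means, the exchangeable units) is uniform:
        # the fraction below 0.05 calibrates to 0.05
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            c = nv.generate_bulk_cohort(
                nv.BulkSimParams(
                    n_genes=80,
                    hub_log2_shift=0.0,
                    beta_inflammation_outcome=0.0,
                    samples_per_patient_range=(6, 6),
                    seed=seed,
                )
            )
            hub = c.expression.loc[c.truth["hub_gene"]]
            means = hub.groupby(c.metadata["patient"]).mean()
            outcome = c.metadata.drop_duplicates("patient").set_index("patient")["outcome"]
            hits += (
                stats.ttest_ind(
                    means[outcome == "healed"], means[outcome == "nonhealed"]
                ).pvalue
                < 0.05
            )
        assert hits / n_seeds == pytest.approx(0.05, abs=0.035)

    def test_mediation_slope_recovery(self):
        # latent-level standardized transport->inflammation slope matches the
        # closed form beta/sqrt(beta^2 + noise_sd^2) over 20 seeds
        a_vals = []
        p = nv.BulkSimParams(n_genes=80)
        for seed in range(20):
            c = nv.generate_bulk_cohort(nv.BulkSimParams(n_genes=80, seed=seed))
            T = c.truth["transport_latent"].to_numpy()
            I = c.truth["inflammation_latent"].to_numpy()
            H = (c.metadata["outcome"] == "healed").to_numpy(float)
            a_vals.append(nv.path_analysis(T, I, H, n_boot=10, seed=seed).a)
        assert np.mean(a_vals) == pytest.approx(p.implied_standardized_a, abs=0.1)

    def test_invalid_params(self):
        with pytest.raises(ValueError, match="module_size"):
            nv.BulkSimParams(n_genes=30, module_size=40)
        with pytest.raises(ValueError, match="rho"):
            nv.BulkSimParams(rho_module_healed=1.0)

    def test_writer_round_trip(self, small_cohort, tmp_path):
        nv.write_bulk_cohort(small_cohort, tmp_path)
        m = nv.read_expression(tmp_path / "expression.tsv", space="lognorm")
        np.testing.assert_allclose(
            m.values.to_numpy(), small_cohort.expression.to_numpy(), rtol=1e-6
        )
        meta = pd.read_csv(tmp_path / "metadata.tsv", sep="\t", index_col=0)
        assert list(meta.columns) == ["patient", "outcome", "week"]
        assert (tmp_path / "truth.json").exists()


class TestSCDataset:
    def test_determinism(self):
        p = nv.SCSimParams(n_cells=200, seed=9)
        a = nv.generate_sc_dataset(p)
        b = nv.generate_sc_dataset(p)
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_counts_non_negative_integers(self, sc_dataset):
        vals = sc_dataset.counts.to_numpy()
        assert (vals >= 0).all()
        assert np.issubdtype(vals.dtype, np.integer)

    def test_lognorm_only_after_normalize(self):
        ds = nv.generate_sc_dataset(nv.SCSimParams(n_cells=150, seed=2))
        assert ds.lognorm is None
        out = ds.normalize()
        assert out.space == "lognorm"
        assert ds.lognorm is out

    def test_null_construction_uncorrelated(self):
        # no dropout, flat response: pathway score independent of driver
        from netvgk.module_scoring import module_zscore

        ds = nv.generate_sc_dataset(
            nv.SCSimParams(
                n_cells=5000, dropout_rate=0.0, slope_above=0.0, migration_shift=0.0, seed=4
            )
        )
        ln = ds.normalize()
        driver = ln.values.loc[ds.counts.index[0]]
        score = module_zscore(ln, ds.gene_sets_truth["EGF_pathway"]).scores
        rho = stats.spearmanr(driver, score)[0]
        assert abs(rho) < 0.05

    def test_zero_detection_class_exists_without_dropout(self):
        ds = nv.generate_sc_dataset(nv.SCSimParams(n_cells=1000, dropout_rate=0.0, seed=1))
        frac_zero = (ds.counts.loc[ds.counts.index[0]] == 0).mean()
        assert frac_zero > 0.1

    def test_invalid_params(self):
        with pytest.raises(ValueError, match="threshold_percentile"):
            nv.SCSimParams(threshold_percentile=0.0)
        with pytest.raises(ValueError, match="dropout"):
            nv.SCSimParams(dropout_rate=1.0)

    def test_writer_outputs(self, sc_dataset, tmp_path):
        nv.write_sc_dataset(sc_dataset, tmp_path)
        back = nv.read_mtx(
            tmp_path / "matrix.mtx", tmp_path / "genes.tsv", tmp_path / "barcodes.tsv"
        )
        np.testing.assert_allclose(
            back.values.to_numpy(), sc_dataset.counts.to_numpy()
        )
        lib = nv.read_gmt(tmp_path / "modules.gmt")
        assert set(lib.names()) == set(sc_dataset.gene_sets_truth)


class TestDrugLibrary:
    def _signature(self, background):
        return Signature(up=background[:200], down=background[200:400])

    def test_planted_overlap_exact_and_gmt_round_trip(self, tmp_path):
        bg = [f"g{i}" for i in range(2000)]
        sig = self._signature(bg)
        lib = nv.generate_drug_library(10, (50, 100), 30, sig, seed=0, background=bg)
        planted = set(lib.genes("PLANTED_REVERSAL"))
        assert len(planted & set(sig.down)) == 30
        nv.write_gmt(lib, tmp_path / "lib.gmt")
        assert nv.read_gmt(tmp_path / "lib.gmt") == lib

    def test_planted_set_ranks_first(self):
        # overlap 30/100 vs signature 200 in background 2000: the planted set
        # dominates 50 random sets by Fisher p, across 20 seeds
        bg = [f"g{i}" for i in range(2000)]
        sig = self._signature(bg)
        for seed in range(20):
            lib = nv.generate_drug_library(50, (100, 100), 30, sig, seed=seed, background=bg)
            tab = nv.enrich(sig, lib, bg)
            assert tab.iloc[0]["drug_set"] == "PLANTED_REVERSAL"
            assert tab.iloc[0]["direction"] == "DOWN"

    def test_zero_overlap_null_behavior(self):
        # planted overlap 0: the planted set's DOWN p is an ordinary null draw
        bg = [f"g{i}" for i in range(2000)]
        sig = self._signature(bg)
        ps = []
        for seed in range(30):
            lib = nv.generate_drug_library(0, (100, 100), 0, sig, seed=seed, background=bg)
            tab = nv.enrich(sig, lib, bg).set_index(["drug_set", "direction"])
            ps.append(tab.loc[("PLANTED_REVERSAL", "DOWN"), "fisher_p"])
        assert np.median(ps) > 0.2  # not systematically small

    def test_overlap_exceeding_signature_rejected(self):
        bg = [f"g{i}" for i in range(600)]
        sig = self._signature(bg)
        with pytest.raises(ValueError, match="overlap"):
            nv.generate_drug_library(5, (50, 100), 300, sig, seed=0, background=bg)
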