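import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from statsmodels.stats.multitest import multipletests

import netvgk as nv

from conftest import make_matrix


class TestBHAdjust:
    def test_hand_step_up(self):
        np.testing.assert_allclose(nv.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert nv.bh_adjust([0.4])[0] == pytest.approx(0.4)

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(nv.bh_adjust([0.2] * 5), [0.2] * 5)

    def test_matches_statsmodels(self, rng):
        for _ in range(20):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(nv.bh_adjust(p), ref, atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_dominates_raw_p_and_in_range(self, p):
        q = nv.bh_adjust(p)
        assert (q >= np.asarray(p) - 1e-15).all()
        assert (q <= 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            nv.bh_adjust([0.5, 1.5])


class TestRankSumTest:
    def test_fully_separated_triples(self):
        # exhaustive: 2 of the 20 assignments are at least as extreme
        assert nv.rank_sum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_multisets_p_one(self):
        assert nv.rank_sum_test([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_symmetry_in_arguments(self, rng):
        a, b = rng.normal(size=8), rng.normal(size=20)
        assert nv.rank_sum_test(a, b) == pytest.approx(nv.rank_sum_test(b, a))

    def test_matches_enumeration_oracle_small_untied(self, rng):
        from scipy import stats

        for _ in range(15):
            na, nb = int(rng.integers(2, 5)), int(rng.integers(2, 5))
            a = rng.normal(size=na)
            b = rng.normal(size=nb)
            pooled = np.concatenate([a, b])
            ranks = stats.rankdata(pooled)
            obs = abs(ranks[:na].sum() - na * (na + nb + 1) / 2)
            hits = sum(
                1
                for combo in itertools.combinations(range(na + nb), na)
                if abs(ranks[list(combo)].sum() - na * (na + nb + 1) / 2) >= obs - 1e-9
            )
            from math import comb

            assert nv.rank_sum_test(a, b) == pytest.approx(hits / comb(na + nb, na))

    def test_large_sample_against_scipy(self, rng):
        from scipy import stats

        a, b = rng.normal(size=30), rng.normal(0.8, 1, size=25)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", use_continuity=False).pvalue
        assert nv.rank_sum_test(a, b) == pytest.approx(ref, abs=1e-6)


class TestDifferentialExpression:
    def _matrix(self, rng, shift=0.0, n1=6, n2=6, n_genes=30):
        vals = rng.normal(size=(n_genes, n1 + n2))
        vals[0, :n1] += shift
        m = make_matrix(vals, space="log2")
        labels = pd.Series(["case"] * n1 + ["ctrl"] * n2, index=m.samples)
        return m, labels

    def test_log2fc_arithmetic(self):
        vals = np.array([[4.0, 4.0, 2.0, 2.0], [1.0, 1.0, 1.0, 1.0]])
        m = make_matrix(vals, space="log2")
        labels = pd.Series(["a", "a", "b", "b"], index=m.samples)
        de = nv.differential_expression(m, labels, "a", "b")
        assert de.loc["g0", "log2fc"] == pytest.approx(2.0)
        assert de.loc["g0", "fold_change"] == pytest.approx(4.0)
        assert de.loc["g0", "direction"] == "Up"

    def test_fold_change_identical_across_methods(self, rng):
        m, labels = self._matrix(rng, shift=1.0)
        welch = nv.differential_expression(m, labels, "case", "ctrl", method="welch")
        mod = nv.differential_expression(m, labels, "case", "ctrl", method="moderated")
        pd.testing.assert_series_equal(
            welch["log2fc"].sort_index(), mod["log2fc"].sort_index()
        )

    def test_null_p_uniform(self):
        # identical group distributions: fraction p < 0.05 near 0.05
        hits = total = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            m, labels = self._matrix(rng, shift=0.0, n_genes=1)
            de = nv.differential_expression(m, labels, "case", "ctrl")
            hits += de["p_raw"].iloc[0] < 0.05
            total += 1
        assert hits / total == pytest.approx(0.05, abs=0.035)

    def test_moderated_detects_planted_shift(self, rng):
        m, labels = self._matrix(rng, shift=3.0, n_genes=100)
        de = nv.differential_expression(m, labels, "case", "ctrl", method="moderated")
        assert de.index[0] == "g0"
        assert de.loc["g0", "p_bh"] < 0.01
        assert (de["p_bh"] >= de["p_raw"] - 1e-15).all()

    def test_small_group_rejected(self, rng):
        m, labels = self._matrix(rng, n1=1, n2=5)
        with pytest.raises(ValueError, match=">= 2"):
            nv.differential_expression(m, labels, "case", "ctrl")


class TestModuleCoherence:
    def test_add_one_p_formula(self, rng):
        # planted perfect module always beats every null draw: p = 1/(B+1)
        lat = rng.normal(size=30)
        module = np.vstack([lat + 0.01 * rng.normal(size=30) for _ in range(5)])
        noise = rng.normal(size=(60, 30))
        m = make_matrix(np.vstack([module, noise]))
        res = nv.module_coherence_test(m, [f"g{i}" for i in range(5)], B=99, seed=1)
        assert res.p_perm == pytest.approx(1 / 100)
        assert res.observed_coherence > 0.9

    def test_null_module_p_uniform(self):
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(1000 + seed)
            m = make_matrix(rng.normal(size=(60, 25)))
            res = nv.module_coherence_test(m, [f"g{i}" for i in range(6)], B=99, seed=seed)
            hits += res.p_perm < 0.05
        assert hits / 200 == pytest.approx(0.05, abs=0.035)

    def test_module_too_small(self, rng):
        m = make_matrix(rng.normal(size=(10, 10)))
        with pytest.raises(ValueError, match=">= 2"):
            nv.module_coherence_test(m, ["g0"])


class TestLopoStability:
    def test_homogeneous_strong_cohort_is_stable(self):
        # strong outcome coupling -> homogeneous patient effects -> low CV
        cohort = nv.generate_bulk_cohort(
            nv.BulkSimParams(n_genes=300, beta_inflammation_outcome=-2.0, seed=5)
        )
        res = nv.lopo_stability(cohort, cohort.truth["module_genes"])
        assert res.cv < 0.5
        assert len(res.effects) == 17 - len(res.skipped)

    def test_duplicated_patient_fold_symmetry(self, small_cohort):
        # cloning patient P under a new ID makes the folds "exclude P" and
        # "exclude clone" operate on identical sample multisets, so their
        # effect sizes must coincide exactly
        module = small_cohort.truth["module_genes"]
        pat = small_cohort.metadata["patient"].iloc[0]
        idx = small_cohort.metadata.index[small_cohort.metadata["patient"] == pat]
        clone_expr = small_cohort.expression[idx].copy()
        clone_expr.columns = [f"dup_{c}" for c in idx]
        meta_clone = small_cohort.metadata.loc[idx].copy()
        meta_clone.index = pd.Index(clone_expr.columns, name="sample")
        meta_clone["patient"] = "PDUP"
        cohort2 = nv.BulkCohort(
            expression=pd.concat([small_cohort.expression, clone_expr], axis=1),
            metadata=pd.concat([small_cohort.metadata, meta_clone]),
            truth=small_cohort.truth,
        )
        res2 = nv.lopo_stability(cohort2, module)
        assert res2.effects[pat] == pytest.approx(res2.effects["PDUP"], abs=1e-12)


class TestPathAnalysis:
    def test_standardized_a_equals_correlation(self, rng):
        T = rng.normal(size=200)
        I = -0.5 * T + rng.normal(size=200)
        H = (rng.random(200) < 0.5).astype(float)
        res = nv.path_analysis(T, I, H, n_boot=10, seed=0)
        r = np.corrcoef(T, I)[0, 1]
        assert res.a == pytest.approx(r, abs=1e-10)

    def test_strong_negative_slope_recovery(self, rng):
        n = 500
        T = rng.normal(size=n)
        I = -0.9 * T + np.sqrt(1 - 0.81) * rng.normal(size=n)
        H = (rng.random(n) < 0.5).astype(float)
        res = nv.path_analysis(T, I, H, n_boot=50, seed=0)
        assert res.a == pytest.approx(-0.9, abs=0.05)

    def test_null_outcome_small_coefficients(self, rng):
        n = 500
        T = rng.normal(size=n)
        I = 0.3 * T + rng.normal(size=n)
        H = (rng.random(n) < 0.5).astype(float)
        res = nv.path_analysis(T, I, H, n_boot=300, seed=1)
        assert abs(res.b) < 0.1 and abs(res.c_prime) < 0.1
        lo, hi = res.indirect_ci
        assert lo < 0 < hi

    def test_collinear_rejected(self, rng):
        T = rng.normal(size=50)
        with pytest.raises(ValueError, match="collinear"):
            nv.path_analysis(T, T * 2 + 1e-9, (T > 0).astype(float))
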