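"""Variance partitioning, behavior clustering, direction tests."""

import numpy as np
import pandas as pd
import pytest

from atacrna import behavior as bh


def make_cov(y, p, e, gene="g"):
    return {"gene_id": gene, "expression": np.asarray(y, dtype=float),
            "promoter_acc": np.asarray(p, dtype=float),
            "enhancer_acc": np.asarray(e, dtype=float)}


class TestBuildCovariates:
    def _tables(self):
        samples = list("abcdef")
        expr = pd.DataFrame([[1.0] * 6], index=["g"], columns=samples)
        prom = pd.DataFrame([[2.0] * 6], index=["g"], columns=samples)
        peaks = pd.DataFrame(np.arange(12, dtype=float).reshape(2, 6),
                             index=["r1", "r2"], columns=samples)
        return expr, prom, peaks

    def test_no_regions_gives_zero_enhancer_vector(self):
        expr, prom, peaks = self._tables()
        cap = pd.DataFrame(columns=["gene_id", "region_id", "d"])
        cov = bh.build_covariates("g", expr, prom, peaks, cap)
        assert np.array_equal(cov["enhancer_acc"], np.zeros(6))

    def test_single_region_at_zero_distance(self):
        expr, prom, peaks = self._tables()
        cap = pd.DataFrame({"gene_id": ["g"], "region_id": ["r1"], "d": [0]})
        cov = bh.build_covariates("g", expr, prom, peaks, cap)
        assert np.allclose(cov["enhancer_acc"],
                           np.exp(-0.5) * peaks.loc["r1"].to_numpy())

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(7)
        samples = list("abcdef")
        expr = pd.DataFrame([[1.0] * 6], index=["g"], columns=samples)
        prom = expr.copy()
        peaks = pd.DataFrame(rng.random((10, 6)) * 100,
                             index=[f"r{i}" for i in range(10)],
                             columns=samples)
        cap = pd.DataFrame({"gene_id": "g",
                            "region_id": [f"r{i}" for i in range(10)],
                            "d": rng.integers(0, 100_001, 10)})
        cov = bh.build_covariates("g", expr, prom, peaks, cap)
        expected = np.zeros(6)
        for row in cap.itertuples(index=False):
            expected += np.exp(-(0.5 + 4 * row.d / 1e5)) \
                * peaks.loc[row.region_id].to_numpy()
        assert np.allclose(cov["enhancer_acc"], expected, atol=1e-10)


class TestVariancePartition:
    def test_perfect_promoter_predictor(self):
        rng = np.random.default_rng(0)
        p = rng.random(6)
        prof = bh.variance_partition(make_cov(p, p, rng.random(6)))
        assert prof["r2_promoter"] == pytest.approx(1.0)
        assert prof["r2_full"] == pytest.approx(1.0)
        assert prof["m_enh"] == pytest.approx(0.0, abs=1e-9)
        assert prof["m_unexpl"] == pytest.approx(0.0, abs=1e-9)

    def test_chance_fit_of_pure_noise_matches_df_ratio(self):
        # full model: 3 of 5 centered df -> E[R2] ~ 0.6
        rng = np.random.default_rng(29)
        r2 = [bh.variance_partition(
            make_cov(rng.normal(size=6), rng.normal(size=6),
                     rng.normal(size=6)))["r2_full"]
            for _ in range(500)]
        assert np.mean(r2) == pytest.approx(0.6, abs=0.05)

    def test_interaction_only_signal_yields_high_combo(self):
        # with n=6 the two single-predictor models absorb ~0.2 R2 each
        # by chance, so interaction-only signal leaves E[m_combo] ~ 0.45
        # versus ~0.2 under pure noise; assert a clear separation
        rng = np.random.default_rng(31)
        signal, noise = [], []
        for _ in range(50):
            p, e = rng.normal(size=6), rng.normal(size=6)
            y = (p - p.mean()) * (e - e.mean())
            signal.append(bh.variance_partition(make_cov(y, p, e))["m_combo"])
            noise.append(bh.variance_partition(
                make_cov(rng.normal(size=6), p, e))["m_combo"])
        assert np.mean(signal) > 0.35
        assert np.mean(signal) > 1.5 * np.mean(noise)

    def test_nesting_invariant(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            prof = bh.variance_partition(
                make_cov(rng.normal(size=8), rng.normal(size=8),
                         rng.normal(size=8)))
            assert prof["r2_full"] >= prof["r2_promoter"] - 1e-10
            assert prof["r2_full"] >= prof["r2_enhancer"] - 1e-10
            assert min(prof["m_enh"], prof["m_prom"],
                       prof["m_combo"]) >= 0
            assert prof["m_unexpl"] + prof["r2_full"] == pytest.approx(1.0)

    def test_zero_variance_expression_flagged(self):
        assert bh.variance_partition(
            make_cov(np.ones(6), np.arange(6), np.arange(6))) is None

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            bh.variance_partition(make_cov(np.arange(4), np.arange(4),
                                           np.arange(4)))


def archetype_profiles(rng, n_per=25, noise=0.03):
    rows = []
    centers = {"enhancer_centric": [0.8, 0.05, 0.02, 0.05],
               "promoter_centric": [0.05, 0.8, 0.02, 0.05],
               "combo_centric": [0.6, 0.6, 0.5, 0.05],
               "unexplained": [0.3, 0.3, 0.15, 0.6]}
    gid = 0
    for label, c in centers.items():
        for _ in range(n_per):
            m = np.clip(np.asarray(c) + rng.normal(0, noise, 4), 0, 1)
            rows.append({"gene_id": f"g{gid}", "truth": label,
                         "r2_full": 1 - m[3], "r2_promoter": np.nan,
                         "r2_enhancer": np.nan,
                         "m_enh": m[0], "m_prom": m[1], "m_combo": m[2],
                         "m_unexpl": m[3]})
            gid += 1
    return pd.DataFrame(rows).set_index("gene_id")


class TestClusterBehaviors:
    def test_separable_archetypes_recovered(self):
        rng = np.random.default_rng(37)
        prof = archetype_profiles(rng)
        out = bh.cluster_behaviors(prof, k=4)
        assert (out["behavior_label"] == out["truth"]).all()
        assert set(out["behavior_label"]) == set(bh.BEHAVIOR_LABELS.values())

    def test_duplicate_rows_cocluster(self):
        rng = np.random.default_rng(1)
        prof = archetype_profiles(rng)
        dup = prof.iloc[[0]].rename(index={prof.index[0]: "dup"})
        out = bh.cluster_behaviors(pd.concat([prof, dup]), k=4)
        assert out.loc["dup", "cluster_id"] == out.iloc[0]["cluster_id"]

    def test_gene_order_permutation_invariant_labels(self):
        rng = np.random.default_rng(3)
        prof = archetype_profiles(rng)
        out1 = bh.cluster_behaviors(prof, k=4)["behavior_label"]
        perm = prof.sample(frac=1.0, random_state=5)
        out2 = bh.cluster_behaviors(perm, k=4)["behavior_label"]
        assert out1.sort_index().equals(out2.sort_index())

    def test_too_few_genes_rejected(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError):
            bh.cluster_behaviors(archetype_profiles(rng, n_per=1).head(3),
                                 k=4)


class TestSharedDirectionTest:
    def test_balanced_table_is_independent(self):
        res = bh.chi_square_2x2(np.array([[50, 50], [50, 50]]))
        assert res["statistic"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)

    def test_perfect_association(self):
        res = bh.chi_square_2x2(np.array([[100, 0], [0, 100]]))
        assert res["p"] < 1e-20

    def test_null_calibration(self):
        rng = np.random.default_rng(41)
        ps = []
        for _ in range(200):
            signs = rng.choice([-1.0, 1.0], size=(3, 1000))
            ps.append(bh.shared_direction_test(*signs)["p"])
        # 200 reps: binomial 3-sigma band around the nominal 0.05
        assert 0.02 <= np.mean(np.asarray(ps) < 0.05) <= 0.097


class TestCrossDatasetDirection:
    def _lfc(self, rng, n=500):
        return pd.Series(rng.normal(size=n),
                         index=[f"g{i}" for i in range(n)])

    def test_identical_datasets_share_perfectly(self):
        lfc = self._lfc(np.random.default_rng(0))
        res = bh.cross_dataset_direction_test(lfc, lfc)
        assert res["shared_fraction"] == 1.0 and res["p"] < 1e-20

    def test_negated_dataset_is_perfectly_associated(self):
        lfc = self._lfc(np.random.default_rng(1))
        res = bh.cross_dataset_direction_test(lfc, -lfc)
        assert res["shared_fraction"] == 0.0 and res["p"] < 1e-20

    def test_random_signs_mostly_null(self):
        rng = np.random.default_rng(43)
        nonsig = 0
        for _ in range(100):
            lfc1 = self._lfc(rng)
            lfc2 = pd.Series(rng.normal(size=500), index=lfc1.index)
            if bh.cross_dataset_direction_test(lfc1, lfc2)["p"] > 0.05:
                nonsig += 1
        assert nonsig >= 90

    def test_missing_genes_dropped(self):
        lfc = self._lfc(np.random.default_rng(2))
        res = bh.cross_dataset_direction_test(lfc, lfc.iloc[:300])
        assert res["n_genes"] <= 300


class TestClusterEffectSizes:
    def test_shifted_cluster_detected(self):
        rng = np.random.default_rng(0)
        labels = pd.Series(["a"] * 50 + ["b"] * 50 + ["c"] * 50,
                           index=[f"g{i}" for i in range(150)])
        lfc = pd.Series(np.concatenate([rng.normal(0, 1, 100),
                                        rng.normal(4, 1, 50)]),
                        index=labels.index)
        res = bh.cluster_effect_size_summary(labels, lfc)
        assert res["anova_p"] < 1e-6
        tk = res["tukey"]
        c_rows = tk[(tk["group1"] == "c") | (tk["group2"] == "c")]
        assert (c_rows["p-adj"].astype(float) < 0.05).all()

    def test_null_tukey_mostly_non_significant(self):
        rng = np.random.default_rng(47)
        labels = pd.Series(["a"] * 40 + ["b"] * 40 + ["c"] * 40,
                           index=[f"g{i}" for i in range(120)])
        hits = 0
        for _ in range(50):
            lfc = pd.Series(rng.normal(size=120), index=labels.index)
            tk = bh.cluster_effect_size_summary(labels, lfc)["tukey"]
            if (tk["p-adj"].astype(float) > 0.05).all():
                hits += 1
        assert hits >= 40

    def test_single_cluster_skips_anova(self):
        labels = pd.Series(["a"] * 10, index=[f"g{i}" for i in range(10)])
        lfc = pd.Series(np.arange(10.0), index=labels.index)
        res = bh.cluster_effect_size_summary(labels, lfc)
        assert np.isnan(res["anova_p"]) and res["tukey"] is None
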