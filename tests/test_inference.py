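"""Permutation tests, MWU, BH, chi-square, bootstrap, arm sex bias."""

import numpy as np
import pandas as pd
import pytest

import testisx as tx
from oracles import bh_stepup, mwu_exact_enumeration


class TestMwu:
    def test_fully_separated_small_sample(self):
        u, p = tx.mwu([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(1 / 3)

    def test_identical_samples_p_one(self):
        _, p = tx.mwu([5, 5, 5], [5, 5, 5])
        assert p == pytest.approx(1.0)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=8), rng.normal(size=5)
        u_xy, p_xy = tx.mwu(x, y)
        u_yx, p_yx = tx.mwu(y, x)
        assert u_xy + u_yx == len(x) * len(y)
        assert p_xy == pytest.approx(p_yx)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tx.mwu([], [1.0])

    def test_exact_path_matches_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            n_x, n_y = rng.integers(2, 7, size=2)
            x = rng.normal(size=n_x)  # continuous, no ties
            y = rng.normal(size=n_y)
            u, p = tx.mwu(x, y)
            u_ref, p_ref = mwu_exact_enumeration(x, y)
            assert u == pytest.approx(u_ref)
            assert p == pytest.approx(p_ref)


class TestPairwisePermutation:
    @staticmethod
    def _frame(values_a, values_b):
        values = pd.Series(np.concatenate([values_a, values_b]))
        labels = pd.Series(["a"] * len(values_a) + ["b"] * len(values_b))
        return values, labels

    def test_floor_at_one_over_iterations(self):
        values, labels = self._frame(np.arange(20) + 100.0, np.arange(20))
        res = tx.pairwise_permutation_test(values, labels, "a", "b", n_iter=999, seed=0)
        assert res.permutation_p == pytest.approx(1 / 1000)

    def test_same_type_rejected(self):
        values, labels = self._frame([1.0, 2.0], [3.0, 4.0])
        with pytest.raises(ValueError):
            tx.pairwise_permutation_test(values, labels, "a", "a")

    def test_reproducible(self):
        rng = np.random.default_rng(3)
        values, labels = self._frame(rng.normal(size=30), rng.normal(size=30))
        r1 = tx.pairwise_permutation_test(values, labels, "a", "b", n_iter=500, seed=7)
        r2 = tx.pairwise_permutation_test(values, labels, "a", "b", n_iter=500, seed=7)
        assert r1.permutation_p == r2.permutation_p

    def test_null_p_is_roughly_uniform(self):
        rng = np.random.default_rng(4)
        ps = []
        for run in range(100):
            values, labels = self._frame(rng.normal(size=50), rng.normal(size=50))
            ps.append(
                tx.pairwise_permutation_test(
                    values, labels, "a", "b", n_iter=400, seed=run
                ).permutation_p
            )
        assert 0.25 <= np.mean(np.array(ps) <= 0.5) <= 0.75


class TestMeanPermutation:
    def test_shifted_type_declared_different(self):
        rng = np.random.default_rng(5)
        values = pd.Series(rng.normal(0, 1, 1500))
        values.iloc[:150] += 3.0
        labels = pd.Series(["t"] * 150 + ["rest"] * 1350)
        res = tx.mean_permutation_test(values, labels, "t", n_iter=300, seed=1)
        assert res.significant_fraction >= 0.95 and res.different

    def test_null_type_rarely_significant(self):
        rng = np.random.default_rng(6)
        values = pd.Series(rng.normal(0, 1, 1500))
        labels = pd.Series(["t"] * 150 + ["rest"] * 1350)
        res = tx.mean_permutation_test(values, labels, "t", n_iter=300, seed=1)
        assert res.significant_fraction <= 0.05 and not res.different

    def test_zero_iterations_rejected(self):
        values = pd.Series([1.0, 2, 3, 4])
        labels = pd.Series(["t", "t", "r", "r"])
        with pytest.raises(ValueError):
            tx.mean_permutation_test(values, labels, "t", n_iter=0)


class TestBhFdr:
    def test_single_value_unchanged(self):
        assert tx.bh_fdr([0.04])[0] == pytest.approx(0.04)

    def test_stepup_by_hand(self):
        np.testing.assert_allclose(tx.bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_ones(self):
        np.testing.assert_allclose(tx.bh_fdr([1.0, 1.0]), [1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            tx.bh_fdr([0.5, 1.2])

    def test_matches_stepup_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            p = rng.uniform(size=int(rng.integers(1, 21)))
            np.testing.assert_allclose(tx.bh_fdr(p), bh_stepup(p), rtol=1e-12)


class TestChi2:
    def test_no_association(self):
        chi2, df, p = tx.chi2_independence([[10, 10], [10, 10]])
        assert chi2 == 0 and p == pytest.approx(1.0)

    def test_hand_computed_value(self):
        chi2, df, _ = tx.chi2_independence([[20, 10], [10, 20]])
        assert df == 1
        assert chi2 == pytest.approx(20 / 3, rel=1e-6)  # 4 * 5^2 / 15

    def test_identical_proportions_give_zero(self):
        chi2, _, _ = tx.chi2_independence([[30, 15, 5], [60, 30, 10]])
        assert chi2 == pytest.approx(0.0, abs=1e-9)

    def test_zero_expected_rejected(self):
        with pytest.raises(ValueError):
            tx.chi2_independence([[5, 0], [7, 0]])


class TestBootstrap:
    def test_constant_vector(self):
        lo, hi = tx.bootstrap_ci_mean([4.2] * 10, seed=0)
        assert lo == pytest.approx(4.2) and hi == pytest.approx(4.2)

    def test_degenerate_level_rejected(self):
        with pytest.raises(ValueError):
            tx.bootstrap_ci_mean([1.0, 2.0], level=1.0)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            tx.bootstrap_ci_mean([1.0])

    def test_coverage_of_true_mean(self):
        rng = np.random.default_rng(8)
        covered = 0
        runs = 1000
        for run in range(runs):
            lo, hi = tx.bootstrap_ci_mean(
                rng.normal(0, 1, 100), n_boot=300, seed=run
            )
            covered += lo <= 0.0 <= hi
        assert 0.92 <= covered / runs <= 0.97


class TestArmSexBias:
    def test_identical_panels_flag_nothing(self, bulk_x_halved):
        panel, ann, tpm = bulk_x_halved
        # duplicate female samples as a fake two-sex panel: no sex effect
        females = panel.meta.index[panel.meta["sex"] == "female"]
        sub = tpm.subset_obs(females)
        meta = panel.meta.loc[females].copy()
        meta["sex"] = ["male", "female"] * (len(females) // 2)
        expressed = tx.expressed_genes(panel.counts, 2)
        out = tx.arm_sex_bias(sub, ann, meta, expressed, seed=0)
        assert not out["male_reduced"].any()

    def test_halved_male_x_flags_x_only_among_majors(self, bulk_x_halved):
        panel, ann, tpm = bulk_x_halved
        expressed = tx.expressed_genes(panel.counts, 2)
        out = tx.arm_sex_bias(tpm, ann, panel.meta, expressed, seed=0)
        assert out.loc["X", "male_reduced"]
        for arm in ["2L", "2R", "3L", "3R"]:
            assert not out.loc[arm, "male_reduced"]

    def test_ci_brackets_mean(self, bulk_x_halved):
        panel, ann, tpm = bulk_x_halved
        expressed = tx.expressed_genes(panel.counts, 2)
        out = tx.arm_sex_bias(tpm, ann, panel.meta, expressed, seed=0)
        assert (out["male_ci_lo"] <= out["male_mean"]).all()
        assert (out["male_mean"] <= out["male_ci_hi"]).all()

    def test_single_replicate_rejected(self, bulk_x_halved):
        panel, ann, tpm = bulk_x_halved
        keep = list(panel.meta.index[:1]) + list(
            panel.meta.index[panel.meta["sex"] == "female"]
        )
        with pytest.raises(ValueError):
            tx.arm_sex_bias(
                tpm.subset_obs(keep),
                ann,
                panel.meta.loc[keep],
                tx.expressed_genes(panel.counts, 2),
            )


class TestSexBiasClasses:
    def test_counts_conserved(self, bulk_x_halved):
        panel, ann, _ = bulk_x_halved
        labels = panel.sex_bias_truth
        table = tx.sex_bias_classes(labels, ann)
        assert table.to_numpy().sum() == len(labels)

    def test_unknown_class_rejected(self, bulk_x_halved):
        _, ann, _ = bulk_x_halved
        labels = pd.Series(["up"], index=ann.genes[:1])
        with pytest.raises(ValueError):
            tx.sex_bias_classes(labels, ann)

    def test_x_depletion_rejects_independence(self, bulk_x_halved):
        _, ann, _ = bulk_x_halved
        rng = np.random.default_rng(9)
        labels = pd.Series("unbiased", index=ann.genes, dtype=object)
        # male-biased genes only on the major autosomes: X depleted
        majors = ann.genes[ann.element.isin(["2L", "2R", "3L", "3R"])]
        labels[rng.choice(majors, 150, replace=False)] = "male"
        table = tx.sex_bias_classes(labels, ann)
        majors_and_x = table.loc[["2L", "2R", "3L", "3R", "X"]]
        _, _, p = tx.chi2_independence(majors_and_x.to_numpy())
        assert p <= 0.01
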