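"""Tau, TSPS, CTSP and the curated-expression concordance rubric."""

import numpy as np
import pandas as pd
import pytest

import testisx as tx
from conftest import make_counts
from oracles import tau_direct, tsps_direct


def panel_from_profiles(profiles):
    """One sample per tissue; columns are genes, rows tissue profiles."""
    arr = np.asarray(profiles, dtype=float).T  # tissues x genes
    cells = [f"t{i}" for i in range(arr.shape[0])]
    tissues = pd.Series(cells, index=pd.Index(cells))
    return make_counts(arr, cells=cells), tissues


class TestTau:
    def test_uniform_profile_is_zero(self):
        panel, tissues = panel_from_profiles([[7, 7, 7, 7]])
        assert tx.compute_tau(panel, tissues)["g0"] == pytest.approx(0.0)

    def test_single_tissue_is_one(self):
        panel, tissues = panel_from_profiles([[9, 0, 0, 0]])
        assert tx.compute_tau(panel, tissues)["g0"] == pytest.approx(1.0)

    def test_hand_computed_profile(self):
        # normalized profile (1, 0.5, 0): tau = (0 + 0.5 + 1)/2 = 0.75
        panel, tissues = panel_from_profiles([[4, 2, 0]])
        tau = tx.compute_tau(panel, tissues, log_transform=False)
        assert tau["g0"] == pytest.approx(0.75)

    def test_all_zero_gene_is_missing(self):
        panel, tissues = panel_from_profiles([[0, 0, 0]])
        assert np.isnan(tx.compute_tau(panel, tissues)["g0"])

    def test_single_tissue_rejected(self):
        panel, _ = panel_from_profiles([[1, 2]])
        tissues = pd.Series(["a", "a"], index=panel.obs_names)
        with pytest.raises(ValueError):
            tx.compute_tau(panel, tissues)

    def test_matches_direct_formula_on_random_tables(self):
        rng = np.random.default_rng(5)
        profiles = rng.gamma(1.0, 10.0, size=(10, 5))  # 10 genes x 5 tissues
        panel, tissues = panel_from_profiles(profiles)
        tau = tx.compute_tau(panel, tissues, log_transform=False)
        for g, profile in enumerate(profiles):
            assert tau[f"g{g}"] == pytest.approx(tau_direct(profile))


class TestTsps:
    def test_uniform_profile_is_zero(self):
        panel, tissues = panel_from_profiles([[3, 3, 3, 3]])
        assert tx.compute_tsps(panel, tissues)["g0"] == pytest.approx(0.0)

    def test_single_of_four_tissues_is_two(self):
        panel, tissues = panel_from_profiles([[8, 0, 0, 0]])
        assert tx.compute_tsps(panel, tissues)["g0"] == pytest.approx(2.0)

    def test_two_of_four_tissues_is_one(self):
        panel, tissues = panel_from_profiles([[5, 5, 0, 0]])
        assert tx.compute_tsps(panel, tissues)["g0"] == pytest.approx(1.0)

    def test_scale_invariance_exact(self):
        rng = np.random.default_rng(6)
        base = rng.gamma(1.0, 5.0, size=(4, 6))
        p1, t1 = panel_from_profiles(base)
        p2, t2 = panel_from_profiles(base * 1000.0)
        pd.testing.assert_series_equal(
            tx.compute_tsps(p1, t1), tx.compute_tsps(p2, t2)
        )

    def test_matches_direct_formula_on_random_tables(self):
        rng = np.random.default_rng(7)
        profiles = rng.gamma(0.7, 10.0, size=(10, 5))
        panel, tissues = panel_from_profiles(profiles)
        tsps = tx.compute_tsps(panel, tissues)
        for g, profile in enumerate(profiles):
            assert tsps[f"g{g}"] == pytest.approx(tsps_direct(profile))


class TestCtsp:
    def test_membership_boundary(self):
        # 2 of 6 cells = 0.333... >= 1/3 -> member
        col = np.array([[1], [1], [0], [0], [0], [0]])
        out = tx.compute_ctsp(make_counts(col))
        assert out.loc["g0", "ctsp_member"]

    def test_below_boundary_excluded(self):
        col = np.array([[1], [0], [0], [0], [0], [0]])
        assert not tx.compute_ctsp(make_counts(col)).loc["g0", "ctsp_member"]

    def test_ubiquitous_gene(self):
        col = np.ones((6, 1))
        out = tx.compute_ctsp(make_counts(col))
        assert out.loc["g0", "ctsp_fraction"] == 1.0 and out.loc["g0", "ctsp_member"]

    def test_cell_order_invariance(self, two_type_dataset):
        _, _, mat, _ = two_type_dataset
        shuffled = mat.subset_obs(
            np.random.default_rng(1).permutation(mat.shape[0])
        )
        pd.testing.assert_frame_equal(
            tx.compute_ctsp(mat).sort_index(), tx.compute_ctsp(shuffled).sort_index()
        )

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            tx.compute_ctsp(make_counts([[1]]), fraction=0.0)


class TestExpressedGenes:
    def test_min_cells_boundary(self):
        arr = np.array([[1, 1, 0], [1, 0, 0], [1, 0, 0]])
        expr = tx.expressed_genes(make_counts(arr), min_cells=3)
        assert list(expr) == ["g0"]

    def test_all_zero_gene_excluded(self):
        expr = tx.expressed_genes(make_counts([[1, 0], [1, 0]]), min_cells=1)
        assert list(expr) == ["g0"]


class TestConcordance:
    def test_exact_match_scores_four(self):
        assert tx.concordance_score({"G"}, set(), {"G"}) == 4

    def test_later_in_lineage_scores_four(self):
        # protein expression lags transcription within the germline chain
        assert tx.concordance_score({"E1"}, set(), {"L1"}) == 4

    def test_earlier_in_lineage_is_not_four(self):
        assert tx.concordance_score({"M1"}, set(), {"G"}) == 2

    def test_high_expression_exact_scores_three(self):
        assert tx.concordance_score(set(), {"C2"}, {"C2"}) == 3

    def test_biased_same_lineage_scores_two(self):
        # curated expression earlier in the chain: same lineage, not a lag
        assert tx.concordance_score({"C3"}, set(), {"C1", "C2"}) == 2

    def test_high_same_lineage_scores_one(self):
        assert tx.concordance_score(set(), {"G"}, {"L1"}) == 1

    def test_different_lineages_score_zero(self):
        assert tx.concordance_score({"C1"}, set(), {"T"}) == 0

    def test_unknown_type_rejected(self):
        with pytest.raises(KeyError):
            tx.concordance_score({"Q7"}, set(), {"G"})

    def test_type_in_two_lineages_rejected(self):
        with pytest.raises(ValueError):
            tx.LineageMap(chains={"a": ("G",), "b": ("G", "T")})


def test_specificity_table_consistency(two_type_dataset):
    cfg, ann, mat, _ = two_type_dataset
    panel = tx.generate_bulk_panel(cfg, n_tissues=4, n_reps=2)
    tpm = tx.normalize(panel.counts, "length_tpm", lengths=panel.lengths)
    table = tx.specificity_table(mat, tpm, panel.meta["tissue"])
    assert ((table["tau"].dropna() >= 0) & (table["tau"].dropna() <= 1 + 1e-9)).all()
    assert (table["tsps"].dropna() >= -1e-9).all()
    # membership flags are consistent with their thresholds
    flagged = table[table["tau_member"]]
    assert (flagged["tau"] <= 0.5).all()
    assert (table.loc[table["ctsp_member"], "ctsp_fraction"] >= 1 / 3).all()
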