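"""Tissue- and grand-mean-corrected log-ratio transformations."""

import numpy as np
import pandas as pd
import pytest

from pancanstrat import (
    grand_correct,
    grand_mean_normal,
    site_mean_normal,
    tissue_correct,
)

from conftest import make_matrix, make_sheet


class TestSiteMeans:
    def test_mean_over_each_sites_samples(self, tiny_pair):
        tumour, normal, sheet = tiny_pair
        sm = site_mean_normal(normal, sheet)
        # site A normals: G1 {2,4} -> 3; site B normals: G1 {2,6} -> 4
        assert sm.means.loc["G1", "A"] == pytest.approx(3.0)
        assert sm.means.loc["G1", "B"] == pytest.approx(4.0)
        assert sm.counts.to_dict() == {"A": 2, "B": 2}

    def test_single_sample_site_mean_is_that_sample(self):
        normal = make_matrix([[5.0], [2.0]], sample_ids=["N1"])
        sheet = make_sheet(["normal"], ["A"], sample_ids=["N1"])
        sm = site_mean_normal(normal, sheet)
        assert sm.means["A"].tolist() == [5.0, 2.0]

    def test_constant_gene_mean_is_constant(self):
        normal = make_matrix(np.full((1, 6), 7.0), sample_ids=[f"N{i}" for i in range(6)])
        sheet = make_sheet(["normal"] * 6, ["A", "A", "B", "B", "C", "C"],
                           sample_ids=[f"N{i}" for i in range(6)])
        sm = site_mean_normal(normal, sheet)
        assert (sm.means.loc["G1"] == 7.0).all()


class TestTissueCorrect:
    def test_hand_values(self, tiny_pair):
        tumour, normal, sheet = tiny_pair
        sm = site_mean_normal(normal, sheet)
        corrected = tissue_correct(tumour, sheet, sm)
        # T1 at site A: G1 tumour 2, site mean 3 -> ln(2/3); G2 3 vs 3 -> 0
        assert corrected.data.loc["G2", "T1"] == pytest.approx(0.0)
        assert corrected.data.loc["G1", "T1"] == pytest.approx(np.log(2 / 3))

    def test_two_to_one_ratio_gives_ln2(self):
        tumour = make_matrix([[6.0]], sample_ids=["T1"])
        normal = make_matrix([[3.0]], sample_ids=["N1"])
        sheet = make_sheet(["tumour", "normal"], ["A", "A"], sample_ids=["T1", "N1"])
        corrected = tissue_correct(tumour, sheet, site_mean_normal(normal, sheet))
        assert corrected.data.iloc[0, 0] == pytest.approx(np.log(2.0), abs=1e-12)

    def test_ratio_invariance_under_doubling(self, tiny_pair):
        tumour, normal, sheet = tiny_pair
        sm = site_mean_normal(normal, sheet)
        base = tissue_correct(tumour, sheet, sm).data
        tumour2 = make_matrix(tumour.data.to_numpy() * 2, gene_ids=tumour.gene_ids,
                              sample_ids=tumour.sample_ids)
        normal2 = make_matrix(normal.data.to_numpy() * 2, gene_ids=normal.gene_ids,
                              sample_ids=normal.sample_ids)
        doubled = tissue_correct(tumour2, sheet, site_mean_normal(normal2, sheet)).data
        np.testing.assert_allclose(doubled.to_numpy(), base.to_numpy(), atol=1e-12)

    def test_missing_site_error_lists_sites(self, tiny_pair):
        tumour, normal, sheet = tiny_pair
        normal_a_only = normal.subset_samples(["N1", "N2"])  # site A only
        sm = site_mean_normal(normal_a_only, sheet.subset(["N1", "N2"]))
        with pytest.raises(ValueError, match="B"):
            tissue_correct(tumour, sheet, sm)

    def test_tumour_equal_to_site_means_gives_zero_matrix(self, rng):
        genes = [f"G{i}" for i in range(5)]
        normal_vals = rng.uniform(1.0, 50.0, size=(5, 8))
        n_ids = [f"N{i}" for i in range(8)]
        sites = ["A"] * 4 + ["B"] * 4
        normal = make_matrix(normal_vals, gene_ids=genes, sample_ids=n_ids)
        sheet_n = make_sheet(["normal"] * 8, sites, sample_ids=n_ids)
        sm = site_mean_normal(normal, sheet_n)
        # tumours replicate their own site's mean-normal profile
        t_ids = ["T1", "T2"]
        t_vals = np.column_stack([sm.means["A"], sm.means["B"]])
        tumour = make_matrix(t_vals, gene_ids=genes, sample_ids=t_ids)
        sheet = make_sheet(["tumour", "tumour", *["normal"] * 8], ["A", "B", *sites],
                           sample_ids=t_ids + n_ids)
        corrected = tissue_correct(tumour, sheet, sm)
        np.testing.assert_allclose(corrected.data.to_numpy(), 0.0, atol=1e-12)


class TestGrandMean:
    def test_mean_of_means_not_pooled_mean(self):
        # site A: {2, 2} -> mean 2 (2 samples); site B: {4, 4, 4, 4} -> mean 4
        normal = make_matrix([[2.0, 2.0, 4.0, 4.0, 4.0, 4.0]],
                             sample_ids=[f"N{i}" for i in range(6)])
        sheet = make_sheet(["normal"] * 6, ["A", "A", "B", "B", "B", "B"],
                           sample_ids=[f"N{i}" for i in range(6)])
        gm = grand_mean_normal(normal, sheet)
        pooled = normal.data.to_numpy().mean()  # 10/3
        assert gm.means.iloc[0] == pytest.approx(3.0)
        assert gm.means.iloc[0] != pytest.approx(pooled)
        assert gm.t == 2

    def test_single_site_grand_equals_site_mean(self):
        normal = make_matrix([[2.0, 6.0]], sample_ids=["N1", "N2"])
        sheet = make_sheet(["normal"] * 2, ["A", "A"], sample_ids=["N1", "N2"])
        gm = grand_mean_normal(normal, sheet)
        assert gm.means.iloc[0] == pytest.approx(4.0)
        assert gm.t == 1

    def test_constant_gene_everywhere(self):
        normal = make_matrix(np.full((1, 4), 9.0), sample_ids=[f"N{i}" for i in range(4)])
        sheet = make_sheet(["normal"] * 4, ["A", "A", "B", "B"],
                           sample_ids=[f"N{i}" for i in range(4)])
        assert grand_mean_normal(normal, sheet).means.iloc[0] == pytest.approx(9.0)


class TestGrandCorrect:
    def test_zero_and_unit_log_ratios(self):
        normal = make_matrix([[4.0, 4.0]], sample_ids=["N1", "N2"])
        sheet = make_sheet(["normal"] * 2, ["A", "A"], sample_ids=["N1", "N2"])
        gm = grand_mean_normal(normal, sheet)
        tumour = make_matrix([[4.0, 4.0 * np.e]], sample_ids=["T1", "T2"])
        corrected = grand_correct(tumour, gm)
        assert corrected.data.loc["G1", "T1"] == pytest.approx(0.0, abs=1e-12)
        assert corrected.data.loc["G1", "T2"] == pytest.approx(1.0)

    def test_site_independence(self):
        """Identical tumour profiles get identical corrections regardless of site."""
        normal = make_matrix([[2.0, 8.0]], sample_ids=["N1", "N2"])
        sheet = make_sheet(["normal"] * 2, ["A", "B"], sample_ids=["N1", "N2"])
        gm = grand_mean_normal(normal, sheet)
        tumour = make_matrix([[5.0, 5.0]], sample_ids=["T1", "T2"])  # T1 site A, T2 site B
        corrected = grand_correct(tumour, gm)
        assert corrected.data.loc["G1", "T1"] == corrected.data.loc["G1", "T2"]

    def test_gene_set_mismatch_error(self):
        normal = make_matrix([[2.0]], gene_ids=["G1"], sample_ids=["N1"])
        sheet = make_sheet(["normal"], ["A"], sample_ids=["N1"])
        gm = grand_mean_normal(normal, sheet)
        tumour = make_matrix([[2.0]], gene_ids=["OTHER"], sample_ids=["T1"])
        with pytest.raises(ValueError, match="gene set"):
            grand_correct(tumour, gm)


class TestIdentities:
    def test_single_site_grand_equals_tissue_elementwise(self, rng):
        """With one primary site the two corrections are the same transformation."""
        genes = [f"G{i}" for i in range(20)]
        t_ids = [f"T{i}" for i in range(10)]
        n_ids = [f"N{i}" for i in range(8)]
        tumour = make_matrix(rng.uniform(1, 100, (20, 10)), gene_ids=genes, sample_ids=t_ids)
        normal = make_matrix(rng.uniform(1, 100, (20, 8)), gene_ids=genes, sample_ids=n_ids)
        sheet = make_sheet(["tumour"] * 10 + ["normal"] * 8, ["A"] * 18,
                           sample_ids=t_ids + n_ids)
        tissue = tissue_correct(tumour, sheet, site_mean_normal(normal, sheet)).data
        grand = grand_correct(tumour, grand_mean_normal(normal, sheet)).data
        np.testing.assert_allclose(tissue.to_numpy(), grand.to_numpy(), atol=1e-12)

    def test_corrections_monotone_in_tumour_expression(self, tiny_pair):
        tumour, normal, sheet = tiny_pair
        sm = site_mean_normal(normal, sheet)
        gm = grand_mean_normal(normal, sheet)
        base_t = tissue_correct(tumour, sheet, sm).data
        base_g = grand_correct(tumour, gm).data
        bumped = make_matrix(tumour.data.to_numpy() * 1.5, gene_ids=tumour.gene_ids,
                             sample_ids=tumour.sample_ids)
        assert (tissue_correct(bumped, sheet, sm).data.to_numpy() > base_t.to_numpy()).all()
        assert (grand_correct(bumped, gm).data.to_numpy() > base_g.to_numpy()).all()

    def test_outputs_finite_on_any_tpm_input(self, rng):
        """TPM+1 numerators and denominators are >= 1, so every log-ratio is finite."""
        genes = [f"G{i}" for i in range(10)]
        t_ids = [f"T{i}" for i in range(6)]
        n_ids = [f"N{i}" for i in range(6)]
        # include the boundary value 1.0 (zero TPM) heavily
        t_vals = np.where(rng.random((10, 6)) < 0.4, 1.0, rng.uniform(1, 1e6, (10, 6)))
        n_vals = np.where(rng.random((10, 6)) < 0.4, 1.0, rng.uniform(1, 1e6, (10, 6)))
        tumour = make_matrix(t_vals, gene_ids=genes, sample_ids=t_ids)
        normal = make_matrix(n_vals, gene_ids=genes, sample_ids=n_ids)
        sheet = make_sheet(["tumour"] * 6 + ["normal"] * 6, ["A", "A", "A", "B", "B", "B"] * 2,
                           sample_ids=t_ids + n_ids)
        tissue = tissue_correct(tumour, sheet, site_mean_normal(normal, sheet)).data
        grand = grand_correct(tumour, grand_mean_normal(normal, sheet)).data
        assert np.isfinite(tissue.to_numpy()).all()
        assert np.isfinite(grand.to_numpy()).all()
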