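"""Normalization, site ranking, and the histone proteomic ruler."""

import numpy as np
import pandas as pd
import pytest
from scipy.constants import Avogadro

from diglyq import (
    equal_loading_normalize,
    median_center,
    normalize_site_to_protein,
    protein_molecular_weight,
    proteomic_ruler_copies,
    rank_site_abundance,
)
from diglyq.quantnorm import MEAN_BASEPAIR_MASS


class TestEqualLoading:
    def test_hand_computed_two_by_two(self):
        m = pd.DataFrame([[1.0, 3.0], [1.0, 1.0]], columns=["a", "b"])
        out = equal_loading_normalize(m)
        # column sums 2 and 4, mean 3 -> scale 1.5 and 0.75
        pd.testing.assert_frame_equal(
            out, pd.DataFrame([[1.5, 2.25], [1.5, 0.75]], columns=["a", "b"])
        )

    def test_equal_sum_matrix_unchanged(self):
        m = pd.DataFrame([[1.0, 2.0], [3.0, 2.0]], columns=["a", "b"])
        pd.testing.assert_frame_equal(equal_loading_normalize(m), m)

    def test_column_sums_equal_after_normalization(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.uniform(1, 100, (30, 11)))
        out = equal_loading_normalize(m)
        sums = out.sum(axis=0)
        np.testing.assert_allclose(sums, sums.iloc[0], rtol=1e-12)

    def test_idempotent_and_scale_equivariant(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.uniform(1, 100, (20, 5)))
        once = equal_loading_normalize(m)
        twice = equal_loading_normalize(once)
        pd.testing.assert_frame_equal(once, twice)
        scaled = equal_loading_normalize(m * 7.0)
        pd.testing.assert_frame_equal(scaled, once * 7.0)

    def test_zero_column_sum_names_channel(self):
        m = pd.DataFrame({"good": [1.0], "dead": [0.0]})
        with pytest.raises(ValueError, match="dead"):
            equal_loading_normalize(m)


class TestSiteToProteinNormalization:
    def test_scalar_and_vector_division(self):
        sites = pd.DataFrame({"c1": [4.0, 2.0], "c2": [4.0, 4.0], "c3": [4.0, 8.0]},
                             index=["s1", "s2"])
        prots = pd.DataFrame({"c1": [2.0, 1.0], "c2": [2.0, 2.0], "c3": [2.0, 2.0]},
                             index=["PA", "PB"])
        out, flags = normalize_site_to_protein(sites, prots, {"s1": "PA", "s2": "PB"})
        np.testing.assert_allclose(out.loc["s1"], [2.0, 2.0, 2.0])
        np.testing.assert_allclose(out.loc["s2"], [2.0, 2.0, 4.0])
        assert flags.all()

    def test_missing_protein_passes_through_flagged(self):
        sites = pd.DataFrame({"c1": [4.0]}, index=["s1"])
        prots = pd.DataFrame({"c1": [2.0]}, index=["other"])
        out, flags = normalize_site_to_protein(sites, prots, {"s1": "absent"})
        assert out.loc["s1", "c1"] == 4.0 and not flags.loc["s1"]

    def test_zero_protein_ratio_not_divided(self):
        sites = pd.DataFrame({"c1": [4.0]}, index=["s1"])
        prots = pd.DataFrame({"c1": [0.0]}, index=["PA"])
        out, flags = normalize_site_to_protein(sites, prots, {"s1": "PA"})
        assert out.loc["s1", "c1"] == 4.0 and not flags.loc["s1"]


class TestMedianCenter:
    def test_column_shifts_to_zero_median(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        np.testing.assert_allclose(median_center(m)["a"], [-1, 0, 1])

    def test_already_centered_unchanged(self):
        m = pd.DataFrame({"a": [-1.0, 0.0, 1.0], "b": [-2.0, 0.0, 5.0]})
        pd.testing.assert_frame_equal(median_center(m), m)

    def test_three_by_three_against_sorted_middle(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.normal(size=(3, 3)))
        out = median_center(m)
        for c in m.columns:
            mid = sorted(m[c])[1]
            np.testing.assert_allclose(out[c], m[c] - mid)

    def test_all_missing_column_rejected(self):
        m = pd.DataFrame({"a": [np.nan, np.nan]})
        with pytest.raises(ValueError):
            median_center(m)


class TestRankSiteAbundance:
    def _sites(self, sn_rows, ms1):
        df = pd.DataFrame(sn_rows, columns=["c1", "c2", "c3"])
        df.insert(0, "protein", [f"P{i}" for i in range(len(df))])
        df.insert(1, "site", [10 + i for i in range(len(df))])
        df["ms1_total"] = ms1
        return df

    def test_hand_apportionment(self):
        out = rank_site_abundance(self._sites([[30.0, 10.0, 60.0]], [100.0]),
                                  ["c1", "c2", "c3"])
        np.testing.assert_allclose(out.loc[0, ["c1", "c2", "c3"]].astype(float),
                                   [30.0, 10.0, 60.0])

    def test_equal_sn_splits_ms1_evenly(self):
        out = rank_site_abundance(self._sites([[1.0, 1.0, 1.0]], [110.0 * 3 / 11]),
                                  ["c1", "c2", "c3"])
        np.testing.assert_allclose(out.loc[0, ["c1", "c2", "c3"]].astype(float), 10.0)

    def test_apportionment_conserves_ms1_mass(self):
        rng = np.random.default_rng(3)
        sites = self._sites(rng.uniform(1, 50, (20, 3)), rng.uniform(10, 1e4, 20))
        out = rank_site_abundance(sites, ["c1", "c2", "c3"])
        merged = out.merge(sites[["protein", "ms1_total"]], on="protein")
        np.testing.assert_allclose(
            merged[["c1", "c2", "c3"]].sum(axis=1), merged["ms1_total"], rtol=1e-12
        )

    def test_zero_sn_site_excluded_with_warning(self):
        sites = self._sites([[0.0, 0.0, 0.0], [1.0, 2.0, 3.0]], [5.0, 6.0])
        with pytest.warns(UserWarning, match="zero summed"):
            out = rank_site_abundance(sites, ["c1", "c2", "c3"])
        assert len(out) == 1

    def test_ranks_are_descending_permutation(self):
        rng = np.random.default_rng(4)
        sites = self._sites(rng.uniform(1, 50, (15, 3)), rng.uniform(10, 1e4, 15))
        out = rank_site_abundance(sites, ["c1", "c2", "c3"])
        assert sorted(out["rank"]) == list(range(1, 16))
        assert (out["rank_abundance"].diff().dropna() <= 1e-12).all()


class TestProteomicRuler:
    def _table(self):
        intens = pd.Series({"HIST1": 50.0, "HIST2": 30.0, "P1": 500.0, "P2": 20.0})
        mw = pd.Series({"HIST1": 11000.0, "HIST2": 14000.0, "P1": 50000.0, "P2": 22000.0})
        return intens, mw

    def test_global_intensity_rescaling_is_invariant(self):
        intens, mw = self._table()
        a = proteomic_ruler_copies(intens, mw, ["HIST1", "HIST2"])
        b = proteomic_ruler_copies(intens * 1e3, mw, ["HIST1", "HIST2"])
        np.testing.assert_allclose(a["copies"], b["copies"], rtol=1e-12)

    def test_linear_in_ploidy(self):
        intens, mw = self._table()
        a = proteomic_ruler_copies(intens, mw, ["HIST1"], ploidy=2)
        b = proteomic_ruler_copies(intens, mw, ["HIST1"], ploidy=4)
        np.testing.assert_allclose(2 * a["copies"], b["copies"], rtol=1e-12)

    def test_single_histone_protein_collapses_to_formula(self):
        mw = 12345.0
        out = proteomic_ruler_copies(
            pd.Series({"H": 7.0}), pd.Series({"H": mw}), ["H"],
            ploidy=2, genome_size_bp=1e9,
        )
        m_dna = 2 * 1e9 * MEAN_BASEPAIR_MASS / Avogadro
        assert out.loc[0, "copies"] == pytest.approx(Avogadro * m_dna / mw, rel=1e-12)

    def test_missing_histone_rejected(self):
        intens, mw = self._table()
        with pytest.raises(ValueError, match="HIST9"):
            proteomic_ruler_copies(intens, mw, ["HIST9"])

    def test_ranks_follow_copies(self):
        intens, mw = self._table()
        out = proteomic_ruler_copies(intens, mw, ["HIST1", "HIST2"])
        assert (out.sort_values("rank")["copies"].diff().dropna() <= 0).all()


def test_molecular_weight_of_short_peptide():
    # G + K residue masses + water
    assert protein_molecular_weight("GK") == pytest.approx(
        57.0519 + 128.1741 + 18.01528, abs=1e-3
    )
    with pytest.raises(ValueError):
        protein_molecular_weight("GZ")
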