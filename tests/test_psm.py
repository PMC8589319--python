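"""PSM filtering, target-decoy FDR, localization scoring, parsimony,
and site aggregation."""

import numpy as np
import pandas as pd
import pytest

from diglyq import (
    FilterThresholds,
    aggregate_to_sites,
    ascore,
    ascore_site,
    filter_psms,
    parsimony_protein_groups,
    target_decoy_fdr,
)
from tests._oracles import binomial_tail, exhaustive_fdr_cutoff, minimal_cover_size

DIGLY = FilterThresholds(digly_mode=True)


class TestFilterPsms:
    def test_each_violation_reported_with_distinct_reason(self, toy_psms):
        kept, report = filter_psms(toy_psms, DIGLY)
        assert len(kept) == 1
        assert report.n_input == 6 and report.n_kept == 1
        assert report.excluded_by_reason == {
            "isolation_specificity": 1,
            "summed_sn": 1,
            "no_ms3": 1,
            "charge": 2,
        }

    def test_boundary_values_are_kept(self, toy_psms):
        # exclusions are strict "less than": 0.70 / 150 / charge 3 pass
        row = toy_psms.iloc[[0]].assign(isolation_specificity=0.70, summed_sn=150.0)
        kept, _ = filter_psms(row, DIGLY)
        assert len(kept) == 1

    def test_charge_window_only_applies_in_digly_mode(self, toy_psms):
        row = toy_psms.iloc[[0]].assign(charge=2)
        kept, _ = filter_psms(row, FilterThresholds(digly_mode=False))
        assert len(kept) == 1

    def test_empty_input_gives_zero_count_report(self, toy_psms):
        kept, report = filter_psms(toy_psms.iloc[0:0], DIGLY)
        assert kept.empty and report.n_input == 0 and report.n_kept == 0

    def test_filtering_is_idempotent(self, toy_psms):
        kept, _ = filter_psms(toy_psms, DIGLY)
        again, report = filter_psms(kept, DIGLY)
        assert report.n_excluded == 0
        pd.testing.assert_frame_equal(kept, again)


def _score_frame(scores, decoys):
    return pd.DataFrame(
        {
            "peptide": [f"PEP{i}" for i in range(len(scores))],
            "proteins": [f"P{i}" for i in range(len(scores))],
            "score": scores,
            "is_decoy": decoys,
        }
    )


class TestTargetDecoyFdr:
    def test_all_targets_kept_when_no_decoys(self):
        df = _score_frame([5.0, 4.0, 3.0], [False] * 3)
        assert len(target_decoy_fdr(df, 0.01)) == 3

    def test_level_zero_keeps_leading_zero_decoy_prefix(self):
        df = _score_frame([5, 4, 3, 2], [False, False, True, False])
        kept = target_decoy_fdr(df, 0.0)
        assert list(kept["score"]) == [5, 4]

    def test_spec_example_cutoff_matches_exhaustive_search(self):
        scores = [10, 9, 8, 7, 6, 5.5, 5, 4, 3, 2.5, 2, 1]
        decoys = [False] * 5 + [True] + [False] * 3 + [True] + [False] * 2
        df = _score_frame(scores, decoys)
        kept = target_decoy_fdr(df, 0.1)
        expect = exhaustive_fdr_cutoff(scores, decoys, 0.1)
        assert sorted(kept.index) == expect

    @pytest.mark.parametrize("seed", range(10))
    def test_cutoff_equals_exhaustive_oracle_on_random_lists(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        scores = rng.permutation(np.arange(n) + rng.uniform(0, 0.5, n)).tolist()
        decoys = (rng.random(n) < 0.3).tolist()
        if all(decoys):
            decoys[0] = False
        level = float(rng.choice([0.05, 0.1, 0.2]))
        df = _score_frame(scores, decoys)
        kept = target_decoy_fdr(df, level)
        assert sorted(kept.index) == exhaustive_fdr_cutoff(scores, decoys, level)

    def test_output_fdr_below_level_and_maximal(self):
        rng = np.random.default_rng(42)
        scores = rng.normal(3, 1, 60).tolist()
        decoys = (rng.random(60) < 0.4).tolist()
        df = _score_frame(scores, decoys)
        level = 0.15
        kept = target_decoy_fdr(df, level)
        if kept.empty:
            return
        cutoff = kept["score"].min()
        above = df[df["score"] >= cutoff]
        d, t = above["is_decoy"].sum(), (~above["is_decoy"]).sum()
        assert d / max(1, t) <= level

    def test_peptide_grouping_uses_best_score(self):
        df = pd.DataFrame(
            {
                "peptide": ["AAA", "AAA", "BBB"],
                "proteins": ["P1", "P1", "P2"],
                "score": [1.0, 9.0, 5.0],
                "is_decoy": [False, False, False],
            }
        )
        kept = target_decoy_fdr(df, 0.05, by="peptide")
        assert len(kept) == 3  # whole passing groups are kept

    def test_no_targets_gives_empty_output(self):
        df = _score_frame([3.0, 2.0], [True, True])
        assert target_decoy_fdr(df, 0.05).empty


class TestAscore:
    def test_score_13_at_95_percent_confidence(self):
        # tail probability exactly 0.05 -> 13.0 to the nearest tenth
        assert round(ascore(1, 1, 0.05), 1) == 13.0

    def test_zero_matches_gives_zero_score(self):
        assert ascore(10, 0, 0.1) == 0.0

    @pytest.mark.parametrize("n,k,p", [(10, 5, 0.1), (15, 3, 0.25), (20, 20, 0.5)])
    def test_matches_explicit_binomial_summation(self, n, k, p):
        expected = -10 * np.log10(binomial_tail(n, k, p))
        assert ascore(n, k, p) == pytest.approx(expected, rel=1e-9)

    def test_full_grid_agrees_with_summation_oracle(self):
        for n in range(1, 21):
            for k in range(0, n + 1, max(1, n // 4)):
                for p in (0.01, 0.1, 0.25, 0.5):
                    tail = binomial_tail(n, k, p)
                    assert ascore(n, k, p) == pytest.approx(
                        -10 * np.log10(tail), rel=1e-8, abs=1e-10
                    )

    def test_monotone_in_k_and_p(self):
        scores_k = [ascore(12, k, 0.2) for k in range(13)]
        assert all(a <= b for a, b in zip(scores_k, scores_k[1:]))
        scores_p = [ascore(12, 6, p) for p in (0.05, 0.1, 0.2, 0.4)]
        assert all(a >= b for a, b in zip(scores_p, scores_p[1:]))

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            ascore(5, 6, 0.1)
        with pytest.raises(ValueError):
            ascore(5, 2, 0.0)

    def test_site_score_is_difference_of_candidates(self):
        assert ascore_site(40.0, 25.0) == 15.0


class TestParsimony:
    def test_unique_peptides_give_one_group_per_protein(self):
        mapping = {"p1": ["A"], "p2": ["B"], "p3": ["C"]}
        groups = parsimony_protein_groups(mapping)
        assert groups == {"A": ["p1"], "B": ["p2"], "C": ["p3"]}

    def test_shared_peptide_resolved_to_minimal_cover(self):
        mapping = {"p1": ["A"], "p2": ["A", "B"], "p3": ["B"]}
        groups = parsimony_protein_groups(mapping)
        assert len(groups) == minimal_cover_size(mapping) == 2
        covered = {p for peps in groups.values() for p in peps}
        assert covered == set(mapping)

    def test_subsumed_protein_absorbed(self):
        mapping = {"p1": ["A", "B"], "p2": ["A"], "p3": ["A", "B"]}
        groups = parsimony_protein_groups(mapping)
        assert set(groups) == {"A"}
        assert groups["A"] == ["p1", "p2", "p3"]

    def test_ties_broken_lexicographically(self):
        mapping = {"p1": ["B", "A"]}
        assert set(parsimony_protein_groups(mapping)) == {"A"}

    def test_empty_input_gives_empty_grouping(self):
        assert parsimony_protein_groups({}) == {}

    def test_every_peptide_assigned_exactly_once_on_random_maps(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            prots = [f"P{i}" for i in range(int(rng.integers(2, 8)))]
            mapping = {
                f"p{j}": sorted(
                    rng.choice(prots, size=int(rng.integers(1, min(4, len(prots) + 1))), replace=False)
                )
                for j in range(int(rng.integers(2, 12)))
            }
            groups = parsimony_protein_groups(mapping)
            assigned = [p for peps in groups.values() for p in peps]
            assert sorted(assigned) == sorted(mapping)


class TestAggregateToSites:
    CHANNELS = ["ch1", "ch2"]

    def _frame(self, rows):
        return pd.DataFrame(rows)

    def _base(self, **kw):
        base = dict(
            peptide="AKGGR",
            proteins="P1",
            mods="2:glygly",
            charge=3,
            score=5.0,
            is_decoy=False,
            isolation_specificity=0.9,
            summed_sn=400.0,
            ms1_intensity=100.0,
            has_ms3=True,
            ascore=30.0,
            ch1=100.0,
            ch2=300.0,
        )
        base.update(kw)
        return base

    SEQS = {"P1": "MAKGGRWK"}

    def test_single_psm_passes_through(self):
        sites, amb = aggregate_to_sites(
            self._frame([self._base()]), self.SEQS, self.CHANNELS
        )
        assert amb.empty
        assert len(sites) == 1
        row = sites.iloc[0]
        assert (row["protein"], row["site"], row["residue"]) == ("P1", 3, "K")
        assert (row["ch1"], row["ch2"]) == (100.0, 300.0)

    def test_vectors_sum_elementwise_across_psms(self):
        rows = [self._base(), self._base(ch1=7.0, ch2=11.0, ms1_intensity=50.0)]
        sites, _ = aggregate_to_sites(self._frame(rows), self.SEQS, self.CHANNELS)
        assert len(sites) == 1
        assert sites.iloc[0]["ch1"] == 107.0 and sites.iloc[0]["ch2"] == 311.0
        assert sites.iloc[0]["ms1_total"] == 150.0
        assert sites.iloc[0]["n_psms"] == 2

    def test_three_psms_across_two_sites_hand_totals(self):
        rows = [
            self._base(),
            self._base(ch1=1.0, ch2=2.0, ms1_intensity=10.0),
            self._base(peptide="WK", mods="2:glygly", ch1=5.0, ch2=6.0, ms1_intensity=1.0),
        ]
        sites, _ = aggregate_to_sites(self._frame(rows), self.SEQS, self.CHANNELS)
        assert len(sites) == 2
        k3 = sites[sites["site"] == 3].iloc[0]
        k8 = sites[sites["site"] == 8].iloc[0]
        assert (k3["ch1"], k3["ch2"], k3["ms1_total"]) == (101.0, 302.0, 110.0)
        assert (k8["ch1"], k8["ch2"], k8["ms1_total"]) == (5.0, 6.0, 1.0)

    def test_poorly_localized_sites_are_flagged_not_dropped(self):
        rows = [self._base(ascore=5.0)]
        sites, amb = aggregate_to_sites(self._frame(rows), self.SEQS, self.CHANNELS)
        assert sites.empty and len(amb) == 1 and not amb.iloc[0]["localized"]

    def test_unmappable_peptide_raises_naming_record(self):
        rows = [self._base(peptide="QQQQQQ")]
        with pytest.raises(ValueError, match="QQQQQQ"):
            aggregate_to_sites(self._frame(rows), self.SEQS, self.CHANNELS)
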