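"""Index formulas: worked examples, published values and properties."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings

from ethnolika import (
    ailment_fidelity,
    category_summary,
    cultural_value_from_counts,
    derive_freelists,
    fidelity_from_counts,
    fidelity_level,
    index_table,
    informant_consensus,
    rank_table,
    rfc,
    rfc_from_counts,
    round_display,
    smiths_s,
)
from ethnolika.io import load_lika_category_totals
from ethnolika.model import CATEGORY_CODES

from conftest import build_survey, small_surveys
from _oracle import (
    oracle_cve,
    oracle_fic,
    oracle_fls,
    oracle_rfc,
    oracle_smiths_s,
    oracle_ur,
)


class TestRfc:
    @pytest.mark.parametrize("fc,n,expected", [
        (37, 40, 0.925),   # most-cited taxon of the Lika survey
        (33, 40, 0.825),
        (40, 40, 1.0),     # cited by every informant
    ])
    def test_count_examples(self, fc, n, expected):
        assert rfc_from_counts(fc, n) == pytest.approx(expected)

    def test_zero_informants_rejected(self):
        with pytest.raises(ValueError):
            rfc_from_counts(5, 0)

    def test_survey_path_counts_distinct_informants(self, tiny_survey):
        vals = rfc(tiny_survey)
        assert vals["A"] == pytest.approx(1.0)
        assert vals["C"] == pytest.approx(0.5)


class TestSmithsS:
    def test_hand_enumerated_two_lists(self, tiny_survey):
        # lists [A, B, C] and [B, A]:
        # Sj(A) = (1 + 1/2)/2 = 0.75 ; Sj(B) = (2/3 + 1)/2 = 0.8333
        sj = smiths_s(derive_freelists(tiny_survey))
        assert sj["A"] == pytest.approx(0.75)
        assert sj["B"] == pytest.approx(5 / 6)
        assert sj["C"] == pytest.approx(1 / 6)  # (1/3)/2

    def test_taxon_first_in_every_list_is_maximally_salient(self):
        s = build_survey(
            freelists={"i1": ["A", "B"], "i2": ["A"], "i3": ["A", "C"]},
            categories={},
        )
        assert smiths_s(derive_freelists(s))["A"] == pytest.approx(1.0)

    def test_unmentioned_taxon_scores_zero(self, tiny_survey):
        table = index_table(tiny_survey)
        assert set(table.index) == {"A", "B", "C"}
        sj = smiths_s(derive_freelists(tiny_survey)).reindex(["Z"], fill_value=0.0)
        assert sj["Z"] == 0.0

    def test_empty_list_collection_rejected(self):
        with pytest.raises(ValueError):
            smiths_s([])


class TestCulturalValue:
    @pytest.mark.parametrize("n_cat,fc,ur,expected", [
        (5, 33, 63, 0.812),  # the survey's top-CVe taxon
        (4, 32, 38, 0.380),
        (3, 37, 41, 0.356),
    ])
    def test_published_values_with_eight_possible_uses(self, n_cat, fc, ur, expected):
        cve = cultural_value_from_counts(n_cat, fc, ur, n_informants=40,
                                         n_possible_uses=8)
        assert round_display(cve, 3) == pytest.approx(expected)

    def test_uncited_taxon_scores_zero(self):
        assert cultural_value_from_counts(0, 0, 0, 40) == 0.0

    def test_denominator_must_cover_observed_categories(self):
        with pytest.raises(ValueError):
            cultural_value_from_counts(9, 10, 12, 40, n_possible_uses=8)
        with pytest.raises(ValueError):
            cultural_value_from_counts(2, 10, 12, 40, n_possible_uses=0)


class TestInformantConsensus:
    @pytest.mark.parametrize("n_ur,n_taxa,expected", [
        (524, 57, 0.89),   # food & drinks of the Lika survey
        (10, 10, 0.0),     # every report a different taxon
        (10, 1, 1.0),      # all reports on one taxon
    ])
    def test_examples(self, n_ur, n_taxa, expected):
        assert round_display(informant_consensus(n_ur, n_taxa), 2) == pytest.approx(expected)

    def test_single_report_is_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(informant_consensus(1, 1))

    def test_monotone_in_ur_and_n_taxa(self):
        base = informant_consensus(20, 5)
        assert informant_consensus(30, 5) > base
        assert informant_consensus(20, 8) < base

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            informant_consensus(0, 1)
        with pytest.raises(ValueError):
            informant_consensus(5, 6)


class TestFidelityLevel:
    @pytest.mark.parametrize("ns,fc,expected", [
        (19, 30, 63.33),  # walnut liqueur
        (21, 32, 65.62),  # dandelion as feed
        (31, 32, 96.88),
    ])
    def test_published_cells(self, ns, fc, expected):
        assert round_display(fidelity_from_counts(ns, fc), 2) == pytest.approx(expected)

    def test_single_purpose_taxon_scores_100(self):
        s = build_survey(
            freelists={"i1": ["A"], "i2": ["A"]},
            categories={("i1", "A"): ["CE"], ("i2", "A"): ["CE"]},
        )
        assert fidelity_level(s).loc["A", "CE"] == pytest.approx(100.0)

    def test_row_sums_at_least_100(self, lika_survey):
        fls = fidelity_level(lika_survey)
        assert ((fls >= 0) & (fls <= 100)).all().all()
        assert (fls.sum(axis=1) >= 100 - 1e-9).all()


class TestAilmentFidelity:
    def test_tilia_like_split(self):
        # 14 medicinal citations, 13 for one ailment -> FL = 13/14 = 0.93
        freelists = {f"i{k}": ["tilia"] for k in range(1, 15)}
        categories = {(f"i{k}", "tilia"): ["MD"] for k in range(1, 15)}
        ailments = {(f"i{k}", "tilia"): "tension" for k in range(1, 14)}
        ailments[("i14", "tilia")] = "cough"
        s = build_survey(freelists, categories, ailments=ailments)
        fl = ailment_fidelity(s)
        tension = fl[(fl["ailment"] == "tension")]["FL"].iloc[0]
        assert round_display(tension, 2) == pytest.approx(0.93)

    def test_single_ailment_taxon_scores_one(self):
        s = build_survey(
            freelists={"i1": ["A"], "i2": ["A"]},
            categories={("i1", "A"): ["MD"], ("i2", "A"): ["MD"]},
            ailments={("i1", "A"): "cough", ("i2", "A"): "cough"},
        )
        assert ailment_fidelity(s)["FL"].iloc[0] == pytest.approx(1.0)

    def test_taxon_without_medicinal_citations_excluded(self):
        s = build_survey(
            freelists={"i1": ["A"]},
            categories={("i1", "A"): ["FO"]},
        )
        assert len(ailment_fidelity(s)) == 0


class TestCategorySummary:
    def test_lika_category_totals_reproduce_published_fic(self, lika_survey):
        cs = category_summary(lika_survey, load_lika_category_totals())
        row = cs[cs["category"] == "FO"].iloc[0]
        assert row["UR"] == 524 and row["n_taxa"] == 57
        assert round_display(row["Fic"], 2) == pytest.approx(0.89)

    def test_single_informant_has_zero_sd(self):
        s = build_survey(
            freelists={"i1": ["A", "B", "C"]},
            categories={("i1", t): ["FO"] for t in "ABC"},
        )
        row = category_summary(s).set_index("category").loc["FO"]
        assert row["mean"] == pytest.approx(3.0)
        assert row["sd"] == 0.0

    def test_cv_percent_definition(self):
        # published food row: mean 13.1, sd 4.8 -> CV 37 %
        assert round_display(100 * 4.8 / 13.1, 0) == pytest.approx(37)

    def test_zeros_counted_for_silent_informants(self):
        s = build_survey(
            freelists={"i1": ["A"], "i2": ["B"]},
            categories={("i1", "A"): ["CT"], ("i2", "B"): ["FO"]},
        )
        row = category_summary(s).set_index("category").loc["CT"]
        assert row["median"] == pytest.approx(0.5)
        assert row["mean"] == pytest.approx(0.5)


class TestRankTable:
    def test_top_taxon_by_total_use_reports(self, lika_survey):
        table = index_table(lika_survey)
        top = rank_table(table, "UR_total", 1)
        assert top.index[0] == "cornus_mas"
        assert top["UR_total"].iloc[0] == 63

    def test_k_zero_gives_empty_table(self, lika_survey):
        assert len(rank_table(index_table(lika_survey), "RFC", 0)) == 0

    def test_ties_break_alphabetically_and_stably(self):
        s = build_survey(
            freelists={"i1": ["B", "A"]},
            categories={("i1", "A"): ["FO"], ("i1", "B"): ["FO"]},
        )
        t = index_table(s)
        first = rank_table(t, "FC", 2)
        again = rank_table(t, "FC", 2)
        assert list(first.index) == ["A", "B"]
        assert list(first.index) == list(again.index)

    def test_unknown_key_rejected(self, tiny_survey):
        with pytest.raises(ValueError):
            rank_table(index_table(tiny_survey), "banana", 3)


class TestOracleEquivalence:
    """Vectorized indices equal naive enumeration on arbitrary small surveys."""

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(survey=small_surveys())
    def test_all_indices_match_bruteforce(self, survey):
        table = index_table(survey)
        fls = fidelity_level(survey)
        cs = category_summary(survey).set_index("category")
        for taxon in table.index:
            assert table.at[taxon, "RFC"] == pytest.approx(oracle_rfc(survey, taxon))
            assert table.at[taxon, "Sj"] == pytest.approx(oracle_smiths_s(survey, taxon))
            assert table.at[taxon, "CVe"] == pytest.approx(oracle_cve(survey, taxon))
            for cat in CATEGORY_CODES:
                assert table.at[taxon, f"UR_{cat}"] == oracle_ur(survey, taxon, cat)
                if table.at[taxon, "FC"] > 0:
                    assert fls.at[taxon, cat] == pytest.approx(
                        oracle_fls(survey, taxon, cat)
                    )
        for cat in CATEGORY_CODES:
            expected = oracle_fic(survey, cat)
            got = cs.at[cat, "Fic"]
            if expected is None:
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(survey=small_surveys())
    def test_salience_never_exceeds_rfc(self, survey):
        table = index_table(survey)
        assert (table["Sj"] <= table["RFC"] + 1e-12).all()

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(survey=small_surveys())
    def test_invariance_under_relabeling_and_permutation(self, survey):
        table = index_table(survey)
        # permute record rows
        shuffled = survey.records.sample(frac=1.0, random_state=1)
        from ethnolika import make_survey
        s2 = make_survey(shuffled, survey.registry)
        pd.testing.assert_frame_equal(table, index_table(s2))
        # relabel informants
        mapping = {i: f"x{i}" for i in survey.records["informant_id"].unique()}
        relabeled = survey.records.assign(
            informant_id=survey.records["informant_id"].map(mapping)
        )
        s3 = make_survey(relabeled, survey.registry)
        pd.testing.assert_frame_equal(table, index_table(s3))
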