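"""The weighted-sum target score: equations, imputation, resolution and ranking."""

from __future__ import annotations

import math

import pytest
from hypothesis import given, settings, strategies as st

from adrepo.evidence_io import ScoringConfig
from adrepo.scoring import (RankedTarget, ScoreBreakdown, impute_metabolomic_fold,
                            rank_targets, score_genetic, score_metabolomic,
                            score_proteomic, score_target)


class TestImputation:
    def test_partial_change_averages_over_all_links(self):
        # N=4 linked metabolites, 2 altered with |F| = {2, 3}: (5 + 2) / 4
        assert impute_metabolomic_fold([2, 3], 4) == pytest.approx(1.75)

    def test_all_links_unchanged_magnitude_is_fixed_point(self):
        assert impute_metabolomic_fold([1, 1, 1], 3) == pytest.approx(1.0)

    def test_single_metabolite_is_identity(self):
        assert impute_metabolomic_fold([2.37], 1) == pytest.approx(2.37)

    def test_signs_are_ignored(self):
        assert impute_metabolomic_fold([-2, 3], 4) == impute_metabolomic_fold([2, -3], 4)

    def test_degenerate_inputs_are_fatal(self):
        with pytest.raises(ValueError):
            impute_metabolomic_fold([], 3)
        with pytest.raises(ValueError):
            impute_metabolomic_fold([2, 2], 1)
        with pytest.raises(ValueError):
            impute_metabolomic_fold([0.5], 1)


class TestEquations:
    def test_genetic_at_reference_constants_scores_one(self):
        assert score_genetic(3.7, 4092, 11294).total == 1.0

    def test_genetic_effect_only(self):
        assert score_genetic(7.4, 0, 0).total == pytest.approx(0.66, abs=1e-12)

    def test_genetic_half_citations(self):
        assert score_genetic(3.7, 2046, 0).total == pytest.approx(0.50, abs=1e-12)

    def test_proteomic_direction_agnostic_reference_scores_one(self):
        assert score_proteomic(-2.37, 4092, 11294).total == 1.0

    def test_proteomic_mixed_components(self):
        assert score_proteomic(4.74, 2046, 5647).total == pytest.approx(0.995, abs=1e-12)

    def test_proteomic_effect_only(self):
        assert score_proteomic(2.37, 0, 0).total == pytest.approx(0.33, abs=1e-12)

    def test_metabolomic_imputed_effect_only(self):
        got = score_metabolomic([2, 3], 4, 0, 0).total
        assert got == pytest.approx(0.33 * 1.75 / 2.37, abs=1e-4)

    def test_metabolomic_at_reference_scores_one(self):
        assert score_metabolomic([2.37], 1, 4092, 11294).total == 1.0

    def test_metabolomic_minimal_case(self):
        assert score_metabolomic([1], 1, 0, 0).total == pytest.approx(0.33 / 2.37, abs=1e-4)

    def test_metabolomic_reduces_to_proteomic_when_single_link(self):
        for fold in (1.0, 1.8, 2.37, 5.0):
            tsm = score_metabolomic([fold], 1, 123, 456).total
            tsp = score_proteomic(fold, 123, 456).total
            assert tsm == pytest.approx(tsp, abs=1e-15)

    def test_terms_sum_to_total(self):
        b = score_proteomic(1.8, 321, 654)
        assert b.total == pytest.approx(b.effect_term + b.citation_term + b.publication_term,
                                        abs=1e-12)

    def test_invalid_evidence_is_fatal(self):
        with pytest.raises(ValueError):
            score_genetic(0.0, 1, 1)
        with pytest.raises(ValueError):
            score_proteomic(0.5, 1, 1)
        with pytest.raises(ValueError):
            score_genetic(1.5, -1, 0)

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(0.1, 50), st.integers(0, 10000), st.integers(0, 30000),
           st.floats(1.2, 8.0), st.integers(1, 10))
    def test_citation_term_homogeneity(self, or_value, C, H, c_scale, k):
        """Scaling C and c_ref together leaves the citation term unchanged."""
        base = ScoringConfig()
        scaled = ScoringConfig(c_ref=base.c_ref * k)
        a = score_genetic(or_value, C, H, base)
        b = score_genetic(or_value, C * k, H, scaled)
        assert a.citation_term == pytest.approx(b.citation_term, rel=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(0.5, 20), st.floats(0.01, 5), st.integers(0, 5000), st.integers(0, 12000))
    def test_strict_monotonicity_in_each_component(self, or_value, delta, C, H):
        assert score_genetic(or_value + delta, C, H).total > score_genetic(or_value, C, H).total
        assert score_genetic(or_value, C + 1, H).total > score_genetic(or_value, C, H).total
        assert score_genetic(or_value, C, H + 1).total > score_genetic(or_value, C, H).total


class TestScoreTarget:
    TARGET = {"uniprot_id": "P1", "platforms": {"proteomics", "genetics"},
              "linked_changed_metabolites": [], "total_linked_metabolites": 0}

    def test_single_platform_dispatch(self):
        target = dict(self.TARGET, platforms={"proteomics"})
        out = score_target(target, fold_by_target={"P1": -2.0})
        assert out.platform_used == "proteomics"
        assert out.total == score_proteomic(2.0, 0, 0).total

    def test_max_resolution_picks_higher_score(self):
        # TSp(1.2) ~ 0.167 < TSg(3.0) ~ 0.268
        out = score_target(self.TARGET, or_by_target={"P1": 3.0}, fold_by_target={"P1": 1.2})
        assert out.platform_used == "genetics"

    def test_priority_resolution_prefers_proteomics(self):
        out = score_target(self.TARGET, or_by_target={"P1": 3.0}, fold_by_target={"P1": 1.2},
                           resolution="priority")
        assert out.platform_used == "proteomics"
        assert out.total == pytest.approx(score_proteomic(1.2, 0, 0).total)

    def test_metabolomics_platform_uses_imputation(self):
        target = {"uniprot_id": "P9", "platforms": {"metabolomics"},
                  "linked_changed_metabolites": ["A", "B"], "total_linked_metabolites": 4}
        out = score_target(target, fold_by_metabolite={"A": 2.0, "B": -3.0})
        assert out.total == pytest.approx(score_metabolomic([2, 3], 4, 0, 0).total)

    def test_epigenetics_only_is_unscoreable(self):
        target = dict(self.TARGET, platforms={"epigenetics"})
        with pytest.raises(ValueError, match="scoreable"):
            score_target(target)

    def test_annotation_counts_feed_the_score(self):
        target = dict(self.TARGET, platforms={"genetics"})
        ann = {"citation_count": 4092, "publication_count": 11294, "role": "GOF"}
        out = score_target(target, or_by_target={"P1": 3.7}, annotation=ann)
        assert out.total == 1.0


class TestRanking:
    def _breakdown(self, acc, total):
        return ScoreBreakdown(uniprot_id=acc, platform_used="proteomics",
                              effect_term=total, citation_term=0.0,
                              publication_term=0.0, total=total)

    def test_control_pinned_to_one_and_ranked_first(self):
        # totals shaped like the published table: two novel targets below the control
        ranked = rank_targets([self._breakdown("P20138", 0.715),
                               self._breakdown("P14174", 0.438),
                               self._breakdown("P05067", 0.62)],
                              internal_control="P05067")
        assert [r.uniprot_id for r in ranked] == ["P05067", "P20138", "P14174"]
        assert ranked[0].total == 1.0 and ranked[0].is_internal_control
        assert [r.rank for r in ranked] == [1, 2, 3]

    def test_ties_break_by_accession(self):
        ranked = rank_targets([self._breakdown("B", 0.5), self._breakdown("A", 0.5)])
        assert [r.uniprot_id for r in ranked] == ["A", "B"]

    def test_empty_input_gives_empty_ranking(self):
        assert rank_targets([]) == []

    def test_duplicate_accession_is_fatal(self):
        with pytest.raises(ValueError, match="duplicate"):
            rank_targets([self._breakdown("A", 0.5), self._breakdown("A", 0.4)])

    def test_unknown_control_is_fatal(self):
        with pytest.raises(ValueError, match="internal control"):
            rank_targets([self._breakdown("A", 0.5)], internal_control="Z")

    def test_ranks_are_dense_from_one(self):
        ranked = rank_targets([self._breakdown(f"P{i}", 0.1 * i) for i in range(1, 8)])
        assert [r.rank for r in ranked] == list(range(1, 8))
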