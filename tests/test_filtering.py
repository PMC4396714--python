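import random

import pytest

from termscout.errors import ConfigurationError, TermscoutError
from termscout.filtering import (
    FilterConfig,
    compare_to_ontology,
    df_band,
    df_band_filter,
    filter_relations,
    recommend_terms,
)
from termscout.lexicon import ConceptMatch
from termscout.preprocess import NGram
from termscout.relations import HierarchyRelation, LexicoSyntacticPattern, SynonymGroup
from termscout.scoring import TermCandidate


def _candidate(
    surface,
    f=10,
    df_clin=3,
    df_bio=2,
    match=None,
    cvalue=0.0,
    termhood_score=0.0,
):
    cand = TermCandidate(ngram=NGram(surface=surface, length_words=len(surface.split())))
    cand.f_a = f
    cand.doc_freq = {"clinical": df_clin, "biomedical": df_bio}
    cand.df_combined = df_clin + df_bio
    cand.concept_match = match
    cand.cvalue = cvalue
    cand.termhood = termhood_score
    return cand


def _match(surface, cui="C1", tui="T047", kind="full"):
    return ConceptMatch(
        surface=surface, cui=cui, tui=tui, kind=kind,
        words_in_common=1, extra_words=0, entry_index=0,
    )


class TestDfBand:
    def test_band_bounds(self):
        low, high = df_band(20, 100, FilterConfig())
        assert (low, high) == (1, 95)

    def test_candidate_above_band_excluded(self):
        cands = {"x": _candidate("x", df_clin=20, df_bio=76)}  # df 96 > 95
        assert df_band_filter(cands, 20, 100) == {}

    def test_candidate_at_lower_bound_kept(self):
        cands = {"x": _candidate("x", df_clin=1, df_bio=0)}
        assert "x" in df_band_filter(cands, 20, 100)

    def test_minimum_lower_bound_is_one(self):
        low, _ = df_band(10, 100, FilterConfig())
        assert low == 1  # ceil(0.05*10) = 1 either way; "minimum value of 1"
        low, _ = df_band(5, 100, FilterConfig())
        assert low == 1

    def test_both_corpora_empty_is_an_error(self):
        with pytest.raises(TermscoutError, match="empty"):
            df_band(0, 0, FilterConfig())


class TestRecommendTerms:
    def test_full_matches_above_threshold_recommended(self):
        cands = {}
        for i in range(5):
            cands[f"hi{i}"] = _candidate(f"hi{i}", f=12, match=_match(f"hi{i}", cui=f"CH{i}"))
        for i in range(3):
            cands[f"lo{i}"] = _candidate(f"lo{i}", f=4, match=_match(f"lo{i}", cui=f"CL{i}"))
        rec = recommend_terms(cands)
        assert len(rec.terms) == 5
        assert all(t.filter_origin == "full" for t in rec.terms)

    def test_low_scoring_non_match_not_recommended(self):
        cands = {"x": _candidate("x y", f=12, cvalue=6.5, termhood_score=0.8889)}
        assert recommend_terms(cands).terms == []

    def test_high_cvalue_non_match_recommended(self):
        cands = {"x": _candidate("long term phrase", f=30, cvalue=55.0)}
        (term,) = recommend_terms(cands).terms
        assert term.filter_origin == "cvalue"

    def test_high_termhood_non_match_recommended(self):
        cands = {"x": _candidate("verbish phrase", f=12, termhood_score=5.0)}
        (term,) = recommend_terms(cands).terms
        assert term.filter_origin == "termhood"

    def test_shared_cui_terms_merge_into_one_entry(self):
        cands = {
            "heart attack": _candidate("heart attack", f=12, match=_match("heart attack", "C1")),
            "myocardial infarction": _candidate(
                "myocardial infarction", f=10, match=_match("myocardial infarction", "C1")
            ),
            "aorta": _candidate("aorta", f=12, match=_match("aorta", "C2")),
        }
        rec = recommend_terms(cands)
        assert len(rec.terms) == 2
        assert rec.merged_cui_groups == 1
        (merged,) = [t for t in rec.terms if t.merged_members]
        assert merged.surface == "heart attack"  # higher frequency wins
        assert merged.merged_members == ["myocardial infarction"]

    def test_qualitative_types_flagged_not_deleted(self):
        cands = {"borderline": _candidate("borderline", match=_match("borderline", tui="T080"))}
        (term,) = recommend_terms(cands).terms
        assert term.qualitative

    def test_corpus_scope_both_requires_presence_in_both(self):
        cands = {"aorta": _candidate("aorta", df_bio=0, match=_match("aorta"))}
        assert recommend_terms(cands).terms == []
        relaxed = FilterConfig(corpus_scope="clinical_only_allowed")
        assert len(recommend_terms(cands, relaxed).terms) == 1

    def test_exactly_one_filter_origin_per_term(self):
        cands = {
            "a": _candidate("a b", f=60, cvalue=60.0, termhood_score=6.0),
            "b": _candidate("b c", f=12, match=_match("b c", cui="C5", kind="partial")),
        }
        rec = recommend_terms(cands)
        origins = {t.surface: t.filter_origin for t in rec.terms}
        assert origins == {"a b": "cvalue", "b c": "partial"}

    def test_raising_thresholds_never_adds_terms(self):
        rng = random.Random(91)
        cands = {}
        for i in range(60):
            kind = rng.choice(["full", "partial", None])
            match = _match(f"t{i}", cui=f"C{i}", kind=kind) if kind else None
            cands[f"t{i}"] = _candidate(
                f"t{i}", f=rng.randint(1, 30), match=match,
                cvalue=rng.uniform(0, 80), termhood_score=rng.uniform(-1, 6),
            )
        base = len(recommend_terms(cands, FilterConfig()).terms)
        for threshold in (12, 15, 20, 40):
            cfg = FilterConfig(
                freq_threshold_full=threshold,
                freq_threshold_partial=threshold,
                freq_threshold_nonmatch=threshold,
            )
            higher = len(recommend_terms(cands, cfg).terms)
            assert higher <= base
            base = higher


class TestFilterRelations:
    def _recommended(self):
        cands = {"delirium": _candidate("delirium", match=_match("delirium"))}
        return recommend_terms(cands)

    def _group(self, members, method, frequency):
        return SynonymGroup(members=frozenset(members), method=method, frequency=frequency)

    def test_pattern_group_kept_at_frequency_one(self):
        kept, _ = filter_relations(
            [self._group({"delirium", "acute confusion"}, "lsp", 1)],
            [], self._recommended(),
        )
        assert len(kept) == 1

    def test_semantic_group_below_ten_dropped(self):
        kept, _ = filter_relations(
            [self._group({"delirium", "confusion"}, "tfidf", 3)],
            [], self._recommended(),
        )
        assert kept == []

    def test_group_without_recommended_member_dropped(self):
        kept, _ = filter_relations(
            [self._group({"unrelated", "terms"}, "lsp", 5)],
            [], self._recommended(),
        )
        assert kept == []

    def test_hierarchy_uses_pattern_threshold(self):
        pattern = LexicoSyntacticPattern("hierarchy", "%such%as%", "np1_parent")
        rel = HierarchyRelation(
            parent="disorders", child="delirium", pattern=pattern, frequency=1
        )
        _, kept = filter_relations([], [rel], self._recommended())
        assert kept == [rel]

    def test_output_is_subset_of_input(self):
        groups = [
            self._group({"delirium", "x"}, "lsp", 1),
            self._group({"y", "z"}, "context", 50),
        ]
        kept, _ = filter_relations(groups, [], self._recommended())
        assert set(id(g) for g in kept) <= set(id(g) for g in groups)


class TestCompareToOntology:
    def test_partial_match_by_shared_word(self):
        out = compare_to_ontology(["hallucinations"], ["visual hallucinations"])
        assert out == {"hallucinations": "partial"}

    def test_full_match(self):
        assert compare_to_ontology(["delirium"], ["delirium"]) == {"delirium": "full"}

    def test_reverse_direction_overlap(self):
        out = compare_to_ontology(["permanent cognitive decline and dementia"], ["dementia"])
        assert out["permanent cognitive decline and dementia"] == "partial"

    def test_no_overlap(self):
        assert compare_to_ontology(["aorta"], ["bowel"]) == {"aorta": "none"}

    def test_empty_ontology_is_an_error(self):
        with pytest.raises(TermscoutError, match="empty"):
            compare_to_ontology(["delirium"], ["  "])


class TestFilterConfig:
    def test_invalid_band_fractions_rejected(self):
        with pytest.raises(ConfigurationError):
            FilterConfig(df_band_low_frac=0.9, df_band_high_frac=0.5)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ConfigurationError):
            FilterConfig(freq_threshold_full=-1)

    def test_unknown_scope_rejected(self):
        with pytest.raises(ConfigurationError):
            FilterConfig(corpus_scope="biomedical_only")

    def test_round_trip_from_file(self, tmp_path):
        path = tmp_path / "run.cfg"
        path.write_text(
            "freq_threshold_full = 20\n"
            "corpus_scope = clinical_only_allowed\n"
            "cvalue_log_adjust = true\n"
            "# comment line\n",
            encoding="utf-8",
        )
        cfg = FilterConfig.from_file(path)
        assert cfg.freq_threshold_full == 20
        assert cfg.corpus_scope == "clinical_only_allowed"
        assert cfg.cvalue_log_adjust is True

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "run.cfg"
        path.write_text("not_a_key = 5\n", encoding="utf-8")
        with pytest.raises(ConfigurationError, match="not_a_key"):
            FilterConfig.from_file(path)
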