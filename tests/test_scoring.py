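import itertools
import math
import random

import numpy as np
import pytest

from termscout.errors import StateError, TermscoutError
from termscout.preprocess import ContextVector, NGram
from termscout.scoring import (
    TERMHOOD_COEFFS,
    TERMHOOD_INTERCEPT,
    CorpusMedians,
    TermCandidate,
    TermhoodFeatures,
    compute_nesting,
    context_similarity,
    corpus_medians,
    cosine,
    cvalue,
    termhood,
    termhood_features,
    tfidf_vector,
)


def _candidates(*pairs):
    """Candidate set from (surface, frequency) pairs, nesting computed."""
    out = {}
    for surface, f in pairs:
        ngram = NGram(surface=surface, length_words=len(surface.split()))
        out[surface.lower()] = TermCandidate(ngram=ngram, f_a=f)
    compute_nesting(out)
    return out


class TestCValue:
    def test_nested_candidate_discounted_by_mean_host_frequency(self):
        cands = _candidates(
            ("coronary artery", 10),
            ("coronary artery disease", 4),
            ("left coronary artery", 3),
        )
        # log2(2) * (10 - (4+3)/2)
        assert cvalue("coronary artery", cands) == pytest.approx(6.5)

    def test_non_nested_candidate(self):
        cands = _candidates(("obstructive coronary artery disease", 3))
        # log2(4) * 3
        assert cvalue("obstructive coronary artery disease", cands) == pytest.approx(6.0)

    def test_unigram_scores_zero(self):
        cands = _candidates(("aorta", 50))
        assert cvalue("aorta", cands) == 0.0

    def test_log_adjust_lets_unigrams_score(self):
        cands = _candidates(("aorta", 50))
        assert cvalue("aorta", cands, log_adjust=True) == pytest.approx(50.0)

    def test_unknown_candidate_is_an_error(self):
        with pytest.raises(TermscoutError, match="not in"):
            cvalue("missing term", _candidates(("aorta", 1)))

    def test_monotone_in_frequency_for_non_nested(self):
        lo = _candidates(("coronary artery", 5))
        hi = _candidates(("coronary artery", 9))
        assert cvalue("coronary artery", hi) > cvalue("coronary artery", lo)

    def test_oracle_equivalence_on_random_candidate_sets(self):
        """Implementation equals a brute force enumerating all containment
        pairs, on 200 random candidate sets of up to 30 strings."""
        rng = random.Random(7041)
        vocab = [f"w{i}" for i in range(8)]
        for _ in range(200):
            surfaces = set()
            while len(surfaces) < rng.randint(2, 30):
                surfaces.add(" ".join(rng.sample(vocab, rng.randint(1, 4))))
            cands = _candidates(*((s, rng.randint(1, 20)) for s in surfaces))
            for key, cand in cands.items():
                words = key.split()
                hosts = []
                for other_key, other in cands.items():
                    other_words = other_key.split()
                    if len(other_words) <= len(words):
                        continue
                    if any(
                        other_words[i : i + len(words)] == words
                        for i in range(len(other_words) - len(words) + 1)
                    ):
                        hosts.append(other.f_a)
                if hosts:
                    expected = math.log2(len(words)) * (
                        cand.f_a - sum(hosts) / len(hosts)
                    )
                else:
                    expected = math.log2(len(words)) * cand.f_a
                assert cvalue(key, cands) == pytest.approx(expected)


class TestTermhood:
    def test_all_zero_features_give_intercept(self):
        assert termhood(TermhoodFeatures()) == pytest.approx(-0.7836)

    def test_noun_phrase_noun_term(self):
        features = TermhoodFeatures(
            first_pos_noun=1, last_pos_noun=1, np_value=1
        )
        assert termhood(features) == pytest.approx(0.8889)

    def test_two_first_pos_features_rejected(self):
        features = TermhoodFeatures(first_pos_noun=1, first_pos_verb=1)
        with pytest.raises(TermscoutError, match="at most one"):
            termhood(features)

    def test_equals_dot_product_for_all_legal_feature_vectors(self):
        names = list(TERMHOOD_COEFFS)
        coeffs = np.array([TERMHOOD_COEFFS[n] for n in names])
        n_checked = 0
        for bits in itertools.product((0, 1), repeat=12):
            values = dict(zip(names, bits))
            if sum(v for k, v in values.items() if k.startswith("first_pos")) > 1:
                continue
            if sum(v for k, v in values.items() if k.startswith("last_pos")) > 1:
                continue
            expected = TERMHOOD_INTERCEPT + float(np.dot(coeffs, bits))
            assert termhood(TermhoodFeatures(**values)) == pytest.approx(expected)
            n_checked += 1
        assert n_checked == 5 * 5 * 16  # 5 first-POS states x 5 last-POS x 2^4


class TestTermhoodFeatures:
    def _candidate(self, surface="aorta", f=5, df=3, parents=(), children=()):
        cand = TermCandidate(ngram=NGram(surface=surface, length_words=len(surface.split())))
        cand.f_a = f
        cand.df_combined = df
        cand.nest_parents = set(parents)
        cand.nest_children = set(children)
        cand.pos_first["NN"] = f
        cand.pos_last["NN"] = f
        cand.np_exact = True
        return cand

    def test_statistic_equal_to_median_scores_zero(self):
        cand = self._candidate(df=3)
        medians = CorpusMedians(repeat_sup=0, repeat_sub=0, doc_freq=3)
        features = termhood_features(cand, medians)
        assert features.distinct_perhost_greater_median == 0

    def test_noun_np_candidate(self):
        features = termhood_features(
            self._candidate(), CorpusMedians(0, 0, 10)
        )
        assert features.first_pos_noun == 1
        assert features.last_pos_noun == 1
        assert features.np_value == 1

    def test_zero_parents_below_positive_median(self):
        features = termhood_features(
            self._candidate(), CorpusMedians(repeat_sup=2, repeat_sub=0, doc_freq=0)
        )
        assert features.repeat_sup_greater_median == 0

    def test_missing_medians_is_a_state_error(self):
        with pytest.raises(StateError, match="corpus statistics"):
            termhood_features(self._candidate(), None)

    def test_corpus_medians_requires_candidates(self):
        with pytest.raises(StateError):
            corpus_medians({})


def _tf_candidate(tf):
    cand = TermCandidate(ngram=NGram(surface="t", length_words=1))
    cand.tf = dict(tf)
    cand.f_a = sum(tf.values())
    return cand


class TestTfIdf:
    def test_worked_value(self):
        # N=10, f_{i,1}=4, max freq in doc = 8, n_i=2 -> 0.5 * log10(5)
        doc_pos = {f"d{i}": i for i in range(10)}
        max_freq = np.array([8.0] + [1.0] * 9)
        cand = _tf_candidate({"d0": 4, "d1": 1})
        vec = tfidf_vector(cand, doc_pos, max_freq, 10)
        assert vec[0] == pytest.approx(0.349485, abs=1e-6)

    def test_term_in_every_document_has_zero_vector(self):
        doc_pos = {f"d{i}": i for i in range(4)}
        cand = _tf_candidate({d: 2 for d in doc_pos})
        vec = tfidf_vector(cand, doc_pos, np.full(4, 2.0), 4)
        assert not vec.any()

    def test_absent_docs_stay_zero(self):
        doc_pos = {"d0": 0, "d1": 1, "d2": 2}
        vec = tfidf_vector(_tf_candidate({"d0": 1}), doc_pos, np.ones(3), 3)
        assert vec[1] == 0.0 and vec[2] == 0.0

    def test_term_absent_from_corpus_is_an_error(self):
        with pytest.raises(TermscoutError, match="does not occur"):
            tfidf_vector(_tf_candidate({}), {"d0": 0}, np.ones(1), 1)


class TestCosine:
    def test_self_similarity_is_one(self):
        v = np.array([0.3, 1.2, 0.0])
        assert cosine(v, v) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        assert cosine(np.array([1, 0, 0]), np.array([0, 1, 0])) == pytest.approx(0.0)

    def test_worked_value(self):
        assert cosine(np.array([1, 1, 0]), np.array([1, 0, 0])) == pytest.approx(
            1 / math.sqrt(2)
        )

    def test_zero_vector_is_an_error(self):
        with pytest.raises(TermscoutError, match="zero vector"):
            cosine(np.zeros(3), np.ones(3))

    def test_dimension_mismatch_is_an_error(self):
        with pytest.raises(TermscoutError, match="dimension"):
            cosine(np.ones(2), np.ones(3))

    def test_idf_invariance(self):
        """cosine(TF-IDF vectors) == cosine(TF vectors) to 1e-12: the IDF
        factor is a per-term positive scalar and cancels."""
        rng = np.random.default_rng(4807)
        for _ in range(50):
            n_docs = int(rng.integers(3, 12))
            tf = rng.integers(0, 5, size=(2, n_docs)).astype(float)
            for row in tf:
                if not row.any():
                    row[0] = 1.0
            max_freq = np.maximum(tf.max(axis=0), 1.0)
            norm_tf = tf / max_freq
            idf = np.array(
                [math.log10(n_docs / np.count_nonzero(row)) + 0.1 for row in tf]
            )  # +0.1 keeps the scalar positive even for ubiquitous terms
            tfidf = norm_tf * idf[:, None]
            assert cosine(tfidf[0], tfidf[1]) == pytest.approx(
                cosine(norm_tf[0], norm_tf[1]), abs=1e-12
            )


class TestContextSimilarity:
    def _vector(self, word_by_slot):
        vec = ContextVector()
        for off, words in word_by_slot.items():
            for word in words:
                vec.add(off, word)
        return vec

    def test_identical_contexts_score_one(self):
        slots = {off: {f"w{off}"} for off in ContextVector.OFFSETS}
        assert context_similarity(self._vector(slots), self._vector(slots)) == 1.0

    def test_disjoint_contexts_score_zero(self):
        a = self._vector({off: {"a"} for off in ContextVector.OFFSETS})
        b = self._vector({off: {"b"} for off in ContextVector.OFFSETS})
        assert context_similarity(a, b) == 0.0

    def test_eight_shared_slots_meet_the_threshold(self):
        offsets = list(ContextVector.OFFSETS)
        a = self._vector({off: {"shared"} for off in offsets})
        b_slots = {off: {"shared"} for off in offsets[:8]}
        b_slots.update({off: {"different"} for off in offsets[8:]})
        b = self._vector(b_slots)
        assert context_similarity(a, b) == pytest.approx(0.80)

    def test_symmetric_and_duplicate_invariant(self):
        a = self._vector({1: {"x"}, -1: {"y"}})
        b = self._vector({1: {"x", "z"}, 2: {"q"}})
        assert context_similarity(a, b) == context_similarity(b, a)
        a.add(1, "x")  # re-adding an already-seen word changes nothing
        assert context_similarity(a, b) == pytest.approx(0.1)
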