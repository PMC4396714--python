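"""Term scoring: c-value, Termhood, TF-IDF vectors and similarities.

c-value rewards long, frequent candidate strings while discounting the
frequency a nested string inherits from the longer candidates containing
it.  Termhood is a fixed-coefficient logistic log-odds score over twelve
binary lexical/statistical features.  TF-IDF vectors have one entry per
document: term frequency normalized by the document's maximum candidate
frequency, scaled by log10(N / n_i); note the IDF factor is a per-term
scalar, so cosine similarity between two terms' TF-IDF vectors equals the
cosine of their raw TF vectors.
"""

from __future__ import annotations

import math
import statistics
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from termscout.corpus import Corpus
from termscout.errors import ConfigurationError, StateError, TermscoutError
from termscout.lexicon import ConceptMatch
from termscout.preprocess import (
    ADJ_TAGS,
    ADV_TAGS,
    NOUN_TAGS,
    VERB_TAGS,
    ContextVector,
    NGram,
    Sentence,
    context_windows,
    extract_ngrams,
    remove_stopword_candidates,
)

#: Fixed Termhood log-odds coefficients (intercept first).
TERMHOOD_INTERCEPT = -0.7836
TERMHOOD_COEFFS: dict[str, float] = {
    "first_pos_adjective": 0.7541,
    "first_pos_adverb": -1.3722,
    "first_pos_noun": 0.3541,
    "first_pos_verb": 1.4182,
    "last_pos_adjective": -0.7722,
    "last_pos_adverb": 2.2576,
    "last_pos_noun": 0.0285,
    "last_pos_verb": 0.6038,
    "np_value": 1.2899,
    "repeat_sup_greater_median": 1.0475,
    "repeat_sub_greater_median": 0.8417,
    "distinct_perhost_greater_median": 0.8422,
}

_POS_CLASS = {}
_POS_CLASS.update({t: "adjective" for t in ADJ_TAGS})
_POS_CLASS.update({t: "adverb" for t in ADV_TAGS})
_POS_CLASS.update({t: "noun" for t in NOUN_TAGS})
_POS_CLASS.update({t: "verb" for t in VERB_TAGS})


@dataclass
class TermhoodFeatures:
    """Twelve binary indicators; at most one first-POS and one last-POS set."""

    first_pos_adjective: int = 0
    first_pos_adverb: int = 0
    first_pos_noun: int = 0
    first_pos_verb: int = 0
    last_pos_adjective: int = 0
    last_pos_adverb: int = 0
    last_pos_noun: int = 0
    last_pos_verb: int = 0
    np_value: int = 0
    repeat_sup_greater_median: int = 0
    repeat_sub_greater_median: int = 0
    distinct_perhost_greater_median: int = 0

    def as_dict(self) -> dict[str, int]:
        return {name: getattr(self, name) for name in TERMHOOD_COEFFS}

    def validate(self) -> None:
        values = self.as_dict()
        if any(v not in (0, 1) for v in values.values()):
            raise TermscoutError("Termhood features must be binary")
        firsts = sum(v for k, v in values.items() if k.startswith("first_pos"))
        lasts = sum(v for k, v in values.items() if k.startswith("last_pos"))
        if firsts > 1 or lasts > 1:
            raise TermscoutError(
                "at most one first-POS and one last-POS feature may be set"
            )


@dataclass
class TermCandidate:
    """An N-gram candidate with its corpus statistics and scores."""

    ngram: NGram
    f_a: int = 0
    doc_freq: dict[str, int] = field(default_factory=dict)  # per corpus class
    df_combined: int = 0
    tf: dict[str, int] = field(default_factory=dict)  # doc_id -> frequency
    nest_parents: set[str] = field(default_factory=set)  # candidates containing a
    nest_children: set[str] = field(default_factory=set)  # contained within a
    concept_match: ConceptMatch | None = None
    context: ContextVector | None = None
    pos_first: Counter = field(default_factory=Counter)
    pos_last: Counter = field(default_factory=Counter)
    np_exact: bool = False  # some occurrence spans exactly an NP chunk
    cvalue: float | None = None
    termhood: float | None = None

    @property
    def surface(self) -> str:
        return self.ngram.surface

    @property
    def key(self) -> str:
        return self.ngram.key

    @property
    def words(self) -> tuple[str, ...]:
        return tuple(self.key.split())

    @property
    def length_words(self) -> int:
        return self.ngram.length_words


# ---------------------------------------------------------------------------
# candidate assembly


def _is_contiguous_subseq(inner: Sequence[str], outer: Sequence[str]) -> bool:
    n, m = len(inner), len(outer)
    if n > m:
        return False
    return any(tuple(outer[i : i + n]) == tuple(inner) for i in range(m - n + 1))


def compute_nesting(candidates: Mapping[str, TermCandidate]) -> None:
    """Link each candidate to the candidates containing it (contiguous,
    case-folded word subsequence) and vice versa."""
    by_word: dict[str, list[str]] = {}
    for key, cand in candidates.items():
        for word in set(cand.words):
            by_word.setdefault(word, []).append(key)
    for key, cand in candidates.items():
        hosts = {k for k in by_word.get(cand.words[0], []) if k != key}
        for host_key in hosts:
            host = candidates[host_key]
            if host.length_words > cand.length_words and _is_contiguous_subseq(
                cand.words, host.words
            ):
                cand.nest_parents.add(host_key)
                host.nest_children.add(key)


def assemble_candidates(
    corpus: Corpus,
    sentences_by_doc: Mapping[str, Sequence[Sentence]],
    stoplist: Iterable[str] | None = None,
) -> dict[str, TermCandidate]:
    """Build scored-candidate shells from chunked sentences.

    Collects N-grams, removes all-stop-word candidates, tallies per-class
    frequencies and document frequencies, modal first/last POS, NP-chunk
    identity, context vectors and nesting links.
    """
    all_sentences = [s for doc in corpus for s in sentences_by_doc[doc.doc_id]]
    grams = remove_stopword_candidates(extract_ngrams(all_sentences), stoplist)
    doc_class = {doc.doc_id: doc.corpus_class for doc in corpus}
    candidates: dict[str, TermCandidate] = {}
    for key, gram in grams.items():
        cand = TermCandidate(ngram=gram)
        docs_by_class: dict[str, set[str]] = {}
        for doc_id, sent_idx, (start, end) in gram.occurrences:
            cand.f_a += 1
            cand.tf[doc_id] = cand.tf.get(doc_id, 0) + 1
            docs_by_class.setdefault(doc_class[doc_id], set()).add(doc_id)
            sent = sentences_by_doc[doc_id][sent_idx]
            cand.pos_first[sent.tokens[start].pos] += 1
            cand.pos_last[sent.tokens[end - 1].pos] += 1
            if any(
                c.kind == "NP" and c.start == start and c.end == end
                for c in sent.chunks
            ):
                cand.np_exact = True
        cand.doc_freq = {cls: len(ids) for cls, ids in docs_by_class.items()}
        cand.df_combined = sum(cand.doc_freq.values())
        candidates[key] = cand
    compute_nesting(candidates)
    vectors = context_windows(grams, sentences_by_doc)
    for key, cand in candidates.items():
        cand.context = vectors[key]
    return candidates


# ---------------------------------------------------------------------------
# c-value


def cvalue(
    candidate: TermCandidate | str,
    candidates: Mapping[str, TermCandidate],
    log_adjust: bool = False,
) -> float:
    """c-value of a candidate within the extracted candidate set.

    Non-nested: log2|a| * f(a).  Nested: log2|a| * (f(a) - mean frequency of
    the candidates containing a).  |a| is the word count, so unigrams score
    0 under the printed formula; ``log_adjust`` switches to log2(|a|+1) for
    callers who want unigrams to participate.
    """
    if isinstance(candidate, str):
        key = candidate.lower()
        if key not in candidates:
            raise TermscoutError(f"candidate {candidate!r} not in candidate set")
        candidate = candidates[key]
    elif candidate.key not in candidates:
        raise TermscoutError(f"candidate {candidate.surface!r} not in candidate set")
    log_term = math.log2(candidate.length_words + (1 if log_adjust else 0))
    parents = candidate.nest_parents
    if not parents:
        return log_term * candidate.f_a
    discount = sum(candidates[p].f_a for p in parents) / len(parents)
    return log_term * (candidate.f_a - discount)


# ---------------------------------------------------------------------------
# Termhood


@dataclass(frozen=True)
class CorpusMedians:
    repeat_sup: float
    repeat_sub: float
    doc_freq: float


def corpus_medians(candidates: Mapping[str, TermCandidate]) -> CorpusMedians:
    """Medians of nesting counts and document frequency over all candidates."""
    if not candidates:
        raise StateError("no candidates; run corpus statistics first")
    values = list(candidates.values())
    return CorpusMedians(
        repeat_sup=statistics.median(len(c.nest_parents) for c in values),
        repeat_sub=statistics.median(len(c.nest_children) for c in values),
        doc_freq=statistics.median(c.df_combined for c in values),
    )


def _modal_pos_class(counter: Counter) -> str | None:
    """Modal POS class; ties break by frequency then tag alphabetical order."""
    if not counter:
        return None
    tag = min(counter.items(), key=lambda kv: (-kv[1], kv[0]))[0]
    return _POS_CLASS.get(tag)


def termhood_features(
    candidate: TermCandidate, medians: CorpusMedians | None
) -> TermhoodFeatures:
    """Binary feature vector for the Termhood score.

    First/last POS comes from the modal tag across occurrences; the three
    median comparisons are strict (a tie at the median scores 0).
    """
    if medians is None:
        raise StateError(
            "corpus medians unavailable; run corpus statistics (corpus_medians) first"
        )
    features = TermhoodFeatures()
    first = _modal_pos_class(candidate.pos_first)
    if first:
        setattr(features, f"first_pos_{first}", 1)
    last = _modal_pos_class(candidate.pos_last)
    if last:
        setattr(features, f"last_pos_{last}", 1)
    features.np_value = int(candidate.np_exact)
    features.repeat_sup_greater_median = int(
        len(candidate.nest_parents) > medians.repeat_sup
    )
    features.repeat_sub_greater_median = int(
        len(candidate.nest_children) > medians.repeat_sub
    )
    features.distinct_perhost_greater_median = int(
        candidate.df_combined > medians.doc_freq
    )
    return features


def termhood(features: TermhoodFeatures) -> float:
    """Log-odds that a candidate is a domain term, from fixed coefficients."""
    features.validate()
    value = TERMHOOD_INTERCEPT
    for name, coeff in TERMHOOD_COEFFS.items():
        value += coeff * getattr(features, name)
    return value


# ---------------------------------------------------------------------------
# TF-IDF and similarities


def tfidf_matrix(
    candidates: Mapping[str, TermCandidate], corpus: Corpus
) -> tuple[dict[str, np.ndarray], list[str]]:
    """Per-candidate TF-IDF vectors over the combined corpus documents.

    TF_{i,j} = f_{i,j} / max_z f_{z,j} (max over candidate keywords in doc
    j); IDF_i = log10(N / n_i).  Returns vectors keyed by candidate plus the
    document order defining the vector dimension.
    """
    doc_ids = [doc.doc_id for doc in corpus]
    doc_pos = {d: i for i, d in enumerate(doc_ids)}
    n_docs = len(doc_ids)
    if n_docs == 0:
        raise StateError("empty corpus")
    max_freq = np.zeros(n_docs)
    for cand in candidates.values():
        for doc_id, freq in cand.tf.items():
            pos = doc_pos[doc_id]
            if freq > max_freq[pos]:
                max_freq[pos] = freq
    vectors: dict[str, np.ndarray] = {}
    for key, cand in candidates.items():
        vectors[key] = tfidf_vector(cand, doc_pos, max_freq, n_docs)
    return vectors, doc_ids


def tfidf_vector(
    candidate: TermCandidate,
    doc_pos: Mapping[str, int],
    max_freq: np.ndarray,
    n_docs: int,
) -> np.ndarray:
    n_i = len(candidate.tf)
    if n_i == 0:
        raise TermscoutError(
            f"term {candidate.surface!r} does not occur in the corpus"
        )
    idf = math.log10(n_docs / n_i)
    vec = np.zeros(n_docs)
    for doc_id, freq in candidate.tf.items():
        pos = doc_pos[doc_id]
        vec[pos] = (freq / max_freq[pos]) * idf
    return vec


def cosine(v1: np.ndarray, v2: np.ndarray) -> float:
    """Standard cosine similarity; zero vectors have no defined direction."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape:
        raise TermscoutError(f"dimension mismatch: {v1.shape} vs {v2.shape}")
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        raise TermscoutError("cosine similarity is undefined for a zero vector")
    return float(np.dot(v1, v2) / (n1 * n2))


def context_similarity(c1: ContextVector, c2: ContextVector) -> float:
    """Fraction of the 10 positional slots where the word sets intersect."""
    hits = sum(
        1 for off in ContextVector.OFFSETS if c1.slots[off] & c2.slots[off]
    )
    return hits / 10.0


def score_candidates(
    candidates: Mapping[str, TermCandidate],
    cvalue_log_adjust: bool = False,
) -> None:
    """Fill in cvalue and termhood for every candidate, in place."""
    if not candidates:
        return
    medians = corpus_medians(candidates)
    for cand in candidates.values():
        cand.cvalue = cvalue(cand, candidates, log_adjust=cvalue_log_adjust)
        cand.termhood = termhood(termhood_features(cand, medians))


def validate_threshold(value: float, name: str) -> None:
    if not 0.0 <= value <= 1.0:
        raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
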