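"""Terminology dictionary lookup: full and partial concept matches.

The dictionary is a minimal UMLS-style join — TSV rows ``CUI<TAB>TUI<TAB>STR``
— indexed as an inverted word index.  Matching follows the recommendation
criteria rather than any engine-specific relevance score: a *full* match is
exact case-insensitive token-sequence equality; a *partial* match shares at
least one word (word-order agnostic), is restricted to an allowed set of
semantic types, and is ranked by most words in common, then fewest extra
words, then dictionary insertion order.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

from termscout.errors import DictionaryError
from termscout.preprocess import NGram, tokenize

logger = logging.getLogger(__name__)

#: The 16 semantic types admitted for partial matches and final
#: recommendations (disorders, anatomy, findings, qualitative/quantitative
#: concepts).
DEFAULT_ALLOWED_TUIS = frozenset(
    {
        "T020",  # Acquired Abnormality
        "T190",  # Anatomical Abnormality
        "T049",  # Cell or Molecular Dysfunction
        "T019",  # Congenital Abnormality
        "T047",  # Disease or Syndrome
        "T050",  # Experimental Model of Disease
        "T037",  # Injury or Poisoning
        "T048",  # Mental or Behavioral Dysfunction
        "T191",  # Neoplastic Process
        "T046",  # Pathologic Function
        "T184",  # Sign or Symptom
        "T033",  # Finding
        "T029",  # Body Location or Region
        "T080",  # Qualitative Concept
        "T023",  # Body Part, Organ or Organ Component
        "T081",  # Quantitative Concept
    }
)

#: Semantic types that are relevant to ontology building but not domain
#: specific; recommended terms of these types are flagged for a separate
#: review section.
QUALITATIVE_TUIS = frozenset({"T080", "T081"})


@dataclass(frozen=True)
class DictionaryEntry:
    cui: str
    tui: str
    term: str

    def __post_init__(self) -> None:
        if not (self.cui and self.tui and self.term):
            raise DictionaryError(f"dictionary entry has empty field: {self!r}")


@dataclass(frozen=True)
class SemanticTypeSet:
    allowed_tuis: frozenset[str] = DEFAULT_ALLOWED_TUIS
    qualitative_tuis: frozenset[str] = QUALITATIVE_TUIS

    def __post_init__(self) -> None:
        if not self.qualitative_tuis <= self.allowed_tuis:
            raise DictionaryError("qualitative TUIs must be a subset of allowed TUIs")


@dataclass(frozen=True)
class ConceptMatch:
    surface: str
    cui: str
    tui: str
    kind: str  # "full" | "partial"
    words_in_common: int
    extra_words: int
    entry_index: int  # dictionary insertion order, the final tie-break

    @property
    def match_score(self) -> tuple[int, int, int]:
        """Orderable score: more common words, fewer extra, earlier entry."""
        return (-self.words_in_common, self.extra_words, self.entry_index)


def _words(term: str) -> tuple[str, ...]:
    return tuple(t.surface.lower() for t in tokenize(term))


class TermIndex:
    """Case-insensitive inverted word index over dictionary entries.

    Entries keep insertion order; duplicates on (cui, term) are logged and
    dropped so ties stay deterministic.
    """

    def __init__(self, entries: Sequence[DictionaryEntry]):
        if not entries:
            raise DictionaryError("cannot index an empty dictionary")
        self.entries: list[DictionaryEntry] = []
        self._entry_words: list[tuple[str, ...]] = []
        self._by_term: dict[tuple[str, ...], list[int]] = {}
        self._by_word: dict[str, list[int]] = {}
        seen: set[tuple[str, str]] = set()
        for entry in entries:
            dedup_key = (entry.cui, entry.term.lower())
            if dedup_key in seen:
                logger.warning("duplicate dictionary entry dropped: %s", entry)
                continue
            seen.add(dedup_key)
            idx = len(self.entries)
            words = _words(entry.term)
            self.entries.append(entry)
            self._entry_words.append(words)
            self._by_term.setdefault(words, []).append(idx)
            for word in dict.fromkeys(words):
                self._by_word.setdefault(word, []).append(idx)

    def postings(self, word: str) -> list[int]:
        return self._by_word.get(word.lower(), [])

    def vocabulary(self) -> Iterable[str]:
        return self._by_word.keys()


def read_dictionary(path: str | os.PathLike) -> list[DictionaryEntry]:
    """Read a TSV dictionary ``CUI<TAB>TUI<TAB>STR`` (UTF-8, no header)."""
    path = os.fspath(path)
    try:
        with open(path, encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    except OSError as exc:
        raise DictionaryError(f"cannot read dictionary {path!r}: {exc}") from exc
    entries = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise DictionaryError(
                f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}"
            )
        entries.append(DictionaryEntry(*[p.strip() for p in parts]))
    if not entries:
        raise DictionaryError(f"dictionary {path!r} contains no entries")
    return entries


def _surface_of(ngram: NGram | str) -> str:
    return ngram.surface if isinstance(ngram, NGram) else ngram


def lookup_full(ngram: NGram | str, index: TermIndex) -> ConceptMatch | None:
    """Exact (case-insensitive, token-sequence) dictionary match.

    Several entries can share a term string; the first-inserted wins — ties
    are not arbitrated beyond index order.  Full matches carry no
    semantic-type restriction.
    """
    surface = _surface_of(ngram)
    words = _words(surface)
    hits = index._by_term.get(words)
    if not hits:
        return None
    entry = index.entries[hits[0]]
    return ConceptMatch(
        surface=surface,
        cui=entry.cui,
        tui=entry.tui,
        kind="full",
        words_in_common=len(set(words)),
        extra_words=0,
        entry_index=hits[0],
    )


def _common_subword(qwords: Sequence[str], ewords: Sequence[str]) -> int:
    """Greedy one-to-one matching where containment either way counts."""
    used = [False] * len(ewords)
    common = 0
    for qw in qwords:
        for k, ew in enumerate(ewords):
            if used[k]:
                continue
            if qw == ew or qw in ew or ew in qw:
                used[k] = True
                common += 1
                break
    return common


def lookup_partial(
    ngram: NGram | str,
    index: TermIndex,
    types: SemanticTypeSet | None = None,
    allow_subword: bool = False,
) -> ConceptMatch | None:
    """Best partial match: >=1 word in common, allowed semantic type only.

    Word order is ignored.  ``extra_words`` counts the unshared words on both
    sides.  With ``allow_subword``, a word also matches when one string
    contains the other (catches ad-hoc abbreviations like "ca" for "cancer",
    at the cost of spurious substring hits).
    """
    types = types or SemanticTypeSet()
    surface = _surface_of(ngram)
    qwords = tuple(dict.fromkeys(_words(surface)))
    if not qwords:
        return None
    if allow_subword:
        candidate_idx: set[int] = set()
        for vocab_word in index.vocabulary():
            if any(qw == vocab_word or qw in vocab_word or vocab_word in qw for qw in qwords):
                candidate_idx.update(index.postings(vocab_word))
        candidates = sorted(candidate_idx)
    else:
        seen: set[int] = set()
        candidates = []
        for qw in qwords:
            for idx in index.postings(qw):
                if idx not in seen:
                    seen.add(idx)
                    candidates.append(idx)
        candidates.sort()
    best: ConceptMatch | None = None
    for idx in candidates:
        entry = index.entries[idx]
        if entry.tui not in types.allowed_tuis:
            continue
        ewords = tuple(dict.fromkeys(index._entry_words[idx]))
        if allow_subword:
            common = _common_subword(qwords, ewords)
        else:
            common = len(set(qwords) & set(ewords))
        if common < 1:
            continue
        extra = len(ewords) + len(qwords) - 2 * common
        match = ConceptMatch(
            surface=surface,
            cui=entry.cui,
            tui=entry.tui,
            kind="partial",
            words_in_common=common,
            extra_words=extra,
            entry_index=idx,
        )
        if best is None or match.match_score < best.match_score:
            best = match
    return best


def lookup(
    ngram: NGram | str,
    index: TermIndex,
    types: SemanticTypeSet | None = None,
    allow_subword: bool = False,
) -> ConceptMatch | None:
    """Full match if one exists, otherwise best partial match."""
    return lookup_full(ngram, index) or lookup_partial(
        ngram, index, types=types, allow_subword=allow_subword
    )
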