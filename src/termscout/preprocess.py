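"""Linguistic preprocessing: tokens, sentences, POS tags, chunks, N-grams.

The POS tagger is pluggable.  The bundled backend is a deterministic
rule-plus-lexicon tagger over a closed vocabulary (packaged TSV): identical
input gives identical tags on every run and platform, which keeps the
downstream extraction logic testable independently of tagger quality.
Tokens are never stemmed; surfaces are case-folded only for aggregation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Iterator, Mapping, Sequence

from termscout.corpus import Document
from termscout.errors import ConfigurationError

# Alphanumeric runs (keeping mixes like "B12" whole), decimal numbers, and
# hyphen/apostrophe compounds ("a-fib", "patient's"); any other non-space
# character is its own token.
_TOKEN_RE = re.compile(r"\d+\.\d+|[^\W_]+(?:['\-][^\W_]+)*|\S")

_SENT_END = {".", "!", "?"}

NOUN_TAGS = frozenset({"NN", "NNS", "NNP", "NNPS"})
ADJ_TAGS = frozenset({"JJ", "JJR", "JJS"})
ADV_TAGS = frozenset({"RB", "RBR", "RBS"})
VERB_TAGS = frozenset({"VB", "VBD", "VBG", "VBN", "VBP", "VBZ", "MD"})
# Tags that may sit inside a noun phrase unconditionally.
_NP_SIMPLE = NOUN_TAGS | ADJ_TAGS | {"DT", "PDT", "PRP$", "CD", "FW", "POS"}
# Surfaces that always break a noun phrase so the Table-3 style connectors
# ("and other", "a type of") stay visible between the NPs.
NP_BREAK_WORDS = frozenset({"other", "type"})


@dataclass(frozen=True)
class Token:
    surface: str
    start: int  # char offset in the document, 0-based
    end: int  # half-open
    pos: str | None = None


@dataclass(frozen=True)
class Chunk:
    kind: str  # "NP" | "VP"
    start: int  # token index in sentence, 0-based
    end: int  # half-open
    surface: str


@dataclass
class Sentence:
    doc_id: str
    index: int
    tokens: list[Token]
    chunks: list[Chunk] = field(default_factory=list)

    @property
    def text_span(self) -> tuple[int, int]:
        return self.tokens[0].start, self.tokens[-1].end

    def token_surfaces(self) -> list[str]:
        return [t.surface for t in self.tokens]


@dataclass
class NGram:
    """A candidate term: a contiguous sub-span of an NP or VP chunk."""

    surface: str  # first-seen original casing, tokens joined by single spaces
    length_words: int
    occurrences: list[tuple[str, int, tuple[int, int]]] = field(default_factory=list)
    # (doc_id, sentence index, [start, end) token span)

    @property
    def key(self) -> str:
        return self.surface.lower()


@dataclass(frozen=True)
class Explanation:
    """NP1 - connector - NP2, the unit of pattern-based relation mining."""

    np1: str
    connector: str
    np2: str
    doc_id: str
    sentence_index: int
    connector_has_verb: bool


@dataclass
class ContextVector:
    """Ten positional word sets: offsets -5..-1 and +1..+5 around a term.

    Slots are sets — repeated context words collapse to one membership, so
    similarity does not reward repetition.
    """

    slots: dict[int, set[str]] = field(default_factory=dict)

    OFFSETS = tuple(range(-5, 0)) + tuple(range(1, 6))

    def __post_init__(self) -> None:
        for off in self.OFFSETS:
            self.slots.setdefault(off, set())

    def add(self, offset: int, word: str) -> None:
        self.slots[offset].add(word)


# ---------------------------------------------------------------------------
# tokenization & segmentation


def tokenize(text: str) -> list[Token]:
    """Every non-whitespace character lands in exactly one token."""
    return [Token(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def segment_and_tokenize(document: Document) -> list[Sentence]:
    """Split a document into sentences of tokens.

    A sentence ends at a terminal-punctuation token (``. ! ?``).  Decimal
    numbers are single tokens, so their dots never split sentences;
    dotted abbreviations do split — acceptable for note-style text.
    """
    sentences: list[Sentence] = []
    current: list[Token] = []
    for tok in tokenize(document.text):
        current.append(tok)
        if tok.surface in _SENT_END:
            sentences.append(Sentence(document.doc_id, len(sentences), current))
            current = []
    if current:
        sentences.append(Sentence(document.doc_id, len(sentences), current))
    return sentences


def sentence_texts(text: str) -> Iterator[str]:
    """Raw sentence strings (document text sliced at sentence spans)."""
    doc = Document(doc_id="_", corpus_class="clinical", text=text) if text.strip() else None
    if doc is None:
        return
    for sent in segment_and_tokenize(doc):
        start, end = sent.text_span
        yield text[start:end]


# ---------------------------------------------------------------------------
# POS tagging


class LexiconTagger:
    """Deterministic closed-vocabulary tagger.

    Order of rules: punctuation, numbers, lexicon (case-insensitive),
    ``-ly`` adverb suffix, default NN.  Clinical vocabulary absent from the
    lexicon therefore tags as a noun, which is the right default for
    term mining.
    """

    name = "lexicon"

    _PUNCT_TAGS = {".": ".", "!": ".", "?": ".", ",": ",", ";": ":", ":": ":",
                   "(": "(", ")": ")", '"': "''", "'": "''"}

    def __init__(self, lexicon: Mapping[str, str]):
        self._lexicon = {w.lower(): t for w, t in lexicon.items()}

    def tag(self, surfaces: Sequence[str]) -> list[str]:
        tags = []
        for word in surfaces:
            if word in self._PUNCT_TAGS:
                tags.append(self._PUNCT_TAGS[word])
            elif not any(ch.isalnum() for ch in word):
                tags.append("SYM")
            elif word[0].isdigit():
                tags.append("CD")
            elif word.lower() in self._lexicon:
                tags.append(self._lexicon[word.lower()])
            elif word.lower().endswith("ly") and len(word) > 3:
                tags.append("RB")
            else:
                tags.append("NN")
        return tags


def _load_packaged_lexicon() -> dict[str, str]:
    text = resources.files("termscout.data").joinpath("tagger_lexicon.tsv").read_text(
        encoding="utf-8"
    )
    lexicon: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        word, tag = line.split("\t")
        lexicon[word] = tag
    return lexicon


_DEFAULT_TAGGER: LexiconTagger | None = None


def get_tagger(name: str = "lexicon") -> LexiconTagger:
    """Return a tagging backend by name.

    Only the bundled deterministic ``lexicon`` backend ships with the
    package; other names raise a configuration error pointing at it.
    """
    global _DEFAULT_TAGGER
    if name != "lexicon":
        raise ConfigurationError(
            f"tagger backend {name!r} is not available; use the bundled "
            "deterministic 'lexicon' tagger"
        )
    if _DEFAULT_TAGGER is None:
        _DEFAULT_TAGGER = LexiconTagger(_load_packaged_lexicon())
    return _DEFAULT_TAGGER


# ---------------------------------------------------------------------------
# chunking


def _np_member(tokens: list[Token], i: int, run_started: bool) -> bool:
    tok = tokens[i]
    word = tok.surface.lower()
    if word in NP_BREAK_WORDS:
        return False
    if tok.pos in _NP_SIMPLE:
        return True
    if tok.pos in ADV_TAGS:
        # adverb joins only as an adjective premodifier ("highly sensitive")
        return i + 1 < len(tokens) and tokens[i + 1].pos in ADJ_TAGS
    if tok.pos == "CC" and run_started:
        # conjunction joins only between NP material ("CAM or CAM ICU"),
        # never before an NP break word ("and other ...")
        if i + 1 >= len(tokens):
            return False
        nxt = tokens[i + 1]
        if nxt.surface.lower() in NP_BREAK_WORDS:
            return False
        return nxt.pos in _NP_SIMPLE or (
            nxt.pos in ADV_TAGS and i + 2 < len(tokens) and tokens[i + 2].pos in ADJ_TAGS
        )
    return False


def _chunk(sentence: Sentence) -> list[Chunk]:
    tokens = sentence.tokens
    chunks: list[Chunk] = []
    i = 0
    n = len(tokens)
    while i < n:
        if _np_member(tokens, i, run_started=False):
            j = i + 1
            while j < n and _np_member(tokens, j, run_started=True):
                j += 1
            if any(t.pos in NOUN_TAGS for t in tokens[i:j]):
                surface = " ".join(t.surface for t in tokens[i:j])
                chunks.append(Chunk("NP", i, j, surface))
            i = j
        elif tokens[i].pos in VERB_TAGS:
            j = i + 1
            while j < n and tokens[j].pos in VERB_TAGS:
                j += 1
            surface = " ".join(t.surface for t in tokens[i:j])
            chunks.append(Chunk("VP", i, j, surface))
            i = j
        else:
            i += 1
    return chunks


def tag_and_chunk(sentence: Sentence, tagger: LexiconTagger | None = None) -> Sentence:
    """Attach one Penn tag per token, then compute NP/VP chunks.

    Determiners are retained inside NP chunks — nouns joined by "is a"
    matter for hierarchy mining.
    """
    if tagger is None:
        tagger = get_tagger()
    tags = tagger.tag(sentence.token_surfaces())
    tagged = [replace(tok, pos=tag) for tok, tag in zip(sentence.tokens, tags)]
    out = Sentence(sentence.doc_id, sentence.index, tagged)
    out.chunks = _chunk(out)
    return out


def preprocess_document(
    document: Document, tagger: LexiconTagger | None = None
) -> list[Sentence]:
    return [tag_and_chunk(s, tagger) for s in segment_and_tokenize(document)]


# ---------------------------------------------------------------------------
# N-gram candidates


def extract_ngrams(sentences: Iterable[Sentence]) -> dict[str, NGram]:
    """Emit every contiguous sub-span of every NP/VP chunk as a candidate.

    Candidates run from unigrams up to the full chunk — a k-token chunk
    yields k(k+1)/2 spans.  Aggregation is case-folded (key = lowercased
    surface) while the first-seen casing is retained for display.
    """
    out: dict[str, NGram] = {}
    for sent in sentences:
        for chunk in sent.chunks:
            toks = sent.tokens[chunk.start : chunk.end]
            k = len(toks)
            for i in range(k):
                for j in range(i + 1, k + 1):
                    surface = " ".join(t.surface for t in toks[i:j])
                    key = surface.lower()
                    gram = out.get(key)
                    if gram is None:
                        gram = NGram(surface=surface, length_words=j - i)
                        out[key] = gram
                    gram.occurrences.append(
                        (sent.doc_id, sent.index, (chunk.start + i, chunk.start + j))
                    )
    return out


def load_stopwords() -> frozenset[str]:
    text = resources.files("termscout.data").joinpath("stopwords.txt").read_text(
        encoding="utf-8"
    )
    return frozenset(w.strip() for w in text.splitlines() if w.strip())


def remove_stopword_candidates(
    candidates: dict[str, NGram], stoplist: Iterable[str] | None = None
) -> dict[str, NGram]:
    """Drop candidates made up entirely of stop words.

    Stop words *within* multi-word candidates are retained (determiners are
    deliberately kept inside noun phrases), so "the heart" survives while
    "the" and "of the" do not.
    """
    stops = frozenset(stoplist) if stoplist is not None else load_stopwords()
    return {
        key: gram
        for key, gram in candidates.items()
        if not all(w in stops for w in key.split())
    }


# ---------------------------------------------------------------------------
# explanations & context windows


def extract_explanations(sentence: Sentence) -> list[Explanation]:
    """One explanation per pair of *consecutive* NP chunks.

    The connector is the exact intervening token sequence (it may contain a
    verb phrase, a parenthesis, punctuation...).
    """
    nps = [c for c in sentence.chunks if c.kind == "NP"]
    out: list[Explanation] = []
    for left, right in zip(nps, nps[1:]):
        between = sentence.tokens[left.end : right.start]
        connector = " ".join(t.surface for t in between)
        out.append(
            Explanation(
                np1=left.surface,
                connector=connector,
                np2=right.surface,
                doc_id=sentence.doc_id,
                sentence_index=sentence.index,
                connector_has_verb=any(t.pos in VERB_TAGS for t in between),
            )
        )
    return out


def context_windows(
    candidates: dict[str, NGram],
    sentences_by_doc: Mapping[str, Sequence[Sentence]],
) -> dict[str, ContextVector]:
    """Positional context vectors: the five tokens before and after each
    occurrence, as per-offset word sets.  Offsets past the sentence edge
    leave the slot untouched."""
    vectors: dict[str, ContextVector] = {}
    for key, gram in candidates.items():
        vec = ContextVector()
        for doc_id, sent_idx, (start, end) in gram.occurrences:
            toks = sentences_by_doc[doc_id][sent_idx].tokens
            for off in range(1, 6):
                if start - off >= 0:
                    vec.add(-off, toks[start - off].surface.lower())
                if end - 1 + off < len(toks):
                    vec.add(off, toks[end - 1 + off].surface.lower())
        vectors[key] = vec
    return vectors
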