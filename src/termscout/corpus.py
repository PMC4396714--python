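"""Corpus loading, labelling and structural preparation.

A *document* is the unit over which document frequencies and TF-IDF columns
are defined, so corpus preparation (amalgamating short clinical summaries,
isolating article body text from PubMed-style XML, spotting boilerplate
pick-list sentences) happens here, before any linguistic processing.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from lxml import etree

from termscout.errors import CorpusError

logger = logging.getLogger(__name__)

CORPUS_CLASSES = ("clinical", "biomedical")


@dataclass(frozen=True)
class Document:
    """One text document with its corpus class fixed at load time."""

    doc_id: str
    corpus_class: str
    text: str
    source_format: str = "plain"

    def __post_init__(self) -> None:
        if self.corpus_class not in CORPUS_CLASSES:
            raise CorpusError(
                f"invalid corpus class {self.corpus_class!r}; "
                f"expected one of {CORPUS_CLASSES}"
            )
        if not self.text:
            raise CorpusError(f"document {self.doc_id!r} has empty text")


@dataclass
class Corpus:
    """An ordered, deterministically iterable collection of documents."""

    documents: list[Document] = field(default_factory=list)

    @property
    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CORPUS_CLASSES}
        for doc in self.documents:
            counts[doc.corpus_class] += 1
        return counts

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self):
        return iter(self.documents)

    def extend(self, other: "Corpus") -> "Corpus":
        """Combined corpus; document order is self's then other's."""
        seen = {d.doc_id for d in self.documents}
        dup = [d.doc_id for d in other.documents if d.doc_id in seen]
        if dup:
            raise CorpusError(f"duplicate doc_id(s) across corpora: {dup[:5]}")
        return Corpus(self.documents + other.documents)


def load_corpus(paths: Sequence[str | os.PathLike], corpus_class: str) -> Corpus:
    """Load plain-text files, one Document per file, in the given path order.

    Files are decoded as UTF-8; anything else is rejected.  Empty files are
    skipped with a logged warning.  ``doc_id`` is the file name without its
    extension (must be unique across the list).
    """
    if corpus_class not in CORPUS_CLASSES:
        raise CorpusError(
            f"invalid corpus class {corpus_class!r}; expected one of {CORPUS_CLASSES}"
        )
    documents: list[Document] = []
    seen: set[str] = set()
    for path in paths:
        path = os.fspath(path)
        try:
            with open(path, "rb") as fh:
                raw = fh.read()
        except OSError as exc:
            raise CorpusError(f"cannot read corpus file {path!r}: {exc}") from exc
        try:
            text = raw.decode("utf-8")
        except UnicodeDecodeError as exc:
            raise CorpusError(
                f"corpus file {path!r} is not valid UTF-8 (byte {exc.start})"
            ) from exc
        if not text.strip():
            logger.warning("skipping empty corpus file %s", path)
            continue
        doc_id = os.path.splitext(os.path.basename(path))[0]
        if doc_id in seen:
            raise CorpusError(f"duplicate doc_id {doc_id!r} from {path!r}")
        seen.add(doc_id)
        documents.append(Document(doc_id=doc_id, corpus_class=corpus_class, text=text))
    return Corpus(documents)


def load_corpus_dir(directory: str | os.PathLike, corpus_class: str) -> Corpus:
    """Load every ``.txt`` (and PubMed-style ``.xml``) file in a directory.

    Files load in sorted-name order so runs are reproducible.
    """
    directory = os.fspath(directory)
    if not os.path.isdir(directory):
        raise CorpusError(f"corpus directory {directory!r} does not exist")
    names = sorted(os.listdir(directory))
    txt = [os.path.join(directory, n) for n in names if n.endswith(".txt")]
    xml = [os.path.join(directory, n) for n in names if n.endswith(".xml")]
    corpus = load_corpus(txt, corpus_class)
    for path in xml:
        with open(path, "rb") as fh:
            raw = fh.read()
        doc_id = os.path.splitext(os.path.basename(path))[0]
        corpus.documents.append(
            parse_pubmed_xml(raw.decode("utf-8"), doc_id=doc_id, corpus_class=corpus_class)
        )
    return corpus


def save_corpus(corpus: Corpus, directory: str | os.PathLike) -> list[str]:
    """Write each document to ``<directory>/<doc_id>.txt`` (UTF-8), returning paths."""
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    paths = []
    for doc in corpus:
        path = os.path.join(directory, f"{doc.doc_id}.txt")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(doc.text)
        paths.append(path)
    return paths


def parse_pubmed_xml(
    xml_text: str, doc_id: str = "article", corpus_class: str = "biomedical"
) -> Document:
    """Isolate article body text from PubMed-style XML.

    Only the content of the ``<body>`` element is kept — title, abstract,
    metadata and references are dropped.  Paragraph texts are joined with a
    single space.
    """
    try:
        root = etree.fromstring(xml_text.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        raise CorpusError(f"malformed XML for {doc_id!r}: {exc}") from exc
    body = root.find(".//body")
    if body is None:
        raise CorpusError(f"no <body> element in XML for {doc_id!r}")
    parts: list[str] = []
    paragraphs = body.findall(".//p")
    for node in paragraphs if paragraphs else [body]:
        chunk = " ".join("".join(node.itertext()).split())
        if chunk:
            parts.append(chunk)
    text = " ".join(parts)
    if not text:
        raise CorpusError(f"no body text in XML for {doc_id!r}")
    return Document(
        doc_id=doc_id, corpus_class=corpus_class, text=text, source_format="pubmed_xml"
    )


def amalgamate_documents(corpus: Corpus, group_size: int) -> Corpus:
    """Concatenate documents in load order in groups of ``group_size``.

    Short clinical summaries are merged to reduce the number of TF-IDF
    columns; the final group may be smaller.  Member texts are joined with a
    single newline so sentence segmentation never merges across sources.
    """
    if group_size < 1:
        raise CorpusError(f"group_size must be >= 1, got {group_size}")
    if group_size == 1:
        return Corpus(list(corpus.documents))
    docs = corpus.documents
    out: list[Document] = []
    n_groups = math.ceil(len(docs) / group_size)
    for g in range(n_groups):
        members = docs[g * group_size : (g + 1) * group_size]
        out.append(
            Document(
                doc_id=f"amalg-{g:04d}",
                corpus_class=members[0].corpus_class,
                text="\n".join(d.text for d in members),
                source_format=members[0].source_format,
            )
        )
    return Corpus(out)


def detect_template_sentences(
    corpus: Corpus | Iterable[Document],
    prefix_len: int = 200,
    min_docs: int = 5,
) -> list[str]:
    """Find boilerplate (pick-list/template) sentences.

    Sentences are grouped by their first ``prefix_len`` characters (short
    sentences compare on their full length); a group is a template when its
    sentences occur in strictly more than ``min_docs`` distinct documents.
    Returns one representative per group — the first occurrence — ordered by
    first occurrence, which makes the result invariant to permuting the
    document list (as a set) and idempotent.
    """
    from termscout.preprocess import sentence_texts

    if prefix_len <= 0:
        raise CorpusError(f"prefix_len must be > 0, got {prefix_len}")
    first_seen: dict[str, tuple[int, str]] = {}
    docs_by_key: dict[str, set[str]] = {}
    order = 0
    for doc in corpus:
        for sent in sentence_texts(doc.text):
            key = sent[:prefix_len]
            if key not in first_seen:
                first_seen[key] = (order, sent)
                order += 1
            docs_by_key.setdefault(key, set()).add(doc.doc_id)
    hits = [
        first_seen[key]
        for key, doc_ids in docs_by_key.items()
        if len(doc_ids) > min_docs
    ]
    return [sent for _, sent in sorted(hits)]
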