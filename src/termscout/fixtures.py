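"""Seeded synthetic corpora with known ground truth.

The generator emulates the paired-corpus study design at desk scale: a
clinical-heavy pair of corpora (30 clinical / 10 biomedical documents by
default) with planted multi-word terms at controlled frequencies and
document frequencies, planted synonym pairs for each extraction mechanism,
planted hierarchy sentences, and planted boilerplate (template) sentences.
A toy dictionary and a ground-truth manifest accompany the corpora so the
whole pipeline is testable without any external resource.

Construction principles (what makes the ground truth exact):

* every planted occurrence sits in a scaffold sentence
  ``n v n of n v TERM v n in n .`` whose nouns/verbs come from small pools
  dedicated to that term, so context windows of different terms are
  disjoint except for the fixed function words;
* pool and filler words cycle deterministically, which caps their corpus
  frequency below the recommendation thresholds and keeps connector/NP2
  combinations aligned (no accidental shared-tail groups);
* a designed context-synonym pair shares its pools; a designed TF-IDF pair
  shares its document assignment; everything else gets distinct documents,
  keeping all non-designed cosines well under threshold;
* filler, pool, template and planted vocabularies are mutually disjoint.
"""

from __future__ import annotations

import json
import os
import random
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from termscout.errors import ConfigurationError
from termscout.preprocess import _load_packaged_lexicon

__all__ = [
    "FixtureSpec",
    "PlantedTerm",
    "PlantedSynonymPair",
    "PlantedHierarchy",
    "TemplateSentence",
    "default_spec",
    "generate",
    "recount_surface",
]

# 256 synthetic compound filler nouns; none collide with planted or
# dictionary vocabulary, none trip the tagger's suffix rules (default NN).
_NOUN_PREFIXES = (
    "north", "south", "east", "west", "blue", "green", "gray", "amber",
    "stone", "river", "cedar", "maple", "willow", "harbor", "meadow", "valley",
)
_NOUN_SUFFIXES = (
    "field", "gate", "bridge", "tower", "lane", "brook", "ridge", "grove",
    "cliff", "shore", "glen", "marsh", "peak", "dale", "ford", "moor",
)
# Verbs the shared-tail / pattern machinery must never see in filler text.
_RESERVED_VERBS = frozenset(
    {"known", "called", "caused", "associated", "referred", "related",
     "used", "found", "seen", "given"}
)


def _noun_inventory() -> list[str]:
    return [p + s for p in _NOUN_PREFIXES for s in _NOUN_SUFFIXES]


def _verb_inventory() -> list[str]:
    lexicon = _load_packaged_lexicon()
    return sorted(
        w for w, t in lexicon.items() if t == "VBD" and w not in _RESERVED_VERBS
    )


@dataclass(frozen=True)
class PlantedTerm:
    """A term planted with an explicit per-document occurrence plan.

    ``clinical_docs``/``biomedical_docs`` list ``(doc_index, n_occurrences)``
    pairs for *plain* scaffold sentences; mechanism sentences declared on
    pairs/hierarchies add further occurrences on top.
    """

    surface: str
    dict_status: str  # "full" | "partial-only" | "absent"
    cui: str | None = None
    tui: str | None = None
    dict_term: str | None = None  # for partial-only: the dictionary-side term
    clinical_docs: tuple[tuple[int, int], ...] = ()
    biomedical_docs: tuple[tuple[int, int], ...] = ()
    pool_group: str | None = None  # terms sharing a group share context pools


@dataclass(frozen=True)
class PlantedSynonymPair:
    members: tuple[str, str]
    mechanism: str  # "tfidf" | "context" | "lsp" | "shared_tail" | "cui"
    doc: int | None = None  # clinical doc for pattern mechanisms
    tail: str | None = None  # shared-tail NP2


@dataclass(frozen=True)
class PlantedHierarchy:
    parent: str
    child: str
    pattern: str
    docs: tuple[int, ...] = ()  # clinical docs, one sentence each


@dataclass(frozen=True)
class TemplateSentence:
    docs: tuple[int, ...]  # clinical docs carrying the verbatim sentence


@dataclass
class FixtureSpec:
    n_clinical_docs: int = 30
    n_biomedical_docs: int = 10
    planted_terms: list[PlantedTerm] = field(default_factory=list)
    planted_synonym_pairs: list[PlantedSynonymPair] = field(default_factory=list)
    planted_hierarchy: list[PlantedHierarchy] = field(default_factory=list)
    template_sentences: list[TemplateSentence] = field(default_factory=list)
    extra_dictionary: list[tuple[str, str, str]] = field(default_factory=list)
    seed: int = 0
    expected: dict | None = None  # ground-truth pipeline output, if known

    def validate(self) -> None:
        problems = []
        for term in self.planted_terms:
            for docs, limit, cls in (
                (term.clinical_docs, self.n_clinical_docs, "clinical"),
                (term.biomedical_docs, self.n_biomedical_docs, "biomedical"),
            ):
                if len({d for d, _ in docs}) != len(docs):
                    problems.append(f"{term.surface}: duplicate {cls} doc index")
                if any(d >= limit or d < 0 for d, _ in docs):
                    problems.append(
                        f"{term.surface}: {cls} df {len(docs)} needs doc index "
                        f"beyond the {limit} {cls} documents"
                    )
                if any(n < 1 for _, n in docs):
                    problems.append(f"{term.surface}: occurrence count < 1")
        by_surface = {t.surface: t for t in self.planted_terms}
        for pair in self.planted_synonym_pairs:
            missing = [m for m in pair.members if m not in by_surface]
            if missing and pair.mechanism != "shared_tail":
                problems.append(f"synonym pair references unplanted term(s) {missing}")
            if pair.mechanism == "tfidf":
                a, b = (by_surface[m] for m in pair.members)
                if (a.clinical_docs, a.biomedical_docs) != (
                    b.clinical_docs, b.biomedical_docs,
                ):
                    problems.append(
                        f"tfidf pair {pair.members} must share a document plan"
                    )
            if pair.mechanism == "context":
                a, b = (by_surface[m] for m in pair.members)
                if not a.pool_group or a.pool_group != b.pool_group:
                    problems.append(
                        f"context pair {pair.members} must share a pool_group"
                    )
        if problems:
            raise ConfigurationError(
                "infeasible fixture spec: " + "; ".join(problems)
            )


# ---------------------------------------------------------------------------
# the standard fixture


def default_spec(seed: int = 0) -> FixtureSpec:
    """The standard study-shaped fixture: 30 clinical + 10 biomedical docs,
    recommendation thresholds at their defaults (frequency 10, both corpora,
    5%/95% df band)."""

    def docs(*pairs):
        return tuple(pairs)

    terms = [
        # mechanism sentences add: 2 hierarchy (c0,c1) + 1 lsp (c2) -> f 8/4
        PlantedTerm("delirium", "full", "C001", "T047",
                    clinical_docs=docs((3, 1), (4, 1), (5, 1), (6, 1), (7, 1)),
                    biomedical_docs=docs((0, 1), (1, 1), (2, 1), (3, 1))),
        # lsp sentence in c2 adds 1 -> f 6/4
        PlantedTerm("acute confusional state", "full", "C001", "T047",
                    clinical_docs=docs((8, 1), (9, 1), (10, 1), (11, 1), (12, 1)),
                    biomedical_docs=docs((4, 1), (5, 1), (6, 1), (7, 1))),
        # shared-tail sentence in c13 adds 1 each -> f 7/3
        PlantedTerm("tremor", "full", "C002", "T184",
                    clinical_docs=docs((14, 1), (15, 1), (16, 1), (17, 1), (18, 1), (19, 1)),
                    biomedical_docs=docs((0, 1), (1, 1), (2, 1))),
        PlantedTerm("agitation", "full", "C003", "T184",
                    clinical_docs=docs((3, 1), (4, 1), (5, 1), (6, 1), (7, 1), (8, 1)),
                    biomedical_docs=docs((5, 1), (6, 1), (7, 1))),
        # not in the dictionary itself; partially matches "visual hallucinations"
        PlantedTerm("hallucinations", "partial-only", "C004", "T184",
                    dict_term="visual hallucinations",
                    clinical_docs=docs((9, 1), (10, 1), (11, 1), (12, 1), (13, 1), (14, 1), (15, 1)),
                    biomedical_docs=docs((0, 1), (1, 1), (2, 1))),
        # qualitative concept: recommended but flagged out of expert review
        PlantedTerm("borderline", "full", "C005", "T080",
                    clinical_docs=docs((16, 1), (17, 1), (18, 1), (19, 1), (20, 1), (21, 1), (22, 1)),
                    biomedical_docs=docs((3, 1), (4, 1), (5, 1))),
        # below the frequency threshold -> absent from recommendations
        PlantedTerm("sepsis", "full", "C006", "T047",
                    clinical_docs=docs((23, 1), (24, 1), (25, 1)),
                    biomedical_docs=docs((6, 1))),
        # clinical corpus only -> absent under corpus_scope=both
        PlantedTerm("aorta", "full", "C007", "T029",
                    clinical_docs=docs(*(((i, 1)) for i in range(12)))),
        # document frequency 30 > floor(0.95*30)=28 -> outside the df band
        PlantedTerm("pneumonia", "full", "C008", "T047",
                    clinical_docs=docs(*(((i, 1)) for i in range(28))),
                    biomedical_docs=docs((8, 1), (9, 1))),
        # designed TF-IDF pair: identical document plans
        PlantedTerm("dyspnea", "full", "C009", "T184",
                    clinical_docs=docs((20, 2), (21, 2), (22, 2), (23, 2)),
                    biomedical_docs=docs((8, 2))),
        PlantedTerm("breathlessness", "full", "C010", "T184",
                    clinical_docs=docs((20, 2), (21, 2), (22, 2), (23, 2)),
                    biomedical_docs=docs((8, 2))),
        # designed context pair: shared context pools, distinct documents
        PlantedTerm("lethargy", "full", "C011", "T184", pool_group="drowsy",
                    clinical_docs=docs((24, 2), (25, 2), (26, 2), (27, 2)),
                    biomedical_docs=docs((9, 2))),
        PlantedTerm("somnolence", "full", "C012", "T184", pool_group="drowsy",
                    clinical_docs=docs((28, 2), (29, 2), (15, 2), (16, 2)),
                    biomedical_docs=docs((9, 2))),
    ]
    pairs = [
        PlantedSynonymPair(("delirium", "acute confusional state"), "lsp", doc=2),
        PlantedSynonymPair(("delirium", "acute confusional state"), "cui"),
        PlantedSynonymPair(("tremor", "agitation"), "shared_tail", doc=13,
                           tail="alcohol withdrawal"),
        PlantedSynonymPair(("dyspnea", "breathlessness"), "tfidf"),
        PlantedSynonymPair(("lethargy", "somnolence"), "context"),
    ]
    hierarchy = [
        PlantedHierarchy("mental disorders", "delirium", "%such%as%", docs=(0, 1)),
    ]
    templates = [
        TemplateSentence(docs=(0, 1, 2, 3, 4, 5)),  # 6 docs: detected
        TemplateSentence(docs=(6, 7, 8, 9, 10)),  # exactly 5: below "more than 5"
    ]
    extra_dictionary = [
        ("C013", "T047", "bowel perforation"),
        ("C014", "T029", "lower bowel"),
    ]
    spec = FixtureSpec(
        planted_terms=terms,
        planted_synonym_pairs=pairs,
        planted_hierarchy=hierarchy,
        template_sentences=templates,
        extra_dictionary=extra_dictionary,
        seed=seed,
        expected=_default_expected(),
    )
    spec.validate()
    return spec


def _default_expected() -> dict:
    """Ground-truth pipeline output for the default spec under the default
    FilterConfig, derived from the plant design (not from running the
    pipeline): which terms clear which filter, the nested sub-N-grams of
    "acute confusional state" that partial-match its CUI and are absorbed by
    CUI merging, and the relation groups that survive phase F."""
    acs_subs = ["acute", "acute confusional", "confusional", "confusional state", "state"]
    return {
        "recommended": [
            {"surface": "delirium", "filter_origin": "full", "qualitative": False,
             "cui": "C001",
             "merged_members": ["acute confusional state"] + acs_subs},
            {"surface": "agitation", "filter_origin": "full", "qualitative": False,
             "cui": "C003", "merged_members": []},
            {"surface": "borderline", "filter_origin": "full", "qualitative": True,
             "cui": "C005", "merged_members": []},
            {"surface": "breathlessness", "filter_origin": "full", "qualitative": False,
             "cui": "C010", "merged_members": []},
            {"surface": "dyspnea", "filter_origin": "full", "qualitative": False,
             "cui": "C009", "merged_members": []},
            {"surface": "lethargy", "filter_origin": "full", "qualitative": False,
             "cui": "C011", "merged_members": []},
            {"surface": "somnolence", "filter_origin": "full", "qualitative": False,
             "cui": "C012", "merged_members": []},
            {"surface": "tremor", "filter_origin": "full", "qualitative": False,
             "cui": "C002", "merged_members": []},
            {"surface": "hallucinations", "filter_origin": "partial",
             "qualitative": False, "cui": "C004", "merged_members": []},
        ],
        "absent": ["sepsis", "aorta", "pneumonia", "mental disorders",
                   "alcohol withdrawal"],
        "merged_cui_groups": 6,
        "synonym_groups": [
            {"method": "context", "members": ["lethargy", "somnolence"],
             "frequency": 10},
            {"method": "cui",
             "members": sorted(["delirium", "acute confusional state"] + acs_subs),
             "frequency": 7},
            {"method": "lsp",
             "members": ["acute confusional state", "delirium"], "frequency": 1},
            {"method": "shared_tail", "members": ["agitation", "tremor"],
             "frequency": 2},
            {"method": "tfidf",
             "members": sorted(["acute confusional state"] + acs_subs),
             "frequency": 10},
            {"method": "tfidf", "members": ["breathlessness", "dyspnea"],
             "frequency": 10},
        ],
        "hierarchy_relations": [
            {"parent": "mental disorders", "child": "delirium",
             "pattern": "%such%as%", "frequency": 2},
        ],
        "n_template_sentences_detected": 1,
    }


# ---------------------------------------------------------------------------
# generation


class _Cycler:
    """Deterministic cycling draw; caps per-word frequency at ceil(n/len)."""

    def __init__(self, words: Sequence[str]):
        self.words = list(words)
        self.i = 0

    def take(self) -> str:
        word = self.words[self.i % len(self.words)]
        self.i += 1
        return word


def _scaffold(surface: str, pools: dict[str, _Cycler], lead: _Cycler) -> str:
    """One plain occurrence: ``N v n of n v TERM v n in n .``

    Nouns and verbs cycle through the term's dedicated pools; the fixed
    prepositions break NP chunks so the term is always its own noun phrase
    and its ten context slots are fully populated.  The lead noun ``N`` sits
    at offset -6 — outside every context window — and cycles through the
    large filler inventory so no scaffold sentence ever repeats verbatim
    (repeated sentences are the template detector's signal).
    """
    return " ".join(
        [
            lead.take(), pools["v0"].take(), pools["n1"].take(), "of",
            pools["n2"].take(), pools["v1"].take(), surface,
            pools["v2"].take(), pools["n3"].take(), "in", pools["n4"].take(), ".",
        ]
    )


_POOL_NOUN_SLOTS = ("n1", "n2", "n3", "n4")
_POOL_VERB_SLOTS = ("v0", "v1", "v2")


def generate(
    spec: FixtureSpec, out_dir: str | os.PathLike
) -> tuple[str, str, str, str]:
    """Write the fixture to disk.

    Returns (clinical dir, biomedical dir, dictionary path, manifest path).
    Documents realize every planted frequency and document frequency
    exactly; the generator tallies what it emits and cross-checks the tally
    against the plan before writing the manifest.
    """
    spec.validate()
    rng = random.Random(spec.seed)
    nouns = _noun_inventory()
    verbs = _verb_inventory()
    rng.shuffle(nouns)
    rng.shuffle(verbs)

    planted_words = set()
    for term in spec.planted_terms:
        planted_words.update(term.surface.lower().split())
    for hier in spec.planted_hierarchy:
        planted_words.update(hier.parent.lower().split())
        planted_words.update(hier.child.lower().split())
    for pair in spec.planted_synonym_pairs:
        if pair.tail:
            planted_words.update(pair.tail.lower().split())
    nouns = [n for n in nouns if n not in planted_words]
    verbs = [v for v in verbs if v not in planted_words]

    # vocabulary allocation: filler first, then per-pool-group slices
    noun_cursor = [0]
    verb_cursor = [0]

    def take_nouns(k):
        if noun_cursor[0] + k > len(nouns):
            raise ConfigurationError("fixture noun inventory exhausted")
        chunk = nouns[noun_cursor[0] : noun_cursor[0] + k]
        noun_cursor[0] += k
        return chunk

    def take_verbs(k):
        if verb_cursor[0] + k > len(verbs):
            raise ConfigurationError("fixture verb inventory exhausted")
        chunk = verbs[verb_cursor[0] : verb_cursor[0] + k]
        verb_cursor[0] += k
        return chunk

    filler_nouns = _Cycler(take_nouns(40))
    filler_verbs = _Cycler(take_verbs(20))

    # plain-occurrence totals per pool group decide pool width: width 1 keeps
    # pool-word frequency = total <= 9; width 4 caps it at ceil(total/4)
    group_of = {
        t.surface: (t.pool_group or t.surface) for t in spec.planted_terms
    }
    totals: dict[str, int] = {}
    for term in spec.planted_terms:
        total = sum(n for _, n in term.clinical_docs) + sum(
            n for _, n in term.biomedical_docs
        )
        group = group_of[term.surface]
        totals[group] = totals.get(group, 0) + total
    words_by_group: dict[str, dict[str, list[str]]] = {}
    for group in dict.fromkeys(group_of[t.surface] for t in spec.planted_terms):
        width = 1 if totals[group] <= 9 else 4
        words_by_group[group] = {
            **{slot: take_nouns(width) for slot in _POOL_NOUN_SLOTS},
            **{slot: take_verbs(width) for slot in _POOL_VERB_SLOTS},
        }

    # Per-term cyclers over the group's word lists.  Members sharing a pool
    # group sweep the same words through the same slots (so their context
    # slot sets coincide), but each later member's verb cycles are rotated:
    # otherwise the members would emit identical (connector, NP2) sequences
    # and manufacture an unplanned shared-tail group.
    member_rank: dict[str, int] = {}
    seen_groups: dict[str, int] = {}
    for term in spec.planted_terms:
        group = group_of[term.surface]
        member_rank[term.surface] = seen_groups.get(group, 0)
        seen_groups[group] = member_rank[term.surface] + 1
    pools_by_term: dict[str, dict[str, _Cycler]] = {}

    def pools_for(surface: str) -> dict[str, _Cycler]:
        if surface not in pools_by_term:
            words = words_by_group[group_of[surface]]
            rank = member_rank[surface]
            pools = {}
            for slot in _POOL_NOUN_SLOTS:
                pools[slot] = _Cycler(words[slot])
            for slot in _POOL_VERB_SLOTS:
                rotated = words[slot][rank % len(words[slot]) :] + words[slot][
                    : rank % len(words[slot])
                ]
                pools[slot] = _Cycler(rotated)
            pools_by_term[surface] = pools
        return pools_by_term[surface]

    # template sentences: long enough to exercise the 200-character prefix
    template_texts = []
    for _ in spec.template_sentences:
        words = []
        for _ in range(6):
            words += [take_nouns(1)[0], take_verbs(1)[0], take_nouns(1)[0], "of",
                      take_nouns(1)[0], ","]
        words[-1] = "."
        template_texts.append(" ".join(words))

    # assemble per-document sentence lists
    clinical_sents: list[list[str]] = [[] for _ in range(spec.n_clinical_docs)]
    biomedical_sents: list[list[str]] = [[] for _ in range(spec.n_biomedical_docs)]
    tally: dict[str, dict[str, list[str]]] = {}

    def plant(sentence: str, cls: str, idx: int, *surfaces: str) -> None:
        target = clinical_sents if cls == "clinical" else biomedical_sents
        target[idx].append(sentence)
        doc_id = f"{'c' if cls == 'clinical' else 'b'}{idx:03d}"
        for surface in surfaces:
            per = tally.setdefault(surface, {"clinical": [], "biomedical": []})
            per[cls].append(doc_id)

    for hier in spec.planted_hierarchy:
        connector = hier.pattern.replace("%", " ").split()
        sentence = " ".join([hier.parent, *connector, hier.child, "."])
        for idx in hier.docs:
            plant(sentence, "clinical", idx, hier.parent, hier.child)
    for pair in spec.planted_synonym_pairs:
        if pair.mechanism == "lsp":
            a, b = pair.members
            plant(f"{a} , also known as {b} .", "clinical", pair.doc, a, b)
        elif pair.mechanism == "shared_tail":
            for member in pair.members:
                plant(
                    f"{member} caused by {pair.tail} .", "clinical", pair.doc,
                    member, pair.tail,
                )
    for term in spec.planted_terms:
        for cls, docs in (
            ("clinical", term.clinical_docs),
            ("biomedical", term.biomedical_docs),
        ):
            for idx, count in docs:
                for _ in range(count):
                    plant(
                        _scaffold(term.surface, pools_for(term.surface), filler_nouns),
                        cls, idx, term.surface,
                    )
    for template, text in zip(spec.template_sentences, template_texts):
        for idx in template.docs:
            clinical_sents[idx].append(text)
    for sents in clinical_sents:
        sents.append(f"{filler_nouns.take()} {filler_verbs.take()} {filler_nouns.take()} .")
        sents.append(f"{filler_nouns.take()} {filler_verbs.take()} {filler_nouns.take()} .")
    for sents in biomedical_sents:
        sents.append(f"{filler_nouns.take()} {filler_verbs.take()} {filler_nouns.take()} .")
        sents.append(f"{filler_nouns.take()} {filler_verbs.take()} {filler_nouns.take()} .")

    # cross-check the tally against the plan before writing anything
    planted_counts = {}
    for term in spec.planted_terms:
        per = tally.get(term.surface, {"clinical": [], "biomedical": []})
        counts = {
            "f_clinical": len(per["clinical"]),
            "f_biomedical": len(per["biomedical"]),
            "df_clinical": len(set(per["clinical"])),
            "df_biomedical": len(set(per["biomedical"])),
        }
        plain_c = sum(n for _, n in term.clinical_docs)
        plain_b = sum(n for _, n in term.biomedical_docs)
        if counts["f_clinical"] < plain_c or counts["f_biomedical"] < plain_b:
            raise ConfigurationError(
                f"internal plan error for {term.surface!r}: emitted {counts}"
            )
        planted_counts[term.surface] = counts
    for surface, per in tally.items():
        if surface not in planted_counts:
            planted_counts[surface] = {
                "f_clinical": len(per["clinical"]),
                "f_biomedical": len(per["biomedical"]),
                "df_clinical": len(set(per["clinical"])),
                "df_biomedical": len(set(per["biomedical"])),
            }

    # write corpora
    out_dir = os.fspath(out_dir)
    clin_dir = os.path.join(out_dir, "clinical")
    bio_dir = os.path.join(out_dir, "biomedical")
    os.makedirs(clin_dir, exist_ok=True)
    os.makedirs(bio_dir, exist_ok=True)
    for idx, sents in enumerate(clinical_sents):
        with open(os.path.join(clin_dir, f"c{idx:03d}.txt"), "w", encoding="utf-8") as fh:
            fh.write(" ".join(sents) + "\n")
    for idx, sents in enumerate(biomedical_sents):
        with open(os.path.join(bio_dir, f"b{idx:03d}.txt"), "w", encoding="utf-8") as fh:
            fh.write(" ".join(sents) + "\n")

    # dictionary
    dict_path = os.path.join(out_dir, "dictionary.tsv")
    with open(dict_path, "w", encoding="utf-8") as fh:
        for term in spec.planted_terms:
            if term.dict_status == "full":
                fh.write(f"{term.cui}\t{term.tui}\t{term.surface}\n")
            elif term.dict_status == "partial-only":
                fh.write(f"{term.cui}\t{term.tui}\t{term.dict_term}\n")
        for cui, tui, surface in spec.extra_dictionary:
            fh.write(f"{cui}\t{tui}\t{surface}\n")

    # manifest
    manifest = {
        "seed": spec.seed,
        "n_clinical_docs": spec.n_clinical_docs,
        "n_biomedical_docs": spec.n_biomedical_docs,
        "planted_counts": dict(sorted(planted_counts.items())),
        "template_sentences": [
            {"text": text, "n_docs": len(template.docs)}
            for template, text in zip(spec.template_sentences, template_texts)
        ],
        "expected": spec.expected,
    }
    manifest_path = os.path.join(out_dir, "manifest.json")
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return clin_dir, bio_dir, dict_path, manifest_path


# ---------------------------------------------------------------------------
# independent recount


def recount_surface(
    directories: Iterable[str | os.PathLike], surface: str
) -> tuple[int, int]:
    """Count a planted surface in generated files, independently of the
    pipeline: whitespace tokenization, case-insensitive contiguous-word
    matching.  Returns (total occurrences, distinct documents)."""
    words = surface.lower().split()
    total = 0
    docs = 0
    for directory in directories:
        directory = os.fspath(directory)
        for name in sorted(os.listdir(directory)):
            if not name.endswith(".txt"):
                continue
            with open(os.path.join(directory, name), encoding="utf-8") as fh:
                tokens = fh.read().lower().split()
            hits = sum(
                1
                for i in range(len(tokens) - len(words) + 1)
                if tokens[i : i + len(words)] == words
            )
            if hits:
                total += hits
                docs += 1
    return total, docs
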