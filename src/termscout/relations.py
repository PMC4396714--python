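"""Synonym-group and hierarchy-relation mining.

Four synonym techniques: two corpus-level (TF-IDF cosine and positional
context-vector similarity above threshold) and two pattern-based over
*explanations* (lexico-syntactic connector patterns, and the shared-tail /
ASIUM-style rule: NP1s sharing a verb-bearing connector and the same NP2).
Hierarchical relations come from directional connector patterns ("such as",
"is", "a type of", ...).
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

from termscout.errors import ConfigurationError
from termscout.preprocess import Explanation
from termscout.scoring import (
    TermCandidate,
    context_similarity,
    cosine,
    validate_threshold,
)

SYNONYM_METHODS = ("tfidf", "context", "lsp", "shared_tail", "cui")
#: The shared-tail technique is also known by its ancestor system's name.
METHOD_ALIASES = {"asium": "shared_tail"}


@dataclass(frozen=True)
class LexicoSyntacticPattern:
    """Wildcard connector pattern; ``%`` matches any (possibly empty) run."""

    relation_kind: str  # "synonymy" | "hierarchy"
    pattern: str
    direction: str  # "symmetric" | "np1_parent" | "np2_parent"

    def __post_init__(self) -> None:
        if self.relation_kind not in ("synonymy", "hierarchy"):
            raise ConfigurationError(f"bad relation kind {self.relation_kind!r}")
        if not self.pattern.replace("%", "").strip():
            raise ConfigurationError(
                f"pattern {self.pattern!r} has no non-wildcard content"
            )
        if self.relation_kind == "synonymy" and self.direction != "symmetric":
            raise ConfigurationError("synonymy patterns must be symmetric")
        if self.relation_kind == "hierarchy" and self.direction not in (
            "np1_parent",
            "np2_parent",
        ):
            raise ConfigurationError(
                f"hierarchy pattern {self.pattern!r} needs an explicit direction"
            )

    @property
    def regex(self) -> re.Pattern:
        parts = [re.escape(p) for p in self.pattern.split("%")]
        return re.compile(".*".join(parts), re.DOTALL)

    def matches(self, connector: str) -> bool:
        return self.regex.fullmatch(connector.strip().lower()) is not None


def load_patterns(path: str | os.PathLike | None = None) -> list[LexicoSyntacticPattern]:
    """Load the pattern table (TSV: kind, pattern, direction).

    The packaged default reproduces the standard connector inventory;
    duplicate rows (after whitespace trim) are dropped keeping first
    occurrence, so "is"/"is " style doublets collapse.
    """
    if path is None:
        text = resources.files("termscout.data").joinpath("patterns.tsv").read_text(
            encoding="utf-8"
        )
    else:
        with open(os.fspath(path), encoding="utf-8") as fh:
            text = fh.read()
    patterns: list[LexicoSyntacticPattern] = []
    seen: set[tuple[str, str]] = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ConfigurationError(
                f"patterns line {lineno}: expected 3 tab-separated fields"
            )
        kind, pattern, direction = parts[0].strip(), parts[1].strip(), parts[2].strip()
        key = (kind, pattern)
        if key in seen:
            continue
        seen.add(key)
        patterns.append(LexicoSyntacticPattern(kind, pattern, direction))
    if not patterns:
        raise ConfigurationError("pattern table is empty")
    return patterns


@dataclass
class SynonymGroup:
    members: frozenset[str]  # case-folded term surfaces, |members| >= 2
    method: str
    frequency: int
    provenance: list = field(default_factory=list)  # (doc_id, sentence) or CUI

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ConfigurationError("a synonym group needs at least 2 members")
        if self.frequency < 1:
            raise ConfigurationError("group frequency must be >= 1")


@dataclass
class HierarchyRelation:
    parent: str
    child: str
    pattern: LexicoSyntacticPattern
    frequency: int
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.parent == self.child:
            raise ConfigurationError("hierarchy relation cannot be self-referential")


def _norm(surface: str) -> str:
    return " ".join(surface.lower().split())


# ---------------------------------------------------------------------------
# pattern matching


def match_lsp(
    explanations: Iterable[Explanation],
    patterns: Sequence[LexicoSyntacticPattern] | None = None,
) -> tuple[list[SynonymGroup], list[HierarchyRelation]]:
    """Fire connector patterns over explanations.

    Each explanation contributes at most one synonymy and one hierarchy
    observation (first pattern in table order wins), so overlapping
    wildcard patterns do not double-count a single connector.  Observations
    aggregate into groups/relations with frequency = observation count.
    """
    if patterns is None:
        patterns = load_patterns()
    syn_patterns = [p for p in patterns if p.relation_kind == "synonymy"]
    hier_patterns = [p for p in patterns if p.relation_kind == "hierarchy"]
    syn_obs: dict[frozenset[str], list] = {}
    hier_obs: dict[tuple[str, str, LexicoSyntacticPattern], list] = {}
    for expl in explanations:
        np1, np2 = _norm(expl.np1), _norm(expl.np2)
        if np1 == np2:
            continue
        prov = (expl.doc_id, expl.sentence_index)
        for pattern in syn_patterns:
            if pattern.matches(expl.connector):
                syn_obs.setdefault(frozenset((np1, np2)), []).append(prov)
                break
        for pattern in hier_patterns:
            if pattern.matches(expl.connector):
                parent, child = (
                    (np1, np2) if pattern.direction == "np1_parent" else (np2, np1)
                )
                hier_obs.setdefault((parent, child, pattern), []).append(prov)
                break
    groups = [
        SynonymGroup(members=pair, method="lsp", frequency=len(provs), provenance=provs)
        for pair, provs in syn_obs.items()
    ]
    relations = [
        HierarchyRelation(
            parent=parent, child=child, pattern=pattern,
            frequency=len(provs), provenance=provs,
        )
        for (parent, child, pattern), provs in hier_obs.items()
    ]
    return groups, relations


def shared_tail_synonyms(explanations: Iterable[Explanation]) -> list[SynonymGroup]:
    """NP1s sharing a verb-bearing connector and the same NP2 are grouped.

    "a pressure pain associated with diaphoresis" and "substernal chest
    pressure associated with diaphoresis" group {a pressure pain,
    substernal chest pressure}.  Frequency is the number of supporting
    explanations in the group.
    """
    buckets: dict[tuple[str, str], list[Explanation]] = {}
    for expl in explanations:
        if not expl.connector_has_verb:
            continue
        key = (_norm(expl.connector), _norm(expl.np2))
        buckets.setdefault(key, []).append(expl)
    groups = []
    for (connector, np2), expls in buckets.items():
        np1s = frozenset(_norm(e.np1) for e in expls)
        if len(np1s) >= 2:
            groups.append(
                SynonymGroup(
                    members=np1s,
                    method="shared_tail",
                    frequency=len(expls),
                    provenance=[(e.doc_id, e.sentence_index) for e in expls],
                )
            )
    return groups


# ---------------------------------------------------------------------------
# corpus-level semantics


class _UnionFind:
    def __init__(self):
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic root choice
            lo, hi = sorted((ra, rb))
            self.parent[hi] = lo


def semantic_synonyms(
    candidates: Mapping[str, TermCandidate],
    tfidf_vectors: Mapping[str, "np.ndarray"],  # noqa: F821 - typing only
    tfidf_threshold: float = 0.90,
    context_threshold: float = 0.80,
    min_frequency: int = 0,
) -> list[SynonymGroup]:
    """Above-threshold TF-IDF-cosine and context-vector synonym groups.

    Every unordered candidate pair is compared; qualifying pairs merge into
    groups by transitive closure, separately per method.  Group frequency is
    the minimum corpus frequency among members (the support of the weakest
    member's vectors).  ``min_frequency`` prefilters candidates; with it set
    to the downstream group-frequency threshold the output after filtering
    is unchanged.
    """
    validate_threshold(tfidf_threshold, "tfidf_threshold")
    validate_threshold(context_threshold, "context_threshold")
    keys = sorted(k for k, c in candidates.items() if c.f_a >= min_frequency)
    uf = {"tfidf": _UnionFind(), "context": _UnionFind()}
    linked: dict[str, set[str]] = {"tfidf": set(), "context": set()}
    for i, k1 in enumerate(keys):
        c1 = candidates[k1]
        v1 = tfidf_vectors.get(k1)
        for k2 in keys[i + 1 :]:
            c2 = candidates[k2]
            v2 = tfidf_vectors.get(k2)
            if v1 is not None and v2 is not None and v1.any() and v2.any():
                if cosine(v1, v2) >= tfidf_threshold:
                    uf["tfidf"].union(k1, k2)
                    linked["tfidf"].update((k1, k2))
            if c1.context is not None and c2.context is not None:
                if context_similarity(c1.context, c2.context) >= context_threshold:
                    uf["context"].union(k1, k2)
                    linked["context"].update((k1, k2))
    groups: list[SynonymGroup] = []
    for method in ("tfidf", "context"):
        clusters: dict[str, set[str]] = {}
        for key in sorted(linked[method]):
            clusters.setdefault(uf[method].find(key), set()).add(key)
        for members in clusters.values():
            if len(members) >= 2:
                groups.append(
                    SynonymGroup(
                        members=frozenset(members),
                        method=method,
                        frequency=min(candidates[m].f_a for m in members),
                        provenance=sorted(members),
                    )
                )
    return groups


def cui_synonym_groups(
    matches: Mapping[str, "ConceptMatch | None"],  # noqa: F821 - typing only
) -> list[SynonymGroup]:
    """Group recommended term surfaces sharing a concept (CUI).

    Input maps case-folded surfaces to their concept matches; singleton
    groups are suppressed.  Frequency is the member count.
    """
    by_cui: dict[str, list[str]] = {}
    for surface in sorted(matches):
        match = matches[surface]
        if match is not None:
            by_cui.setdefault(match.cui, []).append(surface)
    return [
        SynonymGroup(
            members=frozenset(surfaces),
            method="cui",
            frequency=len(surfaces),
            provenance=[cui],
        )
        for cui, surfaces in sorted(by_cui.items())
        if len(surfaces) >= 2
    ]
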