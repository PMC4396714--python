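"""Candidate filtering: the final recommended term and relation lists.

Candidates first pass a document-frequency band (5% of the smaller corpus,
minimum 1, up to 95% of the larger), then one of four term filters:

1. full dictionary matches above a frequency threshold;
2. partial matches (allowed semantic types) above a frequency threshold;
3. non-matched terms with c-value above threshold;
4. non-matched terms with Termhood above threshold.

Terms sharing a CUI merge into one presented entry.  Relation groups are
kept only when they contain a recommended term and meet a per-method
frequency threshold (high for corpus-level semantics, low for
pattern-based techniques, which are few but precise).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, fields
from typing import Iterable, Mapping, Sequence

from termscout.errors import ConfigurationError, StateError, TermscoutError
from termscout.lexicon import QUALITATIVE_TUIS
from termscout.relations import HierarchyRelation, SynonymGroup
from termscout.scoring import TermCandidate

FILTER_ORIGINS = ("full", "partial", "cvalue", "termhood")
_ORIGIN_PRIORITY = {name: i for i, name in enumerate(FILTER_ORIGINS)}

CORPUS_SCOPES = ("both", "clinical_only_allowed")


@dataclass(frozen=True)
class FilterConfig:
    """Run-level thresholds; defaults are the standard configuration."""

    freq_threshold_full: int = 10
    freq_threshold_partial: int = 10
    freq_threshold_nonmatch: int = 10
    cvalue_threshold: float = 50.0
    termhood_threshold: float = 4.6
    corpus_scope: str = "both"
    df_band_low_frac: float = 0.05
    df_band_high_frac: float = 0.95
    syn_freq_threshold_semantic: int = 10
    syn_freq_threshold_pattern: int = 1
    exclude_qualitative_from_review: bool = True
    tfidf_similarity_threshold: float = 0.90
    context_similarity_threshold: float = 0.80
    cvalue_log_adjust: bool = False
    allow_subword_match: bool = False
    review_cap: int = 300

    def __post_init__(self) -> None:
        for name in (
            "freq_threshold_full",
            "freq_threshold_partial",
            "freq_threshold_nonmatch",
            "cvalue_threshold",
            "termhood_threshold",
            "syn_freq_threshold_semantic",
            "syn_freq_threshold_pattern",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0 <= self.df_band_low_frac < self.df_band_high_frac <= 1:
            raise ConfigurationError(
                "need 0 <= df_band_low_frac < df_band_high_frac <= 1"
            )
        if self.corpus_scope not in CORPUS_SCOPES:
            raise ConfigurationError(
                f"corpus_scope must be one of {CORPUS_SCOPES}"
            )
        for name in ("tfidf_similarity_threshold", "context_similarity_threshold"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "FilterConfig":
        """Flat ``key = value`` config file; unknown keys are rejected."""
        valid = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        with open(os.fspath(path), encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ConfigurationError(f"{path}:{lineno}: expected key = value")
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key not in valid:
                    raise ConfigurationError(f"{path}:{lineno}: unknown key {key!r}")
                if valid[key] == "bool":
                    kwargs[key] = value.lower() in ("1", "true", "yes", "on")
                elif valid[key] == "int":
                    kwargs[key] = int(value)
                elif valid[key] == "float":
                    kwargs[key] = float(value)
                else:
                    kwargs[key] = value
        return cls(**kwargs)


@dataclass
class RecommendedTerm:
    candidate: TermCandidate
    filter_origin: str
    qualitative: bool
    merged_members: list[str] = field(default_factory=list)  # absorbed surfaces

    @property
    def surface(self) -> str:
        return self.candidate.surface

    @property
    def key(self) -> str:
        return self.candidate.key


@dataclass
class RecommendationList:
    terms: list[RecommendedTerm]
    merged_cui_groups: int = 0  # number of terms absorbed by CUI merging
    synonym_groups: list[SynonymGroup] = field(default_factory=list)
    hierarchy_relations: list[HierarchyRelation] = field(default_factory=list)

    def recommended_keys(self) -> set[str]:
        """Case-folded surfaces counting as recommended, merged members included."""
        keys = set()
        for term in self.terms:
            keys.add(term.key)
            keys.update(term.merged_members)
        return keys

    def counts_by_origin(self) -> dict[str, int]:
        counts = {name: 0 for name in FILTER_ORIGINS}
        for term in self.terms:
            counts[term.filter_origin] += 1
        return counts


# ---------------------------------------------------------------------------
# document-frequency band


def df_band(clinical_docs: int, biomedical_docs: int, cfg: FilterConfig) -> tuple[int, int]:
    """Inclusive [low, high] band on combined document frequency.

    Low = 5% of the smaller corpus (ceil, minimum 1); high = 95% of the
    larger (floor).  Screens out terms too rare to matter and terms so
    pervasive they cannot be domain specific.
    """
    if clinical_docs <= 0 and biomedical_docs <= 0:
        raise TermscoutError("both corpora are empty")
    sizes = [n for n in (clinical_docs, biomedical_docs)]
    low = max(1, math.ceil(cfg.df_band_low_frac * min(sizes)))
    high = math.floor(cfg.df_band_high_frac * max(sizes))
    return low, high


def df_band_filter(
    candidates: Mapping[str, TermCandidate],
    clinical_docs: int,
    biomedical_docs: int,
    cfg: FilterConfig | None = None,
) -> dict[str, TermCandidate]:
    cfg = cfg or FilterConfig()
    low, high = df_band(clinical_docs, biomedical_docs, cfg)
    return {
        key: cand
        for key, cand in candidates.items()
        if low <= cand.df_combined <= high
    }


# ---------------------------------------------------------------------------
# term recommendation


def _in_scope(cand: TermCandidate, cfg: FilterConfig) -> bool:
    clin = cand.doc_freq.get("clinical", 0)
    bio = cand.doc_freq.get("biomedical", 0)
    if cfg.corpus_scope == "both":
        return clin > 0 and bio > 0
    return clin > 0  # clinical-only terms admitted


def _filter_origin(cand: TermCandidate, cfg: FilterConfig) -> str | None:
    match = cand.concept_match
    if match is not None and match.kind == "full":
        return "full" if cand.f_a >= cfg.freq_threshold_full else None
    if match is not None and match.kind == "partial":
        return "partial" if cand.f_a >= cfg.freq_threshold_partial else None
    if cand.f_a < cfg.freq_threshold_nonmatch:
        return None
    if cand.cvalue is None or cand.termhood is None:
        raise StateError("candidate scores missing; run score_candidates first")
    if cand.cvalue > cfg.cvalue_threshold:
        return "cvalue"
    if cand.termhood > cfg.termhood_threshold:
        return "termhood"
    return None


def recommend_terms(
    candidates: Mapping[str, TermCandidate], cfg: FilterConfig | None = None
) -> RecommendationList:
    """Apply the four term filters and CUI merging.

    Expects scores, concept matches and the df band already applied.  Each
    recommended term records exactly one filter origin (priority full >
    partial > cvalue > termhood, which the mutually exclusive match kinds
    make unambiguous).  Recommended terms sharing a CUI collapse into one
    presented entry — the highest-priority, most frequent member — with the
    absorbed surfaces kept on the entry.
    """
    cfg = cfg or FilterConfig()
    picked: list[RecommendedTerm] = []
    for key in sorted(candidates):
        cand = candidates[key]
        if not _in_scope(cand, cfg):
            continue
        origin = _filter_origin(cand, cfg)
        if origin is None:
            continue
        qualitative = (
            cand.concept_match is not None
            and cand.concept_match.tui in QUALITATIVE_TUIS
        )
        picked.append(RecommendedTerm(cand, origin, qualitative))

    # CUI merging
    by_cui: dict[str, list[RecommendedTerm]] = {}
    no_cui: list[RecommendedTerm] = []
    for term in picked:
        if term.candidate.concept_match is not None:
            by_cui.setdefault(term.candidate.concept_match.cui, []).append(term)
        else:
            no_cui.append(term)
    presented: list[RecommendedTerm] = list(no_cui)
    absorbed = 0
    for cui in sorted(by_cui):
        group = sorted(
            by_cui[cui],
            key=lambda t: (
                _ORIGIN_PRIORITY[t.filter_origin],
                -t.candidate.f_a,
                t.key,
            ),
        )
        head = group[0]
        head.merged_members = [t.key for t in group[1:]]
        absorbed += len(group) - 1
        presented.append(head)
    presented.sort(
        key=lambda t: (_ORIGIN_PRIORITY[t.filter_origin], -t.candidate.f_a, t.key)
    )
    return RecommendationList(terms=presented, merged_cui_groups=absorbed)


# ---------------------------------------------------------------------------
# relation filtering


def filter_relations(
    groups: Iterable[SynonymGroup],
    relations: Iterable[HierarchyRelation],
    recommended: RecommendationList,
    cfg: FilterConfig | None = None,
) -> tuple[list[SynonymGroup], list[HierarchyRelation]]:
    """Keep groups/relations that involve a recommended term and meet the
    per-method frequency threshold.

    Corpus-level semantic methods (tfidf, context) use the high threshold;
    pattern methods (lsp, shared_tail) and hierarchy relations the low one.
    CUI groups pass on membership alone (they exist because their members
    were recommended together).
    """
    cfg = cfg or FilterConfig()
    keys = recommended.recommended_keys()
    kept_groups = []
    for group in groups:
        if not group.members & keys:
            continue
        if group.method in ("tfidf", "context"):
            threshold = cfg.syn_freq_threshold_semantic
        elif group.method in ("lsp", "shared_tail"):
            threshold = cfg.syn_freq_threshold_pattern
        else:  # cui
            threshold = 1
        if group.frequency >= threshold:
            kept_groups.append(group)
    kept_relations = [
        rel
        for rel in relations
        if ({rel.parent, rel.child} & keys)
        and rel.frequency >= cfg.syn_freq_threshold_pattern
    ]
    return kept_groups, kept_relations


# ---------------------------------------------------------------------------
# ontology comparison


def compare_to_ontology(
    recommended: RecommendationList | Iterable[str],
    ontology_terms: Sequence[str],
) -> dict[str, str]:
    """Match recommended terms against an existing ontology's term list.

    ``full`` = exact case-insensitive equality; ``partial`` = at least one
    shared word in either direction (the recommended term overlaps an
    ontology term or vice versa); otherwise ``none``.
    """
    terms = [t.strip() for t in ontology_terms if t.strip()]
    if not terms:
        raise TermscoutError("ontology term list is empty")
    onto_full = {t.lower() for t in terms}
    onto_words = [set(t.lower().split()) for t in terms]
    if isinstance(recommended, RecommendationList):
        surfaces = [t.surface for t in recommended.terms]
    else:
        surfaces = list(recommended)
    out: dict[str, str] = {}
    for surface in surfaces:
        low = " ".join(surface.lower().split())
        if low in onto_full:
            out[surface] = "full"
        elif any(set(low.split()) & words for words in onto_words):
            out[surface] = "partial"
        else:
            out[surface] = "none"
    return out
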