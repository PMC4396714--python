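"""End-to-end pipeline: corpora + dictionary + config -> recommendation TSVs.

Outputs are deterministic: identical inputs and configuration give
byte-identical ``terms.tsv``, ``synonyms.tsv`` and ``hierarchy.tsv`` (the
manifest's timestamp field is the only wall-clock content).
"""

from __future__ import annotations

import datetime
import json
import logging
import os

import pandas as pd

from termscout.corpus import Corpus, load_corpus_dir
from termscout.filtering import (
    FilterConfig,
    RecommendationList,
    compare_to_ontology,
    df_band_filter,
    filter_relations,
    recommend_terms,
)
from termscout.lexicon import SemanticTypeSet, TermIndex, lookup, read_dictionary
from termscout.preprocess import Explanation, Sentence, extract_explanations, preprocess_document
from termscout.relations import (
    cui_synonym_groups,
    load_patterns,
    match_lsp,
    semantic_synonyms,
    shared_tail_synonyms,
)
from termscout.scoring import (
    TermCandidate,
    assemble_candidates,
    score_candidates,
    tfidf_matrix,
)

logger = logging.getLogger(__name__)


class PipelineResult:
    """In-memory pipeline products, for callers who skip the TSV layer."""

    def __init__(
        self,
        corpus: Corpus,
        sentences_by_doc: dict[str, list[Sentence]],
        candidates: dict[str, TermCandidate],
        recommended: RecommendationList,
        manifest: dict,
    ):
        self.corpus = corpus
        self.sentences_by_doc = sentences_by_doc
        self.candidates = candidates
        self.recommended = recommended
        self.manifest = manifest


def analyze(
    clinical: Corpus,
    biomedical: Corpus,
    dictionary_path: str | os.PathLike,
    cfg: FilterConfig | None = None,
    patterns_path: str | os.PathLike | None = None,
) -> PipelineResult:
    """Run every phase in memory and return the filtered recommendations."""
    cfg = cfg or FilterConfig()
    corpus = clinical.extend(biomedical)
    counts = corpus.class_counts

    # phase A: preprocessing and candidate generation
    sentences_by_doc = {doc.doc_id: preprocess_document(doc) for doc in corpus}
    candidates = assemble_candidates(corpus, sentences_by_doc)
    n_candidates = len(candidates)
    logger.info("phase A: %d candidate N-grams", n_candidates)

    # phase A tail: dictionary lookup
    index = TermIndex(read_dictionary(dictionary_path))
    types = SemanticTypeSet()
    for cand in candidates.values():
        cand.concept_match = lookup(
            cand.ngram, index, types=types, allow_subword=cfg.allow_subword_match
        )
    n_matched = sum(1 for c in candidates.values() if c.concept_match)
    logger.info("phase A: %d candidates matched the dictionary", n_matched)

    # phase B: scoring
    score_candidates(candidates, cvalue_log_adjust=cfg.cvalue_log_adjust)
    tfidf_vectors, _ = tfidf_matrix(candidates, corpus)
    logger.info("phase B: scores computed")

    # phases C/D: relation mining
    explanations: list[Explanation] = []
    for doc in corpus:
        for sent in sentences_by_doc[doc.doc_id]:
            explanations.extend(extract_explanations(sent))
    patterns = load_patterns(patterns_path)
    lsp_groups, hier_relations = match_lsp(explanations, patterns)
    tail_groups = shared_tail_synonyms(explanations)
    sem_groups = semantic_synonyms(
        candidates,
        tfidf_vectors,
        tfidf_threshold=cfg.tfidf_similarity_threshold,
        context_threshold=cfg.context_similarity_threshold,
        min_frequency=cfg.syn_freq_threshold_semantic,
    )
    logger.info(
        "phases C/D: %d LSP groups, %d shared-tail, %d semantic, %d hierarchy",
        len(lsp_groups), len(tail_groups), len(sem_groups), len(hier_relations),
    )

    # phase E: term filtering
    banded = df_band_filter(
        candidates, counts["clinical"], counts["biomedical"], cfg
    )
    logger.info("phase E: %d candidates inside the df band", len(banded))
    recommended = recommend_terms(banded, cfg)

    # CUI groups form over the recommended surfaces (pre-merge view)
    rec_keys = recommended.recommended_keys()
    cui_groups = cui_synonym_groups(
        {k: candidates[k].concept_match for k in sorted(rec_keys) if k in candidates}
    )

    # phase F: relation filtering
    all_groups = lsp_groups + tail_groups + sem_groups + cui_groups
    kept_groups, kept_relations = filter_relations(
        all_groups, hier_relations, recommended, cfg
    )
    recommended.synonym_groups = _sorted_groups(kept_groups)
    recommended.hierarchy_relations = sorted(
        kept_relations, key=lambda r: (r.parent, r.child, r.pattern.pattern)
    )
    logger.info(
        "phase F: %d terms, %d synonym groups, %d hierarchy relations",
        len(recommended.terms),
        len(recommended.synonym_groups),
        len(recommended.hierarchy_relations),
    )

    manifest = {
        "config": {k: v for k, v in sorted(vars(cfg).items())},
        "corpus_sizes": counts,
        "phase_counts": {
            "A_candidates": n_candidates,
            "A_dictionary_matched": n_matched,
            "C_synonym_groups_mined": len(lsp_groups) + len(tail_groups) + len(sem_groups) + len(cui_groups),
            "D_hierarchy_mined": len(hier_relations),
            "E_df_band": len(banded),
            "E_recommended_terms": len(recommended.terms),
            "F_synonym_groups": len(recommended.synonym_groups),
            "F_hierarchy_relations": len(recommended.hierarchy_relations),
        },
    }
    return PipelineResult(corpus, sentences_by_doc, candidates, recommended, manifest)


def _sorted_groups(groups):
    return sorted(groups, key=lambda g: (g.method, sorted(g.members)))


# ---------------------------------------------------------------------------
# TSV serialization


def terms_frame(recommended: RecommendationList) -> pd.DataFrame:
    rows = []
    for term in recommended.terms:
        cand = term.candidate
        match = cand.concept_match
        rows.append(
            {
                "surface": cand.surface,
                "filter_origin": term.filter_origin,
                "f": cand.f_a,
                "df_clinical": cand.doc_freq.get("clinical", 0),
                "df_biomedical": cand.doc_freq.get("biomedical", 0),
                "cvalue": round(cand.cvalue, 6) if cand.cvalue is not None else "",
                "termhood": round(cand.termhood, 6) if cand.termhood is not None else "",
                "cui": match.cui if match else "",
                "tui": match.tui if match else "",
                "match_kind": match.kind if match else "",
                "qualitative": int(term.qualitative),
                "merged_members": "|".join(term.merged_members),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "surface", "filter_origin", "f", "df_clinical", "df_biomedical",
            "cvalue", "termhood", "cui", "tui", "match_kind", "qualitative",
            "merged_members",
        ],
    )


def synonyms_frame(recommended: RecommendationList) -> pd.DataFrame:
    rows = []
    for gid, group in enumerate(recommended.synonym_groups):
        rows.append(
            {
                "group_id": gid,
                "members": "|".join(sorted(group.members)),
                "method": group.method,
                "frequency": group.frequency,
            }
        )
    return pd.DataFrame(rows, columns=["group_id", "members", "method", "frequency"])


def hierarchy_frame(recommended: RecommendationList) -> pd.DataFrame:
    rows = [
        {
            "parent": rel.parent,
            "child": rel.child,
            "pattern": rel.pattern.pattern,
            "frequency": rel.frequency,
        }
        for rel in recommended.hierarchy_relations
    ]
    return pd.DataFrame(rows, columns=["parent", "child", "pattern", "frequency"])


def run_pipeline(
    clinical_dir: str | os.PathLike,
    biomedical_dir: str | os.PathLike,
    dictionary_path: str | os.PathLike,
    out_dir: str | os.PathLike,
    config_path: str | os.PathLike | None = None,
    cfg: FilterConfig | None = None,
    patterns_path: str | os.PathLike | None = None,
) -> PipelineResult:
    """Load the two corpora, run every phase, and write the output TSVs.

    Writes ``terms.tsv``, ``synonyms.tsv``, ``hierarchy.tsv`` and
    ``manifest.json`` into ``out_dir``; on any failure partial outputs are
    removed before the error propagates.
    """
    if cfg is None:
        cfg = FilterConfig.from_file(config_path) if config_path else FilterConfig()
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    written: list[str] = []
    try:
        clinical = load_corpus_dir(clinical_dir, "clinical")
        biomedical = load_corpus_dir(biomedical_dir, "biomedical")
        result = analyze(clinical, biomedical, dictionary_path, cfg, patterns_path)
        for name, frame in (
            ("terms.tsv", terms_frame(result.recommended)),
            ("synonyms.tsv", synonyms_frame(result.recommended)),
            ("hierarchy.tsv", hierarchy_frame(result.recommended)),
        ):
            path = os.path.join(out_dir, name)
            frame.to_csv(path, sep="\t", index=False, lineterminator="\n")
            written.append(path)
        manifest = dict(result.manifest)
        manifest["timestamp"] = datetime.datetime.now(datetime.timezone.utc).isoformat()
        path = os.path.join(out_dir, "manifest.json")
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(path)
    except Exception:
        for path in written:
            if os.path.exists(path):
                os.remove(path)
        raise
    return result


def render_report(out_dir: str | os.PathLike, cfg: FilterConfig | None = None) -> str:
    """Human-readable per-filter summary of a pipeline output directory."""
    cfg = cfg or FilterConfig()
    out_dir = os.fspath(out_dir)
    terms = pd.read_csv(os.path.join(out_dir, "terms.tsv"), sep="\t")
    synonyms = pd.read_csv(os.path.join(out_dir, "synonyms.tsv"), sep="\t")
    hierarchy = pd.read_csv(os.path.join(out_dir, "hierarchy.tsv"), sep="\t")
    lines = ["Recommended terms"]
    labels = {
        "full": "Filter 1: direct dictionary matches",
        "partial": "Filter 2: partial dictionary matches",
        "cvalue": "Filter 3: non-matches above c-value threshold",
        "termhood": "Filter 4: non-matches above Termhood threshold",
    }
    origin_counts = terms["filter_origin"].value_counts() if len(terms) else {}
    for origin, label in labels.items():
        count = int(origin_counts.get(origin, 0)) if len(terms) else 0
        lines.append(f"  {label}: {count}")
    merged = (
        int(terms["merged_members"].fillna("").astype(str).str.split("|").apply(
            lambda xs: sum(1 for x in xs if x)
        ).sum())
        if len(terms)
        else 0
    )
    lines.append(f"  Combined recommended terms with the same CUI: -{merged}")
    lines.append(f"  Recommended terms (total): {len(terms)}")
    qualitative = int(terms["qualitative"].sum()) if len(terms) else 0
    if cfg.exclude_qualitative_from_review and qualitative:
        lines.append(
            f"  Qualitative/quantitative terms flagged for separate review: {qualitative}"
        )
    if len(terms) > cfg.review_cap:
        lines.append(
            f"  WARNING: {len(terms)} recommended terms exceed the review cap "
            f"({cfg.review_cap}); consider raising frequency thresholds"
        )
    lines.append("Synonym groups")
    for method in ("tfidf", "lsp", "shared_tail", "context", "cui"):
        count = int((synonyms["method"] == method).sum()) if len(synonyms) else 0
        lines.append(f"  {method}: {count}")
    lines.append(f"  Synonym groups (total): {len(synonyms)}")
    lines.append(f"Hierarchy relations (total): {len(hierarchy)}")
    return "\n".join(lines)


def compare_ontology_file(
    terms_tsv: str | os.PathLike, ontology_path: str | os.PathLike
) -> dict[str, str]:
    """Compare a terms.tsv output against a one-term-per-line ontology list."""
    terms = pd.read_csv(os.fspath(terms_tsv), sep="\t")
    with open(os.fspath(ontology_path), encoding="utf-8") as fh:
        ontology = [line.strip() for line in fh if line.strip()]
    return compare_to_ontology(list(terms["surface"].astype(str)), ontology)
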