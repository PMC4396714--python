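# Methods

## The procedure and its assumptions

`termscout` treats ontology maintenance as a recall-then-precision problem:
collect every plausible candidate term and relationship from a paired corpus
(clinical notes + biomedical articles), then filter aggressively so the
surviving list is small enough for expert review. The central assumptions:

* the *document* is the counting unit — term frequency f(a), document
  frequency, and TF-IDF columns are all defined over documents, so corpus
  preparation (amalgamating very short clinical summaries, isolating XML
  article bodies) matters before any linguistics;
* candidate terms live inside noun/verb phrase chunks; every contiguous
  sub-span of a chunk is a candidate, so multi-word terms and their nested
  fragments compete explicitly (that is what c-value adjudicates);
* no stemming anywhere — the dictionary is assumed to carry lexical
  variants, and clinical abbreviation behavior makes stemming risky. Case
  is folded only for aggregation and matching;
* synonymy signals are redundant by design: two corpus-distributional
  methods (TF-IDF cosine, positional context overlap) and two pattern
  methods (connector patterns, shared-tail) plus repeated-CUI grouping each
  catch different phenomena, and are filtered with different strictness.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `freq_threshold_full/partial/nonmatch` | 10 | occurrences a candidate needs before a filter admits it; raise on large corpora, lower (e.g. 5) on small ones |
| `cvalue_threshold` | 50 | admits non-matched terms only while yield stays selective; below this, precision collapses |
| `termhood_threshold` | 4.6 | same role for the Termhood log-odds score |
| `corpus_scope` | `both` | require presence in both corpora; `clinical_only_allowed` widens to clinical-only terms for highly domain-specific note collections |
| `df_band_low_frac` / `df_band_high_frac` | 0.05 / 0.95 | document-frequency band: ceil(0.05·min corpus) (min 1) to floor(0.95·max corpus), inclusive; screens rare noise and non-specific ubiquity |
| `tfidf_similarity_threshold` | 0.90 | cosine threshold for TF-IDF synonymy |
| `context_similarity_threshold` | 0.80 | fraction of the 10 context slots that must intersect |
| `syn_freq_threshold_semantic` | 10 | group-frequency floor for tfidf/context groups |
| `syn_freq_threshold_pattern` | 1 | floor for LSP/shared-tail groups and hierarchy relations — pattern hits are few but precise |
| `exclude_qualitative_from_review` | true | T080/T081 terms are flagged and sectioned separately, never deleted: they matter for ontology building but are not domain specific |
| `allow_subword_match` | false | lets a word match a dictionary word containing it (catches "ca" → "cancer", at the cost of hits like "ca" inside "defecation"); off by default |
| `cvalue_log_adjust` | false | replaces log2|a| with log2(|a|+1) so unigrams can score; the printed formula gives every unigram c-value 0, and we keep that as the default |

## Numerical and design choices

* **Dictionary match ranking** replaces any engine-specific relevance score
  with the stated criteria only: most words in common, fewest extra words
  (`extra = |entry| + |query| − 2·common`, over unique words,
  order-agnostic), ties broken by dictionary insertion order. This makes
  matching reproducible and exactly brute-force checkable.
* **IDF** uses log base 10. For synonymy this is provably irrelevant: the
  IDF factor is a per-term scalar, so cosine over TF-IDF vectors equals
  cosine over normalized-TF vectors (property-tested to 1e-12).
* **TF normalization** divides by the maximum *candidate* frequency in the
  document, not the maximum token frequency.
* **Context similarity** is the count of slot indices with non-empty
  intersection, divided by 10, compared against the 0.80 threshold. Slots
  are sets — repeated context words deliberately do not count twice.
* **Termhood features**: first/last POS uses the modal tag across
  occurrences (ties: higher count, then alphabetical tag); the three
  median comparisons are strict (a tie at the median scores 0); medians are
  computed over the full candidate set.
* **"Nested"** means: occurs as a contiguous word subsequence of another
  extracted candidate, on case-folded surfaces.
* **Explanations** pair *consecutive* NP chunks only — both canonical
  examples ("CAM or CAM ICU is …", "a-fib on Coumadin") decompose that way
  — and each explanation fires at most one synonymy and one hierarchy
  pattern (first in table order), so overlapping wildcard patterns cannot
  double-count one connector.
* **Pattern directions**: "such as"/"including" make NP₁ the parent;
  "is"/"are"/"type of"/"or other"/"and other"/"associated with" make NP₂
  the parent, following the Hearst conventions for hypernym patterns. The
  doubled "is "/"are " rows of the standard inventory collapse after
  whitespace trimming. Directions are configurable per pattern row.
* **NP break words**: "other" and "type" never join a noun phrase, so the
  connectors "and other …" and "is a type of" remain visible between NPs.
  Without this, a chunker that merges "a type" or "other disorders" into an
  NP would hide exactly the material the hierarchy patterns match.
* **Filter origin** is unique per term with priority full > partial >
  c-value > Termhood, letting per-filter counts partition the list.
* **CUI merging** keeps the highest-priority, most frequent member as the
  presented entry and records absorbed surfaces. Group "frequency" for
  semantic synonym groups is the minimum member corpus frequency (the
  support of the weakest member's vectors); for CUI groups it is the member
  count, and such groups are exempt from the semantic frequency floor since
  they exist only because their members were already recommended.
* The pipeline prefilters semantic-synonym candidates to
  f(a) ≥ `syn_freq_threshold_semantic`. This is output-preserving — any
  group containing a rarer member would have group frequency below the
  floor and be dropped anyway — and keeps the pairwise comparison loop
  proportional to the few frequent candidates.
* Degenerate inputs: cosine of a zero vector raises (a term present in
  every document has IDF 0 and no direction); empty corpora, empty
  dictionaries and malformed pattern rows raise configuration errors
  rather than degrade silently.

## The synthetic corpus generator

The generator (`termscout.fixtures`) emulates the study design at desk
scale: 30 clinical + 10 biomedical documents (a clinical-heavy pairing),
planted terms at exact frequencies and document frequencies spanning every
filter outcome — above/below the occurrence threshold, inside/outside the
document-frequency band, clinical-only, partial-match-only, qualitative —
plus one planted synonym pair per mechanism, a hierarchy sentence, and
boilerplate template sentences repeated in 6 (detected) and exactly 5 (not
detected) documents. Every planted occurrence sits in a scaffold sentence
`N v n of n v TERM v n in n .` built from small per-term word pools:

* pools are dedicated per term, so context windows of different terms share
  only the fixed function words (far below the 8-of-10 slot threshold); a
  designed context pair shares its pools (similarity exactly 1.0);
* a designed TF-IDF pair shares its document plan (cosine exactly 1.0);
  all other document plans overlap little enough that cosines stay well
  under 0.90;
* pool and filler words cycle deterministically, capping their frequencies
  below every recommendation threshold and keeping connector/NP₂
  combinations aligned so no accidental shared-tail groups form (members of
  a shared pool group get rotated verb cycles for the same reason);
* the scaffold's lead noun sits outside every context window and cycles
  through the large filler inventory, so no scaffold sentence repeats
  verbatim — template detection sees only the planted templates.

The manifest records planted counts (verified by an independent file
recount in the tests) and the expected pipeline output, derived from the
plant design rather than from running the pipeline; the end-to-end test
asserts exact set equality.

What the generator does **not** emulate: real clinical language
(abbreviation noise, misspellings, negation, section headers), tagger
ambiguity (the bundled lexicon tagger is deterministic with a closed
vocabulary), dictionary scale (15 entries vs. millions), and graded
similarity structure (designed pairs sit at similarity 1.0, non-pairs far
below threshold, nothing near the decision boundary). Passing tests
therefore demonstrate that the extraction, scoring and filtering machinery
is correct and deterministic — not that the thresholds are well-calibrated
for any particular clinical corpus, which is why they are run-level
configuration.

## Problem sizes

The test suite and acceptance script run the full pipeline on the 40
document synthetic corpus (~360 candidate N-grams), brute-force oracle
comparisons on 200 random instances per operation (candidate sets ≤ 30,
dictionaries ≤ 50 entries, explanation lists ≤ 100), and the exhaustive
Termhood check over all 400 legal feature vectors. These sizes exercise
every code path while keeping a full run in seconds.

## Known limitations

* The lexicon tagger defaults unknown words to NN; texts dominated by
  unknown verbs would chunk poorly. The tagging backend is pluggable for
  that reason.
* Partial matching is word-overlap based; it inherits the known failure
  modes of overlap matching (spurious substring hits under
  `allow_subword_match`, anatomy/disorder compounds that should split).
* Hierarchy mining is pattern-only; no part-of (mereological) relations,
  no learned relation classifiers.
* `parse_pubmed_xml` expects a `<body>` element (PMC-style article XML);
  other article schemas need pre-extraction to plain text.
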