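# termscout

Semi-automated terminology maintenance for clinical domains: given a pair of
corpora — clinical notes on one side, biomedical articles on the other — and a
UMLS-style dictionary, `termscout` produces concise ranked lists of
recommended domain **terms**, **synonym groups** and **hierarchical
relationships** for an expert to review. Keeping a disease-specific ontology
current is slow, manual work; mining both the *common usage* of clinical notes
and the *settled science* of the literature, then filtering hard, yields
review lists small enough (a few hundred entries) to be tractable.

## Method

The pipeline has three stages.

**Preprocessing.** Tokenization, sentence segmentation, POS tagging and NP/VP
chunking (a deterministic lexicon tagger ships with the package; the backend
is pluggable). Candidate terms are all contiguous sub-spans of noun/verb
phrase chunks, unigrams up to the full chunk, without stemming. Candidates
are looked up in the dictionary (TSV `CUI<TAB>TUI<TAB>STR`): a **full match**
equals a dictionary string exactly; a **partial match** shares ≥ 1 word, is
restricted to 16 allowed semantic types, and is ranked by most words in
common, then fewest extra words, then dictionary order. Each sentence also
yields *explanations* — NP₁ / connector / NP₂ triples — and each candidate a
positional context vector (word sets at offsets −5…+5).

**Scoring and relation mining.** For a candidate string *a* with corpus
frequency *f(a)*, nested in the set *T_a* of longer candidates containing it:

```
c-value(a) = log2|a| · f(a)                                   if a is not nested
           = log2|a| · ( f(a) − (1/P(T_a)) · Σ_{b∈T_a} f(b) )  otherwise
```

Termhood is a fixed-coefficient logistic log-odds score over 12 binary
features (first/last POS class, NP status, and whether nesting counts and
document frequency exceed the corpus medians). TF-IDF vectors have one entry
per document, `w_ij = (f_ij / max_z f_zj) · log10(N / n_i)`, compared by
cosine (threshold 0.90); context vectors are compared by the fraction of the
10 slots whose word sets intersect (threshold 0.80). Pattern-based synonymy
and hierarchy mining run over the explanations: a lexico-syntactic pattern
table (`%also%known%as%`, `%such%as%`, `is`, `%type of%`, …) and the
shared-tail rule (NP₁s sharing a verb-bearing connector and the same NP₂ are
likely synonyms).

**Filtering.** Candidates must fall in a document-frequency band
(5 % of the smaller corpus, minimum 1, up to 95 % of the larger) and pass one
of four filters: full match, partial match, c-value > 50, or Termhood > 4.6,
each with an occurrence threshold (default 10) and, by default, presence in
both corpora. Terms sharing a CUI merge into one presented entry;
qualitative/quantitative concepts (T080/T081) are flagged for a separate
review section. Relation groups are kept when they contain a recommended
term and meet a per-method frequency threshold (10 for the corpus-level
semantic methods, 1 for the pattern methods).

## Worked example

The package ships a seeded synthetic-corpus generator with known ground
truth, so the whole pipeline can be exercised without clinical data:

```
termscout make-fixtures --out demo --seed 1
termscout run --clinical demo/clinical --biomedical demo/biomedical \
              --dictionary demo/dictionary.tsv --out demo/out
termscout report --out demo/out
```

prints

```
9 recommended terms, 6 synonym groups, 1 hierarchy relations -> demo/out
Recommended terms
  Filter 1: direct dictionary matches: 8
  Filter 2: partial dictionary matches: 1
  Filter 3: non-matches above c-value threshold: 0
  Filter 4: non-matches above Termhood threshold: 0
  Combined recommended terms with the same CUI: -6
  Recommended terms (total): 9
  Qualitative/quantitative terms flagged for separate review: 1
Synonym groups
  tfidf: 2
  lsp: 1
  shared_tail: 1
  context: 1
  cui: 1
  Synonym groups (total): 6
Hierarchy relations (total): 1
```

Reading the output: eight planted dictionary terms clear the full-match
filter and one ("hallucinations", which only overlaps the dictionary entry
"visual hallucinations") arrives via the partial-match filter. Six further
surfaces — "acute confusional state" and its sub-N-grams, which share CUI
C001 with "delirium" — are merged into the delirium entry (the `-6` row).
One synonym group per mechanism is recovered (plus the nested-term TF-IDF
group), and the planted "mental disorders ⊃ delirium" hierarchy relation
survives filtering. `demo/out/terms.tsv` carries per-term frequencies,
scores, CUI/TUI and the merged surfaces; `synonyms.tsv` and `hierarchy.tsv`
the relation lists.

The flags in a run configuration file (`--config`) mirror the
`FilterConfig` fields — occurrence thresholds, score thresholds, the
similarity thresholds, `corpus_scope` — so the published configurations
(raising the occurrence threshold on a large corpus, admitting
clinical-only terms on a highly specific one) are run-level settings, not
code changes.

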