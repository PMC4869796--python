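# Methods

## Model and assumptions

dxnorm treats disease-name normalisation as unsupervised string matching
against a compiled dictionary. The working assumption is that most surface
variation in disease mentions is (a) inflection and word order, handled by
canonicalisation; (b) small character-level divergence, handled by
similarity retrieval; or (c) Greek/Latin compounding, handled by gloss
translation. No document context is used: mentions are normalised
independently, and abbreviation resolution or learning-to-rank approaches
are out of scope.

## Canonicalisation

Pipeline: NFKC normalisation and casefolding → tokenisation on any
non-alphanumeric character (hyphens split, punctuation vanishes) →
stop-word removal → Porter stemming → lexicographic sort → single-space
join. Details that matter:

- **Stemmer.** The classic Porter algorithm is implemented in
  `dxnorm._porter` and pinned so canonical forms are stable across
  environments. Each token is stemmed to a fixpoint (repeated application
  until unchanged): plain Porter is not idempotent on rare words
  ("callousness" → "callous" → "callou"), and fixpoint stemming is what
  makes `canonicalize(canonicalize(x)) == canonicalize(x)` hold
  unconditionally. The cost is a slightly more aggressive stem for a few
  words ("disease" → "disea" rather than "diseas"); since every name and
  every query pass through the same function, matching is unaffected.
- **Stop words.** A small bundled English list (articles, prepositions,
  copulas, conjunctions), overridable in `CanonConfig`. Stop words are
  filtered again *after* stemming because stemming can map a content token
  onto a stop word ("ins" → "in"), which would otherwise break idempotence.
- **Duplicates** among stemmed tokens are retained (not deduplicated); the
  sort is plain lexicographic byte order.

## Retrieval and ranking

Jaro–Winkler and Levenshtein are implemented natively (they are the core
of the method, and tests cross-check them against independent
implementations). Constants: Winkler prefix weight p = 0.1, maximum prefix
ℓ = 4 — the standard published values, exposed in `RetrievalParams`. The
candidacy threshold (default 0.80) is *inclusive* so that a threshold of
1.0 still admits exact matches. Both retrieval stages compare canonical
forms (not raw names), keeping the two stages consistent. Full ordering:
JW descending, Levenshtein ascending, then concept ID and matched name
ascending — the last two are tie-breaks chosen purely for reproducibility.
Retrieval is a linear scan over dictionary keys; at desk scale
(≤ ~10⁵ entries) this is fast enough, and approximate indexing could be
added behind the same contract.

## Dictionary compilation and augmentation

Lexicon input is a TSV (`id`, semicolon-separated tree numbers, `name`,
pipe-separated `synonyms`) — trivially produced from MeSH or any other
vocabulary, whose licensed distribution formats are deliberately not
parsed here. Subtree filtering keeps records with at least one tree number
under an allowed prefix (default C = Diseases, F = Psychiatry/Psychology);
records without tree numbers are dropped. Homonymous canonical forms keep
all concept IDs; disambiguation happens downstream through the ranking
tie-breaks. Augmentation adds a gold (mention, ID) pair when the canonical
form is missing *or* present only under other IDs — the coverage-maximising
reading; composite IDs ("D1|D2") are split, and the "-1" unmappable
sentinel is skipped. Augmentation never mutates its input and is
idempotent.

## Root/affix translation

Decomposition segments a lowercased token into lexicon forms
(longest-prefix first with backtracking, all full segmentations returned),
allowing one optional connecting vowel "o"/"i" between parts so lexica may
store either "neur" or "neuro". Multi-word mentions decompose token-wise;
unsegmentable tokens ride along as residue and appear verbatim in the
generated phrases. Translation expands, per decomposition, the Cartesian
product of part glosses in surface order — the prefix gloss precedes the
suffix gloss, yielding "nervous disease", not "disease nervous". All
glosses are expanded; downstream similarity scoring picks the winner, so
no gloss-choice heuristic is needed. The bundled lexicon
(`data/roots.tsv`, ~140 entries) is a small curated starter set of common
Greek/Latin combining forms and disorder affixes; users with fuller
proprietary lists can load them through the same TSV contract.

The normaliser attempts translation only when the best direct candidate
scores below τ (`translate_threshold`; presets 0.92/0.94/0.96 balancing
recall against precision). Direct and translated candidates are then
*pooled* and the best by (JW, −Levenshtein) wins, with the direct route
preferred on exact ties — the least surprising precedence rule, and it
preserves the neuropathy example. A translated match in [0.80, τ) can
therefore override a weaker direct match in the same band.

## Recognition features and BIO codec

The feature extractor consumes pre-tokenised sentences (tokenisation, POS,
lemma and chunk tags are upstream concerns) in the common one-token-per-
line TSV layout. The "context window of three" is read as ±3 tokens and is
configurable, since width-3 (±1) is an equally defensible reading.
Character n-grams are position-agnostic (not prefix/suffix-anchored) and
set-valued, so repeated substrings collapse. Dictionary matching is
token-level, case-insensitive, with overlaps resolved longest-then-
leftmost over all matching intervals. `bio_encode` snaps non-aligned spans
outward to token boundaries (logged), rejects same-type overlaps and drops
later-starting cross-type overlaps (logged); `bio_decode` repairs illegal
"I after O" as "B". CRF estimation itself is behind the `SequenceLabeler`
protocol; the built-in `DictionaryTagger` baseline makes the interface
testable with no external model, and `write_crfsuite` emits the standard
CRFsuite text layout for interoperability with external trainers.

## I/O conventions

PubTator offsets are 0-based, half-open, over title + one separator
character + abstract; every read asserts that each annotation's text equals
the corresponding substring, so offset drift fails fast with a line number.
BioC identifiers live under the `MESH` infon key (configurable); DTD
validation is off; everything is UTF-8.

## Synthetic data generator

`gen_lexicon` builds concepts from a closed vocabulary (modifier +
adjective + disorder noun) with unique canonical forms across concepts;
synonyms are reorderings and stop-word insertions of the preferred name,
so they share its canonical form. Tree numbers cycle through C/C/F/D
prefixes so subtree filtering has something to drop. Roughly every fifth
concept is named by a root-compound gloss phrase ("heart disease") so
corpora can plant the corresponding compound ("cardiopathy") as an
invertible translated mention. The adjective vocabulary is deliberately
disjoint from the root-lexicon glosses: a generated gloss phrase can then
only collide with the concept planted for it, which is what makes 100%
recovery on unperturbed corpora a meaningful check rather than an
accident.

`gen_corpus` plants mentions into template title/abstract documents,
cycling surface families (exact / token-reordered / stop-word-inserted /
compound) and then applying independent per-character edits
(substitute/delete/insert, uniform over a–z) at the requested rate. All
randomness flows from one `random.Random(seed)`; output is byte-identical
per seed.

What the generator does **not** emulate: real discourse (templates, not
language models), abbreviations and acronyms, nested or discontinuous
mentions, ambiguous mentions requiring context, and realistic lexicon
scale. Passing recovery tests therefore demonstrates the machinery
(canonicalisation, retrieval, translation, augmentation) is correct, not
that benchmark-corpus scores would be matched; those depend on licensed
vocabularies and gold corpora outside this package's scope.

## Problem sizes and defaults

Tests and the acceptance script use 25-concept lexica (75 records), 3–10
documents of 5 mentions, perturbation rates {0, 0.1, 0.2, 0.3} and 20
seeds per rate — sizes chosen to exercise every code path with tight,
deterministic runtimes. Retrieval-threshold defaults (0.80; τ = 0.92) are
the method's standard operating points and are not tuned to the synthetic
data.

## Known limitations

- Linear-scan retrieval; no blocking/indexing.
- One canonical form per dictionary key means homonym disambiguation rests
  entirely on string distance and deterministic tie-breaks.
- The bundled root lexicon is a starter set; coverage of rare roots is low.
- No abbreviation handling, composite-mention splitting, or document-level
  coherence.
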