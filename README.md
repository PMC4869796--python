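# dxnorm

Disease-mention normalisation for biomedical literature curation: given a
textual mention of a disease ("blocked airways", "neuropathy"), assign the
identifier of the matching concept in a controlled vocabulary such as MeSH.
The package is aimed at text-mining pipelines and curation tooling that
need a transparent, dictionary-based normaliser — plus the token feature
scheme used for CRF-based mention recognition, PubTator/BioC I/O and
micro-averaged evaluation utilities.

## Method

**Canonicalisation.** Every lexicon name and every query mention is mapped
to a canonical form by: lowercasing → stop-word and punctuation removal →
Porter stemming of each remaining token → alphabetical re-ordering of the
stemmed tokens. Surface variants ("airways are blocked", "blockage of
airways") collapse onto one key, so dictionary lookup tolerates word order,
inflection and function words.

**Two-stage retrieval.** A query canonical form *q* is compared with every
dictionary key *c* by Jaro–Winkler similarity

> JW(q,c) = J + ℓ·p·(1 − J),  with J the Jaro similarity, ℓ ≤ 4 the common
> prefix length and p = 0.1,

and all entries with JW ≥ 0.80 become candidates. Because many candidates
tie on JW, they are re-ranked by Levenshtein edit distance (ascending), and
the topmost entry's identifier is assigned.

**Dictionary augmentation.** Gold-annotated corpora are a source of surface
forms the base vocabulary lacks: every (mention, ID) pair whose canonical
form is not yet in the dictionary under that ID is added as a
`corpus_augmented` entry (e.g. "brain damage" → D001930).

**Root/affix translation fallback.** If the best direct candidate scores
below a threshold τ (presets 0.92 / 0.94 / 0.96), the mention is
decomposed into Greek/Latin medical roots and affixes and re-queried
through its English glosses: "neuropathy" → neuro ("nerve"/"nervous") +
pathy ("disease") → "nervous disease", which retrieves "nervous system
disease" and hence the correct identifier.

**Recognition features.** For CRF-based mention recognition the package
emits per-token features — character 2/3/4-grams; token, POS and lemma
uni-/bigrams in a ±3 window; digit/special-character/all-caps flags; word
shape (`IL-6` → `AA_0`); dictionary B/I match flags — together with a BIO
span codec and a pluggable sequence-labeller interface (a dictionary-tagger
baseline is built in; CRF training is delegated to an external backend).

## Worked example

```python
from dxnorm import (LexiconRecord, NormalizationParams, bundled_root_lexicon,
                    compile_dictionary, normalize_mention, translate)

d = compile_dictionary([LexiconRecord("D009422", "nervous system disease", ("C10",))])
roots = bundled_root_lexicon()
print(translate("neuropathy", roots))
r = normalize_mention("neuropathy", d, roots, NormalizationParams.for_run(1))
print(r.concept_id, r.method, round(r.score, 3))
```

prints

```
['nerve disease', 'nervous disease']
D009422 translated 0.926
```

The direct lookup of "neuropathy" finds no candidate at or above τ = 0.92,
so the mention is decomposed and its gloss phrase "nervous disease" is
re-queried; that phrase's canonical form scores 0.926 against the
dictionary key of "nervous system disease", which clears the 0.80
retrieval threshold, and the entry's identifier is assigned.

A CLI mirrors the library for shell use: `dxnorm dist`, `dxnorm compile`,
`dxnorm normalize`, `dxnorm evaluate`, `dxnorm simulate` (see `--help`).
Short narrative scripts live in `examples/`.

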