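"""Expand a base dictionary with mention/ID pairs from a gold corpus.

Gold-annotated corpora contain surface forms that controlled vocabularies
lack; adding each unseen (canonical form, ID) pair makes those mentions
resolvable exactly. Here "brain damage" is absent from the base lexicon but
annotated with D001930 in the corpus.
"""

from dxnorm import (
    LexiconRecord,
    Mention,
    augment_from_corpus,
    bundled_root_lexicon,
    compile_dictionary,
    normalize_mention,
)

base = compile_dictionary(
    [LexiconRecord("D001927", "brain diseases", ("C10.228",))]
)
gold = [Mention("2000", 0, 12, "brain damage", "Disease", "D001930")]

augmented = augment_from_corpus(base, gold)
print(f"entries: base={len(base)}, augmented={len(augmented)}")

before = normalize_mention("brain damage", base, bundled_root_lexicon())
after = normalize_mention("brain damage", augmented, bundled_root_lexicon())
print(f"before augmentation: {before.concept_id} (method={before.method})")
print(f"after  augmentation: {after.concept_id} (score={after.score:.1f}, method={after.method})")

# After augmentation the mention resolves to D001930 with score 1.0: its
# canonical form is now a dictionary key, so lookup is exact.
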