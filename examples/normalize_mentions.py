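"""Normalise disease mentions against a small dictionary.

Shows the two resolution routes: direct canonical lookup (score is the
Jaro-Winkler similarity between canonical forms, 1.0 for an exact variant)
and root/affix translation for Greek/Latin compounds the dictionary does
not contain verbatim.
"""

from dxnorm import (
    LexiconRecord,
    NormalizationParams,
    bundled_root_lexicon,
    compile_dictionary,
    normalize_mention,
    translate,
)

dictionary = compile_dictionary(
    [
        LexiconRecord("D012140", "respiratory tract diseases", ("C08",)),
        LexiconRecord("D009422", "nervous system disease", ("C10",)),
        LexiconRecord("D008171", "lung diseases", ("C08.381",)),
    ]
)
roots = bundled_root_lexicon()
params = NormalizationParams.for_run(1)  # translation threshold 0.92

print("gloss phrases for 'neuropathy':", translate("neuropathy", roots))
for mention in ["disease of the nervous system", "lung disease", "neuropathy"]:
    r = normalize_mention(mention, dictionary, roots, params)
    print(f"{mention!r:38} -> {r.concept_id}  method={r.method}  score={r.score:.3f}")

# The first two match directly because canonicalisation collapses word
# order, stop words and inflection; "neuropathy" only resolves because its
# decomposition neuro+pathy generates "nervous disease", which retrieves
# the "nervous system disease" entry.
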