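"""Token features and BIO labels for sequence-labelling recognition.

Builds the feature families a CRF consumes — character n-grams, windowed
context n-grams, orthographic flags, word shape, dictionary-match flags —
and shows the BIO codec plus the built-in dictionary-tagger baseline.
"""

from dxnorm import LexiconRecord, compile_dictionary
from dxnorm.ner_features import (
    DictionaryTagger,
    Token,
    bio_decode,
    ortho_features,
    word_shape,
    write_crfsuite,
)

sentence = []
pos = 0
for surface in ["IL-6", "rises", "in", "chronic", "obstructive", "pulmonary", "disease"]:
    sentence.append(Token(surface, pos, pos + len(surface), "NN", surface.lower(), "NP"))
    pos += len(surface) + 1

print("word shapes:", {t.surface: word_shape(t.surface) for t in sentence[:1]})
print("ortho flags for IL-6:", ortho_features(sentence[0]))

dx = compile_dictionary([LexiconRecord("D029424", "chronic obstructive pulmonary disease")])
tagger = DictionaryTagger({"Disease": dx})
labels = tagger.label(sentence)
print("BIO labels:", labels)
print("decoded spans:", bio_decode(labels, sentence, "doc1"))

print("--- CRFsuite layout (first token line, truncated) ---")
print(write_crfsuite([sentence], {"Disease": dx}).split("\n")[0][:100], "...")
# Each line holds the gold label then the token's features; the four
# dictionary tokens are tagged B-Disease / I-Disease by the baseline.
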