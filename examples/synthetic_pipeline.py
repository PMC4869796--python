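"""Full synthetic pipeline: generate, serialise, normalise, measure.

Builds a seeded lexicon and an annotated corpus whose mention surfaces are
exact names, reordered/stop-word variants and root compounds, then measures
top-1 ID recovery as character-edit noise increases.
"""

from dxnorm import gen_corpus, gen_lexicon, recovery_rate, write_pubtator

lexicon = gen_lexicon(n_concepts=25, synonyms_per=2, seed=11)
print(f"lexicon: {len(lexicon)} records, {len({r.concept_id for r in lexicon})} concepts")

docs = gen_corpus(lexicon, n_docs=4, perturbation=0.0, seed=11)
print("--- first document, PubTator format ---")
print(write_pubtator(docs[:1]))

for p in (0.0, 0.1, 0.2, 0.3):
    rates = [
        recovery_rate(gen_corpus(lexicon, 3, p, seed=s), lexicon) for s in range(5)
    ]
    print(f"perturbation {p:.1f}: mean top-1 ID recovery = {sum(rates) / len(rates):.2%}")

# At perturbation 0 every planted mention is recovered (surface variants
# collapse to the right canonical form; compounds resolve via translation);
# recovery then degrades as random character edits corrupt the surfaces.
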