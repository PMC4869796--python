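"""Micro-averaged evaluation: span-level, ID-level, and agreement.

Span-level P/R/F counts a prediction correct only on exact (document,
begin, end, type) identity; ID-level P/R/F compares per-document concept-ID
sets; pairwise agreement averages span F over all annotator pairs.
"""

from dxnorm import Mention, id_prf, pairwise_agreement, span_prf

gold = [
    Mention("doc1", 0, 23, "chronic airway blockage"),
    Mention("doc1", 44, 55, "lung cancer"),
    Mention("doc2", 10, 22, "brain damage"),
]
pred = [
    Mention("doc1", 44, 55, "lung cancer"),
    Mention("doc2", 10, 22, "brain damage"),
    Mention("doc2", 30, 35, "cough"),
]

p, r, f = span_prf(gold, pred)
print(f"span level: P={p:.3f} R={r:.3f} F={f:.3f}")  # 2 of 3 correct each way

p, r, f = id_prf({"doc1": {"D1", "D2"}}, {"doc1": {"D2"}})
print(f"id level:   P={p:.3f} R={r:.3f} F={f:.3f}")  # P=1.0, R=0.5, F=2/3

annotators = [gold, pred, gold]
mean_f, matrix = pairwise_agreement(annotators)
print(f"agreement over {len(matrix)} pairs: mean F={mean_f:.3f}")
# 3 annotators -> C(3,2)=3 pairs; identical annotators contribute F=1.
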