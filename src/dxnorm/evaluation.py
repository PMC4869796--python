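"""Micro-averaged precision/recall/F-score for recognition and normalisation.

Span-level scoring matches predictions against gold mentions one-to-one on
exact (document, begin, end, type); ID-level scoring compares per-document
concept-ID sets. Counts are pooled over all documents before the ratios are
taken (micro averaging). The span metric doubles as a pairwise
inter-annotator agreement measure, since F is symmetric in its arguments.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Mapping, Sequence

from .io_formats import Mention

__all__ = ["PRF", "span_prf", "id_prf", "pairwise_agreement"]

PRF = tuple[float, float, float]


def _prf(tp: int, n_pred: int, n_gold: int) -> PRF:
    p = tp / n_pred if n_pred else 0.0
    r = tp / n_gold if n_gold else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


def _span_keys(mentions: Iterable[Mention], which: str) -> set[tuple]:
    keys = [(m.doc_id, m.begin, m.end, m.type) for m in mentions]
    if len(keys) != len(set(keys)):
        raise ValueError(f"duplicate identical mentions in {which} list")
    return set(keys)


def span_prf(gold: Sequence[Mention], pred: Sequence[Mention]) -> PRF:
    """Micro-averaged span-level precision, recall and F-score.

    A prediction is a true positive iff a so-far-unmatched gold mention has
    the identical document ID, begin, end and type (exact matching, no
    partial credit). F = 2PR/(P+R), defined as 0 when P+R = 0.
    """
    g = _span_keys(gold, "gold")
    p = _span_keys(pred, "pred")
    return _prf(len(g & p), len(p), len(g))


def id_prf(
    gold_ids: Mapping[str, Iterable[str]], pred_ids: Mapping[str, Iterable[str]]
) -> PRF:
    """Micro-averaged document-level concept-ID precision, recall, F-score.

    Arguments map document ID to the set of concept IDs annotated/predicted
    in that document; intersection counts are pooled across documents.
    """
    tp = n_gold = n_pred = 0
    for doc in set(gold_ids) | set(pred_ids):
        g = set(gold_ids.get(doc, ()))
        p = set(pred_ids.get(doc, ()))
        tp += len(g & p)
        n_gold += len(g)
        n_pred += len(p)
    return _prf(tp, n_pred, n_gold)


def pairwise_agreement(
    annotator_sets: Sequence[Sequence[Mention]],
) -> tuple[float, dict[tuple[int, int], float]]:
    """Mean pairwise span-level F over all unordered annotator pairs.

    Returns the mean and the per-pair F matrix keyed by annotator index
    pair; with five annotators, C(5,2) = 10 pairs are evaluated. Raises
    with fewer than two annotators.
    """
    if len(annotator_sets) < 2:
        raise ValueError("need at least two annotators")
    matrix: dict[tuple[int, int], float] = {}
    for i, j in itertools.combinations(range(len(annotator_sets)), 2):
        _, _, f = span_prf(annotator_sets[i], annotator_sets[j])
        matrix[(i, j)] = f
    mean = sum(matrix.values()) / len(matrix)
    return mean, matrix
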