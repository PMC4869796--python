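"""Mention-to-identifier normalisation: direct lookup with translation fallback.

A mention is canonicalised and matched against the dictionary by
Jaro-Winkler retrieval with Levenshtein re-ranking. If the best direct
candidate scores below the translation threshold τ, the mention is
decomposed into medical roots/affixes and each generated gloss phrase is
used as a fresh query; the pooled best candidate wins if it clears the
retrieval threshold. Three standard presets set τ to 0.92 (recall-oriented),
0.94 and 0.96 (precision-oriented).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .dictionary import NormalizationDictionary
from .io_formats import Mention
from .rootlex import RootEntry, translate
from .similarity import Candidate, RetrievalParams, retrieve
from .textnorm import CanonConfig, canonicalize

__all__ = ["NormalizationParams", "NormalizationResult", "normalize_mention", "normalize_document"]

#: τ presets: run1 optimised for recall, run3 for precision.
RUN_THRESHOLDS = {"run1": 0.92, "run2": 0.94, "run3": 0.96}


@dataclass(frozen=True)
class NormalizationParams:
    """Normalisation thresholds.

    ``sim_threshold`` gates candidacy in retrieval; ``translate_threshold``
    (τ) decides whether the root/affix translation fallback is attempted:
    translation runs only when the best direct candidate scores below τ.
    """

    sim_threshold: float = 0.80
    translate_threshold: float = 0.92
    run_id: str = "custom"

    def __post_init__(self) -> None:
        if not self.sim_threshold <= self.translate_threshold <= 1.0:
            raise ValueError("need sim_threshold <= translate_threshold <= 1")

    @classmethod
    def for_run(cls, run: str | int) -> "NormalizationParams":
        run_id = f"run{run}" if isinstance(run, int) else run
        if run_id not in RUN_THRESHOLDS:
            raise ValueError(f"unknown run preset {run!r}")
        return cls(translate_threshold=RUN_THRESHOLDS[run_id], run_id=run_id)

    @property
    def retrieval(self) -> RetrievalParams:
        return RetrievalParams(sim_threshold=self.sim_threshold)


@dataclass(frozen=True)
class NormalizationResult:
    """The decision for one mention, with the candidate list kept for audit."""

    concept_id: str | None
    score: float
    method: str  # "direct" | "translated" | "none"
    candidates: tuple[Candidate, ...] = ()

    def __post_init__(self) -> None:
        if (self.method == "none") != (self.concept_id is None):
            raise ValueError("method 'none' iff concept_id is None")


_NO_MATCH = NormalizationResult(None, 0.0, "none")


def normalize_mention(
    text: str,
    d: NormalizationDictionary,
    roots: Iterable[RootEntry],
    params: NormalizationParams | None = None,
    cfg: CanonConfig | None = None,
) -> NormalizationResult:
    """Assign a concept ID to one mention surface string.

    1. Retrieve on the canonical form of *text*; if the best candidate's
       Jaro-Winkler score is at or above τ, assign it (method "direct").
    2. Otherwise translate the mention through the root lexicon and
       retrieve on each gloss phrase's canonical form; pool translated with
       direct candidates and, if the pooled best clears ``sim_threshold``,
       assign it ("translated" if it came from a gloss query, else
       "direct").
    3. Otherwise no identifier is assigned.

    Deterministic: ties are broken by score, Levenshtein distance, then
    concept ID.
    """
    params = params or NormalizationParams()
    cfg = cfg or d.cfg
    query = canonicalize(text, cfg)
    if not query:
        return _NO_MATCH
    direct = retrieve(query, d, params.retrieval)
    if direct and direct[0].jw_score >= params.translate_threshold:
        top = direct[0]
        return NormalizationResult(top.concept_id, top.jw_score, "direct", tuple(direct))
    # translation fallback
    pooled: list[tuple[Candidate, str]] = [(c, "direct") for c in direct]
    root_list = list(roots)
    if root_list:
        for phrase in translate(text, root_list):
            phrase_canonical = canonicalize(phrase, cfg)
            if not phrase_canonical:
                continue
            for c in retrieve(phrase_canonical, d, params.retrieval):
                pooled.append((c, "translated"))
    if not pooled:
        return _NO_MATCH
    pooled.sort(
        key=lambda cm: (
            -cm[0].jw_score,
            cm[0].lev_distance,
            cm[0].concept_id,
            cm[0].matched_name,
            cm[1] != "direct",  # prefer the direct route on exact ties
        )
    )
    best, route = pooled[0]
    if best.jw_score < params.sim_threshold:
        return _NO_MATCH
    ranked = tuple(
        replace(c, rank=i) for i, (c, _) in enumerate(pooled, start=1)
    )
    return NormalizationResult(best.concept_id, best.jw_score, route, ranked)


def normalize_document(
    mentions: Sequence[Mention],
    d: NormalizationDictionary,
    roots: Iterable[RootEntry],
    params: NormalizationParams | None = None,
    cfg: CanonConfig | None = None,
) -> list[Mention]:
    """Normalise each mention independently, filling in concept IDs.

    Spans are untouched; mentions whose normalisation fails keep
    ``concept_id=None``. The per-document ID sets needed for ID-level
    evaluation can be derived from the result.
    """
    root_list = list(roots)
    out: list[Mention] = []
    for m in mentions:
        res = normalize_mention(m.text, d, root_list, params, cfg)
        out.append(replace(m, concept_id=res.concept_id))
    return out
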