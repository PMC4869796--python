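"""Native string-distance implementations and candidate retrieval.

Retrieval is two-stage: every dictionary canonical form scoring at or above
a Jaro-Winkler threshold (default 0.80) is a candidate, and candidates are
then re-ranked by Levenshtein distance to break score ties, yielding a more
informative ordering than the similarity score alone.
"""

from __future__ import annotations

from dataclasses import dataclass

from .dictionary import NormalizationDictionary

__all__ = ["RetrievalParams", "Candidate", "jaro", "jaro_winkler", "levenshtein", "retrieve"]


@dataclass(frozen=True)
class RetrievalParams:
    """Retrieval-stage parameters.

    ``sim_threshold`` is the minimum Jaro-Winkler score for candidacy
    (inclusive, so exact matches survive even at 1.0); ``jw_prefix_weight``
    and ``jw_max_prefix`` are the standard Winkler prefix-bonus constants.
    """

    sim_threshold: float = 0.80
    jw_prefix_weight: float = 0.1
    jw_max_prefix: int = 4

    def __post_init__(self) -> None:
        if not 0.0 < self.sim_threshold <= 1.0:
            raise ValueError("sim_threshold must be in (0, 1]")
        if not 0.0 <= self.jw_prefix_weight <= 0.25:
            raise ValueError("jw_prefix_weight must be in [0, 0.25]")


@dataclass(frozen=True)
class Candidate:
    """A retrieved dictionary entry with its scores and rank."""

    concept_id: str
    matched_name: str
    canonical_form: str
    jw_score: float
    lev_distance: int
    rank: int = 0


def jaro(a: str, b: str) -> float:
    """Jaro similarity in [0, 1].

    Characters match if equal and within ``floor(max(|a|,|b|)/2) - 1``
    positions of each other; the transposition count is half the number of
    matched characters appearing in a different order. Both strings empty
    is defined as 1.0; exactly one empty as 0.0.
    """
    if a == b:
        return 1.0
    la, lb = len(a), len(b)
    if la == 0 or lb == 0:
        return 0.0
    window = max(la, lb) // 2 - 1
    a_match = [False] * la
    b_match = [False] * lb
    matches = 0
    for i, ca in enumerate(a):
        lo = max(0, i - window)
        hi = min(lb, i + window + 1)
        for j in range(lo, hi):
            if not b_match[j] and b[j] == ca:
                a_match[i] = b_match[j] = True
                matches += 1
                break
    if matches == 0:
        return 0.0
    transpositions = 0
    j = 0
    for i in range(la):
        if a_match[i]:
            while not b_match[j]:
                j += 1
            if a[i] != b[j]:
                transpositions += 1
            j += 1
    t = transpositions / 2
    m = matches
    return (m / la + m / lb + (m - t) / m) / 3


def jaro_winkler(a: str, b: str, params: RetrievalParams | None = None) -> float:
    """Jaro-Winkler similarity: Jaro plus a common-prefix bonus.

    ``jw = jaro + l * p * (1 - jaro)`` where ``l`` is the common prefix
    length capped at ``jw_max_prefix`` and ``p`` the prefix weight.
    Symmetric; equals plain Jaro when the prefix weight is 0.
    """
    params = params or RetrievalParams()
    base = jaro(a, b)
    prefix = 0
    for ca, cb in zip(a, b):
        if ca != cb or prefix >= params.jw_max_prefix:
            break
        prefix += 1
    return base + prefix * params.jw_prefix_weight * (1.0 - base)


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (insert / delete / substitute)."""
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(
                min(
                    prev[j] + 1,  # deletion
                    cur[j - 1] + 1,  # insertion
                    prev[j - 1] + (ca != cb),  # substitution
                )
            )
        prev = cur
    return prev[-1]


def retrieve(
    query_canonical: str,
    d: NormalizationDictionary,
    params: RetrievalParams | None = None,
) -> list[Candidate]:
    """Rank all dictionary entries whose canonical form scores >= threshold.

    Ordering: Jaro-Winkler score descending, then Levenshtein distance to
    the query ascending, then concept ID and matched name ascending (a
    deterministic tie-break). An exact key match necessarily ranks first
    with score 1.0. Both distances compare canonical forms, keeping the two
    stages consistent.
    """
    params = params or RetrievalParams()
    if not query_canonical or not d.entries:
        return []
    scored: list[Candidate] = []
    for canonical, bucket in d.entries.items():
        score = jaro_winkler(query_canonical, canonical, params)
        if score >= params.sim_threshold:
            dist = levenshtein(query_canonical, canonical)
            for e in bucket:
                scored.append(
                    Candidate(e.concept_id, e.name, canonical, score, dist)
                )
    scored.sort(
        key=lambda c: (-c.jw_score, c.lev_distance, c.concept_id, c.matched_name)
    )
    return [
        Candidate(c.concept_id, c.matched_name, c.canonical_form, c.jw_score, c.lev_distance, i)
        for i, c in enumerate(scored, start=1)
    ]
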