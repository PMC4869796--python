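"""Independent reference implementations used only as test oracles.

These deliberately use different formulations from the library code (match
sequences instead of flag scans, full DP tables, exhaustive enumeration) so
agreement is meaningful.
"""

from __future__ import annotations

import itertools


def jaro_ref(a: str, b: str) -> float:
    """Jaro similarity via explicit matched-character sequences."""
    if a == b:
        return 1.0
    if not a or not b:
        return 0.0
    window = max(len(a), len(b)) // 2 - 1
    used_b: set[int] = set()
    a_matched: list[str] = []
    b_positions: list[int] = []
    for i, ch in enumerate(a):
        for j in range(max(0, i - window), min(len(b), i + window + 1)):
            if j not in used_b and b[j] == ch:
                used_b.add(j)
                a_matched.append(ch)
                b_positions.append(j)
                break
    m = len(a_matched)
    if m == 0:
        return 0.0
    b_matched = [b[j] for j in sorted(used_b)]
    half_transpositions = sum(x != y for x, y in zip(a_matched, b_matched))
    t = half_transpositions / 2
    return (m / len(a) + m / len(b) + (m - t) / m) / 3


def jaro_winkler_ref(a: str, b: str, p: float = 0.1, max_l: int = 4) -> float:
    base = jaro_ref(a, b)
    l = 0
    while l < min(len(a), len(b), max_l) and a[l] == b[l]:
        l += 1
    return base + l * p * (1 - base)


def levenshtein_ref(a: str, b: str) -> int:
    """Full DP table (no row compaction)."""
    n, m = len(a), len(b)
    dp = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n + 1):
        dp[i][0] = i
    for j in range(m + 1):
        dp[0][j] = j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            dp[i][j] = min(
                dp[i - 1][j] + 1,
                dp[i][j - 1] + 1,
                dp[i - 1][j - 1] + (a[i - 1] != b[j - 1]),
            )
    return dp[n][m]


def all_segmentations(token: str, forms: dict[str, object], linkers: str = "oi"):
    """Exhaustive enumeration of full segmentations of *token* into forms,
    with an optional single connecting vowel between consecutive parts."""
    results: list[tuple[str, ...]] = []

    def rec(i: int, acc: tuple[str, ...]):
        if i == len(token):
            if acc:
                results.append(acc)
            return
        for f in forms:
            if token.startswith(f, i):
                j = i + len(f)
                rec(j, acc + (f,))
                if j < len(token) and token[j] in linkers and j + 1 < len(token):
                    rec(j + 1, acc + (f,))

    rec(0, ())
    return set(results)


def interval_dict_matches(surfaces: list[str], name_seqs: set[tuple[str, ...]]):
    """Exhaustive longest-then-leftmost matching over all intervals."""
    labels = ["O"] * len(surfaces)
    taken = [False] * len(surfaces)
    intervals = [
        (i, j)
        for i in range(len(surfaces))
        for j in range(i + 1, len(surfaces) + 1)
        if tuple(surfaces[i:j]) in name_seqs
    ]
    # longest first, then leftmost
    for i, j in sorted(intervals, key=lambda ij: (-(ij[1] - ij[0]), ij[0])):
        if any(taken[k] for k in range(i, j)):
            continue
        for k in range(i, j):
            taken[k] = True
            labels[k] = "B" if k == i else "I"
    return labels
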