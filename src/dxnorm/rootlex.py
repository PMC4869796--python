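"""Medical root/affix decomposition and gloss translation.

Many disease terms are Greek/Latin compounds absent from lexica that
nevertheless paraphrase an existing entry: "neuropathy" decomposes into
"neuro" (nerve, nervous) and "pathy" (disease), generating the variant
"nervous disease" which retrieves "nervous system disease" from a compiled
dictionary. This module segments mentions against a root/affix lexicon and
expands every segmentation into its gloss phrases for re-querying.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass
from importlib import resources
from typing import IO, Iterable

from .textnorm import tokenize

__all__ = [
    "RootEntry",
    "Decomposition",
    "read_root_lexicon",
    "bundled_root_lexicon",
    "decompose",
    "translate",
]

#: Single characters allowed as connecting vowels between roots
#: ("cardi" + "o" + "myo..."); consumed only when another part follows.
_LINKERS = "oi"


@dataclass(frozen=True)
class RootEntry:
    """A medical root or affix with its English glosses."""

    form: str
    kind: str  # "prefix" | "suffix" | "combining"
    glosses: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.form:
            raise ValueError("empty root form")
        if not self.glosses:
            raise ValueError(f"root {self.form!r} has no glosses")
        if self.kind not in ("prefix", "suffix", "combining"):
            raise ValueError(f"root {self.form!r}: unknown kind {self.kind!r}")


@dataclass(frozen=True)
class Decomposition:
    """One segmentation of a mention into lexicon forms.

    ``linkers[i]`` is the connecting vowel consumed after ``parts[i]``
    ("" if none), so that concatenating forms and linkers, followed by the
    residue tokens, reconstructs the mention. ``residue`` holds tokens of a
    multi-word mention for which no segmentation exists.
    """

    parts: tuple[tuple[str, RootEntry], ...]
    linkers: tuple[str, ...] = ()
    residue: str = ""


def read_root_lexicon(stream: IO[str] | str) -> list[RootEntry]:
    """Read a root lexicon TSV: ``form  kind  glosses`` (pipe-separated)."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    entries: list[RootEntry] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#") or (
            lineno == 1 and line.lower().startswith("form\t")
        ):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"root lexicon line {lineno}: expected 3 columns")
        form, kind, glosses = parts
        entries.append(
            RootEntry(form.lower(), kind, tuple(g for g in glosses.lower().split("|") if g))
        )
    return entries


def bundled_root_lexicon() -> list[RootEntry]:
    """The small curated Greek/Latin root lexicon shipped with the package."""
    text = resources.files("dxnorm").joinpath("data/roots.tsv").read_text("utf-8")
    return read_root_lexicon(text)


def _segment(token: str, lexicon: list[RootEntry]) -> list[Decomposition]:
    """All full segmentations of a single lowercase token, longest-prefix
    first with backtracking, allowing one optional connecting vowel between
    consecutive parts."""
    by_len = sorted(lexicon, key=lambda e: -len(e.form))
    out: list[Decomposition] = []
    seen: set[tuple] = set()

    def walk(i: int, parts: list, linkers: list) -> None:
        if i == len(token):
            key = tuple(f for f, _ in parts) + ("|",) + tuple(linkers)
            if parts and key not in seen:
                seen.add(key)
                out.append(Decomposition(tuple(parts), tuple(linkers)))
            return
        for entry in by_len:
            if token.startswith(entry.form, i):
                j = i + len(entry.form)
                parts.append((entry.form, entry))
                if j == len(token):
                    linkers.append("")
                    walk(j, parts, linkers)
                    linkers.pop()
                else:
                    for linker, nxt in (("", j),) + (
                        ((token[j], j + 1),)
                        if token[j] in _LINKERS and j + 1 < len(token)
                        else ()
                    ):
                        linkers.append(linker)
                        walk(nxt, parts, linkers)
                        linkers.pop()
                parts.pop()

    walk(0, [], [])
    return out


def decompose(mention: str, lexicon: Iterable[RootEntry]) -> list[Decomposition]:
    """Segment *mention* into lexicon forms.

    A single-token mention yields every full segmentation (empty list if
    none exists). Multi-word mentions are decomposed token-wise: the
    cartesian combination of per-token segmentations is returned, with
    unsegmentable tokens accumulated in ``residue``; if no token segments
    at all, the result is empty.
    """
    lex = list(lexicon)
    if not lex:
        raise ValueError("root lexicon must be non-empty")
    tokens = tokenize(mention)
    if not tokens:
        return []
    per_token = [(_segment(t, lex), t) for t in tokens]
    if all(not segs for segs, _ in per_token):
        return []
    choices = [segs if segs else [None] for segs, _ in per_token]
    combined: list[Decomposition] = []
    for combo in itertools.product(*choices):
        parts: list = []
        linkers: list = []
        residue: list[str] = []
        for pick, (_, tok) in zip(combo, per_token):
            if pick is None:
                residue.append(tok)
            else:
                parts.extend(pick.parts)
                linkers.extend(pick.linkers)
        combined.append(
            Decomposition(tuple(parts), tuple(linkers), " ".join(residue))
        )
    return combined


def translate(mention: str, lexicon: Iterable[RootEntry]) -> list[str]:
    """Generate English gloss phrases for every decomposition of *mention*.

    For each decomposition the Cartesian product of its parts' gloss lists
    is joined in surface part order (prefix gloss before suffix gloss,
    reproducing "nervous disease" rather than "disease nervous"); residue
    tokens of multi-word mentions are kept verbatim in their positions.
    Output is deduplicated, ordered by decomposition then gloss-product
    lexicographically; empty if the mention has no decomposition.
    """
    lex = list(lexicon)
    tokens = tokenize(mention)
    if not tokens or not lex:
        return []
    per_token = [(_segment(t, lex), t) for t in tokens]
    if all(not segs for segs, _ in per_token):
        return []
    token_phrase_lists: list[list[str]] = []
    for segs, tok in per_token:
        if not segs:
            token_phrase_lists.append([tok])
            continue
        phrases: list[str] = []
        for dec in segs:
            gloss_lists = [e.glosses for _, e in dec.parts]
            for combo in sorted(itertools.product(*gloss_lists)):
                phrases.append(" ".join(combo))
        token_phrase_lists.append(phrases)
    out: list[str] = []
    seen: set[str] = set()
    for combo in itertools.product(*token_phrase_lists):
        phrase = " ".join(combo)
        if phrase not in seen:
            seen.add(phrase)
            out.append(phrase)
    return out
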