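"""Deterministic canonicalisation of names and mentions.

A surface string is mapped to its *canonical form* by lowercasing, removing
stop words and punctuation, stemming each remaining token and sorting the
stemmed tokens alphabetically. Surface variants of the same concept name
("blocked airways", "airways are blocked") then collide on one dictionary
key, which is the basis of the whole normalisation pipeline.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass

from ._porter import porter_stem

#: Small bundled English stop list: articles, prepositions, copulas,
#: conjunctions. Overridable through :class:`CanonConfig`.
DEFAULT_STOP_WORDS: frozenset[str] = frozenset(
    """a an the of in on at by for to from with without and or nor but
    is are was were be been being am as into onto over under between
    during than then that this these those its it his her their our
    """.split()
)

_TOKEN_RE = re.compile(r"[^\W_]+")  # Unicode letters and digits


@dataclass(frozen=True)
class CanonConfig:
    """Immutable canonicalisation configuration.

    Parameters
    ----------
    stop_words
        Lowercase words removed before stemming.
    stemmer_id
        ``"porter"`` (default) or ``"none"``.
    """

    stop_words: frozenset[str] = DEFAULT_STOP_WORDS
    stemmer_id: str = "porter"

    def __post_init__(self) -> None:
        if self.stemmer_id not in ("porter", "none"):
            raise ValueError(f"unknown stemmer: {self.stemmer_id!r}")
        object.__setattr__(self, "stop_words", frozenset(self.stop_words))


def tokenize(text: str) -> list[str]:
    """Lowercase tokens of *text*, split on any non-alphanumeric character.

    NFKC-normalises and casefolds first so ligatures and Greek letters
    compare stably; hyphens split ("non-small" -> "non", "small") and
    punctuation-only runs vanish.
    """
    text = unicodedata.normalize("NFKC", text).casefold()
    return _TOKEN_RE.findall(text)


def canonicalize(text: str, cfg: CanonConfig | None = None) -> str:
    """Return the canonical form of *text*.

    The pipeline is: lowercase -> tokenise -> drop punctuation and stop
    words -> stem each remaining token -> sort lexicographically -> join
    with single spaces. Idempotent; token-order and case invariant.
    Degenerate inputs map to the empty string. Duplicate tokens are
    retained.
    """
    cfg = cfg or CanonConfig()
    tokens = [t for t in tokenize(text) if t not in cfg.stop_words]
    if cfg.stemmer_id == "porter":
        # re-filter: stemming may map a non-stop word onto a stop word
        # ("ins" -> "in"), which would break idempotence otherwise
        tokens = [s for t in tokens if (s := _stem_fix(t)) not in cfg.stop_words]
    return " ".join(sorted(tokens))


def _stem_fix(token: str) -> str:
    # Porter is not idempotent on rare words ("callousness" -> "callous"
    # -> "callou"); iterate to the fixpoint so canonical forms are stable
    # under re-canonicalisation. Converges in <= 3 steps in practice.
    prev, cur = token, porter_stem(token)
    while cur != prev:
        prev, cur = cur, porter_stem(cur)
    return cur
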