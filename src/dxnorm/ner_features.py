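"""Token feature extraction and BIO span codec for sequence labelling.

Concept recognition is cast as BIO sequence labelling over pre-tokenised
sentences (surface, offsets, POS, lemma, chunk per token — the common
one-token-per-line TSV layout). This module produces the per-token feature
vectors — character n-grams, windowed token/POS/lemma n-grams, orthographic
flags, word shape and dictionary-match flags — consumed by a pluggable
sequence labeller; CRF training itself is delegated to the backend.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Protocol, Sequence

from .dictionary import NormalizationDictionary
from .io_formats import Mention
from .textnorm import tokenize as _canon_tokenize

logger = logging.getLogger(__name__)

__all__ = [
    "Token",
    "FeatureVector",
    "char_ngrams",
    "context_ngrams",
    "ortho_features",
    "word_shape",
    "dict_features",
    "featurize_sentence",
    "bio_encode",
    "bio_decode",
    "SequenceLabeler",
    "DictionaryTagger",
    "read_token_tsv",
    "write_crfsuite",
]

FeatureVector = dict[str, object]


@dataclass(frozen=True)
class Token:
    surface: str
    begin: int = 0
    end: int = 0
    pos: str = ""
    lemma: str = ""
    chunk: str = ""
    label: str = "O"

    def __post_init__(self) -> None:
        if self.end and self.begin >= self.end:
            raise ValueError(f"token {self.surface!r}: begin >= end")


def char_ngrams(token: Token, sizes: tuple[int, ...] = (2, 3, 4)) -> FeatureVector:
    """Position-agnostic character n-grams (lengths 2, 3, 4) of the surface."""
    s = token.surface
    feats: FeatureVector = {}
    for n in sizes:
        for i in range(len(s) - n + 1):
            feats[f"ng{n}[{s[i:i + n]}]"] = True
    return feats


def context_ngrams(
    tokens: Sequence[Token], index: int, window: int = 3
) -> FeatureVector:
    """Token/POS/lemma unigrams and bigrams within ±*window* of *index*.

    Feature names encode the relative offset; the window is clipped at
    sentence bounds.
    """
    if not 0 <= index < len(tokens):
        raise IndexError(index)
    feats: FeatureVector = {}
    lo = max(0, index - window)
    hi = min(len(tokens) - 1, index + window)
    for j in range(lo, hi + 1):
        off = j - index
        t = tokens[j]
        feats[f"w[{off}]={t.surface}"] = True
        if t.pos:
            feats[f"pos[{off}]={t.pos}"] = True
        if t.lemma:
            feats[f"lem[{off}]={t.lemma}"] = True
    for j in range(lo, hi):
        off = j - index
        a, b = tokens[j], tokens[j + 1]
        feats[f"w[{off}]|w[{off + 1}]={a.surface}|{b.surface}"] = True
        if a.pos and b.pos:
            feats[f"pos[{off}]|pos[{off + 1}]={a.pos}|{b.pos}"] = True
        if a.lemma and b.lemma:
            feats[f"lem[{off}]|lem[{off + 1}]={a.lemma}|{b.lemma}"] = True
    return feats


def word_shape(surface: str) -> str:
    """Map uppercase letters to 'A', lowercase to 'a', digits to '0' and
    any other character to '_' ("IL-6" -> "AA_0")."""
    out = []
    for c in surface:
        if c.isalpha():
            out.append("A" if c.isupper() else "a")
        elif c.isdigit():
            out.append("0")
        else:
            out.append("_")
    return "".join(out)


def ortho_features(token: Token) -> FeatureVector:
    """Orthographic flags and the word shape of the surface."""
    s = token.surface
    return {
        "has_digit": any(c.isdigit() for c in s),
        "has_special": any(not c.isalnum() for c in s),
        "all_upper": bool(s) and s.isalpha() and s.isupper(),
        f"shape[{word_shape(s)}]": True,
    }


def _dict_token_sequences(d: NormalizationDictionary) -> set[tuple[str, ...]]:
    """Lowercased token sequences of every original surface name."""
    seqs: set[tuple[str, ...]] = set()
    for bucket in d.entries.values():
        for e in bucket:
            toks = tuple(_canon_tokenize(e.name))
            if toks:
                seqs.add(toks)
    return seqs


def dict_features(
    tokens: Sequence[Token],
    dictionaries: Mapping[str, NormalizationDictionary],
) -> list[FeatureVector]:
    """Per-token B/I dictionary-match flags, one feature family per dictionary.

    Each dictionary's surface names are matched token-level and
    case-insensitively against the sentence with a longest-then-leftmost
    left-to-right scan; tokens inside a match receive ``dict[<name>]=B``
    or ``=I`` features.
    """
    surfaces = [t.surface.casefold() for t in tokens]
    feats: list[FeatureVector] = [{} for _ in tokens]
    for dname, d in dictionaries.items():
        seqs = _dict_token_sequences(d)
        if not seqs:
            continue
        max_len = max(len(s) for s in seqs)
        matches = [
            (i, j)
            for i in range(len(surfaces))
            for j in range(i + 1, min(i + max_len, len(surfaces)) + 1)
            if tuple(surfaces[i:j]) in seqs
        ]
        taken = [False] * len(surfaces)
        for i, j in sorted(matches, key=lambda ij: (ij[0] - ij[1], ij[0])):
            if any(taken[k] for k in range(i, j)):
                continue
            feats[i][f"dict[{dname}]=B"] = True
            taken[i] = True
            for k in range(i + 1, j):
                feats[k][f"dict[{dname}]=I"] = True
                taken[k] = True
    return feats


def featurize_sentence(
    tokens: Sequence[Token],
    dictionaries: Mapping[str, NormalizationDictionary] | None = None,
    window: int = 3,
) -> list[FeatureVector]:
    """Full feature vectors for one sentence (all feature families merged)."""
    dict_feats = (
        dict_features(tokens, dictionaries) if dictionaries else [{} for _ in tokens]
    )
    out: list[FeatureVector] = []
    for i, tok in enumerate(tokens):
        fv: FeatureVector = {}
        fv.update(char_ngrams(tok))
        fv.update(context_ngrams(tokens, i, window))
        fv.update(ortho_features(tok))
        fv.update(dict_feats[i])
        out.append(fv)
    return out


# ------------------------------------------------------------------- BIO


def bio_encode(spans: Sequence[Mention], tokens: Sequence[Token]) -> list[str]:
    """Label tokens with B-<type>/I-<type>/O for the given spans.

    Spans not aligned to token boundaries are snapped outward to the
    nearest covering tokens (logged). Overlapping spans of the same type
    raise; overlapping spans of different types are resolved by keeping the
    earlier-starting (outermost) one, logged.
    """
    labels = ["O"] * len(tokens)
    last_end = -1
    last_type: str | None = None
    for span in sorted(spans, key=lambda s: (s.begin, -s.end)):
        covered = [
            i for i, t in enumerate(tokens) if t.end > span.begin and t.begin < span.end
        ]
        if not covered:
            logger.warning("span %r covers no tokens — dropped", span.text)
            continue
        first, last = covered[0], covered[-1]
        if tokens[first].begin != span.begin or tokens[last].end != span.end:
            logger.info("span %r snapped outward to token boundaries", span.text)
        if tokens[first].begin <= last_end:
            if span.type == last_type:
                raise ValueError(f"overlapping spans of type {span.type!r}")
            logger.warning(
                "span %r overlaps an earlier span of another type — dropped",
                span.text,
            )
            continue
        labels[first] = f"B-{span.type}"
        for i in covered[1:]:
            labels[i] = f"I-{span.type}"
        last_end = tokens[last].end - 1
        last_type = span.type
    return labels


def bio_decode(
    labels: Sequence[str], tokens: Sequence[Token], doc_id: str = ""
) -> list[Mention]:
    """Recover mention spans from a BIO label sequence.

    An illegal "I-X" following "O" or a span of a different type is
    repaired by treating it as "B-X". Inverse of :func:`bio_encode` on
    token-aligned, non-overlapping spans.
    """
    if len(labels) != len(tokens):
        raise ValueError("labels and tokens differ in length")
    spans: list[Mention] = []
    cur_type: str | None = None
    cur_start = 0
    cur_end = 0

    def flush() -> None:
        nonlocal cur_type
        if cur_type is not None:
            # rebuild the surface from token offsets (gaps become spaces)
            buf: list[str] = []
            pos = cur_start
            for t in tokens:
                if t.begin >= cur_start and t.end <= cur_end:
                    buf.append(" " * (t.begin - pos))
                    buf.append(t.surface)
                    pos = t.end
            spans.append(Mention(doc_id, cur_start, cur_end, "".join(buf), cur_type))
            cur_type = None

    for label, tok in zip(labels, tokens):
        if label == "O":
            flush()
            continue
        tag, _, ltype = label.partition("-")
        if tag == "B" or cur_type != ltype:  # I after O / type switch -> repair
            flush()
            cur_type = ltype
            cur_start = tok.begin
        cur_end = tok.end
    flush()
    return spans


# ------------------------------------------------- pluggable labeller


class SequenceLabeler(Protocol):
    """Backend contract: train on featurised sentences, label new ones."""

    def train(self, sentences: Sequence[Sequence[Token]]) -> None: ...

    def label(self, tokens: Sequence[Token]) -> list[str]: ...


class DictionaryTagger:
    """Baseline labeller: tags longest dictionary matches as entities.

    Satisfies the :class:`SequenceLabeler` interface with no external model,
    so pipelines and tests run without a CRF backend; a trained CRF can be
    dropped in behind the same contract.
    """

    def __init__(self, dictionaries: Mapping[str, NormalizationDictionary]):
        self.dictionaries = dict(dictionaries)

    def train(self, sentences: Sequence[Sequence[Token]]) -> None:  # no-op
        return None

    def label(self, tokens: Sequence[Token]) -> list[str]:
        feats = dict_features(tokens, self.dictionaries)
        labels = []
        for fv in feats:
            tag = "O"
            for name in fv:
                if name.startswith("dict[") and name.endswith("=B"):
                    tag = f"B-{name[5:-3]}"
                    break
                if name.startswith("dict[") and name.endswith("=I"):
                    tag = f"I-{name[5:-3]}"
                    break
            labels.append(tag)
        return labels


# ------------------------------------------------------------ token I/O


def read_token_tsv(stream: IO[str] | str) -> list[list[Token]]:
    """Read sentences of tokens from TSV: surface, begin, end, pos, lemma,
    chunk, label (one token per line, blank line between sentences)."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    sentences: list[list[Token]] = []
    cur: list[Token] = []
    for raw in stream:
        line = raw.rstrip("\n")
        if not line.strip():
            if cur:
                sentences.append(cur)
                cur = []
            continue
        parts = line.split("\t")
        parts += [""] * (7 - len(parts))
        surface, begin, end, pos, lemma, chunk, label = parts[:7]
        cur.append(
            Token(surface, int(begin or 0), int(end or 0), pos, lemma, chunk, label or "O")
        )
    if cur:
        sentences.append(cur)
    return sentences


def write_crfsuite(
    sentences: Sequence[Sequence[Token]],
    dictionaries: Mapping[str, NormalizationDictionary] | None = None,
    window: int = 3,
) -> str:
    """Featurised output in CRFsuite text format: per token one line of
    tab-separated label then feature strings; blank line between sentences."""
    blocks: list[str] = []
    for sent in sentences:
        feats = featurize_sentence(sent, dictionaries, window)
        lines = []
        for tok, fv in zip(sent, feats):
            items = sorted(
                name if val is True else f"{name}={val}"
                for name, val in fv.items()
                if val is not False
            )
            lines.append("\t".join([tok.label, *items]))
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + ("\n" if blocks else "")
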