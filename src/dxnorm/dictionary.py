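"""Compile, filter and augment normalisation dictionaries.

A normalisation dictionary maps each canonical form to the set of concept
entries sharing it. It is compiled from a lexicon (MeSH-shaped TSV: id,
tree numbers, preferred name, synonyms) and can be augmented with
mention/ID pairs observed in gold-annotated corpora — e.g. a corpus using
"brain damage" for D001930 when the base lexicon lacks that synonym.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import IO, Iterable

from .io_formats import Mention
from .textnorm import CanonConfig, canonicalize

logger = logging.getLogger(__name__)

__all__ = [
    "LexiconRecord",
    "DictEntry",
    "NormalizationDictionary",
    "read_lexicon_tsv",
    "filter_by_subtree",
    "compile_dictionary",
    "augment_from_corpus",
]

#: Concept-ID sentinel meaning "unmappable" in CDR-style corpora.
UNMAPPABLE_ID = "-1"


@dataclass(frozen=True)
class LexiconRecord:
    """One concept ID paired with one surface name."""

    concept_id: str
    name: str
    tree_numbers: tuple[str, ...] = ()
    source: str = "base"  # "base" | "corpus_augmented"

    def __post_init__(self) -> None:
        if not self.concept_id:
            raise ValueError("empty concept_id")
        if not self.name:
            raise ValueError(f"empty name for concept {self.concept_id}")


@dataclass(frozen=True, order=True)
class DictEntry:
    """A (concept ID, original surface name, source) triple."""

    concept_id: str
    name: str
    source: str = "base"


@dataclass
class NormalizationDictionary:
    """Map from canonical form to the entries sharing that form."""

    cfg: CanonConfig = field(default_factory=CanonConfig)
    entries: dict[str, set[DictEntry]] = field(default_factory=dict)

    def __len__(self) -> int:
        return sum(len(v) for v in self.entries.values())

    def __contains__(self, canonical: str) -> bool:
        return canonical in self.entries

    def add(self, canonical: str, entry: DictEntry) -> bool:
        """Insert an entry; returns True if it was new."""
        bucket = self.entries.setdefault(canonical, set())
        if entry in bucket:
            return False
        bucket.add(entry)
        return True

    def ids_for(self, canonical: str) -> set[str]:
        return {e.concept_id for e in self.entries.get(canonical, ())}

    def to_tsv(self, stream: IO[str] | None = None) -> str | None:
        """Serialise as ``canonical_form  concept_id  original_name  source``."""
        out = stream or io.StringIO()
        for canonical in sorted(self.entries):
            for e in sorted(self.entries[canonical]):
                out.write(f"{canonical}\t{e.concept_id}\t{e.name}\t{e.source}\n")
        if stream is None:
            return out.getvalue()  # type: ignore[union-attr]
        return None

    @classmethod
    def from_tsv(cls, stream: IO[str] | str, cfg: CanonConfig | None = None) -> "NormalizationDictionary":
        if isinstance(stream, str):
            stream = io.StringIO(stream)
        d = cls(cfg=cfg or CanonConfig())
        for line in stream:
            line = line.rstrip("\n")
            if not line:
                continue
            canonical, concept_id, name, source = line.split("\t")
            d.add(canonical, DictEntry(concept_id, name, source))
        return d


def read_lexicon_tsv(stream: IO[str] | str) -> list[LexiconRecord]:
    """Read a lexicon TSV: ``id  tree_numbers  name  synonyms``.

    Tree numbers are semicolon-separated, synonyms pipe-separated; a header
    line starting with ``id`` is skipped. Each synonym yields its own
    record under the same concept ID.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    records: list[LexiconRecord] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or (lineno == 1 and line.lower().startswith("id\t")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"lexicon line {lineno}: expected >=3 columns")
        cid, trees_raw, name = parts[0], parts[1], parts[2]
        synonyms = parts[3].split("|") if len(parts) > 3 and parts[3] else []
        trees = tuple(t for t in trees_raw.split(";") if t)
        records.append(LexiconRecord(cid, name, trees))
        for syn in synonyms:
            if syn:
                records.append(LexiconRecord(cid, syn, trees))
    return records


def filter_by_subtree(
    records: Iterable[LexiconRecord],
    allowed_prefixes: Iterable[str] = ("C", "F"),
) -> list[LexiconRecord]:
    """Keep records with at least one tree number under an allowed prefix.

    The defaults select the Diseases ("C") and Psychiatry/Psychology ("F")
    subtrees of a MeSH-style hierarchy. Records with no tree numbers are
    dropped.
    """
    prefixes = tuple(allowed_prefixes)
    if not prefixes:
        raise ValueError("allowed_prefixes must be non-empty")
    return [
        r
        for r in records
        if any(t.startswith(p) for t in r.tree_numbers for p in prefixes)
    ]


def compile_dictionary(
    records: Iterable[LexiconRecord], cfg: CanonConfig | None = None
) -> NormalizationDictionary:
    """Canonicalise every record name and index it.

    Distinct concepts sharing a canonical form (homonyms) are all kept
    under the same key; exact duplicate (canonical, id, name) triples
    collapse. Names canonicalising to the empty string are skipped with a
    logged warning.
    """
    cfg = cfg or CanonConfig()
    d = NormalizationDictionary(cfg=cfg)
    for rec in records:
        canonical = canonicalize(rec.name, cfg)
        if not canonical:
            logger.warning(
                "skipping %s:%r — canonicalises to empty string",
                rec.concept_id,
                rec.name,
            )
            continue
        d.add(canonical, DictEntry(rec.concept_id, rec.name, rec.source))
    return d


def augment_from_corpus(
    d: NormalizationDictionary,
    gold: Iterable[Mention],
    cfg: CanonConfig | None = None,
) -> NormalizationDictionary:
    """Expand a dictionary with gold mention/ID pairs it does not cover.

    For each gold mention whose canonical form is absent, or present but
    without that mention's concept ID, a ``corpus_augmented`` entry is
    added; existing entries are never touched. Composite IDs ("D1|D2") are
    split and each component added; the "-1" unmappable sentinel and
    mentions lacking IDs are skipped with a warning. Returns a new
    dictionary; the input is not mutated. Idempotent.
    """
    cfg = cfg or d.cfg
    out = NormalizationDictionary(cfg=cfg)
    for canonical, bucket in d.entries.items():
        out.entries[canonical] = set(bucket)
    for m in gold:
        if not m.concept_id:
            logger.warning("gold mention %r lacks a concept ID — skipped", m.text)
            continue
        canonical = canonicalize(m.text, cfg)
        if not canonical:
            logger.warning("gold mention %r canonicalises to empty — skipped", m.text)
            continue
        for cid in m.concept_id.split("|"):
            if not cid or cid == UNMAPPABLE_ID:
                continue
            if cid not in out.ids_for(canonical):
                out.add(canonical, DictEntry(cid, m.text, "corpus_augmented"))
    return out
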