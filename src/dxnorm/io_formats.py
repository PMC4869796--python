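"""Document model plus PubTator and BioC XML readers/writers.

Both formats describe annotated title/abstract documents. Offsets are
0-based, half-open, over the format's native text concatenation; for
PubTator that is ``title + " " + abstract`` (the corpus convention of a
single separator character). Every reader asserts that each annotation's
surface text equals the corresponding substring of the document text.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import IO, Iterable

from lxml import etree

__all__ = [
    "Mention",
    "Document",
    "read_pubtator",
    "write_pubtator",
    "read_bioc",
    "write_bioc",
]


@dataclass(frozen=True, order=True)
class Mention:
    """A text span with a semantic type and an optional concept ID."""

    doc_id: str
    begin: int
    end: int
    text: str
    type: str = "Disease"
    concept_id: str | None = None

    def __post_init__(self) -> None:
        if self.begin < 0 or self.end <= self.begin:
            raise ValueError(
                f"invalid span [{self.begin},{self.end}) in doc {self.doc_id!r}"
            )


@dataclass
class Document:
    """An annotated document: ordered passages plus mention annotations."""

    doc_id: str
    passages: list[tuple[int, str]] = field(default_factory=list)
    mentions: list[Mention] = field(default_factory=list)

    @property
    def text(self) -> str:
        """Full text with passages placed at their declared offsets."""
        out: list[str] = []
        pos = 0
        for off, txt in self.passages:
            if off < pos:
                raise ValueError(f"passage offsets not increasing in {self.doc_id}")
            out.append(" " * (off - pos))
            out.append(txt)
            pos = off + len(txt)
        return "".join(out)

    def validate(self) -> None:
        text = self.text
        for m in self.mentions:
            if m.end > len(text) or text[m.begin : m.end] != m.text:
                raise ValueError(
                    f"mention {m.text!r} does not match document text "
                    f"[{m.begin}:{m.end}] in {self.doc_id}"
                )


# ---------------------------------------------------------------- PubTator


def read_pubtator(stream: IO[str] | str) -> list[Document]:
    """Parse PubTator-formatted text into documents.

    Layout per document: ``PMID|t|title`` and ``PMID|a|abstract`` lines,
    then tab-separated annotation lines ``PMID begin end text type ID``,
    with documents separated by blank lines. Raises ``ValueError`` with the
    offending line number on malformed input or out-of-text offsets.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    docs: list[Document] = []
    cur: Document | None = None
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            if cur is not None:
                cur.validate()
                docs.append(cur)
                cur = None
            continue
        if "|" in line.split("\t")[0]:
            parts = line.split("|", 2)
            if len(parts) != 3 or parts[1] not in ("t", "a"):
                raise ValueError(f"line {lineno}: malformed title/abstract line")
            pmid, kind, text = parts
            if cur is None:
                cur = Document(doc_id=pmid)
            elif cur.doc_id != pmid:
                raise ValueError(f"line {lineno}: document ID changed mid-block")
            offset = 0
            if cur.passages:
                last_off, last_txt = cur.passages[-1]
                offset = last_off + len(last_txt) + 1  # single separator char
            cur.passages.append((offset, text))
        else:
            fields = line.split("\t")
            if cur is None:
                raise ValueError(f"line {lineno}: annotation before title line")
            if len(fields) < 5:
                raise ValueError(f"line {lineno}: malformed annotation line")
            pmid, begin, end, text, mtype = fields[:5]
            concept_id = fields[5] if len(fields) > 5 and fields[5] else None
            try:
                b, e = int(begin), int(end)
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer offsets") from exc
            m = Mention(pmid, b, e, text, mtype, concept_id)
            full = cur.text
            if e > len(full) or full[b:e] != text:
                raise ValueError(
                    f"line {lineno}: annotation text does not match offsets"
                )
            cur.mentions.append(m)
    if cur is not None:
        cur.validate()
        docs.append(cur)
    return docs


def write_pubtator(docs: Iterable[Document]) -> str:
    """Serialise documents to PubTator text."""
    blocks: list[str] = []
    for doc in docs:
        doc.validate()
        lines: list[str] = []
        for i, (_, txt) in enumerate(doc.passages):
            kind = "t" if i == 0 else "a"
            lines.append(f"{doc.doc_id}|{kind}|{txt}")
        for m in sorted(doc.mentions, key=lambda m: (m.begin, m.end)):
            cid = m.concept_id or ""
            lines.append(
                f"{doc.doc_id}\t{m.begin}\t{m.end}\t{m.text}\t{m.type}\t{cid}"
            )
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + ("\n" if blocks else "")


# -------------------------------------------------------------------- BioC

#: Infon key under which concept identifiers are stored (CDR convention).
BIOC_ID_INFON = "MESH"


def write_bioc(docs: Iterable[Document], id_infon: str = BIOC_ID_INFON) -> str:
    """Serialise documents to a BioC XML collection (UTF-8 string)."""
    coll = etree.Element("collection")
    etree.SubElement(coll, "source").text = "dxnorm"
    etree.SubElement(coll, "date").text = ""
    etree.SubElement(coll, "key").text = ""
    ann_counter = 0
    for doc in docs:
        doc.validate()
        d = etree.SubElement(coll, "document")
        etree.SubElement(d, "id").text = doc.doc_id
        full = doc.text
        for pi, (off, txt) in enumerate(doc.passages):
            p = etree.SubElement(d, "passage")
            infon = etree.SubElement(p, "infon", key="type")
            infon.text = "title" if pi == 0 else "abstract"
            etree.SubElement(p, "offset").text = str(off)
            etree.SubElement(p, "text").text = txt
            p_end = off + len(txt)
            for m in sorted(doc.mentions, key=lambda m: (m.begin, m.end)):
                if not (off <= m.begin and m.end <= p_end):
                    continue
                ann_counter += 1
                a = etree.SubElement(p, "annotation", id=str(ann_counter))
                ti = etree.SubElement(a, "infon", key="type")
                ti.text = m.type
                if m.concept_id is not None:
                    mi = etree.SubElement(a, "infon", key=id_infon)
                    mi.text = m.concept_id
                etree.SubElement(
                    a,
                    "location",
                    offset=str(m.begin),
                    length=str(m.end - m.begin),
                )
                etree.SubElement(a, "text").text = m.text
            assert full[off : off + len(txt)] == txt
    return etree.tostring(
        coll, xml_declaration=True, encoding="UTF-8", pretty_print=True
    ).decode("utf-8")


def read_bioc(stream: IO[str] | IO[bytes] | str, id_infon: str = BIOC_ID_INFON) -> list[Document]:
    """Parse a BioC XML collection.

    Annotations must carry a ``type`` infon and a single ``location``;
    concept identifiers are read from the *id_infon* infon key. Raises
    ``ValueError`` naming the offending element on schema violations.
    """
    if isinstance(stream, str):
        data = stream.encode("utf-8")
    else:
        data = stream.read()
        if isinstance(data, str):
            data = data.encode("utf-8")
    if not data.strip():
        return []
    root = etree.fromstring(data)
    if root.tag != "collection":
        raise ValueError(f"expected <collection> root, found <{root.tag}>")
    docs: list[Document] = []
    for d in root.findall("document"):
        id_el = d.find("id")
        if id_el is None or not id_el.text:
            raise ValueError("<document> lacks an <id> element")
        doc = Document(doc_id=id_el.text)
        for p in d.findall("passage"):
            off_el = p.find("offset")
            text_el = p.find("text")
            if off_el is None:
                raise ValueError(f"<passage> in {doc.doc_id} lacks <offset>")
            offset = int(off_el.text or "0")
            text = text_el.text or "" if text_el is not None else ""
            doc.passages.append((offset, text))
            for a in p.findall("annotation"):
                infons = {i.get("key"): (i.text or "") for i in a.findall("infon")}
                if "type" not in infons:
                    raise ValueError(
                        f"<annotation> in {doc.doc_id} lacks a type infon"
                    )
                loc = a.find("location")
                atext_el = a.find("text")
                if loc is None or atext_el is None:
                    raise ValueError(
                        f"<annotation> in {doc.doc_id} lacks location/text"
                    )
                begin = int(loc.get("offset"))
                length = int(loc.get("length"))
                doc.mentions.append(
                    Mention(
                        doc.doc_id,
                        begin,
                        begin + length,
                        atext_el.text or "",
                        infons["type"],
                        infons.get(id_infon) or None,
                    )
                )
        doc.validate()
        docs.append(doc)
    return docs
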