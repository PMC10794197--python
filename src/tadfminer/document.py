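"""Normalized document model for marked-up articles.

Publisher markup is reduced to two minimal fixture dialects:

``xml-like``
    ``<article>`` root; ``<meta>`` block with citation children
    (``<doi>``, ``<authors>``, ``<journal>``, ``<year>``, ...); optional
    ``<title>``; content as ``<h>``, ``<p>`` and ``<table>`` elements,
    optionally grouped in ``<section>``. Tables use ``<caption>``, ``<tr>``,
    ``<th>``, ``<td>``.

``html-like``
    ``<html><head>...</head><body>...</body></html>``; citation fields as
    ``<meta name="..." content="..."/>`` in the head; content as
    ``<h1>``/``<h2>``, ``<p>`` and ``<table>`` (``<thead>``/``<tbody>``
    optional) in the body.

Inline decoration tags (``b``, ``i``, ``em``, ``sub``, ``sup``, ``span``)
are flattened to their text in both dialects. Files are UTF-8; Greek
letters (λ, τ, Δ, Φ) and astral-plane characters survive round trips.

The metadata/citation block becomes a flagged element that the parsing
iterator (:func:`iter_parseable`) never yields, so no property record can
originate from it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from lxml import etree

from .errors import ConfigurationError, MarkupParseError

DIALECTS = ("xml-like", "html-like")

_HEADING_TAGS = {"h", "h1", "h2", "h3"}


@dataclass
class Table:
    """A table with nested headers flattened to per-column header lists."""

    caption: str = ""
    header_rows: list[list[str]] = field(default_factory=list)
    body: list[list[str]] = field(default_factory=list)

    @property
    def n_columns(self) -> int:
        rows = self.body or self.header_rows
        return len(rows[0]) if rows else 0

    @property
    def column_headers(self) -> list[list[str]]:
        """Per-column ordered header strings, outermost first.

        Empty header cells are skipped so every column keeps at least the
        headers that actually name it.
        """
        ncol = self.n_columns
        out: list[list[str]] = []
        for c in range(ncol):
            col = [row[c] for row in self.header_rows if c < len(row) and row[c]]
            out.append(col)
        return out


@dataclass
class Element:
    kind: str  # heading | paragraph | table | metadata
    text: str = ""
    table_payload: Table | None = None
    section_heading: str = ""
    index: int = -1  # position within Document.elements

    @property
    def is_metadata(self) -> bool:
        return self.kind == "metadata"


@dataclass
class Document:
    doc_id: str
    metadata: dict[str, str] = field(default_factory=dict)
    elements: list[Element] = field(default_factory=list)
    source_dialect: str = "xml-like"


def normalize_name(raw: str) -> str:
    """Standardize a chemical name by removing unnecessary whitespace.

    Leading/trailing whitespace is stripped, internal runs collapse to a
    single space, and spaces adjacent to hyphens, commas and brackets are
    removed. Single spaces between alphabetic words are kept so multi-word
    names ("boron nitride") survive. Idempotent.
    """
    s = re.sub(r"\s+", " ", raw.strip())
    s = re.sub(r"\s*([\-,()\[\]{}])\s*", r"\1", s)
    return s


def _text_of(node: etree._Element) -> str:
    return re.sub(r"\s+", " ", "".join(node.itertext())).strip()


def _parse_table(node: etree._Element) -> Table:
    caption = ""
    header_rows: list[list[str]] = []
    body: list[list[str]] = []
    cap = node.find("caption")
    if cap is not None:
        caption = _text_of(cap)
    rows = node.findall(".//tr")
    for tr in rows:
        cells = [c for c in tr if c.tag in ("th", "td")]
        if not cells:
            continue
        values = [_text_of(c) for c in cells]
        in_thead = tr.getparent() is not None and tr.getparent().tag == "thead"
        if in_thead or all(c.tag == "th" for c in cells):
            header_rows.append(values)
        else:
            body.append(values)
    # pad to rectangular so per-column lookups stay in range
    width = max((len(r) for r in header_rows + body), default=0)
    for r in header_rows + body:
        r.extend([""] * (width - len(r)))
    return Table(caption=caption, header_rows=header_rows, body=body)


def _walk_content(nodes: list[etree._Element], doc: Document, section: str) -> None:
    for node in nodes:
        tag = node.tag if isinstance(node.tag, str) else ""
        if tag == "section":
            h = next((c for c in node if isinstance(c.tag, str) and c.tag in _HEADING_TAGS), None)
            inner_section = _text_of(h) if h is not None else section
            _walk_content(list(node), doc, inner_section)
        elif tag in _HEADING_TAGS:
            text = _text_of(node)
            section = text
            doc.elements.append(Element(kind="heading", text=text, section_heading=text))
        elif tag == "p":
            doc.elements.append(
                Element(kind="paragraph", text=_text_of(node), section_heading=section)
            )
        elif tag == "table":
            doc.elements.append(
                Element(kind="table", table_payload=_parse_table(node), section_heading=section)
            )
        # any other tag is decoration or structure we do not model: skip


def read_document(path: str | Path, dialect: str = "xml-like") -> Document:
    """Read a marked-up article file into a :class:`Document`.

    Headings, paragraphs and tables are kept in source order; the citation
    block is mapped to ``Document.metadata`` and flagged so parsers skip it.
    """
    if dialect not in DIALECTS:
        raise ConfigurationError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    path = Path(path)
    try:
        tree = etree.parse(str(path), etree.XMLParser(recover=False))
    except etree.XMLSyntaxError as exc:
        raise MarkupParseError(f"malformed {dialect} markup in {path.name}: {exc.msg}",
                               line=exc.lineno) from exc
    root = tree.getroot()
    doc = Document(doc_id=path.stem, source_dialect=dialect)

    if dialect == "xml-like":
        meta = root.find("meta")
        if meta is not None:
            for child in meta:
                if isinstance(child.tag, str):
                    doc.metadata[child.tag] = _text_of(child)
            doc.elements.append(
                Element(kind="metadata", text=_text_of(meta), section_heading="")
            )
        title = root.find("title")
        if title is not None:
            doc.metadata.setdefault("title", _text_of(title))
        content = [n for n in root
                   if isinstance(n.tag, str) and n.tag not in ("meta", "title")]
        _walk_content(content, doc, section="")
    else:  # html-like
        head = root.find("head")
        if head is not None:
            for m in head.findall("meta"):
                name, content_attr = m.get("name"), m.get("content")
                if name and content_attr is not None:
                    doc.metadata[name] = content_attr
            title = head.find("title")
            if title is not None:
                doc.metadata.setdefault("title", _text_of(title))
            doc.elements.append(
                Element(kind="metadata", text=_text_of(head), section_heading="")
            )
        body = root.find("body")
        if body is not None:
            _walk_content(list(body), doc, section="")

    if "doi" in doc.metadata:
        doc.doc_id = doc.metadata["doi"]
    for i, el in enumerate(doc.elements):
        el.index = i
    return doc


def iter_parseable(doc: Document) -> Iterator[Element]:
    """Yield elements eligible for property parsing (metadata excluded)."""
    for el in doc.elements:
        if not el.is_metadata:
            yield el
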