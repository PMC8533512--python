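"""Small lxml helpers shared by the parser modules (namespace-agnostic)."""

from __future__ import annotations

from lxml import etree

from .errors import ParseError


def parse_xml(doc: bytes) -> etree._Element:
    """Parse bytes into an element tree, mapping syntax errors to ParseError."""
    try:
        return etree.fromstring(doc)
    except etree.XMLSyntaxError as exc:
        line, column = (exc.position or (None, None))
        raise ParseError(f"malformed XML: {exc.msg}", line=line, column=column) from exc


def local_name(el: etree._Element) -> str:
    return etree.QName(el).localname


def find_all(el: etree._Element, name: str) -> list[etree._Element]:
    """All descendant elements with the given local name, in document order."""
    return [e for e in el.iter() if isinstance(e.tag, str) and local_name(e) == name]


def first(el: etree._Element, name: str) -> etree._Element | None:
    hits = find_all(el, name)
    return hits[0] if hits else None


def text_of(el: etree._Element | None) -> str | None:
    if el is None:
        return None
    text = "".join(el.itertext()).strip()
    return text or None
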