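"""Reader/writer for the SemEval-2013 Task 9 DDI XML dialect.

The DDIExtraction2013 corpus annotates biomedical sentences with drug
mentions and, for every unordered pair of mentions, whether the sentence
asserts a drug-drug interaction and of which kind (``mechanism``,
``effect``, ``advice`` or ``int``).  Layout::

    <corpus>                         (optional wrapper)
      <document id="..." origin="drugbank|medline">
        <sentence id="..." text="...">
          <entity id="..." charOffset="s-e[;s-e]" type="drug" text="..."/>
          <pair id="..." e1="..." e2="..." ddi="true|false" [type="effect"]/>
        </sentence>
      </document>
    </corpus>

Character offsets follow the corpus convention of *inclusive* end offsets:
``charOffset="0-11"`` covers twelve characters.  Discontinuous mentions use
``;``-separated spans whose surface fragments are joined by a single space.
"""

from __future__ import annotations

import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

ENTITY_TYPES = ("drug", "brand", "group", "drug_n")
INTERACTION_TYPES = ("mechanism", "effect", "advice", "int")
#: Fixed class order used everywhere downstream (scorer rows, model output).
CLASS_ORDER = ("negative", "mechanism", "effect", "advice", "int")


class CorpusValidationError(ValueError):
    """An object violates a DDI-corpus invariant."""


class CorpusParseError(ValueError):
    """The XML file is malformed or not in the DDI dialect."""


@dataclass
class EntityMention:
    id: str
    char_spans: list[tuple[int, int]]  # inclusive end offsets
    etype: str
    surface: str
    extra: dict = field(default_factory=dict)

    def first_span(self) -> tuple[int, int]:
        return self.char_spans[0]


@dataclass
class DrugPair:
    id: str
    e1: str
    e2: str
    ddi: bool
    itype: str | None = None
    extra: dict = field(default_factory=dict)


@dataclass
class Sentence:
    id: str
    text: str
    entities: list[EntityMention] = field(default_factory=list)
    pairs: list[DrugPair] = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def entity_by_id(self, eid: str) -> EntityMention:
        for ent in self.entities:
            if ent.id == eid:
                return ent
        raise KeyError(eid)


@dataclass
class Document:
    id: str
    source_tag: str = ""
    sentences: list[Sentence] = field(default_factory=list)
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# validation


def validate_entity(ent: EntityMention, text: str) -> None:
    if not ent.char_spans:
        raise CorpusValidationError(f"entity {ent.id}: no character spans")
    prev_end = -1
    fragments = []
    for start, end in ent.char_spans:
        if not (0 <= start <= end < len(text)):
            raise CorpusValidationError(
                f"entity {ent.id}: span {start}-{end} outside sentence text "
                f"(length {len(text)})"
            )
        if start <= prev_end:
            raise CorpusValidationError(
                f"entity {ent.id}: spans unsorted or overlapping"
            )
        prev_end = end
        fragments.append(text[start : end + 1])
    joined = " ".join(fragments)
    if joined != ent.surface:
        raise CorpusValidationError(
            f"entity {ent.id}: surface {ent.surface!r} does not match "
            f"text fragments {joined!r}"
        )


def validate_sentence(sent: Sentence) -> None:
    seen: set[str] = set()
    for ent in sent.entities:
        if ent.id in seen:
            raise CorpusValidationError(
                f"sentence {sent.id}: duplicate entity id {ent.id}"
            )
        seen.add(ent.id)
        validate_entity(ent, sent.text)
    for pair in sent.pairs:
        if pair.e1 == pair.e2:
            raise CorpusValidationError(
                f"pair {pair.id}: e1 and e2 are the same entity id"
            )
        for eid in (pair.e1, pair.e2):
            if eid not in seen:
                raise CorpusValidationError(
                    f"pair {pair.id}: references missing entity {eid}"
                )
        if pair.ddi and pair.itype not in INTERACTION_TYPES:
            raise CorpusValidationError(
                f"pair {pair.id}: ddi=true requires an interaction type, "
                f"got {pair.itype!r}"
            )
        if not pair.ddi and pair.itype is not None:
            raise CorpusValidationError(
                f"pair {pair.id}: ddi=false must not carry a type"
            )


def validate_document(doc: Document) -> None:
    seen: set[str] = set()
    for sent in doc.sentences:
        if sent.id in seen:
            raise CorpusValidationError(
                f"document {doc.id}: duplicate sentence id {sent.id}"
            )
        seen.add(sent.id)
        validate_sentence(sent)


# ---------------------------------------------------------------------------
# reading


def _parse_char_offset(raw: str, entity_id: str) -> list[tuple[int, int]]:
    spans = []
    for part in raw.split(";"):
        try:
            s, e = part.split("-")
            spans.append((int(s), int(e)))
        except ValueError as exc:
            raise CorpusParseError(
                f"entity {entity_id}: bad charOffset {raw!r}"
            ) from exc
    return spans


_KNOWN_ENTITY_ATTRS = {"id", "charOffset", "type", "text"}
_KNOWN_PAIR_ATTRS = {"id", "e1", "e2", "ddi", "type"}


def _read_entity(el: ET.Element, text: str) -> EntityMention:
    eid = el.get("id", "")
    etype = el.get("type", "drug_n").lower()
    if etype not in ENTITY_TYPES:
        warnings.warn(
            f"entity {eid}: unknown type {etype!r}, mapping to drug_n",
            stacklevel=2,
        )
        etype = "drug_n"
    ent = EntityMention(
        id=eid,
        char_spans=_parse_char_offset(el.get("charOffset", ""), eid),
        etype=etype,
        surface=el.get("text", ""),
        extra={k: v for k, v in el.attrib.items() if k not in _KNOWN_ENTITY_ATTRS},
    )
    validate_entity(ent, text)
    return ent


def _read_pair(el: ET.Element) -> DrugPair:
    ddi = el.get("ddi", "false").lower() == "true"
    itype = el.get("type")
    return DrugPair(
        id=el.get("id", ""),
        e1=el.get("e1", ""),
        e2=el.get("e2", ""),
        ddi=ddi,
        itype=itype.lower() if (ddi and itype) else None,
        extra={k: v for k, v in el.attrib.items() if k not in _KNOWN_PAIR_ATTRS},
    )


def _read_document(el: ET.Element) -> Document:
    doc = Document(
        id=el.get("id", ""),
        source_tag=el.get("origin", ""),
        extra={k: v for k, v in el.attrib.items() if k not in {"id", "origin"}},
    )
    for sel in el.findall("sentence"):
        sent = Sentence(
            id=sel.get("id", ""),
            text=sel.get("text", ""),
            extra={k: v for k, v in sel.attrib.items() if k not in {"id", "text"}},
        )
        for cel in sel:
            if cel.tag == "entity":
                sent.entities.append(_read_entity(cel, sent.text))
            elif cel.tag == "pair":
                sent.pairs.append(_read_pair(cel))
        doc.sentences.append(sent)
    validate_document(doc)
    return doc


def read_ddi_xml(path: str | Path) -> list[Document]:
    """Parse a DDI-dialect XML file into a list of :class:`Document`.

    The root element may be a ``<corpus>`` wrapping several documents or a
    single bare ``<document>``.  All offsets and pair references are
    validated on the way in.
    """
    try:
        tree = ET.parse(str(path))
    except ET.ParseError as exc:
        raise CorpusParseError(f"{path}: malformed XML: {exc}") from exc
    root = tree.getroot()
    if root.tag == "document":
        return [_read_document(root)]
    if root.tag != "corpus":
        raise CorpusParseError(
            f"{path}: unexpected root element <{root.tag}>, "
            "expected <corpus> or <document>"
        )
    return [_read_document(el) for el in root.findall("document")]


# ---------------------------------------------------------------------------
# writing


def _offset_string(spans: list[tuple[int, int]]) -> str:
    return ";".join(f"{s}-{e}" for s, e in spans)


def docs_to_element(docs: list[Document]) -> ET.Element:
    root = ET.Element("corpus")
    for doc in docs:
        validate_document(doc)
        del_ = ET.SubElement(root, "document", id=doc.id, **doc.extra)
        if doc.source_tag:
            del_.set("origin", doc.source_tag)
        for sent in doc.sentences:
            sel = ET.SubElement(del_, "sentence", id=sent.id, **sent.extra)
            sel.set("text", sent.text)
            for ent in sent.entities:
                eel = ET.SubElement(sel, "entity", id=ent.id, **ent.extra)
                eel.set("charOffset", _offset_string(ent.char_spans))
                eel.set("type", ent.etype)
                eel.set("text", ent.surface)
            for pair in sent.pairs:
                pel = ET.SubElement(sel, "pair", id=pair.id, **pair.extra)
                pel.set("e1", pair.e1)
                pel.set("e2", pair.e2)
                pel.set("ddi", "true" if pair.ddi else "false")
                if pair.itype is not None:
                    pel.set("type", pair.itype)
    return root


def write_ddi_xml(docs: list[Document], path: str | Path) -> None:
    """Serialize documents to DDI-dialect XML (validates invariants first)."""
    root = docs_to_element(docs)  # raises before any file write
    ET.indent(root)
    ET.ElementTree(root).write(str(path), encoding="utf-8", xml_declaration=True)


def ddi_xml_bytes(docs: list[Document]) -> bytes:
    root = docs_to_element(docs)
    ET.indent(root)
    return ET.tostring(root, encoding="utf-8", xml_declaration=True)


# ---------------------------------------------------------------------------
# statistics


def corpus_stats(docs: list[Document]) -> pd.Series:
    """Per-class pair counts plus document/sentence totals.

    Negative pairs (``ddi="false"``) are counted under ``negative``; the
    per-class counts partition the total pair count.
    """
    counts = {c: 0 for c in CLASS_ORDER}
    n_sent = 0
    n_pairs = 0
    for doc in docs:
        for sent in doc.sentences:
            n_sent += 1
            for pair in sent.pairs:
                n_pairs += 1
                counts[pair.itype if pair.ddi else "negative"] += 1
    out = {"documents": len(docs), "sentences": n_sent, "pairs": n_pairs}
    out.update(counts)
    return pd.Series(out, name="count")
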