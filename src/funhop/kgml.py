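"""Parse, validate and write KEGG KGML pathway files.

KGML (KEGG Markup Language) encodes one pathway diagram as a ``<pathway>``
root holding ``<entry>`` elements (the boxes: genes, orthologs, compounds,
maps, groups), ``<relation>`` elements (edges) and ``<reaction>`` elements
(substrate/product wiring).  A gene-type entry's ``name`` attribute may list
several KEGG gene identifiers (``"hsa:218 hsa:220 ..."``) even though only
the first gene is displayed — that hidden multiplicity is what the rest of
this package makes explicit.

The model here is deliberately conservative: attribute values are kept as
the verbatim strings from the file (typed accessors parse on demand), and
relations/reactions are carried as opaque XML elements.  KEGG's dialect
evolves; round-trip safety beats strict validation.  Targeted at the KGML
v0.7.2 attribute set, but unknown attributes and elements survive a
parse→write→parse cycle untouched.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

from lxml import etree

logger = logging.getLogger(__name__)

GENE_LIKE_TYPES = frozenset({"gene", "ortholog"})
ENTRY_TYPES = frozenset(
    {"gene", "ortholog", "compound", "map", "group", "enzyme", "brite", "other"}
)


class KGMLError(Exception):
    """Base class for KGML handling errors."""


class KGMLParseError(KGMLError):
    """Malformed XML; the message names the offending line when known."""


class KGMLValidationError(KGMLError):
    """Structurally valid XML that violates a KGML invariant."""


class AliasTableError(KGMLError):
    """Malformed KEGG-id → symbol table."""


@dataclass
class Graphics:
    """Drawing instructions for one entry.

    ``label`` is KGML's ``name`` attribute (display string), ``shape`` its
    ``type`` attribute (rectangle, circle, roundrectangle, line).  ``x``/``y``
    are the node *center* on the pathway canvas, per KEGG convention; no
    coordinate transform is applied anywhere in this package.  ``extra``
    preserves attributes we do not interpret (fgcolor, bgcolor, ...).
    """

    label: str | None = None
    shape: str | None = None
    x: float | None = None
    y: float | None = None
    width: float | None = None
    height: float | None = None
    coords: str | None = None
    extra: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_element(cls, el: etree._Element) -> "Graphics":
        attrs = dict(el.attrib)
        def popf(key: str) -> float | None:
            raw = attrs.pop(key, None)
            return None if raw is None else float(raw)
        return cls(
            label=attrs.pop("name", None),
            shape=attrs.pop("type", None),
            x=popf("x"),
            y=popf("y"),
            width=popf("width"),
            height=popf("height"),
            coords=attrs.pop("coords", None),
            extra=attrs,
        )

    def to_element(self) -> etree._Element:
        el = etree.Element("graphics")
        if self.label is not None:
            el.set("name", self.label)
        for key in ("fgcolor", "bgcolor"):
            if key in self.extra:
                el.set(key, self.extra[key])
        if self.shape is not None:
            el.set("type", self.shape)
        for key, val in ((("x"), self.x), ("y", self.y),
                        ("width", self.width), ("height", self.height)):
            if val is not None:
                el.set(key, _fmt_num(val))
        if self.coords is not None:
            el.set("coords", self.coords)
        for key, val in self.extra.items():
            if key not in ("fgcolor", "bgcolor"):
                el.set(key, val)
        return el


def _fmt_num(v: float) -> str:
    """KGML writes integral coordinates without a decimal point."""
    return str(int(v)) if float(v).is_integer() else repr(float(v))


@dataclass
class Entry:
    """One KGML ``<entry>``: a box (or group of boxes) in the diagram."""

    id: str
    type: str
    name: str
    graphics: Graphics | None = None
    components: list[str] = field(default_factory=list)
    extra: dict[str, str] = field(default_factory=dict)
    extra_children: list[etree._Element] = field(default_factory=list)

    @property
    def name_tokens(self) -> list[str]:
        """KEGG identifiers in the name attribute, in document order."""
        return self.name.split()

    @property
    def is_gene_like(self) -> bool:
        return self.type in GENE_LIKE_TYPES

    @classmethod
    def from_element(cls, el: etree._Element, index: int) -> "Entry":
        attrs = dict(el.attrib)
        missing = [k for k in ("id", "type", "name") if k not in attrs]
        if missing:
            raise KGMLValidationError(
                f"entry #{index} (id={attrs.get('id', '?')}) lacks required "
                f"attribute(s): {', '.join(missing)}"
            )
        entry = cls(
            id=attrs.pop("id"),
            type=attrs.pop("type"),
            name=attrs.pop("name"),
            extra=attrs,
        )
        for child in el:
            if child.tag == "graphics" and entry.graphics is None:
                entry.graphics = Graphics.from_element(child)
            elif child.tag == "component":
                entry.components.append(child.get("id", ""))
            else:
                entry.extra_children.append(copy.deepcopy(child))
        return entry

    def to_element(self) -> etree._Element:
        el = etree.Element("entry")
        el.set("id", self.id)
        el.set("name", self.name)
        el.set("type", self.type)
        for key, val in self.extra.items():
            el.set(key, val)
        if self.graphics is not None:
            el.append(self.graphics.to_element())
        for cid in self.components:
            comp = etree.SubElement(el, "component")
            comp.set("id", cid)
        for child in self.extra_children:
            el.append(copy.deepcopy(child))
        return el


@dataclass
class Pathway:
    """In-memory KGML pathway, round-trippable to XML.

    ``relations`` and ``reactions`` are opaque lxml elements: the package
    never rewrites topology, it only checks that endpoints stay resolvable.
    """

    name: str
    title: str = ""
    attrs: dict[str, str] = field(default_factory=dict)
    entries: list[Entry] = field(default_factory=list)
    relations: list[etree._Element] = field(default_factory=list)
    reactions: list[etree._Element] = field(default_factory=list)

    def entry_ids(self) -> list[str]:
        return [e.id for e in self.entries]

    def get_entry(self, entry_id: str) -> Entry:
        for e in self.entries:
            if e.id == entry_id:
                return e
        raise KeyError(entry_id)

    def max_numeric_id(self) -> int:
        best = 0
        for e in self.entries:
            try:
                best = max(best, int(e.id))
            except ValueError:
                continue
        return best

    def validate(self) -> None:
        """Raise :class:`KGMLValidationError` on any invariant breach."""
        ids = self.entry_ids()
        seen: set[str] = set()
        for eid in ids:
            if eid in seen:
                raise KGMLValidationError(f"duplicate entry id {eid!r}")
            seen.add(eid)
        for e in self.entries:
            if e.type not in ENTRY_TYPES:
                raise KGMLValidationError(
                    f"entry {e.id}: unknown type {e.type!r}"
                )
            if e.is_gene_like and not e.name_tokens:
                raise KGMLValidationError(
                    f"entry {e.id}: {e.type} entry with empty name"
                )
            if e.type == "group" and not e.components:
                raise KGMLValidationError(
                    f"entry {e.id}: group entry with no components"
                )
            for cid in e.components:
                if cid not in seen:
                    raise KGMLValidationError(
                        f"entry {e.id}: component references unknown id {cid!r}"
                    )
            g = e.graphics
            if g is not None and g.shape != "line":
                for dim, val in (("width", g.width), ("height", g.height)):
                    if val is not None and val <= 0:
                        raise KGMLValidationError(
                            f"entry {e.id}: non-positive graphics {dim}"
                        )
        for rel in self.relations:
            for key in ("entry1", "entry2"):
                ref = rel.get(key)
                if ref is not None and ref not in seen:
                    raise KGMLValidationError(
                        f"relation references unknown entry id {ref!r}"
                    )
        for rxn in self.reactions:
            ref = rxn.get("id")
            if ref is not None and ref not in seen:
                raise KGMLValidationError(
                    f"reaction references unknown entry id {ref!r}"
                )


def parse_kgml(xml_text: str | bytes) -> Pathway:
    """Parse KGML text into a :class:`Pathway`, preserving document order.

    Raises :class:`KGMLParseError` for malformed XML (the message carries
    the line number lxml reports) and :class:`KGMLValidationError` when a
    required entry attribute (id, type, name) is missing.
    """
    if isinstance(xml_text, str):
        xml_text = xml_text.encode("utf-8")
    parser = etree.XMLParser(resolve_entities=False, load_dtd=False,
                             no_network=True)
    try:
        root = etree.fromstring(xml_text, parser=parser)
    except etree.XMLSyntaxError as exc:
        raise KGMLParseError(
            f"malformed KGML at line {exc.lineno}: {exc.msg}"
        ) from exc
    if root.tag != "pathway":
        raise KGMLParseError(
            f"root element is <{root.tag}>, expected <pathway>"
        )
    attrs = dict(root.attrib)
    pathway = Pathway(
        name=attrs.pop("name", ""),
        title=attrs.pop("title", ""),
        attrs=attrs,
    )
    for i, child in enumerate(root):
        if child.tag == "entry":
            pathway.entries.append(Entry.from_element(child, i))
        elif child.tag == "relation":
            pathway.relations.append(copy.deepcopy(child))
        elif child.tag == "reaction":
            pathway.reactions.append(copy.deepcopy(child))
        # comments/processing instructions in the body are dropped
    return pathway


def write_kgml(pathway: Pathway) -> str:
    """Serialize a :class:`Pathway` back to KGML text.

    Validates invariants first; the output parses back to a pathway
    isomorphic to the input.  Entry, relation and reaction order is
    preserved exactly.
    """
    pathway.validate()
    root = etree.Element("pathway")
    if pathway.name:
        root.set("name", pathway.name)
    for key, val in pathway.attrs.items():
        root.set(key, val)
    if pathway.title:
        root.set("title", pathway.title)
    for entry in pathway.entries:
        root.append(entry.to_element())
    for rel in pathway.relations:
        root.append(copy.deepcopy(rel))
    for rxn in pathway.reactions:
        root.append(copy.deepcopy(rxn))
    body = etree.tostring(root, pretty_print=True, encoding="unicode")
    return '<?xml version="1.0"?>\n' + body


def read_kgml(path) -> Pathway:
    with open(path, "rb") as fh:
        return parse_kgml(fh.read())


def detect_line_entries(pathway: Pathway) -> list[str]:
    """Identifiers of entries drawn as polylines (glycan-style pathways).

    KEGG's glycan pathways draw transitions as lines rather than boxes;
    such entries cannot be expanded or colored, so callers use this to
    reject whole pathways up front.
    """
    return [
        e.id for e in pathway.entries
        if e.graphics is not None and e.graphics.shape == "line"
    ]


class AliasMap:
    """KEGG gene identifier → gene symbol lookup with a graceful fallback.

    KGML files carry KEGG ids but not gene names, so display labels come
    from this table.  Ids absent from the table resolve to the raw id
    itself, with one warning per distinct id — analysis never halts on a
    mapping gap.
    """

    def __init__(self, mapping: dict[str, str] | None = None):
        for key, sym in (mapping or {}).items():
            if not sym:
                raise AliasTableError(f"empty symbol for key {key!r}")
        self.mapping: dict[str, str] = dict(mapping or {})
        self._warned: set[str] = set()

    def lookup(self, kegg_id: str) -> str:
        try:
            return self.mapping[kegg_id]
        except KeyError:
            if kegg_id not in self._warned:
                logger.warning(
                    "no gene symbol for %s; using the raw identifier", kegg_id
                )
                self._warned.add(kegg_id)
            return kegg_id

    def __contains__(self, kegg_id: str) -> bool:
        return kegg_id in self.mapping

    def __len__(self) -> int:
        return len(self.mapping)


def load_alias_table(tsv_path) -> AliasMap:
    """Load a 2-column (kegg_id, symbol) TSV into an :class:`AliasMap`.

    A header row is auto-detected (second column equal to "symbol",
    case-insensitively, or a first row that looks like column names).
    Duplicate keys: last occurrence wins, with a logged warning.
    """
    mapping: dict[str, str] = {}
    with open(tsv_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise AliasTableError(
                    f"{tsv_path}: line {lineno}: expected 2 tab-separated "
                    f"columns, found {len(cols)}"
                )
            key, sym = cols[0].strip(), cols[1].strip()
            if lineno == 1 and sym.lower() in ("symbol", "gene_symbol", "name"):
                continue  # header
            if key in mapping:
                logger.warning(
                    "%s: duplicate key %s at line %d; keeping the later row",
                    tsv_path, key, lineno,
                )
            if not sym:
                raise AliasTableError(
                    f"{tsv_path}: line {lineno}: empty symbol for {key!r}"
                )
            mapping[key] = sym
    return AliasMap(mapping)
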