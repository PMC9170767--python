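"""Expand multi-gene KGML entries into explicit groups of per-gene children.

A KEGG enzyme box whose ``name`` attribute lists several genes represents a
set of functional homologs — alternative enzymes for the same transition,
an "OR group" — yet only the first gene is displayed.  Expansion makes the
hidden genes explicit: each multi-gene entry becomes a KGML ``group`` whose
components are one gene child per identifier, encoded exactly like KEGG's
native protein complexes ("AND groups") so any KGML reader can load the
result.  The group keeps the original entry id, so relations and reactions
need no rewriting and the topology is untouched.

OR groups are visually distinguished from complexes by enlarging the group
box width by a fixed margin on each side, giving the node a white border.
All children share the original entry's coordinates; no re-layout is
attempted (viewers handle that).  Expansion provenance is recorded in a
``funhop`` attribute on the created group, which makes OR/AND
classification and idempotence decidable even after an XML round trip.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Callable, Iterator

from .kgml import AliasMap, Entry, KGMLError, Pathway, detect_line_entries

#: extra width added on each side of an expanded group box, in pixels
DEFAULT_MARGIN_PX = 10.0

#: provenance marker carried on groups created by expansion
PROVENANCE_ATTR = "funhop"
PROVENANCE_VALUE = "or-group"

COMPLEX_AND = "complex_and"
HOMOLOG_OR = "homolog_or"


class ExpansionError(KGMLError):
    """Pathway or entry cannot be expanded."""


class LineNodeError(ExpansionError):
    """The pathway contains polyline entries and cannot be analyzed."""


@dataclass
class ExpansionResult:
    """Outcome of :func:`expand_pathway`.

    ``gene_children`` maps each expanded original entry id to its ordered
    ``(child id, KEGG id, symbol)`` triples, first-displayed gene first.
    """

    pathway: Pathway
    expanded_entry_ids: list[str] = field(default_factory=list)
    gene_children: dict[str, list[tuple[str, str, str]]] = field(
        default_factory=dict
    )


def _id_allocator(pathway: Pathway) -> Iterator[str]:
    next_id = pathway.max_numeric_id() + 1
    while True:
        yield str(next_id)
        next_id += 1


def expand_entry(
    entry: Entry,
    aliases: AliasMap,
    id_allocator: Callable[[], str] | Iterator[str],
    margin_px: float = DEFAULT_MARGIN_PX,
) -> tuple[Entry, list[Entry]]:
    """Expand one multi-gene entry into a group plus per-gene children.

    The group inherits the original id and graphics, widened by
    ``margin_px`` on each side.  Children are created in name-token order
    (the first child carries the gene KEGG displays by default), inherit
    the original coordinates and box size, and are labelled with the alias
    symbol for their KEGG id.

    Raises :class:`ExpansionError` for entries with fewer than two name
    tokens — callers must not expand single-gene entries.
    """
    if not entry.is_gene_like:
        raise ExpansionError(
            f"entry {entry.id}: cannot expand type {entry.type!r}"
        )
    tokens = entry.name_tokens
    if not tokens:
        raise ExpansionError(f"entry {entry.id}: empty name attribute")
    if len(tokens) < 2:
        raise ExpansionError(
            f"entry {entry.id}: single-gene entry needs no expansion"
        )
    fresh = (id_allocator if hasattr(id_allocator, "__next__")
             else iter(id_allocator, None))

    children: list[Entry] = []
    for token in tokens:
        child = Entry(
            id=next(fresh),
            type=entry.type,
            name=token,
            graphics=copy.deepcopy(entry.graphics),
            extra=dict(entry.extra),
        )
        if child.graphics is not None:
            child.graphics.label = aliases.lookup(token)
        children.append(child)

    group = Entry(
        id=entry.id,
        type="group",
        name="undefined",
        graphics=copy.deepcopy(entry.graphics),
        components=[c.id for c in children],
        extra={**entry.extra, PROVENANCE_ATTR: PROVENANCE_VALUE},
    )
    if group.graphics is not None and group.graphics.width is not None:
        group.graphics.width = group.graphics.width + 2 * margin_px
    return group, children


def expand_pathway(
    pathway: Pathway,
    aliases: AliasMap,
    margin_px: float = DEFAULT_MARGIN_PX,
) -> ExpansionResult:
    """Expand every multi-gene (or multi-ortholog) entry of a pathway.

    Single-gene entries and pre-existing KEGG groups (protein complexes)
    pass through untouched; a multi-gene member *inside* a complex is
    expanded in place, the resulting OR group staying a component of the
    complex because it keeps the member's id.  The input pathway is not
    mutated.

    Raises :class:`LineNodeError` when the pathway contains polyline
    entries (glycan-style diagrams), which are not suitable for this kind
    of pathway analysis.
    """
    lines = detect_line_entries(pathway)
    if lines:
        raise LineNodeError(
            f"pathway {pathway.name or '<unnamed>'} contains "
            f"{len(lines)} 'line' node(s) (entries {', '.join(lines)}) and "
            "is not suitable for pathway analysis"
        )
    out = copy.deepcopy(pathway)
    fresh = _id_allocator(out)
    result = ExpansionResult(pathway=out)

    new_entries: list[Entry] = []
    for entry in out.entries:
        if entry.is_gene_like and len(entry.name_tokens) >= 2:
            group, children = expand_entry(entry, aliases, fresh, margin_px)
            new_entries.append(group)
            new_entries.extend(children)
            result.expanded_entry_ids.append(entry.id)
            result.gene_children[entry.id] = [
                (c.id, c.name, aliases.lookup(c.name)) for c in children
            ]
        else:
            new_entries.append(entry)
    out.entries = new_entries
    out.validate()
    return result


def classify_group(entry: Entry) -> str:
    """Classify a group entry as ``complex_and`` or ``homolog_or``.

    Groups created by :func:`expand_entry` carry a provenance attribute and
    are OR groups (functional homologs); any other group came from the
    source KGML and is treated as a protein complex (AND group).
    """
    if entry.type != "group":
        raise ExpansionError(
            f"entry {entry.id}: classify_group requires a group entry, "
            f"got type {entry.type!r}"
        )
    if entry.extra.get(PROVENANCE_ATTR) == PROVENANCE_VALUE:
        return HOMOLOG_OR
    return COMPLEX_AND
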