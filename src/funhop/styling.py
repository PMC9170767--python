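"""Continuous color scales and Cytoscape-importable attribute/style exports.

Two gradients drive the visualization:

* **Differential expression** — signed log-p values on a fixed scale from
  -1200 (black) through -600 (purple), -300 (bright red), 0 (light
  yellow) and 300 (bright green) up to 600 (dark green).  Negative is
  down-regulated, positive up-regulated; values beyond the ends clamp.
* **Read counts** — average counts from 0 (white) to saturation at
  >= 50,000 (dark blue), via pink and blue intermediates.

The scale anchor *positions* above are fixed display conventions; the RGB
bindings for the color *names* (purple = #800080, light yellow = #FFFFE0,
...) are this package's conventions and are configurable per
:class:`StyleSpec`.

Exports: a node attribute TSV loadable as a Cytoscape node table, and a
Cytoscape 3 style XML with a continuous fill-color mapping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from lxml import etree

from .diffexp import DERecord
from .expression import NodeExpression

RGB = tuple[int, int, int]

# named-color bindings (conventions, configurable)
BLACK: RGB = (0, 0, 0)
PURPLE: RGB = (128, 0, 128)
BRIGHT_RED: RGB = (255, 0, 0)
LIGHT_YELLOW: RGB = (255, 255, 224)
BRIGHT_GREEN: RGB = (0, 255, 0)
DARK_GREEN: RGB = (0, 100, 0)
WHITE: RGB = (255, 255, 255)
PINK: RGB = (255, 192, 203)
CORNFLOWER_BLUE: RGB = (100, 149, 237)
DARK_BLUE: RGB = (0, 0, 139)

#: read counts at or above this saturate to the darkest blue
READCOUNT_SATURATION = 50_000.0


class StyleError(Exception):
    """Invalid style specification or export input."""


@dataclass(frozen=True)
class StyleSpec:
    """A continuous color mapping: value anchors with RGB stops.

    Colors between anchors interpolate linearly per channel; outside the
    anchor span values clamp to the end colors when ``clamp`` is true and
    are rejected otherwise.
    """

    anchors: tuple[tuple[float, RGB], ...]
    clamp: bool = True

    def __post_init__(self):
        if len(self.anchors) < 2:
            raise StyleError("a style needs at least 2 anchors")
        values = [v for v, _ in self.anchors]
        if any(b <= a for a, b in zip(values, values[1:])):
            raise StyleError(f"anchor values not strictly increasing: {values}")
        for _, color in self.anchors:
            if len(color) != 3 or any(not 0 <= c <= 255 for c in color):
                raise StyleError(f"invalid RGB triplet {color!r}")

    @property
    def domain(self) -> tuple[float, float]:
        return self.anchors[0][0], self.anchors[-1][0]


def default_de_style() -> StyleSpec:
    """The fixed six-stop differential-expression gradient."""
    return StyleSpec(anchors=(
        (-1200.0, BLACK),
        (-600.0, PURPLE),
        (-300.0, BRIGHT_RED),
        (0.0, LIGHT_YELLOW),
        (300.0, BRIGHT_GREEN),
        (600.0, DARK_GREEN),
    ))


def default_readcount_style() -> StyleSpec:
    """White → pink → blue → dark blue over 0 … ≥50,000 average reads."""
    return StyleSpec(anchors=(
        (0.0, WHITE),
        (5_000.0, PINK),
        (25_000.0, CORNFLOWER_BLUE),
        (READCOUNT_SATURATION, DARK_BLUE),
    ))


def map_color(spec: StyleSpec, value: float) -> RGB:
    """Piecewise-linear interpolation of ``value`` onto the spec's colors.

    Values exactly at an anchor return that anchor's color bit-exactly.
    """
    if not math.isfinite(value):
        raise StyleError(f"cannot map non-finite value {value!r}")
    lo, hi = spec.domain
    if value <= lo or value >= hi:
        if value == lo:
            return spec.anchors[0][1]
        if value == hi:
            return spec.anchors[-1][1]
        if not spec.clamp:
            raise StyleError(
                f"value {value} outside the non-clamping domain [{lo}, {hi}]"
            )
        return spec.anchors[0][1] if value < lo else spec.anchors[-1][1]
    for (v0, c0), (v1, c1) in zip(spec.anchors, spec.anchors[1:]):
        if v0 <= value <= v1:
            if value == v0:
                return c0
            if value == v1:
                return c1
            t = (value - v0) / (v1 - v0)
            return tuple(
                int(round(a + t * (b - a))) for a, b in zip(c0, c1)
            )
    raise AssertionError("unreachable: anchors cover the domain")


def rgb_to_hex(color: RGB) -> str:
    return "#{:02X}{:02X}{:02X}".format(*color)


def hex_to_rgb(text: str) -> RGB:
    text = text.lstrip("#")
    return tuple(int(text[i:i + 2], 16) for i in (0, 2, 4))


def export_attributes(
    node_exprs: list[NodeExpression],
    de_records: list[DERecord],
    path,
    de_style: StyleSpec | None = None,
    count_style: StyleSpec | None = None,
) -> None:
    """Write the joined node table as a Cytoscape-loadable TSV.

    Joins node expression with DE records on the aggregated node name; the
    join must be total in both directions, otherwise the unmatched names
    are listed in the error.  Columns: agg_name, members, n_genes,
    total_count, value, significant, hexcolor_de, hexcolor_count.
    """
    de_style = de_style or default_de_style()
    count_style = count_style or default_readcount_style()
    by_name = {r.target: r for r in de_records}
    expr_names = [e.node.agg_name for e in node_exprs]
    missing_de = sorted(set(expr_names) - set(by_name))
    missing_expr = sorted(set(by_name) - set(expr_names))
    if missing_de or missing_expr:
        raise StyleError(
            "attribute join is not total; nodes without DE record: "
            f"{missing_de}; DE records without node: {missing_expr}"
        )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("agg_name\tmembers\tn_genes\ttotal_count\tvalue\t"
                 "significant\thexcolor_de\thexcolor_count\n")
        for expr in node_exprs:
            rec = by_name[expr.node.agg_name]
            fh.write("\t".join([
                expr.node.agg_name,
                ",".join(expr.node.members),
                str(len(expr.node.members)),
                repr(expr.total),
                repr(rec.value),
                str(rec.significant),
                rgb_to_hex(map_color(de_style, rec.value)),
                rgb_to_hex(map_color(count_style, expr.total)),
            ]) + "\n")


def export_style(spec: StyleSpec, attribute_name: str, path,
                 style_name: str | None = None) -> None:
    """Write a Cytoscape 3 style XML with a continuous fill-color mapping.

    The document defines one visual style whose NODE_FILL_COLOR is a
    continuous mapping from ``attribute_name`` with one mapping point per
    anchor.
    """
    if not attribute_name:
        raise StyleError("attribute name must be non-empty")
    vizmap = etree.Element("vizmap", documentVersion="3.0")
    style = etree.SubElement(
        vizmap, "visualStyle",
        name=style_name or f"funhop-{attribute_name}",
    )
    etree.SubElement(style, "network")
    node = etree.SubElement(style, "node")
    prop = etree.SubElement(
        node, "visualProperty", name="NODE_FILL_COLOR",
        default=rgb_to_hex(spec.anchors[0][1]),
    )
    mapping = etree.SubElement(
        prop, "continuousMapping",
        attributeName=attribute_name, attributeType="float",
    )
    for value, color in spec.anchors:
        hexcolor = rgb_to_hex(color)
        etree.SubElement(
            mapping, "continuousMappingPoint",
            attrValue=repr(float(value)),
            equalValue=hexcolor, lesserValue=hexcolor, greaterValue=hexcolor,
        )
    etree.SubElement(style, "edge")
    with open(path, "wb") as fh:
        fh.write(etree.tostring(vizmap, pretty_print=True,
                                xml_declaration=True, encoding="UTF-8"))


def read_style(path) -> tuple[StyleSpec, str]:
    """Parse back a style document written by :func:`export_style`.

    Returns the reconstructed spec and the attribute name; used to verify
    export round trips.
    """
    tree = etree.parse(str(path))
    mapping = tree.find(".//continuousMapping")
    if mapping is None:
        raise StyleError(f"{path}: no continuous mapping found")
    anchors = tuple(
        (float(pt.get("attrValue")), hex_to_rgb(pt.get("equalValue")))
        for pt in mapping.findall("continuousMappingPoint")
    )
    return StyleSpec(anchors=anchors), mapping.get("attributeName")
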