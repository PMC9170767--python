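import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import funhop as fh

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

# a hand-written KGML fixture exercising unknown attributes, a protein
# complex, a compound, relations and reactions
HISTIDINE_STYLE_KGML = """<?xml version="1.0"?>
<pathway name="path:hsa00340" org="hsa" number="00340"
         title="Histidine metabolism"
         image="https://example.invalid/hsa00340.png"
         link="https://example.invalid/hsa00340">
  <entry id="1" name="hsa:218 hsa:220 hsa:221 hsa:222" type="gene"
         reaction="rn:R02909" link="https://example.invalid/e1">
    <graphics name="ALDH3A1..." fgcolor="#000000" bgcolor="#BFFFBF"
              type="rectangle" x="170" y="300" width="46" height="17"/>
  </entry>
  <entry id="2" name="hsa:3067" type="gene" reaction="rn:R01167">
    <graphics name="HDC" fgcolor="#000000" bgcolor="#BFFFBF"
              type="rectangle" x="330" y="300" width="46" height="17"/>
  </entry>
  <entry id="3" name="hsa:84735 hsa:2356" type="gene" reaction="rn:R01168">
    <graphics name="CNDP1..." fgcolor="#000000" bgcolor="#BFFFBF"
              type="rectangle" x="490" y="300" width="46" height="17"/>
  </entry>
  <entry id="4" name="hsa:1644 hsa:2571" type="gene" reaction="rn:R01169">
    <graphics name="DDC..." fgcolor="#000000" bgcolor="#BFFFBF"
              type="rectangle" x="650" y="300" width="46" height="17"/>
  </entry>
  <entry id="5" name="cpd:C00135" type="compound">
    <graphics name="C00135" fgcolor="#000000" bgcolor="#FFFFFF"
              type="circle" x="250" y="300" width="8" height="8"/>
  </entry>
  <entry id="6" name="undefined" type="group">
    <graphics fgcolor="#000000" bgcolor="#FFFFFF" type="rectangle"
              x="410" y="420" width="92" height="17"/>
    <component id="2"/>
    <component id="3"/>
  </entry>
  <relation entry1="1" entry2="2" type="ECrel">
    <subtype name="compound" value="5"/>
  </relation>
  <relation entry1="2" entry2="3" type="ECrel"/>
  <reaction id="1" name="rn:R02909" type="irreversible">
    <substrate id="5" name="cpd:C00135"/>
    <product id="5" name="cpd:C00135"/>
  </reaction>
</pathway>
"""

ALIAS_ROWS = {
    "hsa:218": "ALDH3A1",
    "hsa:220": "ALDH1A3",
    "hsa:221": "ALDH3B1",
    "hsa:222": "ALDH3B2",
    "hsa:3067": "HDC",
    "hsa:84735": "CNDP1",
    "hsa:2356": "CNDP2",
    "hsa:1644": "DDC",
    "hsa:2571": "GAD1",
}


@pytest.fixture
def histidine_pathway():
    return fh.parse_kgml(HISTIDINE_STYLE_KGML)


@pytest.fixture
def aliases():
    return fh.AliasMap(dict(ALIAS_ROWS))


@pytest.fixture
def alias_tsv(tmp_path):
    path = tmp_path / "alias.tsv"
    lines = ["kegg_id\tsymbol"]
    lines += [f"{k}\t{v}" for k, v in ALIAS_ROWS.items()]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


@pytest.fixture
def small_cm():
    """4 genes x 6 samples, integer counts, balanced groups."""
    genes = ["ALDH3A1", "ALDH1A3", "ALDH3B1", "HDC"]
    samples = [f"s{i}" for i in range(6)]
    rng = np.random.default_rng(42)
    counts = pd.DataFrame(
        rng.integers(0, 500, size=(4, 6)).astype(float),
        index=genes, columns=samples,
    )
    groups = pd.Series(["case"] * 3 + ["control"] * 3, index=samples)
    return fh.CountMatrix(counts=counts, groups=groups)


def graphics_equal(a, b):
    if (a is None) != (b is None):
        return False
    if a is None:
        return True
    return (
        a.label == b.label and a.shape == b.shape and a.coords == b.coords
        and all(
            (x is None and y is None) or
            (x is not None and y is not None and float(x) == float(y))
            for x, y in [(a.x, b.x), (a.y, b.y),
                         (a.width, b.width), (a.height, b.height)]
        )
        and a.extra == b.extra
    )


def assert_isomorphic(p1, p2):
    """Structural equality of two pathways, numeric-aware for coordinates."""
    assert p1.name == p2.name
    assert p1.title == p2.title
    assert p1.attrs == p2.attrs
    assert len(p1.entries) == len(p2.entries)
    for e1, e2 in zip(p1.entries, p2.entries):
        assert (e1.id, e1.type, e1.name) == (e2.id, e2.type, e2.name)
        assert e1.components == e2.components
        assert e1.extra == e2.extra
        assert graphics_equal(e1.graphics, e2.graphics)
    def canonical(el):
        text = (el.text or "").strip()
        return (el.tag, dict(el.attrib), text,
                [canonical(c) for c in el])

    for attr in ("relations", "reactions"):
        s1 = [canonical(el) for el in getattr(p1, attr)]
        s2 = [canonical(el) for el in getattr(p2, attr)]
        assert s1 == s2
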