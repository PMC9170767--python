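# funhop

Analysis of **functional-homolog nodes** in KEGG metabolic pathways.

A KEGG pathway diagram draws one box per enzymatic transition, but that box
often stands for several genes: functionally homologous enzymes that can
all catalyze the same reaction (an "OR group", as opposed to the subunits
of a protein complex, an "AND group"). The KGML XML lists every member in
the box's `name` attribute — yet only the first gene is displayed, so
differential-expression overlays silently ignore the hidden members. A
classic example: the aldehyde-dehydrogenase box in histidine metabolism
shows *ALDH3A1* but carries four paralogs; a phospholipase box in
glycerophospholipid metabolism shows *PLA2G4B* but carries 21 genes, and
the actually dominant transcript (*PLA2G2A*) is among the hidden ones.

`funhop` makes the hidden genes explicit and quantifies them:

1. **Expand** — every multi-gene KGML entry becomes a KGML `group` with
   one gene child per member (encoded like KEGG's native protein-complex
   groups, so any KGML reader loads the result). The group keeps the
   original entry id, leaving relations/reactions untouched; its box is
   widened by a margin so OR groups are visually distinct from complexes.
2. **Aggregate** — RNA-seq read counts are length-adjusted
   (divide by `len_g / mean(len)`), averaged as
   `(mean_case + mean_control) / 2`, and summed over each node's members.
   Nodes are renamed `gene1-Bx` (first member + member count; `x = 1` for
   single-gene nodes). Each member's **contribution ratio**
   `count_g / total` identifies the node's *dominant* gene.
3. **Score** — per gene or node, differential expression is displayed as

   ```
   value = log2(P) × (−10) × regulation
   ```

   with regulation +1 (up) / −1 (down) from the fold-change sign, and
   value 0 for targets not significant at p < 0.05 (strict). External
   DE tables (e.g. voom/limma) are imported; a built-in Welch test on
   log2 CPM is included as a simple reference.
4. **Style** — node attribute TSVs and Cytoscape 3 style XMLs with the
   fixed continuous gradients: signed log-p from −1200 (black) via −600
   (purple), −300 (bright red), 0 (light yellow), 300 (bright green) to
   600 (dark green); read counts from 0 (white) to saturation at
   ≥ 50,000 (dark blue).

Pathways drawn with polyline ("line") entries — KEGG's glycan diagrams —
cannot be expanded or colored and are detected and refused.

A synthetic-data module generates toy KGML pathways and two-group
negative-binomial count matrices with planted dominant genes and planted
node-level effects, so the full pipeline is testable without any KEGG or
cohort downloads.

## Worked example

```python
import funhop as fh

# the 21-gene phospholipase node, displayed as PLA2G4B
pathway, aliases = fh.pla2_fixture()
(node,) = fh.node_membership(pathway, aliases)
print(node.agg_name, len(node.members))

# average read counts: PLA2G2A towers over the runner-up PLA2G12A,
# and the displayed gene PLA2G4B is absent from the dataset
avg = {m: 10.0 for m in node.members if m != "PLA2G4B"}
avg.update(PLA2G2A=71_482.0, PLA2G12A=4_502.0)
expr = fh.node_expression(node, avg)
print(expr.dominant, round(expr.ratios["PLA2G2A"], 3), expr.missing)

value = fh.signed_log_p(0.01, +1)
print(round(value, 4), fh.rgb_to_hex(fh.map_color(fh.default_de_style(), value)))
```

prints

```
PLA2G4B-B21 21
PLA2G2A 0.939 ['PLA2G4B']
66.4386 #C7FFAE
```

— the node is named `PLA2G4B-B21` (first gene + 21 members); `PLA2G2A`
carries 93.9% of the node's reads and is dominant, so the node's overall
direction follows it even though the displayed gene contributes nothing;
a significant up-regulated p = 0.01 maps to +66.4 on the signed log-p
scale, a pale green between the light-yellow (0) and bright-green (300)
anchors.

The same workflow is available from the shell:

```sh
funhop simulate --n-nodes 10 --seed 1 --out-dir demo
funhop expand    --kgml demo/pathway.kgml --alias demo/alias.tsv --out demo/expanded.kgml
funhop aggregate --kgml demo/pathway.kgml --alias demo/alias.tsv \
                 --counts demo/counts.tsv --groups demo/groups.tsv \
                 --lengths demo/lengths.tsv --out-dir demo/agg
funhop style     --kgml demo/pathway.kgml --alias demo/alias.tsv \
                 --counts demo/counts.tsv --groups demo/groups.tsv --out-dir demo/styled
```

Exit codes: 0 success, 1 input error, 2 unsupported (line-node) pathway.

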