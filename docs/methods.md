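# Methods

## The model

A KEGG metabolic pathway represents each enzymatic transition by one node.
When a node lists several genes, those genes are functional homologs: any
of them can catalyze the transition, so the node behaves as an OR over its
members, in contrast to protein complexes whose subunits are all required
(AND). The package's working assumptions are:

* the genes KEGG places in one node catalyze the node's reaction at
  comparable rates, so a gene's contribution to node activity is
  proportional to its expression level;
* RNA-seq read counts are a usable proxy for relative expression within a
  cohort, at least for differences spanning orders of magnitude;
* transcript changes are informative about protein-level changes.

Under these assumptions a node's total activity is summarized by the sum
of its members' read counts, its direction of change by
differential-expression analysis of that sum, and its internal structure
by each member's **contribution ratio** (member count / node total). The
member with the highest ratio is the node's **dominant gene**; when one
gene dominates strongly, the node's overall behavior is essentially that
gene's. Ratios above 0.9 or below 0.1 are treated as the robust classes
when comparing cohorts; intermediate ratios are expected to vary more
between datasets.

## Pipeline and key choices

**KGML handling.** The parser targets the KGML v0.7.2 attribute set but
stores attribute values verbatim and carries relations/reactions as opaque
XML, so unknown or future attributes survive a parse→write→parse cycle
unchanged. Entry order, relation order and reaction order are preserved
exactly. Gene identifiers keep their organism prefix (`hsa:...`); no
organism inference is done. KGML `x`/`y` are node centers (KEGG canvas
convention) and are never transformed. Pathways containing polyline
("line") entries — KEGG's glycan diagrams — are refused for expansion and
analysis, since lines can be neither expanded nor filled with color.

**Expansion.** Each multi-gene `gene` or `ortholog` entry becomes a
`group` entry whose components are per-gene children, one per name token,
token order preserved, the first child carrying the gene KEGG displays by
default. `ortholog` entries are expanded by the same rule because KEGG
uses both types for enzyme boxes. The group keeps the original entry id —
this is what makes topology preservation free: relations, reactions and
enclosing complex-group component lists keep referencing the same id, so
a multi-gene member of a protein complex is expanded "in place". Children
get fresh ids above the pathway's numeric maximum. All children inherit
the original coordinates and box size; overlapping children are left to
the viewer to lay out. The group box is widened by a configurable margin
(default 10 px per side, `--margin-px`) to give OR groups a visible white
border distinguishing them from AND complexes; the exact margin is a
package convention, not a published value. The created group carries a
`funhop="or-group"` attribute so OR/AND classification (by provenance)
and idempotence remain decidable after an XML round trip.

**Alias resolution.** KGML files contain KEGG ids but no gene symbols;
a two-column TSV maps ids to symbols. Unmapped ids fall back to the raw
id with one warning per id — a mapping gap must not halt an analysis.
Duplicate keys: last row wins, with a warning.

**Length adjustment.** Counts are divided by the factor
`length_g / mean(length over genes in the matrix)` (gene length = sum of
exon lengths). Division — shrinking long genes — is the only direction
consistent with length normalization; the mean factor is exactly 1, so
the grand total is preserved when lengths are equal. Genes without a
length entry keep raw counts and are flagged. No further normalization
(TPM/FPKM/CPM) is claimed, and genes are assumed to be represented by
their canonical isoform. Adjustment happens before group averaging.
Because length factors reshuffle relative magnitudes, dominance is
normally assessed on the read-count scale; the ratio export provides both
adjusted and raw average-count columns.

**Averaging and aggregation.** The per-gene summary is the unweighted
mean of the two group means, `(mean_case + mean_control)/2`, which keeps
unequal cohort arms from biasing the average. Node totals are plain sums
over members; members absent from the count matrix contribute zero and
are flagged (mirroring the real situation where a node's displayed gene
is absent from a dataset entirely). Node names follow `gene1-Bx` (first
member symbol, `-B`, member count; `x = 1` for single-gene nodes). Since
distinct nodes can share a first gene and member count, later collisions
get an `.k` ordinal (`G1-B2`, `G1-B2.2`, ...) so names remain unique join
keys for DE tables.

**Signed log-p.** `value = log2(p) × (−10) × regulation`, regulation +1
for positive, −1 for negative fold change. Significance is strict
(`p < alpha`, default 0.05); non-significant targets get value 0. Exact
anchor cases: p = 1 → 0, p = 0.25 → ±20. P-values are floored at 1e−300
before the transform to avoid infinities; values are *not* clamped to the
display range — clamping happens only in the color mapping, whose domain
ends at −1200/600 anyway. No multiple-testing correction is applied by
default, matching the strict-raw-p convention of the workflow; an
optional Benjamini–Hochberg variant (`bh_adjust`) is provided without
changing the default.

**Built-in two-group test.** Welch's unequal-variance t-test on
log2(CPM + 1), with CPM computed against each sample's total of the input
matrix. This is the simplest defensible reference for synthetic data and
smoke tests; it is *not* equivalent to a moderated model such as
voom/limma (no precision weights, no empirical-Bayes shrinkage), and the
importer is the supported route for such results. One caveat the test
suite makes explicit: CPM normalization is compositional, so in very
small pathways a single strongly shifted high-abundance node distorts the
library size and can mask other effects; recovery guarantees are stated
at the 100-node scale where this cancels out. Rows with identical group
means get regulation +1 and p = 1 (never significant).

**Color scales.** Differential expression: anchors at −1200 (black),
−600 (purple), −300 (bright red), 0 (light yellow), 300 (bright green),
600 (dark green), clamped outside. Read counts: 0 (white) to saturation
at ≥ 50,000 (dark blue). The anchor *positions* of the DE scale and the
two read-count endpoints are fixed display conventions of the method; the
RGB values bound to the color *names* (purple = #800080, light yellow =
#FFFFE0, ...) and the positions/colors of the intermediate read-count
stops (pink #FFC0CB at 5,000; #6495ED at 25,000) are this package's
choices and are configurable (`--style-config`). Interpolation is
piecewise-linear per RGB channel; values exactly at an anchor return the
anchor color bit-exactly. Style documents are Cytoscape 3 vizmap XML,
chosen because the target workflow is Cytoscape with a KGML importer.

## The synthetic generator

`simulate_pathway` builds linear pathways: compound — enzyme — compound —
... with reactions and ECrel relations, each enzyme node carrying 1..k
gene ids uniformly (k up to 30, matching the range observed in real
enzyme nodes). `simulate_counts` draws per-gene baseline means log-uniform
over [1, 1e5] (matching the orders-of-magnitude spread of real average
read counts), then raises each node's planted dominant gene to at least
10× the next-highest member mean *and* at least 4× the sum of the other
members, so the designed contribution ratio is ≥ 0.8 and the ten-fold
dominant/runner-up margin seen in real data is reproduced. Node effects
multiply the dominant gene's case-group means by 4 (up) or 1/4 (down) —
placing the effect on the dominant gene only, so node-level recovery
specifically validates the aggregation rationale. Counts are negative
binomial with variance μ + φμ² (default φ = 0.1, a typical bulk RNA-seq
dispersion), sampled as a Gamma–Poisson mixture; gene lengths are
log-normal around 2.5 kb (σ = 0.6). Everything is deterministic per seed;
`noise_seed` resamples counts while pinning the design, which is how two
pseudo-cohorts of the same population are generated for concordance
checks. Not emulated: library-size variation between samples, gene-gene
correlation, batch effects — so passing recovery tests demonstrates the
pipeline's correctness on its own model, not robustness to those real-data
features.

Problem sizes used in the test suite and the acceptance script —
dominance: 100 seeds × 20-node pathways (n = 20 + 20); direction: one
100-node pathway, 4-fold effects, n = 20 + 20, φ = 0.1; null calibration:
50 seeds × 100 null nodes — keep every run in seconds while leaving the
statistical conclusions at the stated scale.

## Numerical details and degenerate inputs

* Ratios: `Σ ratios = 1` is asserted to 1e−9 whenever the node total is
  positive; a zero-total node has all ratios 0 and no dominant gene.
* Dominance ties are broken alphabetically and flagged; they essentially
  never occur on continuous data.
* Cross-cohort concordance excludes nodes with zero total in either
  cohort (flagged) and reports a per-node Spearman rank correlation;
  single-member nodes are trivially concordant (ρ = 1).
* TSV headers are auto-detected (a non-numeric first row in a numeric
  column); alias/length tables are two-column, tab-separated, UTF-8.
* The KGML writer formats integral coordinates without a decimal point,
  making repeated writes byte-stable.

## Known limitations

* The built-in DE test is a reference, not a replacement for a moderated
  count model; use the importer for real analyses.
* Expansion does not re-layout children; dense nodes overlap until the
  user rearranges them in the viewer.
* Enzyme kinetics and efficiency are ignored: equal catalytic competence
  across a node's members is an approximation, reasonable mainly when
  expression differences span orders of magnitude.
* Glycan-style (line-node) pathways are rejected outright rather than
  partially processed.
* No KEGG retrieval is included; KGML files and alias tables are user
  inputs (the synthetic module covers testing needs).
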