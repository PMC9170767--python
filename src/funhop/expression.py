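"""Read-count ingestion, node membership, aggregation and contribution ratios.

The quantitative core of the package: RNA-seq read counts are adjusted for
gene length, averaged per study group, summed over the genes of each
pathway node, and decomposed into per-gene contribution ratios.  A node's
overall activity is assumed to be driven mainly by its most highly
expressed member (the *dominant* gene), so ratios and dominance are the
interpretable output.

Conventions
-----------
* Counts live in a genes × samples :class:`pandas.DataFrame`; every sample
  carries a group label, ``case`` or ``control``.
* Gene-length adjustment divides each gene's counts by
  ``length_g / mean(length)`` so long genes shrink — the only direction
  consistent with length normalization.
* The per-gene average is ``(mean over case + mean over control) / 2``,
  which weights the two groups equally regardless of cohort imbalance.
* Node names follow the ``gene1-Bx`` rule: first member's symbol, ``-B``,
  then the member count (``x = 1`` for single-gene nodes).  Name
  collisions across distinct nodes get an ``.k`` ordinal so names stay
  joinable with differential-expression tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .expansion import ExpansionResult, HOMOLOG_OR, classify_group
from .kgml import AliasMap, Pathway

logger = logging.getLogger(__name__)

GROUP_LABELS = ("case", "control")

#: contribution-ratio cutoffs for cross-cohort concordance classes
HIGH_RATIO = 0.9
LOW_RATIO = 0.1


class ExpressionError(Exception):
    """Invalid count matrix, length table, or node/count mismatch."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class CountMatrix:
    """Genes × samples of non-negative read counts plus group labels."""

    counts: pd.DataFrame
    groups: pd.Series
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].unique()
            raise ExpressionError(f"duplicate gene symbols: {list(dups)}")
        if (self.counts.to_numpy() < 0).any():
            raise ExpressionError("negative read counts")
        self.groups = self.groups.reindex(self.counts.columns)
        if self.groups.isna().any():
            missing = list(self.groups.index[self.groups.isna()])
            raise ExpressionError(f"samples without a group label: {missing}")
        bad = set(self.groups.unique()) - set(GROUP_LABELS)
        if bad:
            raise ExpressionError(
                f"unknown group labels {sorted(bad)}; expected {GROUP_LABELS}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in(self, label: str) -> list[str]:
        return list(self.groups.index[self.groups == label])

    @classmethod
    def from_tsv(cls, counts_path, groups_path) -> "CountMatrix":
        """Load counts (first column = gene symbol) and sample→group TSVs."""
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        counts.index.name = None
        groups_df = pd.read_csv(
            groups_path, sep="\t", header=None,
            names=["sample", "group"], comment="#",
        )
        if str(groups_df.iloc[0, 0]).lower() in ("sample", "sample_id"):
            groups_df = groups_df.iloc[1:]
        groups = pd.Series(
            groups_df["group"].values, index=groups_df["sample"].values
        )
        return cls(counts=counts.astype(float), groups=groups)

    def to_tsv(self, counts_path, groups_path=None) -> None:
        out = self.counts.copy()
        out.index.name = "gene"
        out.to_csv(counts_path, sep="\t")
        if groups_path is not None:
            self.groups.to_csv(groups_path, sep="\t", header=False)


@dataclass
class GeneLengths:
    """Gene symbol → length in bases (sum of exon lengths)."""

    length: dict[str, float]

    def __post_init__(self):
        bad = [g for g, v in self.length.items() if not v > 0]
        if bad:
            raise ExpressionError(f"non-positive gene lengths: {bad}")

    @classmethod
    def from_tsv(cls, path) -> "GeneLengths":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["gene", "length"], comment="#")
        if not str(df.iloc[0, 1]).lstrip("-").replace(".", "", 1).isdigit():
            df = df.iloc[1:]
        return cls(length=dict(zip(df["gene"], df["length"].astype(float))))

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for gene, val in self.length.items():
                fh.write(f"{gene}\t{val:g}\n")


@dataclass
class NodeModel:
    """One enzymatic pathway node: ordered member genes plus its agg name."""

    node_id: str
    members: list[str]
    kegg_ids: list[str] = field(default_factory=list)
    agg_name: str = ""

    @property
    def first_gene(self) -> str:
        return self.members[0]


@dataclass
class NodeExpression:
    """Aggregated expression of one node.

    ``ratios`` maps each member to its fraction of the node total; when the
    total is zero every ratio is zero and there is no dominant gene.  Ties
    for dominance are broken alphabetically and flagged.
    """

    node: NodeModel
    total: float
    ratios: dict[str, float]
    dominant: str | None
    tie: bool = False
    missing: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# operations


def length_adjust(cm: CountMatrix, gl: GeneLengths) -> CountMatrix:
    """Divide each gene's counts by its length factor.

    The factor is ``length_g / mean(length over genes present in the
    matrix)``, so the mean factor over covered genes is exactly 1 and the
    grand total is preserved when all genes share one length.  Genes with
    no known length keep their raw counts and are recorded in
    ``flags["length_unadjusted"]``.
    """
    present = [g for g in cm.genes if g in gl.length]
    if not present:
        raise ExpressionError(
            "no overlap between count-matrix genes and the length table"
        )
    missing = [g for g in cm.genes if g not in gl.length]
    mean_len = float(np.mean([gl.length[g] for g in present]))
    factors = pd.Series(
        [gl.length.get(g, mean_len) / mean_len for g in cm.genes],
        index=cm.counts.index,
    )
    adjusted = cm.counts.div(factors, axis=0)
    if missing:
        logger.warning(
            "%d gene(s) have no length entry and keep raw counts: %s",
            len(missing), ", ".join(missing[:10]),
        )
    flags = dict(cm.flags)
    flags["length_unadjusted"] = missing
    return CountMatrix(counts=adjusted, groups=cm.groups.copy(), flags=flags)


def mean_group_expression(cm: CountMatrix) -> pd.Series:
    """Per-gene average: mean of the case-group and control-group means."""
    per_group = []
    for label in GROUP_LABELS:
        cols = cm.samples_in(label)
        if not cols:
            raise ExpressionError(f"no samples labelled {label!r}")
        per_group.append(cm.counts[cols].mean(axis=1))
    return (per_group[0] + per_group[1]) / 2.0


def _unique_agg_names(raw_names: Iterable[str]) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for name in raw_names:
        n = seen.get(name, 0) + 1
        seen[name] = n
        out.append(name if n == 1 else f"{name}.{n}")
    return out


def node_membership(
    source: Pathway | ExpansionResult, aliases: AliasMap
) -> list[NodeModel]:
    """Derive one :class:`NodeModel` per enzymatic node, in document order.

    Works identically on an original pathway (multi-gene entries carry all
    members in their name string) and on an expanded one (OR groups carry
    them as components).  Children of OR groups are not emitted on their
    own; members of protein complexes are, one node each, matching the
    pre-expansion entry set.
    """
    pathway = source.pathway if isinstance(source, ExpansionResult) else source
    or_children: set[str] = set()
    for e in pathway.entries:
        if e.type == "group" and classify_group(e) == HOMOLOG_OR:
            or_children.update(e.components)

    raw: list[tuple[str, list[str]]] = []
    for e in pathway.entries:
        if e.type == "group" and classify_group(e) == HOMOLOG_OR:
            tokens = [pathway.get_entry(cid).name for cid in e.components]
            raw.append((e.id, tokens))
        elif e.is_gene_like and e.id not in or_children:
            raw.append((e.id, e.name_tokens))

    nodes = []
    for node_id, tokens in raw:
        symbols = [aliases.lookup(t) for t in tokens]
        nodes.append(NodeModel(node_id=node_id, members=symbols,
                               kegg_ids=list(tokens)))
    for node, agg in zip(
        nodes,
        _unique_agg_names(f"{n.members[0]}-B{len(n.members)}" for n in nodes),
    ):
        node.agg_name = agg
    return nodes


def aggregate_counts(cm: CountMatrix, nodes: list[NodeModel]) -> CountMatrix:
    """Sum member-gene counts per node and per sample.

    Members absent from the matrix contribute zero and are recorded in
    ``flags["missing_members"]``.  The output rows are the nodes'
    aggregated names.
    """
    rows = {}
    missing: dict[str, list[str]] = {}
    for node in nodes:
        sub = cm.counts.reindex(node.members)
        absent = [g for g, isna in sub.isna().all(axis=1).items() if isna]
        if absent:
            missing[node.agg_name] = absent
        rows[node.agg_name] = sub.fillna(0.0).sum(axis=0)
    agg = pd.DataFrame.from_dict(rows, orient="index")
    agg = agg[cm.counts.columns] if len(agg) else agg
    if missing:
        logger.warning(
            "%d node(s) have members absent from the count matrix", len(missing)
        )
    return CountMatrix(counts=agg, groups=cm.groups.copy(),
                       flags={"missing_members": missing})


def node_expression(
    node: NodeModel, avg: Mapping[str, float]
) -> NodeExpression:
    """Total average count, per-member contribution ratios and dominance."""
    values = {m: float(avg.get(m, 0.0)) for m in node.members}
    missing = [m for m in node.members if m not in avg]
    total = float(sum(values.values()))
    if total > 0:
        ratios = {m: v / total for m, v in values.items()}
        best = max(ratios.values())
        top = sorted(m for m, r in ratios.items() if r == best)
        dominant, tie = top[0], len(top) > 1
    else:
        ratios = {m: 0.0 for m in values}
        dominant, tie = None, False
    return NodeExpression(node=node, total=total, ratios=ratios,
                          dominant=dominant, tie=tie, missing=missing)


@dataclass
class ConcordanceResult:
    """Cross-cohort comparison of per-gene contribution ratios."""

    pairs: pd.DataFrame            # node, gene, ratio_a, ratio_b
    high_both: int                 # genes with ratio > HIGH_RATIO in both
    low_both: int                  # genes with ratio < LOW_RATIO in both
    high_class_stable: bool        # same gene set above HIGH_RATIO
    low_class_stable: bool
    node_correlations: dict[str, float]   # Spearman rho per node
    excluded_nodes: list[str]      # zero total in either cohort


def cohort_ratio_concordance(
    expr_a: list[NodeExpression],
    expr_b: list[NodeExpression],
    high: float = HIGH_RATIO,
    low: float = LOW_RATIO,
) -> ConcordanceResult:
    """Pair contribution ratios between two cohorts node by node.

    Both inputs must describe the same nodes (same aggregated names and
    members).  Nodes with zero total in either cohort are excluded from
    the rank correlation and flagged.  Genes with ratio above ``high`` or
    below ``low`` in *both* cohorts are counted — the classes expected to
    be robust across datasets.
    """
    by_a = {e.node.agg_name: e for e in expr_a}
    by_b = {e.node.agg_name: e for e in expr_b}
    if set(by_a) != set(by_b):
        only_a = sorted(set(by_a) - set(by_b))
        only_b = sorted(set(by_b) - set(by_a))
        raise ExpressionError(
            f"node sets differ between cohorts (only in A: {only_a}, "
            f"only in B: {only_b})"
        )
    records = []
    correlations: dict[str, float] = {}
    excluded: list[str] = []
    for name in by_a:
        ea, eb = by_a[name], by_b[name]
        if ea.node.members != eb.node.members:
            raise ExpressionError(f"node {name}: member lists differ")
        for gene in ea.node.members:
            records.append((name, gene, ea.ratios[gene], eb.ratios[gene]))
        if ea.total == 0 or eb.total == 0:
            excluded.append(name)
            continue
        if len(ea.node.members) >= 2:
            ra = [ea.ratios[g] for g in ea.node.members]
            rb = [eb.ratios[g] for g in ea.node.members]
            rho = stats.spearmanr(ra, rb).statistic
            correlations[name] = float(rho)
        else:
            correlations[name] = 1.0
    pairs = pd.DataFrame(
        records, columns=["node", "gene", "ratio_a", "ratio_b"]
    )
    high_a = set(pairs.loc[pairs.ratio_a > high, "gene"])
    high_b = set(pairs.loc[pairs.ratio_b > high, "gene"])
    low_a = set(pairs.loc[pairs.ratio_a < low, "gene"])
    low_b = set(pairs.loc[pairs.ratio_b < low, "gene"])
    return ConcordanceResult(
        pairs=pairs,
        high_both=len(high_a & high_b),
        low_both=len(low_a & low_b),
        high_class_stable=high_a == high_b,
        low_class_stable=low_a == low_b,
        node_correlations=correlations,
        excluded_nodes=excluded,
    )


def ratio_table(
    node_exprs: list[NodeExpression],
    avg_raw: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Long-format per-gene table: node, gene, avg_count, ratio, dominance.

    ``avg_raw`` optionally supplies unadjusted averages for a companion
    column, since either scale can be the more natural one to plot.
    """
    rows = []
    for expr in node_exprs:
        for gene in expr.node.members:
            count = expr.ratios[gene] * expr.total if expr.total else 0.0
            row = {
                "node": expr.node.agg_name,
                "gene": gene,
                "avg_count": count,
                "ratio": expr.ratios[gene],
                "dominant_flag": gene == expr.dominant,
            }
            if avg_raw is not None:
                row["avg_count_raw"] = float(avg_raw.get(gene, 0.0))
            rows.append(row)
    return pd.DataFrame(rows)
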