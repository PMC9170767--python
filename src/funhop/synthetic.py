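"""Synthetic pathways and count matrices with planted, recoverable structure.

Everything downstream of KEGG and of an RNA-seq pipeline can be exercised
without downloads: this module generates (a) toy KGML pathways whose
enzyme nodes carry 1..k gene identifiers, wired into a linear
substrate/product chain, and (b) two-group count matrices with
negative-binomial noise, a designed dominant gene per node, and designed
per-node up/down effects placed on that dominant gene.  Placing the effect
on the dominant gene only is intentional: recovering the node direction
then specifically tests the rationale for count aggregation — that a
node's overall activity is driven by its most expressed member.

The generator emulates the shape of real tumor/normal cohorts (baseline
means spread over five orders of magnitude, dominant genes an order of
magnitude above the runner-up, overdispersed counts) but not library-size
variation or transcriptome-wide correlation structure.

Counts are NB(mean μ, dispersion φ) with variance μ + φμ², sampled as a
Gamma–Poisson mixture.  All outputs are deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from lxml import etree

from .expression import CountMatrix, GeneLengths, NodeModel
from .kgml import AliasMap, Entry, Graphics, Pathway
import pandas as pd


@dataclass
class SimulationTruth:
    """Ground truth for one simulated cohort.

    ``node_effects`` assigns each aggregated node name an effect class
    (``up``/``down``/``null``); ``dominant`` names the planted dominant
    member per node.  ``nb_mean_range`` is the log-uniform span of
    baseline gene means; ``nb_dispersion`` the NB dispersion φ.
    """

    node_effects: dict[str, str]
    dominant: dict[str, str]
    nb_mean_range: tuple[float, float] = (1.0, 1e5)
    nb_dispersion: float = 0.1
    effect_fold: float = 4.0
    seed: int = 0

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        data["nb_mean_range"] = tuple(data["nb_mean_range"])
        return cls(**data)


# ---------------------------------------------------------------------------
# pathway simulation


def simulate_pathway(
    n_nodes: int, max_genes_per_node: int, seed: int
) -> tuple[Pathway, AliasMap]:
    """Generate a valid linear KGML pathway plus its alias table.

    ``n_nodes`` enzyme entries, each carrying 1..``max_genes_per_node``
    KEGG gene ids (uniform), alternate with compound entries along a
    substrate → enzyme → product chain encoded as KGML reactions, with
    ECrel relations between consecutive enzymes.  Deterministic per seed:
    two runs produce byte-identical KGML.
    """
    if n_nodes < 1 or max_genes_per_node < 1:
        raise ValueError("n_nodes and max_genes_per_node must be >= 1")
    rng = np.random.default_rng(seed)
    pathway = Pathway(
        name="path:syn00001",
        title="synthetic linear pathway",
        attrs={"org": "syn", "number": "00001"},
    )
    alias: dict[str, str] = {}
    next_entry = 1
    next_gene = 1
    gene_entry_ids: list[str] = []

    def add_compound(i: int) -> str:
        nonlocal next_entry
        entry = Entry(
            id=str(next_entry), type="compound", name=f"cpd:C{90000 + i:05d}",
            graphics=Graphics(
                label=f"C{90000 + i:05d}", shape="circle",
                x=float(60 + 80 * i), y=120.0, width=8.0, height=8.0,
            ),
        )
        pathway.entries.append(entry)
        next_entry += 1
        return entry.id

    compound_ids = [add_compound(0)]
    for i in range(n_nodes):
        k = int(rng.integers(1, max_genes_per_node + 1))
        tokens = []
        for _ in range(k):
            token = f"hsa:{next_gene}"
            alias[token] = f"G{next_gene:04d}"
            tokens.append(token)
            next_gene += 1
        entry = Entry(
            id=str(next_entry), type="gene", name=" ".join(tokens),
            graphics=Graphics(
                label=f"{alias[tokens[0]]}...", shape="rectangle",
                x=float(100 + 80 * i), y=200.0, width=46.0, height=17.0,
                extra={"fgcolor": "#000000", "bgcolor": "#BFFFBF"},
            ),
            extra={"reaction": f"rn:R{10000 + i:05d}"},
        )
        pathway.entries.append(entry)
        gene_entry_ids.append(entry.id)
        next_entry += 1
        compound_ids.append(add_compound(i + 1))

    for i, gid in enumerate(gene_entry_ids):
        rxn = etree.Element("reaction", id=gid,
                            name=f"rn:R{10000 + i:05d}", type="irreversible")
        etree.SubElement(rxn, "substrate", id=compound_ids[i],
                         name=f"cpd:C{90000 + i:05d}")
        etree.SubElement(rxn, "product", id=compound_ids[i + 1],
                         name=f"cpd:C{90000 + i + 1:05d}")
        pathway.reactions.append(rxn)
    for a, b in zip(gene_entry_ids, gene_entry_ids[1:]):
        rel = etree.Element("relation", entry1=a, entry2=b, type="ECrel")
        etree.SubElement(rel, "subtype", name="compound", value=b)
        pathway.relations.append(rel)
    pathway.validate()
    return pathway, AliasMap(alias)


# ---------------------------------------------------------------------------
# count simulation


def plan_truth(
    nodes: list[NodeModel],
    seed: int,
    p_up: float = 1 / 3,
    p_down: float = 1 / 3,
    nb_dispersion: float = 0.1,
    effect_fold: float = 4.0,
) -> SimulationTruth:
    """Assign an effect class and a dominant member to every node."""
    rng = np.random.default_rng(seed)
    effects: dict[str, str] = {}
    dominant: dict[str, str] = {}
    for node in nodes:
        u = rng.random()
        effects[node.agg_name] = (
            "up" if u < p_up else "down" if u < p_up + p_down else "null"
        )
        dominant[node.agg_name] = str(rng.choice(node.members))
    return SimulationTruth(
        node_effects=effects, dominant=dominant,
        nb_dispersion=nb_dispersion, effect_fold=effect_fold, seed=seed,
    )


def _nb_sample(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(μ, φ) with variance μ + φμ², via Gamma–Poisson."""
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, np.asarray(mean) * dispersion)
    return rng.poisson(lam)


def simulate_counts(
    nodes: list[NodeModel],
    n_case: int,
    n_control: int,
    truth: SimulationTruth,
    noise_seed: int | None = None,
) -> tuple[CountMatrix, GeneLengths]:
    """Sample a two-group count matrix honoring the planted truth.

    Baseline means are log-uniform over ``truth.nb_mean_range``; each
    node's planted dominant gene is raised to at least 10× the node's
    next-highest mean and to at least 4× the sum of the other members, so
    its designed contribution ratio is ≥ 0.8.  Up/down node effects
    multiply the dominant gene's *case* means by ``effect_fold`` or its
    reciprocal.  Gene lengths are log-normal around 2.5 kb.

    ``noise_seed``, when given, drives the count sampling with its own
    stream while the design (means, effects, lengths) stays pinned to
    ``truth.seed`` — two noise seeds over one truth act as independent
    cohorts of the same population.
    """
    if n_case < 2 or n_control < 2:
        raise ValueError("need >= 2 samples per group")
    rng = np.random.default_rng(truth.seed)
    lo, hi = truth.nb_mean_range
    genes: list[str] = []
    base_mean: dict[str, float] = {}
    case_mean: dict[str, float] = {}
    for node in nodes:
        if node.agg_name not in truth.node_effects:
            raise ValueError(f"node {node.agg_name} missing from truth")
        means = 10 ** rng.uniform(np.log10(lo), np.log10(hi),
                                  size=len(node.members))
        dom = truth.dominant[node.agg_name]
        if dom not in node.members:
            raise ValueError(
                f"planted dominant {dom} is not a member of {node.agg_name}"
            )
        di = node.members.index(dom)
        if len(node.members) > 1:
            others = np.delete(means, di)
            means[di] = max(10.0 * others.max(), 4.0 * others.sum())
        for gene, mu in zip(node.members, means):
            genes.append(gene)
            base_mean[gene] = float(mu)
            case_mean[gene] = float(mu)
        effect = truth.node_effects[node.agg_name]
        if effect == "up":
            case_mean[dom] = base_mean[dom] * truth.effect_fold
        elif effect == "down":
            case_mean[dom] = base_mean[dom] / truth.effect_fold

    samples = [f"case_{i + 1:03d}" for i in range(n_case)] + \
              [f"control_{i + 1:03d}" for i in range(n_control)]
    labels = ["case"] * n_case + ["control"] * n_control
    mu_case = np.array([case_mean[g] for g in genes])
    mu_ctrl = np.array([base_mean[g] for g in genes])
    noise_rng = rng if noise_seed is None else np.random.default_rng(noise_seed)
    counts = np.column_stack(
        [_nb_sample(noise_rng, mu_case, truth.nb_dispersion)
         for _ in range(n_case)]
        + [_nb_sample(noise_rng, mu_ctrl, truth.nb_dispersion)
           for _ in range(n_control)]
    ).astype(float)
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        groups=pd.Series(labels, index=samples),
    )
    lengths = GeneLengths(length={
        g: float(rng.lognormal(mean=np.log(2500.0), sigma=0.6))
        for g in genes
    })
    return cm, lengths


def write_bundle(
    out_dir,
    pathway: Pathway,
    alias: AliasMap,
    cm: CountMatrix,
    lengths: GeneLengths,
    truth: SimulationTruth,
) -> dict[str, Path]:
    """Serialize a complete simulated fixture set into ``out_dir``."""
    from .kgml import write_kgml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "kgml": out / "pathway.kgml",
        "alias": out / "alias.tsv",
        "counts": out / "counts.tsv",
        "groups": out / "groups.tsv",
        "lengths": out / "lengths.tsv",
        "truth": out / "truth.json",
    }
    paths["kgml"].write_text(write_kgml(pathway), encoding="utf-8")
    with open(paths["alias"], "w", encoding="utf-8") as fh:
        fh.write("kegg_id\tsymbol\n")
        for key, sym in alias.mapping.items():
            fh.write(f"{key}\t{sym}\n")
    cm.to_tsv(paths["counts"], paths["groups"])
    lengths.to_tsv(paths["lengths"])
    truth.to_json(paths["truth"])
    return paths


# ---------------------------------------------------------------------------
# fixtures mirroring published worked examples


#: the four NAD(P)+-dependent aldehyde dehydrogenase paralogs sharing one
#: histidine-pathway node (KEGG ids for ALDH3A1, ALDH1A3, ALDH3B1, ALDH3B2)
ALDH_NODE = [
    ("hsa:218", "ALDH3A1"),
    ("hsa:220", "ALDH1A3"),
    ("hsa:221", "ALDH3B1"),
    ("hsa:222", "ALDH3B2"),
]

#: a 21-member phospholipase node displayed as PLA2G4B.  PLA2G4B, PLA2G2A
#: and PLA2G12A are the documented members; the remaining symbols are a
#: synthetic stand-in drawn from the phospholipase A2 family, since the
#: full published member list is not reproduced here.
PLA2_NODE = [
    ("hsa:100137049", "PLA2G4B"),
    ("hsa:5320", "PLA2G2A"),
    ("hsa:81579", "PLA2G12A"),
    ("hsa:5319", "PLA2G1B"),
    ("hsa:391013", "PLA2G2C"),
    ("hsa:26279", "PLA2G2D"),
    ("hsa:30814", "PLA2G2E"),
    ("hsa:64600", "PLA2G2F"),
    ("hsa:50487", "PLA2G3"),
    ("hsa:5321", "PLA2G4A"),
    ("hsa:8605", "PLA2G4C"),
    ("hsa:283748", "PLA2G4D"),
    ("hsa:255189", "PLA2G4E"),
    ("hsa:255228", "PLA2G4F"),
    ("hsa:5322", "PLA2G5"),
    ("hsa:8398", "PLA2G6"),
    ("hsa:7941", "PLA2G7"),
    ("hsa:8399", "PLA2G10"),
    ("hsa:84647", "PLA2G12B"),
    ("hsa:23659", "PLA2G15"),
    ("hsa:11145", "PLA2G16"),
]


def _single_node_pathway(members, name: str) -> tuple[Pathway, AliasMap]:
    pathway = Pathway(name=name, title="worked-example fixture")
    tokens = [t for t, _ in members]
    pathway.entries.append(Entry(
        id="10", type="gene", name=" ".join(tokens),
        graphics=Graphics(label=members[0][1] + "...", shape="rectangle",
                          x=200.0, y=150.0, width=46.0, height=17.0),
    ))
    return pathway, AliasMap(dict(members))


def aldh_fixture() -> tuple[Pathway, AliasMap]:
    """One-entry pathway with the four-gene aldehyde-dehydrogenase node."""
    return _single_node_pathway(ALDH_NODE, "path:hsa00340")


def pla2_fixture() -> tuple[Pathway, AliasMap]:
    """One-entry pathway with the 21-gene phospholipase node.

    Member list partially synthetic (see :data:`PLA2_NODE`).
    """
    return _single_node_pathway(PLA2_NODE, "path:hsa00564")


def glycan_fixture() -> Pathway:
    """A glycan-style pathway whose entry is drawn as a polyline.

    Such pathways are detected and refused by expansion.
    """
    pathway = Pathway(name="path:syn00601", title="glycan-style fixture")
    pathway.entries.append(Entry(
        id="1", type="gene", name="hsa:2683",
        graphics=Graphics(label="B4GALT1", shape="line",
                          coords="100,100,200,100"),
    ))
    return pathway
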