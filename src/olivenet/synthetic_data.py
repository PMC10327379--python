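"""Synthetic benchmark inputs with the structure the pipeline assumes.

Real inputs (a STRING interactome, curated disease genes, STITCH drug
targets, trial-status labels, KEGG gene sets) cannot be bundled, so
this module generates a miniature study with the same statistical
shape: a connected preferential-attachment (scale-free-like)
interactome; a planted disease module grown by breadth-first expansion;
positive-class molecules whose targets concentrate in the module's
closed 1-hop neighborhood; negative-class molecules with uniformly
random targets; query molecules split evenly between the two regimes
(identities recorded for recovery tests); and gene sets containing the
disease module as a positive control among random decoys.  Everything
is deterministic under the scenario seed, and every emitted file parses
through the production readers.

The module also carries a small frozen reporting fixture: a published
top-10 ranking of olive-oil phytochemicals with their consensus
correlation probabilities and significant-pathway lists, used to test
the report aggregation (top-10 mean, pathway frequencies).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import networkx as nx
import numpy as np

from .associations import LabeledDrugSet, TargetTable, write_labels, write_targets
from .interactome import Interactome, write_edge_list
from .propagation import SeedSet
from .enrichment import write_gmt


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of one synthetic study.

    Defaults give a 300-protein network with a 25-protein disease
    module, 30 positive and 150 negative training molecules (the same
    ~1:5 imbalance direction as a real repurposing screen, scaled
    down), and 40 query molecules half of which are planted near the
    disease module (overlap probability 0.9 per target).
    """

    n_nodes: int = 300
    attachment: int = 3
    module_size: int = 25
    n_pos: int = 30
    n_neg: int = 150
    n_query: int = 40
    targets_min: int = 3
    targets_max: int = 8
    overlap_prob: float = 0.9
    score_min: int = 200
    score_max: int = 999
    rng_seed: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_prob <= 1:
            raise ValueError("overlap_prob must lie in [0, 1]")
        if self.module_size >= self.n_nodes:
            raise ValueError("module_size must be smaller than n_nodes")
        if min(self.n_nodes, self.module_size, self.n_pos, self.n_neg,
               self.n_query, self.targets_min) <= 0:
            raise ValueError("all counts must be positive")
        if self.targets_max < self.targets_min:
            raise ValueError("targets_max < targets_min")
        if not 0 <= self.score_min <= self.score_max <= 999:
            raise ValueError("score range must satisfy 0 <= min <= max <= 999")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticScenario":
        return cls(**d)


def _node_name(i: int) -> str:
    return f"P{i:05d}"


def generate_interactome(scenario: SyntheticScenario) -> Interactome:
    """Connected preferential-attachment graph with uniform integer scores.

    The construction adds ``n_nodes - attachment`` nodes each bringing
    ``attachment`` edges to distinct existing nodes, so the edge count
    is exactly ``(n_nodes - attachment) * attachment``.
    """
    if scenario.n_nodes < scenario.attachment + 1:
        raise ValueError("need n_nodes >= attachment + 1")
    g = nx.barabasi_albert_graph(
        scenario.n_nodes, scenario.attachment, seed=scenario.rng_seed
    )
    rng = np.random.default_rng(np.random.SeedSequence([scenario.rng_seed, 1]))
    edges = []
    for a, b in sorted(g.edges()):
        score = int(rng.integers(scenario.score_min, scenario.score_max + 1))
        edges.append((_node_name(a), _node_name(b), score))
    return Interactome.from_edges(edges)


def plant_disease_module(net: Interactome, scenario: SyntheticScenario) -> SeedSet:
    """Connected disease module grown breadth-first from a random start."""
    if scenario.module_size > net.n_nodes:
        raise ValueError("module_size exceeds the network size")
    rng = np.random.default_rng(np.random.SeedSequence([scenario.rng_seed, 2]))
    adjacency: dict[str, list[str]] = {n: [] for n in net.node_ids}
    for a, b, _ in net.edges:
        adjacency[a].append(b)
        adjacency[b].append(a)
    for n in adjacency:
        adjacency[n].sort()
    start = net.node_ids[int(rng.integers(net.n_nodes))]
    visited = [start]
    seen = {start}
    queue = [start]
    while queue and len(visited) < scenario.module_size:
        node = queue.pop(0)
        # expansion order within a shell is randomised; a fixed (e.g.
        # lexicographic) order would systematically prefer the oldest,
        # highest-degree nodes of the preferential-attachment graph
        for nb in rng.permutation(adjacency[node]):
            if nb not in seen:
                seen.add(nb)
                visited.append(nb)
                queue.append(nb)
                if len(visited) >= scenario.module_size:
                    break
    return SeedSet(
        role="disease",
        members=frozenset(visited[: scenario.module_size]),
        source_label="synthetic_disease_module",
    )


def module_neighborhood(net: Interactome, module: SeedSet) -> frozenset[str]:
    """The disease module together with its direct interaction partners."""
    neigh = set(module.members)
    for a, b, _ in net.edges:
        if a in module.members:
            neigh.add(b)
        if b in module.members:
            neigh.add(a)
    return frozenset(neigh)


def _draw_targets(
    rng: np.random.Generator,
    k: int,
    module: list[str],
    adjacency: dict[str, list[str]],
    all_nodes: list[str],
    overlap_prob: float,
) -> list[str]:
    """Draw k distinct targets.

    A planted draw (probability ``overlap_prob``) is a one-step random
    walk from a uniformly chosen module node: stay on it with
    probability 1/2, else move to one of its interaction partners.
    Its support is exactly the module's closed 1-hop neighborhood while
    keeping the draws concentrated around the module itself — molecules
    perturbing the disease's network region without necessarily
    hitting the disease proteins.  Non-planted draws are uniform over
    the whole network.
    """
    targets: set[str] = set()
    while len(targets) < k:
        if overlap_prob > 0 and rng.random() < overlap_prob:
            node = module[int(rng.integers(len(module)))]
            neighbors = adjacency[node]
            if neighbors and rng.random() < 0.5:
                node = neighbors[int(rng.integers(len(neighbors)))]
            targets.add(node)
        else:
            targets.add(all_nodes[int(rng.integers(len(all_nodes)))])
    return sorted(targets)


def generate_molecules(
    net: Interactome, disease: SeedSet, scenario: SyntheticScenario
) -> tuple[TargetTable, LabeledDrugSet, list[str], dict[str, list[str]]]:
    """Positive, negative, and query molecules with scored targets.

    With probability ``overlap_prob`` a positive's target comes from
    the disease module's closed 1-hop neighborhood (a one-step random
    walk from a uniform module node, see :func:`_draw_targets`),
    otherwise uniformly from the whole network; negatives draw
    uniformly.  Queries are an even split of both regimes; the
    ``truth`` map records which is which.  All target scores are drawn
    at or above the scenario score minimum so that cutoff attrition is
    explicit, never accidental.
    """
    rng = np.random.default_rng(np.random.SeedSequence([scenario.rng_seed, 3]))
    module = sorted(disease.members)
    adjacency: dict[str, list[str]] = {n: [] for n in module}
    for a, b, _ in net.edges:
        if a in adjacency:
            adjacency[a].append(b)
        if b in adjacency:
            adjacency[b].append(a)
    for n in adjacency:
        adjacency[n].sort()
    all_nodes = list(net.node_ids)
    rows: list[tuple[str, str, int]] = []
    labels: dict[str, str] = {}
    queries: list[str] = []
    truth: dict[str, list[str]] = {"planted": [], "random": []}

    def add_molecule(mol_id: str, planted: bool) -> None:
        k = int(rng.integers(scenario.targets_min, scenario.targets_max + 1))
        prob = scenario.overlap_prob if planted else 0.0
        for t in _draw_targets(rng, k, module, adjacency, all_nodes, prob):
            score = int(rng.integers(scenario.score_min, scenario.score_max + 1))
            rows.append((mol_id, t, score))

    for i in range(scenario.n_pos):
        mol = f"POS{i:03d}"
        add_molecule(mol, planted=True)
        labels[mol] = "positive"
    for i in range(scenario.n_neg):
        mol = f"NEG{i:03d}"
        add_molecule(mol, planted=False)
        labels[mol] = "negative"
    n_planted_q = scenario.n_query // 2
    for i in range(scenario.n_query):
        mol = f"QRY{i:03d}"
        planted = i < n_planted_q
        add_molecule(mol, planted=planted)
        queries.append(mol)
        truth["planted" if planted else "random"].append(mol)
    return TargetTable.from_rows(rows), LabeledDrugSet(labels=labels), queries, truth


def generate_gene_sets(
    net: Interactome,
    disease: SeedSet,
    n_sets: int,
    scenario: SyntheticScenario,
) -> dict[str, frozenset[str]]:
    """Gene sets: the disease module plus random decoys of the same size."""
    if n_sets < 1:
        raise ValueError("need at least one gene set")
    rng = np.random.default_rng(np.random.SeedSequence([scenario.rng_seed, 4]))
    sets: dict[str, frozenset[str]] = {"disease_module": frozenset(disease.members)}
    nodes = np.array(net.node_ids)
    for i in range(n_sets - 1):
        members = rng.choice(nodes, size=len(disease.members), replace=False)
        sets[f"random_set_{i:02d}"] = frozenset(str(m) for m in members)
    return sets


def simulate_to_dir(
    scenario: SyntheticScenario, outdir: str | Path, n_gene_sets: int = 20
) -> dict[str, Path]:
    """Write a full synthetic study in the production file dialects.

    Emits net.tsv (STRING dialect), disease_genes.txt, targets.tsv
    (STITCH dialect), labels.tsv, genesets.gmt, truth.json and
    scenario.json; returns the path of each artifact.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    net = generate_interactome(scenario)
    disease = plant_disease_module(net, scenario)
    targets, labels, queries, truth = generate_molecules(net, disease, scenario)
    gene_sets = generate_gene_sets(net, disease, n_gene_sets, scenario)

    paths = {
        "network": outdir / "net.tsv",
        "disease_genes": outdir / "disease_genes.txt",
        "targets": outdir / "targets.tsv",
        "labels": outdir / "labels.tsv",
        "gene_sets": outdir / "genesets.gmt",
        "truth": outdir / "truth.json",
        "scenario": outdir / "scenario.json",
    }
    write_edge_list(net, paths["network"])
    with paths["disease_genes"].open("w") as fh:
        fh.write("# synthetic disease module\n")
        for g in sorted(disease.members):
            fh.write(g + "\n")
    write_targets(targets, paths["targets"])
    write_labels(labels, paths["labels"])
    write_gmt(gene_sets, paths["gene_sets"])
    truth_doc = dict(truth)
    truth_doc["queries"] = queries
    paths["truth"].write_text(json.dumps(truth_doc, indent=1))
    paths["scenario"].write_text(json.dumps(scenario.to_dict(), indent=1))
    return paths


# -- frozen reporting fixture --------------------------------------------

#: Published top-10 phytochemical ranking: (name, consensus probability %).
TABLE1_PROBABILITIES: tuple[tuple[str, float], ...] = (
    ("Quercetin", 78.0),
    ("Genistein", 75.5),
    ("Luteolin", 73.9),
    ("Palmitoleate", 69.5),
    ("Stearic Acid", 67.5),
    ("Apigenin", 67.4),
    ("Epicatechin", 66.4),
    ("Kaempferol", 65.1),
    ("Squalene", 63.7),
    ("Daidzein", 62.1),
)

#: Published significant-pathway lists per top-10 phytochemical.
TABLE1_PATHWAYS: dict[str, tuple[str, ...]] = {
    "Quercetin": (
        "Alzheimer's disease", "Olfactory Transduction",
        "Phosphatidylinositol Signaling System", "Insulin Signaling Pathway",
    ),
    "Genistein": (
        "Alzheimer's disease", "Olfactory Transduction",
        "Insulin Signaling Pathway", "Vascular Smooth Muscle Contraction",
    ),
    "Luteolin": ("Olfactory Transduction",),
    "Palmitoleate": (
        "Alzheimer's disease", "Olfactory Transduction",
        "Insulin Signaling Pathway", "Vascular Smooth Muscle Contraction",
    ),
    "Stearic Acid": ("Alzheimer's disease", "Olfactory Transduction"),
    "Apigenin": (
        "Alzheimer's disease", "Olfactory Transduction", "Long-Term Potentiation",
        "Phosphatidylinositol Signaling System", "Glioma",
        "Insulin Signaling Pathway", "GnRH Signaling Pathway",
        "Neurotrophin Signaling Pathway",
    ),
    "Epicatechin": (
        "Alzheimer's disease", "Olfactory Transduction", "Long-Term Potentiation",
        "Phosphatidylinositol Signaling System", "Insulin Signaling Pathway",
        "Calcium Signaling Pathway",
    ),
    "Kaempferol": (
        "Alzheimer's disease", "Olfactory Transduction",
        "Phosphatidylinositol Signaling System", "Insulin Signaling Pathway",
        "Vascular Smooth Muscle Contraction",
    ),
    "Squalene": (
        "Alzheimer's disease", "Olfactory Transduction",
        "Maturity Onset Diabetes of the Young",
    ),
    "Daidzein": (
        "Alzheimer's disease", "Olfactory Transduction", "Glioma",
        "Phosphatidylinositol Signaling System", "Long-Term Potentiation",
        "Insulin Signaling Pathway", "mTOR Signaling Pathway",
    ),
}


def table1_fixture() -> tuple[tuple[tuple[str, float], ...], dict[str, tuple[str, ...]]]:
    """The published top-10 ranking and pathway lists, as a test fixture."""
    return TABLE1_PROBABILITIES, dict(TABLE1_PATHWAYS)
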