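"""Generators for synthetic inputs with the statistical structure the
pipeline assumes.

Three families of fixtures are produced, mirroring the three real data
sources of the analysis:

* two-group expression matrices with a planted set of "informative" genes
  whose case-group mean is shifted upward on an additive log2-like scale;
* scale-free interactomes (preferential attachment) and clique assemblies
  with planted articulation structure for exercising network decomposition;
* replicate protein-abundance tables with planted up/down fold changes.

Every generator returns its planted ground truth alongside the data, and all
randomness flows from the spec's seed, so downstream recovery claims are
checkable and reruns are byte-identical. Ground truth travels in sidecar
objects/files only — never inside the TSVs the pipeline itself consumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import data_io
from .data_io import CASE, CONTROL, LabeledExpression
from .proteomics import AbundanceTable, write_abundance


class ParameterError(ValueError):
    """Raised for invalid simulation specifications."""


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionSimSpec:
    """Two-group expression design.

    Defaults follow the 70-sample case/control design the pipeline targets:
    40 control and 30 case samples, Gaussian noise of SD 1 around per-gene
    baselines on a log2-like additive scale, with informative genes shifted
    by ``effect_size`` in the case group.
    """

    n_genes: int = 500
    n_informative: int = 20
    n_control: int = 40
    n_case: int = 30
    effect_size: float = 1.5
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_informative, self.n_control, self.n_case) < 1:
            raise ParameterError("all counts must be >= 1")
        if self.n_informative > self.n_genes:
            raise ParameterError("n_informative must not exceed n_genes")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")


@dataclass
class SimulatedExpression:
    expression: LabeledExpression
    informative_genes: list[str]


def simulate_expression(spec: ExpressionSimSpec) -> SimulatedExpression:
    """Generate a gene × sample matrix with planted informative genes.

    Informative genes are the first ``n_informative`` gene rows (recorded in
    the returned ground truth, with nothing in the identifiers themselves);
    their case-group mean is the baseline plus ``effect_size``.
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i:05d}" for i in range(spec.n_genes)]
    samples = [f"CTRL{i:03d}" for i in range(spec.n_control)] + [
        f"CASE{i:03d}" for i in range(spec.n_case)
    ]
    labels = pd.Series(
        [CONTROL] * spec.n_control + [CASE] * spec.n_case, index=samples
    )
    baseline = rng.uniform(6.0, 10.0, size=spec.n_genes)
    n_samples = spec.n_control + spec.n_case
    values = baseline[:, None] + rng.normal(
        0.0, spec.noise_sd, size=(spec.n_genes, n_samples)
    ) if spec.noise_sd > 0 else np.tile(baseline[:, None], (1, n_samples))
    values = np.array(values)
    values[: spec.n_informative, spec.n_control:] += spec.effect_size
    frame = pd.DataFrame(values, index=genes, columns=samples)
    return SimulatedExpression(
        LabeledExpression(frame, labels), genes[: spec.n_informative]
    )


# ---------------------------------------------------------------------------
# interactome
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkSimSpec:
    """Preferential-attachment interactome with optional planted blocks.

    ``planted_blocks`` descriptors are ``(block_size, bridge_node_count)``:
    each block is a clique of fresh nodes tied to the scale-free core through
    that many single-edge attachments from distinct clique members to
    distinct core nodes. A single attachment (``bridge_node_count=1``)
    plants articulation structure: both endpoints of the bridge edge become
    cut vertices.
    """

    n_nodes: int = 1000
    attachment_m: int = 3
    planted_blocks: tuple[tuple[int, int], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.attachment_m < 1:
            raise ParameterError("attachment_m must be >= 1")
        if self.n_nodes <= self.attachment_m:
            raise ParameterError("n_nodes must exceed attachment_m")
        for size, bridges in self.planted_blocks:
            if size < 3:
                raise ParameterError("planted block sizes must be >= 3")
            if not (1 <= bridges <= size):
                raise ParameterError("bridge count must be in [1, block size]")


@dataclass
class SimulatedNetwork:
    graph: nx.Graph
    planted_aps: set[str]


def simulate_interactome(spec: NetworkSimSpec) -> SimulatedNetwork:
    """Scale-free interactome with heavy-tailed degrees, plus planted blocks."""
    core = nx.barabasi_albert_graph(spec.n_nodes, spec.attachment_m, seed=spec.seed)
    graph = nx.relabel_nodes(core, {i: f"P{i:05d}" for i in core.nodes})
    rng = np.random.default_rng(spec.seed + 1)
    planted_aps: set[str] = set()
    next_id = spec.n_nodes
    core_nodes = sorted(graph.nodes)
    for size, bridges in spec.planted_blocks:
        members = [f"P{next_id + j:05d}" for j in range(size)]
        next_id += size
        for i, u in enumerate(members):
            for v in members[i + 1:]:
                graph.add_edge(u, v)
        anchors = rng.choice(len(core_nodes), size=bridges, replace=False)
        for member, anchor_idx in zip(members, anchors):
            graph.add_edge(member, core_nodes[int(anchor_idx)])
        if bridges == 1:
            planted_aps.add(members[0])
            planted_aps.add(core_nodes[int(anchors[0])])
    return SimulatedNetwork(graph, planted_aps)


def plant_articulation_structure(
    blocks: list[int],
    topology: str = "chain",
    prefix: str = "B",
) -> tuple[nx.Graph, set[str]]:
    """Join cliques pairwise at single shared nodes; return graph + true APs.

    ``chain``: consecutive cliques share one node, giving ``len(blocks) - 1``
    articulation points. ``star``: every non-hub clique shares one distinct
    node of the first (hub) clique.
    """
    if len(blocks) < 1:
        raise ParameterError("need at least one block")
    if any(size < 3 for size in blocks):
        raise ParameterError("block sizes must be >= 3")
    if topology not in ("chain", "star"):
        raise ParameterError(f"unknown topology {topology!r}")
    if topology == "star" and len(blocks) - 1 > blocks[0] and len(blocks) > 1:
        raise ParameterError("hub clique too small for star topology")

    graph = nx.Graph()
    ground_truth: set[str] = set()
    members_of: list[list[str]] = []
    counter = 0

    def fresh() -> str:
        nonlocal counter
        name = f"{prefix}{counter:04d}"
        counter += 1
        return name

    for bi, size in enumerate(blocks):
        if bi == 0:
            members = [fresh() for _ in range(size)]
        elif topology == "chain":
            shared = members_of[bi - 1][-1]
            members = [shared] + [fresh() for _ in range(size - 1)]
            if len(blocks) > 1:
                ground_truth.add(shared)
        else:  # star: share the (bi-1)-th node of the hub clique
            shared = members_of[0][bi - 1]
            members = [shared] + [fresh() for _ in range(size - 1)]
            ground_truth.add(shared)
        for i, u in enumerate(members):
            for v in members[i + 1:]:
                graph.add_edge(u, v)
        members_of.append(members)
    return graph, ground_truth


# ---------------------------------------------------------------------------
# proteomics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteomicsSimSpec:
    """Replicate abundance table with planted fold changes vs baseline.

    ``conditions`` lists the arm labels; the first is the baseline. Planted
    proteins follow a geometric time course: arm *i* has mean
    ``baseline × fc^i`` with the per-step fold change ``fc`` sampled outside
    the [2/3, 1.5] null band (up in [``fc_high``, 2·``fc_high``], down in
    [``fc_low``/2, ``fc_low``]). Every pairwise contrast of a planted
    protein therefore carries the planted direction, so planted DEPs land
    in the cross-contrast intersection — the pattern of progressively
    amplified regulation the framework looks for.
    """

    n_proteins: int = 300
    conditions: tuple[str, ...] = ("0h", "24h", "48h")
    n_dep_up: int = 15
    n_dep_down: int = 15
    fc_low: float = 0.5
    fc_high: float = 2.0
    n_replicates: int = 3
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dep_up + self.n_dep_down > self.n_proteins:
            raise ParameterError("planted DEPs exceed protein count")
        if self.fc_high < 1.5:
            raise ParameterError("fc_high must be >= 1.5")
        if self.fc_low > 2.0 / 3.0:
            raise ParameterError("fc_low must be <= 2/3")
        if self.n_replicates < 2:
            raise ParameterError("need >=2 replicates per condition")
        if len(self.conditions) < 2:
            raise ParameterError("need >=2 conditions")


@dataclass
class SimulatedProteomics:
    table: AbundanceTable
    truth: pd.Series  # protein -> "up" | "down" | "none" (vs baseline)


def simulate_proteomics(spec: ProteomicsSimSpec) -> SimulatedProteomics:
    """Reporter-intensity table with planted DEPs relative to the baseline."""
    rng = np.random.default_rng(spec.seed)
    proteins = [f"PRT{i:05d}" for i in range(spec.n_proteins)]
    true_fc = np.ones(spec.n_proteins)
    calls = np.array(["none"] * spec.n_proteins, dtype=object)
    up_idx = np.arange(spec.n_dep_up)
    down_idx = np.arange(spec.n_dep_up, spec.n_dep_up + spec.n_dep_down)
    true_fc[up_idx] = rng.uniform(spec.fc_high, 2.0 * spec.fc_high, size=len(up_idx))
    true_fc[down_idx] = rng.uniform(
        spec.fc_low / 2.0, spec.fc_low, size=len(down_idx)
    )
    calls[up_idx] = "up"
    calls[down_idx] = "down"

    baseline = rng.lognormal(mean=np.log(100.0), sigma=0.5, size=spec.n_proteins)
    columns: dict[str, np.ndarray] = {}
    for ci, cond in enumerate(spec.conditions):
        mean = baseline if ci == 0 else baseline * true_fc**ci
        for rep in range(1, spec.n_replicates + 1):
            noise = (
                rng.lognormal(mean=0.0, sigma=spec.noise_cv, size=spec.n_proteins)
                if spec.noise_cv > 0
                else 1.0
            )
            columns[f"{cond}_rep{rep}"] = mean * noise
    values = pd.DataFrame(columns, index=proteins)
    conditions = {
        cond: [f"{cond}_rep{r}" for r in range(1, spec.n_replicates + 1)]
        for cond in spec.conditions
    }
    truth = pd.Series(calls, index=proteins, name="planted_call")
    return SimulatedProteomics(AbundanceTable(values, conditions), truth)


# ---------------------------------------------------------------------------
# dual-evidence pipeline bundle
# ---------------------------------------------------------------------------

@dataclass
class PipelineBundle:
    """Paths to a written fixture bundle plus its planted ground truth."""

    expression_path: Path
    metadata_path: Path
    edges_path: Path
    abundance_path: Path
    truth_path: Path
    target_genes: list[str]
    informative_genes: list[str]


def simulate_pipeline_bundle(
    out_dir,
    seed: int = 0,
    n_genes: int = 200,
    n_blocks: int = 4,
    block_size: int = 6,
    effect_size: float = 3.0,
    noise_sd: float = 1.0,
    n_background_nodes: int = 40,
    n_decoy_deps: int = 10,
) -> PipelineBundle:
    """Write a coherent end-to-end fixture with dual-evidence target genes.

    The interactome is a clique chain whose junction nodes are the planted
    therapeutic targets: they are articulation points of the induced disease
    subnetwork, their genes are strongly up-shifted in case samples, and
    their proteins carry a planted up fold change in every treatment arm.
    Background interactome nodes and decoy DEPs are planted so that neither
    evidence stream alone reproduces the target set.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    chain, junctions = plant_articulation_structure(
        [block_size] * n_blocks, topology="chain", prefix="N"
    )
    chain_nodes = sorted(chain.nodes)
    n_informative = len(chain_nodes)
    if n_informative >= n_genes:
        raise ParameterError("n_genes too small for the planted chain")

    expr_sim = simulate_expression(
        ExpressionSimSpec(
            n_genes=n_genes,
            n_informative=n_informative,
            effect_size=effect_size,
            noise_sd=noise_sd,
            seed=seed,
        )
    )
    genes = expr_sim.expression.gene_ids
    informative = expr_sim.informative_genes
    # wire the chain onto the informative genes; junctions become targets
    relabel = dict(zip(chain_nodes, informative))
    disease_graph = nx.relabel_nodes(chain, relabel)
    targets = sorted(relabel[j] for j in junctions)

    # scale-free background among non-informative genes, loosely attached so
    # background nodes do not alter the chain's articulation structure
    background_genes = genes[n_informative: n_informative + n_background_nodes]
    bg = nx.barabasi_albert_graph(len(background_genes), 2, seed=seed + 1)
    bg = nx.relabel_nodes(bg, dict(enumerate(background_genes)))
    interactome = nx.compose(disease_graph, bg)
    interactome.add_edge(background_genes[0], informative[0])

    # proteomics over all interactome genes: targets planted up everywhere,
    # plus decoy DEPs drawn from non-AP background genes
    prot_ids = sorted(interactome.nodes)
    decoys = list(rng.choice(background_genes, size=n_decoy_deps, replace=False))
    baseline = rng.lognormal(np.log(100.0), 0.4, size=len(prot_ids))
    true_fc = pd.Series(1.0, index=prot_ids)
    true_fc[targets] = rng.uniform(2.0, 4.0, size=len(targets))
    true_fc[decoys] = rng.uniform(2.0, 4.0, size=len(decoys))
    conditions = ("0h", "24h", "48h")
    columns = {}
    for ci, cond in enumerate(conditions):
        mean = baseline if ci == 0 else baseline * true_fc.to_numpy() ** ci
        for rep in range(1, 4):
            noise = rng.lognormal(0.0, 0.05, size=len(prot_ids))
            columns[f"{cond}_rep{rep}"] = mean * noise
    abundance = AbundanceTable(
        pd.DataFrame(columns, index=prot_ids),
        {c: [f"{c}_rep{r}" for r in range(1, 4)] for c in conditions},
    )

    expression_path = out_dir / "expression.tsv"
    metadata_path = out_dir / "metadata.tsv"
    edges_path = out_dir / "edges.tsv"
    abundance_path = out_dir / "abundance.tsv"
    truth_path = out_dir / "ground_truth.json"
    data_io.write_expression(expr_sim.expression, expression_path, metadata_path)
    data_io.write_edges(interactome, edges_path)
    write_abundance(abundance, abundance_path)
    truth = {
        "target_genes": targets,
        "informative_genes": informative,
        "decoy_deps": sorted(map(str, decoys)),
        "seed": seed,
    }
    truth_path.write_text(json.dumps(truth, indent=2))
    return PipelineBundle(
        expression_path,
        metadata_path,
        edges_path,
        abundance_path,
        truth_path,
        targets,
        informative,
    )
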