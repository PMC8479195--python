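"""Disease-subnetwork construction and topological characterization.

Given the selected transcriptomic features and a confidence-filtered
interactome, this module induces the disease PPI subnetwork (dropping
features with no retained interaction), checks the scale-free hypothesis by
a least-squares power-law fit of the degree distribution on log-log axes,
computes the three hub centralities (degree; unnormalized betweenness over
unordered pairs; stress, the raw shortest-path count through a vertex), and
screens dense modules with the MCODE procedure at its four classical
parameters (degree cutoff 2, node-score cutoff 0.2, k-core 2, depth 100;
haircut on, fluff off).
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class FitError(ValueError):
    """Raised when a degree distribution cannot support a power-law fit."""


@dataclass
class SubnetworkResult:
    graph: nx.Graph
    dropped_isolates: list[str]
    missing_features: list[str]


@dataclass(frozen=True)
class PowerLawFit:
    slope: float
    intercept: float
    r_squared: float
    correlation: float


@dataclass(frozen=True)
class McodeParams:
    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    k_core: int = 2
    max_depth: int = 100


@dataclass(frozen=True)
class McodeModule:
    nodes: frozenset
    score: float
    density: float

    @property
    def size(self) -> int:
        return len(self.nodes)


def induce_subnetwork(features, interactome: nx.Graph) -> SubnetworkResult:
    """Induced subgraph on the features, with zero-degree nodes removed.

    Features absent from the interactome and features left without any
    interaction among the selected set are both reported, not silently
    dropped.
    """
    features = list(dict.fromkeys(features))
    if not features:
        logger.warning("empty feature list: inducing an empty subnetwork")
    present = [f for f in features if f in interactome]
    missing = [f for f in features if f not in interactome]
    sub = nx.Graph(interactome.subgraph(present))
    isolates = sorted(nx.isolates(sub))
    sub.remove_nodes_from(isolates)
    return SubnetworkResult(sub, isolates, missing)


def fit_power_law(graph: nx.Graph, min_count: int = 2) -> PowerLawFit:
    """Least-squares line through (log k, log N(k)) for degrees k >= 1.

    N(k) is the number of nodes with degree exactly k. Degrees observed
    fewer than ``min_count`` times are excluded (default 2): singleton
    counts in the heavy tail are pure sampling noise on log-log axes and
    classically flatten the fitted slope. Requires at least three distinct
    positive degrees after filtering; reports the slope, R² and the
    absolute log-log correlation.
    """
    degrees = np.array([d for _, d in graph.degree() if d >= 1])
    if degrees.size == 0:
        raise FitError("graph has no edges")
    ks, counts = np.unique(degrees, return_counts=True)
    keep = counts >= min_count
    ks, counts = ks[keep], counts[keep]
    if len(ks) < 3:
        raise FitError(f"need >=3 distinct positive degrees, got {len(ks)}")
    fit = stats.linregress(np.log(ks), np.log(counts))
    return PowerLawFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        correlation=float(abs(fit.rvalue)),
    )


def _bfs_sigma(graph: nx.Graph, source):
    """BFS shortest-path counts and predecessor DAG from one source."""
    sigma = {source: 1.0}
    dist = {source: 0}
    preds: dict = {source: []}
    order = [source]
    queue = deque([source])
    while queue:
        v = queue.popleft()
        for w in graph[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                sigma[w] = 0.0
                preds[w] = []
                order.append(w)
                queue.append(w)
            if dist[w] == dist[v] + 1:
                sigma[w] += sigma[v]
                preds[w].append(v)
    return sigma, preds, order


def stress_centrality(graph: nx.Graph) -> dict:
    """Stress of each vertex: number of shortest paths passing through it.

    Unordered source/target pairs are counted once and endpoints excluded,
    matching the convention for unnormalized betweenness but without
    dividing by the pair's total path count.
    """
    stress = dict.fromkeys(graph, 0.0)
    for s in graph:
        sigma, preds, order = _bfs_sigma(graph, s)
        delta = dict.fromkeys(order, 0.0)
        for w in reversed(order):
            for v in preds[w]:
                delta[v] += sigma[v] * (1.0 + delta[w] / sigma[w])
        for v in order:
            if v != s:
                stress[v] += delta[v]
    return {v: x / 2.0 for v, x in stress.items()}


def centralities(graph: nx.Graph) -> pd.DataFrame:
    """Degree, betweenness and stress per node (sorted by degree, descending)."""
    degree = dict(graph.degree())
    betweenness = nx.betweenness_centrality(graph, normalized=False)
    stress = stress_centrality(graph)
    frame = pd.DataFrame(
        {
            "degree": pd.Series(degree, dtype=int),
            "betweenness": pd.Series(betweenness),
            "stress": pd.Series(stress).round(6),
        }
    )
    return frame.sort_values(["degree", "betweenness"], ascending=False)


def _closed_top_k(series: pd.Series, k: int) -> set:
    """Top-k by value with all ties at the k-th position included."""
    ordered = series.sort_values(ascending=False)
    if k >= len(ordered):
        return set(ordered.index)
    cutoff = ordered.iloc[k - 1]
    return set(ordered.index[ordered >= cutoff])


def hub_coverage(
    cent: pd.DataFrame, ap_set: set, k: int
) -> tuple[set, float | None]:
    """Hubs = nodes in the closed top-k of all three centralities.

    Coverage is the fraction of hubs that are articulation proteins;
    ``None`` when the hub intersection is empty (coverage undefined).
    """
    if k > len(cent):
        raise ValueError(f"k={k} exceeds node count {len(cent)}")
    hubs = (
        _closed_top_k(cent["degree"], k)
        & _closed_top_k(cent["betweenness"], k)
        & _closed_top_k(cent["stress"], k)
    )
    if not hubs:
        return hubs, None
    return hubs, len(hubs & set(ap_set)) / len(hubs)


def _density(graph: nx.Graph) -> float:
    n = graph.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * graph.number_of_edges() / (n * (n - 1))


def _vertex_weight(graph: nx.Graph, v, degree_cutoff: int) -> float:
    """MCODE vertex weight: core number × density of the neighborhood's
    highest k-core (closed neighborhood of v)."""
    if graph.degree(v) < degree_cutoff:
        return 0.0
    neighborhood = graph.subgraph(set(graph[v]) | {v})
    core_numbers = nx.core_number(neighborhood)
    k_max = max(core_numbers.values())
    if k_max == 0:
        return 0.0
    core = neighborhood.subgraph(
        [u for u, c in core_numbers.items() if c >= k_max]
    )
    return k_max * _density(core)


def mcode_modules(
    graph: nx.Graph, params: McodeParams = McodeParams()
) -> list[McodeModule]:
    """MCODE dense-module detection.

    Vertices are weighted by the highest-k-core density of their closed
    neighborhood; complexes grow greedily from the highest-weight unvisited
    seed, admitting vertices whose weight is at least
    ``(1 − node_score_cutoff) ×`` the seed weight, to ``max_depth`` hops.
    Post-processing keeps each module's ``k_core``-core (the haircut —
    singly-connected vertices cannot survive a 2-core). Modules are ranked
    by score = density × size.
    """
    weights = {v: _vertex_weight(graph, v, params.degree_cutoff) for v in graph}
    visited: set = set()
    raw_modules: list[set] = []
    for seed in sorted(weights, key=lambda v: (-weights[v], str(v))):
        if seed in visited or weights[seed] <= 0.0:
            continue
        threshold = weights[seed] * (1.0 - params.node_score_cutoff)
        module = {seed}
        frontier = deque([(seed, 0)])
        visited.add(seed)
        while frontier:
            v, depth = frontier.popleft()
            if depth >= params.max_depth:
                continue
            for w in graph[v]:
                if w in visited or weights[w] < threshold:
                    continue
                visited.add(w)
                module.add(w)
                frontier.append((w, depth + 1))
        raw_modules.append(module)

    modules: list[McodeModule] = []
    for nodes in raw_modules:
        trimmed = nx.k_core(graph.subgraph(nodes), params.k_core)
        if trimmed.number_of_nodes() == 0:
            continue
        density = _density(trimmed)
        modules.append(
            McodeModule(
                nodes=frozenset(trimmed.nodes),
                score=density * trimmed.number_of_nodes(),
                density=density,
            )
        )
    modules.sort(key=lambda m: (-m.score, -m.size, sorted(map(str, m.nodes))))
    return modules
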