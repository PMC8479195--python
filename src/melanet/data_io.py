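"""Tabular I/O for expression matrices, interactome edge lists and ID maps.

The on-disk formats are deliberately plain:

* expression matrix — TSV, first column gene identifier, header row of
  sample identifiers, numeric cells (normalized intensities);
* sample metadata — TSV with columns ``sample_id`` and ``group``
  (``control`` or ``case``);
* edge list — TSV with header ``protein1<TAB>protein2[<TAB>combined_score]``;
  the score column may use the STRING 0–999 integer dialect or plain
  0–1 decimals, auto-detected at ingest;
* ID map — two-column TSV ``alias<TAB>official_symbol``.

Interactomes are held as :class:`networkx.Graph` objects: undirected, simple,
with an optional ``score`` attribute per edge (confidence in [0, 1]).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONTROL = "control"
CASE = "case"
VALID_GROUPS = frozenset({CONTROL, CASE})


class IngestError(ValueError):
    """Raised when an input file violates the expected format."""


@dataclass
class LabeledExpression:
    """A gene × sample abundance matrix with binary group labels.

    Attributes
    ----------
    values
        DataFrame indexed by gene identifier with sample identifiers as
        columns; unitless normalized intensities on an additive (log-like)
        scale.
    labels
        Series mapping each sample identifier to ``"control"`` or ``"case"``.
    """

    values: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        self.labels = self.labels.reindex(self.values.columns)
        if self.labels.isna().any():
            missing = list(self.labels.index[self.labels.isna()])
            raise IngestError(f"samples without a group label: {missing}")
        bad = sorted(set(self.labels.unique()) - VALID_GROUPS)
        if bad:
            raise IngestError(f"unknown group labels: {bad}")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()].unique()
            raise IngestError(f"duplicate gene identifiers: {list(dup)[:5]}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.labels.index[self.labels == group])

    @property
    def case_samples(self) -> list[str]:
        return self.samples_in_group(CASE)

    @property
    def control_samples(self) -> list[str]:
        return self.samples_in_group(CONTROL)

    def subset_genes(self, genes) -> "LabeledExpression":
        present = [g for g in genes if g in self.values.index]
        return LabeledExpression(self.values.loc[present], self.labels.copy())

    def subset_samples(self, samples) -> "LabeledExpression":
        samples = list(samples)
        return LabeledExpression(self.values[samples], self.labels.loc[samples])


@dataclass
class IdMap:
    """Alias → official-symbol association table.

    Unmapped identifiers are reported, never silently dropped: mapping
    operations return the identifiers they could not resolve.
    """

    mapping: dict[str, str] = field(default_factory=dict)

    def resolve(self, identifier: str) -> str | None:
        return self.mapping.get(identifier)


def read_expression(
    matrix_path, metadata_path, collapse: str = "max"
) -> LabeledExpression:
    """Read an expression TSV and its sample metadata.

    Duplicate gene rows (e.g. multiple probes per gene) are collapsed by the
    per-sample ``collapse`` rule (``"max"`` by default, ``"mean"`` optional);
    the collapse is logged.
    """
    if collapse not in ("max", "mean"):
        raise ValueError(f"unknown collapse rule {collapse!r}")
    try:
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    except Exception as exc:  # noqa: BLE001 - wrap any parse failure
        raise IngestError(f"cannot parse expression matrix {matrix_path}: {exc}")
    values.index = values.index.astype(str)
    non_numeric = values.columns[
        [not pd.api.types.is_numeric_dtype(values[c]) for c in values.columns]
    ]
    if len(non_numeric):
        raise IngestError(
            f"non-numeric expression values in columns {list(non_numeric)}"
        )
    if values.index.has_duplicates:
        n_dup = int(values.index.duplicated().sum())
        logger.info(
            "collapsing %d duplicate gene rows by per-sample %s", n_dup, collapse
        )
        values = values.groupby(level=0, sort=False).agg(collapse)

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = {"sample_id", "group"}
    if not required.issubset(meta.columns):
        raise IngestError(
            f"metadata must have columns {sorted(required)}, got {list(meta.columns)}"
        )
    labels = pd.Series(
        meta["group"].values, index=meta["sample_id"].values, name="group"
    )
    missing = [s for s in values.columns if s not in labels.index]
    if missing:
        raise IngestError(f"metadata missing samples: {missing}")
    return LabeledExpression(values, labels.loc[values.columns])


def write_expression(expr: LabeledExpression, matrix_path, metadata_path) -> None:
    expr.values.to_csv(matrix_path, sep="\t", index_label="gene_id")
    pd.DataFrame(
        {"sample_id": expr.sample_ids, "group": expr.labels.values}
    ).to_csv(metadata_path, sep="\t", index=False)


def _detect_score_dialect(scores: list[float]) -> float:
    """Return the divisor normalizing scores to [0, 1] (1 or 1000)."""
    if any(s > 1.0 for s in scores):
        logger.info("edge scores look like STRING 0-999 integers; dividing by 1000")
        return 1000.0
    return 1.0


def read_scored_edges(path, min_score: float | None = 0.9) -> nx.Graph:
    """Read an edge-list TSV into a simple undirected graph.

    Edges with confidence below ``min_score`` are excluded; self-loops are
    excluded; duplicate undirected edges collapse keeping the maximum score.
    Files without a score column yield unscored edges which always pass the
    threshold (the confidence cutoff applies only to scored sources).
    """
    path = Path(path)
    rows: list[tuple[str, str, float | None]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        n_cols = len(header)
        if n_cols not in (2, 3):
            raise IngestError(f"{path}:1: expected 2 or 3 columns, got {n_cols}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n_cols:
                raise IngestError(
                    f"{path}:{lineno}: expected {n_cols} fields, got {len(parts)}"
                )
            score: float | None = None
            if n_cols == 3 and parts[2] != "":  # blank score = unscored edge
                try:
                    score = float(parts[2])
                except ValueError:
                    raise IngestError(
                        f"{path}:{lineno}: non-numeric score {parts[2]!r}"
                    )
            rows.append((parts[0], parts[1], score))

    divisor = 1.0
    scored = [s for _, _, s in rows if s is not None]
    if scored:
        divisor = _detect_score_dialect(scored)

    graph = nx.Graph()
    for u, v, score in rows:
        if u == v:
            continue
        if score is not None:
            score /= divisor
            if min_score is not None and score < min_score:
                continue
        if graph.has_edge(u, v):
            old = graph.edges[u, v].get("score")
            if score is not None and (old is None or score > old):
                graph.edges[u, v]["score"] = score
        elif score is not None:
            graph.add_edge(u, v, score=score)
        else:
            graph.add_edge(u, v)
    return graph


def write_edges(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for u, v, data in sorted(graph.edges(data=True)):
            score = data.get("score")
            fh.write(f"{u}\t{v}\t{'' if score is None else score}\n")


def read_id_map(path) -> IdMap:
    frame = pd.read_csv(path, sep="\t", dtype=str, header=0)
    if frame.shape[1] < 2:
        raise IngestError(f"ID map {path} must have two columns")
    return IdMap(dict(zip(frame.iloc[:, 0], frame.iloc[:, 1])))


def apply_id_map(graph: nx.Graph, idmap: IdMap) -> tuple[nx.Graph, list[str]]:
    """Relabel nodes to official symbols; return (graph, unmapped node list).

    Unmapped nodes are kept under their original identifier and reported —
    partial mapping is the norm for real interactomes, so failure is a report,
    not an exception.
    """
    unmapped = [n for n in graph.nodes if idmap.resolve(n) is None]
    relabel = {n: idmap.resolve(n) for n in graph.nodes if idmap.resolve(n)}
    mapped = nx.Graph()
    mapped.add_nodes_from(relabel.get(n, n) for n in graph.nodes)
    for u, v, data in graph.edges(data=True):
        mu, mv = relabel.get(u, u), relabel.get(v, v)
        if mu == mv:
            continue  # aliases collapsing to one symbol create self-loops
        if mapped.has_edge(mu, mv):
            old = mapped.edges[mu, mv].get("score")
            new = data.get("score")
            if new is not None and (old is None or new > old):
                mapped.edges[mu, mv]["score"] = new
        else:
            mapped.add_edge(mu, mv, **data)
    return mapped, unmapped


def merge_interactomes(g1: nx.Graph, g2: nx.Graph) -> nx.Graph:
    """Undirected union of two interactomes in a shared namespace.

    Node set is the union of node sets; edge set the union of edge sets with
    duplicates collapsed keeping the maximum confidence.
    """
    merged = nx.Graph()
    merged.add_nodes_from(g1.nodes)
    merged.add_nodes_from(g2.nodes)
    for graph in (g1, g2):
        for u, v, data in graph.edges(data=True):
            if u == v:
                continue
            if merged.has_edge(u, v):
                old = merged.edges[u, v].get("score")
                new = data.get("score")
                if new is not None and (old is None or new > old):
                    merged.edges[u, v]["score"] = new
            else:
                merged.add_edge(u, v, **data)
    return merged


def assert_simple(graph: nx.Graph) -> None:
    """Assert the interactome invariants: no self-loops, scores in [0, 1]."""
    loops = list(nx.selfloop_edges(graph))
    if loops:
        raise IngestError(f"self-loops present: {loops[:5]}")
    for u, v, data in graph.edges(data=True):
        score = data.get("score")
        if score is not None and not (0.0 <= score <= 1.0):
            raise IngestError(f"edge ({u},{v}) score {score} outside [0,1]")


def read_feature_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_feature_list(features, path) -> None:
    with open(path, "w") as fh:
        for feature in features:
            fh.write(f"{feature}\n")
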