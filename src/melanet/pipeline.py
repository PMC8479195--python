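"""Config-driven orchestration of the full target-discovery framework.

Stages run in order, each reading plain TSV/JSON artifacts and writing its
own, so any stage is usable standalone and a completed stage is skipped on
rerun (resumability). The manifest records the config hash, master seed and
per-stage status/outputs; it carries no timestamps, so resumed runs produce
byte-identical manifests.

Stage order: classify → select → induce → gapr → robustness → netstats →
prioritize → deps → intersect. A stage whose scientific precondition fails
(e.g. a degree distribution too degenerate for a power-law fit) records the
failure in the manifest and the run continues where dependencies allow.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classifier, data_io, gapr, netanalysis, prioritize, proteomics

logger = logging.getLogger(__name__)

STAGES = (
    "classify",
    "select",
    "induce",
    "gapr",
    "robustness",
    "netstats",
    "prioritize",
    "deps",
    "intersect",
)


@dataclass
class PipelineConfig:
    """All inputs and stage parameters, with the framework's defaults."""

    expression_path: str = ""
    metadata_path: str = ""
    edges_path: str = ""
    abundance_path: str = ""
    # classifier
    n_trees: int = 500
    n_folds: int = 10
    n_repeats: int = 100
    train_ratio: float = 0.8
    mda_threshold: float = 1.0
    # interactome
    min_score: float = 0.9
    # robustness
    robustness_rates: tuple = tuple(round(0.01 * i, 2) for i in range(1, 51))
    robustness_reps: int = 100
    # network analysis
    mcode_degree_cutoff: int = 2
    mcode_node_score_cutoff: float = 0.2
    mcode_k_core: int = 2
    mcode_max_depth: int = 100
    hub_k: int = 10
    # prioritization
    alpha: float = 0.05
    # proteomics
    contrasts: tuple = (("24h", "0h"), ("48h", "0h"), ("48h", "24h"))
    fc_up: float = 1.5
    fc_down: float = 2.0 / 3.0
    dep_alpha: float = 0.05
    seed: int = 0

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["robustness_rates"] = [float(r) for r in self.robustness_rates]
        data["contrasts"] = [list(c) for c in self.contrasts]
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "robustness_rates" in data:
            data["robustness_rates"] = tuple(data["robustness_rates"])
        if "contrasts" in data:
            data["contrasts"] = tuple(tuple(c) for c in data["contrasts"])
        return cls(**data)

    def content_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _stage_seed(master: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


class PipelineRun:
    """One run directory; executes stages, tracks the manifest."""

    def __init__(self, config: PipelineConfig, out_dir):
        self.config = config
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {
            "config_hash": config.content_hash(),
            "seed": config.seed,
            "stages": {},
        }

    # -- helpers ----------------------------------------------------------

    def _path(self, name: str) -> Path:
        return self.out / name

    def _record(self, stage: str, outputs: list[str], status: str = "completed",
                reason: str | None = None) -> None:
        entry: dict = {"status": status, "outputs": sorted(outputs)}
        if reason:
            entry["reason"] = reason
        self.manifest["stages"][stage] = entry

    def _outputs_exist(self, names: list[str]) -> bool:
        return all(self._path(n).exists() for n in names)

    def _write_manifest(self) -> None:
        self._path("manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True) + "\n"
        )

    # -- stages -----------------------------------------------------------

    def stage_classify(self) -> None:
        outputs = [
            "train_probabilities.tsv", "test_probabilities.tsv",
            "importance.tsv", "roc_points.tsv", "classify_summary.json",
        ]
        if self._outputs_exist(outputs):
            self._record("classify", outputs)
            return
        cfg = self.config
        expr = data_io.read_expression(cfg.expression_path, cfg.metadata_path)
        seed = _stage_seed(cfg.seed, "classify")
        split = classifier.make_split(expr, cfg.train_ratio, seed)
        rf_cfg = classifier.RfRunConfig(cfg.n_trees, cfg.n_folds, cfg.n_repeats, seed)
        train_probs, ensemble = classifier.train_repeated_cv(expr, split, rf_cfg)
        test_probs = classifier.predict_test(ensemble, expr, split)
        importance = classifier.compute_mda(ensemble, expr, split, seed)
        train_auc = classifier.compute_auc(train_probs["p_case"], train_probs["true"])
        test_auc = classifier.compute_auc(test_probs["p_case"], test_probs["true"])
        test_acc = float((test_probs["predicted"] == test_probs["true"]).mean())
        # empirical ROC of the out-of-fold training probabilities
        order = np.argsort(-train_probs["p_case"].to_numpy(), kind="stable")
        truth = (train_probs["true"].to_numpy() == data_io.CASE)[order]
        tpr = np.concatenate([[0.0], np.cumsum(truth) / max(truth.sum(), 1)])
        fpr = np.concatenate([[0.0], np.cumsum(~truth) / max((~truth).sum(), 1)])
        pd.DataFrame({"fpr": fpr, "tpr": tpr}).to_csv(
            self._path("roc_points.tsv"), sep="\t", index=False
        )
        train_probs.to_csv(self._path("train_probabilities.tsv"), sep="\t",
                           index_label="sample_id")
        test_probs.to_csv(self._path("test_probabilities.tsv"), sep="\t",
                          index_label="sample_id")
        importance.to_csv(self._path("importance.tsv"), sep="\t",
                          index_label="gene_id")
        self._path("classify_summary.json").write_text(json.dumps(
            {"train_oof_auc": train_auc, "test_auc": test_auc,
             "test_accuracy": test_acc,
             "n_train": len(split.train_sample_ids),
             "n_test": len(split.test_sample_ids)}, indent=2, sort_keys=True))
        self._record("classify", outputs)

    def stage_select(self) -> None:
        outputs = ["selected_features.txt"]
        if self._outputs_exist(outputs):
            self._record("select", outputs)
            return
        importance = pd.read_csv(self._path("importance.tsv"), sep="\t",
                                 index_col=0)
        selected = classifier.select_features(
            importance, self.config.mda_threshold
        )
        data_io.write_feature_list(selected, self._path("selected_features.txt"))
        self._record("select", outputs)

    def stage_induce(self) -> None:
        outputs = ["subnetwork_edges.tsv", "induce_report.json"]
        if self._outputs_exist(outputs):
            self._record("induce", outputs)
            return
        features = data_io.read_feature_list(self._path("selected_features.txt"))
        interactome = data_io.read_scored_edges(
            self.config.edges_path, self.config.min_score
        )
        result = netanalysis.induce_subnetwork(features, interactome)
        data_io.write_edges(result.graph, self._path("subnetwork_edges.tsv"))
        self._path("induce_report.json").write_text(json.dumps(
            {"n_nodes": result.graph.number_of_nodes(),
             "n_edges": result.graph.number_of_edges(),
             "dropped_isolates": result.dropped_isolates,
             "missing_features": result.missing_features},
            indent=2, sort_keys=True))
        self._record("induce", outputs)

    def _load_subnetwork(self):
        return data_io.read_scored_edges(self._path("subnetwork_edges.tsv"),
                                         min_score=None)

    def stage_gapr(self) -> None:
        outputs = ["gapr_layers.tsv", "rgb_nodes.txt", "gapr_summary.json"]
        if self._outputs_exist(outputs):
            self._record("gapr", outputs)
            return
        subnet = self._load_subnetwork()
        result = gapr.gapr_decompose(subnet)
        rows = [{"node": str(v), "layer": layer}
                for layer, nodes in enumerate(result.layers, start=1)
                for v in sorted(nodes, key=str)]
        pd.DataFrame(rows, columns=["node", "layer"]).to_csv(
            self._path("gapr_layers.tsv"), sep="\t", index=False)
        data_io.write_feature_list(sorted(result.rgb_nodes, key=str),
                                   self._path("rgb_nodes.txt"))
        self._path("gapr_summary.json").write_text(json.dumps(
            {"n_layers": result.n_layers,
             "n_articulation_proteins": len(result.all_aps),
             "layer_sizes": [len(layer) for layer in result.layers],
             "rgb_size": len(result.rgb_nodes),
             "n_fragments": len(result.residual_fragments)},
            indent=2, sort_keys=True))
        self._record("gapr", outputs)

    def stage_robustness(self) -> None:
        outputs = ["robustness_curve.tsv"]
        if self._outputs_exist(outputs):
            self._record("robustness", outputs)
            return
        subnet = self._load_subnetwork()
        try:
            curve = gapr.robustness_curve(
                subnet, self.config.robustness_rates,
                self.config.robustness_reps,
                _stage_seed(self.config.seed, "robustness"),
            )
        except ValueError as exc:
            self._record("robustness", [], "precondition_failed", str(exc))
            return
        curve.to_csv(self._path("robustness_curve.tsv"), sep="\t", index=False)
        self._record("robustness", outputs)

    def stage_netstats(self) -> None:
        outputs = ["centralities.tsv", "powerlaw_fit.json", "mcode_modules.tsv",
                   "hub_report.json"]
        if self._outputs_exist(outputs):
            self._record("netstats", outputs)
            return
        cfg = self.config
        subnet = self._load_subnetwork()
        cent = netanalysis.centralities(subnet)
        cent.to_csv(self._path("centralities.tsv"), sep="\t", index_label="node")
        try:
            fit = netanalysis.fit_power_law(subnet)
            fit_data = asdict(fit)
        except netanalysis.FitError as exc:
            fit_data = {"error": str(exc)}
        self._path("powerlaw_fit.json").write_text(
            json.dumps(fit_data, indent=2, sort_keys=True))
        params = netanalysis.McodeParams(
            cfg.mcode_degree_cutoff, cfg.mcode_node_score_cutoff,
            cfg.mcode_k_core, cfg.mcode_max_depth)
        modules = netanalysis.mcode_modules(subnet, params)
        pd.DataFrame(
            [{"module": i, "score": m.score, "size": m.size,
              "nodes": ",".join(sorted(map(str, m.nodes)))}
             for i, m in enumerate(modules, start=1)],
            columns=["module", "score", "size", "nodes"],
        ).to_csv(self._path("mcode_modules.tsv"), sep="\t", index=False)
        layers = pd.read_csv(self._path("gapr_layers.tsv"), sep="\t")
        ap_set = set(layers["node"].astype(str))
        k = min(cfg.hub_k, len(cent)) if len(cent) else 0
        if k:
            hubs, coverage = netanalysis.hub_coverage(cent, ap_set, k)
        else:
            hubs, coverage = set(), None
        self._path("hub_report.json").write_text(json.dumps(
            {"k": k, "hubs": sorted(map(str, hubs)),
             "ap_coverage": coverage}, indent=2, sort_keys=True))
        self._record("netstats", outputs)

    def stage_prioritize(self) -> None:
        outputs = ["prioritized_aps.tsv", "prioritize_missing.txt"]
        if self._outputs_exist(outputs):
            self._record("prioritize", outputs)
            return
        cfg = self.config
        expr = data_io.read_expression(cfg.expression_path, cfg.metadata_path)
        layers = pd.read_csv(self._path("gapr_layers.tsv"), sep="\t")
        aps = set(layers["node"].astype(str))
        if not aps:
            self._record("prioritize", [], "precondition_failed",
                         "no articulation proteins")
            return
        result = prioritize.select_up_articulation_proteins(expr, aps, cfg.alpha)
        result.table.to_csv(self._path("prioritized_aps.tsv"), sep="\t",
                            index_label="gene_id")
        data_io.write_feature_list(result.missing,
                                   self._path("prioritize_missing.txt"))
        self._record("prioritize", outputs)

    def stage_deps(self) -> None:
        outputs = ["dep_table.tsv", "dep_union.txt", "dep_intersection.txt",
                   "venn_counts.json"]
        if self._outputs_exist(outputs):
            self._record("deps", outputs)
            return
        cfg = self.config
        table = proteomics.read_abundance(cfg.abundance_path)
        frame = proteomics.dep_table(
            table, [tuple(c) for c in cfg.contrasts],
            cfg.fc_up, cfg.fc_down, cfg.dep_alpha)
        frame.to_csv(self._path("dep_table.tsv"), sep="\t", index=False)
        dep_sets = proteomics.deps_per_contrast(frame)
        union, intersection, overlaps = proteomics.contrast_set_ops(dep_sets)
        data_io.write_feature_list(sorted(union), self._path("dep_union.txt"))
        data_io.write_feature_list(sorted(intersection),
                                   self._path("dep_intersection.txt"))
        self._path("venn_counts.json").write_text(json.dumps(
            {"per_contrast": {c: len(s) for c, s in dep_sets.items()},
             "union": len(union), "intersection": len(intersection),
             "pairwise": {f"{a}&{b}": n for (a, b), n in overlaps.items()}},
            indent=2, sort_keys=True))
        self._record("deps", outputs)

    def stage_intersect(self) -> None:
        outputs = ["target_intersection.tsv"]
        if self._outputs_exist(outputs):
            self._record("intersect", outputs)
            return
        dep_frame = pd.read_csv(self._path("dep_table.tsv"), sep="\t",
                                dtype={"protein": str})
        union = set(data_io.read_feature_list(self._path("dep_union.txt")))
        layers = pd.read_csv(self._path("gapr_layers.tsv"), sep="\t")
        ap_layers = dict(zip(layers["node"].astype(str), layers["layer"]))
        overlap = proteomics.intersect_with_targets(dep_frame, union, ap_layers)
        if not union and ap_layers:
            logger.warning("empty DEP union against nonempty AP set")
        overlap.to_csv(self._path("target_intersection.tsv"), sep="\t",
                       index=False)
        self._record("intersect", outputs)

    # -- driver -----------------------------------------------------------

    def run(self) -> dict:
        for name in STAGES:
            stage = getattr(self, f"stage_{name}")
            try:
                stage()
            except FileNotFoundError as exc:
                raise StageError(name, f"missing input: {exc}") from exc
            self._write_manifest()
        return self.manifest


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute every stage; return the manifest (also written to disk)."""
    return PipelineRun(config, out_dir).run()
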