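"""End-to-end run: expression -> features -> subnetwork -> GAPR ->
prioritization -> proteomics intersection.

Generates the dual-evidence synthetic bundle (planted target genes that are
simultaneously case-up-shifted, articulation points of the disease
subnetwork, and proteomic DEPs), runs all nine pipeline stages and prints
the final multi-target candidates.
"""

import json
from pathlib import Path
from tempfile import TemporaryDirectory

import pandas as pd

from melanet.pipeline import PipelineConfig, run_pipeline
from melanet.synthetic_data import simulate_pipeline_bundle

with TemporaryDirectory() as tmp:
    bundle = simulate_pipeline_bundle(Path(tmp) / "bundle", seed=1)
    print("planted multi-target genes:", ", ".join(bundle.target_genes))

    config = PipelineConfig(
        expression_path=str(bundle.expression_path),
        metadata_path=str(bundle.metadata_path),
        edges_path=str(bundle.edges_path),
        abundance_path=str(bundle.abundance_path),
        n_trees=250, n_repeats=1,          # scaled down for a quick demo
        robustness_rates=(0.1, 0.3), robustness_reps=5,
        seed=1,
    )
    manifest = run_pipeline(config, Path(tmp) / "run")
    done = [s for s, e in manifest["stages"].items() if e["status"] == "completed"]
    print(f"{len(done)}/9 stages completed")

    summary = json.loads((Path(tmp) / "run" / "gapr_summary.json").read_text())
    print(f"disease subnetwork decomposed into {summary['n_layers']} layer(s) "
          f"with {summary['n_articulation_proteins']} articulation proteins")

    final = pd.read_csv(Path(tmp) / "run" / "target_intersection.tsv", sep="\t")
    print("final DEP ∩ articulation-protein candidates "
          "(both evidence streams agree):")
    print(final.to_string(index=False))
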