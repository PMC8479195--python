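"""Greedy articulation-points removal and robustness to missing edges.

Plants a chain of protein complexes joined at single shared proteins — the
junctions are the network's articulation points (single points of failure) —
then peels the network layer by layer and checks how stable the articulation
set is when edges are deleted at random.
"""

from melanet import gapr
from melanet.synthetic_data import plant_articulation_structure

graph, truth = plant_articulation_structure([6] * 10, topology="chain")
print(f"planted network: {graph.number_of_nodes()} proteins, "
      f"{graph.number_of_edges()} interactions, {len(truth)} true junctions")

result = gapr.gapr_decompose(graph)
print(f"GAPR: {result.n_layers} layer(s), {len(result.all_aps)} articulation "
      f"proteins, residual giant bicomponent of {len(result.rgb_nodes)} nodes")
print("layer 1 recovers every planted junction:", truth <= result.layers[0])

curve = gapr.robustness_curve(graph, rates=[0.1, 0.3, 0.5], n_reps=20, seed=1)
for _, row in curve.iterrows():
    print(f"  removing {row['rate']:.0%} of edges -> mean AP overlap "
          f"{row['mean_overlap']:.2f} (1.0 = articulation set unchanged)")
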