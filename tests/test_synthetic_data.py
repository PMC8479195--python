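"""Generators: planted structure bookkeeping, determinism, null calibration."""

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from melanet import gapr
from melanet.synthetic_data import (
    ExpressionSimSpec,
    NetworkSimSpec,
    ParameterError,
    ProteomicsSimSpec,
    plant_articulation_structure,
    simulate_expression,
    simulate_interactome,
    simulate_pipeline_bundle,
    simulate_proteomics,
)


class TestSimulateExpression:
    def test_noiseless_shift_is_exact(self):
        sim = simulate_expression(
            ExpressionSimSpec(n_genes=10, n_informative=4, n_control=6,
                              n_case=5, effect_size=2.0, noise_sd=0.0, seed=1)
        )
        expr = sim.expression
        diff = (
            expr.values[expr.case_samples].mean(axis=1)
            - expr.values[expr.control_samples].mean(axis=1)
        )
        assert np.allclose(diff.loc[sim.informative_genes], 2.0)
        rest = diff.drop(sim.informative_genes)
        assert np.allclose(rest, 0.0)

    def test_null_effect_gives_nominal_rejection_rate(self):
        sim = simulate_expression(
            ExpressionSimSpec(n_genes=800, n_informative=10, n_control=40,
                              n_case=30, effect_size=0.0, noise_sd=1.0, seed=5)
        )
        expr = sim.expression
        case = expr.values[expr.case_samples].to_numpy()
        control = expr.values[expr.control_samples].to_numpy()
        p = stats.ttest_ind(case, control, axis=1).pvalue
        rate = float((p < 0.05).mean())
        # binomial SE at n=800 is ~0.008; allow a generous band around 0.05
        assert 0.02 < rate < 0.08

    def test_monte_carlo_shift_matches_spec(self):
        sim = simulate_expression(
            ExpressionSimSpec(n_genes=500, n_informative=20, n_control=40,
                              n_case=30, effect_size=1.5, noise_sd=1.0, seed=7)
        )
        expr = sim.expression
        diff = (
            expr.values.loc[sim.informative_genes, expr.case_samples].mean(axis=1)
            - expr.values.loc[sim.informative_genes, expr.control_samples].mean(axis=1)
        )
        se = np.sqrt((1 / 30 + 1 / 40) / 20)  # SE of the 20-gene average shift
        assert abs(diff.mean() - 1.5) < 3 * se

    def test_deterministic_under_seed(self):
        spec = ExpressionSimSpec(n_genes=20, n_informative=3, seed=9)
        a = simulate_expression(spec)
        b = simulate_expression(spec)
        assert a.expression.values.equals(b.expression.values)
        assert a.informative_genes == b.informative_genes

    @pytest.mark.parametrize(
        "kwargs",
        [dict(n_informative=30, n_genes=20), dict(noise_sd=-1.0),
         dict(n_control=0), dict(n_genes=0)],
    )
    def test_invalid_spec_raises(self, kwargs):
        with pytest.raises(ParameterError):
            ExpressionSimSpec(**kwargs)


class TestSimulateInteractome:
    def test_attachment_one_gives_tree_of_articulation_points(self):
        sim = simulate_interactome(NetworkSimSpec(n_nodes=50, attachment_m=1, seed=2))
        g = sim.graph
        assert nx.is_tree(g)
        non_leaves = {v for v in g if g.degree(v) > 1}
        assert gapr.find_articulation_points(g) == non_leaves

    def test_edge_count_identity(self):
        sim = simulate_interactome(NetworkSimSpec(n_nodes=200, attachment_m=3, seed=4))
        # preferential attachment adds m edges per node beyond the m-node core
        assert sim.graph.number_of_edges() == 3 * (200 - 3)

    def test_connected_and_simple(self):
        sim = simulate_interactome(NetworkSimSpec(n_nodes=300, attachment_m=2, seed=0))
        assert nx.is_connected(sim.graph)
        assert not list(nx.selfloop_edges(sim.graph))

    def test_planted_block_bridges_are_true_aps(self):
        sim = simulate_interactome(
            NetworkSimSpec(n_nodes=60, attachment_m=2, seed=8,
                           planted_blocks=((5, 1), (4, 1), (6, 2)))
        )
        actual = gapr.find_articulation_points(sim.graph)
        assert sim.planted_aps <= actual

    def test_invalid_spec_raises(self):
        with pytest.raises(ParameterError):
            NetworkSimSpec(n_nodes=3, attachment_m=3)


class TestPlantArticulationStructure:
    def test_two_cliques_share_one_cut_vertex(self):
        g, truth = plant_articulation_structure([5, 5], "chain")
        assert len(truth) == 1
        assert g.number_of_nodes() == 9
        assert gapr.brute_force_aps(g) == truth

    def test_single_biconnected_block_has_no_aps(self):
        g, truth = plant_articulation_structure([4], "chain")
        assert truth == set()
        assert gapr.brute_force_aps(g) == set()

    @pytest.mark.parametrize("topology", ["chain", "star"])
    def test_four_blocks_have_three_junctions(self, topology):
        g, truth = plant_articulation_structure([5, 4, 6, 5], topology)
        assert len(truth) == 3
        assert gapr.brute_force_aps(g) == truth

    def test_block_too_small_raises(self):
        with pytest.raises(ParameterError):
            plant_articulation_structure([5, 2], "chain")


class TestSimulateProteomics:
    def test_null_false_positive_rate_near_alpha(self):
        from melanet.proteomics import dep_table, deps_per_contrast

        sim = simulate_proteomics(
            ProteomicsSimSpec(n_proteins=400, n_dep_up=0, n_dep_down=0,
                              noise_cv=0.05, seed=3)
        )
        frame = dep_table(sim.table, [("24h", "0h")])
        n_called = len(deps_per_contrast(frame)["24h_vs_0h"])
        # the joint FC+p filter is stricter than the t-test alone
        assert n_called <= 0.05 * 400 + 3 * np.sqrt(0.05 * 0.95 * 400)

    def test_planted_up_protein_called_up(self):
        from melanet.proteomics import dep_filter, fold_change, t_test

        sim = simulate_proteomics(
            ProteomicsSimSpec(n_proteins=50, n_dep_up=5, n_dep_down=5,
                              noise_cv=0.02, seed=6)
        )
        up = sim.truth.index[sim.truth == "up"][0]
        fc = float(fold_change(sim.table, ("24h", "0h")).loc[up])
        p = t_test(sim.table.replicates("24h").loc[up],
                   sim.table.replicates("0h").loc[up])
        assert dep_filter(fc, p) == "up"

    def test_byte_identical_rerun(self, tmp_path):
        from melanet.proteomics import write_abundance

        spec = ProteomicsSimSpec(n_proteins=30, n_dep_up=3, n_dep_down=3, seed=11)
        for name in ("a.tsv", "b.tsv"):
            write_abundance(simulate_proteomics(spec).table, tmp_path / name)
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    @pytest.mark.parametrize(
        "kwargs",
        [dict(n_dep_up=30, n_dep_down=30, n_proteins=50),
         dict(fc_high=1.2), dict(fc_low=0.8), dict(n_replicates=1)],
    )
    def test_invalid_spec_raises(self, kwargs):
        with pytest.raises(ParameterError):
            ProteomicsSimSpec(**kwargs)


def test_bundle_targets_are_aps_and_deps(tmp_path):
    """The dual-evidence bundle's targets really carry both evidence types."""
    from melanet import data_io
    from melanet.proteomics import dep_table, deps_per_contrast, read_abundance

    bundle = simulate_pipeline_bundle(tmp_path, seed=5)
    graph = data_io.read_scored_edges(bundle.edges_path, min_score=None)
    sub = graph.subgraph(bundle.informative_genes)
    aps = gapr.find_articulation_points(sub)
    assert set(bundle.target_genes) <= aps
    frame = dep_table(read_abundance(bundle.abundance_path),
                      [("24h", "0h"), ("48h", "0h")])
    for contrast_deps in deps_per_contrast(frame).values():
        assert set(bundle.target_genes) <= contrast_deps
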