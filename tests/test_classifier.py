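"""Splits, repeated-CV probabilities, AUC and permutation importance."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from melanet import classifier
from melanet.classifier import RfRunConfig, SplitError
from melanet.data_io import CASE, CONTROL


class TestMakeSplit:
    def test_stratified_40_30_at_ratio_08(self, small_expression):
        # the fixture is 20+15; emulate the 40+30 design explicitly
        from melanet.synthetic_data import ExpressionSimSpec, simulate_expression

        expr = simulate_expression(
            ExpressionSimSpec(n_genes=5, n_informative=1, n_control=40,
                              n_case=30, seed=0)
        ).expression
        split = classifier.make_split(expr, 0.8, seed=1)
        test_labels = expr.labels.loc[list(split.test_sample_ids)]
        assert (test_labels == CONTROL).sum() == 8
        assert (test_labels == CASE).sum() == 6
        assert len(split.train_sample_ids) == 56
        assert not set(split.train_sample_ids) & set(split.test_sample_ids)

    def test_same_seed_same_split(self, small_expression):
        expr = small_expression.expression
        a = classifier.make_split(expr, 0.8, seed=5)
        b = classifier.make_split(expr, 0.8, seed=5)
        assert a == b

    def test_degenerate_ratio_rejected(self, small_expression):
        with pytest.raises(SplitError):
            classifier.make_split(small_expression.expression, 1.0, seed=0)


class TestComputeAuc:
    @pytest.mark.parametrize(
        "scores, labels, expected",
        [
            ([0.9, 0.8, 0.2, 0.1], [CASE, CASE, CONTROL, CONTROL], 1.0),
            ([0.5, 0.5, 0.5, 0.5], [CASE, CASE, CONTROL, CONTROL], 0.5),
            # 3 of the 4 case/control pairs correctly ordered
            ([0.9, 0.4, 0.6, 0.1], [CASE, CASE, CONTROL, CONTROL], 0.75),
        ],
    )
    def test_reference_values(self, scores, labels, expected):
        assert classifier.compute_auc(scores, labels) == pytest.approx(expected)

    def test_pair_counting_matches_trapezoid_roc(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            n = int(rng.integers(6, 40))
            scores = rng.choice(np.round(rng.uniform(0, 1, 8), 2), size=n)
            labels = np.where(rng.uniform(size=n) < 0.5, CASE, CONTROL)
            if len(set(labels)) < 2:
                continue
            ours = classifier.compute_auc(scores, labels)
            sk = roc_auc_score((labels == CASE).astype(int), scores)
            assert ours == pytest.approx(sk, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            classifier.compute_auc([0.1, 0.9], [CASE, CASE])


@pytest.fixture(scope="module")
def trained_separable(separable_expression):
    expr = separable_expression.expression
    split = classifier.make_split(expr, 0.8, seed=2)
    cfg = RfRunConfig(n_trees=60, n_folds=5, n_repeats=2, seed=2)
    probs, ensemble = classifier.train_repeated_cv(expr, split, cfg)
    return expr, split, probs, ensemble


class TestTrainAndPredict:
    def test_separable_training_auc_is_one(self, trained_separable):
        _, _, probs, _ = trained_separable
        assert classifier.compute_auc(probs["p_case"], probs["true"]) == 1.0

    def test_probabilities_normalized_and_label_is_argmax(self, trained_separable):
        _, _, probs, _ = trained_separable
        total = probs["p_case"] + probs["p_control"]
        assert np.allclose(total, 1.0)
        argmax = np.where(probs["p_case"] >= probs["p_control"], CASE, CONTROL)
        # strict argmax except exact ties, which do not occur here
        assert (probs["predicted"] == argmax).all()

    def test_separable_test_accuracy_is_one(self, trained_separable):
        expr, split, _, ensemble = trained_separable
        test_probs = classifier.predict_test(ensemble, expr, split)
        assert (test_probs["predicted"] == test_probs["true"]).all()
        manual_acc = (test_probs["predicted"] == test_probs["true"]).sum() / len(
            test_probs
        )
        assert manual_acc == 1.0

    def test_train_test_overlap_rejected(self, trained_separable):
        expr, split, _, ensemble = trained_separable
        bad = classifier.SplitPlan(
            split.train_sample_ids, split.train_sample_ids[:3], 0.8, 0
        )
        with pytest.raises(SplitError):
            classifier.predict_test(ensemble, expr, bad)

    def test_too_many_folds_rejected(self, separable_expression):
        expr = separable_expression.expression
        split = classifier.make_split(expr, 0.8, seed=2)
        with pytest.raises(SplitError):
            classifier.train_repeated_cv(
                expr, split, RfRunConfig(n_trees=10, n_folds=50, n_repeats=1)
            )


class TestComputeMda:
    def test_planted_gene_ranks_first_and_nulls_near_zero(self, small_expression):
        from melanet.synthetic_data import ExpressionSimSpec, simulate_expression

        sim = simulate_expression(
            ExpressionSimSpec(n_genes=30, n_informative=1, n_control=25,
                              n_case=20, effect_size=4.0, noise_sd=1.0, seed=13)
        )
        expr = sim.expression
        split = classifier.make_split(expr, 0.8, seed=13)
        _, ensemble = classifier.train_repeated_cv(
            expr, split, RfRunConfig(n_trees=200, n_folds=5, n_repeats=1, seed=13)
        )
        imp = classifier.compute_mda(ensemble, expr, split, seed=13)
        assert imp.index[0] == sim.informative_genes[0]
        nulls = imp.drop(sim.informative_genes)
        drops = nulls["mda_raw"] / 100.0
        se = drops.std() / np.sqrt(len(drops))
        assert abs(drops.mean()) < 3 * max(se, 1e-6)

    def test_deterministic_under_seed(self, trained_separable):
        expr, split, _, ensemble = trained_separable
        a = classifier.compute_mda(ensemble, expr, split, seed=1)
        b = classifier.compute_mda(ensemble, expr, split, seed=1)
        assert a.equals(b)


class TestSelectFeatures:
    def _table(self, mdas):
        frame = pd.DataFrame({"mda": mdas, "mda_raw": mdas},
                             index=[f"g{i}" for i in range(len(mdas))])
        frame["rank"] = frame["mda"].rank(ascending=False).astype(int)
        return frame

    def test_strict_threshold_boundary(self):
        table = self._table([1.0, 1.01, 0.5])
        assert classifier.select_features(table, threshold=1.0) == ["g1"]

    def test_threshold_minus_infinity_selects_all(self):
        table = self._table([0.0, -2.0, 5.0])
        assert set(classifier.select_features(table, threshold=-np.inf)) == {
            "g0", "g1", "g2"
        }
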