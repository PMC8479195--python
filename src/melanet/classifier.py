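"""Random-forest case/control discrimination with repeated cross-validation,
aggregated probabilities, AUC and mean-decrease-in-accuracy feature selection.

Design, mirroring the classical randomForest workflow:

* a stratified 8:2 train/test split of the labeled expression matrix;
* 500-tree forests under 10-fold cross-validation, repeated 100 times with
  reshuffled folds; each training sample's out-of-fold class-probability
  vectors are summed over repeats and renormalized ("normalized additive"
  aggregation), the larger class probability giving the predicted label;
* AUC as the Mann–Whitney pair-ordering probability (ties count 1/2);
* permutation importance (MDA) computed on true out-of-bag samples of a
  bagged forest: the drop in OOB accuracy when one gene's values are
  permuted, averaged over trees. Both the raw average (in accuracy
  percentage points) and the z-scaled variant (mean over its standard
  error across trees, the randomForest ``scale=TRUE`` convention) are
  reported; ranking and the default selection threshold of 1 use the
  z-scaled column.

All randomness flows from one master seed through numpy's seed-sequence
spawning, so every stage is reproducible and streams are independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .data_io import CASE, CONTROL, LabeledExpression

MDA_THRESHOLD_DEFAULT = 1.0


class SplitError(ValueError):
    """Raised when a train/test split cannot satisfy its contract."""


def _child_seed(seed: int, *path: int) -> int:
    """Deterministic child seed below 2**31 from a master seed and a path."""
    return int(np.random.SeedSequence([seed, *path]).generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class SplitPlan:
    train_sample_ids: tuple[str, ...]
    test_sample_ids: tuple[str, ...]
    ratio: float
    seed: int
    stratified: bool = True


@dataclass(frozen=True)
class RfRunConfig:
    n_trees: int = 500
    n_folds: int = 10
    n_repeats: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_trees, self.n_folds, self.n_repeats) < 1:
            raise ValueError("all counts must be >= 1")


def make_split(
    expr: LabeledExpression,
    ratio: float = 0.8,
    seed: int = 0,
    stratified: bool = True,
) -> SplitPlan:
    """Stratified random train/test split preserving class proportions.

    With 40 control + 30 case samples at ratio 0.8 the test set holds
    exactly 8 control and 6 case samples.
    """
    if not (0.0 < ratio < 1.0):
        raise SplitError(f"ratio must be in (0,1), got {ratio}")
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    groups = (
        [expr.control_samples, expr.case_samples]
        if stratified
        else [expr.sample_ids]
    )
    for members in groups:
        members = list(members)
        if stratified and not members:
            raise SplitError("both classes must be present")
        order = rng.permutation(len(members))
        n_test = int(round((1.0 - ratio) * len(members)))
        test += [members[i] for i in order[:n_test]]
        train += [members[i] for i in order[n_test:]]
    for side, name in ((train, "training"), (test, "test")):
        labels = set(expr.labels.loc[side]) if side else set()
        if labels != {CONTROL, CASE}:
            raise SplitError(f"{name} set lacks a class (has {sorted(labels)})")
    return SplitPlan(tuple(sorted(train)), tuple(sorted(test)), ratio, seed, stratified)


class ForestEnsemble:
    """Bagged forest of decision trees with explicit OOB bookkeeping.

    Each tree is fit on a bootstrap sample of the training set (sqrt-feature
    subsampling at each split, as in classical random forests); the indices
    left out of each bootstrap are stored so out-of-bag accuracy — and hence
    permutation importance — can be computed exactly.
    """

    def __init__(self, n_trees: int = 500, seed: int = 0):
        self.n_trees = n_trees
        self.seed = seed
        self.trees: list[DecisionTreeClassifier] = []
        self.oob_indices: list[np.ndarray] = []
        self.classes_: np.ndarray | None = None
        self.feature_names: list[str] = []
        self.train_sample_ids: tuple[str, ...] = ()

    def fit(self, X: np.ndarray, y: np.ndarray, feature_names: list[str]) -> "ForestEnsemble":
        n = X.shape[0]
        self.classes_ = np.unique(y)
        self.feature_names = list(feature_names)
        rng = np.random.default_rng(self.seed)
        self.trees, self.oob_indices = [], []
        for t in range(self.n_trees):
            boot = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), boot)
            tree = DecisionTreeClassifier(
                max_features="sqrt",
                random_state=_child_seed(self.seed, 1, t),
            )
            tree.fit(X[boot], y[boot])
            self.trees.append(tree)
            self.oob_indices.append(oob)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        total = np.zeros((X.shape[0], len(self.classes_)))
        for tree in self.trees:
            proba = tree.predict_proba(X)
            # map the tree's class order onto the ensemble's
            for ci, cls in enumerate(tree.classes_):
                total[:, np.searchsorted(self.classes_, cls)] += proba[:, ci]
        return total / self.n_trees


def _probability_table(
    prob_sum: np.ndarray, classes: np.ndarray, sample_ids, true_labels
) -> pd.DataFrame:
    agg = prob_sum / prob_sum.sum(axis=1, keepdims=True)
    case_col = int(np.searchsorted(classes, CASE))
    predicted = [classes[i] for i in np.argmax(agg, axis=1)]
    return pd.DataFrame(
        {
            "p_case": agg[:, case_col],
            "p_control": agg[:, 1 - case_col],
            "predicted": predicted,
            "true": list(true_labels),
        },
        index=list(sample_ids),
    )


def train_repeated_cv(
    expr: LabeledExpression, split: SplitPlan, cfg: RfRunConfig
) -> tuple[pd.DataFrame, ForestEnsemble]:
    """Repeated k-fold CV on the training split plus a final bagged forest.

    Returns the out-of-fold probability table (one row per training sample:
    normalized additive probabilities over all repeats, predicted and true
    labels) and a :class:`ForestEnsemble` fit on the whole training split
    for test-set prediction and MDA.
    """
    train_ids = list(split.train_sample_ids)
    X = expr.values[train_ids].to_numpy().T
    y = expr.labels.loc[train_ids].to_numpy()
    classes = np.unique(y)
    class_counts = pd.Series(y).value_counts()
    if cfg.n_folds > int(class_counts.min()):
        raise SplitError(
            f"n_folds={cfg.n_folds} exceeds the smallest training class "
            f"({int(class_counts.min())})"
        )
    prob_sum = np.zeros((len(train_ids), len(classes)))
    for rep in range(cfg.n_repeats):
        skf = StratifiedKFold(
            n_splits=cfg.n_folds, shuffle=True,
            random_state=_child_seed(cfg.seed, 2, rep),
        )
        for fold, (fit_idx, oof_idx) in enumerate(skf.split(X, y)):
            forest = RandomForestClassifier(
                n_estimators=cfg.n_trees,
                random_state=_child_seed(cfg.seed, 3, rep, fold),
                n_jobs=1,
            )
            forest.fit(X[fit_idx], y[fit_idx])
            proba = forest.predict_proba(X[oof_idx])
            for ci, cls in enumerate(forest.classes_):
                prob_sum[oof_idx, np.searchsorted(classes, cls)] += proba[:, ci]
    table = _probability_table(prob_sum, classes, train_ids, y)
    ensemble = ForestEnsemble(cfg.n_trees, _child_seed(cfg.seed, 4))
    ensemble.fit(X, y, expr.gene_ids)
    ensemble.train_sample_ids = tuple(train_ids)
    return table, ensemble


def predict_test(
    ensemble: ForestEnsemble, expr: LabeledExpression, split: SplitPlan
) -> pd.DataFrame:
    """Aggregated class probabilities and labels for the held-out test set."""
    overlap = set(split.train_sample_ids) & set(split.test_sample_ids)
    if overlap:
        raise SplitError(f"train/test overlap: {sorted(overlap)[:5]}")
    test_ids = list(split.test_sample_ids)
    X = expr.values[test_ids].to_numpy().T
    proba = ensemble.predict_proba(X)
    return _probability_table(
        proba, ensemble.classes_, test_ids, expr.labels.loc[test_ids]
    )


def compute_auc(scores, labels) -> float:
    """AUC as the probability a random case outranks a random control.

    Computed by midrank pair counting (Mann–Whitney U / (n_case·n_control)),
    so ties contribute 1/2; identical to the trapezoidal area under the
    empirical ROC curve.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    is_case = labels == CASE
    n_case, n_control = int(is_case.sum()), int((~is_case).sum())
    if n_case == 0 or n_control == 0:
        raise ValueError("AUC requires both classes")
    ranks = stats.rankdata(scores)
    u = ranks[is_case].sum() - n_case * (n_case + 1) / 2.0
    return float(u / (n_case * n_control))


def compute_mda(
    ensemble: ForestEnsemble,
    expr: LabeledExpression,
    split: SplitPlan,
    seed: int = 0,
) -> pd.DataFrame:
    """Out-of-bag permutation importance per gene.

    For each tree: OOB accuracy minus OOB accuracy after permuting one
    gene's values (a fresh permutation per tree and gene). ``mda_raw`` is
    the per-tree average in accuracy percentage points; ``mda`` is the
    z-scaled variant (mean / SE over trees). Ranking and the ``selected``
    flag (strict threshold 1) use ``mda``.
    """
    train_ids = list(ensemble.train_sample_ids or split.train_sample_ids)
    X = expr.values[train_ids].to_numpy().T
    y = expr.labels.loc[train_ids].to_numpy()
    n_features = X.shape[1]
    rng = np.random.default_rng(seed)
    drops = np.zeros((ensemble.n_trees, n_features))
    for t, (tree, oob) in enumerate(zip(ensemble.trees, ensemble.oob_indices)):
        if len(oob) == 0:
            continue
        X_oob, y_oob = X[oob], y[oob]
        base_acc = float(np.mean(tree.predict(X_oob) == y_oob))
        n_oob = len(oob)
        # one stacked prediction per tree: block g has gene g permuted
        stacked = np.tile(X_oob, (n_features, 1))
        for g in range(n_features):
            stacked[g * n_oob : (g + 1) * n_oob, g] = X_oob[
                rng.permutation(n_oob), g
            ]
        perm_pred = tree.predict(stacked).reshape(n_features, n_oob)
        perm_acc = (perm_pred == y_oob[None, :]).mean(axis=1)
        drops[t] = base_acc - perm_acc
    mean_drop = drops.mean(axis=0)
    se = drops.std(axis=0, ddof=1) / np.sqrt(ensemble.n_trees)
    z = np.divide(
        mean_drop, np.maximum(se, 1e-12),
        out=np.zeros_like(mean_drop), where=(mean_drop != 0) | (se != 0),
    )
    table = pd.DataFrame(
        {"mda": z, "mda_raw": 100.0 * mean_drop}, index=ensemble.feature_names
    )
    order = np.argsort(-table["mda"].to_numpy(), kind="stable")
    ranks = np.empty(n_features, dtype=int)
    ranks[order] = np.arange(1, n_features + 1)
    table["rank"] = ranks
    table["selected"] = table["mda"] > MDA_THRESHOLD_DEFAULT
    return table.sort_values("rank")


def select_features(
    importance: pd.DataFrame,
    threshold: float = MDA_THRESHOLD_DEFAULT,
    column: str = "mda",
) -> list[str]:
    """Genes with importance strictly greater than the threshold, by rank."""
    keep = importance[importance[column] > threshold]
    return list(keep.sort_values("rank").index)
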