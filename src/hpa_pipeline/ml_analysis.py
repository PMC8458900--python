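"""Machine-learning analyses of simulation outputs.

Two analyses mirror the pipeline's study design:

* a CART classification tree over the three stress phenotypes, fitted on the
  16 model parameters plus the 4 post-stress component levels with the
  classes downsampled to equal size, giving an interpretable overview of
  what distinguishes control, low- and high-cortisol individuals;
* a random forest over random-scan treatment records (features: the signed
  delta of the one perturbed parameter, zero elsewhere; target: effective /
  non-effective), whose out-of-bag permutation importance -- scaled so the
  top feature reads 100% -- ranks candidate treatment targets, plus a
  decision tree over the same table whose split thresholds expose the
  direction and rough magnitude of change an effective treatment needs.

Trees and forests are scikit-learn CARTs (Gini impurity); the forest is a
bagging ensemble of depth-unlimited trees with sqrt(p) feature subsampling
at each split, i.e. a classical random forest with public access to each
tree's bootstrap sample for out-of-bag scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import BaggingClassifier
from sklearn.tree import DecisionTreeClassifier

from .model_core import COMPONENTS, PARAM_NAMES
from .protocols import PatientRecord, TreatmentRecord

__all__ = [
    "FeatureTable", "TreeSummary", "TreeNode", "ImportanceReport",
    "build_phenotype_features", "balance_classes", "fit_classification_tree",
    "build_treatment_features", "random_forest_importance",
    "treatment_direction_tree",
]


@dataclass(frozen=True)
class FeatureTable:
    """Feature matrix plus a categorical target, one row per observation."""

    X: pd.DataFrame
    y: pd.Series

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y):
            raise ValueError("X and y must have the same number of rows")
        if self.X.isna().any().any() or self.y.isna().any():
            raise ValueError("feature table must not contain missing values")
        k = self.y.nunique()
        if not 2 <= k <= 3:
            raise ValueError(f"target must have 2 or 3 classes, got {k}")

    def class_counts(self) -> dict[str, int]:
        return self.y.value_counts().to_dict()


@dataclass(frozen=True)
class TreeNode:
    """One node of a fitted CART; leaves have feature = None."""

    node_id: int
    feature: str | None
    threshold: float | None
    counts: dict[str, int]
    majority: str
    depth: int
    left: int | None
    right: int | None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


@dataclass(frozen=True)
class TreeSummary:
    """Interpretable summary of a fitted classification tree."""

    nodes: tuple[TreeNode, ...]
    classes: tuple[str, ...]
    depth: int

    @property
    def root(self) -> TreeNode:
        return self.nodes[0]

    def node(self, node_id: int) -> TreeNode:
        return next(n for n in self.nodes if n.node_id == node_id)

    def splits_on(self, feature: str) -> list[TreeNode]:
        """All split nodes on ``feature``, shallowest first."""
        hits = [n for n in self.nodes if n.feature == feature]
        return sorted(hits, key=lambda n: (n.depth, n.node_id))

    def subtree_class_fraction(self, node_id: int, label: str) -> float:
        counts = self.node(node_id).counts
        total = sum(counts.values())
        return counts.get(label, 0) / total if total else 0.0

    def render(self) -> str:
        """Plain-text rendering, one node per line."""
        lines = []

        def walk(node_id: int) -> None:
            n = self.node(node_id)
            pad = "  " * n.depth
            counts = ", ".join(f"{c}={n.counts.get(c, 0)}"
                               for c in self.classes)
            if n.is_leaf:
                lines.append(f"{pad}leaf: {n.majority} [{counts}]")
            else:
                lines.append(f"{pad}{n.feature} <= {n.threshold:.4g} "
                             f"[{counts}] -> {n.majority}")
                walk(n.left)
                walk(n.right)

        walk(0)
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "node_id": n.node_id, "depth": n.depth, "feature": n.feature,
            "threshold": n.threshold, "majority": n.majority,
            "left": n.left, "right": n.right,
            **{f"n_{c}": n.counts.get(c, 0) for c in self.classes},
        } for n in self.nodes])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TreeSummary":
        classes = tuple(c[2:] for c in df.columns if c.startswith("n_"))
        nodes = []
        for _, r in df.iterrows():
            leaf = pd.isna(r["feature"])
            nodes.append(TreeNode(
                node_id=int(r["node_id"]),
                feature=None if leaf else str(r["feature"]),
                threshold=None if leaf else float(r["threshold"]),
                counts={c: int(r[f"n_{c}"]) for c in classes},
                majority=str(r["majority"]),
                depth=int(r["depth"]),
                left=None if leaf else int(r["left"]),
                right=None if leaf else int(r["right"]),
            ))
        return cls(tuple(nodes), classes, int(df["depth"].max()))


@dataclass(frozen=True)
class ImportanceReport:
    """Permutation importances scaled so the top feature reads 100%."""

    features: tuple[tuple[str, float, float], ...]  # (name, raw, scaled)
    ranking: tuple[str, ...]

    def scaled(self, name: str) -> float:
        for n, _, s in self.features:
            if n == name:
                return s
        raise KeyError(name)

    def top(self, k: int = 2) -> tuple[str, ...]:
        return self.ranking[:k]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features,
                          columns=["feature", "raw_importance",
                                   "scaled_importance"])
        return df.sort_values(["scaled_importance", "feature"],
                              ascending=[False, True],
                              ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ImportanceReport":
        features = tuple((str(r["feature"]), float(r["raw_importance"]),
                          float(r["scaled_importance"]))
                         for _, r in df.iterrows())
        scaled = {n: s for n, _, s in features}
        ranking = tuple(sorted(scaled, key=lambda nm: (-scaled[nm], nm)))
        return cls(features, ranking)


def build_phenotype_features(patients: list[PatientRecord]) -> FeatureTable:
    """Parameters plus post-stress component levels, phenotype as target.

    The 4 component columns are the final-window time-averaged activities
    (the individual's post-stress steady behavior).
    """
    if not patients:
        raise ValueError("no patients to build features from")
    rows = []
    for p in patients:
        row = p.params.to_dict()
        row.update(dict(zip(COMPONENTS, p.post_state_mean)))
        rows.append(row)
    X = pd.DataFrame(rows, columns=list(PARAM_NAMES) + list(COMPONENTS))
    y = pd.Series([p.phenotype.label for p in patients], name="phenotype")
    return FeatureTable(X, y)


def balance_classes(table: FeatureTable, seed: int = 0) -> FeatureTable:
    """Downsample every class (without replacement) to the minority count."""
    counts = table.y.value_counts()
    if (counts == 0).any():
        empty = counts[counts == 0].index.tolist()
        raise ValueError(f"cannot balance: class(es) {empty} have no rows")
    n_min = int(counts.min())
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for cls in sorted(counts.index):
        idx = np.flatnonzero((table.y == cls).to_numpy())
        keep.append(rng.choice(idx, size=n_min, replace=False))
    sel = np.sort(np.concatenate(keep))
    return FeatureTable(table.X.iloc[sel].reset_index(drop=True),
                        table.y.iloc[sel].reset_index(drop=True))


def _summarize_tree(clf: DecisionTreeClassifier, X: pd.DataFrame,
                    y: pd.Series) -> TreeSummary:
    """Extract per-node raw class counts and structure from a fitted CART."""
    tree = clf.tree_
    classes = tuple(str(c) for c in clf.classes_)
    feature_names = list(X.columns)
    # raw counts per node via the decision path (immune to sklearn's
    # internal value normalization / class weighting)
    path = clf.decision_path(X.to_numpy(dtype=np.float32))
    y_codes = pd.Categorical(y, categories=list(classes)).codes
    counts = np.zeros((tree.node_count, len(classes)), dtype=int)
    for c in range(len(classes)):
        counts[:, c] = np.asarray(
            path[y_codes == c].sum(axis=0)).ravel()

    depths = np.zeros(tree.node_count, dtype=int)
    order = [0]
    while order:
        i = order.pop()
        if tree.children_left[i] != -1:
            for child in (tree.children_left[i], tree.children_right[i]):
                depths[child] = depths[i] + 1
                order.append(child)

    nodes = []
    for i in range(tree.node_count):
        leaf = tree.children_left[i] == -1
        cdict = {classes[c]: int(counts[i, c]) for c in range(len(classes))}
        majority = max(sorted(cdict), key=lambda k: cdict[k])
        nodes.append(TreeNode(
            node_id=i,
            feature=None if leaf else feature_names[tree.feature[i]],
            threshold=None if leaf else float(tree.threshold[i]),
            counts=cdict,
            majority=majority,
            depth=int(depths[i]),
            left=None if leaf else int(tree.children_left[i]),
            right=None if leaf else int(tree.children_right[i]),
        ))
    return TreeSummary(tuple(nodes), classes, int(depths.max()))


def fit_classification_tree(table: FeatureTable, max_depth: int = 4,
                            min_leaf: int = 5, seed: int = 0,
                            class_weight: str | None = None) -> TreeSummary:
    """Greedy Gini CART with depth control over a (balanced) feature table."""
    if max_depth < 1:
        raise ValueError(f"max_depth must be >= 1, got {max_depth}")
    clf = DecisionTreeClassifier(criterion="gini", max_depth=max_depth,
                                 min_samples_leaf=min_leaf,
                                 class_weight=class_weight,
                                 random_state=seed)
    clf.fit(table.X.to_numpy(dtype=np.float32), table.y)
    return _summarize_tree(clf, table.X, table.y)


def build_treatment_features(records: list[TreatmentRecord]) -> FeatureTable:
    """Signed parameter deltas (one nonzero column per row) vs outcome.

    The low- and high-cortisol cohorts are analysed separately; mixing
    phenotype classes in one table is an error.
    """
    if not records:
        raise ValueError("no treatment records")
    classes = {r.phenotype.label for r in records}
    if len(classes) > 1:
        raise ValueError(f"records mix phenotype classes {sorted(classes)}; "
                         "analyse each class separately")
    X = pd.DataFrame(0.0, index=range(len(records)),
                     columns=list(PARAM_NAMES))
    for i, r in enumerate(records):
        X.loc[i, r.treatment.target] = r.treatment.delta
    y = pd.Series([r.outcome for r in records], name="outcome")
    return FeatureTable(X, y)


def _tree_predict(est: DecisionTreeClassifier, X32: np.ndarray) -> np.ndarray:
    """Low-overhead class-index prediction via the underlying Cython tree."""
    proba = est.tree_.predict(X32)
    if proba.ndim == 3:          # (n, n_outputs, n_classes)
        proba = proba[:, 0, :]
    return np.argmax(proba, axis=1)


def random_forest_importance(table: FeatureTable, n_trees: int = 500,
                             n_permutations: int = 10,
                             seed: int = 0) -> ImportanceReport:
    """Out-of-bag permutation importance of a random forest, scaled to 100%.

    Each tree is scored on its out-of-bag rows; a feature's raw importance
    is the mean accuracy drop when its column is permuted (``n_permutations``
    independent permutations per tree), averaged over trees.  Negative raw
    importances are floored at zero before scaling the maximum to 100.
    Classes are reweighted inversely to their frequency when fitting, since
    effective treatments are typically the minority.
    """
    if n_trees < 100:
        raise ValueError(f"n_trees must be >= 100, got {n_trees}")
    if table.y.nunique() != 2:
        raise ValueError("random forest importance expects a binary target")

    X = table.X.to_numpy(dtype=np.float32)
    classes = np.array(sorted(table.y.unique()))
    y = np.searchsorted(classes, table.y.to_numpy())
    n, p = X.shape

    forest = BaggingClassifier(
        estimator=DecisionTreeClassifier(max_features="sqrt",
                                         class_weight="balanced"),
        n_estimators=n_trees, bootstrap=True, random_state=seed, n_jobs=1)
    forest.fit(X, y)

    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=seed, spawn_key=(1,)))
    raw = np.zeros(p)
    n_scored = 0
    for est, samp in zip(forest.estimators_, forest.estimators_samples_):
        oob = np.ones(n, dtype=bool)
        oob[samp] = False
        if not oob.any():
            continue
        Xo = np.ascontiguousarray(X[oob])
        yo = y[oob]
        acc0 = float(np.mean(_tree_predict(est, Xo) == yo))
        for j in range(p):
            col = Xo[:, j].copy()
            drop = 0.0
            for _ in range(n_permutations):
                Xo[:, j] = col[rng.permutation(col.size)]
                drop += acc0 - float(np.mean(_tree_predict(est, Xo) == yo))
            Xo[:, j] = col
            raw[j] += drop / n_permutations
        n_scored += 1
    raw /= max(n_scored, 1)

    floored = np.maximum(raw, 0.0)
    top = floored.max()
    scaled = floored / top * 100.0 if top > 0 else floored
    names = list(table.X.columns)
    features = tuple((names[j], float(raw[j]), float(scaled[j]))
                     for j in range(p))
    ranking = tuple(sorted(names, key=lambda nm: (-scaled[names.index(nm)],
                                                  nm)))
    return ImportanceReport(features, ranking)


def treatment_direction_tree(table: FeatureTable,
                             max_depth: int = 4,
                             min_leaf: int = 5,
                             seed: int = 0) -> TreeSummary:
    """CART over treatment deltas vs outcome.

    Split thresholds on a target's delta column expose the direction (and
    rough magnitude) of change that separates effective from non-effective
    treatments; classes are reweighted since effective records are rare.
    """
    return fit_classification_tree(table, max_depth=max_depth,
                                   min_leaf=min_leaf, seed=seed,
                                   class_weight="balanced")
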