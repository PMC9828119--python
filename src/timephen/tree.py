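"""CART surrogate: map intra-tumoral single-marker densities to phenotypes.

Screens whether the immune phenotypes (discovered from the full multiplex
feature set) can be recovered from the handful of intra-tumoral measurements
a single-marker IHC workflow provides: CD8, CD68, FOXP3 and tumor-cell
PD-L1 densities.  Splits are grown greedily on Gini impurity (min leaf 5,
max depth 5), then pruned rpart-style: a subtree is collapsed unless it
reduces the resubstitution misclassification risk by at least
``cp x R(root)`` per additional leaf (default cp = 0.01).  Per-class
resubstitution precision is reported; a simplified variant restricted to
CD8 and PD-L1 mirrors a minimal two-marker triage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

SURROGATE_FEATURES = (
    "density_cd8_tumor",
    "density_cd68_tumor",
    "density_foxp3_tumor",
    "density_ck_pdl1_tumor",
)
SIMPLIFIED_FEATURES = ("density_cd8_tumor", "density_ck_pdl1_tumor")


@dataclass
class _Node:
    counts: np.ndarray  # per-class training counts reaching this node
    feature: int = -1
    threshold: float = float("nan")
    left: "_Node | None" = None
    right: "_Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    @property
    def label_index(self) -> int:
        return int(np.argmax(self.counts))

    @property
    def risk(self) -> float:  # misclassified count if this node were a leaf
        return float(self.counts.sum() - self.counts.max())


def _extract(t, i: int) -> _Node:
    node = _Node(counts=t.value[i][0] * t.weighted_n_node_samples[i])
    # sklearn normalizes value; recover counts from weighted sample counts
    node.counts = np.round(t.value[i][0] * t.weighted_n_node_samples[i])
    if t.children_left[i] != -1:
        node.feature = int(t.feature[i])
        node.threshold = float(t.threshold[i])
        node.left = _extract(t, t.children_left[i])
        node.right = _extract(t, t.children_right[i])
    return node


def _prune(node: _Node, min_gain: float) -> tuple[float, int]:
    """Bottom-up weakest-link pruning; returns (subtree risk, leaf count)."""
    if node.is_leaf:
        return node.risk, 1
    risk_l, leaves_l = _prune(node.left, min_gain)
    risk_r, leaves_r = _prune(node.right, min_gain)
    subtree_risk = risk_l + risk_r
    leaves = leaves_l + leaves_r
    # collapse unless the subtree buys >= min_gain risk reduction per extra leaf
    if node.risk - subtree_risk < min_gain * (leaves - 1):
        node.left = node.right = None
        node.feature = -1
        node.threshold = float("nan")
        return node.risk, 1
    return subtree_risk, leaves


@dataclass
class SurrogateTree:
    root: _Node
    feature_names: tuple[str, ...]
    classes: tuple[str, ...]
    min_leaf: int
    max_depth: int
    cp: float
    precision_mode: str = "resubstitution"
    flags: list[str] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        def count(n: _Node) -> int:
            return 1 if n.is_leaf else count(n.left) + count(n.right)

        return count(self.root)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        X = table[list(self.feature_names)].to_numpy(dtype=float)
        out = np.empty(len(X), dtype=object)
        for i, row in enumerate(X):
            node = self.root
            while not node.is_leaf:
                node = node.left if row[node.feature] <= node.threshold else node.right
            out[i] = self.classes[node.label_index]
        return out.astype(str)

    def to_json(self) -> dict:
        def node(n: _Node) -> dict:
            if n.is_leaf:
                return {
                    "leaf": True,
                    "label": self.classes[n.label_index],
                    "class_counts": dict(zip(self.classes, n.counts.astype(int).tolist())),
                }
            return {
                "leaf": False,
                "feature": self.feature_names[n.feature],
                "threshold": n.threshold,
                "left": node(n.left),
                "right": node(n.right),
            }

        return {
            "params": {"min_leaf": self.min_leaf, "max_depth": self.max_depth, "cp": self.cp},
            "precision_mode": self.precision_mode,
            "tree": node(self.root),
        }

    def to_text(self) -> str:
        lines: list[str] = []

        def walk(n: _Node, indent: str):
            if n.is_leaf:
                lines.append(f"{indent}-> {self.classes[n.label_index]} {n.counts.astype(int).tolist()}")
                return
            name = self.feature_names[n.feature]
            lines.append(f"{indent}{name} <= {n.threshold:.2f}")
            walk(n.left, indent + "  ")
            lines.append(f"{indent}{name} >  {n.threshold:.2f}")
            walk(n.right, indent + "  ")

        walk(self.root, "")
        return "\n".join(lines)


def fit_cart(
    table: pd.DataFrame,
    labels,
    features: tuple[str, ...] = SURROGATE_FEATURES,
    min_leaf: int = 5,
    max_depth: int = 5,
    cp: float = 0.01,
) -> SurrogateTree:
    """Greedy Gini recursive partitioning with rpart-style relative pruning.

    ``cp`` is relative to the root misclassification risk: a split survives
    only if its subtree removes at least ``cp * R(root)`` misclassified
    training points per additional leaf.  Deterministic given the data.
    Single-class input yields a trivial one-leaf tree with a warning.
    """
    y = np.asarray(labels).astype(str)
    flags: list[str] = []
    if len(np.unique(y)) < 2:
        warnings.warn("single-class labels; fitting a trivial one-leaf tree")
        flags.append("single_class")
    X = table[list(features)].to_numpy(dtype=float)
    est = DecisionTreeClassifier(
        criterion="gini",
        min_samples_leaf=min_leaf,
        max_depth=max_depth,
        random_state=0,
    )
    est.fit(X, y)
    root = _extract(est.tree_, 0)
    root_risk = root.risk
    if root_risk > 0 and cp > 0:
        _prune(root, min_gain=cp * root_risk)
    return SurrogateTree(
        root=root,
        feature_names=tuple(features),
        classes=tuple(str(c) for c in est.classes_),
        min_leaf=min_leaf,
        max_depth=max_depth,
        cp=cp,
        flags=flags,
    )


def simplified_tree(table: pd.DataFrame, labels, **params) -> SurrogateTree:
    """Two-marker triage tree restricted to intra-tumoral CD8 and PD-L1."""
    return fit_cart(table, labels, features=SIMPLIFIED_FEATURES, **params)


def per_class_precision(tree: SurrogateTree, table: pd.DataFrame, labels) -> dict[str, float]:
    """TP / (TP + FP) of the tree's predictions per class.

    Classes the tree never predicts get NaN precision (flagged by absence of
    any predicted positives), never 0.
    """
    y = np.asarray(labels).astype(str)
    pred = tree.predict(table)
    out: dict[str, float] = {}
    for cls in np.unique(y):
        predicted = pred == cls
        if not predicted.any():
            out[str(cls)] = float("nan")
            continue
        out[str(cls)] = float((y[predicted] == cls).mean())
    return out
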