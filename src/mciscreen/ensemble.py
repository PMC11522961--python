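"""Bagged ensemble of small decision trees for binary screening.

The classifier is deliberately simple: an odd number of shallow CART trees,
each trained on a with-replacement resample of 25% of the training set, and
combined by summing their 0/1 votes (Healthy = 0, MCI = 1).  A case is
labelled MCI when the vote sum reaches the decision threshold ``th``.

The induction here is hand-written CART (Gini impurity, axis-aligned
``<= threshold`` splits at midpoints between observed values) because the
missing-data policy is part of the contract: candidate splits on a feature
are evaluated on the cases where that feature is present, no value is ever
imputed, and at prediction time a tree whose path reaches a missing score
abstains (``INACTIVE``) instead of guessing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import train_test_split

from .schema import BatterySchema, SubjectRecord

__all__ = [
    "INACTIVE",
    "CLASS_ENCODING",
    "TreeNode",
    "DecisionTreeModel",
    "EnsembleConfig",
    "EnsembleModel",
    "split_train_test",
    "bootstrap_subsets",
    "induce_tree",
    "train_ensemble",
    "tree_predict",
    "ensemble_votes",
    "majority_threshold",
]

#: Vote value of a tree that could not traverse to a leaf (missing score).
INACTIVE = None

#: Numeric class encoding used throughout (votes must be summable).
CLASS_ENCODING = {"Healthy": 0, "MCI": 1}


@dataclass
class TreeNode:
    """Binary tree node: either an internal split or a leaf.

    Internal nodes route ``score <= threshold`` to the left child and
    ``score > threshold`` to the right child.  Leaves carry the majority
    class, the fraction of MCI training cases (``probability``) and the
    number of training cases that reached them (``support``).
    """

    test_id: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    class_label: int | None = None
    probability: float | None = None
    support: int | None = None

    @property
    def is_leaf(self) -> bool:
        return self.test_id is None

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {
                "leaf": True,
                "class_label": int(self.class_label),
                "probability": float(self.probability),
                "support": int(self.support),
            }
        return {
            "leaf": False,
            "test_id": self.test_id,
            "threshold": float(self.threshold),
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        if d["leaf"]:
            return cls(
                class_label=int(d["class_label"]),
                probability=float(d["probability"]),
                support=int(d["support"]),
            )
        return cls(
            test_id=d["test_id"],
            threshold=float(d["threshold"]),
            left=cls.from_dict(d["left"]),
            right=cls.from_dict(d["right"]),
        )


@dataclass
class DecisionTreeModel:
    """One tree of the ensemble, identified by its index."""

    tree_index: int
    root: TreeNode

    @property
    def feature_set(self) -> frozenset[str]:
        feats: set[str] = set()
        stack = [self.root]
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                feats.add(node.test_id)
                stack.extend((node.left, node.right))
        return frozenset(feats)

    def leaves(self) -> list[tuple[list[tuple[str, str, float]], TreeNode]]:
        """Root-to-leaf paths as (conditions, leaf) pairs, left-first order.

        Each condition is ``(test_id, op, threshold)`` with op one of
        ``lessThanOrEqual`` (left branch) / ``greaterThan`` (right branch).
        """
        out: list[tuple[list[tuple[str, str, float]], TreeNode]] = []

        def walk(node: TreeNode, conds: list[tuple[str, str, float]]) -> None:
            if node.is_leaf:
                out.append((conds, node))
                return
            walk(node.left, conds + [(node.test_id, "lessThanOrEqual", node.threshold)])
            walk(node.right, conds + [(node.test_id, "greaterThan", node.threshold)])

        walk(self.root, [])
        return out


@dataclass(frozen=True)
class EnsembleConfig:
    """Training configuration; defaults reproduce the screening setup
    (11 trees, 80/20 split, 25% bootstrap subsets)."""

    n_trees: int = 11
    train_fraction: float = 0.8
    subset_fraction: float = 0.25
    max_depth: int = 4
    min_leaf: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 3 or self.n_trees % 2 == 0:
            raise ValueError(
                f"n_trees must be odd and >= 3 to avoid voting ties, got {self.n_trees}"
            )
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError(f"train_fraction must be in (0, 1), got {self.train_fraction}")
        if not 0.0 < self.subset_fraction <= 1.0:
            raise ValueError(f"subset_fraction must be in (0, 1], got {self.subset_fraction}")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")


@dataclass
class EnsembleModel:
    """A trained odd-count tree ensemble with its decision threshold."""

    battery_id: str
    trees: list[DecisionTreeModel]
    threshold: int
    config: EnsembleConfig
    class_encoding: dict[str, int] = field(default_factory=lambda: dict(CLASS_ENCODING))

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def to_json(self) -> str:
        doc = {
            "battery_id": self.battery_id,
            "class_encoding": self.class_encoding,
            "threshold": int(self.threshold),
            "config": asdict(self.config),
            "trees": [
                {"tree_index": t.tree_index, "root": t.root.to_dict()}
                for t in self.trees
            ],
        }
        return json.dumps(doc, indent=2, sort_keys=False) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "EnsembleModel":
        doc = json.loads(text)
        return cls(
            battery_id=doc["battery_id"],
            trees=[
                DecisionTreeModel(t["tree_index"], TreeNode.from_dict(t["root"]))
                for t in doc["trees"]
            ],
            threshold=int(doc["threshold"]),
            config=EnsembleConfig(**doc["config"]),
            class_encoding=dict(doc["class_encoding"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "EnsembleModel":
        return cls.from_json(Path(path).read_text())


def majority_threshold(n_trees: int) -> int:
    """Smallest vote sum that is a strict majority (6 for 11 trees)."""
    return n_trees // 2 + 1


# ---------------------------------------------------------------------------
# data partitioning
# ---------------------------------------------------------------------------

def split_train_test(
    records: Sequence[SubjectRecord],
    train_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[list[SubjectRecord], list[SubjectRecord]]:
    """Deterministic stratified train/test partition of labeled records."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    records = list(records)
    if len(records) < 2:
        raise ValueError("need at least 2 labeled records to split")
    labels = [r.gold_label for r in records]
    if any(lab is None for lab in labels):
        raise ValueError("all records must carry a gold label to split")
    # stratify unless a class is too small for sklearn to honour it
    counts = {lab: labels.count(lab) for lab in set(labels)}
    stratify = labels if len(counts) > 1 and min(counts.values()) >= 2 else None
    idx = np.arange(len(records))
    train_idx, test_idx = train_test_split(
        idx, train_size=train_fraction, random_state=seed, stratify=stratify
    )
    train = [records[i] for i in sorted(train_idx)]
    test = [records[i] for i in sorted(test_idx)]
    return train, test


def bootstrap_subsets(
    train: Sequence[SubjectRecord],
    n_trees: int = 11,
    subset_fraction: float = 0.25,
    seed: int = 0,
) -> list[list[SubjectRecord]]:
    """Draw one with-replacement resample per tree, all of the same size."""
    train = list(train)
    if not train:
        raise ValueError("training set is empty")
    if n_trees % 2 == 0:
        raise ValueError(
            f"n_trees must be odd so that ensemble votes cannot tie, got {n_trees}"
        )
    size = max(1, int(round(subset_fraction * len(train))))
    rng = np.random.default_rng(seed)
    return [
        [train[i] for i in rng.integers(0, len(train), size)] for _ in range(n_trees)
    ]


# ---------------------------------------------------------------------------
# CART induction
# ---------------------------------------------------------------------------

def _gini(n1: float, n: float) -> float:
    if n <= 0:
        return 0.0
    p = n1 / n
    return 2.0 * p * (1.0 - p)


def _best_split(
    X: np.ndarray, y: np.ndarray, min_leaf: int
) -> tuple[int, float] | None:
    """Best (feature, midpoint threshold) by Gini gain on complete cases.

    The gain on a feature is computed over the cases where the feature is
    present and scaled by the fraction of node cases that are complete for
    it, so features with more missing values must earn their keep.  Ties go
    to the lower feature index, then the lower threshold.
    """
    n_node = len(y)
    best: tuple[float, int, float] | None = None
    for j in range(X.shape[1]):
        col = X[:, j]
        mask = ~np.isnan(col)
        m = int(mask.sum())
        if m < 2 * min_leaf:
            continue
        xs = col[mask]
        ys = y[mask]
        order = np.argsort(xs, kind="stable")
        xs = xs[order]
        ys = ys[order]
        cum1 = np.cumsum(ys)
        total1 = cum1[-1]
        parent = _gini(total1, m)
        # candidate split after position k (1..m-1) where the value changes
        for k in range(min_leaf, m - min_leaf + 1):
            if k > m - 1 or xs[k] == xs[k - 1]:
                continue
            left1 = cum1[k - 1]
            g = (
                parent
                - (k / m) * _gini(left1, k)
                - ((m - k) / m) * _gini(total1 - left1, m - k)
            )
            score = g * (m / n_node)
            if score <= 1e-12:
                continue
            thr = (xs[k - 1] + xs[k]) / 2.0
            if best is None or score > best[0] + 1e-12:
                best = (score, j, thr)
    if best is None:
        return None
    return best[1], best[2]


def _leaf(y: np.ndarray) -> TreeNode:
    n = len(y)
    n1 = int(y.sum())
    # equal counts predict Healthy: the ensemble, not one leaf, decides MCI
    label = 1 if 2 * n1 > n else 0
    return TreeNode(class_label=label, probability=n1 / n, support=n)


def induce_tree(
    sample: Sequence[SubjectRecord],
    schema: BatterySchema,
    config: EnsembleConfig,
    tree_index: int = 0,
) -> DecisionTreeModel:
    """Grow one CART tree on a bootstrap sample.

    Missing scores never block training: each candidate split is scored on
    the cases where its feature is present, and cases missing the chosen
    split feature are set aside at that node.
    """
    sample = list(sample)
    if not sample:
        raise ValueError("cannot induce a tree from an empty sample")
    if any(r.gold_label is None for r in sample):
        raise ValueError("all training records must carry a gold label")
    feats = list(schema.test_ids)
    X = np.full((len(sample), len(feats)), np.nan)
    for i, r in enumerate(sample):
        for j, f in enumerate(feats):
            if f in r.scores:
                X[i, j] = r.scores[f]
    y = np.array([r.gold_label for r in sample], dtype=int)
    root = _grow_named(X, y, 0, config, feats)
    return DecisionTreeModel(tree_index=tree_index, root=root)


def _grow_named(
    X: np.ndarray,
    y: np.ndarray,
    depth: int,
    config: EnsembleConfig,
    feats: list[str],
) -> TreeNode:
    if depth >= config.max_depth or len(y) < 2 * config.min_leaf or y.min() == y.max():
        return _leaf(y)
    split = _best_split(X, y, config.min_leaf)
    if split is None:
        return _leaf(y)
    j, thr = split
    col = X[:, j]
    present = ~np.isnan(col)
    left = present & (col <= thr)
    right = present & (col > thr)
    return TreeNode(
        test_id=feats[j],
        threshold=float(thr),
        left=_grow_named(X[left], y[left], depth + 1, config, feats),
        right=_grow_named(X[right], y[right], depth + 1, config, feats),
    )


def train_ensemble(
    records: Sequence[SubjectRecord],
    schema: BatterySchema,
    config: EnsembleConfig | None = None,
) -> EnsembleModel:
    """Train the full bagged ensemble on (already split) training records.

    The decision threshold is initialised to the strict majority
    (``n_trees // 2 + 1``); threshold tuning via F-beta curves replaces it
    afterwards (see :mod:`mciscreen.metrics`).
    """
    config = config or EnsembleConfig()
    records = list(records)
    if len(records) < config.min_leaf:
        raise ValueError(
            f"need at least min_leaf={config.min_leaf} labeled records, got {len(records)}"
        )
    samples = bootstrap_subsets(
        records, config.n_trees, config.subset_fraction, seed=config.seed
    )
    trees = [
        induce_tree(sample, schema, config, tree_index=i)
        for i, sample in enumerate(samples)
    ]
    return EnsembleModel(
        battery_id=schema.battery_id,
        trees=trees,
        threshold=majority_threshold(config.n_trees),
        config=config,
    )


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def tree_predict(tree: DecisionTreeModel | TreeNode, record: SubjectRecord):
    """Traverse one tree; return 0, 1, or :data:`INACTIVE`.

    The tree abstains (returns ``INACTIVE``) as soon as the traversed path
    needs a score the record does not have — a missing feature elsewhere in
    the tree is irrelevant.
    """
    node = tree.root if isinstance(tree, DecisionTreeModel) else tree
    while not node.is_leaf:
        value = record.scores.get(node.test_id)
        if value is None:
            return INACTIVE
        node = node.left if value <= node.threshold else node.right
    return node.class_label


def ensemble_votes(model: EnsembleModel, record: SubjectRecord) -> list:
    """Direct-traversal votes for every tree (the rule engine's oracle)."""
    return [tree_predict(t, record) for t in model.trees]
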