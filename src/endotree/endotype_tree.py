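"""Information-gain decision tree over metagene scores.

Greedy recursive partitioning of subjects on thresholded metagene scores,
maximizing reduction in Shannon entropy of the binary disease label under
a minimum-leaf-size constraint.  No pruning: the leaf-size floor and a
gain epsilon are the only stopping rules.  Includes resubstitution and
bootstrap evaluation of a fitted tree, plus text/JSON/DOT export.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_model import PipelineConfig, ValidationError
from .metagene import MetageneSet

logger = logging.getLogger(__name__)

__all__ = [
    "TreeNode",
    "DecisionTreeModel",
    "SegregationReport",
    "entropy",
    "info_gain",
    "best_split",
    "grow_tree",
    "evaluate_segregation",
    "bootstrap_evaluate",
    "agreement",
    "export_tree_json",
    "export_tree_dot",
    "export_tree_text",
    "tree_from_json",
]

LABEL_NAMES = {0: "non_asthmatic", 1: "asthmatic"}


@dataclass
class TreeNode:
    """Internal node (feature/threshold/children) or leaf (class counts)."""

    leaf_id: int | None = None
    counts: tuple[int, int] | None = None  # (non_asthmatic, asthmatic)
    feature: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def majority_label(self) -> int:
        # tie -> non_asthmatic (label 0)
        n0, n1 = self.counts
        return 1 if n1 > n0 else 0

    @property
    def n_subjects(self) -> int:
        return sum(self.counts)


@dataclass
class DecisionTreeModel:
    root: TreeNode
    feature_names: list[str]
    n_subjects: int
    min_leaf: int
    gain_epsilon: float

    def leaves(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                out.append(node)
            else:
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return out

    def n_nodes(self) -> int:
        count = 0
        stack = [self.root]
        while stack:
            node = stack.pop()
            count += 1
            if not node.is_leaf:
                stack.extend([node.left, node.right])
        return count

    def route(self, scores: pd.DataFrame) -> np.ndarray:
        """Leaf id per row of a subject x metagene score frame."""
        out = np.empty(len(scores), dtype=int)
        X = scores[self.feature_names].to_numpy()
        cols = {f: j for j, f in enumerate(self.feature_names)}
        for i in range(X.shape[0]):
            node = self.root
            while not node.is_leaf:
                node = node.left if X[i, cols[node.feature]] <= node.threshold else node.right
            out[i] = node.leaf_id
        return out

    def predict(self, scores: pd.DataFrame) -> np.ndarray:
        """Majority-label prediction (1 = asthmatic) per subject."""
        leaf_label = {leaf.leaf_id: leaf.majority_label for leaf in self.leaves()}
        return np.array([leaf_label[i] for i in self.route(scores)], dtype=int)


@dataclass
class SegregationReport:
    overall_accuracy: float  # percent
    group_counts: tuple[int, int]  # (asthmatic leaves, non-asthmatic leaves)
    per_leaf: pd.DataFrame  # leaf_id, majority_label, pct_correct, n
    bootstrap: dict | None = None
    agreement_pct: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return self.per_leaf


def entropy(counts) -> float:
    """Shannon entropy in bits of a label-count vector, with 0*log0 = 0."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValidationError("counts must be non-negative")
    total = counts.sum()
    if total == 0:
        raise ValidationError("entropy undefined for all-zero counts")
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def info_gain(scores: np.ndarray, labels: np.ndarray, threshold: float) -> float:
    """Entropy reduction of splitting at score <= threshold vs > threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    left = scores <= threshold
    n_l, n_r = int(left.sum()), int((~left).sum())
    if n_l == 0 or n_r == 0:
        raise ValidationError("both sides of a split must be non-empty")
    n = n_l + n_r
    h_parent = entropy(np.bincount(labels, minlength=2))
    h_l = entropy(np.bincount(labels[left], minlength=2))
    h_r = entropy(np.bincount(labels[~left], minlength=2))
    return h_parent - (n_l / n) * h_l - (n_r / n) * h_r


def best_split(
    scores: np.ndarray,
    labels: np.ndarray,
    min_leaf: int,
    gain_epsilon: float = 1e-6,
) -> tuple[float, float] | None:
    """Max-gain threshold over midpoints of consecutive distinct scores.

    Only splits leaving at least ``min_leaf`` subjects on each side are
    admissible; ties in gain break towards the smaller threshold.  Returns
    (threshold, gain) or None if no admissible split gains more than
    ``gain_epsilon``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n = scores.size
    if n < 2 * min_leaf:
        return None
    order = np.argsort(scores, kind="stable")
    s, y = scores[order], labels[order]

    # prefix label counts; candidate cut after position i (1-based count)
    ones = np.cumsum(y)
    total1 = int(ones[-1])
    total0 = n - total1

    h_parent = entropy((total0, total1))
    best: tuple[float, float] | None = None
    for i in range(min_leaf, n - min_leaf + 1):
        if s[i - 1] == s[i]:
            continue  # not a boundary between distinct values
        n_l = i
        n_r = n - i
        l1 = int(ones[i - 1])
        l0 = n_l - l1
        r1 = total1 - l1
        r0 = total0 - l0
        gain = h_parent - (n_l / n) * entropy((l0, l1)) - (n_r / n) * entropy((r0, r1))
        thr = (s[i - 1] + s[i]) / 2.0
        if best is None or gain > best[1] + 1e-15:
            best = (thr, gain)
    if best is None or best[1] <= gain_epsilon:
        return None
    return best


def grow_tree(
    metagenes: MetageneSet | pd.DataFrame,
    labels: np.ndarray,
    config: PipelineConfig | None = None,
    min_leaf: int | None = None,
    gain_epsilon: float | None = None,
) -> DecisionTreeModel:
    """Fit the greedy information-gain tree on metagene scores.

    At each node the (metagene, threshold) pair with the largest gain is
    chosen subject to the min-leaf constraint; growth stops when the node
    is pure or no admissible split improves gain beyond the epsilon.
    Tie-breaking: smaller threshold, then lexicographically first metagene
    name.  Deterministic given inputs.
    """
    scores = metagenes.score_frame() if isinstance(metagenes, MetageneSet) else metagenes
    labels = np.asarray(labels, dtype=int)
    if len(scores) != labels.size:
        raise ValidationError("label vector length must match score rows")
    if not np.all(np.isin(labels, [0, 1])):
        raise ValidationError("labels must be binary 0/1")
    config = config or PipelineConfig()
    if min_leaf is None:
        min_leaf = config.effective_min_leaf(labels.size)
    if gain_epsilon is None:
        gain_epsilon = config.gain_epsilon
    if labels.size < 2 * min_leaf:
        raise ValidationError(
            f"need at least 2*min_leaf={2 * min_leaf} labeled subjects, got {labels.size}"
        )

    features = sorted(scores.columns)
    X = scores[features].to_numpy()
    next_leaf = [0]

    def build(idx: np.ndarray) -> TreeNode:
        y = labels[idx]
        counts = (int((y == 0).sum()), int((y == 1).sum()))
        pure = counts[0] == 0 or counts[1] == 0
        chosen: tuple[float, float, str] | None = None  # (gain, threshold, feature)
        if not pure and idx.size >= 2 * min_leaf:
            for j, fname in enumerate(features):
                res = best_split(X[idx, j], y, min_leaf, gain_epsilon)
                if res is None:
                    continue
                thr, gain = res
                if (
                    chosen is None
                    or gain > chosen[0] + 1e-12
                    or (abs(gain - chosen[0]) <= 1e-12 and thr < chosen[1])
                ):
                    chosen = (gain, thr, fname)
        if chosen is None:
            leaf = TreeNode(leaf_id=next_leaf[0], counts=counts)
            next_leaf[0] += 1
            return leaf
        gain, thr, fname = chosen
        j = features.index(fname)
        go_left = X[idx, j] <= thr
        node = TreeNode(feature=fname, threshold=float(thr), counts=counts)
        node.left = build(idx[go_left])
        node.right = build(idx[~go_left])
        return node

    root = build(np.arange(labels.size))
    return DecisionTreeModel(root, features, int(labels.size), int(min_leaf), float(gain_epsilon))


def evaluate_segregation(
    tree: DecisionTreeModel,
    metagenes: MetageneSet | pd.DataFrame,
    labels: np.ndarray,
) -> SegregationReport:
    """Route subjects through the tree, scoring leaf-majority agreement.

    A leaf's label is the majority of the subjects routed to it (ties go
    to non_asthmatic); overall accuracy is the share of subjects whose
    own label matches their leaf's.
    """
    scores = metagenes.score_frame() if isinstance(metagenes, MetageneSet) else metagenes
    labels = np.asarray(labels, dtype=int)
    leaf_ids = tree.route(scores)
    rows = []
    n_correct = 0
    asthmatic_leaves = non_leaves = 0
    for leaf in sorted(set(leaf_ids)):
        mask = leaf_ids == leaf
        y = labels[mask]
        n0, n1 = int((y == 0).sum()), int((y == 1).sum())
        if n1 > n0:
            majority, correct = 1, n1
            asthmatic_leaves += 1
        else:
            majority, correct = 0, n0
            non_leaves += 1
            if n1 == n0 and n1 > 0:
                logger.info("leaf %d tie broken towards non_asthmatic", leaf)
        n_correct += correct
        rows.append((leaf, LABEL_NAMES[majority], 100.0 * correct / (n0 + n1), n0 + n1))
    per_leaf = pd.DataFrame(rows, columns=["leaf_id", "majority_label", "pct_correct", "n"])
    overall = 100.0 * n_correct / labels.size
    return SegregationReport(overall, (asthmatic_leaves, non_leaves), per_leaf)


def bootstrap_evaluate(
    tree: DecisionTreeModel,
    metagenes: MetageneSet | pd.DataFrame,
    labels: np.ndarray,
    B: int = 10000,
    seed: int | None = None,
) -> dict:
    """Accuracy distribution of the FIXED tree over B subject resamples.

    Each bootstrap sample draws subjects with replacement and is routed
    through the already-fitted tree (no refitting); accuracy is measured
    against the resampled labels using the training leaf majorities.
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    scores = metagenes.score_frame() if isinstance(metagenes, MetageneSet) else metagenes
    labels = np.asarray(labels, dtype=int)
    preds = tree.predict(scores)
    correct = (preds == labels).astype(float)
    rng = np.random.default_rng(seed)
    n = labels.size
    acc = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        acc[b] = correct[idx].mean()
    return {
        "B": B,
        "mean": float(acc.mean()),
        "sd": float(acc.std(ddof=1)) if B > 1 else 0.0,
        "pct_2.5": float(np.percentile(acc, 2.5)),
        "pct_97.5": float(np.percentile(acc, 97.5)),
    }


def agreement(assign_a: np.ndarray, assign_b: np.ndarray) -> float:
    """Percent of subjects with identical binary calls in both assignments."""
    a = np.asarray(assign_a)
    b = np.asarray(assign_b)
    if a.shape != b.shape or a.size == 0:
        raise ValidationError("assignments must cover the same non-empty subject set")
    return float(100.0 * np.mean(a == b))


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------


def _node_to_dict(node: TreeNode) -> dict:
    if node.is_leaf:
        return {"leaf_id": node.leaf_id, "counts": list(node.counts)}
    return {
        "feature": node.feature,
        "threshold": node.threshold,
        "counts": list(node.counts) if node.counts else None,
        "left": _node_to_dict(node.left),
        "right": _node_to_dict(node.right),
    }


def _node_from_dict(d: dict) -> TreeNode:
    if "feature" not in d or d.get("feature") is None:
        if "leaf_id" not in d:
            raise ValidationError("leaf node JSON must carry leaf_id")
        return TreeNode(leaf_id=int(d["leaf_id"]), counts=tuple(d["counts"]))
    for key in ("threshold", "left", "right"):
        if d.get(key) is None:
            raise ValidationError(f"internal node JSON missing {key!r}")
    node = TreeNode(
        feature=str(d["feature"]),
        threshold=float(d["threshold"]),
        counts=tuple(d["counts"]) if d.get("counts") else None,
    )
    node.left = _node_from_dict(d["left"])
    node.right = _node_from_dict(d["right"])
    return node


def export_tree_json(tree: DecisionTreeModel) -> str:
    return json.dumps(
        {
            "feature_names": tree.feature_names,
            "n_subjects": tree.n_subjects,
            "min_leaf": tree.min_leaf,
            "gain_epsilon": tree.gain_epsilon,
            "root": _node_to_dict(tree.root),
        },
        indent=2,
    )


def tree_from_json(text: str) -> DecisionTreeModel:
    d = json.loads(text)
    return DecisionTreeModel(
        _node_from_dict(d["root"]),
        list(d["feature_names"]),
        int(d["n_subjects"]),
        int(d["min_leaf"]),
        float(d["gain_epsilon"]),
    )


def export_tree_dot(tree: DecisionTreeModel) -> str:
    lines = ["digraph endotype_tree {", "  node [shape=box];"]
    counter = [0]

    def walk(node: TreeNode) -> int:
        nid = counter[0]
        counter[0] += 1
        if node.is_leaf:
            n0, n1 = node.counts
            lines.append(
                f'  n{nid} [label="leaf {node.leaf_id}\\n{LABEL_NAMES[node.majority_label]}'
                f'\\n(non={n0}, asth={n1})"];'
            )
        else:
            lines.append(f'  n{nid} [label="{node.feature} <= {node.threshold:.4g}"];')
            lid = walk(node.left)
            rid = walk(node.right)
            lines.append(f'  n{nid} -> n{lid} [label="yes"];')
            lines.append(f'  n{nid} -> n{rid} [label="no"];')
        return nid

    walk(tree.root)
    lines.append("}")
    return "\n".join(lines)


def export_tree_text(tree: DecisionTreeModel) -> str:
    lines: list[str] = []

    def walk(node: TreeNode, indent: int) -> None:
        pad = "  " * indent
        if node.is_leaf:
            n0, n1 = node.counts
            lines.append(
                f"{pad}leaf {node.leaf_id}: {LABEL_NAMES[node.majority_label]} "
                f"(non={n0}, asth={n1})"
            )
        else:
            lines.append(f"{pad}{node.feature} <= {node.threshold:.6g}:")
            walk(node.left, indent + 1)
            lines.append(f"{pad}{node.feature} > {node.threshold:.6g}:")
            walk(node.right, indent + 1)

    walk(tree.root, 0)
    return "\n".join(lines)
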