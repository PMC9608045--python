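"""Recursive partitioning by the likelihood-ratio chi-square (G²).

At each node every binary drug indicator (present vs absent) and every
midpoint threshold of the drug-count covariate is evaluated as a candidate
split of the node's cases; the candidate maximizing the G² statistic of the
resulting 2x2 (group x event) table is chosen, subject to both children
containing at least ``min_node`` cases (default 10).  There is no pruning
and no cross-validation: signal screening happens downstream through the
node-wise proportion tests, not through tree complexity control.

The "drug present" / "count >= threshold" side is always the *right* child,
so a node's path of presence conditions reads directly as a drug
combination.

G² = 2 * sum O*ln(O/E) over the four cells, with 0*ln(0/E) taken as 0.  A
Pearson chi-square alternative is provided for sensitivity analysis; G² is
the default and the tested path.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterator, Literal, Optional, Sequence

import numpy as np

from .feature_builder import FeatureMatrix

__all__ = [
    "TreeConfig",
    "Split",
    "Condition",
    "TreeNode",
    "g2_statistic",
    "pearson_statistic",
    "find_best_split",
    "grow_tree",
    "enumerate_nodes",
    "tree_to_dict",
    "tree_to_json",
]

DRUG_COUNT = "drug_count"


@dataclass(frozen=True)
class TreeConfig:
    """Stopping rules of the partitioner.

    ``min_node`` is the minimum number of cases in any node (default 10);
    ``min_g2_to_split`` requires a strictly larger statistic to accept a
    split (default 0: any positive improvement splits, bounded by node size
    and depth).
    """

    min_node: int = 10
    max_depth: int = 10
    min_g2_to_split: float = 0.0
    criterion: Literal["g2", "pearson"] = "g2"

    def __post_init__(self) -> None:
        if self.min_node < 2:
            raise ValueError("min_node must be >= 2")
        if self.max_depth < 0:
            raise ValueError("max_depth must be >= 0")


@dataclass(frozen=True)
class Condition:
    """One edge of a node's path.

    For a binary drug variable ``present`` says which side; for the numeric
    drug-count variable the side is ``value >= threshold`` (right child)
    or ``value < threshold`` (left child).
    """

    variable: str
    kind: Literal["binary", "numeric"]
    present: Optional[bool] = None  # binary kind
    op: Optional[str] = None  # ">=" or "<", numeric kind
    threshold: Optional[float] = None

    def describe(self) -> str:
        if self.kind == "binary":
            return f"{self.variable}={'present' if self.present else 'absent'}"
        return f"{self.variable} {self.op} {self.threshold:g}"


@dataclass(frozen=True)
class Split:
    variable: str
    kind: Literal["binary", "numeric"]
    g2: float
    threshold: Optional[float] = None  # numeric kind: right child is value >= threshold


@dataclass
class TreeNode:
    """A node of the grown tree with its defining condition path."""

    depth: int
    index: np.ndarray  # row indices into the FeatureMatrix
    n: int
    k: int
    path_conditions: tuple[Condition, ...] = ()
    split: Optional[Split] = None
    children: tuple["TreeNode", ...] = ()

    @property
    def rate(self) -> float:
        return self.k / self.n

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def case_ids(self, matrix: FeatureMatrix) -> set[str]:
        return {matrix.case_ids[i] for i in self.index}


def _g2_cells(o: np.ndarray, e: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = o * np.log(o / e)
    return np.where(o > 0, t, 0.0)


def g2_statistic(n1: int, k1: int, n0: int, k0: int) -> float:
    """Likelihood-ratio chi-square of the 2x2 table {group x event}.

    Rows are the two groups (sizes ``n1``, ``n0`` with ``k1``, ``k0``
    events); expected counts come from the table margins.  Returns 0 for a
    degenerate margin (no events or all events overall).
    """
    if not (0 <= k1 <= n1 and 0 <= k0 <= n0) or n1 < 1 or n0 < 1:
        raise ValueError("invalid 2x2 counts")
    n = n1 + n0
    k = k1 + k0
    if k == 0 or k == n:
        return 0.0
    total = 0.0
    for o, row, col in ((k1, n1, k), (n1 - k1, n1, n - k), (k0, n0, k), (n0 - k0, n0, n - k)):
        if o > 0:
            total += o * math.log(o * n / (row * col))
    return max(2.0 * total, 0.0)


def pearson_statistic(n1: int, k1: int, n0: int, k0: int) -> float:
    """Pearson chi-square of the same 2x2 table (sensitivity alternative)."""
    n = n1 + n0
    k = k1 + k0
    if k == 0 or k == n:
        return 0.0
    total = 0.0
    for o, row, col in ((k1, n1, k), (n1 - k1, n1, n - k), (k0, n0, k), (n0 - k0, n0, n - k)):
        e = row * col / n
        total += (o - e) ** 2 / e
    return total


def _stat_vec(
    n1: np.ndarray, k1: np.ndarray, n: int, k: int, criterion: str
) -> np.ndarray:
    """Vectorized split statistic for many right-group candidates at once."""
    n1 = n1.astype(float)
    k1 = k1.astype(float)
    n0 = n - n1
    k0 = k - k1
    if criterion == "g2":
        tot = np.zeros_like(n1)
        for o, row, col in (
            (k1, n1, k),
            (n1 - k1, n1, n - k),
            (k0, n0, k),
            (n0 - k0, n0, n - k),
        ):
            e = row * col / n
            tot += _g2_cells(o, e)
        return np.maximum(2.0 * tot, 0.0)
    tot = np.zeros_like(n1)
    for o, row, col in (
        (k1, n1, k),
        (n1 - k1, n1, n - k),
        (k0, n0, k),
        (n0 - k0, n0, n - k),
    ):
        e = row * col / n
        tot += (o - e) ** 2 / e
    return tot


def find_best_split(
    matrix: FeatureMatrix,
    index: np.ndarray,
    config: TreeConfig,
) -> Optional[Split]:
    """Best admissible split of the cases in ``index``, or None.

    Candidates: every drug column (present vs absent) and every midpoint
    between consecutive observed drug-count values.  A candidate is
    admissible when both children have at least ``min_node`` cases.  Ties
    are broken deterministically: binary before numeric, then lexicographic
    variable name (the column order), then the smaller threshold.
    """
    n = len(index)
    if n < 2 * config.min_node:
        return None
    y = matrix.event[index].astype(np.int64)
    k = int(y.sum())
    if k == 0 or k == n:
        return None

    best: Optional[Split] = None

    X = matrix.indicators[index]
    n1 = X.sum(axis=0, dtype=np.int64)
    k1 = (X * y[:, None]).sum(axis=0, dtype=np.int64)
    admissible = (n1 >= config.min_node) & ((n - n1) >= config.min_node)
    if admissible.any():
        stats = np.where(
            admissible, _stat_vec(n1, k1, n, k, config.criterion), -np.inf
        )
        j = int(np.argmax(stats))  # argmax keeps the first (lexicographic) tie
        best = Split(matrix.drug_columns[j], "binary", float(stats[j]))

    counts = matrix.drug_count[index]
    uniq = np.unique(counts)
    for lo, hi in zip(uniq[:-1], uniq[1:]):
        t = (lo + hi) / 2.0
        right = counts >= t
        nr = int(right.sum())
        if nr < config.min_node or n - nr < config.min_node:
            continue
        kr = int(y[right].sum())
        if config.criterion == "g2":
            stat = g2_statistic(nr, kr, n - nr, k - kr)
        else:
            stat = pearson_statistic(nr, kr, n - nr, k - kr)
        if best is None or stat > best.g2:
            best = Split(DRUG_COUNT, "numeric", stat, threshold=t)

    if best is None or not (best.g2 > config.min_g2_to_split):
        return None
    return best


def _apply_split(
    matrix: FeatureMatrix, index: np.ndarray, split: Split
) -> tuple[np.ndarray, np.ndarray]:
    """(left, right) index arrays; right is present / >= threshold."""
    if split.kind == "binary":
        j = matrix.drug_columns.index(split.variable)
        mask = matrix.indicators[index, j] == 1
    else:
        mask = matrix.drug_count[index] >= split.threshold
    return index[~mask], index[mask]


def grow_tree(matrix: FeatureMatrix, config: TreeConfig = TreeConfig()) -> TreeNode:
    """Grow the full greedy tree; deterministic for identical input."""
    if matrix.n_cases == 0:
        raise ValueError("empty feature matrix")
    root_index = np.arange(matrix.n_cases)
    root = TreeNode(
        depth=0,
        index=root_index,
        n=matrix.n_cases,
        k=matrix.n_events,
    )
    _grow(root, matrix, config)
    return root


def _grow(node: TreeNode, matrix: FeatureMatrix, config: TreeConfig) -> None:
    if node.depth >= config.max_depth or node.k in (0, node.n):
        return
    split = find_best_split(matrix, node.index, config)
    if split is None:
        return
    left_idx, right_idx = _apply_split(matrix, node.index, split)
    if split.kind == "binary":
        cond_l = Condition(split.variable, "binary", present=False)
        cond_r = Condition(split.variable, "binary", present=True)
    else:
        cond_l = Condition(split.variable, "numeric", op="<", threshold=split.threshold)
        cond_r = Condition(split.variable, "numeric", op=">=", threshold=split.threshold)
    y = matrix.event
    children = []
    for idx, cond in ((left_idx, cond_l), (right_idx, cond_r)):
        child = TreeNode(
            depth=node.depth + 1,
            index=idx,
            n=len(idx),
            k=int(y[idx].sum()),
            path_conditions=node.path_conditions + (cond,),
        )
        children.append(child)
    node.split = split
    node.children = tuple(children)
    for child in node.children:
        _grow(child, matrix, config)


def enumerate_nodes(root: TreeNode) -> list[TreeNode]:
    """Pre-order list of all nodes except the root.

    The root carries the initial rate itself and is the reference of the
    downstream proportion tests, so it is not part of the tested family.
    """
    out: list[TreeNode] = []

    def walk(node: TreeNode) -> None:
        for child in node.children:
            out.append(child)
            walk(child)

    walk(root)
    return out


def _node_dict(node: TreeNode) -> dict:
    d = {
        "depth": node.depth,
        "n": node.n,
        "k": node.k,
        "path_conditions": [c.describe() for c in node.path_conditions],
    }
    if node.split is not None:
        d["split"] = {
            "variable": node.split.variable,
            "kind": node.split.kind,
            "g2": node.split.g2,
            "threshold": node.split.threshold,
        }
        d["children"] = [_node_dict(c) for c in node.children]
    return d


def tree_to_dict(root: TreeNode) -> dict:
    return _node_dict(root)


def tree_to_json(root: TreeNode, indent: int = 2) -> str:
    return json.dumps(tree_to_dict(root), indent=indent, sort_keys=True)
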