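"""Applying fixed decision trees to new cohorts and combining rules.

A fitted tree is used in two ways: *routing* (every subject descends the
stored thresholds to a terminal node, giving per-node outcome counts on a
new cohort) and *selection* (an actionable rule — a root-to-node path
whose node non-remission proportion reaches the clinical-action bar of
80% — selects the subjects satisfying its conditions as predicted
non-remitters).  Two trees can be combined in series (intersection of
their selections; a subject must satisfy both rule sets) or in parallel
(union; either suffices).

Boundary convention: a subject exactly at a threshold routes to the
``>=`` branch, everywhere.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .partition import DecisionTree, TreeNode

__all__ = [
    "Condition",
    "Rule",
    "TreeRouting",
    "SelectionResult",
    "apply_tree",
    "extract_actionable_rules",
    "apply_rules",
    "combine_series",
    "combine_parallel",
]


@dataclass(frozen=True)
class Condition:
    feature: str
    threshold: float
    side: str  # 'ge' | 'lt'

    def __post_init__(self) -> None:
        if self.side not in ("ge", "lt"):
            raise ValueError("side must be 'ge' or 'lt'")

    def holds(self, x: np.ndarray) -> np.ndarray:
        """Vectorized evaluation; NaN never satisfies a condition."""
        if self.side == "ge":
            return x >= self.threshold
        return x < self.threshold

    def __str__(self) -> str:
        op = ">=" if self.side == "ge" else "<"
        return f"{self.feature} {op} {self.threshold:g}"


@dataclass(frozen=True)
class Rule:
    """A conjunction of threshold conditions predicting non-remission."""

    conditions: tuple[Condition, ...]
    predicted: str = "non-remitter"
    source_tree: str | None = None
    node_id: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "conditions", tuple(self.conditions))

    def mask(self, df: pd.DataFrame) -> np.ndarray:
        m = np.ones(len(df), dtype=bool)
        for c in self.conditions:
            m &= c.holds(df[c.feature].to_numpy(dtype=float))
        return m

    def __str__(self) -> str:
        return " & ".join(str(c) for c in self.conditions) or "<everyone>"


@dataclass
class TreeRouting:
    """Per-subject terminal-node assignment of a fixed tree on a cohort."""

    node_of: pd.Series                      # subject_id -> terminal node id
    node_counts: dict[str, tuple[int, int]]  # node_id -> (n_remit, n_nonremit)
    unclassified_ids: tuple[str, ...]        # subjects missing a path feature

    @property
    def n_unclassified(self) -> int:
        return len(self.unclassified_ids)


@dataclass
class SelectionResult:
    """Subjects selected (predicted non-remitters) by a rule set."""

    selected_ids: tuple[str, ...]
    n_remitters: int
    n_nonremitters: int
    rule_of: dict = field(default_factory=dict)  # subject_id -> first matching rule idx

    @property
    def n_selected(self) -> int:
        return len(self.selected_ids)

    @property
    def accuracy(self) -> float:
        """Non-remitters among the selected (the rule's positive accuracy)."""
        return (self.n_nonremitters / self.n_selected
                if self.n_selected else float("nan"))


def apply_tree(tree: DecisionTree, df: pd.DataFrame,
               outcome: str = "remitted") -> TreeRouting:
    """Route every subject of ``df`` through the stored thresholds.

    Subjects missing a feature needed on their path are reported as
    ``unclassified`` rather than guessed.
    """
    n = len(df)
    node_ids = np.full(n, "", dtype=object)

    def descend(node: TreeNode, mask: np.ndarray) -> None:
        if node.is_leaf:
            node_ids[mask] = node.node_id
            return
        x = df[node.cut.feature].to_numpy(dtype=float)
        present = ~np.isnan(x)
        node_ids[mask & ~present] = "unclassified"
        descend(node.children["ge"], mask & present & (x >= node.cut.threshold))
        descend(node.children["lt"], mask & present & (x < node.cut.threshold))

    descend(tree.root, np.ones(n, dtype=bool))
    ids = df["subject_id"].to_numpy()
    remitted = df[outcome].to_numpy(dtype=bool) if outcome in df else np.zeros(n, bool)
    counts: dict[str, tuple[int, int]] = {}
    for nid in pd.unique(node_ids):
        sel = node_ids == nid
        counts[nid] = (int(remitted[sel].sum()), int((sel & ~remitted).sum()))
    return TreeRouting(
        node_of=pd.Series(node_ids, index=ids, name="node_id"),
        node_counts=counts,
        unclassified_ids=tuple(ids[node_ids == "unclassified"]),
    )


def _path_conditions(tree: DecisionTree, target: TreeNode) -> tuple[Condition, ...]:
    path: list[Condition] = []

    def search(node: TreeNode, acc: list[Condition]) -> bool:
        if node is target:
            path.extend(acc)
            return True
        if node.is_leaf:
            return False
        c = node.cut
        return (search(node.children["ge"], acc + [Condition(c.feature, c.threshold, "ge")])
                or search(node.children["lt"], acc + [Condition(c.feature, c.threshold, "lt")]))

    search(tree.root, [])
    return tuple(path)


def extract_actionable_rules(tree: DecisionTree,
                             min_accuracy: float = 0.80) -> list[Rule]:
    """Root-to-node paths whose non-remission proportion reaches the bar.

    Every node (internal or terminal) with at least ``min_accuracy``
    non-remission qualifies; rules are returned in preorder.
    """
    rules = []
    for node in tree.root.walk():
        if node.n and node.p_nonremission >= min_accuracy:
            rules.append(Rule(
                conditions=_path_conditions(tree, node),
                source_tree=tree.fit_cohort,
                node_id=node.node_id,
            ))
    return rules


def apply_rules(rules: Sequence[Rule], df: pd.DataFrame,
                outcome: str = "remitted") -> SelectionResult:
    """Select subjects matching any rule of the set."""
    ids = df["subject_id"].to_numpy()
    selected = np.zeros(len(df), dtype=bool)
    rule_of: dict = {}
    for ri, rule in enumerate(rules):
        m = rule.mask(df)
        for sid in ids[m & ~selected]:
            rule_of[sid] = ri
        selected |= m
    remitted = (df[outcome].to_numpy(dtype=bool) if outcome in df
                else np.zeros(len(df), bool))
    return SelectionResult(
        selected_ids=tuple(ids[selected]),
        n_remitters=int((selected & remitted).sum()),
        n_nonremitters=int((selected & ~remitted).sum()),
        rule_of=rule_of,
    )


def _from_id_set(id_set: set, df: pd.DataFrame, outcome: str) -> SelectionResult:
    ids = df["subject_id"].to_numpy()
    sel = np.isin(ids, list(id_set))
    remitted = (df[outcome].to_numpy(dtype=bool) if outcome in df
                else np.zeros(len(df), bool))
    return SelectionResult(
        selected_ids=tuple(ids[sel]),
        n_remitters=int((sel & remitted).sum()),
        n_nonremitters=int((sel & ~remitted).sum()),
    )


def combine_series(rules_a: Sequence[Rule], rules_b: Sequence[Rule],
                   df: pd.DataFrame, outcome: str = "remitted") -> SelectionResult:
    """Subjects selected by *both* rule sets (order-invariant intersection)."""
    a = set(apply_rules(rules_a, df, outcome).selected_ids)
    b = set(apply_rules(rules_b, df, outcome).selected_ids)
    return _from_id_set(a & b, df, outcome)


def combine_parallel(rules_a: Sequence[Rule], rules_b: Sequence[Rule],
                     df: pd.DataFrame, outcome: str = "remitted") -> SelectionResult:
    """Subjects selected by *either* rule set (union)."""
    a = set(apply_rules(rules_a, df, outcome).selected_ids)
    b = set(apply_rules(rules_b, df, outcome).selected_ids)
    return _from_id_set(a | b, df, outcome)
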