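"""Kappa-maximizing ROC recursive partitioning.

The splitting procedure follows the signal-detection ROC approach used for
clinical prediction rules: at each node, candidate cut-points are generated
at *every observed value* of every candidate predictor; each candidate's
quality is the unweighted Cohen's kappa between the branch indicator
(interpreted as predicted non-remission) and the observed outcome.  The
best significant candidate (two-sided Fisher exact p below ``alpha``,
default 0.01) splits the node, and the procedure recurses into both
branches until no candidate qualifies.  The fitted object is a binary
decision tree annotated with node counts and remission probabilities.

Conventions (all deterministic, recorded in tree metadata):

* a threshold ``v`` splits a node into ``{x >= v}`` and ``{x < v}``;
* the *positive* branch (``CutPoint.direction``) is the side with the
  higher observed non-remission rate — that side predicts non-remission;
* ties in kappa break by smaller p-value, then earlier position in the
  caller-supplied feature list, then smaller threshold;
* both branches of a candidate must contain at least ``MIN_BRANCH``
  subjects (Fisher's test is degenerate below that);
* subjects missing a feature are excluded from that feature's candidate
  tables (complete-case per feature) and are left unrouted when that
  feature is chosen for the split.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CutPoint",
    "TreeNode",
    "DecisionTree",
    "kappa_2x2",
    "enumerate_cutpoints",
    "best_cutpoint",
    "build_tree",
]

#: minimum subjects required on each side of a candidate split
MIN_BRANCH = 2

Table = tuple[tuple[int, int], tuple[int, int]]


def kappa_2x2(table: Table | np.ndarray) -> float:
    """Unweighted Cohen's kappa for a 2x2 agreement table.

    Rows index the prediction (positive branch first), columns the observed
    outcome (positive class first).  Returns 0.0 when chance agreement is 1
    (a degenerate margin), so the value is always defined.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("kappa_2x2 expects a 2x2 table")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if not np.allclose(t, np.round(t)):
        raise ValueError("counts must be integers")
    n = t.sum()
    if n < 1:
        raise ValueError("table total must be >= 1")
    po = (t[0, 0] + t[1, 1]) / n
    pe = (t[0].sum() * t[:, 0].sum() + t[1].sum() * t[:, 1].sum()) / n**2
    if pe >= 1.0 - 1e-15:
        return 0.0
    return float((po - pe) / (1.0 - pe))


@dataclass(frozen=True)
class CutPoint:
    """A candidate (or chosen) split with its evaluation.

    ``direction`` names the branch that predicts non-remission: ``"ge"``
    means subjects with ``feature >= threshold`` are called non-remitters.
    ``table`` rows are (positive branch, negative branch), columns are
    (non-remitter, remitter).
    """

    feature: str
    threshold: float
    direction: str  # 'ge' | 'lt'
    table: Table
    kappa: float
    p_value: float

    def __post_init__(self) -> None:
        if self.direction not in ("ge", "lt"):
            raise ValueError("direction must be 'ge' or 'lt'")

    @property
    def sensitivity(self) -> float:
        """Selected non-remitters / all non-remitters in the subsample."""
        (a, _), (c, _) = self.table
        return a / (a + c) if a + c else float("nan")

    @property
    def specificity(self) -> float:
        """Unselected remitters / all remitters in the subsample."""
        (_, b), (_, d) = self.table
        return d / (b + d) if b + d else float("nan")

    def to_dict(self) -> dict:
        return {
            "feature": self.feature,
            "threshold": self.threshold,
            "direction": self.direction,
            "table": [list(r) for r in self.table],
            "kappa": self.kappa,
            "p_value": self.p_value,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CutPoint":
        return cls(
            feature=d["feature"],
            threshold=float(d["threshold"]),
            direction=d["direction"],
            table=tuple(tuple(int(x) for x in r) for r in d["table"]),
            kappa=float(d["kappa"]),
            p_value=float(d["p_value"]),
        )


@dataclass
class _Scan:
    """Vectorized candidate evaluations for one feature at one node."""

    feature: str
    thresholds: np.ndarray  # candidate thresholds (observed values)
    nr_ge: np.ndarray       # non-remitters with x >= v
    n_ge: np.ndarray
    nr_lt: np.ndarray
    n_lt: np.ndarray
    kappa: np.ndarray       # kappa of the chosen direction
    direction: np.ndarray   # True where 'ge' side predicts non-remission


def _kappa_vec(a, b, c, d):
    """Vectorized kappa for tables [[a, b], [c, d]]; 0 on degenerate margins."""
    n = a + b + c + d
    po = (a + d) / n
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / n.astype(float) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        k = (po - pe) / (1.0 - pe)
    return np.where(pe >= 1.0 - 1e-15, 0.0, k)


def _scan_feature(feature: str, x: np.ndarray, nonremit: np.ndarray,
                  min_branch: int = MIN_BRANCH) -> _Scan | None:
    """Evaluate every observed-value cut-point of one feature.

    ``x`` and ``nonremit`` are aligned arrays for the node's subjects that
    have this feature (NaNs already removed).  Candidates whose smaller
    branch has fewer than ``min_branch`` subjects are dropped; the
    empty-branch candidate at the observed minimum is always dropped.
    """
    if x.size == 0:
        return None
    order = np.argsort(x, kind="stable")
    xs = x[order]
    ys = nonremit[order].astype(np.int64)
    values, first = np.unique(xs, return_index=True)
    if values.size < 2:
        return None
    cum = np.concatenate([[0], np.cumsum(ys)])
    n_total = xs.size
    nr_total = int(cum[-1])
    # skip the minimum: its '< v' branch is empty
    v = values[1:]
    n_lt = first[1:]
    nr_lt = cum[first[1:]]
    n_ge = n_total - n_lt
    nr_ge = nr_total - nr_lt
    keep = (n_lt >= min_branch) & (n_ge >= min_branch)
    if not keep.any():
        return None
    v, n_lt, nr_lt, n_ge, nr_ge = (arr[keep] for arr in (v, n_lt, nr_lt, n_ge, nr_ge))
    # positive branch = side with the higher non-remission rate (ties -> 'ge')
    ge_dir = nr_ge * n_lt >= nr_lt * n_ge
    k_ge = _kappa_vec(nr_ge, n_ge - nr_ge, nr_lt, n_lt - nr_lt)
    k_lt = _kappa_vec(nr_lt, n_lt - nr_lt, nr_ge, n_ge - nr_ge)
    kappa = np.where(ge_dir, k_ge, k_lt)
    return _Scan(feature, v.astype(float), nr_ge, n_ge, nr_lt, n_lt, kappa, ge_dir)


def _fisher_p(a: int, b: int, c: int, d: int) -> float:
    return float(stats.fisher_exact([[a, b], [c, d]])[1])


def _cutpoint_at(scan: _Scan, i: int, p_value: float) -> CutPoint:
    a, b = int(scan.nr_ge[i]), int(scan.n_ge[i] - scan.nr_ge[i])
    c, d = int(scan.nr_lt[i]), int(scan.n_lt[i] - scan.nr_lt[i])
    if scan.direction[i]:
        table = ((a, b), (c, d))
        direction = "ge"
    else:
        table = ((c, d), (a, b))
        direction = "lt"
    return CutPoint(
        feature=scan.feature,
        threshold=float(scan.thresholds[i]),
        direction=direction,
        table=table,
        kappa=float(scan.kappa[i]),
        p_value=p_value,
    )


def _node_arrays(df: pd.DataFrame, feature: str, outcome: str):
    x = df[feature].to_numpy(dtype=float)
    y = ~df[outcome].to_numpy(dtype=bool)  # positive class = non-remitter
    ok = ~np.isnan(x)
    return x[ok], y[ok]


def enumerate_cutpoints(df: pd.DataFrame, feature: str,
                        outcome: str = "remitted") -> list[CutPoint]:
    """All candidate cut-points of one feature at this subsample.

    One candidate per distinct observed value ``v`` (split ``{x >= v}`` vs
    ``{x < v}``); candidates with an undersized branch are dropped.  Each
    candidate carries its 2x2 table, kappa, direction, and a two-sided
    Fisher exact p-value.
    """
    if feature not in df.columns:
        raise KeyError(f"feature {feature!r} not in table")
    x, y = _node_arrays(df, feature, outcome)
    if x.size == 0:
        raise ValueError(f"feature {feature!r} has no observed values here")
    scan = _scan_feature(feature, x, y, min_branch=1)
    if scan is None:
        return []
    out = []
    for i in range(scan.thresholds.size):
        a = int(scan.nr_ge[i]); b = int(scan.n_ge[i] - a)
        c = int(scan.nr_lt[i]); d = int(scan.n_lt[i] - c)
        out.append(_cutpoint_at(scan, i, _fisher_p(a, b, c, d)))
    return out


def best_cutpoint(df: pd.DataFrame, features: Sequence[str],
                  alpha: float = 0.01,
                  outcome: str = "remitted") -> CutPoint | None:
    """The maximal-kappa candidate with Fisher p < ``alpha``, or ``None``.

    Deterministic tie-break: larger kappa, then smaller p-value, then the
    feature earliest in ``features``, then the smallest threshold.  Fisher
    p-values are evaluated lazily from the top kappa down, which is exact
    because candidates with larger kappa always take precedence.
    """
    if not features:
        raise ValueError("empty feature list")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    scans: list[tuple[int, _Scan]] = []
    for fi, feat in enumerate(features):
        x, y = _node_arrays(df, feat, outcome)
        s = _scan_feature(feat, x, y)
        if s is not None:
            scans.append((fi, s))
    if not scans:
        return None
    # flatten candidates: (kappa, feature_index, threshold, scan, i); a
    # vectorized one-sided hypergeometric tail is a lower bound on the
    # two-sided Fisher p (the pmf is unimodal, so the same-direction tail
    # is always part of the two-sided sum), letting us discard hopeless
    # candidates without the exact test
    cand = []
    for fi, s in scans:
        n_tot = s.n_ge + s.n_lt
        nr_tot = s.nr_ge + s.nr_lt
        lower = stats.hypergeom.sf(s.nr_ge - 1, n_tot, nr_tot, s.n_ge)
        lower = np.where(s.direction, lower,
                         stats.hypergeom.cdf(s.nr_ge, n_tot, nr_tot, s.n_ge))
        for i in range(s.thresholds.size):
            if s.kappa[i] > 0.0 and lower[i] < alpha:
                cand.append((s.kappa[i], fi, s.thresholds[i], s, i))
    cand.sort(key=lambda t: (-t[0], t[1], t[2]))
    j = 0
    while j < len(cand):
        # evaluate whole groups of equal kappas together (equal up to float
        # noise, since different tables can tie mathematically) so the
        # p-value tie-break sees every member
        k = cand[j][0]
        group = []
        while j < len(cand) and cand[j][0] >= k - 1e-12:
            group.append(cand[j])
            j += 1
        passing = []
        for _, fi, thr, s, i in group:
            a = int(s.nr_ge[i]); b = int(s.n_ge[i] - a)
            c = int(s.nr_lt[i]); d = int(s.n_lt[i] - c)
            p = _fisher_p(a, b, c, d)
            if p < alpha:
                passing.append((p, fi, thr, s, i))
        if passing:
            # p-values equal up to float noise count as tied; fall through
            # to feature order, then threshold
            p_min = min(p for p, *_ in passing)
            tied = [t for t in passing if t[0] <= p_min * (1 + 1e-9)]
            p, fi, thr, s, i = min(tied, key=lambda t: (t[1], t[2]))
            return _cutpoint_at(s, i, p)
    return None


@dataclass
class TreeNode:
    """One node of a fitted tree, annotated with outcome counts."""

    node_id: str
    n_remit: int
    n_nonremit: int
    cut: CutPoint | None = None
    children: dict[str, "TreeNode"] | None = None  # keys 'ge', 'lt'
    n_unrouted: int = 0  # subjects missing the split feature

    @property
    def n(self) -> int:
        return self.n_remit + self.n_nonremit

    @property
    def p_remission(self) -> float:
        return self.n_remit / self.n if self.n else float("nan")

    @property
    def p_nonremission(self) -> float:
        return self.n_nonremit / self.n if self.n else float("nan")

    @property
    def is_leaf(self) -> bool:
        return self.cut is None

    def walk(self) -> Iterable["TreeNode"]:
        """Preorder traversal ('ge' child before 'lt')."""
        yield self
        if self.children:
            yield from self.children["ge"].walk()
            yield from self.children["lt"].walk()

    def to_dict(self) -> dict:
        d = {
            "node_id": self.node_id,
            "n_remit": self.n_remit,
            "n_nonremit": self.n_nonremit,
        }
        if self.cut is not None:
            d.update(self.cut.to_dict())
            d["n_unrouted"] = self.n_unrouted
            d["children"] = {
                side: child.to_dict() for side, child in self.children.items()
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        node = cls(
            node_id=d["node_id"],
            n_remit=int(d["n_remit"]),
            n_nonremit=int(d["n_nonremit"]),
        )
        if "feature" in d:
            node.cut = CutPoint.from_dict(d)
            node.n_unrouted = int(d.get("n_unrouted", 0))
            node.children = {
                side: cls.from_dict(c) for side, c in d["children"].items()
            }
        return node


@dataclass
class DecisionTree:
    """A fitted hierarchical partition plus the method metadata."""

    root: TreeNode
    features: tuple[str, ...]
    alpha: float
    fit_cohort: str | None = None
    metadata: dict = field(default_factory=dict)

    def nodes(self) -> list[TreeNode]:
        return list(self.root.walk())

    def to_dict(self) -> dict:
        return {
            "features": list(self.features),
            "alpha": self.alpha,
            "fit_cohort": self.fit_cohort,
            "metadata": self.metadata,
            "root": self.root.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DecisionTree":
        return cls(
            root=TreeNode.from_dict(d["root"]),
            features=tuple(d["features"]),
            alpha=float(d["alpha"]),
            fit_cohort=d.get("fit_cohort"),
            metadata=dict(d.get("metadata", {})),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "DecisionTree":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def build_tree(df: pd.DataFrame, features: Sequence[str],
               alpha: float = 0.01, outcome: str = "remitted",
               fit_cohort: str | None = None) -> DecisionTree:
    """Fit the recursive partition on a cohort table.

    Rows missing *all* candidate features are dropped up front (they could
    never be routed); the dropped count is recorded in metadata.  Fitting is
    fully deterministic for a given table and feature order.
    """
    if df.shape[0] == 0:
        raise ValueError("empty cohort")
    features = tuple(features)
    usable = df[~df[list(features)].isna().all(axis=1)]
    n_dropped = df.shape[0] - usable.shape[0]

    def grow(sub: pd.DataFrame, node_id: str) -> TreeNode:
        y = sub[outcome].to_numpy(dtype=bool)
        node = TreeNode(node_id=node_id, n_remit=int(y.sum()),
                        n_nonremit=int((~y).sum()))
        if node.n_remit == 0 or node.n_nonremit == 0 or node.n < 2 * MIN_BRANCH:
            return node
        cut = best_cutpoint(sub, features, alpha=alpha, outcome=outcome)
        if cut is None:
            return node
        x = sub[cut.feature].to_numpy(dtype=float)
        present = ~np.isnan(x)
        ge = present & (x >= cut.threshold)
        lt = present & (x < cut.threshold)
        node.cut = cut
        node.n_unrouted = int((~present).sum())
        node.children = {
            "ge": grow(sub[ge], node_id + "/ge"),
            "lt": grow(sub[lt], node_id + "/lt"),
        }
        return node

    root = grow(usable, "root")
    return DecisionTree(
        root=root,
        features=features,
        alpha=alpha,
        fit_cohort=fit_cohort,
        metadata={
            "test": "fisher-exact-two-sided",
            "tie_break": "kappa-desc, p-asc, feature-order, threshold-asc",
            "min_branch": MIN_BRANCH,
            "n_input": int(df.shape[0]),
            "n_dropped_all_missing": int(n_dropped),
        },
    )
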