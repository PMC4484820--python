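"""Replication and characterization statistics.

Exact binomial tails test whether a rule's accuracy in a new cohort
replicates the accuracy observed at fit time (lower tail against the
reference accuracy) and whether it beats chance (upper tail against the
non-remission probability implied by the literature remission rate of
35%).  2x2 association uses Pearson chi-square (no continuity
correction) or the two-sided Fisher exact test.  A multiple-sampling
bootstrap re-applies a fixed rule set to random subsamples of the pooled
cohorts, giving the distribution of specificity (non-remitters among the
selected) and coverage (fraction of a subsample's non-remitters that the
rules catch).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .apply import Rule, SelectionResult, apply_rules, extract_actionable_rules
from .partition import DecisionTree

__all__ = [
    "EvaluationResult",
    "BootstrapResult",
    "binom_test_vs_reference",
    "chance_test",
    "chi2_2x2",
    "fisher_exact_2x2",
    "evaluate_selection",
    "bootstrap_cv",
    "compare_groups",
]

#: literature / whole-trial remission rate defining "chance"
DEFAULT_CHANCE_REMISSION = 0.35


def binom_test_vs_reference(successes: int, n: int, p0: float) -> float:
    """One-sided lower-tail exact binomial p: P(X <= successes | n, p0).

    Used to ask whether an observed replication accuracy (successes/n) is
    credibly as high as a reference accuracy ``p0`` from the fit cohort.
    """
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie in (0, 1)")
    if not 0 <= successes <= n or n < 1:
        raise ValueError("need 0 <= successes <= n and n >= 1")
    return float(sps.binom.cdf(successes, n, p0))


def chance_test(n_correct: int, n_selected: int,
                chance_remission: float = DEFAULT_CHANCE_REMISSION) -> float:
    """One-sided upper-tail exact binomial p: P(X >= n_correct | n, 1-rate).

    Under chance, each selected subject is a non-remitter with
    probability ``1 - chance_remission``.
    """
    if not 0.0 < chance_remission < 1.0:
        raise ValueError("chance_remission must lie in (0, 1)")
    if not 0 <= n_correct <= n_selected or n_selected < 1:
        raise ValueError("need 0 <= n_correct <= n_selected and n_selected >= 1")
    return float(sps.binom.sf(n_correct - 1, n_selected, 1.0 - chance_remission))


def _check_table(table) -> np.ndarray:
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    return t.astype(np.int64)


def chi2_2x2(table) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) and its p."""
    t = _check_table(table)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined with a zero margin")
    res = sps.chi2_contingency(t, correction=False)
    return float(res.statistic), float(res.pvalue)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p (hypergeometric probability ordering)."""
    t = _check_table(table)
    return float(sps.fisher_exact(t)[1])


@dataclass
class EvaluationResult:
    """A rule set applied to one cohort, with replication/chance tests."""

    rule_id: str
    cohort: str
    n_selected: int
    n_correct: int            # non-remitters among the selected
    coverage: float           # selected non-remitters / cohort non-remitters
    p_vs_reference: float | None = None
    p_vs_chance: float | None = None

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_selected if self.n_selected else float("nan")

    def to_dict(self) -> dict:
        import math
        acc = self.accuracy
        cov = self.coverage
        return {
            "rule_id": self.rule_id, "cohort": self.cohort,
            "n_selected": self.n_selected, "n_correct": self.n_correct,
            "accuracy": None if math.isnan(acc) else acc,
            "coverage": None if math.isnan(cov) else cov,
            "p_vs_reference": self.p_vs_reference, "p_vs_chance": self.p_vs_chance,
        }


def evaluate_selection(selection: SelectionResult, df: pd.DataFrame,
                       rule_id: str = "", cohort: str = "",
                       reference_accuracy: float | None = None,
                       chance_remission: float | None = DEFAULT_CHANCE_REMISSION,
                       outcome: str = "remitted") -> EvaluationResult:
    """Score a selection on a cohort and attach the exact tests."""
    n_nr_cohort = int((~df[outcome].astype(bool)).sum())
    n_sel = selection.n_selected
    n_cor = selection.n_nonremitters
    p_ref = None
    p_chance = None
    if n_sel > 0:
        if reference_accuracy is not None:
            p_ref = binom_test_vs_reference(n_cor, n_sel, reference_accuracy)
        if chance_remission is not None:
            p_chance = chance_test(n_cor, n_sel, chance_remission)
    return EvaluationResult(
        rule_id=rule_id, cohort=cohort,
        n_selected=n_sel, n_correct=n_cor,
        coverage=n_cor / n_nr_cohort if n_nr_cohort else float("nan"),
        p_vs_reference=p_ref, p_vs_chance=p_chance,
    )


@dataclass
class BootstrapResult:
    """Distributions over bootstrap subsamples of a fixed rule set."""

    n_iterations: int
    subsample_size: int
    specificity: np.ndarray   # NaN where no subject was selected
    coverage: np.ndarray      # NaN where the subsample had no non-remitter
    seed: int | None
    with_replacement: bool = False

    @property
    def n_undefined_specificity(self) -> int:
        return int(np.isnan(self.specificity).sum())

    @property
    def n_undefined_coverage(self) -> int:
        return int(np.isnan(self.coverage).sum())

    @property
    def mean_specificity(self) -> float:
        return float(np.nanmean(self.specificity))

    @property
    def sd_specificity(self) -> float:
        ok = self.specificity[~np.isnan(self.specificity)]
        return float(ok.std(ddof=1)) if ok.size > 1 else 0.0

    @property
    def mean_coverage(self) -> float:
        return float(np.nanmean(self.coverage))

    @property
    def sd_coverage(self) -> float:
        ok = self.coverage[~np.isnan(self.coverage)]
        return float(ok.std(ddof=1)) if ok.size > 1 else 0.0

    def summary(self) -> dict:
        return {
            "n_iterations": self.n_iterations,
            "subsample_size": self.subsample_size,
            "mean_specificity": self.mean_specificity,
            "sd_specificity": self.sd_specificity,
            "mean_coverage": self.mean_coverage,
            "sd_coverage": self.sd_coverage,
            "n_undefined_specificity": self.n_undefined_specificity,
            "n_undefined_coverage": self.n_undefined_coverage,
            "seed": self.seed,
            "with_replacement": self.with_replacement,
        }


def bootstrap_cv(pooled: pd.DataFrame, tree: DecisionTree | None = None,
                 n_iter: int = 1000, m: int = 100,
                 seed: int | None = None, rules: Sequence[Rule] | None = None,
                 min_accuracy: float = 0.80, with_replacement: bool = False,
                 outcome: str = "remitted") -> BootstrapResult:
    """Cross-validate a fixed rule set on random subsamples of a pool.

    Per iteration, ``m`` subjects are drawn (without replacement by
    default) from the pooled cohorts; the rule set selects its predicted
    non-remitters; specificity = non-remitters / selected and coverage =
    selected non-remitters / subsample non-remitters are recorded.
    Iterations with an empty selection (or no non-remitters) contribute
    NaN and are excluded from the summaries but counted.
    """
    if rules is None:
        if tree is None:
            raise ValueError("provide a fitted tree or an explicit rule set")
        rules = extract_actionable_rules(tree, min_accuracy=min_accuracy)
    if not rules:
        raise ValueError("rule set is empty: no non-remission rule to test")
    n_pool = len(pooled)
    if m > n_pool and not with_replacement:
        raise ValueError("subsample size exceeds pool size")
    # evaluate each rule's mask once; iterations only index into them
    sel_any = np.zeros(n_pool, dtype=bool)
    for r in rules:
        sel_any |= r.mask(pooled)
    nonremit = ~pooled[outcome].to_numpy(dtype=bool)
    rng = np.random.default_rng(seed)
    spec = np.empty(n_iter)
    cov = np.empty(n_iter)
    for it in range(n_iter):
        idx = rng.choice(n_pool, size=m, replace=with_replacement)
        s = sel_any[idx]
        nr = nonremit[idx]
        n_sel = int(s.sum())
        spec[it] = (nr[s].sum() / n_sel) if n_sel else np.nan
        n_nr = int(nr.sum())
        cov[it] = ((s & nr).sum() / n_nr) if n_nr else np.nan
    return BootstrapResult(
        n_iterations=n_iter, subsample_size=m,
        specificity=spec, coverage=cov, seed=seed,
        with_replacement=with_replacement,
    )


def compare_groups(a: pd.DataFrame, b: pd.DataFrame,
                   variables: Sequence[str],
                   welch: bool = False) -> pd.DataFrame:
    """Per-variable two-group comparison (t-test or chi-square).

    Continuous variables get an independent two-sided t-test
    (pooled-variance by default, Welch with ``welch=True``); binary
    variables get the Pearson chi-square on the 2x2 table.  Returns one
    row per variable with the statistic, p-value and group summaries.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    rows = []
    for var in variables:
        if var not in a.columns or var not in b.columns:
            raise KeyError(f"variable {var!r} absent from a group")
        xa = a[var]
        xb = b[var]
        if xa.dtype == bool or set(pd.concat([xa, xb]).dropna().unique()) <= {0, 1, True, False}:
            ca = int(xa.astype(bool).sum())
            cb = int(xb.astype(bool).sum())
            table = [[ca, len(xa) - ca], [cb, len(xb) - cb]]
            stat, p = chi2_2x2(table)
            rows.append({
                "variable": var, "kind": "binary", "statistic": stat, "p": p,
                "group_a": ca / len(xa), "group_b": cb / len(xb),
            })
        else:
            va = xa.astype(float).dropna()
            vb = xb.astype(float).dropna()
            stat, p = sps.ttest_ind(va, vb, equal_var=not welch)
            rows.append({
                "variable": var, "kind": "continuous",
                "statistic": float(stat), "p": float(p),
                "group_a": float(va.mean()), "group_b": float(vb.mean()),
            })
    return pd.DataFrame(rows).set_index("variable")
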