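"""Independent oracles used by the test suite.

Everything here is written from first principles (log-factorials,
explicit enumeration, brute-force search) and never calls the package's
own implementations, so agreement is evidence rather than tautology.
"""
from __future__ import annotations

import math
from itertools import product


def kappa_oracle(table) -> float:
    """Chance-corrected agreement from the defining sums."""
    (a, b), (c, d) = table
    n = a + b + c + d
    observed = (a + d) / n
    chance = ((a + b) / n) * ((a + c) / n) + ((c + d) / n) * ((b + d) / n)
    if chance >= 1.0 - 1e-15:
        return 0.0
    return (observed - chance) / (1.0 - chance)


def _log_comb(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def binom_pmf(k: int, n: int, p: float) -> float:
    if k < 0 or k > n:
        return 0.0
    return math.exp(_log_comb(n, k) + k * math.log(p) + (n - k) * math.log1p(-p))


def binom_lower_tail(k: int, n: int, p: float) -> float:
    """P(X <= k) by direct pmf summation."""
    return sum(binom_pmf(i, n, p) for i in range(0, k + 1))


def binom_upper_tail(k: int, n: int, p: float) -> float:
    """P(X >= k) by direct pmf summation."""
    return sum(binom_pmf(i, n, p) for i in range(k, n + 1))


def hypergeom_pmf(a: int, table_margins) -> float:
    """P of cell a given fixed margins (row1, row2, col1) of a 2x2 table."""
    r1, r2, c1 = table_margins
    n = r1 + r2
    if a < max(0, c1 - r2) or a > min(r1, c1):
        return 0.0
    return math.exp(_log_comb(r1, a) + _log_comb(r2, c1 - a) - _log_comb(n, c1))


def fisher_two_sided_oracle(table) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration.

    Sums the probabilities of all tables (same margins) whose point
    probability does not exceed the observed one, with the same relative
    tolerance scipy documents for ties (1 + 1e-7).
    """
    (a, b), (c, d) = table
    margins = (a + b, c + d, a + c)
    p_obs = hypergeom_pmf(a, margins)
    total = 0.0
    for k in range(0, min(a + b, a + c) + 1):
        p = hypergeom_pmf(k, margins)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(total, 1.0)


def chi2_closed_form(table) -> float:
    """Pearson statistic n(ad - bc)^2 / (product of the four margins)."""
    (a, b), (c, d) = table
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / (
        (a + b) * (c + d) * (a + c) * (b + d))


def brute_force_best_cutpoint(df, features, alpha=0.01, min_branch=2):
    """Exhaustive maximizer over every (feature, observed value) candidate.

    Re-derives the selection rule from its definition: for each candidate
    the branch with the higher non-remitter fraction predicts
    non-remission; keep candidates with two-sided Fisher p < alpha; pick
    max kappa, then min p, then earliest feature, then smallest threshold.
    Returns (feature, threshold, direction, kappa, p) or None.
    """
    candidates = []
    for fi, feat in enumerate(features):
        col = df[feat]
        sub = df[col.notna()]
        xs = sub[feat].tolist()
        ys = [not r for r in sub["remitted"].tolist()]  # non-remitter flags
        for v in sorted(set(xs)):
            ge = [(x, y) for x, y in zip(xs, ys) if x >= v]
            lt = [(x, y) for x, y in zip(xs, ys) if x < v]
            if len(ge) < min_branch or len(lt) < min_branch:
                continue
            nr_ge = sum(y for _, y in ge)
            nr_lt = sum(y for _, y in lt)
            if nr_ge * len(lt) >= nr_lt * len(ge):
                direction = "ge"
                table = ((nr_ge, len(ge) - nr_ge), (nr_lt, len(lt) - nr_lt))
            else:
                direction = "lt"
                table = ((nr_lt, len(lt) - nr_lt), (nr_ge, len(ge) - nr_ge))
            k = kappa_oracle(table)
            if k <= 0:
                continue
            p = fisher_two_sided_oracle(table)
            if p >= alpha:
                continue
            candidates.append((k, p, fi, float(v), feat, direction))
    if not candidates:
        return None
    k_max = max(k for k, *_ in candidates)
    top = [c for c in candidates if c[0] >= k_max - 1e-12]
    p_min = min(c[1] for c in top)
    tied = [c for c in top if c[1] <= p_min * (1 + 1e-9)]
    k, p, fi, v, feat, direction = min(tied, key=lambda c: (c[2], c[3]))
    return (feat, v, direction, k, p)


def enumerate_cutpoints_oracle(df, feature):
    """All (threshold, table) candidates of one feature, non-empty branches."""
    sub = df[df[feature].notna()]
    xs = sub[feature].tolist()
    ys = [not r for r in sub["remitted"].tolist()]
    out = []
    for v in sorted(set(xs)):
        ge = [y for x, y in zip(xs, ys) if x >= v]
        lt = [y for x, y in zip(xs, ys) if x < v]
        if not ge or not lt:
            continue
        out.append((float(v),
                    ((sum(ge), len(ge) - sum(ge)), (sum(lt), len(lt) - sum(lt)))))
    return out
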