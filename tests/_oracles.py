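"""Independent brute-force / closed-form oracles used by the test suite.

Each oracle is deliberately written without reference to the library code
path it checks: exhaustive enumeration, direct summation, or the textbook
formula.
"""

from __future__ import annotations

import math

import numpy as np


def brute_merge(spans: list[tuple[int, int]], max_gap: int) -> list[tuple[int, int]]:
    """Transitive-closure merge of (start, end) spans on one chromosome."""
    spans = [list(s) for s in sorted(spans)]
    changed = True
    while changed:
        changed = False
        out: list[list[int]] = []
        for s in spans:
            merged = False
            for o in out:
                if s[0] - o[1] <= max_gap and o[0] - s[1] <= max_gap:
                    o[0], o[1] = min(o[0], s[0]), max(o[1], s[1])
                    merged = changed = True
                    break
            if not merged:
                out.append(s)
        spans = sorted(out)
    return [tuple(s) for s in spans]


def brute_intersect_any(
    queries: list[tuple[str, int, int]], subjects: list[tuple[str, int, int]]
) -> list[bool]:
    """Quadratic all-pairs >= 1 bp overlap check."""
    return [
        any(qc == sc and qs < se and ss < qe for sc, ss, se in subjects)
        for qc, qs, qe in queries
    ]


def bridged_runs(eligible: list[bool], gap: int) -> list[tuple[int, int]]:
    """Enumerate gap-bridged runs by explicitly filling bridgeable gaps.

    An ineligible stretch of length <= gap flanked by eligible windows on
    both sides is marked bridged; islands are the connected runs of
    eligible-or-bridged windows, trimmed to their eligible endpoints.
    """
    n = len(eligible)
    marked = list(eligible)
    i = 0
    while i < n:
        if not eligible[i]:
            j = i
            while j < n and not eligible[j]:
                j += 1
            left = i > 0 and eligible[i - 1]
            right = j < n and eligible[j]
            if left and right and (j - i) <= gap:
                for k in range(i, j):
                    marked[k] = True
            i = j
        else:
            i += 1
    runs: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if marked[i]:
            j = i
            while j < n and marked[j]:
                j += 1
            members = [k for k in range(i, j) if eligible[k]]
            if members:
                runs.append((members[0], members[-1]))
            i = j
        else:
            i += 1
    return runs


def poisson_tail(c: int, lam: float, terms: int = 4000) -> float:
    """P(X >= c) for X ~ Poisson(lam) by direct term summation."""
    if c <= 0:
        return 1.0
    parts = []
    log_t = -lam + c * math.log(lam) - math.lgamma(c + 1)
    k = c
    while k < c + terms:
        parts.append(math.exp(log_t))
        log_t += math.log(lam) - math.log(k + 1)
        k += 1
        if parts[-1] < 1e-320:
            break
    return min(1.0, math.fsum(parts))


def binom_tail(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p) by direct term summation."""
    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    lp, lq = math.log(p), math.log1p(-p)
    parts = [
        math.exp(math.lgamma(n + 1) - math.lgamma(j + 1) - math.lgamma(n - j + 1)
                 + j * lp + (n - j) * lq)
        for j in range(k, n + 1)
    ]
    return min(1.0, math.fsum(parts))


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact-integer hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    pobs_num = math.comb(r1, a) * math.comb(r2, c1 - a)
    denom = math.comb(r1 + r2, c1)
    tot = 0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        num = math.comb(r1, k) * math.comb(r2, c1 - k)
        if num <= pobs_num:
            tot += num
    return tot / denom


def pearson_direct(x, y) -> float:
    """Textbook Pearson correlation from raw sums."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    num = n * (x * y).sum() - sx * sy
    den = math.sqrt(n * (x * x).sum() - sx * sx) * math.sqrt(n * (y * y).sum() - sy * sy)
    return num / den


def base_coverage_direct(
    site: tuple[str, int, int], tags: list[tuple[str, int, int]]
) -> int:
    """Per-base overlap depth summed across a site, tag by tag."""
    sc, ss, se = site
    return sum(
        max(0, min(te, se) - max(ts, ss)) for tc, ts, te in tags if tc == sc
    )
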