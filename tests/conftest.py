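import math

import pytest

from germburden.qc import FilterConfig


@pytest.fixture
def cfg():
    return FilterConfig()


# ---------------------------------------------------------------------------
# Independent brute-force oracles.  These deliberately recompute each
# quantity from first principles (exact integer arithmetic / enumeration)
# rather than calling the code paths they are used to check.


def hwe_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact-integer enumeration of the conditional HWE distribution."""
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = n_het + 2 * n_hom_alt
    weights = {}
    for h in range(n_alt % 2, min(n_alt, 2 * n - n_alt) + 1, 2):
        a = (n_alt - h) // 2
        r = n - h - a
        if r < 0:
            continue
        weights[h] = (
            math.factorial(n)
            // (math.factorial(r) * math.factorial(h) * math.factorial(a))
            * 2**h
        )
    total = sum(weights.values())
    if total == 0 or n_alt == 0 or n_alt == 2 * n:
        return 1.0
    obs = weights[n_het]
    return sum(w for w in weights.values() if w <= obs) / total


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact-integer hypergeometric enumeration."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0

    def weight(k):  # number of tables with cell (0,0) = k, up to 1/C(n, c1)
        return math.comb(r1, k) * math.comb(r2, c1 - k)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = {k: weight(k) for k in range(lo, hi + 1)}
    total = sum(weights.values())
    obs = weights[a]
    return sum(w for w in weights.values() if w <= obs) / total


def mannwhitney_exact_oracle(x, y):
    """Exact two-sided Mann-Whitney p by enumerating every split of the
    pooled values (no ties expected)."""
    from itertools import combinations

    pooled = sorted(x + y)
    n1 = len(x)

    def u_stat(group1):
        s1 = set(group1)
        u = 0
        for xi in group1:
            for yj in pooled:
                if yj in s1:
                    continue
                u += 1 if xi > yj else 0
        return u

    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    n1n2 = n1 * (len(pooled) - n1)
    dev_obs = abs(u_obs - n1n2 / 2)
    count = total = 0
    for group1 in combinations(pooled, n1):
        u = u_stat(group1)
        total += 1
        if abs(u - n1n2 / 2) >= dev_obs - 1e-9:
            count += 1
    return count / total


def bh_oracle(pvals, m):
    """Naive O(n^2) step-up q-values straight from the definition."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    ranks = [0] * n
    for rank0, i in enumerate(order):
        # ties share the largest rank
        tied = [j for j in range(n) if pvals[j] == pvals[i]]
        ranks[i] = max(order.index(j) for j in tied) + 1
    q = [0.0] * n
    for i in range(n):
        q[i] = min(
            min(pvals[j] * m / ranks[j] for j in range(n) if pvals[j] >= pvals[i]),
            1.0,
        )
    return q
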