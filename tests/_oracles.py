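"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately written from first principles (exact
arithmetic, explicit loops, enumeration) and independently of the package's
own code paths.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
from scipy import optimize, special, stats


def binomial_tail_onethird(n: int, k: int) -> float:
    """P(X >= k) for X ~ Binomial(n, 1/3), exact rational arithmetic."""
    p = Fraction(1, 3)
    total = Fraction(0)
    for i in range(k, n + 1):
        total += math.comb(n, i) * p**i * (1 - p) ** (n - i)
    return float(total)


def fisher_greater(table) -> float:
    """One-sided (greater) Fisher exact p by hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    total = Fraction(0)
    for a2 in range(max(0, c1 - r2), min(r1, c1) + 1):
        if a2 >= a:
            total += Fraction(math.comb(r1, a2) * math.comb(r2, c1 - a2), denom)
    return float(total)


def fisher_two_sided(table) -> float:
    """Two-sided Fisher exact p: sum of table probabilities <= the observed
    one (with a small relative gate for floating ties, as exact tests do)."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    pmf = {}
    for a2 in range(max(0, c1 - r2), min(r1, c1) + 1):
        pmf[a2] = Fraction(math.comb(r1, a2) * math.comb(r2, c1 - a2), denom)
    p_obs = pmf[a]
    gate = p_obs + p_obs / 10**7
    return float(sum(p for p in pmf.values() if p <= gate))


def bh_reference(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up, hand-coded: sort ascending, scale by
    n/rank, enforce monotonicity from the largest down, clip at 1."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    scaled = np.empty(n)
    for rank, idx in enumerate(order, start=1):
        scaled[idx] = p[idx] * n / rank
    # running minimum from the largest p downwards
    adj = scaled.copy()
    for i in range(n - 2, -1, -1):
        hi, lo = order[i + 1], order[i]
        adj[lo] = min(adj[lo], adj[hi])
    return np.minimum(adj, 1.0)


def _ranks_average_ties(x: np.ndarray) -> np.ndarray:
    """1-based ranks with tie averaging, written without scipy."""
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def tmm_reference(counts: np.ndarray, trim_m: float = 0.30, trim_a: float = 0.05) -> np.ndarray:
    """Step-by-step TMM factors written independently (explicit loops)."""
    counts = np.asarray(counts, dtype=float)
    nfeat, nsamp = counts.shape
    lib = counts.sum(axis=0)
    f75 = np.array([np.quantile(counts[:, j] / lib[j], 0.75) for j in range(nsamp)])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.ones(nsamp)
    for j in range(nsamp):
        if j == ref:
            continue
        M_list, A_list, v_list = [], [], []
        for g in range(nfeat):
            o, r = counts[g, j], counts[g, ref]
            if o <= 0 or r <= 0:
                continue
            po, pr = o / lib[j], r / lib[ref]
            M_list.append(math.log2(po / pr))
            A_list.append(0.5 * math.log2(po * pr))
            v_list.append((lib[j] - o) / (lib[j] * o) + (lib[ref] - r) / (lib[ref] * r))
        M = np.array(M_list)
        A = np.array(A_list)
        v = np.array(v_list)
        n = len(M)
        loM = math.floor(n * trim_m) + 1
        hiM = n + 1 - loM
        loA = math.floor(n * trim_a) + 1
        hiA = n + 1 - loA
        rM = _ranks_average_ties(M)
        rA = _ranks_average_ties(A)
        num = den = 0.0
        for g in range(n):
            if loM <= rM[g] <= hiM and loA <= rA[g] <= hiA:
                num += M[g] / v[g]
                den += 1.0 / v[g]
        factors[j] = 2.0 ** (num / den) if den > 0 else 1.0
    log_mean = np.mean([math.log(f) for f in factors])
    return factors / math.exp(log_mean)


def moderated_t_reference(X: np.ndarray, n_a: int):
    """Independent moderated t: per-row pooled variances, scaled-F prior by
    moment matching on log variances (trigamma inversion via brentq), shrunken
    variances and Student-t p-values.  Returns (d0, s0², t, p)."""
    A, B = X[:, :n_a], X[:, n_a:]
    nA, nB = A.shape[1], B.shape[1]
    d = nA + nB - 2
    s2 = np.array(
        [
            ((row_a - row_a.mean()) ** 2).sum() + ((row_b - row_b.mean()) ** 2).sum()
            for row_a, row_b in zip(A, B)
        ]
    ) / d
    z = np.log(s2)
    e = z - special.digamma(d / 2) + math.log(d / 2)
    ebar = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, d / 2)
    if evar > 0:
        g = optimize.brentq(lambda x: special.polygamma(1, x) - evar, 1e-6, 1e6)
        d0 = 2 * g
        s0_2 = math.exp(ebar + special.digamma(g) - math.log(g))
        post = (d0 * s0_2 + d * s2) / (d0 + d)
        dft = d0 + d
    else:
        d0 = math.inf
        s0_2 = math.exp(ebar)
        post = np.full(len(s2), s0_2)
        dft = math.inf
    diff = B.mean(axis=1) - A.mean(axis=1)
    t = diff / np.sqrt(post * (1 / nA + 1 / nB))
    p = 2 * stats.t.sf(np.abs(t), dft)
    return d0, s0_2, t, p


def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t**2 / (n - 2 + t**2))
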