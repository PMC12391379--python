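"""Label-free differential peptide presentation.

The workhorse is an empirical-Bayes moderated t-test: per-peptide pooled
variances are shrunk toward a prior (d0, s0²) fitted by matching the moments
of log(s²) across peptides (the scaled-F model for sample variances), and
the moderated statistic is referred to a Student-t with d0 + d degrees of
freedom.  BH adjustment and the hit/candidate fold-change–FDR classification
follow.

Missing intensities are handled by pairwise deletion: a peptide needs at
least two valid values per group to be tested; no imputation is performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ModeratedTestResult",
    "moderated_t_test",
    "bh_adjust",
    "classify_hits",
    "differential_peptides",
    "fit_variance_prior",
    "trigamma_inverse",
]


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by bisection.

    trigamma is strictly decreasing on (0, ∞) with range (0, ∞), so the root
    is unique; brackets are widened geometrically before bisecting.
    """
    if y <= 0:
        raise ValueError("trigamma is positive on (0, inf)")
    lo, hi = 1e-8, 1e8
    tri = lambda x: float(special.polygamma(1, x))
    while tri(lo) < y:
        lo /= 10.0
        if lo < 1e-300:
            return lo
    while tri(hi) > y:
        hi *= 10.0
        if hi > 1e300:
            return hi
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if tri(mid) > y:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def fit_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Fit the scaled-F prior (d0, s0²) to observed sample variances.

    Moment matching on z = log(s²): under the model, E[z] and Var[z] involve
    digamma/trigamma terms of d/2 and d0/2; the trigamma term in the excess
    variance is inverted by bisection.  Returns (inf, exp(mean)) when the
    observed spread is no larger than the sampling spread (complete
    shrinkage).  Zero or non-finite variances are excluded from the fit.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        raise ValueError("need at least two positive variances to fit the prior")
    s2, df = s2[ok], df[ok]
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    n = len(e)
    evar = float(e.var(ddof=1)) - float(np.mean(special.polygamma(1, df / 2.0)))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_2 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_2 = float(np.exp(emean))
    return d0, s0_2


@dataclass
class ModeratedTestResult:
    table: pd.DataFrame
    prior_df: float
    prior_var: float


def moderated_t_test(
    matrix: pd.DataFrame,
    groups: Sequence[str],
    prior_df_override: Optional[float] = None,
) -> ModeratedTestResult:
    """Per-peptide log2FC, moderated t and two-sided p (group B vs group A).

    ``matrix`` holds log2 intensities (rows peptides, columns samples);
    ``groups`` labels each column with one of exactly two group names (sorted
    order defines A and B; the fold change is B − A).  Missing values are
    excluded pairwise; peptides with fewer than two valid values in either
    group are skipped (status ``insufficient``).  ``prior_df_override=0``
    reduces the statistic to the classical pooled-variance t-test.
    """
    groups = np.asarray(groups)
    if len(groups) != matrix.shape[1]:
        raise ValueError("one group label per column required")
    names = sorted(set(groups))
    if len(names) != 2:
        raise ValueError(f"exactly two groups required, got {names}")
    a_cols = groups == names[0]
    b_cols = groups == names[1]

    X = matrix.to_numpy(dtype=float)
    A, B = X[:, a_cols], X[:, b_cols]
    nA = np.sum(np.isfinite(A), axis=1)
    nB = np.sum(np.isfinite(B), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        meanA = np.nansum(A, axis=1) / nA
        meanB = np.nansum(B, axis=1) / nB
        varA = np.nansum((A - meanA[:, None]) ** 2, axis=1)
        varB = np.nansum((B - meanB[:, None]) ** 2, axis=1)
    testable = (nA >= 2) & (nB >= 2)
    d = np.where(testable, nA + nB - 2, np.nan)
    s2 = np.where(testable, (varA + varB) / np.where(testable, d, 1), np.nan)
    log2fc = meanB - meanA

    if prior_df_override is not None:
        d0 = float(prior_df_override)
        s0_2 = 0.0 if d0 == 0 else float(np.nanmedian(s2[testable]))
    else:
        try:
            d0, s0_2 = fit_variance_prior(s2[testable], d[testable])
        except ValueError:
            # too few informative variances to borrow strength: no moderation
            d0, s0_2 = 0.0, 0.0

    n = len(matrix)
    t_stat = np.full(n, np.nan)
    p_val = np.full(n, np.nan)
    df_total = np.full(n, np.nan)
    idx = np.where(testable)[0]
    for i in idx:
        if np.isinf(d0):
            post_var = s0_2
            dft = np.inf
        else:
            post_var = (d0 * s0_2 + d[i] * s2[i]) / (d0 + d[i])
            dft = d0 + d[i]
        se = np.sqrt(post_var * (1.0 / nA[i] + 1.0 / nB[i]))
        if se == 0:
            t_stat[i] = np.inf if log2fc[i] != 0 else 0.0
            p_val[i] = 0.0 if log2fc[i] != 0 else 1.0
        else:
            t_stat[i] = log2fc[i] / se
            p_val[i] = 2.0 * stats.t.sf(abs(t_stat[i]), dft)
        df_total[i] = dft

    table = pd.DataFrame(
        {
            "peptide_id": matrix.index,
            "log2fc": log2fc,
            "moderated_t": t_stat,
            "p_value": p_val,
            "df_total": df_total,
            "n_valid_a": nA,
            "n_valid_b": nB,
            "status": np.where(testable, "tested", "insufficient"),
        }
    ).set_index("peptide_id")
    return ModeratedTestResult(table, d0, s0_2)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(len(p), np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def classify_hits(
    log2fc: Sequence[float],
    adj_p: Sequence[float],
    fc_hit: float = 2.0,
    fdr_hit: float = 0.05,
    fc_cand: float = 1.5,
    fdr_cand: float = 0.2,
) -> np.ndarray:
    """Hit/candidate classification on absolute fold change and FDR.

    FC = 2^|log2fc|.  Hits: FC strictly > ``fc_hit`` and adj_p ≤ ``fdr_hit``;
    candidates: FC ≥ ``fc_cand`` and adj_p ≤ ``fdr_cand``; otherwise ns.
    The sign of log2fc gives the up/down label; missing inputs are ns.
    """
    lfc = np.asarray(log2fc, dtype=float)
    ap = np.asarray(adj_p, dtype=float)
    fc = 2.0 ** np.abs(lfc)
    out = np.full(len(lfc), "ns", dtype=object)
    valid = np.isfinite(lfc) & np.isfinite(ap)
    cand = valid & (fc >= fc_cand) & (ap <= fdr_cand)
    hit = valid & (fc > fc_hit) & (ap <= fdr_hit)
    up = lfc > 0
    out[cand & up] = "candidate_up"
    out[cand & ~up] = "candidate_down"
    out[hit & up] = "hit_up"
    out[hit & ~up] = "hit_down"
    return out.astype(str)


def differential_peptides(
    matrix: pd.DataFrame,
    groups: Sequence[str],
    fc_hit: float = 2.0,
    fdr_hit: float = 0.05,
    fc_cand: float = 1.5,
    fdr_cand: float = 0.2,
) -> ModeratedTestResult:
    """Full differential-presentation analysis: moderated t, BH, classes."""
    res = moderated_t_test(matrix, groups)
    t = res.table
    t["adj_p"] = bh_adjust(t["p_value"])
    t["class"] = classify_hits(
        t["log2fc"], t["adj_p"], fc_hit, fdr_hit, fc_cand, fdr_cand
    )
    return res
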