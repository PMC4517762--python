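"""Independent brute-force oracles used by the test suite.

Each oracle deliberately avoids the code path (and the library routine)
it is used to check: binomial tail sums are summed termwise instead of
using beta quantiles, Fisher p-values enumerate the hypergeometric
support with exact integer weights, AUC counts pairs, and the grid-search
oracle recomputes every scenario from scratch with plain loops.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


# --- exact binomial interval via tail-sum bisection ------------------------

def _binom_pmf_terms(n: int, p: float) -> np.ndarray:
    js = np.arange(n + 1)
    # log-space for numerical safety at large n
    with np.errstate(divide="ignore"):
        logpmf = (
            [math.lgamma(n + 1) - math.lgamma(j + 1) - math.lgamma(n - j + 1) for j in js]
            + js * (np.log(p) if p > 0 else -np.inf)
            + (n - js) * (np.log1p(-p) if p < 1 else -np.inf)
        )
    out = np.exp(logpmf)
    if p == 0:
        out = np.zeros(n + 1)
        out[0] = 1.0
    if p == 1:
        out = np.zeros(n + 1)
        out[n] = 1.0
    return out


def _tail_ge(k: int, n: int, p: float) -> float:
    return float(_binom_pmf_terms(n, p)[k:].sum())


def _tail_le(k: int, n: int, p: float) -> float:
    return float(_binom_pmf_terms(n, p)[: k + 1].sum())


def _bisect(fn, lo: float, hi: float, increasing: bool, iters: int = 52) -> float:
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if (fn(mid) < 0) == increasing:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def clopper_pearson_oracle(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed exact interval from the two one-sided tail conditions."""
    alpha = 1 - level
    if k == 0:
        lower = 0.0
    else:
        # P(X >= k | p) is increasing in p; solve = alpha/2
        lower = _bisect(lambda p: _tail_ge(k, n, p) - alpha / 2, 0.0, 1.0, increasing=True)
    if k == n:
        upper = 1.0
    else:
        # P(X <= k | p) is decreasing in p; solve = alpha/2
        upper = _bisect(lambda p: alpha / 2 - _tail_le(k, n, p), 0.0, 1.0, increasing=True)
    return lower, upper


def clopper_pearson_oracle_all(n: int, level: float = 0.95, iters: int = 52):
    """Tail-sum bisection bounds for every k in 0..n at once (vectorized).

    Returns (lower, upper) arrays of length n+1. Same construction as
    :func:`clopper_pearson_oracle` but the binomial pmf is evaluated as a
    matrix over (k-specific probe p, support j) per bisection step.
    """
    alpha2 = (1 - level) / 2
    js = np.arange(n + 1)
    logcomb = np.array(
        [math.lgamma(n + 1) - math.lgamma(j + 1) - math.lgamma(n - j + 1) for j in js]
    )

    def pmf_matrix(p: np.ndarray) -> np.ndarray:
        # rows: one probe probability per k; columns: support j
        p = p[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            logpmf = logcomb[None, :] + js[None, :] * np.log(p) + (n - js)[None, :] * np.log1p(-p)
        return np.exp(logpmf)

    ks = js
    # lower bounds: solve P(X >= k | p) = alpha/2 (increasing in p), k >= 1
    lo, hi = np.zeros(n + 1), np.ones(n + 1)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        m = pmf_matrix(mid)
        tail_ge = np.cumsum(m[:, ::-1], axis=1)[:, ::-1][ks, ks]
        take_lo = tail_ge < alpha2
        lo = np.where(take_lo, mid, lo)
        hi = np.where(take_lo, hi, mid)
    lower = 0.5 * (lo + hi)
    lower[0] = 0.0

    # upper bounds: solve P(X <= k | p) = alpha/2 (decreasing in p), k <= n-1
    lo, hi = np.zeros(n + 1), np.ones(n + 1)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        m = pmf_matrix(mid)
        tail_le = np.cumsum(m, axis=1)[ks, ks]
        take_lo = tail_le > alpha2
        lo = np.where(take_lo, mid, lo)
        hi = np.where(take_lo, hi, mid)
    upper = 0.5 * (lo + hi)
    upper[n] = 1.0
    return lower, upper


# --- Fisher exact by full-support enumeration ------------------------------

def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided point-probability p by exact integer enumeration.

    Tables with probability at most the observed one (within 1e-7
    relative slack, the conventional guard against representation noise)
    are summed over the whole hypergeometric support.
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    kmin, kmax = max(0, c1 - r2), min(r1, c1)
    weights = {k: math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(kmin, kmax + 1)}
    obs = weights[a]
    total = sum(w for w in weights.values() if w <= obs * (1 + 1e-7))
    return float(Fraction(total, denom))


# --- AUC by pair counting --------------------------------------------------

def auc_pair_counting(scores_malignant, scores_benign) -> float:
    """P(score_mal > score_ben) + 0.5 P(tie), by brute force over all pairs."""
    wins = ties = 0
    for sm in scores_malignant:
        for sb in scores_benign:
            if sm > sb:
                wins += 1
            elif sm == sb:
                ties += 1
    return (wins + 0.5 * ties) / (len(scores_malignant) * len(scores_benign))


# --- grid-search re-implementation ----------------------------------------

def gridsearch_oracle(records, grid_scenarios, floor: float):
    """Recompute every scenario from scratch and pick per-group winners.

    ``grid_scenarios`` is an iterable of (fpsa_threshold, psa_low,
    psa_high). Returns {group_label: (t, low, high) | None}. The ranking
    maximizes (specificity, ppv, npv, -psa_low, fpsa_threshold,
    -psa_high), with undefined ratios ranked below any defined value.
    """
    from psascreen.cohort import assign_age_group

    groups: dict[str, list] = {}
    for r in records:
        groups.setdefault(assign_age_group(r.age).label, []).append(r)

    neg = float("-inf")
    out = {}
    for label, sub in groups.items():
        best = None
        best_key = None
        for t, low, high in grid_scenarios:
            tp = fp = tn = fn = 0
            for r in sub:
                flagged = (r.psa >= low) if r.fpsa_pct <= t else (r.psa >= high)
                if r.malignant:
                    tp += flagged
                    fn += not flagged
                else:
                    fp += flagged
                    tn += not flagged
            if tp + fn == 0 or tp / (tp + fn) < floor:
                continue
            spec = tn / (tn + fp) if tn + fp else neg
            ppv = tp / (tp + fp) if tp + fp else neg
            npv = tn / (tn + fn) if tn + fn else neg
            key = (spec, ppv, npv, -low, t, -high)
            if best_key is None or key > best_key:
                best, best_key = (t, low, high), key
        out[label] = best
    return out
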