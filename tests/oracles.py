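"""Independent brute-force oracles used to cross-check the implementation.

Each oracle is deliberately naive — closed forms, exhaustive enumeration,
direct formula evaluation — and shares no code path with the package.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def nnls_active_set_oracle(p: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Solve min ||y - (p*bT + (1-p)*bS)||^2, bT,bS >= 0 by enumerating the
    four sign cases: both free (closed-form 2x2 normal equations), one
    coefficient pinned at zero with a clipped 1-D projection, and both zero.
    Returns (coefficients, SSE) of the feasible case with smallest SSE.
    """
    design = np.column_stack([p, 1.0 - p])
    candidates = [np.zeros(2)]
    xtx = design.T @ design
    xty = design.T @ y
    if np.linalg.matrix_rank(xtx) == 2:
        free = np.linalg.solve(xtx, xty)
        if (free >= 0).all():
            candidates.append(free)
    for pinned in (0, 1):
        col = design[:, 1 - pinned]
        denom = col @ col
        coef = max(0.0, (col @ y) / denom) if denom > 0 else 0.0
        candidate = np.zeros(2)
        candidate[1 - pinned] = coef
        candidates.append(candidate)
    sses = [float(np.sum((y - design @ c) ** 2)) for c in candidates]
    best = int(np.argmin(sses))
    return candidates[best], sses[best]


def km_product_limit_oracle(times: np.ndarray, events: np.ndarray) -> dict[float, float]:
    """S(t) at each distinct event time by direct product over Pi(1 - d/n)."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    surv = {}
    s = 1.0
    for t in sorted(set(times[events])):
        n_at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & events))
        s *= 1.0 - d / n_at_risk
        surv[t] = s
    return surv


def km_median_oracle(times: np.ndarray, events: np.ndarray) -> float:
    """Smallest event time with S(t) <= 0.5, NaN if never reached."""
    for t, s in km_product_limit_oracle(times, events).items():
        if s <= 0.5 + 1e-15:
            return t
    return float("nan")


def logrank_oracle(
    times_a: np.ndarray,
    events_a: np.ndarray,
    times_b: np.ndarray,
    events_b: np.ndarray,
) -> tuple[float, float]:
    """Hand-tabulated O/E/Var log-rank with hypergeometric variance."""
    times_a, times_b = np.asarray(times_a, float), np.asarray(times_b, float)
    events_a, events_b = np.asarray(events_a, bool), np.asarray(events_b, bool)
    all_times = np.concatenate([times_a, times_b])
    all_events = np.concatenate([events_a, events_b])
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(all_times[all_events])):
        n1 = int(np.sum(times_a >= t))
        n2 = int(np.sum(times_b >= t))
        n = n1 + n2
        d1 = int(np.sum((times_a == t) & events_a))
        d = int(np.sum((all_times == t) & all_events))
        if n == 0 or n1 == 0 and n2 == 0:
            continue
        expected = d * n1 / n
        o_minus_e += d1 - expected
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = o_minus_e**2 / var if var > 0 else 0.0
    return chi2, float(stats.chi2.sf(chi2, df=1))


def bh_stepup_oracle(p_values: np.ndarray) -> np.ndarray:
    """Direct formula q_(i) = min_{j >= i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p_values, float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    for rank_pos, idx in enumerate(order):
        candidates = [p[order[j]] * m / (j + 1) for j in range(rank_pos, m)]
        adjusted[idx] = min(1.0, min(candidates))
    return adjusted


def spearman_rank_difference_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Classical 1 - 6*sum(d^2)/(n(n^2-1)); valid only for tie-free data."""
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    d2 = np.sum((rx - ry) ** 2)
    return 1.0 - 6.0 * d2 / (n * (n**2 - 1))


def membership_count_oracle(sets: dict[str, set[str]], min_sets: int) -> set[str]:
    """Exhaustive scan over the union counting each symbol's memberships."""
    universe = set().union(*sets.values())
    return {
        g for g in universe if sum(g in s for s in sets.values()) >= min_sets
    }
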