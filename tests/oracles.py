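"""Independent reference implementations used to check the package.

Everything here is deliberately written in the most direct way possible
(explicit loops, normal equations, exhaustive enumeration) and shares no
code with the package paths it validates.
"""

from __future__ import annotations

import itertools

import numpy as np


def ols_normal_equations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Closed-form OLS coefficients from the normal equations."""
    return np.linalg.solve(X.T @ X, X.T @ y)


def bh_step_up(p):
    """Literal Benjamini-Hochberg: q_(i) = min_{j>=i} p_(j) * m / j."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    running_min = float("inf")
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        q[i] = min(running_min, 1.0)
    return q


def pooled_t(a, b):
    """Textbook equal-variance two-sample t statistic."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))


def running_sum_es(scores, in_set, weight_exponent):
    """Brute-force weighted-KS enrichment score, one step at a time."""
    best_pos, best_neg = running_sum_extrema(scores, in_set, weight_exponent)
    return best_pos if best_pos >= -best_neg else best_neg


def running_sum_extrema(scores, in_set, weight_exponent):
    """(max positive deviation, min negative deviation) of the running sum."""
    scores = [float(s) for s in scores]
    n = len(scores)
    hits = [bool(h) for h in in_set]
    k = sum(hits)
    total = sum(abs(s) ** weight_exponent for s, h in zip(scores, hits) if h)
    run = 0.0
    best_pos, best_neg = 0.0, 0.0
    for s, h in zip(scores, hits):
        if h:
            if total > 0:
                run += abs(s) ** weight_exponent / total
            else:
                run += 1.0 / k
        else:
            run -= 1.0 / (n - k)
        best_pos = max(best_pos, run)
        best_neg = min(best_neg, run)
    return best_pos, best_neg


def spearman_reference(x, y):
    from scipy.stats import spearmanr

    return float(spearmanr(x, y).statistic)


# ---------------------------------------------------------------------------
# exhaustive causal-network oracle


def _explainable(edges, states, perturbation):
    """Fixed-point propagation: every active node must eventually be
    explained by a consistent in-edge from an already-explained node."""
    active = {v for v, s in states.items() if s != 0}
    if perturbation not in active:
        return not active
    explained = {perturbation}
    changed = True
    while changed:
        changed = False
        for src, sign, tgt in edges:
            if (
                tgt in active
                and tgt not in explained
                and src in explained
                and states[src] != 0
                and sign * states[src] == states[tgt]
            ):
                explained.add(tgt)
                changed = True
    return active <= explained


def exhaustive_min_objective(
    edges, perturbation, pert_sign, tf_measurements, weights, beta
):
    """Minimum objective (and all optimal state maps) by full enumeration.

    ``pert_sign`` may be +1, -1 or "free". Returns (best_objective,
    list of optimal state dicts).
    """
    nodes = sorted({v for e in edges for v in (e[0], e[2])})
    others = [v for v in nodes if v != perturbation]
    signs = [1, -1] if pert_sign == "free" else [pert_sign]
    best = None
    best_states = []
    for ps in signs:
        for combo in itertools.product([-1, 0, 1], repeat=len(others)):
            states = dict(zip(others, combo))
            states[perturbation] = ps
            if not _explainable(edges, states, perturbation):
                continue
            obj = beta * sum(1 for s in states.values() if s != 0)
            for tf, measured in tf_measurements.items():
                if states.get(tf, 0) != measured:
                    obj += weights[tf]
            if best is None or obj < best - 1e-9:
                best = obj
                best_states = [states]
            elif abs(obj - best) <= 1e-9:
                best_states.append(states)
    return best, best_states
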