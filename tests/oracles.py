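"""Independent brute-force oracles used to check the fast implementations.

These are deliberately written as plain loops / exhaustive enumerations,
kept separate from the library code paths they verify.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def ks_running_sum_oracle(positions, n: int) -> float:
    """Signed KS statistic by walking the full ranking once.

    Tracks the set's empirical CDF step by step; the top excess is taken
    at each hit (after the step), the bottom excess just before it.
    """
    pos = set(int(p) for p in positions)
    t = len(pos)
    best_top = -np.inf
    best_bottom = -np.inf
    j = 0
    for k in range(1, n + 1):
        if k in pos:
            best_bottom = max(best_bottom, k / n - j / t)
            j += 1
            best_top = max(best_top, j / t - k / n)
    return best_top if best_top > best_bottom else -best_bottom


def mann_whitney_enumeration(x, y, alternative: str = "greater") -> float:
    """Exact Mann-Whitney p by enumerating all C(n+m, n) labelings.

    Assumes no ties in the pooled sample.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = x + y
    n = len(x)

    def u_of(xs, ys):
        return sum(1 for a in xs for b in ys if a > b)

    u_obs = u_of(x, y)
    us = []
    for idx in combinations(range(len(pooled)), n):
        chosen = set(idx)
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in chosen]
        us.append(u_of(xs, ys))
    us = np.array(us, dtype=float)
    p_greater = float(np.mean(us >= u_obs))
    p_less = float(np.mean(us <= u_obs))
    if alternative == "greater":
        return p_greater
    if alternative == "less":
        return p_less
    return min(1.0, 2.0 * min(p_greater, p_less))


def cooccurrence_tally_oracle(list_of_drug_lists) -> dict[str, int]:
    """Per-drug count of lists containing it, by scanning every pair."""
    all_drugs = sorted({d for lst in list_of_drug_lists for d in lst})
    counts = {}
    for drug in all_drugs:
        c = 0
        for lst in list_of_drug_lists:
            if drug in set(lst):
                c += 1
        counts[drug] = c
    return counts


def drug_ranking_positions_oracle(es_by_drug: dict[str, float], drug_set) -> list[int]:
    """Positions of a drug set in the es-descending ranking (ties by id)."""
    ranking = sorted(es_by_drug, key=lambda d: (-es_by_drug[d], d))
    return sorted(ranking.index(d) + 1 for d in drug_set)
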