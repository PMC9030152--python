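"""Brute-force oracles kept independent of the library code paths they check."""

from __future__ import annotations

from itertools import combinations

import numpy as np


def mann_whitney_enumeration(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by enumerating all C(n1+n2, n1) labelings.

    Returns (U for x, two-sided p). Assumes tie-free pooled data.
    U(labeling) = number of (xi, yj) pairs with xi > yj.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = x + y
    n1, n2 = len(x), len(y)

    def u_of(x_vals, y_vals):
        return sum(1.0 for xi in x_vals for yj in y_vals if xi > yj) + 0.5 * sum(
            1 for xi in x_vals for yj in y_vals if xi == yj
        )

    u_obs = u_of(x, y)
    us = []
    idx = range(n1 + n2)
    for chosen in combinations(idx, n1):
        chosen_set = set(chosen)
        xs = [pooled[i] for i in chosen]
        ys = [pooled[i] for i in idx if i not in chosen_set]
        us.append(u_of(xs, ys))
    us = np.array(us)
    p_low = np.mean(us <= u_obs)
    p_high = np.mean(us >= u_obs)
    p = min(1.0, 2.0 * min(p_low, p_high))
    return u_obs, float(p)


def highest_kcore_weight_bruteforce(adjacency: dict[str, set[str]], v: str) -> float:
    """MCODE vertex weight via subset enumeration over the closed neighborhood.

    The highest k-core is found by scanning every vertex subset of N[v] for
    the largest achievable minimum induced degree; the core is the union of
    all subsets achieving it (unions preserve the minimum-degree bound).
    """
    closed = sorted({v} | adjacency[v])
    n = len(closed)
    index = {u: i for i, u in enumerate(closed)}
    masks = [0] * n
    for i, u in enumerate(closed):
        for w in adjacency[u]:
            if w in index:
                masks[i] |= 1 << index[w]

    best_k = 0
    for subset in range(1, 1 << n):
        if subset & (subset - 1) == 0:
            continue  # single vertex: no edges
        min_deg = min(
            bin(masks[i] & subset).count("1") for i in range(n) if subset >> i & 1
        )
        best_k = max(best_k, min_deg)
    if best_k == 0:
        return 0.0
    core_mask = 0
    for subset in range(1, 1 << n):
        if subset & (subset - 1) == 0:
            continue
        min_deg = min(
            bin(masks[i] & subset).count("1") for i in range(n) if subset >> i & 1
        )
        if min_deg >= best_k:
            core_mask |= subset
    members = [i for i in range(n) if core_mask >> i & 1]
    m = len(members)
    edges = sum(bin(masks[i] & core_mask).count("1") for i in members) // 2
    density = 2.0 * edges / (m * (m - 1))
    return best_k * density
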