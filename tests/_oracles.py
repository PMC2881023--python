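"""Independent brute-force oracles used by the test suite.

Each function here re-derives a quantity by the most literal method
available (definition-level loops, exhaustive enumeration, textbook
formulas) and is kept free of any package internals beyond plain numpy.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats


def naive_bh(p):
    """Benjamini–Hochberg step-up straight from the definition, O(n²).

    adj_i = min over thresholds t ∈ {p_j : p_j ≥ p_i} of n·t / #{p ≤ t},
    capped at 1.
    """
    p = np.asarray(p, dtype=float)
    n = len(p)
    adj = np.empty(n)
    for i in range(n):
        candidates = [
            min(1.0, n * t / np.sum(p <= t)) for t in p if t >= p[i]
        ]
        adj[i] = min(candidates)
    return adj


def complete_linkage_heights(dist):
    """Complete-linkage agglomeration by definition-level loops, O(n³).

    Returns the sorted list of merge heights.
    """
    d = np.asarray(dist, dtype=float)
    clusters = [[i] for i in range(d.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = (None, None, np.inf)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                h = max(d[a, b] for a in clusters[i] for b in clusters[j])
                if h < best[2]:
                    best = (i, j, h)
        i, j, h = best
        heights.append(h)
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return sorted(heights)


def yates_two_proportion_p(x1, n1, x2, n2):
    """Textbook Yates-corrected chi-square for a 2×2 table, df = 1."""
    a, b = x1, n1 - x1
    c, d = x2, n2 - x2
    n = a + b + c + d
    num = n * (abs(a * d - b * c) - n / 2.0) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    chi2 = max(num / den, 0.0)
    return float(stats.chi2.sf(chi2, 1))


def welch_p(a, b):
    """Welch t-test from the textbook formulas."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return 2 * stats.t.sf(abs(t), df)


def enumerate_family_fdr(universe, categories, list_size, observed_list):
    """Family-wise empirical FDR by exhaustive enumeration of all possible
    gene lists of the given size (the exact limit of the permutation FDR).

    Returns {category: fdr} for the observed list, before any monotonicity
    enforcement — enforced separately by the caller if needed.
    """
    universe = sorted(universe)
    N = len(universe)
    cat_names = sorted(categories)
    K = {c: len(set(categories[c]) & set(universe)) for c in cat_names}

    def e_values(genes):
        out = {}
        for c in cat_names:
            k = len(set(categories[c]) & set(genes))
            out[c] = (k / list_size) / (K[c] / N)
        return out

    e_obs = e_values(observed_list)
    all_perm_es = []
    for combo in itertools.combinations(universe, list_size):
        all_perm_es.append(e_values(combo))
    n_perm = len(all_perm_es)

    fdr = {}
    for c in cat_names:
        thresh = e_obs[c]
        mean_exceed = (
            sum(sum(1 for d in cat_names if es[d] >= thresh)
                for es in all_perm_es) / n_perm
        )
        obs_exceed = sum(1 for d in cat_names if e_obs[d] >= thresh)
        fdr[c] = min(1.0, mean_exceed / max(obs_exceed, 1))
    # monotone in E, mirroring a q-value-style suffix minimum
    order = sorted(cat_names, key=lambda c: -e_obs[c])
    suffix = {}
    running = np.inf
    for c in reversed(order):
        running = min(running, fdr[c])
        suffix[c] = running
    return {c: suffix[c] for c in cat_names}, e_obs


def tally_two_way(r_scores, s_scores):
    """Brute-force 5×5 tally of (R, S) pairs."""
    grid = np.zeros((5, 5), dtype=int)
    for r, s in zip(r_scores, s_scores):
        grid[r + 2, s + 2] += 1
    return grid
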