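"""Permutation-based category over-representation for gene lists.

For a gene list of size n drawn from a universe of N genes, a category with
K members in the universe and k in the list has enrichment ratio

    E = (k / n) / (K / N),

i.e. how many times more often category members appear in the list than
expected by chance. Significance comes from permutations: random gene sets
of the same size are drawn without replacement from the universe and every
category's E recomputed. The default FDR is the family-wise empirical FDR of
classic over-representation tools: for each observed threshold E_c,

    FDR(c) = mean_perm #{categories with E_perm >= E_c}
             ----------------------------------------------
                  #{real categories with E_obs >= E_c}

clipped to [0, 1] and made monotone non-increasing in E. A per-category
empirical p-value mode is available via ``mode="per_category"``.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .data import InputError
from .linmod import adjust_bh

__all__ = [
    "AnnotationMap",
    "read_gmt",
    "enrichment_ratio",
    "permutation_fdr",
    "significant_categories",
    "compare_term_overlap",
]


@dataclass
class AnnotationMap:
    """Category → gene-set annotation over a gene universe.

    On construction, category members are restricted to the universe and
    categories with fewer than ``min_size`` remaining genes are dropped.
    """

    categories: dict[str, set[str]]
    universe: set[str]
    min_size: int = 5
    dropped: list[str] = field(default_factory=list, init=False)

    def __post_init__(self) -> None:
        restricted: dict[str, set[str]] = {}
        for cat, genes in self.categories.items():
            inter = set(genes) & self.universe
            if len(inter) >= self.min_size:
                restricted[cat] = inter
            else:
                self.dropped.append(cat)
        self.categories = restricted

    @property
    def category_ids(self) -> list[str]:
        return sorted(self.categories)

    def sizes(self) -> dict[str, int]:
        return {c: len(g) for c, g in self.categories.items()}


def read_gmt(path) -> dict[str, set[str]]:
    """Parse a GMT file (category, description, genes...), tab-separated."""
    cats: dict[str, set[str]] = {}
    for line in pathlib.Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise InputError(f"malformed GMT line (need >= 3 fields): {line[:60]!r}")
        cats[parts[0]] = set(g for g in parts[2:] if g)
    return cats


def write_gmt(categories: Mapping[str, Iterable[str]], path) -> None:
    lines = ["\t".join([cat, "na", *sorted(genes)])
             for cat, genes in sorted(categories.items())]
    pathlib.Path(path).write_text("\n".join(lines) + "\n")


def read_two_column(path) -> dict[str, set[str]]:
    """Parse a two-column TSV of (category, gene) pairs."""
    df = pd.read_csv(path, sep="\t", header=None, names=["category", "gene"],
                     dtype=str)
    return {c: set(g["gene"]) for c, g in df.groupby("category")}


# ----------------------------------------------------------------- ratios
def enrichment_ratio(k: int, n: int, K: int, N: int) -> float:
    """E = (k/n)/(K/N); NaN when K = 0 (undefined, reported as NA)."""
    if not 0 < n <= N:
        raise ValueError(f"need 0 < n <= N, got n={n}, N={N}")
    if not 0 <= K <= N:
        raise ValueError(f"need 0 <= K <= N, got K={K}, N={N}")
    if not 0 <= k <= min(n, K):
        raise ValueError(f"need 0 <= k <= min(n, K), got k={k}")
    if K == 0:
        return float("nan")
    return (k / n) / (K / N)


def _exceedance_ge(sorted_vals: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """#{values >= t} for each t, values pre-sorted ascending."""
    return sorted_vals.size - np.searchsorted(sorted_vals, thresholds, side="left")


def permutation_fdr(
    gene_list: Iterable[str],
    annotation: AnnotationMap,
    n_perm: int = 1000,
    seed: int = 0,
    mode: str = "family",
) -> pd.DataFrame:
    """Observed enrichment and permutation FDR for every category.

    Each permutation draws a random gene set of size ``len(gene_list)``
    without replacement from the universe and recomputes all category E
    values. Deterministic given ``seed``.

    Returns a DataFrame indexed by category with columns ``n, k, N, K, E,
    fdr`` (family mode) plus ``p_empirical`` in per-category mode, where the
    empirical p uses the add-one convention (r+1)/(n_perm+1) and ``fdr`` is
    its BH adjustment.
    """
    genes = sorted(set(gene_list))
    universe = sorted(annotation.universe)
    stray = set(genes) - set(universe)
    if stray:
        raise InputError(f"genes not in universe: {sorted(stray)[:10]}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if mode not in ("family", "per_category"):
        raise ValueError(f"unknown mode {mode!r}")

    N, n = len(universe), len(genes)
    if n == 0:
        raise InputError("gene list is empty")
    idx_of = {g: i for i, g in enumerate(universe)}
    cats = annotation.category_ids
    member = np.zeros((len(cats), N), dtype=bool)
    for ci, cat in enumerate(cats):
        member[ci, [idx_of[g] for g in annotation.categories[cat]]] = True
    K = member.sum(axis=1)

    list_idx = np.array([idx_of[g] for g in genes])
    k_obs = member[:, list_idx].sum(axis=1)
    with np.errstate(invalid="ignore"):
        e_obs = (k_obs / n) / (K / N)

    rng = np.random.default_rng(seed)
    e_perm = np.empty((n_perm, len(cats)))
    for p in range(n_perm):
        draw = rng.choice(N, size=n, replace=False)
        k_p = member[:, draw].sum(axis=1)
        e_perm[p] = (k_p / n) / (K / N)

    out = pd.DataFrame(
        {"n": n, "k": k_obs, "N": N, "K": K, "E": e_obs},
        index=pd.Index(cats, name="category"),
    )

    finite = np.isfinite(e_obs)
    if mode == "per_category":
        exceed = (e_perm >= e_obs[None, :]).sum(axis=0)
        p_emp = (exceed + 1) / (n_perm + 1)
        out["p_empirical"] = np.where(finite, p_emp, np.nan)
        fdr = np.full(len(cats), np.nan)
        if finite.any():
            fdr[finite] = adjust_bh(p_emp[finite])
        out["fdr"] = fdr
        return out

    # family-wise empirical FDR
    obs_sorted = np.sort(e_obs[finite])
    perm_sorted = np.sort(e_perm[:, finite].ravel())
    fdr = np.full(len(cats), np.nan)
    fin_idx = np.where(finite)[0]
    thresholds = e_obs[fin_idx]
    mean_perm_exceed = _exceedance_ge(perm_sorted, thresholds) / n_perm
    obs_exceed = _exceedance_ge(obs_sorted, thresholds)
    raw = np.clip(mean_perm_exceed / np.maximum(obs_exceed, 1), 0.0, 1.0)
    # monotone in E: a category with larger E never gets a larger FDR
    order = np.argsort(-thresholds, kind="stable")
    raw_sorted = raw[order]
    adj_sorted = np.minimum.accumulate(raw_sorted[::-1])[::-1]
    fdr[fin_idx[order]] = adj_sorted
    out["fdr"] = fdr
    return out


def significant_categories(rows: pd.DataFrame, fdr_threshold: float = 0.05) -> set[str]:
    """Category IDs with FDR below the threshold (default 5%)."""
    mask = rows["fdr"] < fdr_threshold
    return set(rows.index[mask.fillna(False)])


def compare_term_overlap(named_sets: Mapping[str, set[str]]) -> dict:
    """All-way and pairwise overlap of significant-category sets."""
    names = list(named_sets)
    if len(names) < 2:
        raise ValueError("need at least 2 category sets to compare")
    sets = [named_sets[k] for k in names]
    inter_all = set.intersection(*sets)
    union_all = set.union(*sets)
    pairwise = {
        (a, b): len(named_sets[a] & named_sets[b])
        for i, a in enumerate(names)
        for b in names[i + 1:]
    }
    return {
        "sizes": {k: len(v) for k, v in named_sets.items()},
        "intersection_all": len(inter_all),
        "intersection_all_ids": sorted(inter_all),
        "union_all": len(union_all),
        "pairwise": pairwise,
    }
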