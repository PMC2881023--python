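"""Tri-state response scoring and cross-strain concordance classification.

Each gene receives, per strain, a score in {−1, 0, +1}: significantly
repressed, unaltered, or significantly induced at an adjusted-p threshold
(default 0.01). Scores are summed within each phenotype collective —
``R`` over the two resistant strains and ``S`` over the two sensitive
strains, each in −2..+2 — and the pair (R, S) classifies the gene:

========================  =======================================
total T = R + S = ±4      TYPE_I_UP / TYPE_I_DOWN (concordant in
                          all four strains)
|R| = |S| = 2, T = 0      TYPE_I_DISCORDANT (opposite directions
                          in the two collectives; empirically
                          unobserved)
|R| = 2, S = 0            TYPE_II_RESISTANT (resistant-only)
|S| = 2, R = 0            TYPE_II_SENSITIVE (sensitive-only)
R = S = 0                 UNRESPONSIVE
anything else             PARTIAL
========================  =======================================

The 5×5 table of gene counts over (R, S) summarizes the whole experiment;
:func:`summarize_overlap` derives the headline counts (genes responsive
anywhere / per collective, within-collective overlap, Type-I/Type-II
tallies) and :func:`proportion_test` compares overlap proportions between
collectives.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .data import RESISTANT, SENSITIVE, InputError

logger = logging.getLogger(__name__)

SCORE_RANGE = (-2, -1, 0, 1, 2)

TYPE_I_UP = "TYPE_I_UP"
TYPE_I_DOWN = "TYPE_I_DOWN"
TYPE_I_DISCORDANT = "TYPE_I_DISCORDANT"
TYPE_II_SENSITIVE = "TYPE_II_SENSITIVE"
TYPE_II_RESISTANT = "TYPE_II_RESISTANT"
PARTIAL = "PARTIAL"
UNRESPONSIVE = "UNRESPONSIVE"

CLASS_LABELS = (
    TYPE_I_UP,
    TYPE_I_DOWN,
    TYPE_I_DISCORDANT,
    TYPE_II_SENSITIVE,
    TYPE_II_RESISTANT,
    PARTIAL,
    UNRESPONSIVE,
)


# ------------------------------------------------------------------ scoring
def score_gene(p_adj: Mapping[str, float], log2fc: Mapping[str, float],
               alpha: float = 0.01) -> dict[str, int]:
    """Tri-state score per strain: sign(log2FC) when p_adj < alpha, else 0.

    An exact-zero fold change with a significant p (sign undefined) scores 0
    with a warning; practically unreachable in floating point.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    scores: dict[str, int] = {}
    for strain in p_adj:
        p, fc = p_adj[strain], log2fc.get(strain)
        if p is None or fc is None or not np.isfinite(p) or not np.isfinite(fc):
            raise InputError(f"incomplete record for strain {strain!r}")
        if p < alpha:
            if fc == 0.0:
                logger.warning(
                    "significant adjusted p with exact-zero fold change in "
                    "strain %s; scoring 0", strain)
                scores[strain] = 0
            else:
                scores[strain] = int(np.sign(fc))
        else:
            scores[strain] = 0
    return scores


def classify(r: int, s: int) -> str:
    """Class label from the (resistant, sensitive) collective score pair."""
    if r not in SCORE_RANGE or s not in SCORE_RANGE:
        raise ValueError(f"collective scores must lie in -2..2, got ({r}, {s})")
    t = r + s
    if t == 4:
        return TYPE_I_UP
    if t == -4:
        return TYPE_I_DOWN
    if abs(r) == 2 and abs(s) == 2:  # t == 0 here
        return TYPE_I_DISCORDANT
    if abs(r) == 2 and s == 0:
        return TYPE_II_RESISTANT
    if abs(s) == 2 and r == 0:
        return TYPE_II_SENSITIVE
    if r == 0 and s == 0:
        return UNRESPONSIVE
    return PARTIAL


@dataclass
class TwoWayTable:
    """5×5 grid of gene counts indexed by (R, S) ∈ {−2..2}²."""

    counts: pd.DataFrame  # rows: R = -2..2, columns: S = -2..2

    def __post_init__(self) -> None:
        self.counts = self.counts.reindex(
            index=list(SCORE_RANGE), columns=list(SCORE_RANGE), fill_value=0
        ).astype(int)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("two-way table counts must be non-negative")

    @classmethod
    def from_grid(cls, grid) -> "TwoWayTable":
        arr = np.asarray(grid, dtype=int)
        if arr.shape != (5, 5):
            raise ValueError("grid must be 5x5 (R = -2..2 by S = -2..2)")
        return cls(pd.DataFrame(arr, index=list(SCORE_RANGE),
                                columns=list(SCORE_RANGE)))

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def cell(self, r: int, s: int) -> int:
        return int(self.counts.loc[r, s])

    def marginals(self) -> tuple[pd.Series, pd.Series]:
        """(resistant-score marginal, sensitive-score marginal)."""
        return self.counts.sum(axis=1), self.counts.sum(axis=0)

    def class_counts(self) -> dict[str, int]:
        out: dict[str, int] = {lab: 0 for lab in CLASS_LABELS}
        for r in SCORE_RANGE:
            for s in SCORE_RANGE:
                out[classify(r, s)] += self.cell(r, s)
        return out

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.index.name = "resistant_score"
        out.columns.name = "sensitive_score"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "TwoWayTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(int)
        df.columns = df.columns.astype(int)
        return cls(df)


class GeneScores:
    """Per-gene tri-state scores with collective sums and class labels.

    ``table`` holds one row per gene: ``score_<strain>`` for each strain,
    ``R``, ``S``, ``T`` and ``label``.
    """

    def __init__(self, table: pd.DataFrame, strains: tuple[str, ...],
                 collectives: Mapping[str, str], alpha: float):
        self.table = table
        self.strains = tuple(strains)
        self.collectives = dict(collectives)
        self.alpha = alpha

    @property
    def labels(self) -> pd.Series:
        return self.table["label"]

    def strain_scores(self) -> pd.DataFrame:
        cols = [f"score_{s}" for s in self.strains]
        return self.table[cols].set_axis(list(self.strains), axis=1)

    def two_way_table(self) -> TwoWayTable:
        return build_two_way_table(self.table)

    def summarize(self) -> dict[str, int | float]:
        return summarize_overlap(records=self.table)

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t")


def score_contrasts(contrasts: Mapping[str, pd.DataFrame],
                    collectives: Mapping[str, str],
                    alpha: float = 0.01) -> GeneScores:
    """Score every gene from per-strain contrast tables.

    ``contrasts`` maps strain → DataFrame with ``log2fc`` and ``p_adj``
    columns on a shared gene index; ``collectives`` maps each strain to
    ``resistant`` or ``sensitive`` (two each).
    """
    strains = tuple(contrasts)
    res = [s for s in strains if collectives.get(s) == RESISTANT]
    sen = [s for s in strains if collectives.get(s) == SENSITIVE]
    if len(res) != 2 or len(sen) != 2:
        raise InputError(
            f"need exactly 2 resistant and 2 sensitive strains, got "
            f"{len(res)} resistant / {len(sen)} sensitive"
        )
    genes = next(iter(contrasts.values())).index
    for s, c in contrasts.items():
        if not c.index.equals(genes):
            raise InputError(f"contrast gene index mismatch for strain {s!r}")
        if c[["p_adj", "log2fc"]].isna().any().any():
            raise InputError(f"incomplete record(s) in strain {s!r}")

    tbl = pd.DataFrame(index=genes.copy())
    for s in strains:
        c = contrasts[s]
        sig = c["p_adj"].to_numpy() < alpha
        fc = c["log2fc"].to_numpy()
        if np.any(sig & (fc == 0.0)):
            logger.warning("exact-zero fold change with significant p in "
                           "strain %s; scoring 0", s)
        tbl[f"score_{s}"] = np.where(sig, np.sign(fc), 0).astype(int)
    tbl["R"] = sum(tbl[f"score_{s}"] for s in res)
    tbl["S"] = sum(tbl[f"score_{s}"] for s in sen)
    tbl["T"] = tbl["R"] + tbl["S"]
    tbl["label"] = [classify(r, s) for r, s in zip(tbl["R"], tbl["S"])]
    return GeneScores(tbl, strains, collectives, alpha)


def build_two_way_table(records: pd.DataFrame) -> TwoWayTable:
    """Tally genes by (R, S); ``records`` needs ``R`` and ``S`` columns."""
    if records[["R", "S"]].isna().any().any():
        raise InputError("incomplete collective scores")
    grid = pd.crosstab(records["R"], records["S"])
    return TwoWayTable(grid)


# ------------------------------------------------------------------ summary
def summarize_overlap(records: pd.DataFrame | None = None,
                      table: TwoWayTable | None = None) -> dict:
    """Headline overlap counts from gene records or a collapsed table.

    Collective-level counts (responsive per collective, within-collective
    overlap, Type-I/II tallies) are functions of (R, S) and are identical
    either way. ``multi_strain`` — genes altered in more than one strain —
    is computed from raw strain scores when records are available, because a
    +1/−1 pair within one collective cancels in R or S; the table-based
    count (``multi_strain_table``) is also reported.
    """
    if records is None and table is None:
        raise ValueError("provide records or a two-way table")
    if table is None:
        table = build_two_way_table(records)

    c = table.counts
    total = table.total
    responsive_any = total - table.cell(0, 0)
    responsive_sensitive = int(c.loc[:, [s for s in SCORE_RANGE if s != 0]]
                               .to_numpy().sum())
    responsive_resistant = int(c.loc[[r for r in SCORE_RANGE if r != 0], :]
                               .to_numpy().sum())
    overlap_within_sensitive = int(c.loc[:, [-2, 2]].to_numpy().sum())
    overlap_within_resistant = int(c.loc[[-2, 2], :].to_numpy().sum())

    cls = table.class_counts()
    type_i_up, type_i_down = cls[TYPE_I_UP], cls[TYPE_I_DOWN]
    type_i = type_i_up + type_i_down + cls[TYPE_I_DISCORDANT]
    type_ii_sens = cls[TYPE_II_SENSITIVE]
    type_ii_res = cls[TYPE_II_RESISTANT]

    single_cells = (table.cell(0, -1) + table.cell(0, 1)
                    + table.cell(-1, 0) + table.cell(1, 0))
    multi_strain_table = responsive_any - single_cells

    out = {
        "universe": total,
        "responsive_any": responsive_any,
        "responsive_sensitive": responsive_sensitive,
        "responsive_resistant": responsive_resistant,
        "overlap_within_sensitive": overlap_within_sensitive,
        "overlap_within_resistant": overlap_within_resistant,
        "multi_strain_table": multi_strain_table,
        "type_i": type_i,
        "type_i_up": type_i_up,
        "type_i_down": type_i_down,
        "type_i_discordant": cls[TYPE_I_DISCORDANT],
        "type_ii": type_ii_sens + type_ii_res,
        "type_ii_sensitive": type_ii_sens,
        "type_ii_resistant": type_ii_res,
        "type_ii_sensitive_up": table.cell(0, 2),
        "type_ii_sensitive_down": table.cell(0, -2),
        "type_ii_resistant_up": table.cell(2, 0),
        "type_ii_resistant_down": table.cell(-2, 0),
        "partial": cls[PARTIAL],
        "unresponsive": cls[UNRESPONSIVE],
    }
    if records is not None:
        score_cols = [col for col in records.columns if col.startswith("score_")]
        nonzero = (records[score_cols] != 0).sum(axis=1)
        out["multi_strain"] = int((nonzero >= 2).sum())
    else:
        out["multi_strain"] = multi_strain_table
    return out


def proportion_test(x1: int, n1: int, x2: int, n2: int,
                    continuity: bool = True) -> tuple[float, float, float]:
    """Two-sided two-proportion test (chi-square on the 2×2 table).

    Yates continuity correction is applied by default, matching the
    conventional "proportion test". Returns (p̂1, p̂2, p-value).
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0 or not 0 <= x <= n:
            raise ValueError(f"invalid counts: x={x}, n={n}")
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    p1, p2 = x1 / n1, x2 / n2
    if p1 == p2:
        return p1, p2, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # low expected counts are the caller's call
        res = chi2_contingency(table, correction=continuity)
    return p1, p2, float(res.pvalue)


def threshold_sweep(contrasts: Mapping[str, pd.DataFrame],
                    neg_log10_grid=None) -> pd.DataFrame:
    """Responsive-gene counts per strain across significance thresholds.

    Counts genes with ``p_adj ≤ alpha`` for alpha = 10^(−x) over a grid of
    x (default 0..5 in steps of 0.1), so x = 0 counts every gene. Counts
    are monotone non-increasing in x.
    """
    if neg_log10_grid is None:
        neg_log10_grid = np.round(np.arange(0.0, 5.0 + 1e-9, 0.1), 10)
    neg_log10_grid = np.asarray(neg_log10_grid, dtype=float)
    alphas = 10.0 ** (-neg_log10_grid)
    if np.any((alphas <= 0) | (alphas > 1)):
        raise ValueError("alpha grid must lie within (0, 1]")
    out = {}
    for strain, c in contrasts.items():
        padj = c["p_adj"].to_numpy()
        out[strain] = [(padj <= a).sum() for a in alphas]
    return pd.DataFrame(out, index=pd.Index(neg_log10_grid,
                                            name="neg_log10_alpha"))
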