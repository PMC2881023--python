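"""Relative qPCR quantification (2^−ΔΔCt) and validation statistics.

Ct is the PCR cycle at which fluorescence crosses threshold; lower Ct means
more template. For each animal, ΔCt = Ct_target − Ct_reference normalizes to
a housekeeping gene; ΔΔCt subtracts the mean ΔCt of a calibrator group
(typically the strain's own controls), and relative expression is 2^−ΔΔCt.
Group means are often rescaled so the highest group is 100%. Control-vs-
treated comparisons use Welch t-tests; multi-group designs use one-way
ANOVA with Bonferroni-adjusted pairwise post-hoc tests. Values below the
detection limit (ND) are carried as missing, never imputed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .data import InputError, InsufficientDataError

__all__ = [
    "read_ct_table",
    "ddct",
    "percent_of_max",
    "welch_test",
    "anova_bonferroni",
    "group_tests",
    "significance_tier",
    "efficiency_check",
]

REQUIRED_CT_COLUMNS = ("animal", "group", "gene", "ct")


def read_ct_table(path) -> pd.DataFrame:
    """Read a long-format Ct TSV: animal, group, gene, ct[, detected].

    'ND' (or empty) in the ct column marks below-detection measurements and
    becomes NaN with ``detected=False``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"animal": str, "group": str,
                                            "gene": str})
    missing = [c for c in REQUIRED_CT_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"Ct table missing columns: {missing}")
    ct_raw = df["ct"].astype(str).str.strip()
    nd = ct_raw.str.upper().isin(["ND", "", "NA", "NAN"])
    df["ct"] = pd.to_numeric(ct_raw.where(~nd), errors="coerce")
    if "detected" in df.columns:
        df["detected"] = df["detected"].astype(bool) & ~nd
    else:
        df["detected"] = ~nd & df["ct"].notna()
    if ((df["ct"] <= 0) & df["detected"]).any():
        raise InputError("detected Ct values must be positive")
    return df


def ddct(ct: pd.DataFrame, target: str, reference: str,
         calibrator_group: str) -> pd.DataFrame:
    """Per-animal relative expression of ``target`` as 2^−ΔΔCt.

    ΔCt = Ct_target − Ct_reference per animal; ΔΔCt subtracts the mean ΔCt
    of ``calibrator_group``; expression = 2^−ΔΔCt. ND targets propagate as
    NaN with ``detected=False``. Every animal must have a detected
    reference-gene Ct.
    """
    tgt = ct[ct["gene"] == target].set_index("animal")
    ref = ct[ct["gene"] == reference].set_index("animal")
    if tgt.empty:
        raise InputError(f"no rows for target gene {target!r}")
    missing_ref = [a for a in tgt.index if a not in ref.index
                   or not ref.loc[a, "detected"]]
    if missing_ref:
        raise InputError(
            f"missing/undetected reference {reference!r} for animals: "
            f"{missing_ref[:5]}"
        )
    delta = tgt["ct"] - ref.loc[tgt.index, "ct"]
    cal = delta[tgt["group"] == calibrator_group].dropna()
    if cal.empty:
        raise InputError(
            f"calibrator group {calibrator_group!r} has no detected values"
        )
    dd = delta - cal.mean()
    out = pd.DataFrame({
        "group": tgt["group"],
        "delta_ct": delta,
        "ddct": dd,
        "expression": np.power(2.0, -dd),
        "detected": tgt["detected"],
    })
    out.loc[~out["detected"], ["delta_ct", "ddct", "expression"]] = np.nan
    return out


def percent_of_max(expression: pd.DataFrame) -> pd.DataFrame:
    """Group means/SDs rescaled so the highest group mean is 100%.

    ``expression`` needs ``group`` and ``expression`` columns (ND rows are
    NaN and are excluded from means). SDs are scaled by the same factor, so
    ratios are preserved. Ties for the maximum resolve to the first group in
    order of appearance.
    """
    vals = expression.dropna(subset=["expression"])
    if vals.empty:
        raise InputError("all values are below detection; nothing to scale")
    grouped = vals.groupby("group", sort=False)["expression"]
    means = grouped.mean()
    sds = grouped.std(ddof=1)
    top = means.to_numpy().argmax()  # first occurrence on ties
    factor = 100.0 / means.iloc[top]
    return pd.DataFrame({
        "mean": means,
        "sd": sds,
        "pct_mean": means * factor,
        "pct_sd": sds * factor,
        "n": grouped.size(),
    })


# ------------------------------------------------------------------ tests
def welch_test(a, b) -> tuple[float, float]:
    """Two-tailed unequal-variance (Welch) t-test; returns (t, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each group needs >= 2 detected values")
    if np.array_equal(a, b) and np.var(a) == 0:
        return 0.0, 1.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def anova_bonferroni(groups: dict[str, np.ndarray]) -> dict:
    """One-way ANOVA with Bonferroni-adjusted pooled-variance post-hoc tests.

    Returns the ANOVA p plus, per group pair, the pooled-MSE t-test p-value
    multiplied by the number of comparisons (clipped at 1).
    """
    names = list(groups)
    arrays = []
    for g in names:
        a = np.asarray(groups[g], dtype=float)
        a = a[~np.isnan(a)]
        if len(a) < 2:
            raise InsufficientDataError(f"group {g!r} has < 2 detected values")
        arrays.append(a)
    if len(arrays) < 2:
        raise InsufficientDataError("need >= 2 groups")
    if all(np.var(a) == 0 for a in arrays) and len({a.mean() for a in arrays}) == 1:
        anova_p = 1.0
    else:
        anova_p = float(stats.f_oneway(*arrays).pvalue)
    # pooled residual variance across all groups
    n_total = sum(len(a) for a in arrays)
    df_resid = n_total - len(arrays)
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrays) / df_resid
    pairs = [(names[i], names[j]) for i in range(len(names))
             for j in range(i + 1, len(names))]
    m = len(pairs)
    pairwise = {}
    for gi, gj in pairs:
        a = arrays[names.index(gi)]
        b = arrays[names.index(gj)]
        se = np.sqrt(mse * (1 / len(a) + 1 / len(b)))
        if se == 0:
            p = 1.0 if a.mean() == b.mean() else 0.0
        else:
            t = (a.mean() - b.mean()) / se
            p = 2 * stats.t.sf(abs(t), df_resid)
        pairwise[(gi, gj)] = min(1.0, p * m)
    return {"anova_p": anova_p, "pairwise": pairwise, "df_resid": df_resid}


def significance_tier(p: float) -> str:
    """Conventional star tiers: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def group_tests(values: pd.DataFrame, mode: str = "rat") -> pd.DataFrame:
    """Significance tests for qPCR group designs.

    ``mode="rat"``: Welch t-test control vs treated per (gene, strain);
    expects columns ``gene, strain, treatment, expression`` with treatment
    ∈ {control, exposed}. ``mode="mouse"``: one-way ANOVA + Bonferroni
    pairwise per gene; expects ``gene, group, expression``.
    """
    rows = []
    if mode == "rat":
        for (gene, strain), sub in values.groupby(["gene", "strain"],
                                                  sort=False):
            ctrl = sub.loc[sub["treatment"] == "control", "expression"]
            trt = sub.loc[sub["treatment"] == "exposed", "expression"]
            t, p = welch_test(ctrl, trt)
            rows.append({"gene": gene, "strain": strain, "t": t, "p": p,
                         "tier": significance_tier(p)})
        return pd.DataFrame(rows)
    if mode == "mouse":
        for gene, sub in values.groupby("gene", sort=False):
            groups = {g: s["expression"].to_numpy()
                      for g, s in sub.groupby("group", sort=False)}
            res = anova_bonferroni(groups)
            for (gi, gj), p in res["pairwise"].items():
                rows.append({"gene": gene, "comparison": f"{gi} vs {gj}",
                             "anova_p": res["anova_p"], "p_bonferroni": p,
                             "tier": significance_tier(p)})
        return pd.DataFrame(rows)
    raise ValueError(f"unknown mode {mode!r}")


def efficiency_check(ct_values, log10_input) -> dict:
    """Amplification efficiency from a serial-dilution standard curve.

    Fits Ct against log10 input by least squares; efficiency (%) =
    (10^(−1/slope) − 1) × 100. A perfect doubling per cycle gives slope
    ≈ −3.32 and 100%. ``ok`` flags the conventional 90–110% QC window.
    Needs at least 3 dilution points.
    """
    ct = np.asarray(ct_values, dtype=float)
    x = np.asarray(log10_input, dtype=float)
    if ct.size < 3 or x.size != ct.size:
        raise InsufficientDataError("need >= 3 dilution points")
    slope, intercept = np.polyfit(x, ct, 1)
    if slope >= 0:
        raise InputError("non-negative standard-curve slope; check inputs")
    efficiency = (10.0 ** (-1.0 / slope) - 1.0) * 100.0
    return {
        "slope": float(slope),
        "intercept": float(intercept),
        "efficiency_pct": float(efficiency),
        "ok": bool(90.0 <= efficiency <= 110.0),
    }
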