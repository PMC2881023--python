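"""Per-strain differential expression with empirical-Bayes variance moderation.

The model is a condition-means (cell-means) linear model over the eight
strain × treatment conditions. For gene g the pooled residual variance
``s_g²`` on ``d_g`` degrees of freedom is shrunk toward a prior variance
``s0²`` with prior degrees of freedom ``d0``,

    s̃_g² = (d0·s0² + d_g·s_g²) / (d0 + d_g),

and the exposed−control contrast within each strain is tested with the
moderated t statistic ``t̃_g = β̂_g / sqrt(s̃_g²·v_g)`` on ``d0 + d_g``
degrees of freedom. (d0, s0²) are estimated by moment matching on log s²
through the digamma/trigamma equations of a scaled-F fit. Benjamini–Hochberg
adjustment is applied within each strain's contrast separately.

:class:`StrainContrastModel` / :class:`StrainContrastResults` wrap these
operations in the usual model-object idiom: build from data, ``fit()``,
inspect the results, ``summary()``.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .data import (
    CONTROL,
    EXPOSED,
    DegenerateDataError,
    DesignError,
    ExpressionMatrix,
    InsufficientDataError,
)

P_FLOOR = 1e-300

__all__ = [
    "fit_condition_model",
    "moderate_variances",
    "moderated_t",
    "adjust_bh",
    "run_strain_contrasts",
    "StrainContrastModel",
    "StrainContrastResults",
]


# ----------------------------------------------------------------- fitting
def fit_condition_model(matrix: ExpressionMatrix):
    """Cell-means fit over all present (strain, treatment) conditions.

    Returns ``(means, s2, df, n_per_condition)`` where ``means`` is a
    genes × conditions DataFrame of arithmetic means, ``s2`` the per-gene
    pooled residual variance and ``df = n_samples − n_conditions`` the shared
    residual degrees of freedom (24 for a full 4×2×4 design).
    """
    cond = matrix.condition_labels()
    counts = cond.value_counts()
    if (counts < 1).any():  # pragma: no cover - defensive
        raise DesignError("every condition must have at least one sample")
    df = matrix.n_samples - len(counts)
    if df < 1:
        raise DesignError(
            f"zero residual degrees of freedom: {matrix.n_samples} samples, "
            f"{len(counts)} conditions"
        )
    vals = matrix.values
    means = vals.T.groupby(cond).mean().T
    fitted = means[cond.to_numpy()]
    fitted.columns = vals.columns
    rss = ((vals - fitted) ** 2).sum(axis=1)
    s2 = rss / df
    return means, s2, df, counts.to_dict()


def _trigamma(x):
    return polygamma(1, x)


def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration on 1/trigamma."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(_trigamma(x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if -dif / x < tol:
            break
    return x


def moderate_variances(s2, df, d0: float | None = None):
    """Estimate the variance prior and return shrunken variances.

    Parameters
    ----------
    s2 : array-like
        Per-gene residual variances (≥ 10 finite non-negative values).
    df : float or array-like
        Residual degrees of freedom (scalar shared df or per-gene).
    d0 : float, optional
        Force the prior degrees of freedom instead of estimating them:
        ``0`` disables moderation (s̃² = s²), ``inf`` collapses every
        variance to s0².

    Returns
    -------
    (d0, s0_sq, s_tilde_sq)

    Notes
    -----
    Estimation matches moments of log s² against the log scaled-F
    distribution: with ``z = log s²`` and
    ``e = z − ψ(d/2) + log(d/2)``, solve ``ψ′(d0/2) = var(e) − ψ′(d/2)``
    for d0 (Newton inversion of the trigamma function, tolerance 1e−8) and
    set ``s0² = exp(mean(e) + ψ(d0/2) − log(d0/2))``. A non-positive
    right-hand side means no excess dispersion: d0 = ∞ and s̃² = s0².

    Exact-zero variances are included through a log-offset convention:
    zeros are floored at 1e−8 × (median positive s²) before taking logs.
    """
    s2 = np.asarray(s2, dtype=float)
    if s2.size and np.all(s2 == 0):
        raise DegenerateDataError("all residual variances are zero")
    if np.sum(np.isfinite(s2) & (s2 > 0)) < 10:
        raise InsufficientDataError(
            "need at least 10 genes with finite positive variances"
        )
    df_arr = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)

    pos_median = np.median(s2[s2 > 0])
    z_input = np.where(s2 > 0, s2, pos_median * 1e-8)
    z = np.log(z_input)
    e = z - digamma(df_arr / 2.0) + np.log(df_arr / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1))
    rhs = evar - float(np.mean(_trigamma(df_arr / 2.0)))

    if d0 is None:
        if rhs > 0:
            d0_est = 2.0 * _trigamma_inverse(rhs)
            s0_sq = math.exp(emean + float(digamma(d0_est / 2.0))
                             - math.log(d0_est / 2.0))
        else:
            d0_est = math.inf
            s0_sq = math.exp(emean)
    else:
        d0_est = float(d0)
        if math.isinf(d0_est):
            s0_sq = math.exp(emean)
        elif d0_est == 0.0:
            s0_sq = math.exp(emean)  # reported but unused in shrinkage
        else:
            s0_sq = math.exp(emean + float(digamma(d0_est / 2.0))
                             - math.log(d0_est / 2.0))

    if math.isinf(d0_est):
        s_tilde = np.full_like(s2, s0_sq)
    elif d0_est == 0.0:
        s_tilde = s2.copy()
    else:
        s_tilde = (d0_est * s0_sq + df_arr * s2) / (d0_est + df_arr)
    return d0_est, s0_sq, s_tilde


def moderated_t(beta, s_tilde_sq, v, d0, df):
    """Moderated t statistic and two-sided p-value.

    ``v`` is the unscaled variance factor of the contrast (``1/n1 + 1/n2``
    for a difference of condition means); the statistic is referred to a
    Student t with ``d0 + df`` degrees of freedom (normal limit when d0 is
    infinite). p-values are clipped to [1e−300, 1].
    """
    beta = np.asarray(beta, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0):
        raise ValueError("unscaled variance factor v must be positive")
    s_tilde_sq = np.asarray(s_tilde_sq, dtype=float)
    se = np.sqrt(s_tilde_sq * v)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / np.where(se > 0, se, 1.0), 0.0)
        t = np.where((se == 0) & (beta != 0), np.sign(beta) * np.inf, t)
    total_df = d0 + df
    if np.isinf(total_df) if np.isscalar(total_df) else np.any(np.isinf(total_df)):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), total_df)
    p = np.clip(p, P_FLOOR, 1.0)
    return t, p


def adjust_bh(p):
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ------------------------------------------------------------- composition
def _strain_contrast_frame(genes, beta, t, p, p_adj) -> pd.DataFrame:
    return pd.DataFrame(
        {"log2fc": beta, "t": t, "p": p, "p_adj": p_adj},
        index=pd.Index(genes, name="gene"),
    )


def run_strain_contrasts(
    matrix: ExpressionMatrix,
    per_strain_fit: bool = False,
    d0: float | None = None,
) -> "StrainContrastResults":
    """Exposed−control moderated-t contrasts for every strain.

    With the default pooled fit, one cell-means model over all eight
    conditions supplies a single residual variance per gene (df 24 for the
    full design); ``per_strain_fit=True`` refits within each strain's eight
    samples instead (df 6). BH adjustment treats each strain's contrast as
    its own family.
    """
    strains = matrix.strains
    if len(strains) == 0:
        raise DesignError("matrix contains no strains")
    matrix.validate_for_testing()

    contrasts: dict[str, pd.DataFrame] = {}
    meta: dict[str, dict] = {}

    def one_strain(sub: ExpressionMatrix, strain: str, means, s2, df, counts):
        key_c, key_e = f"{strain}:{CONTROL}", f"{strain}:{EXPOSED}"
        for key in (key_c, key_e):
            if key not in means.columns:
                raise DesignError(f"missing condition {key!r}")
        beta = (means[key_e] - means[key_c]).to_numpy()
        v = 1.0 / counts[key_e] + 1.0 / counts[key_c]
        d0_est, s0_sq, s_tilde = moderate_variances(s2.to_numpy(), df, d0=d0)
        t, p = moderated_t(beta, s_tilde, v, d0_est, df)
        p_adj = adjust_bh(p)
        contrasts[strain] = _strain_contrast_frame(means.index, beta, t, p, p_adj)
        meta[strain] = {"d0": d0_est, "s0_sq": s0_sq, "df": df, "v": v}

    if per_strain_fit:
        for strain in strains:
            sub = matrix.subset_strain(strain)
            means, s2, df, counts = fit_condition_model(sub)
            one_strain(sub, strain, means, s2, df, counts)
    else:
        means, s2, df, counts = fit_condition_model(matrix)
        for strain in strains:
            one_strain(matrix, strain, means, s2, df, counts)

    return StrainContrastResults(matrix, contrasts, meta,
                                 per_strain_fit=per_strain_fit)


# ----------------------------------------------------------- model objects
class StrainContrastModel:
    """Cross-strain differential-expression model.

    Examples
    --------
    >>> model = StrainContrastModel(matrix)            # doctest: +SKIP
    >>> res = model.fit()                              # doctest: +SKIP
    >>> res.summary()                                  # doctest: +SKIP
    >>> scores = res.score(alpha=0.01)                 # doctest: +SKIP
    """

    def __init__(self, matrix: ExpressionMatrix, per_strain_fit: bool = False):
        self.matrix = matrix
        self.per_strain_fit = per_strain_fit

    @classmethod
    def from_dataframe(cls, values: pd.DataFrame, samples: pd.DataFrame,
                       collectives: Mapping[str, str] | None = None,
                       **kwargs) -> "StrainContrastModel":
        return cls(ExpressionMatrix(values, samples,
                                    dict(collectives) if collectives else None),
                   **kwargs)

    @classmethod
    def from_files(cls, matrix_path, samples_path,
                   collectives: Mapping[str, str] | None = None,
                   **kwargs) -> "StrainContrastModel":
        return cls(ExpressionMatrix.from_tsv(
            matrix_path, samples_path,
            dict(collectives) if collectives else None), **kwargs)

    def fit(self, d0: float | None = None) -> "StrainContrastResults":
        """Fit the cell-means model and moderated contrasts.

        ``d0`` forces the prior degrees of freedom (0 = no moderation);
        by default it is estimated from the data.
        """
        return run_strain_contrasts(self.matrix,
                                    per_strain_fit=self.per_strain_fit, d0=d0)


class StrainContrastResults:
    """Fitted per-strain contrasts.

    Attributes
    ----------
    contrasts : dict of DataFrame
        One table per strain with columns ``log2fc``, ``t``, ``p``,
        ``p_adj`` indexed by gene.
    meta : dict
        Per strain: estimated ``d0``, ``s0_sq``, residual ``df`` and the
        contrast variance factor ``v``.
    """

    def __init__(self, matrix, contrasts, meta, per_strain_fit=False):
        self.matrix = matrix
        self.contrasts = contrasts
        self.meta = meta
        self.per_strain_fit = per_strain_fit

    @property
    def strains(self) -> list[str]:
        return list(self.contrasts)

    @property
    def genes(self) -> pd.Index:
        return next(iter(self.contrasts.values())).index

    def n_significant(self, alpha: float = 0.01) -> dict[str, int]:
        return {s: int((c["p_adj"] < alpha).sum())
                for s, c in self.contrasts.items()}

    def score(self, alpha: float = 0.01):
        """Tri-state scoring of every gene; returns a ``GeneScores`` object."""
        from .scoring import score_contrasts

        if self.matrix.collectives is None:
            raise DesignError(
                "scoring requires a strain -> collective mapping on the matrix"
            )
        return score_contrasts(self.contrasts, self.matrix.collectives,
                               alpha=alpha)

    def threshold_sweep(self, neg_log10_grid=None) -> pd.DataFrame:
        from .scoring import threshold_sweep

        return threshold_sweep(self.contrasts, neg_log10_grid)

    def summary(self, alpha: float = 0.01) -> str:
        lines = [
            "Cross-strain moderated-t contrasts (exposed - control)",
            f"  genes: {len(self.genes)}   "
            f"samples: {self.matrix.n_samples}   "
            f"fit: {'per-strain' if self.per_strain_fit else 'pooled'}",
            "",
            f"  {'strain':<10}{'d0':>10}{'s0^2':>12}{'df':>6}"
            f"{'sig@' + format(alpha, 'g'):>12}",
        ]
        nsig = self.n_significant(alpha)
        for s in self.strains:
            m = self.meta[s]
            d0s = "inf" if math.isinf(m["d0"]) else f"{m['d0']:.2f}"
            lines.append(
                f"  {s:<10}{d0s:>10}{m['s0_sq']:>12.5f}{m['df']:>6}"
                f"{nsig[s]:>12}"
            )
        return "\n".join(lines)

    def to_tsv(self, out_dir) -> None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for s, c in self.contrasts.items():
            c.to_csv(out / f"contrast_{s.replace('/', '')}.tsv", sep="\t")
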