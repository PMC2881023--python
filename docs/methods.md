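# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical choices, and the design decisions behind `crossdiff`, in the
package's own terms.

## Differential-expression model

Input is a normalized log2 expression matrix (genes × samples) with a
sample sheet assigning each sample one of four strains and a treatment
(control/exposed). The package deliberately starts downstream of
preprocessing: probe-level handling, normalization, and array QC are out
of scope.

For each gene a cell-means linear model is fit over all present
strain × treatment conditions. Condition estimates are arithmetic means;
the residual variance s²_g pools across all conditions with
df = n_samples − n_conditions (24 for the full 4 × 2 × 4 design). The
exposed−control contrast within strain j is β̂_gj with unscaled variance
factor v = 1/n_exposed + 1/n_control.

Because variance pooling across strains is a modeling choice the data
cannot settle by itself, `per_strain_fit=True` restricts the model to each
strain's own eight samples (df 6). The pooled fit is the default: with
four replicates per condition, per-gene variance estimates on 6 df are
noisy enough that pooling plus moderation clearly dominates.

### Empirical-Bayes moderation

The hierarchical model is s²_g | σ²_g ~ σ²_g·χ²_d/d with the conjugate
scaled inverse-chi-square prior σ²_g ~ s0²·d0/χ²(d0). The posterior mean
variance is the shrinkage formula

    s̃²_g = (d0·s0² + d·s²_g) / (d0 + d)

and t̃_g = β̂_g/√(s̃²_g·v) follows a Student t with d0 + d df under the
null. (d0, s0²) are estimated by moment matching on z = log s²: with
e = z − ψ(d/2) + log(d/2), solve ψ′(d0/2) = var(e) − ψ′(d/2) for d0 and
set s0² = exp(mean(e) + ψ(d0/2) − log(d0/2)).

Numerical conventions:

- The trigamma equation is inverted by Newton iteration (tolerance 1e−8,
  max 50 iterations), with asymptotic branches for arguments above 1e7 or
  below 1e−6.
- A non-positive right-hand side (no excess dispersion beyond chi-square
  sampling noise) gives d0 = ∞: every s̃² equals s0² and the reference
  distribution is normal.
- d0 may be forced: 0 disables moderation entirely (the chain then equals
  an ordinary pooled two-sample t-test, verified to 10 significant
  figures in the tests).
- Exact-zero residual variances are floored at 1e−8 × median(positive s²)
  before taking logs; this affects only the log-moment estimation, not
  the shrinkage formula.
- p-values are two-sided and clipped to [1e−300, 1].

The estimator is cross-checked in the test suite against the Bioconductor
reference implementation (limma's `squeezeVar`, run through Rscript) at
rtol 1e−4, and against parameter recovery from the generating prior.

### Multiple testing

Benjamini–Hochberg step-up adjustment (via statsmodels) is applied within
each strain's contrast separately — each strain's gene list is its own
family, matching how per-strain gene lists are then consumed. No
dependence correction is applied. The implementation is property-tested
against a naive O(n²) step-up oracle.

## Tri-state scoring and classification

At threshold α (default 0.01 on adjusted p), gene scores per strain are
sign(log2FC) if p_adj < α else 0. An exact-zero fold change with
significant p would have an undefined sign and scores 0 with a logged
warning (unreachable in practice in floating point).

Collective scores R (resistant pair) and S (sensitive pair) each range
over −2..2; the label is a pure function of (R, S):

- T = R + S = +4 / −4 → TYPE_I_UP / TYPE_I_DOWN;
- |R| = |S| = 2 with T = 0 → TYPE_I_DISCORDANT. The prose definition of a
  concordant (Type-I) response — significant in all four strains — and the
  score rule T = ±4 disagree exactly on this cell; both are honored by
  splitting out the discordant case, which is empty in the published data
  and in every realistic simulation;
- |R| = 2, S = 0 → TYPE_II_RESISTANT; |S| = 2, R = 0 → TYPE_II_SENSITIVE;
- R = S = 0 → UNRESPONSIVE; everything else PARTIAL.

`summarize_overlap` derives headline counts from the 5×5 table. One count
needs care: "altered in more than one strain" is computed from the raw
per-strain scores when available, because a +1/−1 pair inside one
collective cancels to R or S = 0 and is invisible in the collapsed table;
the table-based count is reported alongside (`multi_strain_table`) since
published tables can only be recounted that way. On the bundled published
table both routes agree (144 of 452).

The two-proportion comparison of within-collective overlap uses the
Yates-corrected chi-square on the 2×2 table (the conventional "proportion
test"); with the published counts (31/138 vs 108/412) it gives p = 0.445,
matching the printed 0.44, where the uncorrected z-test would give ≈0.38.
The correction can be disabled.

The threshold sweep counts genes with p_adj ≤ α across a grid of
−log10 α ∈ [0, 5]; the inclusive inequality makes α = 1 count every gene
(adjusted p can be exactly 1), whereas scoring itself uses the strict
p_adj < α rule.

## Enrichment

Enrichment ratio E = (k/n)/(K/N); K = 0 yields NA. Categories are
restricted to the analysis universe and dropped below `min_size`
(default 5) members; the analysis is one-sided (over-representation only).

The permutation FDR draws random gene lists of the observed size without
replacement from the universe and recomputes all category E values. The
default ("family") mode is the family-wise empirical FDR of classic
over-representation tools: for each observed threshold E_c, the mean
number of permuted categories at or above E_c divided by the number of
real categories at or above E_c, clipped to [0, 1]. A suffix-minimum over
categories ordered by decreasing E enforces monotonicity (a more enriched
category never gets a larger FDR), the same convention as BH/q-value
adjustment. Because the historical tool's exact normalization is not
recoverable, a per-category empirical p-value mode
(`mode="per_category"`, add-one convention, BH-adjusted) ships as well;
neither mode is claimed to be the historical implementation. The family
mode is validated against exhaustive enumeration of all C(6,2) lists on a
toy universe (agreement within 0.01 at 1e5 permutations).

## Clustering

Genes with sample variance (ddof = 1) ≤ threshold are dropped — default
0.1; retained rows are z-scored (sample SD). Sample distances are
1 − Pearson r over retained genes, clipped to [0, 2]; a zero-variance
sample column is an error. Agglomerative complete linkage (scipy) is the
primary mode with scipy's deterministic leaf ordering; distance ties
resolve by cluster insertion order. A "divisive hierarchical clustering
with complete linkage" is a contradiction in terms (divisive algorithms
have no linkage parameter), so divisive clustering is offered as a
separate DIANA-style mode (`method="divisive"`: largest-diameter cluster
split by splinter-group reallocation), not as the default.

`treatment_separation_score` quantifies the top split: the fraction of
(exposed, control) sample pairs separated by the root bipartition — 1 for
perfect separation, ≈0.5 at chance, NaN if only one treatment is present.

## qPCR quantification

ΔCt = Ct_target − Ct_reference per animal; ΔΔCt subtracts the mean ΔCt of
the calibrator group — by convention the same strain's control group, so
treated/control comparisons are strain-wise; expression = 2^−ΔΔCt. The
reference gene is a required input (either of the usual housekeeping
genes may be appropriate; the package does not choose). Below-detection
values (ND) propagate as missing and are excluded from group means, never
imputed. Percent-of-maximum scaling sets the largest group mean to 100%
and scales SDs by the same factor (first group wins ties).

Rat-style designs use Welch (unequal-variance, two-tailed) t-tests per
gene per strain; multi-group designs use one-way ANOVA with
Bonferroni-corrected pooled-variance pairwise post-hoc tests. Stars
follow the usual tiers (0.05/0.01/0.001). Amplification efficiency from a
serial dilution is (10^(−1/slope) − 1)×100% with a 90–110% QC window; it
is a report only — quantification is plain 2^−ΔΔCt, not
efficiency-corrected.

## Synthetic-data generator

The generator emulates the 4-strain × 2-treatment × 4-replicate design
with known truth:

    y_gij = mu_g + b_gs + delta_gs·1[exposed] + eps_gij,
    eps ~ N(0, sigma²_g),  sigma²_g ~ s0²·d0/chi²(d0)

- `mu_g` ~ Uniform(6, 12) log2 units, a typical normalized-intensity
  range.
- `b_gs` ~ N(0, 0.2²): gene × strain baseline offsets, large enough for
  strain structure to be visible to clustering, small against the large
  treatment effects.
- Planted classes (defaults mirror the published tallies in an 8605-gene
  universe): 20 + 5 concordant up/down, 17 + 26 sensitive-only up/down,
  2 + 1 resistant-only up/down, 308 single-strain responders, remainder
  null. Direction splits are explicit in the class counts so truth
  tallies are deterministic.
- Effect magnitudes are drawn per gene from per-class ranges: 1.1–6.6
  log2 units for concordant genes and 0.5–1.2 for collective-specific
  genes, patterned on the fold-change ranges published for those classes;
  single-strain responders use 0.5–2.0.
- Variance prior defaults d0 = 4, s0² = 0.01 (log2-intensity²). The prior
  degrees of freedom reflect visibly heterogeneous gene variances; the
  prior scale is back-calculated from the published per-gene (fold
  change, adjusted p) pairs, which imply contrast standard errors around
  0.06–0.15 at n = 4 — i.e. typical gene variances near 0.01, not an
  order of magnitude larger. With this prior, collective-specific effects
  of 0.5–1.2 log2 units are detectable at adjusted p < 0.01 with the same
  regularity the published gene lists display.
- Single-strain responders are allocated 140/90/50/28 to L-E/LnC/LnA/H/W.
  Only the qualitative ordering of per-strain responsive counts is
  published; this allocation reproduces that ordering with a realistic
  spread and is a package choice, configurable via
  `single_strain_allocation`.

What the generator does *not* emulate: probe-level effects, spatial
artifacts, correlated noise across genes, non-Gaussian tails,
intensity-dependent variance, or missing values. Passing recovery tests
on this generator therefore demonstrates the pipeline's correctness under
its own model assumptions — not robustness to real-array pathologies.

All draws flow from one `numpy` Generator seeded by `SimConfig.seed`;
identical configs give bit-identical matrices. In the pipeline, stage k
derives its seed from `SeedSequence([run_seed, k])`, so stages are
independently reproducible.

## Problem sizes

Defaults throughout match the study design they emulate: 8605 genes, 32
samples. The test suite uses the full scale where the claim depends on it
(classification recovery, null calibration) and compact designs (a few
hundred genes) for structural checks; prior-recovery checks use 10,000
simulated variances, and the enumeration oracle for the permutation FDR
runs on a 6-gene toy universe where exhaustive enumeration is exact.

## Known limitations

- The moderated-t chain assumes exchangeable gene variances from a single
  scaled inverse-chi-square prior; real arrays show intensity-dependent
  trends the model ignores.
- BH is applied per strain without cross-strain dependence handling; the
  tri-state scores inherit whatever correlation exists between contrasts.
- The permutation FDR's historical normalization is ambiguous; both
  provided modes are documented approximations.
- The divisive clustering mode is a minimal DIANA variant intended for
  qualitative comparison, not a reference implementation.
- Published real-data gene lists and category enrichments depend on the
  original arrays and annotation-database versions and are out of scope;
  the bundled published two-way table supports arithmetic-level
  reproduction only.
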