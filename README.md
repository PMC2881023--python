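# crossdiff

Cross-strain differential-expression concordance analysis for toxicogenomic
designs: which transcriptional responses to a toxicant are shared across
genetically distinct animal strains, and which track a resistance phenotype?

The motivating design is a rat dioxin (TCDD) study: four strains/lines —
two carrying an AHR transactivation-domain variant that makes them highly
resistant to dioxin toxicity (the *resistant collective*, H/W and LnA) and
two with wildtype AHR (the *sensitive collective*, L-E and LnC) — each
profiled in liver under vehicle control and TCDD exposure, four animals per
condition (4 strains × 2 treatments × 4 replicates = 32 arrays). Genes whose
response is shared by all four strains (*Type-I*) are AHR-driven but
unlikely to explain the phenotype difference; genes responding in exactly
one collective (*Type-II*) are candidates for mediating — or protecting
from — toxicity.

`crossdiff` implements the full analysis as a tested library plus a `crp`
command line tool, with a synthetic-data generator so every stage is
verifiable without the original arrays.

## The model

**Per-strain contrasts.** A cell-means linear model over the eight
strain × treatment conditions gives, for gene *g*, the exposed−control
log2 fold change β̂*g* per strain, a pooled residual variance *s²g* on
*d* = 24 df, and an empirical-Bayes moderated t-statistic

    s̃²g = (d0·s0² + d·s²g) / (d0 + d),    t̃g = β̂g / √(s̃²g·vg)

on *d0 + d* df, with the prior (*d0*, *s0²*) estimated by moment matching
of log *s²* (digamma/trigamma equations, Newton inversion). Each strain's
p-values are Benjamini–Hochberg adjusted as their own family.

**Tri-state scoring.** At adjusted p < 0.01 each gene scores −1/0/+1
(repressed/unaltered/induced) per strain. Collective sums
R = Σ(resistant scores) and S = Σ(sensitive scores), each in −2..+2,
classify the gene: total R+S = ±4 → Type-I; (|R|, |S|) = (2, 0) or
(0, 2) → Type-II (resistant-only / sensitive-only); R = S = 0 →
unresponsive; anything else partial. The 5×5 table of gene counts over
(R, S) summarizes the experiment, and a Yates-corrected two-proportion test
compares within-collective overlap between collectives.

**Downstream.** Category over-representation uses the enrichment ratio
E = (k/n)/(K/N) with a permutation FDR (random same-size gene lists drawn
from the universe); sample clustering uses 1 − Pearson-r distances with
complete linkage after variance filtering and row scaling; qPCR validation
implements 2^−ΔΔCt quantification, percent-of-maximum scaling, Welch
t-tests and one-way ANOVA with Bonferroni post-hoc tests.

**Synthetic data.** The generator plants Type-I / Type-II / single-strain /
null genes at configurable counts and effect sizes on the 4 × 2 × n design,
with gene variances drawn from the scaled inverse-chi-square prior
σ²g ~ s0²·d0/χ²(d0) that the moderated t assumes — so prior recovery,
power, and label recovery are all testable against known truth.

## Worked example

```python
from crossdiff import SimConfig, generate_dataset, StrainContrastModel
from crossdiff.scoring import proportion_test

matrix, truth = generate_dataset(SimConfig(seed=17))
results = StrainContrastModel(matrix).fit()
print(results.summary())
```

```
Cross-strain moderated-t contrasts (exposed - control)
  genes: 8605   samples: 32   fit: pooled

  strain            d0        s0^2    df    sig@0.01
  L-E             3.95     0.00991    24         203
  LnC             3.95     0.00991    24         154
  LnA             3.95     0.00991    24          77
  H/W             3.95     0.00991    24          56
```

The estimated prior (d0 ≈ 3.95, s0² ≈ 0.0099) recovers the generator's
(4, 0.01), and the per-strain responsive counts reproduce the qualitative
ordering L-E > LnC > LnA > H/W: sensitive strains respond more broadly.
Scoring and classification:

```python
scores = results.score(alpha=0.01)
summary = scores.summarize()
print(scores.two_way_table().counts)
p1, p2, p = proportion_test(
    summary["overlap_within_resistant"], summary["responsive_resistant"],
    summary["overlap_within_sensitive"], summary["responsive_sensitive"])
```

```
S   -2   -1     0    1   2
R
-2   5    0     1    0   0
-1   0    0    32    0   0
 0  23  107  8233  120  17
 1   0    0    45    0   0
 2   0    0     2    0  20

responsive_any 372   multi_strain 68
type_i 25   type_ii 43 (40 sensitive-only, 3 resistant-only)
overlap 26.7% vs 22.3%, p = 0.44
```

All 25 planted Type-I genes land in the (±2, ±2) corners; Type-II genes
(planted at log2 effects of 0.5–1.2, the hardest class) are recovered at
~90%. The same chain runs from the shell:

```sh
crp simulate --seed 17 --out run/
crp fit --matrix run/matrix.tsv --samples run/samples.tsv --out run/contrasts
crp run --out run2/ --seed 17      # full pipeline incl. cluster + enrich
crp report run2/
```

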