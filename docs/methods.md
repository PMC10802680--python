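# Methods

## Data model

An assay is a dense tensor of log₂ fold changes `x_tg(b)` over genes
*g = 1..G*, time points *t = 0..T* (strictly increasing numeric labels; the
smallest time is the baseline and its expected LFC is 0 by construction)
and replicates *b = 1..B*.  The working model is

```
x_tg(b) = μ_tg + ε,     ε ~ N(0, σ_g²),
```

one noise scale per gene, shared across time points and (in the simulator)
across the two assays of a pair.  Inputs must already be LFC: no count
normalization, library-size modeling or variance-stabilizing transform is
performed here, and callers with count data must transform upstream.
Missing cells are an error by default; an optional `drop` policy carries
them as NaN and the pairwise tests then use per-cell available replicate
counts (the spline test and correlation stage require complete data).

## Differential-expression evidence (p_gX, p_gY)

**Pairwise route.**  For each post-baseline time *t*, the two-sided
equal-variance t-test of baseline replicates against time-*t* replicates:

```
t_gt = (x̄_tg − x̄_0g) / sqrt(s_g² (1/B_0 + 1/B_t)) .
```

Because the model puts a single σ_g² behind all time points of a gene, the
residual variance `s_g²` is pooled across all T+1 groups of that gene,
giving `(T+1)(B−1)` degrees of freedom.  For a single contrast (T = 1) this
reduces exactly to the textbook pooled two-sample t with `2B−2` df, and it
makes the moderated and unmoderated tests nest exactly: moderation acts on
the same per-gene variance.  The per-gene summary is `p_g = min_t p_gt`,
the raw minimum — deliberately not multiplicity-adjusted, since it is used
as a ranking statistic, not an error rate (`sidak_adjust_minp` provides the
1−(1−p)^T correction for users who want it).

**Empirical-Bayes moderation.**  With `moderate=True` the per-gene
variances are shrunk toward a common prior via the standard hierarchical
model `s_g² | σ_g² ~ σ_g² χ²_df / df`, `1/σ_g² ~ χ²_d0 / (d0 s0²)`, giving

```
s̃_g² = (d0·s0² + df·s_g²) / (d0 + df),
```

and the t reference gains d0 degrees of freedom.  `(d0, s0²)` are estimated
by moment-matching the log sample variances against digamma/trigamma
moments of the scaled-F marginal, with a Newton trigamma-inverse solve;
when the observed dispersion of log variances is at or below the pure-χ²
expectation the d0 = ∞ branch engages and every posterior variance equals
s0² (the t becomes a z).  Two documented degenerate rules: all sample
variances exactly equal → point-mass prior at the common value; a zero
pooled variance yields P = 1 when the means agree (no evidence either way)
and P = 0 when they differ (continuity of the evidence scale).

**Spline route.**  Alternatively, per gene, OLS of all `(T+1)·B` values on
an intercept plus a cubic B-spline basis of time with 5 columns (interior
knots at quantiles of the distinct times), summarized by the F-test of all
spline coefficients being zero on `(spline_df, (T+1)B − spline_df − 1)`
df.  "Order 5" descriptions of spline course models are ambiguous between
order, degree and df; this package fixes *df = 5 basis columns* and exposes
`spline_df`.  A constant gene is the 0/0 form and returns P = 1; an exact
fit with signal returns P = 0.

## Within-gene correlation evidence (p_gXY)

For each gene, its course in X is correlated with its course in Y — the
*within-gene* sense (one gene, two modalities, correlation over time), not
gene–gene co-expression.  Replicates are averaged per (gene, time) by
default, so n = T+1 paired points per gene; `concat` instead pairs all
(time, replicate) cells and requires equal replicate counts.  Averaging is
the default because the quantity of interest is concordance of the mean
trajectories, and it keeps the correlation test's n honest (replicate noise
is not pseudo-replication in the course).  The baseline point is included.

Two-sided P-values: Pearson via the exact `t = r√((n−2)/(1−r²))` transform
on n−2 df; Spearman by full enumeration of the n! rank permutations when
n ≤ 8 and ranks are untied (the enumerated null is cached per n), otherwise
the same t transform applied to the rank correlation.  Spearman is the
default: monotone concordance is the biologically meaningful notion when
mRNA and protein respond on different scales.  A gene with zero variance on
either side has no defined correlation: r is recorded missing and P = 1.

With n = 14 the Spearman t-approximation is accurate but not exact; the
null-calibration tests bound its error empirically (KS uniformity at level
0.01 on 2000 null genes).

## Evidence combination and selection

Per gene the triple `(p_gX, p_gY, p_gXY)` is combined two ways:

* **Edgington:** `S_g = p_gX + p_gY + p_gXY`, ranked ascending.  The
  Irwin–Hall CDF `P(U₁+…+U_k ≤ s) = (1/k!) Σ_j (−1)^j C(k,j)(s−j)^k` turns
  the sum into a combined P-value — a strictly monotone transform for fixed
  k, so the ranking is unchanged; it is reported for interpretability.  The
  CDF is evaluated directly (with `fsum`) below k/2 and by reflection
  `1 − F(k−s)` above, which makes the symmetry `F(s) + F(k−s) = 1` exact in
  floating point.
* **Fisher:** `X = −2 Σ ln p`, upper-tail χ² with 2k df.  P-values are
  floored at 1e-300 before the log (the same floor applied to every
  P-value written to disk).

Both accept k ≥ 2 P-values; the pipeline wires k = 3.  The combined
P-values are calibrated only under independence of the three inputs, which
is not guaranteed (DE and correlation evidence share the same data); they
should be read as monotone evidence scores, and the calibration tests use
independent uniform triples by construction.

Ranking ties (equal sums) are broken by smaller `p_gXY`, then gene id —
a declared convention, favouring cross-assay concordance.  Selection is
either **top-n** on the ranked list (n sweep used in evaluation:
10, 20, 50, 100, 200, 500, 1000, 2000) or the **commonDE** baseline
`G_τ = {g : p_gX < τ_X and p_gY < τ_Y}` with strict inequalities, ordered
by `max(p_gX, p_gY)`; `commonDE_tau_for_size` inverts τ for a target
selection size, mirroring how a τ is chosen in practice to select a fixed
number of genes.  An optional Benjamini–Hochberg column on the Edgington
combined P is written for convenience; the method itself performs no FDR
control, and none is claimed.

## Evaluation statistics

* `range(x_g) = max_{t,b} x_tg(b) − min_{t,b} x_tg(b)` (baseline included)
  — large for genuinely responding genes.
* `cv(x_g) = average over post-baseline t of sd(x_tg)/mean(x_tg)` with the
  **population** (1/B) standard deviation, exactly as the replicate-
  consistency formula is defined.  On LFC data the replicate mean crosses
  zero, where the ratio diverges; time points with `|mean| < 1e-8` are
  excluded and counted, and the average is over the included time points
  (a fixed 1/T denominator would silently drag excluded genes toward 0).
  A gene with every time point excluded has undefined CV.  CV is scale-
  invariant but not shift-invariant — inherent to applying CV on LFC.
* `pseudo_assay_split` partitions one assay's replicates (e.g. 1–2 vs 3–4)
  into a known-concordant assay pair, enabling the benchmark where truth is
  "these are the same biology".
* `selection_recovery` reports sensitivity/specificity/precision of a
  selection against planted truth classes.

## Synthetic data

The generator reproduces the study shape the package targets: G = 2000
genes, 14 time points (hourly from 0 to 6, then every 2 h to 20 — a fly
embryogenesis sampling design), B = 4 replicates per assay, Gaussian
replicate noise σ = 0.5 LFC around smooth mean trajectories with baseline
mean 0.  Trajectories come from a fixed closed-form template library
(sigmoid rise, transient pulse, monotone decay, flat) so the planted
cross-assay correlation is analytically controlled.  Six gene classes
(default fractions): null 0.85; DE-in-X-only, DE-in-Y-only,
DE-both-uncorrelated, DE-both-correlated, correlated-moderate-DE at 0.03
each.  Correlated classes share one template across assays, sign-flipped
with probability ½ (target r = ±1).  The uncorrelated-DE-both class draws
an *independent random mixture* of templates per assay rather than two
fixed distinct templates, because several fixed pairs are themselves
strongly (anti)correlated and would not plant uncorrelated genes.

Amplitudes: strong = 3.0 LFC (6σ), moderate = 1.5 LFC (3σ).  The moderate
amplitude is deliberately calibrated between the detection floor and the
commonDE threshold: at 2σ the gap class is barely detectable by any route,
at 4σ the per-assay tests themselves reach it and the commonDE contrast
the class exists to exhibit disappears; 3σ is the regime where combined
ranking recovers it but a per-assay threshold intersection does not.
σ is homogeneous by default; `sigma_gene_varying` draws gene-wise variances
from a scaled inverse-χ² prior to exercise moderation.  All randomness
flows through one `numpy` generator seeded from the config — identical
configs give bit-identical data.

What the simulator does **not** emulate: empirical LFC distributions of
real data, autocorrelated or heteroscedastic noise, assay-specific
replicate structure, network/pathway structure among genes, or missing
data.  Passing recovery tests therefore demonstrates correctness of the
machinery and the qualitative method contrast under the stated model, not
performance on any real dataset.

## Numerical conventions

* Floats are written with 17 significant digits and parsed with the
  correctly rounded `float()`, so write→read round trips are bit-exact
  (and reruns byte-identical).
* P-values in files are floored at 1e-300; in-memory degenerate values may
  be exactly 0 or 1 as documented above.
* Gene order is stable input order everywhere; ranking is the only
  reordering, with the declared tie rule.
* Spearman exact enumeration is capped at n = 8 (8! = 40320 permutations);
  ties fall back to the t approximation because the exact null with ties is
  input-dependent.

## Problem sizes used in the checks

The test suite and the acceptance script run the generator at its default
shape (2000 genes) for calibration and recovery checks, 10 seeds for the
multi-seed recovery property, a 10⁶-draw Monte-Carlo oracle for the
Irwin–Hall CDF, and full permutation enumeration at n = 6 for Spearman
exactness; the whole suite completes in well under a minute.

## Known limitations

* The three combined P-values are treated as independent; no dependence
  correction is attempted, and combined P-values are evidence scores, not
  calibrated error rates.  No FDR guarantee is provided.
* The correlation stage ignores temporal structure (no lagged or partial
  autocorrelation variants) — each course is an exchangeable n-vector as
  far as the test is concerned.
* The pairwise DE route reuses the baseline group across the T contrasts,
  so per-timepoint P-values of one gene are dependent; only their minimum
  is consumed downstream.
* CV on LFC courses is fragile near zero means even with the floor; the
  exclusion count is reported so users can judge.
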