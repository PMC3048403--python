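# Methods

`stagewise` analyses expression across a three-stage cell-progression
model — early/benign (E), intermediate (I), and late/malignant (L)
passages, each with replicate arrays — and asks three questions: which
probes change between the ends of the progression, *when* along the
progression each change happens, and whether the resulting gene lists are
coherent (over-represented categories, concordance with independent
tumour-vs-normal data sets).

## Normalization and differential expression

Arrays are put on a common scale by **global trimmed-mean scaling**: each
column is multiplied by a scalar so that its mean, after discarding
`floor(trim_fraction * n)` values from each tail, equals a fixed target.

| parameter | default | meaning |
|---|---|---|
| `target_trimmed_mean` | 500 fluorescence units | common per-array scale |
| `trim_fraction` | 0.02 per tail | conventional global-scaling trim for this platform |

Global scaling assumes the bulk of the array is unchanged between
conditions; the scalar is then dominated by non-differential probes and
between-stage ratios are preserved. When a large fraction of probes carry
real effects the column trimmed means themselves absorb the effects and
scaling compresses true fold changes — see *Synthetic data* below for how
the test conditions respect this.

Per probe, the three pairwise stage contrasts (I vs E, L vs E, L vs I)
are summarized by a **signed fold change** (ratio of stage means with
magnitude ≥ 1; −2 means 2-fold lower) and a **two-sided two-sample
t-test** on the linear-scale replicate intensities. The pooled-variance
(homoscedastic) test is the default — it mirrors the spreadsheet-style
two-sample test such data sets were historically analysed with — with
Welch and a log2-scale analysis available as options. Degenerate rows
(zero variance in both groups) get p = 1 for equal means and p = 0
otherwise, so constant probes never produce NaNs.

A probe is **differentially expressed** when all of:

* max intensity over all arrays > `intensity_floor` (500 units) — an
  expressed-above-background filter;
* |fold change L vs E| ≥ `fold_threshold` (2.0), threshold inclusive;
* p(L vs E) ≤ `alpha` (0.05), threshold inclusive.

No multiple-testing correction is applied to the per-probe p-values; the
design this reproduces used none, and the fold + intensity filters do the
practical false-positive control. DE probes collapse to per-direction
gene lists through a probe→symbol map; a gene with probes in both
directions is kept in both lists and logged.

## Trajectory classification

Each DE probe is assigned a pattern describing *when* its change occurs,
by rules evaluated in fixed precedence:

1. **late** — p(I vs E) > α and p(L vs I) ≤ α: nothing happened by the
   intermediate stage; the change comes after it.
2. **early** — |fc(I/E) − fc(L/E)| ≤ `early_window` (0.4 on the signed
   fold-change scale, inclusive), same sign, p(I vs E) ≤ α: the change is
   already complete at the intermediate stage.
3. **progressive** — both legs significant with consistent signs: a
   stepwise change across the whole progression.
4. **other** — anything else (non-monotone, underpowered legs).

Placing *late* first is safe because a genuine plateau (early) probe has
a significant E→I leg and cannot satisfy the late rule; placing *early*
before *progressive* keeps the early class exclusive, matching the small
early set such data show. The window comparison is inclusive because the
canonical boundary case sits at exactly 0.4 at printed precision. A
missing leg p-value (as when only the printed I/E and L/E columns of a
published table are available) simply fails its significance condition.

`summarize` reports counts and percent fractions over all DE probes.

## Over-representation

Gene-set enrichment of a DE list against a background of *expressed*
genes (max intensity above the floor; configurable to all annotated
genes) uses the exact one-sided **hypergeometric upper tail**
P(X ≥ k | N, K, n), computed by integer summation over the support — no
normal or saddlepoint approximation, so the unit tests can demand exact
agreement with brute-force enumeration. Significance is flagged on the
raw p < 0.01, mirroring how such category tables are conventionally
reported; Benjamini–Hochberg adjusted values are always reported
alongside so the reader can apply the stricter criterion.

## Cross-species concordance

Each mouse DE gene is looked up (case-insensitively) on a reference
platform's tumour-vs-normal table and scored by its **percentile rank**
when the platform is sorted by increasing p-value (1-based mean rank for
ties, divided by platform size, ×100). A gene is significant when its
rank ≤ `rank_threshold` (default 10%), and concordant when significant
and — optionally — changing in the same direction as the mouse call.
Genes absent or below detection are printed `x`; they count in n, never
in k. Direction checking defaults off because the published comparison
this reproduces counts one opposite-direction gene (ITGB5) among its
significant entries.

The overlap statistic is the exact **cumulative binomial**
P(X ≥ k | n, p_null). Under the null a random gene lands in the top r%
of a platform's p-value ranking with probability r/100, so `p_null`
defaults to `rank_threshold / 100`; both are explicit, user-visible
parameters because the choice is a modelling assumption, not an estimate.

## Assay statistics

* **ΔΔCt**: ΔCt = Ct(target) − Ct(reference) per sample; ΔΔCt =
  mean ΔCt(test) − mean ΔCt(control); fold = 2^(−ΔΔCt). The t-test is
  applied to the ΔCt values (standard Livak practice), not to folds.
* **Densitometry**: band/loading ratios as percent of the control-group
  mean ratio; the control group averages exactly 100 by construction.
* **F-actin per cell**: z̄ = x̄/ȳ with the quotient propagation-of-error
  σ_z = z̄·sqrt((σ_x/x̄)² + (σ_y/ȳ)²). σ is the sample (n−1) standard
  deviation throughout.

## Synthetic data

The generator emulates the 3-stage × 3-replicate array design with known
ground truth. Probe baselines are log-normal (log2 intensity
N(9, 1.2), putting the median near the 500-unit floor so the
expressed-above-background filter is genuinely exercised); each gene
(1–3 probes, all sharing one truth) is planted with a trajectory class
and direction; replicate noise is multiplicative log-normal
parameterized by CV and mean-corrected so stage means are unbiased.
Class semantics in log2 offsets (e = ±log2(effect_fold)): early (0, e, e),
progressive (0, e/2, e), late (0, 0, e), null (0, 0, 0). Defaults: 4-fold
effect, CV 0.05, equal up/down probability, class proportions
late/progressive/early/null = 0.6/0.3/0.05/0.05.

Because the generator writes all columns on one common scale, its output
can be analysed directly; the classifier-recovery tests therefore run
contrast → filter → classify without rescaling. The end-to-end test that
*includes* trimmed-mean scaling uses a null-dominated array (10,000
probes, ~4% effect probes in the 58.9/33.3/3.9 late/progressive/early
ratio) — the regime global scaling is valid in, and the one real arrays
occupy. Running the scaler on an array where most probes change
compresses the planted folds (the late-stage trimmed mean rises up to
~2×) and is a misuse of the method, not a defect of either component.

Companion generators plant one enriched gene set (members drawn from the
DE list at `enrichment_factor` × the background DE rate), a reference
platform whose concordant genes draw p-values safely inside the top
rank-threshold percent with matching sign, and qPCR Ct tables (reference
gene at 18 cycles, control target at 24, test target shifted by
−log2(fold), Gaussian cycle noise).

What the generator does **not** emulate: probe-level summarization
artifacts, intensity-dependent (non-multiplicative) noise, correlated
probes within a gene beyond shared truth, batch/chip spatial effects, and
annotation ambiguity. Passing tests therefore demonstrate the statistics
and the decision rules, not robustness to platform artifacts.

## Numerical choices

* Exact tail sums use Python integers (hypergeometric) and float powers
  (binomial); both are compared against full outcome enumeration for all
  parameter combinations with N ≤ 12 / n ≤ 12 in the test suite.
* All thresholds are inclusive (≥ fold, ≤ p, ≤ window); the intensity
  floor is strictly `>`.
* Probes with a non-positive stage mean get NaN fold changes and are
  excluded by the DE filter rather than raising mid-pipeline.
* Simulation sizes in the test suite (2,000–10,000 probes, 40–100 seeded
  replicates for detection-rate checks) are chosen to hold Monte-Carlo
  error well inside the asserted bands while keeping the suite fast.

## Known limitations

* The linear-scale pooled t-test with n = 3 is what the emulated design
  used, not what a modern analysis would choose (log-scale moderated
  statistics); both alternatives are exposed as options but not default.
* Cross-species matching is by case-insensitive symbol only; no ortholog
  mapping.
* The Series Matrix reader handles the data table and `!` metadata
  subset only — it is not a general SOFT/GEO parser, and it never
  downloads anything.
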