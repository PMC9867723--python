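# Methods

This note documents the statistical model behind `tck`, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
cohorts do and do not establish about real data.

## Study design assumed

Two groups (`PD`, `HC`) of five donors each, sampled at 0, 2, 4, 8, 12 and
24 h after in-vitro stimulation; one donor/time combination may be missing
(the default synthetic cohort drops donor P5 at 4 h, leaving 59 samples).
Groups are treated as independent; there is no paired-donor modelling.
Missing samples are simply absent — no imputation anywhere; downstream
group statistics use whatever samples remain (group medians with even n use
the midpoint-of-middle-two convention).

## Preprocessing

Order is fixed and enforced through a stage flag on the expression matrix:
`raw → bgcorr → qnorm → log2 → batchcorr`.  Applying a step out of order
raises rather than silently proceeding.

**Normexp background correction.**  Observed intensity X = B + S with
B ~ N(μ, σ²), S ~ Exp(mean α), fitted per sample column.  The primary
estimator is joint maximum likelihood of (μ, log σ, log α) by Nelder–Mead on
the convolution likelihood

    f(x) = (1/α) · exp((μ−x)/α + σ²/(2α²)) · Φ((x−μ−σ²/α)/σ),

started from moment-matching estimates (the exponential component carries
all the skewness: α₀ = (m₃/2)^⅓, σ₀² = s² − α₀², μ₀ = x̄ − α₀).  The moment
estimator is available as `method="moments"` and is the automatic fallback
if the optimizer fails to converge.  Corrected values are E[S | X] + offset
(default 16), computed in log space so extremely negative z-scores do not
underflow; the conditional mean is the mean of a positively truncated
normal and is strictly positive and monotone in x.  A constant intensity
column is rejected with advice to skip correction — there is nothing to fit.

**Quantile normalization.**  Each column is mapped onto the across-column
mean of order statistics.  Ties within a column receive the mean of the
tied ranks' reference values, which makes the map deterministic and
independent of input order.  On tie-free data the operation is exactly
idempotent.

**Batch correction.**  Per feature, OLS of log2 expression on the
group×time cell indicators plus sum-to-zero batch contrasts; only the
fitted batch component is subtracted, so fitted group×time means are
untouched.  Requires ≥ 2 batch levels and a design in which batch is not
aliased with group×time (checked by matrix rank; violations raise with the
aliased terms listed).  Additive offsets on a balanced design are removed
to machine precision.  Batch correction is intended for the transcriptome
matrix; assays processed in a single batch should pass
`batch_correct=False`.

## Two-step differential procedure

**Step 1 — time-course gate.**  For each feature and donor trajectory the
log2 deviation from the 0 h baseline is evaluated at every later time
point, and the *signed* deviation at the point of maximum absolute
deviation is kept; the per-group median of these signed scores is
thresholded in absolute value.  Signed-then-median (rather than
median-of-absolutes) preserves direction and makes the null distribution
symmetric around zero, so random excursions in different donors cancel
instead of accumulating.  The default gate is 0.5 log2 units; a 1.5-fold
gate (log2 1.5 ≈ 0.585) is available via
`Thresholds.from_fold_change(1.5)`.  The 0.5 default was chosen because the
downstream core-gene definition uses the same 0.5 constant, keeping the two
steps on one scale.

**Step 2 — shrinkage t per time point.**  Per group, per-feature empirical
variances v_g are shrunk toward their median v_target with James–Stein
intensity

    λ* = min(1, Σ_g V̂ar(v_g) / Σ_g (v_g − v_target)²),
    V̂ar(v_g) = n/(n−1)³ · Σ_i (w_ig − w̄_g)²,  w_ig = (x_ig − x̄_g)²,

computed separately for each group; the statistic is the unequal-variance t
with shrunk variances.  When every v_g equals the target the denominator is
zero and λ* is set to 1, which leaves the variances unchanged.  λ* = 0
recovers the ordinary Welch t exactly; λ* = 1 gives a common denominator
within each group so |t| ranks features by |mean difference|.

*p-values.*  The reference distribution of a shrinkage-t statistic has no
closed form; we use a Student-t with n_PD + n_HC − 2 degrees of freedom
(normal approximation available).  Because shrinkage reduces the spread of
the denominators, this choice is conservative for the features whose
variances are shrunk downward least, and it is deterministic — no
permutation machinery.  This is an interpretation, not a property of the
statistic.

*Multiplicity.*  BH step-up across features, separately within each time
point (six adjustments), because per-timepoint adjusted p-values are what
the core-gene definition consumes.  Degenerate cases: zero mean difference
with zero variance gives t = 0, p = 1; nonzero difference with zero
variance gives p = 0.

**Core classification.**  Core = adjusted p ≤ 0.05 and |median log2FC| ≥
0.5 at ≥ 1 time point.  Windows: early {0, 2}, intermediary {4, 8}, late
{12, 24} h.  Direction is `increased`/`decreased` if all core-timepoint FCs
share a sign, `mixed` otherwise; mixed features are excluded from
enrichment.  Recurrence is the number of core time points; "recurrent"
summaries use ≥ 2.

**Activation-marker QC.**  Markers must rise from baseline by ≥ 1 log2 unit
in both groups (group medians), and no marker×timepoint group difference
may be significant at α = 0.05 after BH adjustment across the whole
marker×timepoint family.  The family-level adjustment is deliberate: with 3
markers × 6 time points, raw α = 0.05 would fail about one clean cohort in
three by chance, which would make the QC uninformative; under a global null
the BH family rejects anything with probability ≤ α.  Raw p-values are
still reported per row.  Note that a clean cohort therefore still fails QC
in roughly 5% of runs — the report should be read, not only the flag.

## Ordination

Pairwise Euclidean distances either between samples or between donors after
feature-wise concatenation of each donor's time points (the combined
time-course view).  If any donor lacks a time point, that time block is
dropped for *all* donors, keeping vectors comparable and the result
deterministic.  Classical MDS is Torgerson scaling: B = −½ J D² J,
eigendecomposition, coordinates from the top-k eigenvectors scaled by
√eigenvalues.  Negative eigenvalues (non-Euclidean inputs) are reported but
never used for coordinates; goodness of fit is the positive-eigenvalue mass
captured by the k dimensions.  Features are not standardized before the
distance computation — preprocessing already puts columns on a common
scale, and standardizing would up-weight near-background noise.

## miRNA–target matching

Profiles are the six per-timepoint median log2FCs (PD − HC), not per-sample
values: the matching criterion is about the *shape* of the group-level
time-course change.  A (miRNA, gene) pair matches when the Pearson
correlation of the profiles is ≤ −0.5 and the gene moves opposite to the
miRNA's deregulation direction by ≥ 0.3 log2 units at ≥ 1 time point.  The
"≥ 1 time point" quantifier is the default (configurable); the looser
reading is what produces target lists in the hundreds-to-thousands from a
genome-scale candidate pool.  Candidate genes default to all genes with a
computable profile, not only deregulated ones.  Pairs with undefined
correlation (zero variance, or fewer than 3 shared finite time points) are
skipped and counted.  With n = 6 points the PCC-gate null rate is
substantial — P(r ≤ −0.5) ≈ 0.156 under independence — so matches are
regulatory *candidates*; the validated-target intersection (evidence tier
"strong", case-insensitive) marks the directly supported subset.

## Over-representation analysis

Upper-tail hypergeometric test: p = P(X ≥ k) for overlap k between the test
set (n genes) and a gene set (K genes) within a reference universe of N
genes, the conventional ORA statistic (numerically identical to one-sided
Fisher).  Test genes outside the reference are dropped with a warning; sets
with fewer than 2 reference members are skipped and listed.  BH adjustment
runs jointly across all sets of all loaded collections by default, giving a
single adjusted ranking.  The reference universe ("all protein-coding
genes" in the intended application) is a plain ID list supplied by the
user; no genome annotation is bundled.

## Synthetic cohorts

Raw intensity = background + amplitude · 2^latent, where background ~
N(50, 5²) (clipped strictly positive), amplitude ~ Exp(mean 1000) per
feature, and latent collects activation kinetics, group effects, batch
offsets and N(0, noise_sd²) measurement noise, so the generator is
consistent with the normexp model the preprocessing assumes and group
effects are only recoverable after background correction.

Parameter choices and what they emulate:

- `noise_sd` (default 0.4 log2): per-observation biological+technical
  residual.  Null-control experiments use 0.1.
- `signal_rate` = 1000 against background 50 ± 5: the exponential signal
  dominates background for > 95% of features, so `noise_sd` is the
  operative noise knob.  Near-background features behave like real dim
  probes: the offset-16 correction stabilizes but does not eliminate their
  extra log2 variance.
- Activation kinetics: scaled 1 − exp(−t/τ), τ = 4 h — zero at baseline,
  plateau by 8–12 h, identical in both groups (a CD69/IFIT3/NME1-like
  pattern).  Only the shared, saturating shape matters for the QC it feeds.
- Batch offsets: per-feature N(0, 0.2²) log2 units, batches assigned per
  donor (a donor's arrays are processed together), alternating donors so
  batch is balanced against group and time.
- Group effects: constant log2 shifts applied to the PD group inside the
  chosen activation windows; `mixed_direction` alternates sign across its
  windows; `mirna_coupled` pairs apply opposite-signed shifts to a miRNA
  and its partner gene, so their noise-free group-difference profiles have
  correlation exactly −1.
- Default scaled-down size: 2,000 genes + 200 miRNAs (the full ~30k-feature
  design is supported but not the default); recovery and null studies in
  the test-suite and acceptance script use this size with 20 seeds, chosen
  to keep a complete run in minutes on one CPU.

What the generator does *not* emulate: probe-level replicate spots, scanner
saturation, intensity-dependent (nonlinear) batch or dye effects, donor
pairing or longitudinal correlation beyond the shared kinetics, heavy-tailed
per-feature variance heterogeneity, and correlated gene modules.  Passing
recovery tests therefore show the pipeline's operating characteristics
under its own model assumptions — correctness and power in the regime the
method was designed for — not performance guarantees on real cohorts, where
variance structure and confounding are richer.

## Known limitations

- The shrinkage-t p-value calibration is approximate (see above); ranks are
  more trustworthy than absolute p-values near the significance boundary.
- With 5 donors per group, group medians are coarse (FC resolution limited
  by order statistics of n = 5).
- The PCC gate at n = 6 has limited specificity by construction; it is a
  screen, not a test.
- Quantile normalization slightly attenuates group fold changes when a
  noticeable fraction of features carries one-directional signal, since
  group-specific distribution shifts are forced onto the common reference.
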