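# Methods

## Scope and model

The package implements a two-arm biomarker workflow. The discovery arm
operates on a gene-by-sample RNA-Seq coverage matrix (RPKM units) from a
tumor panel and reduces it to "top candidate genes" through three
filters; the validation arm operates on serum analyte tables and
implements the statistics used to judge a candidate marker: ELISA
calibration, group comparisons, ROC operating points, and serial
surveillance. Both arms are deterministic given their inputs; all
randomness lives in the synthetic-data generator, driven by a single
integer seed per simulator call.

## Expression quantification

Coverage is RPKM computed on union exon models: exon intervals (0-based,
half-open) are merged per gene before length normalization so overlapping
or nested exons are never double-counted. The formula is
`count / (length_kb × total_mapped_reads / 1e6)`. Isoform-level
quantification and multi-mapping resolution are out of scope; counts are
taken as given.

Rank standing is reported as a *top-fraction*: within each sample, the
fraction of expressed genes (coverage > 0) with strictly greater coverage
than the query gene. Strict-greater counting makes ties harmless — tied
genes share the better rank — and the statistic is deterministic and
order-independent. "Expressed" is defined as coverage > 0 because the
workflow ranks among expressed genes without imposing a floor; the
expression floor belongs to the screen, not to the ranking.

All standard deviations use the n−1 (sample) denominator; that convention
reproduces the published two-tumor group SDs exactly from their range
endpoints (for n = 2, sd = range/√2). Single-observation groups report a
missing sd rather than zero.

qPCR validation data are normalized as 2^(−ΔCt) with ΔCt measured
against the arithmetic mean of the housekeeping-gene Ct values.

## Candidate screen

Stages, in order: (1) mean coverage strictly > `min_mean_coverage`
(default 1.0); (2) membership in a user-supplied secretome gene list,
matched case-sensitively; (3) retention when sd ≤ `cv_threshold` × mean
(default 0.75), i.e. disqualification is strict `sd > 0.75·mean`. Both
filters use strict inequalities, so boundary genes survive stage 1's
complement (a gene at exactly the floor is excluded) and survive stage 3
(a gene at exactly 75 % is retained). Genes with zero mean inside the
candidate pool have an undefined CV and are disqualified by convention
rather than raising, which keeps the cascade total on degenerate
synthetic inputs. Candidates are ordered by mean coverage descending with
gene-id tie-breaks. Because the three stages are pure set operations, the
final candidate set equals the intersection of the three stage sets in
any evaluation order; the accounting identity
`n_candidates = n_secreted − n_disqualified` is asserted in the result
object itself.

The secretome is deliberately an injected list, not a bundled database:
secretome annotations are versioned external resources and any snapshot
would go stale.

## ELISA reduction

Each plate is calibrated independently: background-corrected absorbance
(A450 − A620) of the standards is fit with a four-parameter logistic
`y = d + (a−d)/(1 + (x/c)^b)` by bounded least squares
(`scipy.optimize.curve_fit`). In this parameterization `a` is the
response at zero concentration and `d` at saturation, so an ascending
sandwich assay has a < d and a descending competitive assay a > d, with
b > 0 in both cases. Initialization anchors `a` at the
lowest-concentration standards' mean response, `d` at the highest, `c` at
the geometric mean of the nonzero standard concentrations, and b = 1;
this converges deterministically for both curve orientations. At least
five distinct standard concentrations (including a blank) are required,
and a flat standard series raises instead of producing an unidentifiable
fit.

Concentrations are recovered through the exact analytic inverse
`x = c·((a−d)/(y−d) − 1)^(1/b)`, defined only for absorbances strictly
between the asymptotes; wells outside that open interval are flagged as
out-of-range, not extrapolated. Duplicates are averaged on the
concentration scale after inversion — robust to local curve curvature —
and a curve is never applied to another plate's wells (the reduction API
is plate-scoped).

The kit's actual standard concentrations and QC acceptance ranges are not
published; the simulator's defaults (two-fold-ish serial dilution spanning
the assay range, duplicate wells, Gaussian absorbance noise) are declared
choices, not inferences.

## Serum statistics

Group summaries pool exactly: pooled mean is the size-weighted mean, and
pooled variance combines within-group and between-group sums of squares
with the n−1 denominator, so pooling (n, mean, sd) triples is identical
to computing moments of the concatenated raw data (tested to 1e-10, and
associative). This is what lets the published per-group table reproduce
the published pooled malignant mean (1344.09 ng/ml) without raw data.

The default two-sample test is Welch's (unequal variances) with
Welch–Satterthwaite degrees of freedom, because the published group SDs
differ by about two-fold; the pooled-variance Student variant is
available, and for two groups its square equals the one-way ANOVA F.
A summaries-only Welch test is provided so published (n, mean, sd)
triples can be tested directly; on summaries computed from raw data it is
identical to the raw-data Welch test. All p-values are two-sided.
Zero-variance degenerate inputs resolve by convention (equal means →
p = 1; unequal → the p = 0 limit, flagged).

The ANOVA post-hoc family is all pairwise group comparisons with
Bonferroni adjustment `min(1, p × n_pairs)` — the most plausible reading
of a "Bonferroni correction and post-hoc test" battery. Pairwise tests
default to Welch for consistency with the headline test.

## ROC

Candidate thresholds are the distinct observed scores plus a +∞ sentinel;
classification is score ≥ threshold ⇒ positive (the marker is elevated in
disease). The sentinel guarantees the (sensitivity 0, specificity 1)
corner exists, so a threshold meeting any specificity target in (0, 1) is
always available. AUC is the trapezoidal area over (1 − specificity,
sensitivity); with the ≥ convention tied scores move together and the
trapezoids contribute exactly the ½-credit tie terms, making the
trapezoidal AUC equal the pairwise-comparison AUC — an identity the test
suite checks to 1e-12 on a thousand random fixtures, alongside
invariance under monotone score transforms and the complementation rule
AUC(−scores) = 1 − AUC.

`threshold_at_specificity` returns, among thresholds whose attained
specificity meets the target, the one with maximal sensitivity, breaking
ties toward the lower threshold (the least conservative cutoff with the
same performance). Reported thresholds are observed concentrations; no
interpolation between operating points is performed, matching how
data-adjacent threshold values are reported in practice.

## Surveillance

Composite mode averages each patient's readings over the whole
post-surgical period, then compares the per-patient composites between
NED and AWD; serial mode pools every reading as an independent
observation. The serial convention ignores within-patient correlation —
it mirrors how pooled serial comparisons are reported in this setting —
and the result object carries a note saying so. "Above threshold" is
strict (>), declared for determinism; the working threshold defaults to
1000 ng/ml, with the cutoff configurable since ROC-derived cutoffs
(e.g. 1064.5 ng/ml at 90 % specificity) are equally defensible.
Percentages are reported round-half-up to integers (19/33 → 58 %,
8/35 → 23 %); underlying reports always carry full precision.

## Synthetic data: what it does and does not emulate

*Serum cohorts* are lognormal per group with parameters solved
analytically from the requested mean m and sd s
(σ² = ln(1 + s²/m²), μ = ln m − σ²/2), defaulting to the published group
summaries. Lognormality is forced by the data shape: group SDs are of the
order of the means on strictly positive support, which a normal model
cannot produce. Moment recovery is tested at n = 10⁵ (means within 1 %,
SDs within 2 %).

*Expression matrices* are zero-inflated lognormal: gene-level means are
lognormal(log_mean = 0, log_sd = 2), per-sample multiplicative noise is
lognormal(0, 0.25), and a 25 % dropout mass sits at zero. With ~20k
genes these defaults put roughly half the genes above 1 RPKM mean
coverage, matching the reported ~10,000-of-annotated expressed fraction;
the default secreted fraction (17 %) mirrors the published
working-set/expressed ratio, and the default sample layout is the
22-tumor panel (2 borderline, 5 early, 11 late, 2 disseminated,
2 recurrent). Spike genes are planted at a level chosen so the expected
fraction of gene-sample values above them is a third of their target
top-fraction, with multiplicative noise capped well under their CV
budget; they are always flagged secreted. A planted marker must survive
the full screen in every seeded replicate, and the suite checks 100
seeds.

*Surveillance series* draw 5 + 5 patients with 5-9 visits each and
lognormal levels around the published NED/AWD pooled means; the published
data include no dispersion for these groups, so sd = 60 % of the mean was
chosen once to match the case-group coefficient of variation in the serum
table.

What the generator does **not** reproduce: the real cohort's
between-group overlap beyond first and second moments, within-patient
serial correlation, assay batch effects, and any covariance between the
marker, CA125, age, and ethnicity. Consequently dataset-level published
results — AUC 0.700 / 0.816, sensitivities 45.3 / 36.8 / 73 %, thresholds
1064.5 / 1304.7 / 641.5 ng/ml, and the composite-mode p-values — are not
recoverable from summaries and are covered by structural property tests
(identities, monotonicity, enumeration oracles) rather than by value
reproduction. Passing tests therefore certify the correctness of the
computations and the summary-level published numbers, not performance of
the marker on real patients.

## Numerical choices and problem sizes

- Percentage reporting: round-half-up to integer; JSON reports keep full
  precision.
- 4PL fitting: bounded trust-region least squares, b ∈ (1e-6, ∞),
  c ∈ (1e-12, ∞); noise-free standards recover generating parameters to
  1e-6 relative (tested over 25 random parameter sets).
- Printed-table comparisons use the table's own precision (3 dp for
  coverage summaries, 2 dp for serum means); exact half-cases such as a
  two-sample mean of 13.8925 may legitimately round either way and are
  compared with a ±0.0005 band.
- Test problem sizes: 10⁵ draws per group for moment recovery, 10³ ROC
  fixtures for the AUC identity, 2×10⁵ permutations for the t-test
  oracle, 100 seeds for the spike-gene screen property; the full suite
  runs in well under a minute on one CPU.

## Known limitations

- The screen reports exact stage counts; reconciling them with rounded
  prose counts ("~1700" vs 541 + 1169 = 1710) is left to the caller.
- ELISA inter-plate bridging/normalization beyond per-plate curves is out
  of scope, as are kit-lot calibration values.
- The serial-mode surveillance test inherits the independence convention
  described above; a mixed-effects treatment would be more defensible
  statistically but is deliberately not what this workflow computes.
- CA125 enters only as a concordance cutoff (35 U/ml); its kinetics are
  not modeled.
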