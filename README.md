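# seroscreen

Discovery and validation analytics for secreted serum biomarkers of
epithelial ovarian cancer (EOC), built around the workflow that first
identified IGFBP-4 as a candidate marker: screen a tumor RNA-Seq
expression matrix for highly and consistently expressed secreted genes,
then evaluate the chosen candidate in serum by ELISA with group
statistics, ROC analysis, and serial post-surgical surveillance.

It is aimed at translational researchers who have (a) a gene-by-sample
coverage matrix plus a secretome gene list, and/or (b) serum analyte
tables from a case/control cohort, and want the whole published analysis
battery as tested, scriptable functions rather than spreadsheet steps.

## What it computes

**Expression screen.** Coverage is RPKM — mapped reads per kilobase of
(union) exon per million mapped reads:

    RPKM_g = count_g / (L_g/10^3 · N/10^6)

with `L_g` the merged-exon length and `N` the library size. The candidate
cascade keeps genes with mean coverage > 1, intersects them with a
user-supplied secretome list, and disqualifies genes whose across-sample
standard deviation exceeds 75 % of their mean (a coefficient-of-variation
stability filter). Survivors are ranked by mean coverage, and any gene's
standing among expressed genes is reported as its top-fraction (the
fraction of expressed genes with strictly greater coverage).

**ELISA calibration.** Per-plate four-parameter logistic standard curves
on background-corrected absorbance (A450 − A620),

    y = d + (a − d) / (1 + (x/c)^b),

inverted analytically to concentrations; duplicates averaged on the
concentration scale.

**Serum statistics.** Group summaries and their exact pooling from
(n, mean, sd) triples, Welch or pooled t tests (from raw data or from
summary statistics alone), one-way ANOVA with Bonferroni-corrected
pairwise post-hoc tests, fold changes, and Pearson R².

**ROC.** Empirical curve over all observed thresholds (score ≥ threshold
⇒ positive), trapezoidal AUC (provably equal to the pairwise
P(case > control) + ½ P(tie)), and threshold selection at a target
specificity: the maximal-sensitivity operating point whose specificity
meets the constraint.

**Surveillance.** Per-patient composite averages over the post-surgical
period, pooled fractions of serial readings above a working threshold
(default 1000 ng/ml), and NED-vs-AWD comparisons in composite and serial
modes.

**Synthetic cohorts.** Because the original per-sample data are not
deposited, `seroscreen.synthetic` generates expression matrices, serum
cohorts (lognormal, analytically moment-matched to the published group
means/SDs), surveillance series, and ELISA plates with the published
summary structure, so the full pipeline runs and is tested end to end.

## Worked example

Simulate a serum validation cohort at the published group parameters
(82 Control / 6 Benign / 16 Early / 40 Late / 16 Recurrent) and run the
ROC analysis with healthy + benign subjects as controls:

```sh
biomarker simulate --kind serum --seed 1 --out-dir sim
biomarker roc --cohort sim/cohort.csv --specificity 0.9 --specificity 0.95 --out-dir roc_out
```

prints

```json
{
  "auc": 0.9324494949494949,
  "queries": [
    {"target_specificity": 0.9,  "threshold_ng_ml": 597.38, "sensitivity": 0.819, "attained_specificity": 0.909},
    {"target_specificity": 0.95, "threshold_ng_ml": 693.97, "sensitivity": 0.722, "attained_specificity": 0.955}
  ]
}
```

(thresholds and sensitivities abbreviated here; the JSON on disk carries
full precision). Reading: at the lowest observed concentration cutoff
whose specificity is at least 90 %, about 82 % of the simulated cases are
detected, and the cutoff is an observed concentration, not an
interpolated one. The simulated AUC (0.93) is higher than reported for
the real cohort (0.700): two moment-matched independent lognormals
overlap less than the real case/control data did, which is exactly why
dataset-level ROC numbers cannot be reproduced from summaries alone (see
`docs/methods.md`).

The same battery is available as library calls (`roc_curve`,
`threshold_at_specificity`, `anova_bonferroni`, `run_screen`, ...), and
`biomarker run --config config.yaml` executes every stage whose inputs
are configured, writing a JSON report plus per-stage tables.

## Layout

- `src/seroscreen/expression.py` — RPKM, union-exon lengths, summaries, ranking, qPCR ΔCt
- `src/seroscreen/screen.py` — the three-stage candidate cascade
- `src/seroscreen/elisa.py` — 4PL calibration and plate reduction
- `src/seroscreen/stats.py` — pooling, t tests, ANOVA/Bonferroni, fold change, R²
- `src/seroscreen/roc.py` — ROC curve, AUC, threshold-at-specificity
- `src/seroscreen/surveillance.py` — composite/serial monitoring analytics
- `src/seroscreen/synthetic.py` — cohort and plate simulators
- `src/seroscreen/cohorts.py` — published summary tables used as defaults
- `src/seroscreen/pipeline.py`, `cli.py`, `io.py` — orchestration, CLI, table I/O
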