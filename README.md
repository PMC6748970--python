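# driverburden

Estimating how many somatic single-nucleotide variants (SNVs) actually *drive*
a tumour — as opposed to the far larger number of passenger mutations — from
per-variant classifier confidence scores. `driverburden` is a small analysis
library plus CLI for researchers who have a table of scored variants across a
tumour cohort (one *p-score* in [0, 1] per variant, 1 = maximal confidence the
variant is a driver) and a balanced labelled test set of the same scores, and
who want per-sample **tumour driver burden** (TDB) estimates and cohort-level
summaries by cancer type, clinical stage and gene.

## The method

Given a 50:50 balanced labelled score set (drivers vs neutral variants):

1. **FDR threshold calibration.** For a threshold *t*, count labelled scores
   at or above *t*: TP drivers, FP neutrals; the empirical false discovery
   rate is FDR(*t*) = FP/(TP+FP). The selected threshold is the smallest grid
   value (default grid 0.00…1.00 step 0.01) that *sustains* FDR ≤ target
   (default 5%) at every larger threshold where the FDR is defined.
2. **Thresholded count.** A sample's TDB is the number of its variants with
   p-score ≥ *t*.
3. **Threshold-independent weighted count.** Bin the labelled scores in bins
   of width 0.01. Under class balance the in-bin fraction of driver-labelled
   examples estimates the posterior p̂_b = p(driver | score ∈ b). A variant in
   bin *b* is eligible when p̂_b > 0.5 and then contributes
   (+1)·p̂_b + (−1)·(1−p̂_b) = 2p̂_b − 1 — the expected true-positive minus
   false-positive weight. Summing over a sample's variants gives a count that
   needs no FDR choice.
4. **Cohort statistics.** Samples with more than 500 estimated drivers
   (hypermutants) are excluded; per cancer type the pipeline reports the
   primary mode, median, mean and quartiles, a two-sided Mann-Whitney U test
   of each type against the pooled remainder, stage-stratified (I–IV)
   quartile tables, and per-gene incidence — the percentage of samples with
   at least one driver call in the gene at the calibrated threshold.
5. **Gene-referenced threshold fit.** When an external model supplies
   per-gene driver counts, a one-dimensional line search picks the threshold
   minimising the summed absolute (or squared) per-gene count differences.

A synthetic cohort generator (Beta-distributed class-conditional scores,
Poisson or Poisson-mixture driver counts, planted high-incidence driver
genes, hypermutant outliers, stage-dependent rates) provides ground truth for
every estimator; see `docs/methods.md`.

## Worked example

```python
import numpy as np
from driverburden import (
    ClassScoreModel, DriverBurdenEstimator,
    simulate_calibration_set, simulate_cohort, default_cohort_model,
    summarize, counts_by_type, mann_whitney_vs_rest, gene_incidence, rank_genes,
)

score_model = ClassScoreModel()                      # Beta(8,2) vs Beta(2,8) p-scores
calib = simulate_calibration_set(score_model, 50_000, seed=1)
X, y = calib["p_score"].to_numpy(), calib["label"].to_numpy()

est = DriverBurdenEstimator(target_fdr=0.05).fit(X, y)
print(f"threshold at 5% FDR: {est.threshold_:.2f}")

cohort, truth = simulate_cohort(default_cohort_model(), score_model, seed=2)
counts = est.transform(cohort)                       # hypermutants dropped
print(summarize(counts).to_string(index=False))

res = mann_whitney_vs_rest(counts_by_type(counts), "THCA")
print(f"THCA vs rest: U={res.u_statistic:.0f}, p={res.p_value:.3g} ({res.method})")

clean = cohort[cohort["sample_id"].isin(counts["sample_id"])]
top = rank_genes(gene_incidence(clean, est.threshold_), "PACA", top_k=3)
print(top[["gene", "incidence"]].to_string(index=False))
```

prints

```
threshold at 5% FDR: 0.43
cancer_type  n_samples  mode  median     mean   q1   q3  count_kind
       BLCA        494  12.0    14.0 13.92915 11.0 16.0 thresholded
       BRCA        500   7.0     7.0  7.26600  5.0  9.0 thresholded
       PACA        500   8.0     7.0  7.50200  6.0  9.0 thresholded
       PRAD        500   4.0     4.0  4.48600  3.0  6.0 thresholded
       SKCM        500   6.0     7.0 10.26600  5.0 16.0 thresholded
       THCA        500   2.0     2.0  2.07200  1.0  3.0 thresholded
THCA vs rest: U=83306, p=7.65e-207 (normal_approx)
  gene  incidence
  KRAS      0.874
  TP53      0.676
PIK3CA      0.526
```

Reading this: with well-separated but overlapping score classes, a 0.43
threshold already sustains a 5% FDR. The thyroid-like type (generating rate 1
driver/sample) reports a median TDB of 2 — driver counts at a permissive
threshold are biased upward by false-positive passengers, which is exactly
why the weighted count and the threshold sweep exist — yet its burden
distribution is separated from the rest of the cohort at p ≈ 10⁻²⁰⁷, and the
planted KRAS-like gene tops the pancreatic-like ranking with 87% of samples
carrying at least one confident driver call. Six of the 500 bladder-like
samples were excluded as hypermutants.

The same pipeline is available from the shell:

```bash
driverburden simulate --seed 5 --out cohort.tsv --truth truth.tsv --calibration calib.tsv
driverburden calibrate --calibration calib.tsv --target-fdr 0.05 --out calib_model.tsv
driverburden count --cohort cohort.tsv --calibration calib.tsv --weighted --out counts.tsv
driverburden summarize --counts counts.tsv --mann-whitney --out summary.tsv
driverburden genes --cohort cohort.tsv --threshold 0.43 --top-k 5 --out genes.tsv
driverburden stages --counts counts.tsv --out stages.tsv
```

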