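# Methods

## Model and assumptions

The pipeline treats each scored variant as a Bernoulli trial whose latent
label (driver, n = +1; neutral, n = −1) is unobserved, while a classifier's
Platt-scaled confidence — the *p-score* in [0, 1] — is observed. Everything
rests on one assumption: the labelled calibration set is an unbiased,
approximately 50:50 balanced sample of the same score distributions the
cohort's variants follow, conditioned on their true labels. Under exact
balance, the in-bin proportion of driver-labelled calibration scores equals
the posterior p(n = +1 | score ∈ b), and the tail counts of the two classes
give an unbiased empirical FDR at any threshold. Imbalance biases both, which
is why ingestion enforces a balance tolerance (default 0.05, overridable but
never silent).

Per-sample estimators:

* **thresholded count** — #{variants with score ≥ t}, with t selected at a
  target FDR (default 5%);
* **weighted count** — Σ over variants in bins with p̂_b > 0.5 of
  (2p̂_b − 1). The identity 2p̂ − 1 = p̂ − (1 − p̂) makes this the expected
  number of true positives minus false positives among eligible calls, so it
  is an (approximately) bias-corrected count that requires no FDR choice.

Both estimators count *calls*, not latent truth: at a permissive threshold
the thresholded count includes false-positive passengers, and comparisons of
the worked example's per-type means against the generating rates show
exactly that upward bias. The package reports it rather than hiding it — the
threshold sweep and the weighted count are the tools for reasoning about it.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `target_fdr` | 0.05 | FDR the selected threshold must sustain |
| `bin_width` | 0.01 | score-histogram bin width (100 bins) |
| `smoothing` | `add_one_isotonic` | per-bin posterior estimator |
| `hypermutation_max` | 500 | samples with count > 500 are excluded |
| `threshold_grid` | 0.00…1.00 step 0.01 | candidate thresholds (two-decimal reporting resolution) |
| `mode_bin_width` | 1.0 | histogram bin for the mode of real-valued weighted counts |

## Numerical and procedural choices

**FDR from raw scores, not the histogram.** Tail counts are computed from the
sorted labelled scores (exact), while the 0.01-bin histogram is used only for
posteriors. Binning the FDR would quantise it with no benefit.

**Sustained-control threshold rule.** Empirical FDR curves need not be
monotone. The selected threshold is the smallest grid value t such that
every grid value ≥ t with a *defined* FDR satisfies FDR ≤ target, with the
additional requirement that at least one defined FDR exists at or above t: a
stretch of the grid where no calibration score passes is no evidence of
control, and without this requirement any threshold beyond the largest
calibration score would qualify vacuously. When no grid value qualifies
(e.g. the class score distributions coincide), `select_threshold` returns
`None` and the estimator raises `FdrNotAchievableError`.

**Posterior smoothing.** Raw per-bin proportions at width 0.01 are noisy and
undefined in empty bins. The default adds one pseudo-count per class
((pos+1)/(pos+neg+2)) and then applies pool-adjacent-violators isotonic
regression (bins weighted by smoothed occupancy, via scikit-learn), encoding
that a Platt-scaled score should be monotone in the driver posterior.
`none` and plain `add_one` are available; with `none`, use of an
undefined-posterior bin is a hard error naming the bin.

**Tie-breaking and boundaries.** Threshold comparisons are inclusive
(score ≥ t) everywhere. Eligibility for the weighted count is strict
(p̂_b > 0.5); a bin at exactly 0.5 contributes zero either way, so strictness
only fixes determinism. Hypermutation is strict: a sample at exactly 500 is
retained, 501 is excluded. The integer-count mode breaks ties to the
smallest value, the binned real-valued mode to the leftmost bin; the
gene-referenced line search breaks ties toward the larger (more
conservative) threshold. Scores of exactly 1.0 fall in the closed last bin.

**Quantiles** use the linear-interpolation rule (order statistic at position
1 + (n−1)p; numpy's default), so fixture values are exact.

**Mann-Whitney U.** Each type is tested two-sided against the pooled counts
of all other types. For combined n ≤ 12 the p-value is computed by full
enumeration of the C(n, n₁) group assignments with 0.5 tie credit — this
exists for testability and exactness at small n; real cohorts take the
scipy asymptotic path with tie and continuity corrections. p-values are
clamped to (0, 1].

**Hypermutation filtering in sweeps** is recomputed at every grid threshold
(hypermutant status depends on the threshold). Per-sample counts are always
non-increasing in the threshold; per-type means over a *fixed* retained
sample set inherit that monotonicity, but re-filtering can let a previously
excluded high-count sample re-enter at a higher threshold and locally raise
a per-type mean. The monotonicity guarantees are therefore stated per sample
and for hypermutant-free cohorts.

**Gene incidence denominators** include every sample of the type present in
the cohort, with or without qualifying variants or gene annotations; a gene
observed only below threshold reports incidence 0. Gene symbols are matched
as exact strings.

## The synthetic generator

`synthetic_cohort` draws, per cancer type: a stage (optional categorical
marginals), a driver count K from Poisson(λ) or a two-component mixture
(λ × per-stage multiplier), a passenger count M from Poisson(μ), driver
scores from Beta(a_pos, b_pos) (default (8,2)), passenger scores from
Beta(a_neg, b_neg) (default (2,8)), driver genes from a weighted (Zipf-like)
pool and passenger genes uniformly. Hypermutants (fraction per type) get
K = 501 + Poisson(200): the analysis defines only the cutoff, so the
distribution above it is a modelling choice. Point-mass score overrides give
perfect-separation scenarios in which the thresholded count must equal the
true count exactly — the sharpest possible correctness probe.

The default cohort (`default_cohort_model`) spans the qualitative regimes of
pan-cancer data: a very-low-burden type (λ=1), a moderate type (λ=6), a
high-burden type (λ=12) with 1% hypermutants, a bimodal type
(0.6·Poisson(3) + 0.4·Poisson(15)) standing in for heterogeneous "neo-modal"
populations, a type with a planted KRAS-like gene carrying a third of a λ=6
driver process (at-least-one incidence 1 − e⁻² ≈ 86%), and a
stage-accumulating type (multipliers 1, 1.5, 2, 2.5). Sizes of 500
samples/type keep full-pipeline runs interactive.

`expected_weighted_count_oracle` integrates the weighted estimator against
the known Beta (or point-mass) class distributions:
Σ_{b: p̂_b>0.5} (2p̂_b − 1)[λ·P_driver(b) + μ·P_neutral(b)]. It shares the
fitted posteriors but not the counting path, making it an independent check
of the estimator's Monte-Carlo mean.

What the generator deliberately omits: mutational signatures and
trinucleotide context, realistic genomic positions, linkage between variants,
intra-tumour subclones, region-dependent score families, and any correlation
between a variant's gene and its score. Passing tests therefore demonstrate
that the estimators recover the truth *when the calibration assumption
holds*; they say nothing about classifier miscalibration on real cohorts,
which enters through the calibration table, not through this code.

## Problem sizes used in tests and the acceptance script

Calibration draws of 5×10⁴ per class (10⁶ for the oracle comparison),
cohorts of 5×10³–10⁴ samples for recovery checks, 2×10³ samples per stage
for stage profiles, and 500 samples/type for the default cohort. These sizes
put Monte-Carlo standard errors well below the assertion tolerances (3
standard errors for distributional checks, exact equality for point-mass
recovery) while keeping the full suite fast.

## Known limitations

* The FDR is calibrated on the labelled test set and transferred to the
  cohort; covariate shift between them transfers bias directly.
* The weighted count corrects the expected FP/TP trade-off per bin but not
  the class-prior mismatch between 50:50 calibration data and cohorts where
  true drivers are rare — counts at permissive thresholds remain
  upward-biased, as the sweep makes visible.
* Multi-modality is reported (modes vs medians), not deconvolved.
* Region handling is a column filter; coding and noncoding analyses are
  independent runs with their own calibration.
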