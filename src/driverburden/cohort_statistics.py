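"""Cohort-level summary statistics of per-sample driver counts.

Per cancer type: primary mode / median / mean / quartiles of the driver
count, a threshold sweep of those statistics, a two-sided Mann-Whitney U
test of each type against the pooled remainder of the cohort, and
stratification of counts by clinical stage I-IV.

Quantiles use the linear-interpolation rule (order statistic at position
``1 + (n-1)p``), i.e. numpy's default.  The *primary mode* is the highest
peak of the count histogram: for integer counts, the most frequent value
(ties to the smallest); for real-valued weighted counts, the midpoint of the
most populated bin of configurable width anchored at 0 (ties to the
leftmost).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort_io import STAGES
from .driver_counting import apply_hypermutation_filter, count_cohort
from .errors import ValidationError

logger = logging.getLogger(__name__)

#: Switch from exact enumeration to the normal approximation above this
#: combined sample size (exact enumeration is for testability at small n;
#: real cohorts are far larger).
EXACT_ENUMERATION_MAX_N = 12

SUMMARY_COLUMNS = ("cancer_type", "n_samples", "mode", "median", "mean", "q1", "q3", "count_kind")


@dataclass
class ThresholdSweep:
    """Per-type median/mean of the thresholded count across a threshold grid."""

    thresholds: np.ndarray
    stats: pd.DataFrame  # columns: threshold, cancer_type, n_samples, median, mean


@dataclass
class DifferentiationResult:
    """Two-sided Mann-Whitney U of one type's counts vs all other types pooled."""

    cancer_type: str
    u_statistic: float
    p_value: float
    n_type: int
    n_rest: int
    method: str  # "exact" | "normal_approx"


@dataclass
class StageSummary:
    """Per-stage count statistics for one cancer type.

    ``stages`` holds one row per observed stage (columns stage, n, mean, q1,
    median, q3); stages with no samples are omitted, not zero-filled.
    ``monotone_medians`` is True when the medians are non-decreasing across
    the observed stages in I < II < III < IV order.
    """

    cancer_type: str
    stages: pd.DataFrame
    monotone_medians: bool


def _counts_column(count_kind: str) -> str:
    if count_kind == "thresholded":
        return "count_thresholded"
    if count_kind == "weighted":
        return "count_weighted"
    raise ValidationError(f"unknown count_kind {count_kind!r}")


def primary_mode(values: np.ndarray, integer: bool, mode_bin_width: float = 1.0) -> float:
    """Highest histogram peak of a set of counts.

    Integer counts: most frequent value, ties broken to the smallest value.
    Real counts: midpoint of the most populated histogram bin of width
    ``mode_bin_width`` anchored at 0, ties broken to the leftmost bin.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError("cannot take the mode of an empty set")
    if integer:
        ints = values.astype(int)
        freq = np.bincount(ints)
        return float(np.argmax(freq))  # argmax takes the first (smallest) on ties
    if mode_bin_width <= 0:
        raise ValidationError("mode_bin_width must be positive")
    bins = np.floor(values / mode_bin_width).astype(int)
    freq = np.bincount(bins)
    b = int(np.argmax(freq))
    return float((b + 0.5) * mode_bin_width)


def summarize(counts: pd.DataFrame, count_kind: str = "thresholded",
              mode_bin_width: float = 1.0) -> pd.DataFrame:
    """Per-cancer-type mode/median/mean/quartiles of per-sample counts.

    ``counts`` is a per-sample table from
    :func:`driverburden.driver_counting.count_cohort`, already hypermutation
    filtered.  Types whose count column is entirely missing are omitted with
    a warning.
    """
    col = _counts_column(count_kind)
    if counts is None or len(counts) == 0:
        raise ValidationError("counts table is empty")
    rows = []
    for ctype, group in counts.groupby("cancer_type", sort=True):
        vals = group[col].to_numpy(float)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            logger.warning("summarize: no %s counts for type %s; omitted", count_kind, ctype)
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append(
            {
                "cancer_type": ctype,
                "n_samples": int(vals.size),
                "mode": primary_mode(vals, integer=(count_kind == "thresholded"),
                                     mode_bin_width=mode_bin_width),
                "median": float(med),
                "mean": float(vals.mean()),
                "q1": float(q1),
                "q3": float(q3),
                "count_kind": count_kind,
            }
        )
    return pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))


def sweep_thresholds(cohort: pd.DataFrame, grid: Sequence[float],
                     hypermutation_max: int = 500,
                     region: str | None = None) -> ThresholdSweep:
    """Per-type median and mean of the thresholded count at every grid threshold.

    Counts and the hypermutation filter are recomputed at each threshold
    (hypermutant status depends on the threshold), so the retained sample set
    may differ between grid points.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValidationError("threshold grid is empty")
    rows = []
    for t in grid:
        counts = count_cohort(cohort, threshold=float(t),
                              hypermutation_max=hypermutation_max, region=region)
        retained, _ = apply_hypermutation_filter(counts, hypermutation_max)
        for ctype, group in retained.groupby("cancer_type", sort=True):
            vals = group["count_thresholded"].to_numpy(float)
            rows.append(
                {
                    "threshold": float(t),
                    "cancer_type": ctype,
                    "n_samples": int(vals.size),
                    "median": float(np.median(vals)),
                    "mean": float(vals.mean()),
                }
            )
    return ThresholdSweep(thresholds=grid, stats=pd.DataFrame(rows))


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of x vs y with 0.5 credit for ties (pairwise form)."""
    greater = (x[:, None] > y[None, :]).sum()
    equal = (x[:, None] == y[None, :]).sum()
    return float(greater) + 0.5 * float(equal)


def _exact_mannwhitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided p by full enumeration of group assignments of the pooled values.

    p = fraction of the C(n1+n2, n1) assignments whose U deviates from the
    null mean n1*n2/2 at least as much as the observed U.  Handles ties
    (0.5 credit), unlike the classical tie-free recursion.
    """
    u_obs = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    n = pooled.size
    n1 = x.size
    mu = n1 * (n - n1) / 2.0
    dev_obs = abs(u_obs - mu) - 1e-12
    hits = 0
    total = 0
    idx = np.arange(n)
    for chosen in combinations(idx, n1):
        mask = np.zeros(n, dtype=bool)
        mask[list(chosen)] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        if abs(u - mu) >= dev_obs:
            hits += 1
        total += 1
    return u_obs, hits / total


def mann_whitney_vs_rest(counts_by_type: Mapping[str, Sequence[float]],
                         cancer_type: str) -> DifferentiationResult:
    """Two-sided Mann-Whitney U of one type's counts against the pooled rest.

    Tests whether the type's driver-count distribution is representative of
    the distribution across all other cancer types pooled.  Uses exact
    enumeration of group assignments when the combined sample size is at most
    :data:`EXACT_ENUMERATION_MAX_N`, otherwise the normal approximation with
    tie and continuity corrections.
    """
    if cancer_type not in counts_by_type:
        raise ValidationError(f"unknown cancer type {cancer_type!r}")
    x = np.asarray(counts_by_type[cancer_type], dtype=float)
    rest_parts = [np.asarray(v, float) for k, v in counts_by_type.items() if k != cancer_type]
    if not rest_parts or sum(p.size for p in rest_parts) == 0:
        raise ValidationError("rest pool is empty; need at least one other cancer type")
    if x.size == 0:
        raise ValidationError(f"no samples for cancer type {cancer_type!r}")
    rest = np.concatenate(rest_parts)

    if x.size + rest.size <= EXACT_ENUMERATION_MAX_N:
        u, p = _exact_mannwhitney(x, rest)
        method = "exact"
    else:
        res = sps.mannwhitneyu(x, rest, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
        u, p = float(res.statistic), float(res.pvalue)
        method = "normal_approx"
    p = min(max(p, math.ulp(0.0)), 1.0)
    return DifferentiationResult(
        cancer_type=cancer_type, u_statistic=u, p_value=p,
        n_type=int(x.size), n_rest=int(rest.size), method=method,
    )


def counts_by_type(counts: pd.DataFrame, count_kind: str = "thresholded") -> dict[str, np.ndarray]:
    """Split a per-sample count table into {cancer_type: count array}."""
    col = _counts_column(count_kind)
    return {
        str(ctype): group[col].to_numpy(float)
        for ctype, group in counts.groupby("cancer_type", sort=True)
    }


def stratify_by_stage(counts: pd.DataFrame, count_kind: str = "thresholded"
                      ) -> list[StageSummary]:
    """Per-type, per-stage count statistics (n, mean, quartiles).

    Samples with unknown stage are excluded (tally logged); cancer types with
    no staged samples are omitted with a warning.  ``monotone_medians``
    records whether medians are non-decreasing across the observed stages.
    """
    col = _counts_column(count_kind)
    if counts is None or len(counts) == 0:
        raise ValidationError("counts table is empty")
    n_unknown = int(counts["stage"].isna().sum())
    if n_unknown:
        logger.info("stratify_by_stage: excluded %d samples with unknown stage", n_unknown)
    staged = counts[counts["stage"].notna()]
    summaries: list[StageSummary] = []
    for ctype, group in counts.groupby("cancer_type", sort=True):
        sub = staged[staged["cancer_type"] == ctype]
        if len(sub) == 0:
            logger.warning("stratify_by_stage: type %s has no staged samples; omitted", ctype)
            continue
        rows = []
        medians = []
        for stage in STAGES:
            vals = sub.loc[sub["stage"] == stage, col].to_numpy(float)
            vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                continue
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            rows.append(
                {"stage": stage, "n": int(vals.size), "mean": float(vals.mean()),
                 "q1": float(q1), "median": float(med), "q3": float(q3)}
            )
            medians.append(med)
        monotone = bool(np.all(np.diff(medians) >= 0)) if medians else True
        summaries.append(
            StageSummary(
                cancer_type=str(ctype),
                stages=pd.DataFrame(rows, columns=["stage", "n", "mean", "q1", "median", "q3"]),
                monotone_medians=monotone,
            )
        )
    return summaries


def stage_table(summaries: list[StageSummary]) -> pd.DataFrame:
    """Flatten stage summaries into one long table for writing."""
    frames = []
    for s in summaries:
        df = s.stages.copy()
        df.insert(0, "cancer_type", s.cancer_type)
        df["monotone_medians"] = s.monotone_medians
        frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=["cancer_type", "stage", "n", "mean", "q1", "median", "q3", "monotone_medians"]
        )
    return pd.concat(frames, ignore_index=True)
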