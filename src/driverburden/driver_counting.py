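"""Per-sample SNV-driver counts: thresholded, posterior-weighted, hypermutation filter.

Two estimators of the tumour driver burden (TDB) of a sample:

* ``count_thresholded`` — the number of variants at or above a score
  threshold (typically the FDR-calibrated one),
* ``count_weighted`` — a threshold-independent estimate summing, over
  variants in score bins whose driver posterior exceeds 0.5, the posterior
  margin ``2*p_hat_b - 1``; equivalently the expected number of true
  positives minus expected false positives among eligible calls.

Samples whose applicable count exceeds ``hypermutation_max`` (default 500)
are flagged hypermutant and excluded from cohort statistics.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ValidationError
from .score_calibration import ScoreHistogram, weighted_contributions

logger = logging.getLogger(__name__)

#: Columns of a per-sample driver-count table.
COUNT_COLUMNS = (
    "sample_id",
    "cancer_type",
    "stage",
    "region",
    "n_variants",
    "count_thresholded",
    "count_weighted",
    "hypermutant",
    "threshold_used",
)


def _check_single_sample_region(records: pd.DataFrame) -> None:
    if len(records) == 0:
        return
    if records["sample_id"].nunique() > 1:
        raise ValidationError("records span multiple samples; count one sample at a time")
    if records["region"].nunique() > 1:
        raise ValidationError("records span multiple regions; count one region at a time")


def count_thresholded(records: pd.DataFrame, threshold: float) -> int:
    """Number of one sample's variants with score >= threshold (inclusive)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError(f"threshold {threshold} outside [0, 1]")
    _check_single_sample_region(records)
    if len(records) == 0:
        return 0
    return int((records["p_score"].to_numpy(float) >= threshold).sum())


def count_weighted(records: pd.DataFrame, hist: ScoreHistogram) -> float:
    """Threshold-independent weighted driver count for one sample.

    Each variant whose score lands in a bin with posterior > 0.5 contributes
    ``2*p_hat_b - 1``; others contribute nothing.  The result lies in
    ``[0, n_variants]``.
    """
    _check_single_sample_region(records)
    if len(records) == 0:
        return 0.0
    if hist.region is not None:
        regions = records["region"].unique()
        if len(regions) and regions[0] != hist.region:
            raise ValidationError(
                f"records are {regions[0]!r} but histogram was calibrated for {hist.region!r}"
            )
    return float(weighted_contributions(records["p_score"].to_numpy(float), hist).sum())


def count_cohort(cohort: pd.DataFrame, threshold: float | None = None,
                 hist: ScoreHistogram | None = None,
                 hypermutation_max: int = 500,
                 region: str | None = None) -> pd.DataFrame:
    """Per-sample driver counts for a whole cohort table.

    At least one of ``threshold`` / ``hist`` must be given; the respective
    count column is NaN when the corresponding rule was not applied.  The
    hypermutant flag is set from the thresholded count when a threshold was
    applied (the filter precedes all reported statistics and the thresholded
    count is the one available at that point in the pipeline), otherwise from
    the weighted count.
    """
    if threshold is None and hist is None:
        raise ValidationError("provide a threshold, a calibrated histogram, or both")
    df = cohort
    if region is not None:
        df = df[df["region"] == region]
    if len(df) == 0:
        return pd.DataFrame(columns=list(COUNT_COLUMNS))

    scores = df["p_score"].to_numpy(float)
    work = df.loc[:, ["sample_id", "cancer_type", "stage", "region"]].copy()
    if threshold is not None:
        if not 0.0 <= threshold <= 1.0:
            raise ValidationError(f"threshold {threshold} outside [0, 1]")
        work["_thr"] = (scores >= threshold).astype(int)
    if hist is not None:
        work["_wgt"] = weighted_contributions(scores, hist)

    grouped = work.groupby("sample_id", sort=True)
    out = grouped.agg(
        cancer_type=("cancer_type", "first"),
        stage=("stage", "first"),
        region=("region", "first"),
        n_variants=("region", "size"),
    )
    out["count_thresholded"] = grouped["_thr"].sum() if threshold is not None else np.nan
    out["count_weighted"] = grouped["_wgt"].sum() if hist is not None else np.nan
    applicable = out["count_thresholded"] if threshold is not None else out["count_weighted"]
    out["hypermutant"] = applicable > hypermutation_max
    out["threshold_used"] = threshold if threshold is not None else np.nan
    out = out.reset_index()
    return out.loc[:, list(COUNT_COLUMNS)]


def applicable_count(counts: pd.DataFrame) -> pd.Series:
    """The count the hypermutation rule applies to: thresholded when present."""
    thr = counts["count_thresholded"]
    if thr.notna().all():
        return thr
    return thr.where(thr.notna(), counts["count_weighted"])


def apply_hypermutation_filter(counts: pd.DataFrame, hypermutation_max: int = 500
                               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition per-sample counts into retained and excluded hypermutants.

    A sample is excluded when its applicable count strictly exceeds
    ``hypermutation_max`` ("more than 500 drivers"); a sample at exactly the
    maximum is retained.
    """
    if hypermutation_max < 0:
        raise ValidationError("hypermutation_max must be non-negative")
    mask = applicable_count(counts) > hypermutation_max
    counts = counts.copy()
    counts["hypermutant"] = mask.to_numpy()
    excluded = counts[mask]
    retained = counts[~mask]
    if len(excluded):
        logger.info(
            "hypermutation filter: excluded %d of %d samples (count > %d)",
            len(excluded), len(counts), hypermutation_max,
        )
    return retained, excluded
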