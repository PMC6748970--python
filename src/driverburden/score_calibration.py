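"""FDR calibration of a driver/neutral score threshold from balanced labelled scores.

The upstream classifier emits a Platt-scaled confidence (the *p-score*) in
[0, 1] for each variant, 1 being maximal confidence that the variant is a
driver.  Given a balanced labelled test set of such scores, this module

* bins the class-conditional score distributions into a
  :class:`ScoreHistogram` (default bin width 0.01),
* estimates the per-bin posterior probability ``p_hat_b`` that a variant
  whose score falls in bin *b* is truly a driver — under 50:50 class balance
  the in-bin proportion of driver-labelled examples is exactly that
  posterior,
* computes an empirical FDR-versus-threshold curve from the raw labelled
  scores (exact tail counts, not re-binned), and
* selects the smallest threshold that *sustains* a target FDR (default 5%),
  i.e. keeps the empirical FDR at or below target at every larger threshold
  where it is defined.  Empirical FDR curves need not be monotone; the
  sustained rule is conservative and deterministic.

A separate line-search, :func:`fit_threshold_to_gene_reference`, fits the
threshold to external per-gene driver counts (e.g. from a dN/dS-style
comparator) by minimising absolute or squared count differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .cohort_io import check_balance
from .errors import CalibrationStateError, ValidationError

logger = logging.getLogger(__name__)

SMOOTHINGS = ("none", "add_one", "add_one_isotonic")


@dataclass
class ScoreHistogram:
    """Binned class-conditional score counts with optional per-bin posteriors.

    Bins are half-open ``[k*w, (k+1)*w)``; the final bin is closed at 1 so a
    score of exactly 1.0 is counted.
    """

    bin_width: float
    bin_edges: np.ndarray
    pos_counts: np.ndarray
    neg_counts: np.ndarray
    region: str | None = None
    posterior: np.ndarray | None = None
    smoothing: str | None = None

    @property
    def n_bins(self) -> int:
        return len(self.pos_counts)

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    def bin_index(self, scores) -> np.ndarray:
        """Bin index for each score; exactly 1.0 maps into the last bin."""
        scores = np.asarray(scores, dtype=float)
        if scores.size and (scores.min() < 0 or scores.max() > 1):
            raise ValidationError("scores outside [0, 1]")
        idx = np.floor(scores / self.bin_width).astype(int)
        return np.minimum(idx, self.n_bins - 1)

    def bin_interval(self, b: int) -> tuple[float, float]:
        return float(self.bin_edges[b]), float(self.bin_edges[b + 1])


@dataclass
class FdrCurve:
    """Empirical false discovery rate on a threshold grid.

    ``fdr[i] = fp[i] / (tp[i] + fp[i])`` where ``tp``/``fp`` count labelled
    driver/neutral calibration scores at or above ``thresholds[i]``;
    undefined (no scores pass) entries are NaN.
    """

    thresholds: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    fdr: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "tp": self.tp, "fp": self.fp, "fdr": self.fdr}
        )


def _scores_by_label(calibration: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    pos = calibration.loc[calibration["label"] == "driver", "p_score"].to_numpy(float)
    neg = calibration.loc[calibration["label"] == "neutral", "p_score"].to_numpy(float)
    return pos, neg


def build_histogram(calibration: pd.DataFrame, bin_width: float = 0.01,
                    region: str | None = None) -> ScoreHistogram:
    """Bin a labelled calibration set into class-conditional score counts.

    ``bin_width`` must divide 1.0 into an integer number of bins (100 bins at
    the default 0.01).  Posteriors are not yet estimated; see
    :func:`estimate_posteriors`.
    """
    if calibration is None or len(calibration) == 0:
        raise ValidationError("calibration set is empty")
    n_bins_f = 1.0 / bin_width
    n_bins = int(round(n_bins_f))
    if abs(n_bins - n_bins_f) > 1e-9 or n_bins < 1:
        raise ValidationError(f"bin_width {bin_width} does not divide 1.0 into integer bins")
    if region is not None:
        calibration = calibration[calibration["region"] == region]
        if len(calibration) == 0:
            raise ValidationError(f"calibration set has no rows for region {region!r}")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    pos, neg = _scores_by_label(calibration)
    idx_pos = np.minimum(np.floor(pos / bin_width).astype(int), n_bins - 1)
    idx_neg = np.minimum(np.floor(neg / bin_width).astype(int), n_bins - 1)
    pos_counts = np.bincount(idx_pos, minlength=n_bins)
    neg_counts = np.bincount(idx_neg, minlength=n_bins)
    return ScoreHistogram(
        bin_width=bin_width,
        bin_edges=edges,
        pos_counts=pos_counts,
        neg_counts=neg_counts,
        region=region,
    )


def estimate_posteriors(hist: ScoreHistogram, smoothing: str = "add_one_isotonic") -> ScoreHistogram:
    """Estimate the per-bin posterior p(driver | predicted score in bin).

    ``none``
        raw in-bin proportion ``pos / (pos + neg)``; empty bins are NaN
        (undefined) and any later use of such a bin is an error.
    ``add_one``
        Laplace-smoothed ``(pos + 1) / (pos + neg + 2)``.
    ``add_one_isotonic``
        add-one followed by pool-adjacent-violators so the posterior is
        non-decreasing with score, matching the monotone meaning of a
        Platt-scaled confidence.  Bins are weighted by their smoothed
        occupancy ``pos + neg + 2``.
    """
    if smoothing not in SMOOTHINGS:
        raise ValidationError(f"unknown smoothing {smoothing!r}")
    pos = hist.pos_counts.astype(float)
    neg = hist.neg_counts.astype(float)
    total = pos + neg
    if smoothing == "none":
        with np.errstate(invalid="ignore", divide="ignore"):
            posterior = np.where(total > 0, pos / np.where(total > 0, total, 1.0), np.nan)
    else:
        posterior = (pos + 1.0) / (total + 2.0)
        if smoothing == "add_one_isotonic":
            iso = IsotonicRegression(y_min=0.0, y_max=1.0, increasing=True)
            posterior = iso.fit_transform(
                hist.bin_centers, posterior, sample_weight=total + 2.0
            )
    return replace(hist, posterior=np.asarray(posterior, float), smoothing=smoothing)


def fdr_curve(calibration: pd.DataFrame, thresholds: Sequence[float],
              balance_tolerance: float = 0.05, allow_imbalance: bool = False) -> FdrCurve:
    """Empirical FDR at each grid threshold from raw labelled scores.

    At threshold ``t``: ``tp`` = driver-labelled scores >= t, ``fp`` =
    neutral-labelled scores >= t, ``fdr = fp/(tp+fp)`` (NaN when no score
    passes).  The FDR estimate is only a valid proxy on balanced data, so
    balance is enforced as in :func:`driverburden.cohort_io.check_balance`.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ValidationError("threshold grid is empty")
    if np.any(np.diff(thresholds) <= 0):
        raise ValidationError("threshold grid must be strictly increasing")
    check_balance(calibration, tolerance=balance_tolerance, allow_imbalance=allow_imbalance)
    pos, neg = _scores_by_label(calibration)
    pos_sorted = np.sort(pos)
    neg_sorted = np.sort(neg)
    tp = pos.size - np.searchsorted(pos_sorted, thresholds, side="left")
    fp = neg.size - np.searchsorted(neg_sorted, thresholds, side="left")
    called = tp + fp
    with np.errstate(invalid="ignore", divide="ignore"):
        fdr = np.where(called > 0, fp / np.where(called > 0, called, 1), np.nan)
    return FdrCurve(thresholds=thresholds, tp=tp.astype(int), fp=fp.astype(int), fdr=fdr)


def select_threshold(curve: FdrCurve, target_fdr: float) -> float | None:
    """Smallest grid threshold that sustains the target FDR.

    Returns the smallest ``t`` on the grid such that every larger-or-equal
    grid threshold with a defined FDR has ``fdr <= target_fdr``, requiring
    at least one defined FDR at or above ``t`` — a region of the grid where
    nothing is called is no evidence of control.  Returns ``None`` when no
    grid threshold achieves sustained control.
    """
    if not 0.0 < target_fdr < 1.0:
        raise ValidationError(f"target_fdr must be in (0,1), got {target_fdr}")
    defined = ~np.isnan(curve.fdr)
    ok = ~defined | (curve.fdr <= target_fdr)
    # sustained[i] == all(ok[i:]) and any(defined[i:])
    sustained = np.logical_and.accumulate(ok[::-1])[::-1]
    sustained &= np.logical_or.accumulate(defined[::-1])[::-1]
    if not sustained.any():
        logger.warning("select_threshold: no grid threshold sustains FDR <= %g", target_fdr)
        return None
    return float(curve.thresholds[int(np.argmax(sustained))])


def fit_threshold_to_gene_reference(cohort: pd.DataFrame,
                                    reference: Mapping[str, float],
                                    grid: Sequence[float],
                                    loss: str = "absolute") -> float:
    """One-dimensional line search for the threshold matching per-gene counts.

    For each grid threshold ``t`` the predicted count for gene ``g`` is the
    number of cohort records annotated to ``g`` with score >= t; the returned
    threshold minimises the summed absolute (or squared) differences to the
    external ``reference`` counts.  Ties are broken toward the larger
    threshold (the more conservative call set).
    """
    if loss not in ("absolute", "squared"):
        raise ValidationError(f"unknown loss {loss!r}")
    if not reference:
        raise ValidationError("reference gene counts are empty")
    genes = cohort["gene"]
    if genes.isna().all():
        raise ValidationError("cohort has no gene annotations")
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValidationError("threshold grid is empty")

    # per-gene sorted scores -> counts at every grid point via searchsorted
    ref_genes = list(reference)
    predicted = np.zeros((len(ref_genes), grid.size))
    for i, g in enumerate(ref_genes):
        scores = np.sort(cohort.loc[genes == g, "p_score"].to_numpy(float))
        predicted[i] = scores.size - np.searchsorted(scores, grid, side="left")
    residual = predicted - np.asarray([reference[g] for g in ref_genes], float)[:, None]
    objective = (
        np.abs(residual).sum(axis=0) if loss == "absolute" else (residual ** 2).sum(axis=0)
    )
    best = 0
    for j in range(1, grid.size):  # ties toward the larger threshold
        if objective[j] <= objective[best]:
            best = j
    return float(grid[best])


def calibrate(calibration: pd.DataFrame, target_fdr: float = 0.05,
              bin_width: float = 0.01, smoothing: str = "add_one_isotonic",
              thresholds: Sequence[float] | None = None,
              region: str | None = None) -> tuple[ScoreHistogram, FdrCurve, float | None]:
    """Convenience wrapper: histogram + posteriors, FDR curve, and threshold."""
    if region is not None:
        calibration = calibration[calibration["region"] == region]
    if thresholds is None:
        thresholds = np.round(np.arange(101) / 100.0, 2)
    hist = estimate_posteriors(build_histogram(calibration, bin_width=bin_width), smoothing)
    hist = replace(hist, region=region)
    curve = fdr_curve(calibration, thresholds)
    threshold = select_threshold(curve, target_fdr)
    return hist, curve, threshold


def weighted_contributions(scores, hist: ScoreHistogram) -> np.ndarray:
    """Per-variant contribution ``2*p_hat_b - 1`` for eligible bins, else 0.

    A variant whose score falls in bin *b* is eligible when the bin posterior
    ``p_hat_b`` exceeds 0.5 — the classifier is then more likely right than
    wrong about a driver call — and contributes the posterior margin
    ``p_hat_b - (1 - p_hat_b)``, its expected true-positive minus
    false-positive weight.
    """
    if hist.posterior is None:
        raise CalibrationStateError("histogram posteriors have not been estimated")
    idx = hist.bin_index(scores)
    post = hist.posterior[idx]
    if np.isnan(post).any():
        b = int(idx[np.isnan(post)][0])
        lo, hi = hist.bin_interval(b)
        raise CalibrationStateError(
            f"score falls in bin {b} [{lo:.4g}, {hi:.4g}) with undefined posterior "
            "(empty calibration bin under smoothing='none')"
        )
    return np.where(post > 0.5, 2.0 * post - 1.0, 0.0)
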