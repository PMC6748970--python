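"""Scikit-learn-style estimators wrapping the calibrate-then-count pipeline.

:class:`FdrThresholdClassifier` fits a score threshold controlling a target
false discovery rate on balanced labelled calibration scores and predicts
driver/neutral labels for new variant scores.  :class:`DriverBurdenEstimator`
composes calibration with per-sample counting: fitted on a calibration
table, it transforms a cohort prediction table into per-sample driver
counts.  Both follow sklearn conventions (``get_params``/``set_params``,
fitted attributes with a trailing underscore) and compose with sklearn
model-selection utilities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .cohort_io import LABEL_ALIASES
from .driver_counting import apply_hypermutation_filter, count_cohort
from .errors import FdrNotAchievableError, ValidationError
from .score_calibration import (
    build_histogram,
    estimate_posteriors,
    fdr_curve,
    select_threshold,
    weighted_contributions,
)


def _as_scores(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2 and X.shape[1] == 1:
        X = X[:, 0]
    if X.ndim != 1:
        raise ValidationError("expected a 1-d array of p-scores (or a single column)")
    if X.size and (X.min() < 0 or X.max() > 1):
        raise ValidationError("p-scores must lie in [0, 1]")
    return X


def _as_labels(y) -> np.ndarray:
    out = []
    for v in np.asarray(y).ravel():
        if isinstance(v, (int, np.integer, float, np.floating)):
            token = "+1" if v > 0 else "-1"
        else:
            token = str(v)
        label = LABEL_ALIASES.get(token)
        if label is None:
            raise ValidationError(f"unknown label {v!r}")
        out.append(label)
    return np.asarray(out, dtype=object)


class FdrThresholdClassifier(BaseEstimator):
    """Driver/neutral variant caller at an FDR-calibrated score threshold.

    Parameters
    ----------
    target_fdr : float, default 0.05
        False discovery rate the fitted threshold must sustain.
    bin_width : float, default 0.01
        Score-histogram bin width for posterior estimation.
    smoothing : {"none", "add_one", "add_one_isotonic"}
        Per-bin posterior smoothing rule.
    threshold_grid : array-like or None
        Candidate thresholds; default 0.00..1.00 in steps of 0.01.
    balance_tolerance : float, default 0.05
        Maximum tolerated calibration class imbalance.

    Attributes
    ----------
    threshold_ : float
        Smallest grid threshold sustaining the target FDR.
    histogram_ : ScoreHistogram
        Class-conditional score histogram with estimated posteriors.
    fdr_curve_ : FdrCurve
        Empirical FDR across the grid.
    classes_ : ndarray
        ``[-1, 1]`` (neutral, driver).
    """

    def __init__(self, target_fdr: float = 0.05, bin_width: float = 0.01,
                 smoothing: str = "add_one_isotonic", threshold_grid=None,
                 balance_tolerance: float = 0.05, allow_imbalance: bool = False):
        self.target_fdr = target_fdr
        self.bin_width = bin_width
        self.smoothing = smoothing
        self.threshold_grid = threshold_grid
        self.balance_tolerance = balance_tolerance
        self.allow_imbalance = allow_imbalance

    def fit(self, X, y):
        scores = _as_scores(X)
        labels = _as_labels(y)
        if scores.size != labels.size:
            raise ValidationError("X and y have different lengths")
        calibration = pd.DataFrame({"p_score": scores, "label": labels, "region": "coding"})
        grid = (np.round(np.arange(101) / 100.0, 2) if self.threshold_grid is None
                else np.asarray(self.threshold_grid, float))
        hist = build_histogram(calibration, bin_width=self.bin_width)
        self.histogram_ = estimate_posteriors(hist, smoothing=self.smoothing)
        self.fdr_curve_ = fdr_curve(calibration, grid,
                                    balance_tolerance=self.balance_tolerance,
                                    allow_imbalance=self.allow_imbalance)
        threshold = select_threshold(self.fdr_curve_, self.target_fdr)
        if threshold is None:
            raise FdrNotAchievableError(
                f"no grid threshold sustains FDR <= {self.target_fdr}"
            )
        self.threshold_ = threshold
        self.classes_ = np.array([-1, 1])
        return self

    def decision_function(self, X):
        check_is_fitted(self, "threshold_")
        return _as_scores(X) - self.threshold_

    def predict(self, X):
        """+1 (driver) for scores at or above the fitted threshold, else -1."""
        return np.where(self.decision_function(X) >= 0, 1, -1)

    def variant_weights(self, X):
        """Posterior-margin weight ``2*p_hat - 1`` of each score's bin
        (zero for ineligible bins) — the threshold-independent per-variant
        contribution to the weighted driver count."""
        check_is_fitted(self, "histogram_")
        return weighted_contributions(_as_scores(X), self.histogram_)

    def score(self, X, y):
        """Balanced accuracy of driver/neutral calls at the fitted threshold."""
        y_true = np.where(_as_labels(y) == "driver", 1, -1)
        y_pred = self.predict(X)
        accs = [np.mean(y_pred[y_true == c] == c) for c in (-1, 1) if np.any(y_true == c)]
        return float(np.mean(accs))


class DriverBurdenEstimator(BaseEstimator, TransformerMixin):
    """Per-sample tumour driver burden from a cohort prediction table.

    ``fit`` takes calibration scores and labels (as
    :class:`FdrThresholdClassifier`); ``transform`` maps a cohort prediction
    DataFrame to a per-sample count table with thresholded and weighted
    counts plus the hypermutant flag.

    Parameters
    ----------
    threshold : float or None
        Fixed threshold overriding FDR calibration (None = calibrate).
    filter_hypermutants : bool, default True
        Drop samples whose count exceeds ``hypermutation_max`` from the
        transformed output.
    """

    def __init__(self, target_fdr: float = 0.05, bin_width: float = 0.01,
                 smoothing: str = "add_one_isotonic", threshold: float | None = None,
                 hypermutation_max: int = 500, filter_hypermutants: bool = True,
                 region: str | None = None):
        self.target_fdr = target_fdr
        self.bin_width = bin_width
        self.smoothing = smoothing
        self.threshold = threshold
        self.hypermutation_max = hypermutation_max
        self.filter_hypermutants = filter_hypermutants
        self.region = region

    def fit(self, X, y):
        calibrator = FdrThresholdClassifier(
            target_fdr=self.target_fdr, bin_width=self.bin_width, smoothing=self.smoothing
        ).fit(X, y)
        self.calibrator_ = calibrator
        self.threshold_ = self.threshold if self.threshold is not None else calibrator.threshold_
        self.histogram_ = calibrator.histogram_
        return self

    def transform(self, cohort: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "threshold_")
        counts = count_cohort(
            cohort, threshold=self.threshold_, hist=self.histogram_,
            hypermutation_max=self.hypermutation_max, region=self.region,
        )
        if self.filter_hypermutants:
            counts, self.excluded_ = apply_hypermutation_filter(counts, self.hypermutation_max)
        else:
            self.excluded_ = counts.iloc[0:0]
        return counts
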