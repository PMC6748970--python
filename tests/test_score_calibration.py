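"""Histogram binning, posterior estimation, FDR curve and threshold selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from driverburden import (
    ValidationError,
    build_histogram,
    estimate_posteriors,
    fdr_curve,
    fit_threshold_to_gene_reference,
    select_threshold,
)
from driverburden.score_calibration import weighted_contributions

from conftest import make_calibration, make_histogram, make_predictions


class TestBuildHistogram:
    def test_default_bin_width_gives_100_bins(self):
        hist = build_histogram(make_calibration([0.5], [0.5]), bin_width=0.01)
        assert hist.n_bins == 100
        assert hist.bin_edges[0] == 0.0 and hist.bin_edges[-1] == 1.0

    def test_half_open_binning_by_hand(self):
        hist = build_histogram(make_calibration([0.905, 0.915], [0.905]), bin_width=0.01)
        assert hist.pos_counts[90] == 1 and hist.neg_counts[90] == 1  # [0.90, 0.91)
        assert hist.pos_counts[91] == 1 and hist.neg_counts[91] == 0  # [0.91, 0.92)

    def test_score_of_exactly_one_falls_in_last_bin(self):
        hist = build_histogram(make_calibration([1.0], [0.0]), bin_width=0.01)
        assert hist.pos_counts[99] == 1

    def test_counts_conserve_class_totals(self):
        rng = np.random.default_rng(0)
        calib = make_calibration(rng.random(137), rng.random(141))
        hist = build_histogram(calib, bin_width=0.05)
        assert hist.pos_counts.sum() == 137 and hist.neg_counts.sum() == 141

    def test_empty_calibration_rejected(self):
        with pytest.raises(ValidationError):
            build_histogram(make_calibration([], []))

    def test_bin_width_must_divide_one(self):
        with pytest.raises(ValidationError):
            build_histogram(make_calibration([0.5], [0.5]), bin_width=0.03)


class TestEstimatePosteriors:
    def test_raw_proportion(self):
        hist = build_histogram(
            make_calibration([0.55] * 9, [0.55] * 1 + [0.1] * 8), bin_width=0.1
        )
        out = estimate_posteriors(hist, smoothing="none")
        assert out.posterior[5] == pytest.approx(0.9)

    def test_add_one_formula(self):
        hist = build_histogram(
            make_calibration([0.55] * 9, [0.55] * 1 + [0.1] * 8), bin_width=0.1
        )
        out = estimate_posteriors(hist, smoothing="add_one")
        assert out.posterior[5] == pytest.approx(10 / 12)

    def test_empty_bin_is_nan_with_no_smoothing(self):
        hist = build_histogram(make_calibration([0.95], [0.05]), bin_width=0.25)
        out = estimate_posteriors(hist, smoothing="none")
        assert np.isnan(out.posterior[1]) and np.isnan(out.posterior[2])

    def test_pool_adjacent_violators_merges_descending_bins(self):
        # add-one posteriors [0.2, 0.8, 0.5] with equal bin weights:
        # (pos, neg) = (1,7), (7,1), (4,4) in three equal-width bins
        calib = make_calibration(
            [0.1] * 1 + [0.5] * 7 + [0.9] * 4,
            [0.1] * 7 + [0.5] * 1 + [0.9] * 4,
        )
        hist = build_histogram(calib, bin_width=1 / 3)
        out = estimate_posteriors(hist, smoothing="add_one_isotonic")
        np.testing.assert_allclose(out.posterior, [0.2, 0.65, 0.65])

    def test_isotonic_posterior_is_non_decreasing(self):
        rng = np.random.default_rng(3)
        calib = make_calibration(rng.beta(8, 2, 2000), rng.beta(2, 8, 2000))
        out = estimate_posteriors(build_histogram(calib, 0.01), "add_one_isotonic")
        assert np.all(np.diff(out.posterior) >= -1e-12)
        assert np.all((out.posterior >= 0) & (out.posterior <= 1))


DRIVERS = [0.9, 0.8, 0.6]
NEUTRALS = [0.1, 0.2, 0.7]


class TestFdrCurve:
    def test_hand_counted_examples(self):
        curve = fdr_curve(make_calibration(DRIVERS, NEUTRALS), [0.0, 0.5, 0.75])
        assert curve.tp.tolist() == [3, 3, 2]
        assert curve.fp.tolist() == [3, 1, 0]
        np.testing.assert_allclose(curve.fdr, [0.5, 0.25, 0.0])

    def test_threshold_zero_on_balanced_set_gives_half(self):
        rng = np.random.default_rng(1)
        curve = fdr_curve(make_calibration(rng.random(50), rng.random(50)), [0.0])
        assert curve.fdr[0] == pytest.approx(0.5)

    def test_undefined_fdr_is_nan(self):
        curve = fdr_curve(make_calibration([0.4], [0.3]), [0.35, 0.9])
        assert curve.fdr[0] == 0.0 and np.isnan(curve.fdr[1])

    def test_empty_grid_rejected(self):
        with pytest.raises(ValidationError):
            fdr_curve(make_calibration(DRIVERS, NEUTRALS), [])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1, width=32), min_size=1, max_size=40))
    def test_tail_counts_monotone_non_increasing(self, scores):
        calib = make_calibration(scores, scores)  # balanced by construction
        curve = fdr_curve(calib, np.linspace(0, 1, 21))
        assert np.all(np.diff(curve.tp) <= 0)
        assert np.all(np.diff(curve.fp) <= 0)


class TestSelectThreshold:
    def test_sustained_control_rule(self):
        curve = fdr_curve(make_calibration(DRIVERS, NEUTRALS), [0.0, 0.5, 0.75])
        assert select_threshold(curve, 0.05) == 0.75

    def test_degenerates_to_minimum_when_all_controlled(self):
        curve = fdr_curve(make_calibration([0.9, 0.8], [0.1, 0.2]), [0.3, 0.5, 0.7])
        assert select_threshold(curve, 0.05) == 0.3

    def test_identical_class_distributions_not_achievable(self):
        rng = np.random.default_rng(5)
        scores = rng.random(2000)
        curve = fdr_curve(make_calibration(scores, scores), np.round(np.arange(101) / 100, 2))
        assert select_threshold(curve, 0.05) is None


class TestFitThresholdToGeneReference:
    @staticmethod
    def _cohort(seed=11, n=2000):
        rng = np.random.default_rng(seed)
        genes = rng.choice(["KRAS", "TP53", "APC", "BRAF"], size=n)
        return make_predictions(
            [(s, f"S{i % 50}", "PACA", None, g)
             for i, (s, g) in enumerate(zip(rng.random(n), genes))]
        )

    @pytest.mark.parametrize("loss", ["absolute", "squared"])
    def test_recovers_generating_threshold(self, loss):
        cohort = self._cohort()
        reference = {
            g: int((cohort.loc[cohort["gene"] == g, "p_score"] >= 0.7).sum())
            for g in ["KRAS", "TP53", "APC", "BRAF"]
        }
        grid = np.round(np.arange(101) / 100, 2)
        assert fit_threshold_to_gene_reference(cohort, reference, grid, loss=loss) == 0.7

    def test_all_zero_reference_breaks_ties_to_largest_threshold(self):
        cohort = self._cohort()
        reference = {g: 0 for g in ["KRAS", "TP53", "APC", "BRAF"]}
        grid = np.round(np.arange(101) / 100, 2)
        assert fit_threshold_to_gene_reference(cohort, reference, grid) == 1.0

    def test_missing_gene_annotations_rejected(self):
        cohort = make_predictions([(0.9, "S1", "PACA", None, None)])
        with pytest.raises(ValidationError, match="gene"):
            fit_threshold_to_gene_reference(cohort, {"KRAS": 1}, [0.5])

    def test_empty_reference_rejected(self):
        with pytest.raises(ValidationError, match="reference"):
            fit_threshold_to_gene_reference(self._cohort(), {}, [0.5])


def test_weighted_contributions_eligibility_rule():
    hist = make_histogram([0.4, 0.55, 0.9, 1.0])
    out = weighted_contributions([0.1, 0.3, 0.6, 0.9], hist)
    np.testing.assert_allclose(out, [0.0, 0.1, 0.8, 1.0])
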