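"""Per-type summaries, threshold sweeps, Mann-Whitney differentiation, stage strata."""

import numpy as np
import pandas as pd
import pytest

from driverburden import (
    ClassScoreModel,
    ValidationError,
    counts_by_type,
    mann_whitney_vs_rest,
    simulate_cohort,
    stage_table,
    stratify_by_stage,
    summarize,
    sweep_thresholds,
)

from conftest import make_predictions, single_type_model


def counts_frame(values, ctype="THCA", stages=None, kind="thresholded"):
    n = len(values)
    return pd.DataFrame(
        {
            "sample_id": [f"{ctype}_{i}" for i in range(n)],
            "cancer_type": ctype,
            "stage": stages if stages is not None else [pd.NA] * n,
            "region": "coding",
            "n_variants": [int(v) + 5 for v in values],
            "count_thresholded": values if kind == "thresholded" else np.nan,
            "count_weighted": values if kind == "weighted" else np.nan,
            "hypermutant": False,
            "threshold_used": 0.88,
        }
    )


class TestSummarize:
    def test_hand_arithmetic(self):
        out = summarize(counts_frame([0, 1, 1, 2, 10]))
        row = out.iloc[0]
        assert row["mode"] == 1 and row["median"] == 1 and row["mean"] == pytest.approx(2.8)
        assert row["n_samples"] == 5

    def test_mode_tie_broken_to_smallest(self):
        assert summarize(counts_frame([1, 1, 2, 2])).iloc[0]["mode"] == 1

    def test_weighted_mode_uses_binned_midpoint(self):
        out = summarize(counts_frame([0.4, 1.2, 1.3], kind="weighted"),
                        count_kind="weighted", mode_bin_width=1.0)
        assert out.iloc[0]["mode"] == pytest.approx(1.5)  # bin [1,2) holds two

    def test_quartile_ordering_invariant(self):
        rng = np.random.default_rng(2)
        out = summarize(counts_frame(rng.poisson(6, 500)))
        row = out.iloc[0]
        assert row["q1"] <= row["median"] <= row["q3"]

    def test_multiple_types_sorted(self):
        counts = pd.concat(
            [counts_frame([1, 2, 3], "THCA"), counts_frame([5, 6, 7], "BLCA")],
            ignore_index=True,
        )
        out = summarize(counts)
        assert list(out["cancer_type"]) == ["BLCA", "THCA"]

    def test_empty_counts_rejected(self):
        with pytest.raises(ValidationError):
            summarize(counts_frame([]).iloc[0:0])


class TestSweepThresholds:
    @staticmethod
    def _cohort(seed=3, n_samples=20, ctypes=("THCA", "BLCA")):
        rng = np.random.default_rng(seed)
        rows = []
        for ctype in ctypes:
            for i in range(n_samples):
                for s in rng.random(rng.integers(1, 15)):
                    rows.append((s, f"{ctype}_{i}", ctype, None, None))
        return make_predictions(rows)

    def test_threshold_zero_recovers_n_variants_medians(self):
        cohort = self._cohort()
        sweep = sweep_thresholds(cohort, [0.0])
        per_type = cohort.groupby(["cancer_type", "sample_id"]).size()
        for rec in sweep.stats.itertuples():
            assert rec.median == np.median(per_type[rec.cancer_type].to_numpy())

    def test_threshold_one_with_all_scores_below_gives_zero(self):
        cohort = self._cohort()
        cohort["p_score"] = cohort["p_score"].clip(upper=0.99)
        sweep = sweep_thresholds(cohort, [1.0])
        assert (sweep.stats["median"] == 0).all()
        assert (sweep.stats["mean"] == 0).all()

    def test_per_type_mean_non_increasing_over_grid(self):
        cohort = self._cohort(seed=4)
        grid = np.round(np.linspace(0, 1, 21), 2)
        sweep = sweep_thresholds(cohort, grid)
        for _, group in sweep.stats.groupby("cancer_type"):
            means = group.sort_values("threshold")["mean"].to_numpy()
            assert np.all(np.diff(means) <= 1e-12)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValidationError):
            sweep_thresholds(self._cohort(), [])


class TestMannWhitneyVsRest:
    def test_exact_enumeration_hand_case(self):
        res = mann_whitney_vs_rest({"A": [1, 2], "B": [3, 4]}, "A")
        assert res.method == "exact"
        assert res.u_statistic == 0
        assert res.p_value == pytest.approx(2 / 6)

    def test_identical_multisets_give_p_one(self):
        res = mann_whitney_vs_rest({"A": [1, 2, 3], "B": [1, 2, 3]}, "A")
        assert res.method == "exact"
        assert res.p_value == 1.0

    def test_normal_approximation_close_to_exact_at_boundary(self):
        """Tie-free (6,6) cases: asymptotic p within 0.02 of exact enumeration."""
        rng = np.random.default_rng(6)
        for _ in range(10):
            x = rng.permutation(np.arange(12) + rng.random(12) * 0.1)
            a, b = x[:6], x[6:]
            from scipy import stats as sps

            exact = mann_whitney_vs_rest({"A": a, "B": b}, "A").p_value
            p_norm = sps.mannwhitneyu(a, b, alternative="two-sided",
                                      method="asymptotic").pvalue
            assert abs(exact - p_norm) < 0.02

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(7)
        res = mann_whitney_vs_rest(
            {"A": rng.poisson(1, 100), "B": rng.poisson(8, 100)}, "A"
        )
        assert res.method == "normal_approx"
        assert res.p_value < 1e-10
        assert 0 <= res.u_statistic <= res.n_type * res.n_rest

    def test_empty_rest_pool_rejected(self):
        with pytest.raises(ValidationError, match="rest"):
            mann_whitney_vs_rest({"A": [1, 2]}, "A")

    def test_counts_by_type_split(self):
        counts = pd.concat(
            [counts_frame([1, 2], "THCA"), counts_frame([5], "BLCA")], ignore_index=True
        )
        by_type = counts_by_type(counts)
        assert set(by_type) == {"THCA", "BLCA"}
        assert by_type["THCA"].tolist() == [1, 2]


class TestStratifyByStage:
    def test_linear_interpolation_quartiles(self):
        counts = counts_frame([1, 2, 3, 4], stages=["I"] * 4)
        summary = stratify_by_stage(counts)[0]
        row = summary.stages.iloc[0]
        assert row["mean"] == pytest.approx(2.5)
        assert row["q1"] == pytest.approx(1.75)
        assert row["median"] == pytest.approx(2.5)
        assert row["q3"] == pytest.approx(3.25)

    def test_monotone_medians_flag(self):
        values = [2, 2, 3, 3, 4, 4, 5, 5]
        stages = ["I", "I", "II", "II", "III", "III", "IV", "IV"]
        summary = stratify_by_stage(counts_frame(values, stages=stages))[0]
        assert summary.monotone_medians
        summary = stratify_by_stage(counts_frame(values[::-1], stages=stages))[0]
        assert not summary.monotone_medians

    def test_unstaged_samples_excluded_and_empty_result_warns(self, caplog):
        with caplog.at_level("WARNING"):
            out = stratify_by_stage(counts_frame([1, 2, 3]))
        assert out == []
        assert any("no staged samples" in m for m in caplog.messages)

    def test_absent_stages_omitted_not_zero_filled(self):
        counts = counts_frame([1, 2, 9, 9], stages=["I", "I", "III", "III"])
        summary = stratify_by_stage(counts)[0]
        assert list(summary.stages["stage"]) == ["I", "III"]

    def test_stage_table_flattens(self):
        counts = counts_frame([1, 2, 3, 4], stages=["I", "I", "II", "II"])
        table = stage_table(stratify_by_stage(counts))
        assert list(table["stage"]) == ["I", "II"]
        assert "monotone_medians" in table.columns


def test_point_mass_cohort_summary_matches_ground_truth(point_mass_model):
    """With perfectly separated scores the thresholded summary reproduces the
    generating distribution's per-type statistics exactly."""
    from driverburden import count_cohort

    model = single_type_model(2000, 4.0, 10.0, seed=1)
    records, truth = simulate_cohort(model, point_mass_model, seed=1)
    counts = count_cohort(records, threshold=0.5)
    out = summarize(counts)
    k = truth.samples["true_driver_count"]
    assert out.iloc[0]["mean"] == pytest.approx(k.mean())
    assert out.iloc[0]["median"] == np.median(k)
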