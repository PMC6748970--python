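import numpy as np
import pandas as pd
import pytest

from driverburden import (
    CancerTypeModel,
    ClassScoreModel,
    CohortModel,
    ScoreHistogram,
)
from driverburden.cohort_io import PREDICTION_COLUMNS


@pytest.fixture
def beta_score_model():
    """Well-separated but overlapping score classes: Beta(8,2) vs Beta(2,8)."""
    return ClassScoreModel()


@pytest.fixture
def point_mass_model():
    """Perfect separation: drivers score exactly 1.0, neutrals exactly 0.0."""
    return ClassScoreModel(point_mass_driver=1.0, point_mass_neutral=0.0)


def make_predictions(rows):
    """Build a cohort prediction table from
    (p_score, sample_id, cancer_type, stage, gene) tuples."""
    records = []
    for i, (p, sample, ctype, stage, gene) in enumerate(rows):
        records.append(
            ("1", i + 1, "A", "C", p, "coding", sample, ctype,
             stage if stage is not None else pd.NA,
             gene if gene is not None else pd.NA)
        )
    df = pd.DataFrame(records, columns=list(PREDICTION_COLUMNS))
    df["pos"] = df["pos"].astype("int64")
    df["p_score"] = df["p_score"].astype(float)
    return df


def make_calibration(driver_scores, neutral_scores, region="coding"):
    return pd.DataFrame(
        {
            "p_score": list(driver_scores) + list(neutral_scores),
            "label": ["driver"] * len(driver_scores) + ["neutral"] * len(neutral_scores),
            "region": region,
        }
    )


def make_histogram(posteriors, bin_width=None):
    """A ScoreHistogram with directly imposed per-bin posteriors."""
    posteriors = np.asarray(posteriors, dtype=float)
    n = posteriors.size
    if bin_width is None:
        bin_width = 1.0 / n
    return ScoreHistogram(
        bin_width=bin_width,
        bin_edges=np.linspace(0.0, 1.0, n + 1),
        pos_counts=np.zeros(n, dtype=int),
        neg_counts=np.zeros(n, dtype=int),
        posterior=posteriors,
        smoothing="none",
    )


def single_type_model(n_samples, driver_rate, passenger_rate, *, seed=0, **kw):
    """One-type cohort model with the default gene pools."""
    from driverburden.synthetic_cohort import default_driver_genes, default_passenger_genes

    kw.setdefault("driver_gene_weights", default_driver_genes())
    kw.setdefault("passenger_gene_pool", default_passenger_genes())
    return CohortModel(
        types={
            "TST": CancerTypeModel(
                n_samples=n_samples, driver_rate=driver_rate,
                passenger_rate=passenger_rate, **kw,
            )
        },
        seed=seed,
    )
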