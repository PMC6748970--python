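"""Synthetic tumour cohorts with known ground truth.

The generator emulates the statistical structure the burden analysis
assumes, not genomic realism:

* class-conditional p-scores — Beta distributions on [0, 1] (default
  Beta(8,2) for drivers vs Beta(2,8) for passengers), with optional
  point-mass overrides for exact-recovery scenarios,
* per-sample true driver counts — Poisson, or a two-component Poisson
  mixture emulating multi-modal ("neo-modal") populations,
* Poisson passenger counts, a hypermutant outlier fraction whose driver
  count is drawn above 500 (501 + Poisson(200) by default: only the cutoff
  is defined by the analysis, not the hypermutant distribution),
* planted high-incidence driver genes (a KRAS-like gene in a
  pancreatic-like type), and
* stage-dependent or stage-constant driver accumulation via per-stage
  multipliers on the driver rate.

Variant positions are synthesised as unique integers per sample; positions
play no computational role downstream.  :func:`expected_weighted_count_oracle`
provides an analytic expectation for the weighted count estimator, computed
by numerical integration of the known score model — an independent check of
the estimator, not part of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort_io import PREDICTION_COLUMNS, STAGES
from .errors import CalibrationStateError, ConfigurationError
from .score_calibration import ScoreHistogram

_NUC = np.array(list("ACGT"))


@dataclass
class ClassScoreModel:
    """Parametric class-conditional p-score distributions.

    Beta(a_pos, b_pos) for drivers and Beta(a_neg, b_neg) for neutral
    variants; a point-mass override per class replaces the Beta with a
    degenerate distribution at the given score (perfect-separation
    scenarios).
    """

    a_pos: float = 8.0
    b_pos: float = 2.0
    a_neg: float = 2.0
    b_neg: float = 8.0
    point_mass_driver: float | None = None
    point_mass_neutral: float | None = None

    def __post_init__(self) -> None:
        for name in ("a_pos", "b_pos", "a_neg", "b_neg"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"shape parameter {name} must be > 0")
        for name in ("point_mass_driver", "point_mass_neutral"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")

    def sample(self, label: str, n: int, rng: np.random.Generator) -> np.ndarray:
        if label == "driver":
            if self.point_mass_driver is not None:
                return np.full(n, self.point_mass_driver)
            return rng.beta(self.a_pos, self.b_pos, size=n)
        if label == "neutral":
            if self.point_mass_neutral is not None:
                return np.full(n, self.point_mass_neutral)
            return rng.beta(self.a_neg, self.b_neg, size=n)
        raise ValueError(f"unknown label {label!r}")

    def bin_probabilities(self, hist: ScoreHistogram, label: str) -> np.ndarray:
        """P(score in bin b) under the class distribution, per histogram bin."""
        if label == "driver":
            point, a, b = self.point_mass_driver, self.a_pos, self.b_pos
        elif label == "neutral":
            point, a, b = self.point_mass_neutral, self.a_neg, self.b_neg
        else:
            raise ValueError(f"unknown label {label!r}")
        if point is not None:
            probs = np.zeros(hist.n_bins)
            probs[int(hist.bin_index([point])[0])] = 1.0
            return probs
        cdf = sps.beta.cdf(hist.bin_edges, a, b)
        return np.diff(cdf)


@dataclass
class CancerTypeModel:
    """Generative model of one cancer type's samples.

    ``driver_rate`` / ``driver_rate_2`` with ``mixture_weight`` (probability
    of the first component) define a Poisson or two-component Poisson
    mixture for true driver counts; ``stage_multipliers`` scale the driver
    rate per stage before sampling (all 1.0 = stage-constant accumulation).
    ``stage_probs`` of None leaves every sample unstaged.
    """

    n_samples: int
    driver_rate: float = 4.0
    driver_rate_2: float | None = None
    mixture_weight: float = 1.0
    passenger_rate: float = 20.0
    stage_probs: tuple[float, float, float, float] | None = None
    stage_multipliers: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    hypermutant_fraction: float = 0.0
    hypermutant_rate: float = 200.0  # hypermutant count = 501 + Poisson(rate)
    driver_gene_weights: Mapping[str, float] = field(default_factory=dict)
    passenger_gene_pool: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ConfigurationError("n_samples must be >= 1")
        if self.driver_rate < 0 or self.passenger_rate < 0:
            raise ConfigurationError("rates must be non-negative")
        if self.driver_rate_2 is not None and self.driver_rate_2 < 0:
            raise ConfigurationError("driver_rate_2 must be non-negative")
        if not 0.0 <= self.mixture_weight <= 1.0:
            raise ConfigurationError("mixture_weight must lie in [0, 1]")
        if not 0.0 <= self.hypermutant_fraction < 1.0:
            raise ConfigurationError("hypermutant_fraction must lie in [0, 1)")
        if self.stage_probs is not None:
            p = np.asarray(self.stage_probs, float)
            if p.size != 4 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                raise ConfigurationError("stage_probs must be 4 non-negative values summing to 1")
        if any(w < 0 for w in self.driver_gene_weights.values()):
            raise ConfigurationError("driver gene weights must be non-negative")

    def mean_driver_count(self) -> float:
        """Analytic mean of the (non-hypermutant) driver-count mixture,
        averaged over the stage marginals and multipliers."""
        lam2 = self.driver_rate_2 if self.driver_rate_2 is not None else self.driver_rate
        base = self.mixture_weight * self.driver_rate + (1 - self.mixture_weight) * lam2
        if self.stage_probs is None:
            return base
        mult = float(np.dot(self.stage_probs, self.stage_multipliers))
        return base * mult


@dataclass
class CohortModel:
    """A cohort: one :class:`CancerTypeModel` per cancer type code."""

    types: Mapping[str, CancerTypeModel]
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.types:
            raise ConfigurationError("cohort model has no cancer types")


@dataclass
class GroundTruth:
    """Latent truth of a simulated cohort.

    ``samples``: one row per sample (including variant-free samples) with
    true_driver_count, n_passengers and the hypermutant flag.
    ``variant_is_driver``: boolean series aligned with the record table's
    index.  ``gene_incidence``: per (cancer_type, gene) fraction of samples
    with at least one true driver in the gene.
    """

    samples: pd.DataFrame
    variant_is_driver: pd.Series
    gene_incidence: pd.DataFrame

    def per_type_summary(self) -> pd.DataFrame:
        g = self.samples.groupby("cancer_type")["true_driver_count"]
        return g.agg(["mean", "median"]).reset_index()


def default_driver_genes() -> dict[str, float]:
    """Zipf-weighted placement over recurrent driver genes."""
    genes = ["KRAS", "TP53", "PIK3CA", "BRAF", "NRAS", "SMAD4", "APC", "IDH1", "EGFR", "PRKCA"]
    return {g: 1.0 / (i + 1) for i, g in enumerate(genes)}


def default_passenger_genes(n: int = 100) -> tuple[str, ...]:
    return ("TTN", "MUC16", "RYR2") + tuple(f"GENE{i:04d}" for i in range(n - 3))


def simulate_calibration_set(model: ClassScoreModel, n_per_class: int, seed: int,
                             region: str = "coding") -> pd.DataFrame:
    """An exactly 50:50 balanced labelled score set (n_per_class per class)."""
    if n_per_class < 1:
        raise ConfigurationError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    pos = model.sample("driver", n_per_class, rng)
    neg = model.sample("neutral", n_per_class, rng)
    return pd.DataFrame(
        {
            "p_score": np.concatenate([pos, neg]),
            "label": ["driver"] * n_per_class + ["neutral"] * n_per_class,
            "region": region,
        }
    )


def _simulate_type(ctype: str, tm: CancerTypeModel, score_model: ClassScoreModel,
                   rng: np.random.Generator, region: str):
    n = tm.n_samples
    sample_ids = np.array([f"{ctype}_S{i:05d}" for i in range(n)])

    if tm.stage_probs is None:
        stages = np.full(n, None, dtype=object)
        mult = np.ones(n)
    else:
        stage_idx = rng.choice(4, size=n, p=np.asarray(tm.stage_probs, float))
        stages = np.array(STAGES, dtype=object)[stage_idx]
        mult = np.asarray(tm.stage_multipliers, float)[stage_idx]

    lam2 = tm.driver_rate_2 if tm.driver_rate_2 is not None else tm.driver_rate
    comp1 = rng.random(n) < tm.mixture_weight
    lam = np.where(comp1, tm.driver_rate, lam2) * mult
    k_drivers = rng.poisson(lam)
    hyper = rng.random(n) < tm.hypermutant_fraction
    n_hyper = int(hyper.sum())
    if n_hyper:
        k_drivers[hyper] = 501 + rng.poisson(tm.hypermutant_rate, n_hyper)
    m_passengers = rng.poisson(tm.passenger_rate, n)

    total_drivers = int(k_drivers.sum())
    total_passengers = int(m_passengers.sum())
    if total_drivers and not tm.driver_gene_weights:
        raise ConfigurationError(f"type {ctype}: drivers drawn but driver_gene_weights is empty")
    if total_passengers and not tm.passenger_gene_pool:
        raise ConfigurationError(f"type {ctype}: passengers drawn but passenger_gene_pool is empty")

    # sample-major assembly: per sample, drivers first then passengers
    totals = k_drivers + m_passengers
    n_var = int(totals.sum())
    sidx = np.repeat(np.arange(n), totals)
    offsets = np.cumsum(totals) - totals
    within = np.arange(n_var) - np.repeat(offsets, totals)
    is_driver = within < k_drivers[sidx]

    scores = np.empty(n_var)
    genes = np.empty(n_var, dtype=object)
    scores[is_driver] = score_model.sample("driver", total_drivers, rng)
    scores[~is_driver] = score_model.sample("neutral", total_passengers, rng)
    if total_drivers:
        dg = list(tm.driver_gene_weights)
        w = np.asarray([tm.driver_gene_weights[g] for g in dg], float)
        genes[is_driver] = rng.choice(np.asarray(dg, dtype=object), size=total_drivers,
                                      p=w / w.sum())
    if total_passengers:
        genes[~is_driver] = rng.choice(np.asarray(tm.passenger_gene_pool, dtype=object),
                                       size=total_passengers)

    ref_idx = rng.integers(0, 4, n_var)
    alt_idx = (ref_idx + rng.integers(1, 4, n_var)) % 4
    records = pd.DataFrame(
        {
            "chrom": rng.integers(1, 23, n_var).astype(str),
            "pos": within + 1,  # unique per sample by construction
            "ref": _NUC[ref_idx],
            "alt": _NUC[alt_idx],
            "p_score": scores,
            "region": region,
            "sample_id": sample_ids[sidx],
            "cancer_type": ctype,
            "stage": stages[sidx],
            "gene": genes,
        },
        columns=list(PREDICTION_COLUMNS),
    )
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "cancer_type": ctype,
            "stage": stages,
            "true_driver_count": k_drivers,
            "n_passengers": m_passengers,
            "hypermutant": hyper,
        }
    )
    return records, samples, pd.Series(is_driver)


def simulate_cohort(model: CohortModel, score_model: ClassScoreModel,
                    seed: int | None = None, region: str = "coding"
                    ) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a full cohort prediction table plus its ground truth.

    Reproducible for a fixed (model, score_model, seed); ``seed=None`` uses
    ``model.seed``.
    """
    rng = np.random.default_rng(model.seed if seed is None else seed)
    rec_parts, sample_parts, flag_parts = [], [], []
    for ctype in sorted(model.types):
        records, samples, flags = _simulate_type(ctype, model.types[ctype],
                                                 score_model, rng, region)
        rec_parts.append(records)
        sample_parts.append(samples)
        flag_parts.append(flags)
    records = pd.concat(rec_parts, ignore_index=True)
    records["stage"] = records["stage"].where(records["stage"].notna(), pd.NA)
    samples = pd.concat(sample_parts, ignore_index=True)
    samples["stage"] = samples["stage"].where(samples["stage"].notna(), pd.NA)
    flags = pd.concat(flag_parts, ignore_index=True)

    driver_rec = records[flags.to_numpy()]
    if len(driver_rec):
        hits = driver_rec.groupby(["cancer_type", "gene"])["sample_id"].nunique()
        denom = samples.groupby("cancer_type")["sample_id"].nunique()
        gene_inc = hits.reset_index(name="n_with_driver")
        gene_inc["incidence"] = [
            r.n_with_driver / denom[r.cancer_type] for r in gene_inc.itertuples()
        ]
    else:
        gene_inc = pd.DataFrame(columns=["cancer_type", "gene", "n_with_driver", "incidence"])
    truth = GroundTruth(samples=samples, variant_is_driver=flags, gene_incidence=gene_inc)
    return records, truth


def expected_weighted_count_oracle(score_model: ClassScoreModel, hist: ScoreHistogram,
                                   mean_drivers: float, mean_passengers: float) -> float:
    """Analytic expectation of the weighted count per sample.

    Integrates the estimator against the known score model: each eligible
    bin (posterior > 0.5) contributes ``(2*p_hat_b - 1)`` times the expected
    number of variants landing in it, ``mean_drivers * P_driver(bin) +
    mean_passengers * P_neutral(bin)``.  Deterministic; used as an
    independent oracle for the Monte-Carlo behaviour of the estimator.
    """
    if hist.posterior is None:
        raise CalibrationStateError("histogram posteriors have not been estimated")
    p_pos = score_model.bin_probabilities(hist, "driver")
    p_neg = score_model.bin_probabilities(hist, "neutral")
    post = hist.posterior
    eligible = ~np.isnan(post) & (post > 0.5)
    margin = 2.0 * post[eligible] - 1.0
    load = mean_drivers * p_pos[eligible] + mean_passengers * p_neg[eligible]
    return float(np.sum(margin * load))


def default_cohort_model(seed: int = 0) -> CohortModel:
    """A small multi-type cohort emulating the qualitative structure of real
    pan-cancer data: a very-low-burden thyroid-like type, a breast-like type
    around 6 drivers, a high-burden bladder-like type, a bimodal (neo-modal)
    type, a pancreatic-like type with a planted KRAS-like high-incidence
    gene, and a stage-accumulating prostate-like type."""
    dg = default_driver_genes()
    pg = default_passenger_genes()
    kras_heavy = dict(dg)
    # a ~1/3 share of a rate-6 driver process plants an at-least-one-KRAS
    # incidence of 1 - exp(-2) ~ 86% of samples
    kras_heavy["KRAS"] = sum(w for g, w in dg.items() if g != "KRAS") / 2.0
    return CohortModel(
        types={
            "THCA": CancerTypeModel(n_samples=500, driver_rate=1.0, passenger_rate=20,
                                    driver_gene_weights=dg, passenger_gene_pool=pg),
            "BRCA": CancerTypeModel(n_samples=500, driver_rate=6.0, passenger_rate=30,
                                    driver_gene_weights=dg, passenger_gene_pool=pg),
            "BLCA": CancerTypeModel(n_samples=500, driver_rate=12.0, passenger_rate=40,
                                    hypermutant_fraction=0.01,
                                    driver_gene_weights=dg, passenger_gene_pool=pg),
            "SKCM": CancerTypeModel(n_samples=500, driver_rate=3.0, driver_rate_2=15.0,
                                    mixture_weight=0.6, passenger_rate=40,
                                    driver_gene_weights=dg, passenger_gene_pool=pg),
            "PACA": CancerTypeModel(n_samples=500, driver_rate=6.0, passenger_rate=25,
                                    driver_gene_weights=kras_heavy, passenger_gene_pool=pg),
            "PRAD": CancerTypeModel(n_samples=500, driver_rate=2.0, passenger_rate=20,
                                    stage_probs=(0.25, 0.25, 0.25, 0.25),
                                    stage_multipliers=(1.0, 1.5, 2.0, 2.5),
                                    driver_gene_weights=dg, passenger_gene_pool=pg),
        },
        seed=seed,
    )


def cohort_model_from_dict(data: dict) -> tuple[CohortModel, ClassScoreModel]:
    """Build (CohortModel, ClassScoreModel) from a plain config mapping."""
    score = ClassScoreModel(**(data.get("score_model") or {}))
    types = {}
    for code, spec in (data.get("cancer_types") or {}).items():
        spec = dict(spec)
        if "stage_probs" in spec and spec["stage_probs"] is not None:
            spec["stage_probs"] = tuple(spec["stage_probs"])
        if "stage_multipliers" in spec:
            spec["stage_multipliers"] = tuple(spec["stage_multipliers"])
        if "passenger_gene_pool" in spec:
            spec["passenger_gene_pool"] = tuple(spec["passenger_gene_pool"])
        spec.setdefault("driver_gene_weights", default_driver_genes())
        if not spec.get("passenger_gene_pool"):
            spec["passenger_gene_pool"] = default_passenger_genes()
        types[code] = CancerTypeModel(**spec)
    if not types:
        raise ConfigurationError("config defines no cancer_types")
    return CohortModel(types=types, seed=int(data.get("seed", 0))), score
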