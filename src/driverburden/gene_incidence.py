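"""Driver-gene incidence: fraction of samples with at least one confident driver call.

Within a cancer type, a gene's *incidence* is the percentage of samples
carrying at least one variant in that gene whose score meets or exceeds the
(FDR-calibrated) threshold.  A sample counts once however many qualifying
variants it carries; the denominator is every sample of the type present in
the cohort, including samples with no qualifying variant anywhere.
Hypermutant samples are expected to have been excluded upstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError

INCIDENCE_COLUMNS = (
    "cancer_type", "gene", "n_samples", "n_with_driver", "incidence", "threshold_used",
)


def gene_incidence(cohort: pd.DataFrame, threshold: float,
                   region: str | None = None) -> pd.DataFrame:
    """Per (cancer_type, gene) at-least-one-driver incidence at a threshold.

    The gene universe per type is every gene annotated on the type's records
    (so a gene observed only below threshold reports incidence 0.0).  Records
    without a gene annotation contribute to denominators but to no gene.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError(f"threshold {threshold} outside [0, 1]")
    df = cohort
    if region is not None:
        df = df[df["region"] == region]
    if len(df) == 0:
        raise ValidationError("cohort is empty (after region filtering)")
    if df["gene"].isna().all():
        raise ValidationError("cohort has no gene annotations")

    denominators = df.groupby("cancer_type")["sample_id"].nunique()
    annotated = df[df["gene"].notna()]
    universe = annotated.loc[:, ["cancer_type", "gene"]].drop_duplicates()
    qualifying = annotated[annotated["p_score"].to_numpy(float) >= threshold]
    hits = (
        qualifying.groupby(["cancer_type", "gene"])["sample_id"].nunique()
        if len(qualifying)
        else pd.Series(dtype=int)
    )
    rows = []
    for ctype, gene in universe.itertuples(index=False):
        n_samples = int(denominators[ctype])
        n_with = int(hits.get((ctype, gene), 0))
        rows.append(
            {
                "cancer_type": ctype,
                "gene": gene,
                "n_samples": n_samples,
                "n_with_driver": n_with,
                "incidence": n_with / n_samples,
                "threshold_used": threshold,
            }
        )
    out = pd.DataFrame(rows, columns=list(INCIDENCE_COLUMNS))
    return out.sort_values(["cancer_type", "gene"], ignore_index=True)


def rank_genes(incidences: pd.DataFrame, cancer_type: str, top_k: int) -> pd.DataFrame:
    """Top-k genes of one type by descending incidence, ties lexicographic."""
    if top_k < 1:
        raise ValidationError("top_k must be >= 1")
    sub = incidences[incidences["cancer_type"] == cancer_type]
    if len(sub) == 0:
        raise ValidationError(f"no incidences computed for cancer type {cancer_type!r}")
    ranked = sub.sort_values(
        ["incidence", "gene"], ascending=[False, True], ignore_index=True
    )
    return ranked.head(top_k)


def gene_across_cancers(incidences: pd.DataFrame, gene: str) -> pd.DataFrame:
    """One gene's incidence profiled across every cancer type.

    Types where the gene was never observed report incidence 0.0; types are
    ordered deterministically by type code.
    """
    types = sorted(incidences["cancer_type"].unique())
    sub = incidences[incidences["gene"] == gene].set_index("cancer_type")
    n_per_type = incidences.groupby("cancer_type")["n_samples"].first()
    rows = []
    for ctype in types:
        if ctype in sub.index:
            rec = sub.loc[ctype]
            rows.append(
                {"cancer_type": ctype, "gene": gene, "n_samples": int(rec["n_samples"]),
                 "n_with_driver": int(rec["n_with_driver"]),
                 "incidence": float(rec["incidence"])}
            )
        else:
            rows.append(
                {"cancer_type": ctype, "gene": gene,
                 "n_samples": int(n_per_type.get(ctype, 0)),
                 "n_with_driver": 0, "incidence": 0.0}
            )
    return pd.DataFrame(rows, columns=["cancer_type", "gene", "n_samples",
                                       "n_with_driver", "incidence"])
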