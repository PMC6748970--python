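"""Tabular input/output for cohort prediction tables, calibration sets and summaries.

Two in-memory containers flow through the pipeline, both plain pandas DataFrames:

* a *cohort prediction table* with one scored variant per row
  (columns :data:`PREDICTION_COLUMNS`); the unit being counted,
* a *calibration table* of labelled scores with known driver/neutral status
  (columns :data:`CALIBRATION_COLUMNS`), assumed to come from a 50:50
  balanced test set of the upstream classifier.

Coordinates are 1-based point positions (VCF convention).  Positions are
carried through but never used in arithmetic.  Missing stage/gene values are
encoded as ``.`` on disk and as missing values (``pd.NA``) in memory.
"""

from __future__ import annotations

import csv
import io
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    BalanceError,
    ConfigurationError,
    ParseError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Column order of a cohort prediction table.
PREDICTION_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "p_score",
    "region",
    "sample_id",
    "cancer_type",
    "stage",
    "gene",
)

#: Column order of a calibration table.
CALIBRATION_COLUMNS = ("p_score", "label", "region")

REGIONS = ("coding", "noncoding")
STAGES = ("I", "II", "III", "IV")
NUCLEOTIDES = frozenset("ACGT")
MISSING = "."

#: Accepted spellings of the two calibration labels.
LABEL_ALIASES = {
    "driver": "driver",
    "+1": "driver",
    "1": "driver",
    "neutral": "neutral",
    "-1": "neutral",
    "−1": "neutral",  # unicode minus
}

_VCF_INFO_KEYS = {
    "p_score": "PSCORE",
    "region": "RGN",
    "sample_id": "SMP",
    "cancer_type": "CTYPE",
    "stage": "STG",
    "gene": "GENE",
}


@dataclass
class AnalysisConfig:
    """Run configuration shared across the pipeline.

    Defaults follow the analysis conditions: a conservative 5% target FDR,
    score histogram bins of width 0.01, and exclusion of hypermutant samples
    carrying more than 500 estimated drivers.
    """

    target_fdr: float = 0.05
    bin_width: float = 0.01
    hypermutation_max: int = 500
    region: str = "coding"
    threshold_grid: tuple = field(default_factory=lambda: tuple(np.round(np.arange(101) / 100.0, 2)))
    mode_bin_width: float = 1.0
    smoothing: str = "add_one_isotonic"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_fdr < 1.0:
            raise ConfigurationError(f"target_fdr must be in (0,1), got {self.target_fdr}")
        n_bins = 1.0 / self.bin_width
        if abs(n_bins - round(n_bins)) > 1e-9:
            raise ConfigurationError(f"bin_width {self.bin_width} does not divide 1.0 into integer bins")
        if self.region not in REGIONS:
            raise ConfigurationError(f"unknown region {self.region!r}")
        if self.smoothing not in ("none", "add_one", "add_one_isotonic"):
            raise ConfigurationError(f"unknown smoothing {self.smoothing!r}")
        grid = np.asarray(self.threshold_grid, dtype=float)
        if grid.size == 0 or np.any(np.diff(grid) <= 0):
            raise ConfigurationError("threshold_grid must be non-empty and strictly increasing")
        if grid[0] < 0 or grid[-1] > 1:
            raise ConfigurationError("threshold_grid values must lie in [0,1]")
        if self.hypermutation_max < 0:
            raise ConfigurationError("hypermutation_max must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} must hold a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "threshold_grid" in data:
            data["threshold_grid"] = tuple(data["threshold_grid"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = {f: getattr(self, f) for f in self.__dataclass_fields__}
        d["threshold_grid"] = list(d["threshold_grid"])
        return d


def _parse_p_score(token: str, lineno: int) -> float:
    try:
        value = float(token)
    except ValueError:
        raise ParseError(f"line {lineno}: p_score {token!r} is not numeric") from None
    if not 0.0 <= value <= 1.0:
        raise ValidationError(f"line {lineno}: p_score {value} outside [0, 1]")
    return value


def _validate_prediction_row(row: Sequence[str], lineno: int) -> tuple:
    if len(row) != len(PREDICTION_COLUMNS):
        raise ParseError(
            f"line {lineno}: expected {len(PREDICTION_COLUMNS)} fields, got {len(row)}"
        )
    chrom, pos_s, ref, alt, p_s, region, sample_id, cancer_type, stage, gene = (
        t.strip() for t in row
    )
    try:
        pos = int(pos_s)
    except ValueError:
        raise ParseError(f"line {lineno}: position {pos_s!r} is not an integer") from None
    if pos < 1:
        raise ValidationError(f"line {lineno}: position {pos} must be >= 1")
    if ref not in NUCLEOTIDES:
        raise ValidationError(f"line {lineno}: ref allele {ref!r} not one of A/C/G/T")
    if alt not in NUCLEOTIDES:
        raise ValidationError(f"line {lineno}: alt allele {alt!r} not one of A/C/G/T")
    if ref == alt:
        raise ValidationError(f"line {lineno}: ref and alt alleles are both {ref!r}")
    p_score = _parse_p_score(p_s, lineno)
    if region not in REGIONS:
        raise ValidationError(f"line {lineno}: unknown region token {region!r}")
    if not sample_id or sample_id == MISSING:
        raise ValidationError(f"line {lineno}: missing sample_id")
    if not cancer_type or cancer_type == MISSING:
        raise ValidationError(f"line {lineno}: missing cancer_type")
    if stage not in STAGES and stage not in (MISSING, "", "unknown"):
        raise ValidationError(f"line {lineno}: unknown stage token {stage!r}")
    stage_v = stage if stage in STAGES else pd.NA
    gene_v = gene if gene not in (MISSING, "") else pd.NA
    return chrom, pos, ref, alt, p_score, region, sample_id, cancer_type, stage_v, gene_v


def _predictions_frame(rows: list[tuple]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=list(PREDICTION_COLUMNS))
    if df.empty:
        df = df.astype({"pos": "int64", "p_score": "float64"}, errors="ignore")
        return df
    df["pos"] = df["pos"].astype("int64")
    df["p_score"] = df["p_score"].astype("float64")
    key = ["sample_id", "chrom", "pos", "ref", "alt"]
    dup = df.duplicated(subset=key)
    if dup.any():
        first = df.loc[dup.idxmax(), key].tolist()
        raise ValidationError(
            f"duplicate variant key {tuple(first)}: (sample_id, chrom, pos, ref, alt) "
            "must be unique within a cohort table"
        )
    return df


def read_predictions(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    """Read and validate a cohort prediction table.

    Parameters
    ----------
    path
        Input file. For ``tsv``: tab-separated, UTF-8, mandatory header row,
        ``#``-prefixed comment lines skipped, missing stage/gene as ``.``.
        For ``vcf``: one variant-sample pair per record with the annotations
        in INFO keys PSCORE/RGN/SMP/CTYPE/STG/GENE.
    format
        ``"tsv"`` or ``"vcf"``.

    Returns
    -------
    pandas.DataFrame with columns :data:`PREDICTION_COLUMNS`, row order
    preserved.
    """
    if format == "tsv":
        return _read_predictions_tsv(path)
    if format == "vcf":
        return _read_predictions_vcf(path)
    raise ValueError(f"unknown format {format!r} (expected 'tsv' or 'vcf')")


def _read_predictions_tsv(path: str | Path) -> pd.DataFrame:
    rows: list[tuple] = []
    n_comments = 0
    header_seen = False
    with open(path, newline="", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                n_comments += 1
                continue
            if not line.strip():
                continue
            fields = next(csv.reader([line], delimiter="\t"))
            if not header_seen:
                header = [f.strip() for f in fields]
                if header != list(PREDICTION_COLUMNS):
                    raise ParseError(
                        f"line {lineno}: header {header} does not match expected "
                        f"columns {list(PREDICTION_COLUMNS)}"
                    )
                header_seen = True
                continue
            rows.append(_validate_prediction_row(fields, lineno))
    if not header_seen:
        raise ParseError(f"{path}: no header row found")
    if n_comments:
        logger.info("read_predictions: skipped %d comment line(s) in %s", n_comments, path)
    if not rows:
        logger.warning("read_predictions: %s contains a header but no data rows", path)
    return _predictions_frame(rows)


def _read_predictions_vcf(path: str | Path) -> pd.DataFrame:
    from cyvcf2 import VCF

    rows: list[tuple] = []
    vcf = VCF(str(path))
    try:
        for i, variant in enumerate(vcf, start=1):
            alts = variant.ALT
            if len(alts) != 1:
                raise ParseError(f"VCF record {i}: expected exactly one ALT allele, got {alts}")
            info = variant.INFO
            raw = [
                str(variant.CHROM),
                str(variant.POS),
                str(variant.REF),
                str(alts[0]),
                str(info.get(_VCF_INFO_KEYS["p_score"])),
                str(info.get(_VCF_INFO_KEYS["region"]) or ""),
                str(info.get(_VCF_INFO_KEYS["sample_id"]) or ""),
                str(info.get(_VCF_INFO_KEYS["cancer_type"]) or ""),
                str(info.get(_VCF_INFO_KEYS["stage"]) or MISSING),
                str(info.get(_VCF_INFO_KEYS["gene"]) or MISSING),
            ]
            rows.append(_validate_prediction_row(raw, i))
    finally:
        vcf.close()
    return _predictions_frame(rows)


def write_predictions(df: pd.DataFrame, path: str | Path, format: str = "tsv",
                      comments: Iterable[str] = ()) -> None:
    """Write a cohort prediction table as TSV or as the single-sample VCF dialect."""
    if format == "tsv":
        _write_tsv(df.loc[:, list(PREDICTION_COLUMNS)], path, comments=comments)
        return
    if format != "vcf":
        raise ValueError(f"unknown format {format!r}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=PSCORE,Number=1,Type=Float,Description="Driver confidence p-score">\n')
        fh.write('##INFO=<ID=RGN,Number=1,Type=String,Description="Genomic region class">\n')
        fh.write('##INFO=<ID=SMP,Number=1,Type=String,Description="Tumour sample id">\n')
        fh.write('##INFO=<ID=CTYPE,Number=1,Type=String,Description="Cancer type code">\n')
        fh.write('##INFO=<ID=STG,Number=1,Type=String,Description="Clinical stage I-IV">\n')
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n')
        for c in sorted({str(c) for c in df["chrom"]}, key=lambda s: (len(s), s)):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for rec in df.itertuples(index=False):
            info = [
                f"PSCORE={rec.p_score:.6g}",
                f"RGN={rec.region}",
                f"SMP={rec.sample_id}",
                f"CTYPE={rec.cancer_type}",
            ]
            if not pd.isna(rec.stage):
                info.append(f"STG={rec.stage}")
            if not pd.isna(rec.gene):
                info.append(f"GENE={rec.gene}")
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t.\t.\t{';'.join(info)}\n"
            )


def class_balance(labels: pd.Series) -> float:
    """Normalised class imbalance |#driver - #neutral| / total."""
    n_pos = int((labels == "driver").sum())
    n_neg = int((labels == "neutral").sum())
    total = n_pos + n_neg
    if total == 0:
        return 0.0
    return abs(n_pos - n_neg) / total


def check_balance(calibration: pd.DataFrame, tolerance: float = 0.05,
                  allow_imbalance: bool = False) -> float:
    """Check the 50:50 balance assumption of a calibration table.

    The posterior and FDR estimators are only valid proxies under
    approximately balanced driver/neutral data, so imbalance beyond
    ``tolerance`` raises :class:`BalanceError` unless explicitly overridden.
    Returns the imbalance fraction.
    """
    imbalance = class_balance(calibration["label"])
    if imbalance > tolerance and not allow_imbalance:
        raise BalanceError(
            f"calibration set imbalance {imbalance:.3f} exceeds tolerance {tolerance}; "
            "pass allow_imbalance=True to accept a biased calibration set"
        )
    return imbalance


def read_labeled_scores(path: str | Path, tolerance: float = 0.05,
                        allow_imbalance: bool = False) -> pd.DataFrame:
    """Read a labelled calibration table (columns p_score, label, region).

    Label tokens ``driver``/``neutral`` and the aliases ``+1``/``-1`` are
    accepted.  Class balance is checked against ``tolerance``.
    """
    rows: list[tuple] = []
    header_seen = False
    with open(path, newline="", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = [t.strip() for t in next(csv.reader([line], delimiter="\t"))]
            if not header_seen:
                if fields != list(CALIBRATION_COLUMNS):
                    raise ParseError(
                        f"line {lineno}: header {fields} does not match "
                        f"{list(CALIBRATION_COLUMNS)}"
                    )
                header_seen = True
                continue
            if len(fields) != 3:
                raise ParseError(f"line {lineno}: expected 3 fields, got {len(fields)}")
            p_score = _parse_p_score(fields[0], lineno)
            label = LABEL_ALIASES.get(fields[1])
            if label is None:
                raise ValidationError(f"line {lineno}: unknown label token {fields[1]!r}")
            if fields[2] not in REGIONS:
                raise ValidationError(f"line {lineno}: unknown region token {fields[2]!r}")
            rows.append((p_score, label, fields[2]))
    if not header_seen:
        raise ParseError(f"{path}: no header row found")
    df = pd.DataFrame(rows, columns=list(CALIBRATION_COLUMNS))
    imbalance = check_balance(df, tolerance=tolerance, allow_imbalance=allow_imbalance)
    n_pos = int((df["label"] == "driver").sum())
    logger.info(
        "read_labeled_scores: %d rows (%d driver / %d neutral), imbalance %.3f",
        len(df), n_pos, len(df) - n_pos, imbalance,
    )
    return df


def write_labeled_scores(df: pd.DataFrame, path: str | Path,
                         comments: Iterable[str] = ()) -> None:
    _write_tsv(df.loc[:, list(CALIBRATION_COLUMNS)], path, comments=comments)


def _format_value(v) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v is pd.NA:
        return MISSING
    if isinstance(v, (bool, np.bool_)):
        return str(bool(v))
    if isinstance(v, (float, np.floating)):
        return f"{v:.6g}"
    return str(v)


def _write_tsv(df: pd.DataFrame, path: str | Path, comments: Iterable[str] = ()) -> None:
    buf = io.StringIO()
    for c in comments:
        buf.write(f"# {c}\n")
    buf.write("\t".join(df.columns) + "\n")
    for row in df.itertuples(index=False):
        buf.write("\t".join(_format_value(v) for v in row) + "\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def write_summary(table: pd.DataFrame, path: str | Path,
                  comments: Iterable[str] = ()) -> None:
    """Write a summary table as TSV with a deterministic column order.

    Floats are rendered with 6 significant digits, so re-reading the file
    reproduces every value to that precision.  An empty table is an error —
    silently writing an empty file would mask an upstream failure.
    """
    if table is None or len(table) == 0:
        raise ValidationError("refusing to write an empty summary table")
    _write_tsv(table, path, comments=comments)


def read_summary(path: str | Path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_summary`, inferring dtypes."""
    return pd.read_csv(path, sep="\t", comment="#", na_values=[MISSING])
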