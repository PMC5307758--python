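"""Raw Cq wells -> QC-flagged, calibrator-corrected 40-ΔΔCq expression.

Each sample is measured in triplicate for the four target genes and the two
reference genes.  Per gene the triplicate median is taken (robust against a
single aberrant well), target medians are normalized against the mean
reference-gene Cq of the same sample, and the same quantity computed on the
run's calibrator sample is subtracted to cancel inter-run shifts (Livak
ΔΔCq).  The result is reported as ``40 - ΔΔCq`` so that larger values mean
higher mRNA expression:

    40-ΔΔCq[g]_S = 40 - ((Cq[g]_S - meanCq[REF]_S)
                         - (Cq[g]_PC - meanCq[REF]_PC))

Quality control happens between aggregation and normalization: samples with
a missing reference gene, a high mean reference Cq (too little RNA), an
excessive replicate spread, or too few detected replicates for any panel
gene are flagged invalid and carry no expression values.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .panel import (
    CALIBRATOR_ID,
    CYCLE_CEILING,
    GENE_PANEL,
    REF_GENES,
    TARGET_GENES,
)

CQ_COLUMNS = ["sample_id", "run_id", "gene", "replicate", "cq"]
EXPRESSION_COLUMNS = ["sample_id", "qc_status"] + list(TARGET_GENES)


class QcRules(BaseModel):
    """Validity criteria applied to per-sample aggregated Cq values.

    The vendor's own acceptance criteria are not public; these defaults are
    this package's operationalization and are echoed into every report.
    """

    max_ref_mean_cq: float = Field(32.0, gt=0)
    max_replicate_spread: float = Field(1.0, gt=0)
    min_valid_replicates: int = Field(2, gt=0)


@dataclass
class GeneMedianCq:
    sample_id: str
    run_id: str
    gene: str
    median_cq: float | None
    n_replicates_used: int
    spread: float | None  # max - min of the detected replicates


@dataclass
class CalibratorProfile:
    """Per-run calibrator: target-gene Cqs and the mean reference Cq."""

    run_id: str
    cq_target: dict[str, float]
    mean_cq_ref: float


@dataclass
class ExpressionProfile:
    sample_id: str
    qc_status: str  # "valid" or "invalid(<reason>)"
    values: dict[str, float] = field(default_factory=dict)

    @property
    def is_valid(self) -> bool:
        return self.qc_status == "valid"


class CqTableError(ValueError):
    """Malformed Cq input (schema, duplicate keys, unknown genes)."""


def read_cq_table(path_or_buf) -> pd.DataFrame:
    """Read and validate a long-format Cq CSV.

    Expected header ``sample_id,run_id,gene,replicate,cq``; an empty ``cq``
    field denotes an undetected well.  Raises :class:`CqTableError` with the
    offending row number on schema violations.
    """
    df = pd.read_csv(path_or_buf, dtype={"sample_id": str, "run_id": str, "gene": str})
    missing = [c for c in CQ_COLUMNS if c not in df.columns]
    if missing:
        raise CqTableError(f"cq table missing columns: {missing}")
    df = df[CQ_COLUMNS].copy()
    df["cq"] = pd.to_numeric(df["cq"], errors="coerce")
    validate_cq_table(df)
    return df


def validate_cq_table(df: pd.DataFrame) -> None:
    """Check panel membership, Cq range and key uniqueness; row-numbered errors."""
    bad_gene = ~df["gene"].isin(GENE_PANEL)
    if bad_gene.any():
        i = int(df.index[bad_gene][0])
        raise CqTableError(
            f"row {i}: unknown gene symbol {df.loc[i, 'gene']!r} "
            f"(panel: {', '.join(GENE_PANEL)})"
        )
    detected = df["cq"].notna()
    out_of_range = detected & ~((df["cq"] > 0) & (df["cq"] <= CYCLE_CEILING))
    if out_of_range.any():
        i = int(df.index[out_of_range][0])
        raise CqTableError(
            f"row {i}: cq {df.loc[i, 'cq']} outside (0, {CYCLE_CEILING:g}]"
        )
    dup = df.duplicated(subset=["sample_id", "run_id", "gene", "replicate"])
    if dup.any():
        i = int(df.index[dup][0])
        key = tuple(df.loc[i, ["sample_id", "run_id", "gene", "replicate"]])
        raise CqTableError(f"row {i}: duplicate well key {key}")


def aggregate_triplicates(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicate wells to one median Cq per (sample, gene).

    Undetected wells are excluded (not imputed at the cycle ceiling, which
    would bias upward-censored genes).  With two detected replicates the
    mean is taken (equal to their median); a single detected replicate is
    kept but flagged through ``n_replicates_used``; zero detected replicates
    yield a missing median.

    Returns a frame with columns
    ``sample_id, run_id, gene, median_cq, n_replicates_used, spread``.
    """
    validate_cq_table(records)
    multi_run = records.groupby("sample_id")["run_id"].nunique()
    multi_run = multi_run[(multi_run > 1) & (multi_run.index != CALIBRATOR_ID)]
    if len(multi_run):
        raise CqTableError(
            f"sample {multi_run.index[0]!r} appears in more than one run"
        )

    def _agg(g: pd.DataFrame) -> pd.Series:
        vals = g["cq"].dropna().to_numpy()
        n = len(vals)
        return pd.Series(
            {
                "median_cq": float(np.median(vals)) if n else np.nan,
                "n_replicates_used": n,
                "spread": float(vals.max() - vals.min()) if n else np.nan,
            }
        )

    out = (
        records.groupby(["sample_id", "run_id", "gene"], sort=False)
        .apply(_agg, include_groups=False)
        .reset_index()
    )
    out["n_replicates_used"] = out["n_replicates_used"].astype(int)
    return out


def calibrator_profiles(medians: pd.DataFrame) -> dict[str, CalibratorProfile]:
    """Extract one :class:`CalibratorProfile` per run from aggregated medians."""
    cal = medians[medians["sample_id"] == CALIBRATOR_ID]
    profiles: dict[str, CalibratorProfile] = {}
    for run_id, grp in cal.groupby("run_id"):
        by_gene = grp.set_index("gene")["median_cq"]
        missing = [g for g in GENE_PANEL if g not in by_gene.index or pd.isna(by_gene.get(g))]
        if missing:
            raise CqTableError(
                f"calibrator for run {run_id!r} missing genes: {missing}"
            )
        profiles[str(run_id)] = CalibratorProfile(
            run_id=str(run_id),
            cq_target={g: float(by_gene[g]) for g in TARGET_GENES},
            mean_cq_ref=float(np.mean([by_gene[g] for g in REF_GENES])),
        )
    return profiles


def apply_qc(medians: pd.DataFrame, rules: QcRules) -> pd.DataFrame:
    """Assign a QC status to every non-calibrator sample.

    A sample is ``invalid(<reason>)`` if any reference gene is missing, the
    mean reference Cq exceeds ``max_ref_mean_cq`` (low RNA yield), any used
    replicate spread exceeds ``max_replicate_spread``, or any panel gene has
    fewer than ``min_valid_replicates`` detected replicates.

    Returns a frame ``sample_id, qc_status``.
    """
    rows = []
    samples = medians[medians["sample_id"] != CALIBRATOR_ID]
    for sample_id, grp in samples.groupby("sample_id", sort=False):
        by_gene = grp.set_index("gene")
        status = "valid"
        ref_medians = [
            by_gene["median_cq"].get(g, np.nan) for g in REF_GENES
        ]
        if any(pd.isna(v) for v in ref_medians):
            status = "invalid(reference gene missing)"
        elif float(np.mean(ref_medians)) > rules.max_ref_mean_cq:
            status = "invalid(low RNA yield)"
        elif (by_gene["spread"].dropna() > rules.max_replicate_spread).any():
            status = "invalid(replicate spread)"
        else:
            for g in GENE_PANEL:
                n = int(by_gene["n_replicates_used"].get(g, 0))
                if n < rules.min_valid_replicates:
                    status = f"invalid(insufficient replicates: {g})"
                    break
        rows.append({"sample_id": sample_id, "qc_status": status})
    return pd.DataFrame(rows, columns=["sample_id", "qc_status"])


def normalize_expression(
    medians: Mapping[str, float], calibrator: CalibratorProfile, sample_id: str = ""
) -> ExpressionProfile:
    """Apply the 40-ΔΔCq formula to one sample's per-gene median Cqs.

    ``medians`` maps gene -> median Cq and must contain both reference
    genes; target genes with a missing median get no value.
    """
    ref_vals = [medians.get(g) for g in REF_GENES]
    if any(v is None or (isinstance(v, float) and math.isnan(v)) for v in ref_vals):
        raise CqTableError(f"sample {sample_id!r}: reference gene median missing")
    mean_ref_s = float(np.mean([float(v) for v in ref_vals]))
    values: dict[str, float] = {}
    for gene in TARGET_GENES:
        cq = medians.get(gene)
        if cq is None or (isinstance(cq, float) and math.isnan(cq)):
            continue
        ddcq = (float(cq) - mean_ref_s) - (
            calibrator.cq_target[gene] - calibrator.mean_cq_ref
        )
        values[gene] = CYCLE_CEILING - ddcq
    return ExpressionProfile(sample_id=sample_id, qc_status="valid", values=values)


def quantify(records: pd.DataFrame, rules: QcRules | None = None) -> pd.DataFrame:
    """Full stage: aggregate, QC, and normalize a raw Cq table.

    Returns the wide expression frame with columns
    ``sample_id, qc_status, ESR1, PGR, MKI67, ERBB2``; QC-invalid samples
    keep their status string and have missing value fields.  Raises on a
    missing calibrator for any sample's run.
    """
    rules = rules or QcRules()
    medians = aggregate_triplicates(records)
    profiles = calibrator_profiles(medians)
    qc = apply_qc(medians, rules).set_index("sample_id")["qc_status"]

    rows = []
    samples = medians[medians["sample_id"] != CALIBRATOR_ID]
    for (sample_id, run_id), grp in samples.groupby(["sample_id", "run_id"], sort=False):
        status = qc.loc[sample_id]
        row: dict[str, object] = {"sample_id": sample_id, "qc_status": status}
        if status == "valid":
            if str(run_id) not in profiles:
                raise CqTableError(
                    f"no calibrator profile for run {run_id!r} (sample {sample_id!r})"
                )
            by_gene = grp.set_index("gene")["median_cq"].to_dict()
            prof = normalize_expression(by_gene, profiles[str(run_id)], sample_id)
            row.update(prof.values)
        rows.append(row)
    out = pd.DataFrame(rows, columns=EXPRESSION_COLUMNS)
    return out


def write_expression_table(expression: pd.DataFrame, path: str | Path) -> None:
    """Write ``expression.tsv`` (two-decimal expression values, empty if invalid)."""
    df = expression.copy()
    for g in TARGET_GENES:
        df[g] = df[g].map(lambda v: "" if pd.isna(v) else f"{v:.2f}")
    df.to_csv(path, sep="\t", index=False)


def read_expression_table(path_or_buf) -> pd.DataFrame:
    df = pd.read_csv(path_or_buf, sep="\t", dtype={"sample_id": str})
    for g in TARGET_GENES:
        df[g] = pd.to_numeric(df[g], errors="coerce")
    return df
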