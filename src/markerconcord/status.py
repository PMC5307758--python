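"""Dichotomization of protein and mRNA measurements into marker statuses.

Hormone receptors (ER, PR) are called positive from IHC when the Remmele
immunoreactive score exceeds 3 or the fraction of positive nuclei exceeds
1% (both comparisons strict).  Continuous measurements — Ki-67 labelling
indices and 40-ΔΔCq expression values — are dichotomized at a supplied
cutoff, value >= cutoff meaning high/positive.  Cutoffs derived by the ROC
search in :mod:`markerconcord.prediction` are midpoints between observed
values, so no observed value ever sits on such a boundary; for externally
supplied cutoffs the inclusive rule keeps a responder whose value equals
the cutoff on the test-positive side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd
from pydantic import BaseModel, Field

from .panel import (
    ASSAY_QIHC,
    ASSAY_RTQPCR,
    ASSAY_VIHC,
    MARKER_GENE,
    MARKERS,
    METHOD_ASSAY,
)

STATUS_COLUMNS = ["sample_id", "marker", "assay", "status", "cutoff_used"]
POSITIVE_STATUSES = frozenset({"positive", "high"})
NEGATIVE_STATUSES = frozenset({"negative", "low"})


class CutoffConfig(BaseModel):
    """Dichotomization rules and cutoffs.

    ``mki67_cutoffs`` defaults to the study's ROC-derived operating points
    (40-ΔΔCq units for RT-qPCR, percent positive nuclei for the two IHC
    routes).  Hormone-receptor mRNA cutoffs have no defensible default and
    must be supplied when hormone mRNA status is requested.
    """

    irs_positive_above: float = Field(3.0, description="IRS strictly above -> positive")
    percent_positive_above: float = Field(1.0, description="% nuclei strictly above -> positive")
    mki67_cutoffs: dict[str, float] = Field(
        default_factory=lambda: {ASSAY_RTQPCR: 37.31, ASSAY_QIHC: 13.2, ASSAY_VIHC: 3.5}
    )
    hormone_mrna_cutoffs: dict[str, float] | None = None


@dataclass
class IhcScore:
    """One marker scored on one slide by one method (visual or digital)."""

    sample_id: str
    marker: str
    method: str  # "visual" | "digital"
    percent_positive: float
    intensity: int | None = None
    irs: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.percent_positive <= 100:
            raise ValueError(f"percent_positive {self.percent_positive} outside [0, 100]")
        if self.marker == "Ki67" and self.irs is not None:
            raise ValueError("Ki67 records carry no IRS")
        if self.irs is not None and not 0 <= self.irs <= 12:
            raise ValueError(f"irs {self.irs} outside 0-12")


@dataclass
class MarkerStatus:
    sample_id: str
    marker: str
    assay: str
    status: str | None  # positive/negative, high/low, or None when undetermined
    cutoff_used: object


def hormone_status_ihc(score: IhcScore, cfg: CutoffConfig | None = None) -> MarkerStatus:
    """Call ER/PR status from an IHC score by the IRS-or-percent rule."""
    cfg = cfg or CutoffConfig()
    if score.marker not in ("ER", "PR"):
        raise ValueError(f"hormone status undefined for marker {score.marker!r}")
    irs = score.irs if score.irs is not None else 0
    positive = (irs > cfg.irs_positive_above) or (
        score.percent_positive > cfg.percent_positive_above
    )
    rule = f"IRS>{cfg.irs_positive_above:g}|%>{cfg.percent_positive_above:g}"
    return MarkerStatus(
        sample_id=score.sample_id,
        marker=score.marker,
        assay=METHOD_ASSAY[score.method],
        status="positive" if positive else "negative",
        cutoff_used=rule,
    )


def dichotomize_expression(
    value: float | None, cutoff: float, high_is_positive: bool = True
) -> str | None:
    """High/low call at an inclusive cutoff; missing values stay undetermined."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    at_or_above = value >= cutoff
    high = at_or_above if high_is_positive else not at_or_above
    return "high" if high else "low"


def status_table(
    ihc: pd.DataFrame | None,
    expression: pd.DataFrame | None,
    cfg: CutoffConfig | None = None,
) -> pd.DataFrame:
    """Build the long status table across all markers and assays.

    ``ihc`` follows the ``ihc.csv`` schema (sample_id, marker, method,
    percent_positive, intensity, irs); ``expression`` is the wide
    expression frame.  Hormone mRNA statuses are emitted only when
    ``cfg.hormone_mrna_cutoffs`` provides the gene's cutoff.
    """
    cfg = cfg or CutoffConfig()
    rows: list[dict] = []

    if ihc is not None:
        for rec in ihc.itertuples(index=False):
            irs = None if pd.isna(getattr(rec, "irs", None)) else int(rec.irs)
            intensity = (
                None if pd.isna(getattr(rec, "intensity", None)) else int(rec.intensity)
            )
            score = IhcScore(
                sample_id=str(rec.sample_id),
                marker=str(rec.marker),
                method=str(rec.method),
                percent_positive=float(rec.percent_positive),
                intensity=intensity,
                irs=irs,
            )
            if score.marker in ("ER", "PR"):
                st = hormone_status_ihc(score, cfg)
            else:
                assay = METHOD_ASSAY[score.method]
                cutoff = cfg.mki67_cutoffs[assay]
                st = MarkerStatus(
                    sample_id=score.sample_id,
                    marker="Ki67",
                    assay=assay,
                    status=dichotomize_expression(score.percent_positive, cutoff),
                    cutoff_used=cutoff,
                )
            rows.append(vars(st))

    if expression is not None:
        valid = expression[expression["qc_status"] == "valid"]
        for marker in MARKERS:
            gene = MARKER_GENE[marker]
            if marker == "Ki67":
                cutoff = cfg.mki67_cutoffs[ASSAY_RTQPCR]
            else:
                if not cfg.hormone_mrna_cutoffs or gene not in cfg.hormone_mrna_cutoffs:
                    continue
                cutoff = cfg.hormone_mrna_cutoffs[gene]
            for rec in valid.itertuples(index=False):
                value = getattr(rec, gene)
                call = dichotomize_expression(
                    None if pd.isna(value) else float(value), cutoff
                )
                if marker != "Ki67" and call is not None:
                    call = "positive" if call == "high" else "negative"
                rows.append(
                    {
                        "sample_id": str(rec.sample_id),
                        "marker": marker,
                        "assay": ASSAY_RTQPCR,
                        "status": call,
                        "cutoff_used": cutoff,
                    }
                )

    return pd.DataFrame(rows, columns=STATUS_COLUMNS)


def read_ihc_table(path_or_buf) -> pd.DataFrame:
    """Read and validate ``ihc.csv``; row-numbered diagnostics on bad values."""
    df = pd.read_csv(path_or_buf, dtype={"sample_id": str, "marker": str, "method": str})
    required = ["sample_id", "marker", "method", "percent_positive"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"ihc table missing columns: {missing}")
    for col in ("intensity", "irs"):
        if col not in df.columns:
            df[col] = pd.NA
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["percent_positive"] = pd.to_numeric(df["percent_positive"], errors="coerce")
    bad_marker = ~df["marker"].isin(MARKERS)
    if bad_marker.any():
        i = int(df.index[bad_marker][0])
        raise ValueError(f"row {i}: unknown marker {df.loc[i, 'marker']!r}")
    bad_method = ~df["method"].isin(METHOD_ASSAY)
    if bad_method.any():
        i = int(df.index[bad_method][0])
        raise ValueError(f"row {i}: unknown method {df.loc[i, 'method']!r}")
    bad_pct = ~df["percent_positive"].between(0, 100)
    if bad_pct.any():
        i = int(df.index[bad_pct][0])
        raise ValueError(
            f"row {i}: percent_positive {df.loc[i, 'percent_positive']} outside [0, 100]"
        )
    dup = df.duplicated(subset=["sample_id", "marker", "method"])
    if dup.any():
        i = int(df.index[dup][0])
        raise ValueError(f"row {i}: duplicate (sample, marker, method) record")
    return df


def write_status_table(status: pd.DataFrame, path: str | Path) -> None:
    status.to_csv(path, sep="\t", index=False)
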