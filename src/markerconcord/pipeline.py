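"""End-to-end orchestration: simulate/read -> quantify -> status -> stats.

A single :class:`PipelineConfig` drives the whole run.  Inputs come either
from files (``cq.csv``, ``ihc.csv``, ``outcomes.csv``) or from the
synthetic-cohort generator; every stage's table is written to the output
directory together with a plain-text run log, a machine-readable JSON
summary, and a config echo sufficient to reproduce the run byte for byte.
Sample attrition (QC failures, incomplete pairs) is counted explicitly so
that n_input = n_analyzed + n_excluded always reconciles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .concordance import MethodConcordance
from .panel import (
    ASSAY_QIHC,
    ASSAY_RTQPCR,
    ASSAY_VIHC,
    CALIBRATOR_ID,
    MARKER_GENE,
    MARKERS,
)
from .prediction import ResponsePredictor
from .quantification import (
    QcRules,
    quantify,
    read_cq_table,
    write_expression_table,
)
from .status import (
    CutoffConfig,
    read_ihc_table,
    status_table,
    write_status_table,
)
from .synthetic import (
    GeneratorConfig,
    emit_cq_table,
    emit_ihc_table,
    emit_outcome_table,
    generate_cohort,
)

CONCORDANCE_COLUMNS = [
    "marker", "reference", "comparator", "n", "a", "b", "c", "d",
    "ppa", "npa", "opa", "spearman_rho", "spearman_p",
]
PREDICTION_COLUMNS = [
    "assay", "n", "auc", "auc_p", "cutoff", "sensitivity", "specificity",
    "mw_u", "mw_p", "rate_high", "rate_low", "fisher_p",
]


class InputPaths(BaseModel):
    cq: str
    ihc: str
    outcomes: str


class PipelineConfig(BaseModel):
    """One configuration object for a full run (files or simulation)."""

    inputs: InputPaths | None = None
    generator: GeneratorConfig | None = None
    qc: QcRules = Field(default_factory=QcRules)
    cutoffs: CutoffConfig = Field(
        default_factory=lambda: CutoffConfig(
            hormone_mrna_cutoffs={"ESR1": 33.5, "PGR": 30.0}
        )
    )
    constraint_axis: str = "sensitivity"
    constraint_level: float = Field(1.0, ge=0, le=1)
    out_dir: str | None = None
    seed: int | None = None
    percent_decimals: int = 1
    correlation_decimals: int = 2
    expression_decimals: int = 2

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        if (self.inputs is None) == (self.generator is None):
            raise ValueError("exactly one of 'inputs' or 'generator' must be given")
        if self.constraint_axis not in ("sensitivity", "specificity"):
            raise ValueError(f"unknown constraint axis {self.constraint_axis!r}")
        if self.generator is not None and self.seed is not None:
            self.generator = self.generator.model_copy(update={"seed": self.seed})
        return self

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        return cls.model_validate(data)


def read_outcome_table(path_or_buf) -> pd.DataFrame:
    df = pd.read_csv(path_or_buf, dtype={"sample_id": str})
    if "sample_id" not in df.columns or "pcr" not in df.columns:
        raise ValueError("outcomes table requires columns sample_id, pcr")
    bad = ~df["pcr"].isin((0, 1))
    if bad.any():
        i = int(df.index[bad][0])
        raise ValueError(f"row {i}: pcr must be 0/1, got {df.loc[i, 'pcr']!r}")
    dup = df.duplicated(subset=["sample_id"])
    if dup.any():
        i = int(df.index[dup][0])
        raise ValueError(f"row {i}: duplicate sample_id {df.loc[i, 'sample_id']!r}")
    return df


def read_tables(config: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Load and validate the three input tables named by the config."""
    assert config.inputs is not None
    cq = read_cq_table(config.inputs.cq)
    ihc = read_ihc_table(config.inputs.ihc)
    outcomes = read_outcome_table(config.inputs.outcomes)
    return cq, ihc, outcomes


@dataclass
class ReportBundle:
    """All tables and logs produced by one pipeline run."""

    config: PipelineConfig
    cq: pd.DataFrame
    ihc: pd.DataFrame
    outcomes: pd.DataFrame
    expression: pd.DataFrame
    status: pd.DataFrame
    concordance: pd.DataFrame
    prediction: pd.DataFrame
    roc: dict
    run_log: list[str] = dc_field(default_factory=list)
    summary: dict = dc_field(default_factory=dict)

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if self.config.generator is not None:
            self.cq.to_csv(out / "cq.csv", index=False, float_format="%.4f")
            self.ihc.to_csv(out / "ihc.csv", index=False, float_format="%.4f")
            self.outcomes.to_csv(out / "outcomes.csv", index=False)
        write_expression_table(self.expression, out / "expression.tsv")
        write_status_table(self.status, out / "status.tsv")
        conc = self.concordance.copy()
        for col in ("ppa", "npa", "opa"):
            conc[col] = conc[col].map(self._fmt(self.config.percent_decimals))
        for col in ("spearman_rho",):
            conc[col] = conc[col].map(self._fmt(self.config.correlation_decimals))
        conc["spearman_p"] = conc["spearman_p"].map(self._fmt_p)
        conc.to_csv(out / "concordance.tsv", sep="\t", index=False)
        pred = self.prediction.copy()
        for col in ("sensitivity", "specificity", "rate_high", "rate_low"):
            pred[col] = pred[col].map(self._fmt(self.config.percent_decimals))
        pred["cutoff"] = pred["cutoff"].map(self._fmt(self.config.expression_decimals))
        pred["auc"] = pred["auc"].map(self._fmt(2))
        for col in ("auc_p", "mw_p", "fisher_p"):
            pred[col] = pred[col].map(self._fmt_p)
        pred.to_csv(out / "prediction.tsv", sep="\t", index=False)
        (out / "prediction.json").write_text(json.dumps(self.roc, indent=2, sort_keys=True))
        (out / "run_log.txt").write_text("\n".join(self.run_log) + "\n")
        (out / "summary.json").write_text(json.dumps(self.summary, indent=2, sort_keys=True))
        (out / "config_echo.json").write_text(self.config.model_dump_json(indent=2))
        return out

    @staticmethod
    def _fmt(decimals: int):
        return lambda v: "" if v is None or (isinstance(v, float) and np.isnan(v)) else f"{v:.{decimals}f}"

    @staticmethod
    def _fmt_p(v):
        return "" if v is None or (isinstance(v, float) and np.isnan(v)) else f"{v:.4g}"


def _concordance_stage(
    config: PipelineConfig,
    status: pd.DataFrame,
    expression: pd.DataFrame,
    ihc: pd.DataFrame,
    log: list[str],
) -> pd.DataFrame:
    """Pairwise method agreement per marker (complete-case, drops logged)."""
    values: dict[tuple[str, str], dict[str, float]] = {}
    valid = expression[expression["qc_status"] == "valid"]
    for marker in MARKERS:
        gene = MARKER_GENE[marker]
        values[(marker, ASSAY_RTQPCR)] = {
            str(r.sample_id): float(getattr(r, gene))
            for r in valid.itertuples(index=False)
            if not pd.isna(getattr(r, gene))
        }
        for method, assay in (("digital", ASSAY_QIHC), ("visual", ASSAY_VIHC)):
            sub = ihc[(ihc["marker"] == marker) & (ihc["method"] == method)]
            values[(marker, assay)] = {
                str(r.sample_id): float(r.percent_positive)
                for r in sub.itertuples(index=False)
            }

    statuses: dict[tuple[str, str], dict[str, str]] = {}
    for (marker, assay), grp in status.groupby(["marker", "assay"]):
        statuses[(marker, assay)] = dict(zip(grp["sample_id"], grp["status"]))

    pairs = [
        (ASSAY_RTQPCR, ASSAY_QIHC),
        (ASSAY_RTQPCR, ASSAY_VIHC),
        (ASSAY_QIHC, ASSAY_VIHC),
    ]
    rows = []
    for marker in MARKERS:
        for ref, comp in pairs:
            if (marker, ref) not in statuses or (marker, comp) not in statuses:
                log.append(
                    f"concordance: skipped {marker} {ref} vs {comp} (no status calls)"
                )
                continue
            model = MethodConcordance(
                reference_status=statuses[(marker, ref)],
                comparator_status=statuses[(marker, comp)],
                reference_values=values[(marker, ref)],
                comparator_values=values[(marker, comp)],
                reference_label=ref,
                comparator_label=comp,
                marker=marker,
            )
            res = model.fit()
            row = res.summary().iloc[0].to_dict()
            log.append(
                f"concordance: {marker} {ref} vs {comp}: n={res.table.n}, "
                f"dropped {res.table.n_dropped} incomplete pairs"
            )
            rows.append(row)
    return pd.DataFrame(rows)[CONCORDANCE_COLUMNS]


def _prediction_stage(
    config: PipelineConfig,
    expression: pd.DataFrame,
    ihc: pd.DataFrame,
    outcomes: pd.DataFrame,
    log: list[str],
) -> tuple[pd.DataFrame, dict]:
    """Evaluate each proliferation assay as a pCR predictor."""
    outcome_map = dict(zip(outcomes["sample_id"].astype(str), outcomes["pcr"].astype(int)))
    series: dict[str, dict[str, float]] = {}
    valid = expression[expression["qc_status"] == "valid"]
    series[ASSAY_RTQPCR] = {
        str(r.sample_id): float(r.MKI67)
        for r in valid.itertuples(index=False)
        if not pd.isna(r.MKI67)
    }
    for method, assay in (("digital", ASSAY_QIHC), ("visual", ASSAY_VIHC)):
        sub = ihc[(ihc["marker"] == "Ki67") & (ihc["method"] == method)]
        series[assay] = {
            str(r.sample_id): float(r.percent_positive)
            for r in sub.itertuples(index=False)
        }

    rows, roc_json = [], {}
    for assay, vals in series.items():
        keys = sorted(k for k in vals if k in outcome_map)
        if not keys:
            log.append(f"prediction: skipped {assay} (no paired outcome data)")
            continue
        y = [outcome_map[k] for k in keys]
        if len(set(y)) < 2:
            log.append(f"prediction: skipped {assay} (single-class outcomes)")
            continue
        model = ResponsePredictor(
            values=[vals[k] for k in keys], labels=y, assay=assay, sample_ids=keys
        )
        res = model.fit(config.constraint_axis, config.constraint_level)
        rows.append(res.summary().iloc[0].to_dict())
        roc_json[assay] = {
            "thresholds": res.roc.thresholds.tolist(),
            "sensitivity": res.roc.sensitivity.tolist(),
            "specificity": res.roc.specificity.tolist(),
            "auc": res.auc.auc,
            "cutoff": res.cutoff.cutoff,
            "constraint": res.cutoff.constraint,
        }
        log.append(
            f"prediction: {assay}: n={len(keys)} ({sum(y)} pCR), AUC={res.auc.auc:.3f}, "
            f"cutoff={res.cutoff.cutoff:.3f}, sens={res.cutoff.sensitivity:.1f}%, "
            f"spec={res.cutoff.specificity:.1f}%"
        )
    pred = pd.DataFrame(rows)
    if len(pred):
        pred = pred[PREDICTION_COLUMNS]
    else:
        pred = pd.DataFrame(columns=PREDICTION_COLUMNS)
    return pred, roc_json


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> ReportBundle:
    """Execute every stage; writes outputs when an output directory is known."""
    log: list[str] = [f"markerconcord {__version__}"]
    log.append(f"config: {config.model_dump_json()}")

    if config.generator is not None:
        cohort = generate_cohort(config.generator)
        cq = emit_cq_table(cohort)
        ihc = emit_ihc_table(cohort)
        outcomes = emit_outcome_table(cohort)
        log.append(
            f"simulate: n={len(cohort)} samples over {len(cohort.runs)} runs, "
            f"seed={config.generator.seed}"
        )
    else:
        cq, ihc, outcomes = read_tables(config)
        log.append(f"inputs: cq={config.inputs.cq} ihc={config.inputs.ihc} "
                   f"outcomes={config.inputs.outcomes}")

    expression = quantify(cq, config.qc)
    n_input = len(expression)
    n_valid = int((expression["qc_status"] == "valid").sum())
    n_excluded = n_input - n_valid
    reasons = (
        expression.loc[expression["qc_status"] != "valid", "qc_status"]
        .value_counts()
        .to_dict()
    )
    log.append(
        f"quantify: {n_input} samples, {n_valid} valid, {n_excluded} excluded "
        f"(n_input = n_analyzed + n_excluded: {n_input} = {n_valid} + {n_excluded})"
    )
    for reason, count in sorted(reasons.items()):
        log.append(f"quantify:   {count} x {reason}")

    status = status_table(ihc, expression, config.cutoffs)
    log.append(f"status: {len(status)} marker-status calls")

    concordance = _concordance_stage(config, status, expression, ihc, log)
    prediction, roc_json = _prediction_stage(config, expression, ihc, outcomes, log)

    summary = {
        "version": __version__,
        "n_input": n_input,
        "n_valid": n_valid,
        "n_excluded": n_excluded,
        "exclusion_reasons": reasons,
        "pcr_prevalence_pct": (
            100.0 * float(outcomes["pcr"].mean()) if len(outcomes) else None
        ),
        "concordance": concordance.to_dict(orient="records"),
        "prediction": prediction.to_dict(orient="records"),
    }
    bundle = ReportBundle(
        config=config,
        cq=cq,
        ihc=ihc,
        outcomes=outcomes,
        expression=expression,
        status=status,
        concordance=concordance,
        prediction=prediction,
        roc=roc_json,
        run_log=log,
        summary=summary,
    )
    target = out_dir or config.out_dir
    if target is not None:
        bundle.write(target)
    return bundle
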