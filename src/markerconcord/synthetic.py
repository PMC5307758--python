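"""Synthetic neoadjuvant cohorts with the joint structure the analysis assumes.

Each of the three IHC markers (ER, PR, Ki-67) is modelled by a trivariate
Gaussian copula over three measurement layers — mRNA (RT-qPCR), digital
IHC (qIHC) and visual IHC (vIHC).  Because every observed scale is a
monotone transform of its latent normal score, the configured rank
correlations between layers survive the marginal transforms.  Target rank
correlations are converted to the latent Pearson scale through
``r = 2 sin(pi * rho_s / 6)`` before the copula is built.

Marginals: the mRNA layer is linear on the 40-ΔΔCq scale; the protein
layers use a logistic transform of the latent score into [0, 100] percent
positive nuclei, parametrized by the median percent (location) and a
logit-scale spread.  The Remmele immunoreactive score is derived from the
percent category (0; <10; 10-50; 51-80; >80 -> 0-4) times a staining
intensity (0-3) sampled conditionally on the percentage.

The binary pCR outcome follows a logistic model on the standardized latent
proliferation score (the Ki-67 mRNA-layer z); by default the intercept is
solved numerically so the marginal prevalence equals the configured value.

Raw Cq plates are emitted so that quantification round-trips: with zero
replicate noise the pipeline recovers ``true_expression`` exactly, and
per-run gene offsets applied identically to sample and calibrator wells
cancel.  Assay failure is emulated as a reference-gene Cq shift (too
little RNA), which downstream QC flags as invalid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.optimize import brentq
from scipy.special import expit, logit

from .panel import (
    CALIBRATOR_ID,
    CYCLE_CEILING,
    GENE_PANEL,
    MARKER_GENE,
    MARKERS,
    REF_GENES,
    TARGET_GENES,
)
from .quantification import CQ_COLUMNS

# fixed labels for per-purpose RNG streams derived from the master seed
_STREAMS = {
    "latent": 0,
    "erbb2": 1,
    "intensity": 2,
    "outcome": 3,
    "failure": 4,
    "categorical": 5,
    "runs": 6,
    "replicates": 7,
    "refgenes": 8,
}

IHC_COLUMNS = ["sample_id", "marker", "method", "percent_positive", "intensity", "irs"]
OUTCOME_COLUMNS = ["sample_id", "pcr", "grade", "histotype", "her2_status"]


def pearson_from_spearman(rho_s: float) -> float:
    """Latent Pearson correlation giving Spearman ``rho_s`` under a Gaussian copula."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def percent_category(pct: float) -> int:
    """Remmele percentage category: 0; <10; 10-50; 51-80; >80 -> 0..4."""
    if pct <= 0:
        return 0
    if pct < 10:
        return 1
    if pct <= 50:
        return 2
    if pct <= 80:
        return 3
    return 4


class MarkerLayerParams(BaseModel):
    """Marginals and inter-layer rank-correlation targets for one marker."""

    mrna_mean: float
    mrna_sd: float = Field(ge=0)
    protein_median: dict[str, float]  # {"qihc": %, "vihc": %} at z = 0
    protein_spread: dict[str, float]  # logit-scale slope per method
    rho_mrna_qihc: float = Field(ge=-1, le=1)
    rho_mrna_vihc: float = Field(ge=-1, le=1)
    rho_qihc_vihc: float = Field(ge=-1, le=1)

    @model_validator(mode="after")
    def _check(self) -> "MarkerLayerParams":
        for d in (self.protein_median,):
            for m, v in d.items():
                if not 0 <= v <= 100:
                    raise ValueError(f"protein median {v} for {m} outside [0, 100]")
        return self

    def latent_correlation(self) -> np.ndarray:
        """3x3 latent Pearson matrix over (mRNA, qIHC, vIHC)."""
        a = pearson_from_spearman(self.rho_mrna_qihc)
        b = pearson_from_spearman(self.rho_mrna_vihc)
        c = pearson_from_spearman(self.rho_qihc_vihc)
        return np.array([[1.0, a, b], [a, 1.0, c], [b, c, 1.0]])


class OutcomeLink(BaseModel):
    """Logistic model of pCR on the standardized latent proliferation score.

    ``intercept=None`` means: solve it so the marginal prevalence matches
    the generator's ``pcr_prevalence``.
    """

    intercept: float | None = None
    slope: float = 1.2


class RefGeneParams(BaseModel):
    b2m_mean: float = 23.0
    b2m_sd: float = Field(1.2, ge=0)
    calm2_mean: float = 24.0
    calm2_sd: float = Field(1.2, ge=0)


class CalibratorSettings(BaseModel):
    """Base Cq levels of the per-run calibrator sample (before run offsets)."""

    target_cq: dict[str, float] = Field(
        default_factory=lambda: {"ESR1": 25.0, "PGR": 27.0, "MKI67": 26.0, "ERBB2": 26.0}
    )
    ref_cq: dict[str, float] = Field(
        default_factory=lambda: {"B2M": 23.0, "CALM2": 24.0}
    )


def _default_markers() -> dict[str, MarkerLayerParams]:
    return {
        "ER": MarkerLayerParams(
            mrna_mean=36.0, mrna_sd=2.5,
            protein_median={"qihc": 75.0, "vihc": 75.0},
            protein_spread={"qihc": 6.0, "vihc": 6.0},
            rho_mrna_qihc=0.82, rho_mrna_vihc=0.85, rho_qihc_vihc=0.88,
        ),
        "PR": MarkerLayerParams(
            mrna_mean=33.0, mrna_sd=3.0,
            protein_median={"qihc": 40.0, "vihc": 40.0},
            protein_spread={"qihc": 5.0, "vihc": 5.0},
            rho_mrna_qihc=0.86, rho_mrna_vihc=0.88, rho_qihc_vihc=0.90,
        ),
        "Ki67": MarkerLayerParams(
            mrna_mean=37.0, mrna_sd=1.5,
            protein_median={"qihc": 23.4, "vihc": 35.0},
            protein_spread={"qihc": 1.0, "vihc": 1.0},
            rho_mrna_qihc=0.50, rho_mrna_vihc=0.56, rho_qihc_vihc=0.80,
        ),
    }


class GeneratorConfig(BaseModel):
    """Full specification of a synthetic cohort.

    Defaults mirror the study conditions of the trial population this
    package's analysis is designed around: 101 biopsies, ~18% assay
    failure, pCR prevalence 12/83, and the reported inter-layer rank
    correlations.
    """

    n_samples: int = Field(101, ge=0)
    pcr_prevalence: float = Field(12 / 83, ge=0, le=1)
    marker_params: dict[str, MarkerLayerParams] = Field(default_factory=_default_markers)
    outcome_link: OutcomeLink = Field(default_factory=OutcomeLink)
    ref_gene_params: RefGeneParams = Field(default_factory=RefGeneParams)
    erbb2_mean: float = 31.0
    erbb2_sd: float = Field(1.5, ge=0)
    replicate_sd: float = Field(0.15, ge=0)
    run_count: int = Field(4, ge=1)
    run_gene_offset_sd: float = Field(0.3, ge=0)
    failure_rate: float = Field(18 / 101, ge=0, le=1)
    failure_ref_shift: float = Field(10.0, ge=0)
    calibrator_profile: CalibratorSettings = Field(default_factory=CalibratorSettings)
    grade_frequencies: dict[str, float] = Field(
        default_factory=lambda: {"2": 1 / 3, "3": 2 / 3}
    )
    histotype_frequencies: dict[str, float] = Field(
        default_factory=lambda: {"ductal": 0.85, "lobular": 0.13, "other": 0.02}
    )
    her2_frequencies: dict[str, float] = Field(
        default_factory=lambda: {"negative": 0.83, "positive": 0.17}
    )
    seed: int = Field(0, ge=0, lt=2**31)

    @model_validator(mode="after")
    def _check_psd(self) -> "GeneratorConfig":
        if set(self.marker_params) != set(MARKERS):
            raise ValueError(f"marker_params must cover exactly {MARKERS}")
        for marker, params in self.marker_params.items():
            eig = np.linalg.eigvalsh(params.latent_correlation())
            if eig.min() < -1e-9:
                raise ValueError(
                    f"latent correlation matrix for marker {marker!r} is not "
                    f"positive semi-definite (min eigenvalue {eig.min():.3g})"
                )
        return self

    def rng(self, purpose: str) -> np.random.Generator:
        """Per-purpose stream: a fixed labeled child of the master seed."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, _STREAMS[purpose]]))

    def outcome_intercept(self) -> float:
        """Configured intercept, or the one matching the marginal prevalence."""
        if self.outcome_link.intercept is not None:
            return self.outcome_link.intercept
        if self.pcr_prevalence in (0.0, 1.0):
            return math.inf if self.pcr_prevalence else -math.inf
        nodes, weights = np.polynomial.hermite_e.hermegauss(80)
        w = weights / math.sqrt(2 * math.pi)
        b = self.outcome_link.slope

        def marginal(a: float) -> float:
            return float(np.sum(w * expit(a + b * nodes))) - self.pcr_prevalence

        return brentq(marginal, -30.0, 30.0)


@dataclass
class SyntheticSample:
    sample_id: str
    run_id: str
    latent_z: dict[str, np.ndarray]  # marker -> (z_mrna, z_qihc, z_vihc)
    true_expression: dict[str, float]  # gene -> 40-ΔΔCq value
    true_protein: dict[tuple[str, str], float]  # (marker, method) -> percent
    intensity: dict[tuple[str, str], int | None]
    irs: dict[tuple[str, str], int | None]
    pcr: int
    assay_failed: bool
    grade: str
    histotype: str
    her2_status: str


@dataclass
class SyntheticCohort:
    config: GeneratorConfig
    samples: list[SyntheticSample]
    runs: dict[str, dict[str, float]]  # run_id -> gene -> Cq offset

    def __iter__(self) -> Iterator[SyntheticSample]:
        return iter(self.samples)

    def __len__(self) -> int:
        return len(self.samples)

    def truth_frame(self) -> pd.DataFrame:
        """Wide per-sample table of the generator's ground truth."""
        rows = []
        for s in self.samples:
            row = {
                "sample_id": s.sample_id,
                "run_id": s.run_id,
                "pcr": s.pcr,
                "assay_failed": s.assay_failed,
                "latent_proliferation": s.latent_z["Ki67"][0],
            }
            row.update({g: s.true_expression[g] for g in TARGET_GENES})
            for marker in MARKERS:
                for method in ("qihc", "vihc"):
                    row[f"{marker}_{method}_pct"] = s.true_protein[(marker, method)]
            rows.append(row)
        return pd.DataFrame(rows)


def _intensity_given_percent(pct: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Staining intensity 0-3 sampled conditionally on percent positive."""
    base = 1 + (pct >= 10).astype(int) + (pct >= 50).astype(int)
    jitter = rng.choice([-1, 0, 1], size=len(pct), p=[0.2, 0.6, 0.2])
    out = np.clip(base + jitter, 1, 3)
    out[pct <= 0] = 0
    return out


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Draw a full cohort; deterministic given ``config`` (incl. its seed)."""
    n = config.n_samples
    run_ids = [f"R{i + 1}" for i in range(config.run_count)]
    rng_runs = config.rng("runs")
    offsets = rng_runs.normal(0.0, config.run_gene_offset_sd, (config.run_count, len(GENE_PANEL)))
    runs = {
        rid: {g: float(offsets[i, j]) for j, g in enumerate(GENE_PANEL)}
        for i, rid in enumerate(run_ids)
    }
    if n == 0:
        return SyntheticCohort(config=config, samples=[], runs=runs)

    rng_latent = config.rng("latent")
    latent: dict[str, np.ndarray] = {}
    for marker in MARKERS:  # fixed order
        corr = config.marker_params[marker].latent_correlation()
        # eigendecomposition instead of Cholesky: tolerates singular matrices
        evals, evecs = np.linalg.eigh(corr)
        root = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None)))
        latent[marker] = rng_latent.standard_normal((n, 3)) @ root.T

    expression: dict[str, np.ndarray] = {}
    protein: dict[tuple[str, str], np.ndarray] = {}
    for marker in MARKERS:
        p = config.marker_params[marker]
        expression[MARKER_GENE[marker]] = p.mrna_mean + p.mrna_sd * latent[marker][:, 0]
        for j, method in enumerate(("qihc", "vihc"), start=1):
            med = p.protein_median[method]
            if med <= 0:
                pct = np.zeros(n)
            elif med >= 100:
                pct = np.full(n, 100.0)
            else:
                pct = 100.0 * expit(
                    logit(med / 100.0) + p.protein_spread[method] * latent[marker][:, j]
                )
            protein[(marker, method)] = pct
    expression["ERBB2"] = config.erbb2_mean + config.erbb2_sd * config.rng(
        "erbb2"
    ).standard_normal(n)

    rng_intensity = config.rng("intensity")
    intensity: dict[tuple[str, str], np.ndarray] = {}
    for marker in ("ER", "PR"):  # Ki-67 has no IRS
        for method in ("qihc", "vihc"):
            intensity[(marker, method)] = _intensity_given_percent(
                protein[(marker, method)], rng_intensity
            )

    a = config.outcome_intercept()
    b = config.outcome_link.slope
    z_prolif = latent["Ki67"][:, 0]
    with np.errstate(over="ignore"):
        p_pcr = expit(a + b * z_prolif) if np.isfinite(a) else np.full(n, float(a > 0))
    pcr = (config.rng("outcome").random(n) < p_pcr).astype(int)
    failed = config.rng("failure").random(n) < config.failure_rate

    rng_cat = config.rng("categorical")

    def draw_cat(freqs: dict[str, float]) -> np.ndarray:
        labels = list(freqs)
        probs = np.array([freqs[k] for k in labels], dtype=float)
        probs = probs / probs.sum()
        return rng_cat.choice(labels, size=n, p=probs)

    grade = draw_cat(config.grade_frequencies)
    histotype = draw_cat(config.histotype_frequencies)
    her2 = draw_cat(config.her2_frequencies)

    samples = []
    for i in range(n):
        samples.append(
            SyntheticSample(
                sample_id=f"S{i + 1:04d}",
                run_id=run_ids[i % config.run_count],
                latent_z={m: latent[m][i] for m in MARKERS},
                true_expression={g: float(expression[g][i]) for g in TARGET_GENES},
                true_protein={
                    (m, meth): float(protein[(m, meth)][i])
                    for m in MARKERS
                    for meth in ("qihc", "vihc")
                },
                intensity={
                    (m, meth): (
                        int(intensity[(m, meth)][i]) if (m, meth) in intensity else None
                    )
                    for m in MARKERS
                    for meth in ("qihc", "vihc")
                },
                irs={
                    (m, meth): (
                        int(intensity[(m, meth)][i])
                        * percent_category(float(protein[(m, meth)][i]))
                        if (m, meth) in intensity
                        else None
                    )
                    for m in MARKERS
                    for meth in ("qihc", "vihc")
                },
                pcr=int(pcr[i]),
                assay_failed=bool(failed[i]),
                grade=str(grade[i]),
                histotype=str(histotype[i]),
                her2_status=str(her2[i]),
            )
        )
    return SyntheticCohort(config=config, samples=samples, runs=runs)


def emit_cq_table(
    cohort: SyntheticCohort, config: GeneratorConfig | None = None
) -> pd.DataFrame:
    """Emit the raw triplicate Cq plate for the cohort plus calibrator wells.

    Target-gene Cqs are constructed so the quantification stage recovers
    the generator's true expression::

        Cq[g]_S = meanCq[REF]_S + (40 - E[g]_S)
                  + (Cq[g]_PC - meanCq[REF]_PC) + run_offset + noise

    Run offsets are applied identically to sample and calibrator wells of
    the run, so they cancel downstream.  Failed samples have their
    reference (and hence target) Cqs shifted upward by
    ``failure_ref_shift`` cycles, emulating insufficient RNA.  Constructed
    values above the 40-cycle ceiling are emitted as undetected.
    """
    config = config or cohort.config
    n = len(cohort.samples)
    rng_ref = config.rng("refgenes")
    rp = config.ref_gene_params
    b2m = rng_ref.normal(rp.b2m_mean, rp.b2m_sd, n)
    calm2 = rng_ref.normal(rp.calm2_mean, rp.calm2_sd, n)

    cal = config.calibrator_profile
    cal_mean_ref = float(np.mean(list(cal.ref_cq.values())))

    # deterministic row construction order: calibrators by run, then samples
    centers: list[tuple[str, str, str, float]] = []
    for rid in cohort.runs:
        off = cohort.runs[rid]
        for g in TARGET_GENES:
            centers.append((CALIBRATOR_ID, rid, g, cal.target_cq[g] + off[g]))
        for g in REF_GENES:
            centers.append((CALIBRATOR_ID, rid, g, cal.ref_cq[g] + off[g]))
    for i, s in enumerate(cohort.samples):
        off = cohort.runs[s.run_id]
        shift = config.failure_ref_shift if s.assay_failed else 0.0
        ref_cq = {"B2M": b2m[i] + shift, "CALM2": calm2[i] + shift}
        mean_ref = (ref_cq["B2M"] + ref_cq["CALM2"]) / 2.0
        for g in TARGET_GENES:
            center = (
                mean_ref
                + (CYCLE_CEILING - s.true_expression[g])
                + (cal.target_cq[g] - cal_mean_ref)
                + off[g]
            )
            centers.append((s.sample_id, s.run_id, g, center))
        for g in REF_GENES:
            centers.append((s.sample_id, s.run_id, g, ref_cq[g] + off[g]))

    rng_rep = config.rng("replicates")
    noise = rng_rep.normal(0.0, config.replicate_sd, (len(centers), 3))
    rows = []
    for k, (sample_id, run_id, gene, center) in enumerate(centers):
        for rep in range(3):
            cq = center + noise[k, rep]
            detected = 0.0 < cq <= CYCLE_CEILING
            rows.append(
                {
                    "sample_id": sample_id,
                    "run_id": run_id,
                    "gene": gene,
                    "replicate": rep + 1,
                    "cq": float(cq) if detected else np.nan,
                }
            )
    return pd.DataFrame(rows, columns=CQ_COLUMNS)


def emit_ihc_table(cohort: SyntheticCohort) -> pd.DataFrame:
    """One IHC score record per sample x marker x method (Ki-67 has no IRS)."""
    method_name = {"qihc": "digital", "vihc": "visual"}
    rows = []
    for s in cohort.samples:
        for marker in MARKERS:
            for method in ("qihc", "vihc"):
                rows.append(
                    {
                        "sample_id": s.sample_id,
                        "marker": marker,
                        "method": method_name[method],
                        "percent_positive": s.true_protein[(marker, method)],
                        "intensity": s.intensity[(marker, method)],
                        "irs": s.irs[(marker, method)],
                    }
                )
    return pd.DataFrame(rows, columns=IHC_COLUMNS)


def emit_outcome_table(cohort: SyntheticCohort) -> pd.DataFrame:
    """Per-sample outcome and clinicopathological covariates."""
    rows = [
        {
            "sample_id": s.sample_id,
            "pcr": s.pcr,
            "grade": s.grade,
            "histotype": s.histotype,
            "her2_status": s.her2_status,
        }
        for s in cohort.samples
    ]
    return pd.DataFrame(rows, columns=OUTCOME_COLUMNS)


def recover_outcome_link(cohort: SyntheticCohort) -> tuple[float, float]:
    """Refit the logistic outcome model on the latent proliferation score.

    Diagnostic for generator fidelity: at large n the fitted slope should
    approach the configured one.  Returns (intercept, slope).
    """
    import statsmodels.api as sm

    z = np.array([s.latent_z["Ki67"][0] for s in cohort.samples])
    y = np.array([s.pcr for s in cohort.samples])
    fit = sm.Logit(y, sm.add_constant(z)).fit(disp=0)
    return float(fit.params[0]), float(fit.params[1])
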