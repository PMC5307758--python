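"""Response prediction: ROC analysis with a sensitivity-constrained cutoff.

A continuous proliferation measurement (MKI67 40-ΔΔCq, or a Ki-67
labelling index) is evaluated against pathological complete response.
The ROC curve is built over midpoint thresholds between consecutive
distinct observed values (plus sentinels below the minimum and above the
maximum); a sample is test-positive when its value is at or above the
threshold.  The clinically motivated operating point fixes one axis —
by default sensitivity at 100%, i.e. detect every responder — and
maximizes the other.  The AUC is computed through its rank-sum identity
(favorable pairs, ties counted half) and tested against the no-information
value 0.5 via the normal approximation of the Mann-Whitney statistic.

:class:`ResponsePredictor` is the model object; ``fit()`` returns a
:class:`ResponsePredictionResults` with the curve, AUC, constrained
cutoff, rank test, stratified response rates and a ``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .concordance import FisherResult, fisher_exact


@dataclass
class RocCurve:
    thresholds: np.ndarray   # ascending candidate cutoffs
    sensitivity: np.ndarray  # fraction of responders at/above each threshold
    specificity: np.ndarray  # fraction of non-responders below each threshold
    n_pos: int
    n_neg: int


@dataclass
class CutoffResult:
    cutoff: float
    sensitivity: float  # percent
    specificity: float  # percent
    constraint: str


@dataclass
class RankTestResult:
    u_statistic: float
    p_value: float
    method: str  # "exact" | "normal_approximation"
    n1: int
    n2: int


@dataclass
class AucResult:
    auc: float
    p_vs_half: float


@dataclass
class ResponseTable:
    n_high: int
    n_high_pcr: int
    n_low: int
    n_low_pcr: int
    rate_high: float | None  # percent
    rate_low: float | None
    fisher_p: float


def _clean_groups(values, labels):
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    keep = ~np.isnan(v)
    v, y = v[keep], y[keep]
    y = y.astype(int)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    pos, neg = v[y == 1], v[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need at least one responder and one non-responder")
    return pos, neg


def roc_curve(values: Sequence[float], labels: Sequence[int]) -> RocCurve:
    """ROC over midpoint thresholds; test-positive iff value >= threshold."""
    pos, neg = _clean_groups(values, labels)
    v = np.concatenate([pos, neg])
    distinct = np.unique(v)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate(([distinct[0] - 1.0], mids, [distinct[-1] + 1.0]))
    sens = np.array([(pos >= t).mean() for t in thresholds])
    spec = np.array([(neg < t).mean() for t in thresholds])
    return RocCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        n_pos=len(pos),
        n_neg=len(neg),
    )


def _u_statistic(pos: np.ndarray, neg: np.ndarray) -> float:
    """Favorable pairs for the responders, ties counted half."""
    diff = pos[:, None] - neg[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def auc_with_p(values: Sequence[float], labels: Sequence[int]) -> AucResult:
    """AUC via the rank-sum identity, tested against 0.5.

    The p-value comes from the tie-corrected normal approximation of the
    Mann-Whitney statistic (no continuity correction).  When every value is
    tied the statistic is degenerate and p is reported as 1.
    """
    pos, neg = _clean_groups(values, labels)
    u = _u_statistic(pos, neg)
    auc = u / (len(pos) * len(neg))
    all_vals = np.concatenate([pos, neg])
    if np.all(all_vals == all_vals[0]):
        return AucResult(auc=auc, p_vs_half=1.0)
    res = stats.mannwhitneyu(
        pos, neg, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    return AucResult(auc=float(auc), p_vs_half=float(res.pvalue))


def constrained_cutoff(
    values: Sequence[float],
    labels: Sequence[int],
    fixed_axis: str = "sensitivity",
    level: float = 1.0,
) -> CutoffResult:
    """Best operating point subject to a floor on one ROC axis.

    Among candidate thresholds whose ``fixed_axis`` is at least ``level``,
    the one maximizing the free axis is returned; ties are broken toward
    the larger cutoff.  Fixing sensitivity is always satisfiable (the
    low sentinel classifies everyone positive).
    """
    if fixed_axis not in ("sensitivity", "specificity"):
        raise ValueError(f"unknown axis {fixed_axis!r}")
    curve = roc_curve(values, labels)
    fixed = curve.sensitivity if fixed_axis == "sensitivity" else curve.specificity
    free = curve.specificity if fixed_axis == "sensitivity" else curve.sensitivity
    eligible = np.flatnonzero(fixed >= level - 1e-12)
    if len(eligible) == 0:
        raise ValueError(f"no threshold attains {fixed_axis} >= {level}")
    best_free = free[eligible].max()
    winners = eligible[free[eligible] >= best_free - 1e-12]
    idx = int(winners[np.argmax(curve.thresholds[winners])])
    return CutoffResult(
        cutoff=float(curve.thresholds[idx]),
        sensitivity=100.0 * float(curve.sensitivity[idx]),
        specificity=100.0 * float(curve.specificity[idx]),
        constraint=f"{fixed_axis}>={100.0 * level:g}%",
    )


def mann_whitney(
    group_pos: Sequence[float], group_neg: Sequence[float]
) -> RankTestResult:
    """Two-sided Mann-Whitney U test comparing responders vs non-responders.

    Exact p (full enumeration of the U distribution) for n1+n2 <= 16
    without ties; otherwise the normal approximation with tie and
    continuity correction.  The reported U counts favorable pairs for the
    first group, ties half.
    """
    pos = np.asarray(group_pos, dtype=float)
    neg = np.asarray(group_neg, dtype=float)
    pos, neg = pos[~np.isnan(pos)], neg[~np.isnan(neg)]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both groups must be non-empty")
    u = _u_statistic(pos, neg)
    all_vals = np.concatenate([pos, neg])
    has_ties = len(np.unique(all_vals)) < len(all_vals)
    if len(all_vals) <= 16 and not has_ties:
        res = stats.mannwhitneyu(pos, neg, alternative="two-sided", method="exact")
        method = "exact"
        p = float(res.pvalue)
    elif np.all(all_vals == all_vals[0]):
        method = "normal_approximation"
        p = 1.0
    else:
        res = stats.mannwhitneyu(
            pos, neg, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        method = "normal_approximation"
        p = float(res.pvalue)
    return RankTestResult(
        u_statistic=u, p_value=min(p, 1.0), method=method, n1=len(pos), n2=len(neg)
    )


def response_rates(
    statuses: Mapping[str, str], outcomes: Mapping[str, int]
) -> ResponseTable:
    """pCR rates in the high and low strata with a two-sided Fisher p."""
    n_high = n_high_pcr = n_low = n_low_pcr = 0
    for k, s in statuses.items():
        if k not in outcomes or s is None:
            continue
        y = int(outcomes[k])
        if str(s).lower() in ("high", "positive", "1", "true"):
            n_high += 1
            n_high_pcr += y
        else:
            n_low += 1
            n_low_pcr += y
    fisher = fisher_exact(
        [[n_high_pcr, n_high - n_high_pcr], [n_low_pcr, n_low - n_low_pcr]]
    )
    return ResponseTable(
        n_high=n_high,
        n_high_pcr=n_high_pcr,
        n_low=n_low,
        n_low_pcr=n_low_pcr,
        rate_high=100.0 * n_high_pcr / n_high if n_high else None,
        rate_low=100.0 * n_low_pcr / n_low if n_low else None,
        fisher_p=fisher.p_value,
    )


class ResponsePredictor:
    """Evaluate one continuous assay as a predictor of pCR.

    Parameters
    ----------
    values : per-sample continuous measurement (higher = more proliferative)
    labels : per-sample binary outcome (1 = pCR)
    assay : label used in reports
    """

    def __init__(
        self,
        values: Sequence[float],
        labels: Sequence[int],
        assay: str = "assay",
        sample_ids: Sequence[str] | None = None,
    ) -> None:
        self.values = np.asarray(values, dtype=float)
        self.labels = np.asarray(labels, dtype=int)
        if len(self.values) != len(self.labels):
            raise ValueError("values and labels must align")
        self.assay = assay
        self.sample_ids = (
            [str(s) for s in sample_ids]
            if sample_ids is not None
            else [f"S{i}" for i in range(len(self.values))]
        )

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        value_col: str,
        outcome_col: str = "pcr",
        sample_col: str = "sample_id",
        assay: str | None = None,
    ) -> "ResponsePredictor":
        sub = data[[sample_col, value_col, outcome_col]].dropna()
        return cls(
            values=sub[value_col].to_numpy(),
            labels=sub[outcome_col].to_numpy(),
            assay=assay or value_col,
            sample_ids=sub[sample_col].tolist(),
        )

    def fit(
        self, constraint_axis: str = "sensitivity", constraint_level: float = 1.0
    ) -> "ResponsePredictionResults":
        keep = ~np.isnan(self.values)
        values, labels = self.values[keep], self.labels[keep]
        ids = [s for s, k in zip(self.sample_ids, keep) if k]
        roc = roc_curve(values, labels)
        auc = auc_with_p(values, labels)
        cutoff = constrained_cutoff(values, labels, constraint_axis, constraint_level)
        mw = mann_whitney(values[labels == 1], values[labels == 0])
        statuses = {
            s: ("high" if v >= cutoff.cutoff else "low") for s, v in zip(ids, values)
        }
        outcomes = {s: int(y) for s, y in zip(ids, labels)}
        rates = response_rates(statuses, outcomes)
        return ResponsePredictionResults(
            model=self, roc=roc, auc=auc, cutoff=cutoff, rank_test=mw, rates=rates
        )


@dataclass
class ResponsePredictionResults:
    """ROC, AUC, constrained operating point and stratified response rates."""

    model: ResponsePredictor
    roc: RocCurve
    auc: AucResult
    cutoff: CutoffResult
    rank_test: RankTestResult
    rates: ResponseTable

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "assay": self.model.assay,
                    "n": self.roc.n_pos + self.roc.n_neg,
                    "n_pcr": self.roc.n_pos,
                    "auc": self.auc.auc,
                    "auc_p": self.auc.p_vs_half,
                    "cutoff": self.cutoff.cutoff,
                    "sensitivity": self.cutoff.sensitivity,
                    "specificity": self.cutoff.specificity,
                    "constraint": self.cutoff.constraint,
                    "mw_u": self.rank_test.u_statistic,
                    "mw_p": self.rank_test.p_value,
                    "rate_high": self.rates.rate_high,
                    "rate_low": self.rates.rate_low,
                    "fisher_p": self.rates.fisher_p,
                }
            ]
        )

    def roc_points(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.roc.thresholds,
                "sensitivity": self.roc.sensitivity,
                "specificity": self.roc.specificity,
            }
        )

    def plot_roc(self, ax=None):  # pragma: no cover - optional matplotlib
        """1 - specificity vs sensitivity; requires matplotlib."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(1 - self.roc.specificity, self.roc.sensitivity, drawstyle="steps-post")
        ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.set_title(f"{self.model.assay} (AUC {self.auc.auc:.2f})")
        return ax

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.summary().to_string(index=False)
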