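"""Between-method agreement statistics.

Two binary classification methods are compared in a 2x2 cross-
classification (reference in rows, comparator in columns):

            comparator +   comparator -
  ref +          a              c
  ref -          b              d

with positive percent agreement PPA = 100*a/(a+c), negative percent
agreement NPA = 100*d/(b+d), and overall percent agreement
OPA = 100*(a+d)/n.  Continuous measurements are compared with the
tie-corrected Spearman rank correlation, and contingency tables are tested
with Fisher's exact test (probability-mass two-sided convention; the
Freeman-Halton extension for r x c tables is computed by full enumeration
over margin-fixed tables).

The :class:`MethodConcordance` model bundles these for one method pair and
returns a :class:`ConcordanceResults` object with a ``summary()`` table.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .status import NEGATIVE_STATUSES, POSITIVE_STATUSES


@dataclass
class ConcordanceTable:
    a: int  # both positive
    b: int  # reference negative, comparator positive
    c: int  # reference positive, comparator negative
    d: int  # both negative
    reference_label: str = "reference"
    comparator_label: str = "comparator"
    n_dropped: int = 0  # incomplete pairs excluded

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"count {name}={v} must be a nonnegative integer")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def swapped(self) -> "ConcordanceTable":
        """Exchange the roles of reference and comparator."""
        return ConcordanceTable(
            a=self.a,
            b=self.c,
            c=self.b,
            d=self.d,
            reference_label=self.comparator_label,
            comparator_label=self.reference_label,
            n_dropped=self.n_dropped,
        )


@dataclass
class AgreementMetrics:
    ppa: float | None
    npa: float | None
    opa: float | None
    n: int


@dataclass
class CorrelationResult:
    rho: float | None
    p_value: float | None
    n: int


@dataclass
class FisherResult:
    p_value: float
    degenerate: bool = False  # zero row/column margin -> p = 1 by convention


def _is_positive(status: object) -> bool | None:
    if status is None or (isinstance(status, float) and math.isnan(status)):
        return None
    s = str(status).lower()
    if s in POSITIVE_STATUSES or s in ("1", "true"):
        return True
    if s in NEGATIVE_STATUSES or s in ("0", "false"):
        return False
    return None


def crosstab(
    reference: Mapping[str, object],
    comparator: Mapping[str, object],
    reference_label: str = "reference",
    comparator_label: str = "comparator",
) -> ConcordanceTable:
    """Cross-classify per-sample statuses; incomplete pairs are dropped.

    Statuses may be positive/negative, high/low, or booleans.  Raises when
    no complete pair remains.
    """
    a = b = c = d = 0
    dropped = 0
    keys = set(reference) | set(comparator)
    for k in keys:
        r = _is_positive(reference.get(k))
        m = _is_positive(comparator.get(k))
        if r is None or m is None:
            dropped += 1
            continue
        if r and m:
            a += 1
        elif r and not m:
            c += 1
        elif not r and m:
            b += 1
        else:
            d += 1
    if a + b + c + d == 0:
        raise ValueError("no complete pairs")
    return ConcordanceTable(
        a=a, b=b, c=c, d=d,
        reference_label=reference_label,
        comparator_label=comparator_label,
        n_dropped=dropped,
    )


def agreement_metrics(table: ConcordanceTable) -> AgreementMetrics:
    """PPA/NPA/OPA in percent; undefined ratios are reported as missing."""
    if table.n < 1:
        raise ValueError("empty table")
    ppa = 100.0 * table.a / (table.a + table.c) if table.a + table.c else None
    npa = 100.0 * table.d / (table.b + table.d) if table.b + table.d else None
    opa = 100.0 * (table.a + table.d) / table.n
    return AgreementMetrics(ppa=ppa, npa=npa, opa=opa, n=table.n)


def _exact_spearman_p(xr: np.ndarray, yr: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p for Spearman's rho by full enumeration (n <= 9)."""
    n = len(xr)
    xr = (xr - xr.mean()) / xr.std()
    yr = (yr - yr.mean()) / yr.std()
    perms = np.array(list(itertools.permutations(range(n))))
    rhos = (yr[perms] @ xr) / n
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman_correlation(
    x: Sequence[float], y: Sequence[float]
) -> CorrelationResult:
    """Tie-corrected Spearman rho with a two-sided p.

    The p-value uses the t approximation for n > 9 and exact permutation
    enumeration for n <= 9.  Constant inputs have no defined rank
    correlation and are reported as missing.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(rho=None, p_value=None, n=n)
    rho, p_t = stats.spearmanr(x, y)
    if n <= 9:
        xr = stats.rankdata(x)
        yr = stats.rankdata(y)
        p = _exact_spearman_p(xr, yr, float(rho))
    else:
        p = float(p_t)
    return CorrelationResult(rho=float(rho), p_value=p, n=n)


def _table_log_prob(table: np.ndarray, log_fact: np.ndarray) -> float:
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = table.sum()
    return (
        log_fact[rows].sum()
        + log_fact[cols].sum()
        - log_fact[n]
        - log_fact[table].sum()
    )


def _enumerate_tables(row_margins, col_margins):
    """Yield all nonnegative integer tables with the given margins."""
    r = len(row_margins)
    if r == 1:
        yield [list(col_margins)]
        return
    first, rest = row_margins[0], row_margins[1:]

    def fill(idx, remaining, row, cols_left):
        if idx == len(cols_left) - 1:
            if remaining <= cols_left[idx]:
                yield row + [remaining]
            return
        for v in range(min(remaining, cols_left[idx]) + 1):
            yield from fill(idx + 1, remaining - v, row + [v], cols_left)

    for row in fill(0, first, [], list(col_margins)):
        new_cols = [c - v for c, v in zip(col_margins, row)]
        for sub in _enumerate_tables(rest, new_cols):
            yield [row] + sub


def fisher_exact(table: Sequence[Sequence[int]]) -> FisherResult:
    """Two-sided Fisher exact test for a 2x2 or r x c count table.

    Two-sidedness follows the probability-mass criterion: the p-value sums
    the hypergeometric probabilities of all margin-fixed tables whose point
    probability does not exceed the observed one.  For r x c tables the
    Freeman-Halton generalization is computed by full enumeration, feasible
    at cohort scale.  A zero row or column margin makes the table
    degenerate: p = 1 by convention, flagged on the result.
    """
    t = np.asarray(table, dtype=int)
    if (t < 0).any() or not np.array_equal(t, np.asarray(table, dtype=float)):
        raise ValueError("counts must be nonnegative integers")
    if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
        return FisherResult(p_value=1.0, degenerate=True)
    if t.shape == (2, 2):
        _, p = stats.fisher_exact(t, alternative="two-sided")
        return FisherResult(p_value=float(min(p, 1.0)))
    log_fact = np.concatenate(([0.0], np.cumsum(np.log(np.arange(1, t.sum() + 1)))))
    lp_obs = _table_log_prob(t, log_fact)
    total = 0.0
    for cand in _enumerate_tables(tuple(t.sum(axis=1)), tuple(t.sum(axis=0))):
        lp = _table_log_prob(np.asarray(cand, dtype=int), log_fact)
        if lp <= lp_obs + 1e-9:
            total += math.exp(lp)
    return FisherResult(p_value=float(min(total, 1.0)))


class MethodConcordance:
    """Agreement analysis between two measurement routes for one marker.

    Parameters
    ----------
    reference_status, comparator_status : mapping sample_id -> status
    reference_values, comparator_values : optional mappings of the
        underlying continuous measurements, enabling the rank correlation.
    """

    def __init__(
        self,
        reference_status: Mapping[str, object],
        comparator_status: Mapping[str, object],
        reference_values: Mapping[str, float] | None = None,
        comparator_values: Mapping[str, float] | None = None,
        reference_label: str = "reference",
        comparator_label: str = "comparator",
        marker: str | None = None,
    ) -> None:
        self.reference_status = dict(reference_status)
        self.comparator_status = dict(comparator_status)
        self.reference_values = dict(reference_values or {})
        self.comparator_values = dict(comparator_values or {})
        self.reference_label = reference_label
        self.comparator_label = comparator_label
        self.marker = marker

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        reference: str,
        comparator: str,
        reference_values: str | None = None,
        comparator_values: str | None = None,
        sample_col: str = "sample_id",
        marker: str | None = None,
    ) -> "MethodConcordance":
        idx = data[sample_col].astype(str)
        get = lambda col: dict(zip(idx, data[col])) if col else None
        return cls(
            reference_status=get(reference),
            comparator_status=get(comparator),
            reference_values=get(reference_values),
            comparator_values=get(comparator_values),
            reference_label=reference,
            comparator_label=comparator,
            marker=marker,
        )

    def fit(self) -> "ConcordanceResults":
        table = crosstab(
            self.reference_status,
            self.comparator_status,
            self.reference_label,
            self.comparator_label,
        )
        metrics = agreement_metrics(table)
        correlation = None
        if self.reference_values and self.comparator_values:
            keys = sorted(set(self.reference_values) & set(self.comparator_values))
            if len(keys) >= 3:
                correlation = spearman_correlation(
                    [self.reference_values[k] for k in keys],
                    [self.comparator_values[k] for k in keys],
                )
        fisher = fisher_exact([[table.a, table.c], [table.b, table.d]])
        return ConcordanceResults(
            model=self, table=table, metrics=metrics,
            correlation=correlation, fisher=fisher,
        )


@dataclass
class ConcordanceResults:
    """Fitted agreement statistics for one method pair."""

    model: MethodConcordance
    table: ConcordanceTable
    metrics: AgreementMetrics
    correlation: CorrelationResult | None
    fisher: FisherResult

    def summary(self) -> pd.DataFrame:
        t, m = self.table, self.metrics
        rows = {
            "marker": self.model.marker,
            "reference": t.reference_label,
            "comparator": t.comparator_label,
            "n": t.n,
            "n_dropped": t.n_dropped,
            "a": t.a, "b": t.b, "c": t.c, "d": t.d,
            "ppa": m.ppa, "npa": m.npa, "opa": m.opa,
            "fisher_p": self.fisher.p_value,
            "spearman_rho": self.correlation.rho if self.correlation else None,
            "spearman_p": self.correlation.p_value if self.correlation else None,
        }
        return pd.DataFrame([rows])

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.summary().to_string(index=False)
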