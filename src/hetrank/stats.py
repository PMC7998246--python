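"""Contingency-table association tests for biomarker crosstabs.

Implements the two tests routinely used on pathology crosstabs of a
biomarker category against a clinicopathological variable:

* Pearson's chi-square test of independence on an r x c table,
  statistic ``sum (O - E)^2 / E`` with ``E = row_total * col_total / N``,
  *no* Yates continuity correction, asymptotic p-value from the upper
  tail of the chi-square distribution with ``(r-1)(c-1)`` degrees of
  freedom.
* Fisher's exact test for 2 x 2 tables, two-sided by the
  probability-mass rule: the p-value sums the hypergeometric
  probabilities of every margin-fixed table no more likely than the one
  observed.

The chi-square tail is the regularized upper incomplete gamma function
Q(df/2, x/2); Fisher probabilities are assembled in log space from
log-factorials so that tables with large counts do not underflow.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

__all__ = [
    "ContingencyTable",
    "TestResult",
    "chi2_sf",
    "pearson_chi2",
    "fisher_exact_2x2",
    "crosstab",
]

#: Relative slack when comparing table probabilities against the observed
#: table's probability in the two-sided Fisher rule; absorbs floating-point
#: noise between tables that are exactly equiprobable by symmetry.
_FISHER_REL_TOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """Observed counts of an r x c crosstab with row/column labels."""

    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        if counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValueError(f"need at least a 2x2 table, got shape {counts.shape}")
        if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
            raise ValueError("counts must be non-negative integers")
        counts = np.round(counts).astype(np.int64)
        if counts.sum() == 0:
            raise ValueError("table is empty (grand total 0)")
        if len(self.row_labels) != counts.shape[0] or len(self.col_labels) != counts.shape[1]:
            raise ValueError("label lengths do not match table shape")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "row_labels", tuple(self.row_labels))
        object.__setattr__(self, "col_labels", tuple(self.col_labels))

    @classmethod
    def from_counts(cls, counts, row_labels=None, col_labels=None) -> "ContingencyTable":
        counts = np.asarray(counts)
        rl = tuple(row_labels) if row_labels else tuple(f"r{i}" for i in range(counts.shape[0]))
        cl = tuple(col_labels) if col_labels else tuple(f"c{j}" for j in range(counts.shape[1]))
        return cls(counts=counts, row_labels=rl, col_labels=cl)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.row_labels), columns=list(self.col_labels))


@dataclass(frozen=True)
class TestResult:
    """Outcome of an association test.

    ``statistic`` and ``df`` are None for exact tests, which have no
    asymptotic reference distribution.
    """

    p_value: float
    method: str
    statistic: float | None = None
    df: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


def chi2_sf(x: float, df: int) -> float:
    """Upper tail P(X >= x) of the chi-square distribution.

    Evaluated as the regularized upper incomplete gamma function
    Q(df/2, x/2); for df=1 this reduces to erfc(sqrt(x/2)) and for df=2
    to exp(-x/2).
    """
    if x < 0:
        raise ValueError("chi-square statistic must be non-negative")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(special.gammaincc(df / 2.0, x / 2.0))


def pearson_chi2(table: ContingencyTable) -> TestResult:
    """Pearson chi-square test of independence, without continuity correction.

    Warns when any expected count is below 5 (the usual validity caveat of
    the asymptotic approximation); errors on a zero row or column total,
    for which the degrees of freedom are ill-defined.
    """
    obs = table.counts.astype(float)
    row_tot = obs.sum(axis=1)
    col_tot = obs.sum(axis=0)
    if np.any(row_tot == 0) or np.any(col_tot == 0):
        raise ValueError(
            "table has an empty row or column; drop it before testing"
        )
    n = obs.sum()
    expected = np.outer(row_tot, col_tot) / n
    if np.any(expected < 5):
        warnings.warn(
            f"{int((expected < 5).sum())} cell(s) have expected count < 5; "
            "the asymptotic chi-square p-value may be unreliable",
            stacklevel=2,
        )
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return TestResult(
        statistic=stat, df=df, p_value=chi2_sf(stat, df), method="pearson-chi2"
    )


def _log_hypergeom_pmf(a: int, r1: int, c1: int, n: int) -> float:
    # P(A = a | margins) for the top-left cell of a 2x2 table, via
    # log-factorials: C(r1, a) C(n - r1, c1 - a) / C(n, c1).
    lg = special.gammaln
    return float(
        lg(r1 + 1) - lg(a + 1) - lg(r1 - a + 1)
        + lg(n - r1 + 1) - lg(c1 - a + 1) - lg(n - r1 - c1 + a + 1)
        + lg(c1 + 1) + lg(n - c1 + 1) - lg(n + 1)
    )


def fisher_exact_2x2(table: ContingencyTable) -> TestResult:
    """Two-sided Fisher's exact test for a 2x2 table.

    Enumerates every table with the observed margins and sums the
    hypergeometric probabilities of those no more likely than the observed
    table (probability-mass two-sided rule, the convention of mainstream
    statistics software), allowing a 1e-7 relative tolerance so that
    symmetric equiprobable tables are always included.
    """
    if table.counts.shape != (2, 2):
        raise ValueError(f"Fisher's exact test needs a 2x2 table, got {table.counts.shape}")
    a, b = (int(v) for v in table.counts[0])
    c, d = (int(v) for v in table.counts[1])
    r1, c1, n = a + b, a + c, a + b + c + d
    if min(r1, c1, n - r1, n - c1) <= 0:
        raise ValueError("Fisher's exact test needs positive margins")
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    log_obs = _log_hypergeom_pmf(a, r1, c1, n)
    cutoff = log_obs + math.log1p(_FISHER_REL_TOL)
    p = 0.0
    for k in range(lo, hi + 1):
        lp = _log_hypergeom_pmf(k, r1, c1, n)
        if lp <= cutoff:
            p += math.exp(lp)
    return TestResult(p_value=min(p, 1.0), method="fisher-exact")


def crosstab(
    cases: pd.DataFrame,
    row_var: str,
    col_var: str,
    merge_rows: tuple[str, ...] | None = None,
    merged_label: str | None = None,
    keep_missing_as_level: bool = False,
    missing_label: str = "Unspecified",
    row_order: tuple[str, ...] | None = None,
    col_order: tuple[str, ...] | None = None,
) -> tuple[ContingencyTable, int]:
    """Build the observed-count table for two categorical columns.

    ``merge_rows`` pools the named levels of ``row_var`` into one row
    (e.g. hypo-intense + intermediate vs hyper-intense for a dichotomized
    marker analysis).  Rows with a missing value in either variable are
    dropped and counted, unless ``keep_missing_as_level`` retains them as
    an explicit ``missing_label`` level — the right choice when
    "unspecified" is itself an informative stratum.

    Returns ``(table, n_excluded)``.
    """
    for var in (row_var, col_var):
        if var not in cases.columns:
            raise KeyError(f"column {var!r} not present in the case table")
    sub = cases[[row_var, col_var]].copy()
    if keep_missing_as_level:
        sub = sub.fillna(missing_label)
        n_excluded = 0
    else:
        n_before = len(sub)
        sub = sub.dropna()
        n_excluded = n_before - len(sub)
    if merge_rows:
        merged = merged_label or "/".join(merge_rows)
        sub[row_var] = sub[row_var].where(~sub[row_var].isin(merge_rows), merged)
    ct = pd.crosstab(sub[row_var], sub[col_var])
    if row_order:
        ct = ct.reindex(index=[r for r in row_order if r in ct.index])
    if col_order:
        ct = ct.reindex(columns=[c for c in col_order if c in ct.columns])
    if ct.shape[0] < 2 or ct.shape[1] < 2:
        raise ValueError(
            f"crosstab of {row_var!r} x {col_var!r} has fewer than 2 observed "
            f"levels on one margin (shape {ct.shape})"
        )
    table = ContingencyTable(
        counts=ct.to_numpy(),
        row_labels=tuple(str(x) for x in ct.index),
        col_labels=tuple(str(x) for x in ct.columns),
    )
    return table, n_excluded
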