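"""Survival and association statistics for candidate gene validation.

Provides the Kaplan-Meier product-limit estimator, the two-group log-rank
test, the 91-cutoff minimum-p expression dichotomization scan (integer
percentiles 5..95), and the Pearson chi-square test for 2x2 tables
without continuity correction.

The minimum-p scan deliberately performs no multiple-testing correction
over cutoffs; results carry an explicit caveat flag instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

MINP_CAVEAT = (
    "best p-value selected as minimum over percentile cutoffs; "
    "not corrected for multiple testing"
)


class ClinicalStatsError(ValueError):
    """Raised on invalid survival/association inputs."""


def _as_survival_arrays(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    time = np.asarray(table["time"], dtype=float)
    event = np.asarray(table["event"], dtype=int)
    if (time < 0).any():
        raise ClinicalStatsError("survival times must be non-negative")
    if not np.isin(event, (0, 1)).all():
        raise ClinicalStatsError("event flags must be 0 or 1")
    return time, event


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def km_estimate(table: pd.DataFrame) -> pd.DataFrame:
    """Product-limit survival curve for one group.

    Returns one row per distinct event time with columns ``time``,
    ``n_at_risk``, ``n_events`` and ``survival``; the curve starts at 1
    and is non-increasing.
    """
    if len(table) == 0:
        raise ClinicalStatsError("empty group")
    time, event = _as_survival_arrays(table)
    order = np.argsort(time, kind="mergesort")
    time, event = time[order], event[order]
    rows = []
    surv = 1.0
    n = len(time)
    for t in np.unique(time[event == 1]):
        at_risk = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        surv *= 1.0 - d / at_risk
        rows.append((float(t), at_risk, d, surv))
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])


def km_by_group(table: pd.DataFrame, group) -> dict:
    """Kaplan-Meier curves per group label."""
    group = pd.Series(group, index=table.index)
    return {g: km_estimate(table[group == g]) for g in sorted(group.unique())}


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    p: float
    df: int = 1


def logrank_test(table: pd.DataFrame, group) -> LogRankResult:
    """Standard two-group log-rank test.

    Statistic is ``(sum(O1 - E1))^2 / sum(V)`` over distinct event times,
    referred to chi-square with 1 degree of freedom.
    """
    time, event = _as_survival_arrays(table)
    labels = pd.Series(group, index=table.index)
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ClinicalStatsError(f"log-rank needs exactly 2 groups, got {uniq}")
    in1 = (labels == uniq[0]).to_numpy()
    if in1.sum() == 0 or (~in1).sum() == 0:
        raise ClinicalStatsError("both groups must be non-empty")
    if event.sum() == 0:
        raise ClinicalStatsError("no events observed; log-rank undefined")
    # vectorized O1 - E1 and hypergeometric variance per distinct event time
    te, d = np.unique(time[event == 1], return_counts=True)
    t1, c1 = np.unique(time[(event == 1) & in1], return_counts=True)
    d1 = np.zeros_like(d)
    d1[np.searchsorted(te, t1)] = c1
    sorted_all = np.sort(time)
    sorted_g1 = np.sort(time[in1])
    n_risk = len(time) - np.searchsorted(sorted_all, te, side="left")
    n1_risk = in1.sum() - np.searchsorted(sorted_g1, te, side="left")
    frac = n1_risk / n_risk
    o_minus_e = float((d1 - d * frac).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        v = d * frac * (1 - frac) * (n_risk - d) / (n_risk - 1)
    var = float(np.where(n_risk > 1, v, 0.0).sum())
    if var <= 0:
        return LogRankResult(statistic=0.0, p=1.0)
    stat = o_minus_e**2 / var
    return LogRankResult(statistic=float(stat), p=float(chi2.sf(stat, df=1)))


# ---------------------------------------------------------------------------
# minimum-p cutoff scan
# ---------------------------------------------------------------------------

@dataclass
class CutoffScanResult:
    """Outcome of the repeated log-rank dichotomization scan."""

    table: pd.DataFrame  # percentile, cutoff, n_low, n_high, p, skipped
    best_percentile: int
    best_cutoff: float
    best_p: float
    n_low: int
    n_high: int
    caveat: str = MINP_CAVEAT

    @property
    def n_enumerated(self) -> int:
        return len(self.table)

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def cutoff_scan(
    table: pd.DataFrame, percentiles=tuple(range(5, 96))
) -> CutoffScanResult:
    """Scan integer expression percentiles 5..95 for the minimum log-rank p.

    For each percentile the low group is ``expression <= cutoff`` and the
    high group is ``expression > cutoff``; cutoffs leaving a group empty
    or without any event are skipped but still enumerated. Ties in the
    minimum p are broken by the percentile nearest the median.
    """
    if len(table) < 20:
        raise ClinicalStatsError(f"need >= 20 samples for a cutoff scan, got {len(table)}")
    time, event = _as_survival_arrays(table)
    if event.sum() == 0:
        raise ClinicalStatsError("no events observed; cutoff scan undefined")
    expr = np.asarray(table["expression"], dtype=float)
    if not np.isfinite(expr).all():
        raise ClinicalStatsError("expression must be finite")
    rows = []
    for q in percentiles:
        cutoff = float(np.percentile(expr, q))
        low = expr <= cutoff
        n_low, n_high = int(low.sum()), int((~low).sum())
        if n_low == 0 or n_high == 0:
            rows.append((q, cutoff, n_low, n_high, np.nan, "empty group"))
            continue
        if event[low].sum() == 0 or event[~low].sum() == 0:
            rows.append((q, cutoff, n_low, n_high, np.nan, "no events in a group"))
            continue
        res = logrank_test(table, np.where(low, "low", "high"))
        rows.append((q, cutoff, n_low, n_high, res.p, ""))
    scan = pd.DataFrame(
        rows, columns=["percentile", "cutoff", "n_low", "n_high", "p", "skipped"]
    )
    valid = scan[scan["skipped"] == ""]
    if valid.empty:
        raise ClinicalStatsError("every cutoff was skipped; no valid dichotomization")
    best_p = valid["p"].min()
    ties = valid[valid["p"] == best_p]
    best = ties.loc[
        sorted(ties.index, key=lambda i: (abs(int(ties.loc[i, "percentile"]) - 50),
                                          int(ties.loc[i, "percentile"])))[0]
    ]
    return CutoffScanResult(
        table=scan,
        best_percentile=int(best["percentile"]),
        best_cutoff=float(best["cutoff"]),
        best_p=float(best["p"]),
        n_low=int(best["n_low"]),
        n_high=int(best["n_high"]),
    )


# ---------------------------------------------------------------------------
# 2x2 association
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]] with optional row/column labels."""

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("row1", "row2")
    col_labels: tuple[str, str] = ("low", "high")

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in counts):
            raise ClinicalStatsError(f"counts must be non-negative integers, got {counts}")
        if sum(counts) == 0:
            raise ClinicalStatsError("contingency table is empty")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    p: float
    df: int = 1


def chi_square_2x2(table) -> Chi2Result:
    """Pearson chi-square for a 2x2 table, no continuity correction.

    ``chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))`` with a chi-square(1)
    reference. Accepts a :class:`ContingencyTable2x2` or any 2x2
    array-like ``[[a, b], [c, d]]``.
    """
    if isinstance(table, ContingencyTable2x2):
        arr = table.as_array()
    else:
        arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ClinicalStatsError(f"expected a 2x2 table, got shape {arr.shape}")
    if (arr < 0).any():
        raise ClinicalStatsError("counts must be non-negative")
    a, b = arr[0]
    c, d = arr[1]
    n = arr.sum()
    margins = np.array([a + b, c + d, a + c, b + d])
    if (margins == 0).any():
        raise ClinicalStatsError("a table margin is zero; chi-square undefined")
    stat = n * (a * d - b * c) ** 2 / margins.prod()
    return Chi2Result(statistic=float(stat), p=float(chi2.sf(stat, df=1)))
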