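"""Error-rate statistics for the two-period order-entry comparison.

Implements the four exposure units used to express medication-error rates
(patient-day, medication-day, order, ordered medication), rate ratios with
Miettinen's test-based confidence intervals, the uncorrected Pearson 2x2
chi-square, the Mantel-extension chi-square for linear trend over ordered
severity categories, the Mann-Whitney rank test with an exact small-sample
permutation p, per-patient error summaries and warning-compliance rates.

Conventions follow the epidemiological report the package reproduces: the
rate ratio is the NOE-period rate divided by the POE-period rate, so values
below one mean fewer errors under nurse order entry; the rate difference
``d`` is the absolute difference of the two rates in percentage points.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

UNITS = ("patient_day", "medication_day", "order", "ordered_medication")

NONINTERCEPTED = "nonintercepted"


class DegenerateTableError(ValueError):
    """A contingency table with an empty margin (no test possible)."""


class UndefinedRateRatioError(ZeroDivisionError):
    """Reference-period rate is zero: the rate ratio is undefined."""


@dataclass(frozen=True)
class UnitCounts:
    """Erroneous and total counts of one exposure unit in one period."""

    unit: str
    erroneous: int
    total: int
    period: str = ""

    def __post_init__(self):
        if not 0 <= self.erroneous <= self.total:
            raise ValueError(
                f"need 0 <= erroneous <= total, got {self.erroneous}/{self.total}"
            )

    @property
    def rate(self) -> float:
        return self.erroneous / self.total


@dataclass(frozen=True)
class RateComparison:
    """Paired-period comparison of one unit's error rates."""

    unit: str
    counts_poe: UnitCounts
    counts_noe: UnitCounts
    rr: float
    rate_difference_d: float      # percentage points, absolute
    ci_low: float
    ci_high: float
    chi2: float
    p: float
    level: float = 0.95


def count_units(
    classifications: pd.DataFrame,
    lines: pd.DataFrame,
    unit: str,
    status: str | Iterable[str] = NONINTERCEPTED,
    period: str = "",
) -> UnitCounts:
    """Count erroneous and total units of the requested exposure unit.

    A coarser unit (order, medication-day, patient-day) is erroneous as soon
    as one of its constituent medication lines is erroneous.  ``status``
    selects which classifications count as erroneous (nonintercepted by
    default; pass a list to pool categories, e.g. all intercepted ones).
    """
    if unit not in UNITS:
        raise ValueError(f"unknown unit {unit!r}; expected one of {UNITS}")
    statuses = {status} if isinstance(status, str) else set(status)
    merged = lines.merge(
        classifications[["ordered_medication_id", "interception"]],
        on="ordered_medication_id",
        how="left",
        validate="one_to_one",
    )
    erroneous = merged["interception"].isin(statuses)

    if unit == "ordered_medication":
        return UnitCounts(unit, int(erroneous.sum()), len(merged), period)
    keys = {
        "order": ["order_id"],
        "patient_day": ["patient_id", "day"],
        "medication_day": ["patient_id", "day", "drug"],
    }[unit]
    grouped = merged.assign(err=erroneous).groupby(keys)["err"].any()
    return UnitCounts(unit, int(grouped.sum()), len(grouped), period)


def rate_ratio(err_a: int, n_a: int, err_b: int, n_b: int) -> float:
    """(err_b/n_b) / (err_a/n_a): period-b rate relative to period-a."""
    if n_a <= 0 or n_b <= 0:
        raise ValueError("denominators must be positive")
    if err_a == 0:
        raise UndefinedRateRatioError(
            "reference-period error count is zero; rate ratio undefined"
        )
    return (err_b / n_b) / (err_a / n_a)


def pearson_chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Uncorrected Pearson chi-square of a 2x2 table, with 1-df p-value.

    Table layout: rows are groups, columns outcomes — (a, b) / (c, d).
    """
    n = a + b + c + d
    margins = [a + b, c + d, a + c, b + d]
    if any(m == 0 for m in margins):
        raise DegenerateTableError(f"empty margin in table ({a},{b},{c},{d})")
    chi2 = n * (a * d - b * c) ** 2 / math.prod(margins)
    return chi2, float(sps.chi2.sf(chi2, df=1))


def poisson_rate_chi2(err_a: int, n_a: int, err_b: int, n_b: int) -> tuple[float, float]:
    """Person-time chi-square: events split binomially by exposure share.

    Conditional on the total event count, under equal rates the period-a
    events are Binomial(m, n_a/(n_a+n_b)); the statistic is the squared
    standardized deviation.  This is the test implied by treating events
    per unit exposure as Poisson.
    """
    m = err_a + err_b
    if m == 0:
        raise DegenerateTableError("no events in either period")
    p = n_a / (n_a + n_b)
    chi2 = (err_a - m * p) ** 2 / (m * p * (1 - p))
    return chi2, float(sps.chi2.sf(chi2, df=1))


def miettinen_ci(rr: float, chi2: float, level: float = 0.95) -> tuple[float, float]:
    """Test-based confidence interval RR^(1 ± z/χ) (Miettinen).

    χ is the square root of the chi-square statistic of the null-hypothesis
    test on the same counts; z the standard-normal quantile for ``level``.
    """
    if rr < 0:
        raise ValueError("rate ratio cannot be negative")
    if rr == 0:
        raise DegenerateTableError(
            "zero rate ratio (no events in the comparison period): "
            "test-based CI undefined"
        )
    if chi2 <= 0:
        raise DegenerateTableError(
            "chi-square is zero: rates identical, test-based CI undefined"
        )
    z = sps.norm.ppf(0.5 + level / 2)
    chi = math.sqrt(chi2)
    bounds = sorted((rr ** (1 - z / chi), rr ** (1 + z / chi)))
    return bounds[0], bounds[1]


def compare_rates(
    unit: str,
    counts_poe: UnitCounts,
    counts_noe: UnitCounts,
    level: float = 0.95,
    ci_chi2: str = "pearson",
) -> RateComparison:
    """Full paired-period comparison: RR, d, chi-square and test-based CI.

    ``ci_chi2`` selects the chi-square feeding Miettinen's approximation:
    ``"pearson"`` (2x2 on erroneous/non-erroneous counts — the reference
    method, which reproduces the published intervals) or ``"poisson"``
    (person-time variant).
    """
    a, n_a = counts_poe.erroneous, counts_poe.total
    b, n_b = counts_noe.erroneous, counts_noe.total
    rr = rate_ratio(a, n_a, b, n_b)
    if ci_chi2 == "pearson":
        chi2, p = pearson_chi2_2x2(a, n_a - a, b, n_b - b)
    elif ci_chi2 == "poisson":
        chi2, p = poisson_rate_chi2(a, n_a, b, n_b)
    else:
        raise ValueError(f"unknown ci_chi2 {ci_chi2!r}")
    low, high = miettinen_ci(rr, chi2, level)
    d = abs(counts_poe.rate - counts_noe.rate) * 100.0
    return RateComparison(
        unit=unit,
        counts_poe=counts_poe,
        counts_noe=counts_noe,
        rr=rr,
        rate_difference_d=d,
        ci_low=low,
        ci_high=high,
        chi2=chi2,
        p=p,
        level=level,
    )


def mantel_trend_chi2(
    table: np.ndarray | Sequence[Sequence[int]],
    scores: Optional[Sequence[float]] = None,
    corrected: bool = False,
) -> tuple[float, float]:
    """Mantel-extension (Cochran-Armitage-type) 1-df chi-square for trend.

    ``table`` has two rows (the compared groups) and one column per ordered
    category; ``scores`` default to 1..K.  The statistic tests a linear
    trend in the proportion belonging to the first row across categories.
    With ``corrected=False`` (default) the score-test variance is used, so
    a two-category table reproduces the uncorrected Pearson 2x2 chi-square
    exactly; ``corrected=True`` applies Mantel's (N−1)/N hypergeometric
    variance.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] < 2:
        raise ValueError("table must be 2 x K with K >= 2 ordered categories")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if t.sum(axis=1).min() == 0:
        raise DegenerateTableError("one group has no observations")
    s = np.arange(1, t.shape[1] + 1, dtype=float) if scores is None else np.asarray(
        scores, dtype=float
    )
    if len(s) != t.shape[1]:
        raise ValueError("one score per category required")
    n_k = t.sum(axis=0)
    n = n_k.sum()
    r = t[0].sum()
    p = r / n
    obs = float(s @ t[0])
    exp = p * float(s @ n_k)
    var = p * (1 - p) * (float(s**2 @ n_k) - float(s @ n_k) ** 2 / n)
    if corrected:
        var *= n / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = (obs - exp) ** 2 / var
    return chi2, float(sps.chi2.sf(chi2, df=1))


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    diff = a[:, None] - b[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def mann_whitney(
    a: Sequence[float], b: Sequence[float], exact_max_n: int = 10
) -> tuple[float, float]:
    """Mann-Whitney U with a two-sided p-value.

    Small samples (combined n ≤ ``exact_max_n``) use the exact permutation
    distribution of U (ties handled by enumeration); larger samples use the
    tie-corrected normal approximation.  Returns (U of the first sample, p).
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    u = _u_statistic(x, y)
    n = len(x) + len(y)
    if n <= exact_max_n:
        pooled = np.concatenate([x, y])
        mu = len(x) * len(y) / 2.0
        extreme = total = 0
        for idx in itertools.combinations(range(n), len(x)):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            u_perm = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u_perm - mu) >= abs(u - mu) - 1e-12:
                extreme += 1
        return u, extreme / total
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):     # every value tied: no evidence either way
        return u, 1.0
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class PerPatientSummary:
    median: float
    q25: float
    q75: float
    fraction_error_free: float
    n_patients: int


def summarize_per_patient(counts: Sequence[int]) -> PerPatientSummary:
    """Median, quartiles and error-free fraction of per-patient error counts."""
    arr = np.asarray(counts, dtype=float)
    if arr.size == 0:
        raise ValueError("no patients to summarize")
    q25, med, q75 = np.percentile(arr, [25, 50, 75])
    return PerPatientSummary(
        median=float(med),
        q25=float(q25),
        q75=float(q75),
        fraction_error_free=float((arr == 0).mean()),
        n_patients=int(arr.size),
    )


def per_patient_summary(
    classifications: pd.DataFrame,
    lines: pd.DataFrame,
    patients: pd.DataFrame,
    status: str = NONINTERCEPTED,
) -> PerPatientSummary:
    """Per-patient nonintercepted-error summary over the full cohort.

    Patients without a single erroneous line contribute a zero count, which
    is why the patient table (not just the lines) is required.
    """
    merged = lines.merge(
        classifications[["ordered_medication_id", "interception"]],
        on="ordered_medication_id",
    )
    err_per_patient = (
        merged[merged["interception"] == status].groupby("patient_id").size()
    )
    counts = (
        err_per_patient.reindex(patients["patient_id"], fill_value=0)
        .astype(int)
        .to_numpy()
    )
    return summarize_per_patient(counts)


def compliance_rate(responses: Iterable[str]) -> float:
    """Fraction of resolved warnings the prescriber complied with."""
    tally = pd.Series(list(responses)).value_counts()
    complied = int(tally.get("complied", 0))
    ignored = int(tally.get("ignored", 0))
    if complied + ignored == 0:
        raise ValueError("no resolved warnings: compliance rate undefined")
    return complied / (complied + ignored)
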