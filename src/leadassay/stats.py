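"""Accuracy and validation statistics.

Device accuracy is assessed by repeated measurement of samples of known
concentration: the mean of the measured values carries a Student-t confidence
interval, CI = mean +/- t_score * se, two-tailed, because the sample sizes
are far below the n ~ 30 where a z interval would be defensible.  Field
performance against the reference laboratory method (atomic absorption
spectroscopy) is quantified with the Pearson correlation coefficient.

With only two repeats a confidence interval is not meaningful; the summary
then reports the mean and raw values but declines the CI.  The p-value is a
two-tailed one-sample t-test of the mean against the nominal concentration
and is flagged provisional: it is one defensible recipe, not a uniquely
determined one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class AccuracySummary:
    nominal_ppb: float
    n: int
    mean: float
    se: float
    t_score: float
    ci_half_width: float  # NaN when declined (n == 2)
    p_value: float  # NaN when declined
    confidence: float
    ci_declined: bool = False
    p_value_method: str = "one-sample two-tailed t-test vs nominal (provisional)"
    values: tuple[float, ...] = ()


def t_critical(confidence: float, n: int) -> float:
    """Two-tailed Student-t critical value at df = n - 1."""
    if n < 2:
        raise StatsError("t critical value requires n >= 2")
    if not 0.0 < confidence < 1.0:
        raise StatsError("confidence must be in (0, 1)")
    return float(sps.t.ppf(0.5 + confidence / 2.0, df=n - 1))


def accuracy_summary(
    measurements,
    nominal: float,
    confidence: float = 0.95,
) -> AccuracySummary:
    """Repeated-measurement accuracy at one nominal concentration.

    mean, se = sd/sqrt(n), and CI half-width = t_critical * se.  With n == 2
    the CI and p-value are declined (reported NaN) — two points do not
    support a meaningful interval — but the mean and raw values are kept.
    """
    x = np.asarray(list(measurements), dtype=float)
    n = x.size
    if n < 2:
        raise StatsError("accuracy summary requires n >= 2 measurements")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    se = sd / math.sqrt(n)
    tcrit = t_critical(confidence, n)
    if n == 2:
        return AccuracySummary(
            nominal_ppb=float(nominal), n=n, mean=mean, se=se, t_score=tcrit,
            ci_half_width=float("nan"), p_value=float("nan"),
            confidence=confidence, ci_declined=True, values=tuple(x),
        )
    if sd == 0.0:
        p = 1.0 if mean == float(nominal) else 0.0
    else:
        p = float(sps.ttest_1samp(x, float(nominal)).pvalue)
    return AccuracySummary(
        nominal_ppb=float(nominal), n=n, mean=mean, se=se, t_score=tcrit,
        ci_half_width=tcrit * se, p_value=p, confidence=confidence,
        values=tuple(x),
    )


def pearson_correlation(x, y) -> float:
    """Sample Pearson correlation between device and reference values."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size:
        raise StatsError("input lengths differ")
    if x.size < 3:
        raise StatsError("Pearson correlation requires >= 3 pairs")
    if x.std() == 0.0 or y.std() == 0.0:
        raise StatsError("zero variance input")
    return float(sps.pearsonr(x, y).statistic)
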