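"""Reliability and inferential statistics for the damage-indicator layer.

Test-retest reliability of two baseline visits is summarized by the
coefficient of variation (CV%), the intraclass correlation coefficient, and
the standard error of measurement.  The ICC model is fixed to ICC(3,1) --
two-way mixed effects, consistency, single measurement:

    ICC(3,1) = (MS_subjects - MS_error) / (MS_subjects + (k-1) MS_error)

with the mean squares from the subjects x visits two-way ANOVA, and
SEm = SD_pooled * sqrt(1 - ICC).  Identical test-retest data with zero
between-subject variance (e.g. a soreness scale at floor) are reported as
CV 0, SEm 0, ICC 1.0 rather than NaN, and flagged as degenerate.

Time-course comparisons use a classical one-way repeated-measures ANOVA
(sphericity assumed) and two-tailed paired t-tests; group changes are
expressed as percent change of the means.  A-priori power for a paired
design comes from the noncentral t distribution with noncentrality
d_z * sqrt(n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class ReliabilityReport:
    """Test-retest reliability summary for one indicator."""

    cv_pct: float
    sem: float
    icc: float
    icc_model: str = "ICC(3,1)"
    degenerate: bool = False
    n: int = 0


def _two_way_mean_squares(data: np.ndarray):
    """(MS_rows, MS_cols, MS_error) for a subjects x measurements table."""
    n, k = data.shape
    grand = data.mean()
    ss_rows = k * ((data.mean(axis=1) - grand) ** 2).sum()
    ss_cols = n * ((data.mean(axis=0) - grand) ** 2).sum()
    ss_tot = ((data - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    return ms_rows, ms_cols, ms_err


def icc_3_1(data: np.ndarray) -> float:
    """ICC(3,1): two-way mixed, consistency, single measurement."""
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    if n < 2 or k < 2:
        raise StatsError("ICC needs at least 2 subjects and 2 measurements")
    ms_rows, _, ms_err = _two_way_mean_squares(data)
    denom = ms_rows + (k - 1) * ms_err
    if denom <= 0:
        return 1.0    # identical measurements with zero subject variance
    return float((ms_rows - ms_err) / denom)


def test_retest_reliability(visit1, visit2) -> ReliabilityReport:
    """CV%, SEm, and ICC(3,1) for two paired visits.

    CV% is the mean over subjects of (SD of the subject's two values /
    mean of the two values) x 100, with 0/0 taken as 0.  A subject with a
    zero mean but nonzero spread makes the CV undefined.
    """
    v1 = np.asarray(visit1, dtype=float)
    v2 = np.asarray(visit2, dtype=float)
    if v1.shape != v2.shape or v1.ndim != 1:
        raise StatsError("visits must be equal-length 1-D arrays")
    n = v1.size
    if n < 2:
        raise StatsError("need at least 2 subjects")
    pair = np.column_stack([v1, v2])
    sd = pair.std(axis=1, ddof=1)
    mean = pair.mean(axis=1)
    cv = np.zeros(n)
    nonzero = np.abs(mean) > 1e-12
    cv[nonzero] = sd[nonzero] / np.abs(mean[nonzero]) * 100.0
    if (~nonzero & (sd > 1e-12)).any():
        raise StatsError("CV undefined: a subject has zero mean but "
                         "nonzero test-retest spread")
    cv_pct = float(cv.mean())

    degenerate = np.allclose(v1, v2)
    if degenerate and np.allclose(v1, v1.mean()):
        return ReliabilityReport(cv_pct=0.0, sem=0.0, icc=1.0,
                                 degenerate=True, n=n)
    icc = icc_3_1(pair)
    pooled_sd = float(np.sqrt(0.5 * (v1.var(ddof=1) + v2.var(ddof=1))))
    sem = pooled_sd * np.sqrt(max(0.0, 1.0 - icc))
    return ReliabilityReport(cv_pct=cv_pct, sem=float(sem), icc=float(icc),
                             degenerate=degenerate, n=n)


def rm_anova_oneway(data) -> tuple[float, int, int, float]:
    """Classical one-way repeated-measures ANOVA on a complete
    subjects x timepoints matrix; returns (F, df1, df2, p).

    F = MS_time / MS_error with df (t-1) and (n-1)(t-1); sphericity is
    assumed.  With two timepoints F equals the squared paired t statistic.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise StatsError("data must be a subjects x timepoints matrix")
    if np.isnan(data).any():
        raise StatsError("repeated-measures ANOVA requires complete data")
    n, k = data.shape
    if n < 2 or k < 2:
        raise StatsError("need at least 2 subjects and 2 timepoints")
    _, ms_time, ms_err = _two_way_mean_squares(data)
    df1, df2 = k - 1, (n - 1) * (k - 1)
    if ms_err <= 0:
        # no residual variance: any timepoint effect is infinitely strong
        f = np.inf if ms_time > 0 else 0.0
        return f, df1, df2, 0.0 if ms_time > 0 else 1.0
    f = float(ms_time / ms_err)
    p = float(sps.f.sf(f, df1, df2))
    return f, df1, df2, p


def paired_t(pre, post) -> tuple[float, int, float, float]:
    """Two-tailed paired t-test; returns (t, df, p, mean_diff).

    Zero variance of the differences is degenerate: reported as t = +/-inf
    with p = 0 when the mean difference is nonzero, and t = 0, p = 1 when
    the samples are identical.
    """
    a = np.asarray(pre, dtype=float)
    b = np.asarray(post, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise StatsError("paired samples must be equal-length 1-D arrays")
    n = a.size
    if n < 2:
        raise StatsError("need at least 2 pairs")
    d = b - a
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd < 1e-300:
        if abs(md) < 1e-300:
            return 0.0, df, 1.0, md
        return float(np.sign(md)) * np.inf, df, 0.0, md
    t = md / (sd / np.sqrt(n))
    p = float(2 * sps.t.sf(abs(t), df))
    return float(t), df, p, md


def percent_change(pre: float, post: float) -> float:
    """100 * (post - pre) / pre; invariant to common scaling of both."""
    if pre == 0:
        raise StatsError("percent change undefined for a zero baseline")
    return 100.0 * (post - pre) / pre


def paired_power(d: float, n: int, alpha: float = 0.05) -> float:
    """Power of a two-tailed paired t-test at effect size d_z and n pairs."""
    if d <= 0:
        raise StatsError("effect size must be > 0")
    if not 0 < alpha < 1:
        raise StatsError("alpha must be in (0, 1)")
    if n < 2:
        raise StatsError("need n >= 2 pairs")
    df = n - 1
    nc = d * np.sqrt(n)
    tcrit = sps.t.isf(alpha / 2, df)
    return float(sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))


def required_sample_size(d: float, power: float = 0.8,
                         alpha: float = 0.05, n_max: int = 10_000) -> int:
    """Smallest n with paired_power(d, n) >= power."""
    if not 0 < power < 1:
        raise StatsError("target power must be in (0, 1)")
    for n in range(2, n_max + 1):
        if paired_power(d, n, alpha) >= power:
            return n
    raise StatsError(f"power {power} not reachable with n <= {n_max}")
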