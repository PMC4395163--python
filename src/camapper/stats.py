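"""The study-style statistical toolbox.

Continuous measures are summarized as mean +/- SEM and compared with a paired
t-test (two conditions within heart) or a one-way repeated-measures ANOVA
with unadjusted LSD pairwise comparisons (several conditions within heart);
binary inducibility across conditions is compared with Cochran's Q test.
Significance threshold alpha = 0.05 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

ALPHA = 0.05


@dataclass
class SummaryStats:
    mean: float
    sem: float
    n: int

    @property
    def significant_nonzero(self) -> bool:
        return self.sem > 0 and abs(self.mean) / self.sem > 1.96


@dataclass
class RMAnovaResult:
    f_stat: float
    df: tuple[int, int]
    p: float
    pairwise: list  # (i, j, mean_diff, t, p_unadjusted)


@dataclass
class CochranQResult:
    q_stat: float
    df: int
    p: float
    undefined: bool = False


def mean_sem(values) -> SummaryStats:
    """Mean and standard error of the mean (sample SD / sqrt(n), n-1
    denominator).  Requires n >= 2; a single observation has no SEM."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("undefined SEM: need at least 2 values")
    return SummaryStats(float(x.mean()), float(x.std(ddof=1) / np.sqrt(x.size)), int(x.size))


def paired_t(x, y) -> tuple[float, int, float]:
    """Two-sided paired t-test; returns (t, df, p).

    All-zero differences (x identical to y) return t=0, p=1; a nonzero
    constant difference has zero variance and an undefined (infinite) t,
    which is raised as an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired t-test needs two equal-length 1-D samples")
    if x.size < 2:
        raise ValueError("paired t-test needs n >= 2")
    d = x - y
    if np.all(d == 0):
        return 0.0, int(x.size - 1), 1.0
    if d.std(ddof=1) == 0:
        raise ValueError("zero-variance nonzero differences: t undefined")
    res = sps.ttest_rel(x, y)
    return float(res.statistic), int(x.size - 1), float(res.pvalue)


def rm_anova_lsd(table) -> RMAnovaResult:
    """One-way repeated-measures ANOVA with unadjusted LSD pairwise t-tests.

    ``table`` is subjects x conditions; rows containing NaN are dropped
    (listwise deletion).  Total variation is partitioned into condition,
    subject and error sums of squares; F = MS_conditions / MS_error with
    df = (k-1, (k-1)(n-1)).  LSD compares each condition pair with
    t = (mean_i - mean_j) / sqrt(2 MS_error / n) on the error df, two-sided,
    with no multiplicity adjustment (that is what LSD means).
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a subjects x conditions matrix with >= 2 conditions")
    complete = ~np.isnan(x).any(axis=1)
    x = x[complete]
    n, k = x.shape
    if n < 2:
        raise ValueError("fewer than 2 complete subject rows")
    grand = x.mean()
    ss_cond = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((x - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    df_cond = k - 1
    df_err = (k - 1) * (n - 1)
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err
    if ms_err <= 0:
        f = float("inf") if ms_cond > 0 else 0.0
        p = 0.0 if ms_cond > 0 else 1.0
    else:
        f = float(ms_cond / ms_err)
        p = float(sps.f.sf(f, df_cond, df_err))
    pairwise = []
    means = x.mean(axis=0)
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(means[i] - means[j])
            if ms_err <= 0:
                t = float("inf") if diff != 0 else 0.0
                pij = 0.0 if diff != 0 else 1.0
            else:
                t = diff / np.sqrt(2.0 * ms_err / n)
                pij = float(2.0 * sps.t.sf(abs(t), df_err))
            pairwise.append((i, j, diff, float(t), pij))
    return RMAnovaResult(f, (df_cond, df_err), p, pairwise)


def cochran_q(binary) -> CochranQResult:
    """Cochran's Q test for k related binary samples.

    Q = (k-1) [k * sum(C_j^2) - N^2] / (k N - sum(R_i^2)) with C_j the
    condition (column) totals, R_i the subject (row) totals and N the grand
    total; p from chi-square with k-1 df.  Rows that are all 0 or all 1
    contribute nothing; if every row is constant the statistic is undefined.
    At k=2 Q equals the McNemar statistic without continuity correction.
    """
    x = np.asarray(binary, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a subjects x conditions 0/1 matrix with >= 2 conditions")
    if not np.isin(x, (0, 1)).all():
        raise ValueError("entries must be 0/1")
    n_subj, k = x.shape
    col = x.sum(axis=0)
    row = x.sum(axis=1)
    big_n = x.sum()
    denom = k * big_n - (row**2).sum()
    if denom == 0:
        # every row constant (equivalently: identical columns) — the numerator
        # is 0 too, so Q = 0/0; by continuity report the null value, flagged
        return CochranQResult(0.0, k - 1, 1.0, undefined=True)
    q = (k - 1) * (k * (col**2).sum() - big_n**2) / denom
    p = float(sps.chi2.sf(q, k - 1))
    return CochranQResult(float(q), k - 1, p)
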