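"""Normality-gated paired comparisons, ICC/SEM reliability, report tables.

Pre/post comparisons use the two-tailed paired t-test when the paired
differences pass a Shapiro-Wilk normality check at alpha = 0.05, and the
Wilcoxon signed-rank test otherwise (zero differences dropped, mid-rank
ties, exact p for n <= 25 without ties else a continuity-corrected normal
approximation).  No multiple-testing correction is applied by default
(alpha = 0.05 per metric); a Holm option exists.

Test-retest reliability is the two-way mixed-model, single-measure,
consistency ICC,

    ICC = (MS_subjects - MS_error) / (MS_subjects + (k - 1) MS_error),

with the subject x trial interaction/residual as the error term (the trial
main effect is removed, so a constant offset between trials does not lower
the ICC), and the standard error of measurement SEM = SD * sqrt(1 - ICC)
with SD pooled over both trials (the square root of MS_error is available
as an alternative formula).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05


class StatsInputError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Paired comparison
# ---------------------------------------------------------------------------

def shapiro_gate(differences, alpha: float = ALPHA) -> str:
    """"normal" or "non_normal" by Shapiro-Wilk on the paired differences.

    A (near-)constant vector, for which the test is undefined, is treated as
    non-normal and routed to the Wilcoxon branch.
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 3:
        raise StatsInputError("need at least 3 differences")
    if np.ptp(d) < 1e-12:
        return "non_normal"
    _, p = sps.shapiro(d)
    return "normal" if p >= alpha else "non_normal"


@dataclass
class ComparisonResult:
    metric: str
    n: int
    pre_mean: float
    pre_sd: float
    post_mean: float
    post_sd: float
    diff_mean: float            # mean(post - pre) over complete pairs
    diff_sd: float
    test: str                   # "paired_t" | "wilcoxon"
    p: float
    significant: bool
    flagged: bool = False       # zero-variance differences under the t branch


def paired_compare(pre, post, metric: str = "", alpha: float = ALPHA) -> ComparisonResult:
    """Normality-gated paired comparison of pre vs post values.

    Incomplete pairs (NaN on either side) are dropped; at least 3 complete
    pairs are required.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise StatsInputError("pre and post must have equal length")
    keep = np.isfinite(pre) & np.isfinite(post)
    pre, post = pre[keep], post[keep]
    n = pre.size
    if n < 3:
        raise StatsInputError(f"need >= 3 complete pairs, got {n}")
    d = post - pre

    gate = shapiro_gate(d, alpha=alpha)
    flagged = False
    if gate == "normal":
        test = "paired_t"
        if np.ptp(d) < 1e-12 or np.std(d, ddof=1) == 0.0:
            p = math.nan
            flagged = True
        else:
            p = float(sps.ttest_rel(post, pre).pvalue)
    else:
        test = "wilcoxon"
        if np.all(d == 0):
            p = 1.0
            flagged = True
        else:
            nz = d[d != 0]
            method = "exact" if (nz.size <= 25 and nz.size > 0
                                 and np.unique(np.abs(nz)).size == nz.size) else "approx"
            p = float(sps.wilcoxon(d[d != 0], correction=True, method=method).pvalue)
    return ComparisonResult(
        metric=metric, n=n,
        pre_mean=float(pre.mean()), pre_sd=float(pre.std(ddof=1)),
        post_mean=float(post.mean()), post_sd=float(post.std(ddof=1)),
        diff_mean=float(d.mean()), diff_sd=float(d.std(ddof=1)),
        test=test, p=p,
        significant=bool(np.isfinite(p) and p < alpha),
        flagged=flagged,
    )


def mean_difference(pre_mean: float, post_mean: float) -> float:
    """Post minus pre group means."""
    return post_mean - pre_mean


def percent_change(pre_mean: float, post_mean: float) -> int:
    """100 * post / pre, rounded to the nearest integer percent."""
    if pre_mean == 0:
        raise StatsInputError("pre mean is zero; percent change undefined")
    return int(round(100.0 * post_mean / pre_mean))


# ---------------------------------------------------------------------------
# Reliability
# ---------------------------------------------------------------------------

@dataclass
class ReliabilityResult:
    metric: str
    n: int
    k: int
    icc: float
    sem: float
    flagged: bool = False       # zero between-subject variance


def icc_consistency(trial1, trial2) -> float:
    """Two-way mixed, single-measure, consistency ICC for k = 2 trials."""
    y1 = np.asarray(trial1, dtype=float)
    y2 = np.asarray(trial2, dtype=float)
    if y1.shape != y2.shape:
        raise StatsInputError("trials must have equal length")
    keep = np.isfinite(y1) & np.isfinite(y2)
    y1, y2 = y1[keep], y2[keep]
    n = y1.size
    if n < 3:
        raise StatsInputError(f"need >= 3 subjects, got {n}")
    k = 2
    y = np.column_stack([y1, y2])
    grand = y.mean()
    subj_means = y.mean(axis=1)
    trial_means = y.mean(axis=0)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_trial = n * np.sum((trial_means - grand) ** 2)
    ss_tot = np.sum((y - grand) ** 2)
    ss_err = ss_tot - ss_subj - ss_trial
    ms_subj = ss_subj / (n - 1)
    ms_err = max(ss_err / ((n - 1) * (k - 1)), 0.0)
    denom = ms_subj + (k - 1) * ms_err
    if denom <= 0:
        return math.nan
    return float((ms_subj - ms_err) / denom)


def sem_from_icc(sd: float, icc: float) -> float:
    """SEM = SD * sqrt(1 - ICC); requires SD >= 0 and ICC <= 1."""
    if sd < 0:
        raise StatsInputError("SD must be >= 0")
    if icc > 1 + 1e-12:
        raise StatsInputError("ICC cannot exceed 1")
    return float(sd * math.sqrt(max(0.0, 1.0 - min(icc, 1.0))))


def reliability(trial1, trial2, metric: str = "",
                sem_formula: str = "wagner") -> ReliabilityResult:
    """ICC and SEM for one metric measured in two trials.

    ``sem_formula``: "wagner" (SD * sqrt(1-ICC), SD pooled over both trials)
    or "ms_error" (sqrt of the ANOVA error mean square).
    """
    y1 = np.asarray(trial1, dtype=float)
    y2 = np.asarray(trial2, dtype=float)
    keep = np.isfinite(y1) & np.isfinite(y2)
    y1, y2 = y1[keep], y2[keep]
    n = y1.size
    icc = icc_consistency(y1, y2)
    flagged = not np.isfinite(icc)
    if np.allclose(y1, y2):
        # duplicated trials: perfect repeatability by definition
        return ReliabilityResult(metric=metric, n=n, k=2, icc=1.0, sem=0.0,
                                 flagged=flagged)
    pooled_sd = math.sqrt((np.var(y1, ddof=1) + np.var(y2, ddof=1)) / 2.0)
    if sem_formula == "wagner":
        sem = sem_from_icc(pooled_sd, icc) if np.isfinite(icc) else math.nan
    elif sem_formula == "ms_error":
        d = y2 - y1
        # for k=2, MS_error = var of (d - mean(d)) / 2
        sem = math.sqrt(max(np.var(d, ddof=1) / 2.0, 0.0))
    else:
        raise StatsInputError(f"unknown sem formula {sem_formula!r}")
    return ReliabilityResult(metric=metric, n=n, k=2, icc=icc, sem=sem,
                             flagged=flagged)


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

def holm_correct(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values (optional; off by default in reports)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def summary_table(
    comparisons: dict,
    reliabilities: dict = None,
    healthy: dict = None,
) -> pd.DataFrame:
    """Assemble the pre/post/reliability/healthy report table.

    ``comparisons`` maps metric id -> :class:`ComparisonResult`;
    ``reliabilities`` maps metric id -> :class:`ReliabilityResult`;
    ``healthy`` maps metric id -> (mean, sd).  Missing cells stay empty (NaN).
    """
    reliabilities = reliabilities or {}
    healthy = healthy or {}
    columns = ["metric", "n", "pre_mean", "pre_sd", "post_mean", "post_sd",
               "p", "test", "diff", "diff_sd", "significant", "icc", "sem",
               "healthy_mean", "healthy_sd"]
    if not comparisons:
        return pd.DataFrame(columns=columns).set_index("metric")
    rows = []
    for metric, c in comparisons.items():
        r = reliabilities.get(metric)
        h = healthy.get(metric)
        rows.append({
            "metric": metric,
            "n": c.n,
            "pre_mean": c.pre_mean, "pre_sd": c.pre_sd,
            "post_mean": c.post_mean, "post_sd": c.post_sd,
            "p": c.p, "test": c.test,
            "diff": c.diff_mean, "diff_sd": c.diff_sd,
            "significant": c.significant,
            "icc": r.icc if r else math.nan,
            "sem": r.sem if r else math.nan,
            "healthy_mean": h[0] if h else math.nan,
            "healthy_sd": h[1] if h else math.nan,
        })
    return pd.DataFrame(rows).set_index("metric")
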