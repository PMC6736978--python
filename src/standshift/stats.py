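"""Within-participant repeated-measures ANOVA and Tukey post-hoc comparisons.

One-way repeated-measures decomposition of an ``n_subjects x k_conditions``
table of session means: total variation splits into between-conditions,
between-subjects and residual sums of squares; the omnibus F is
``MS_conditions / MS_error`` on ``(k-1, (k-1)(n-1))`` degrees of freedom
(no sphericity correction). Post-hoc pairwise contrasts use the
studentized-range distribution (Tukey's HSD), with the ANOVA's error mean
square as the variance estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError


@dataclass
class RmAnovaResult:
    """Omnibus repeated-measures ANOVA result."""

    F: float
    df_factor: int
    df_error: int
    p: float
    ms_error: float
    ss_conditions: float
    ss_subjects: float
    ss_error: float

    def format_p(self) -> str:
        """p truncated to 4 decimal places, the reporting convention."""
        return f"{np.floor(self.p * 1e4) / 1e4:.4f}"


def rm_anova(table) -> RmAnovaResult:
    """One-way repeated-measures ANOVA on an ``n_subjects x k_conditions`` table.

    Rows are subjects, columns conditions (e.g. session numbers); cells are
    the per-subject condition means. Missing cells are a data error — the
    design must be complete, no imputation is attempted.
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2:
        raise DataError("expected a 2-D subjects x conditions table")
    n, k = x.shape
    if n < 2 or k < 2:
        raise DataError("need at least 2 subjects and 2 conditions")
    if not np.all(np.isfinite(x)):
        raise DataError("table contains missing or non-finite cells")
    grand = x.mean()
    ss_cond = n * np.sum((x.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((x.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df_f = k - 1
    df_e = (k - 1) * (n - 1)
    ms_cond = ss_cond / df_f
    ms_err = ss_err / df_e
    F = ms_cond / ms_err if ms_err > 0 else np.inf
    p = float(sps.f.sf(F, df_f, df_e))
    return RmAnovaResult(
        F=float(F),
        df_factor=df_f,
        df_error=df_e,
        p=p,
        ms_error=float(ms_err),
        ss_conditions=float(ss_cond),
        ss_subjects=float(ss_subj),
        ss_error=float(ss_err),
    )


def tukey_hsd(condition_means, ms_error: float, df_error: int, n_per_mean: int) -> pd.DataFrame:
    """All-pairs Tukey HSD given the ANOVA error term.

    For each pair, ``q = |mean_i - mean_j| / sqrt(ms_error / n)`` and the
    p-value comes from the studentized-range distribution with parameters
    ``(k, df_error)``.
    """
    means = np.asarray(condition_means, dtype=float)
    if ms_error <= 0:
        raise DataError("ms_error must be positive")
    k = means.size
    se = np.sqrt(ms_error / n_per_mean)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            q = abs(means[i] - means[j]) / se
            p = float(sps.studentized_range.sf(q, k, df_error))
            rows.append({"i": i, "j": j, "diff": means[i] - means[j], "q": q, "p": p})
    return pd.DataFrame(rows)


@dataclass
class PeriodComparison:
    """Early-vs-late report over a session-ordered series of session means."""

    early_mean: float
    late_mean: float
    early_sd: float
    late_sd: float
    early_se: float
    late_se: float
    per_subject_diff: np.ndarray
    mean_diff: float
    anova: RmAnovaResult
    tukey_q: float
    tukey_p: float
    n_group: int

    def to_dict(self) -> dict:
        return {
            "early_mean": self.early_mean,
            "late_mean": self.late_mean,
            "early_sd": self.early_sd,
            "late_sd": self.late_sd,
            "early_se": self.early_se,
            "late_se": self.late_se,
            "per_subject_diff": [float(d) for d in self.per_subject_diff],
            "mean_diff": self.mean_diff,
            "F": self.anova.F,
            "df": [self.anova.df_factor, self.anova.df_error],
            "anova_p": self.anova.format_p(),
            "tukey_q": self.tukey_q,
            "tukey_p": float(np.floor(self.tukey_p * 1e4) / 1e4),
            "n_group": self.n_group,
        }


def compare_periods(session_means, n_group: int = 5) -> PeriodComparison:
    """Compare the first and last ``n_group`` sessions of each subject.

    ``session_means`` is an ``n_subjects x n_sessions`` array (rows are
    subjects, columns session order). The omnibus ANOVA runs on the
    ``n x 2*n_group`` table of the selected sessions; the early-vs-late
    contrast is a Tukey comparison of the two grouped means using the
    ANOVA's error term with ``n_subjects * n_group`` observations per
    group mean.
    """
    x = np.asarray(session_means, dtype=float)
    if x.ndim != 2:
        raise DataError("expected a 2-D subjects x sessions array")
    n, m = x.shape
    if m < 2 * n_group:
        raise DataError(f"need at least {2 * n_group} sessions, got {m}")
    early = x[:, :n_group]
    late = x[:, -n_group:]
    table = np.hstack([early, late])
    res = rm_anova(table)
    early_mean, late_mean = float(early.mean()), float(late.mean())
    n_obs = n * n_group
    se_q = np.sqrt(res.ms_error / n_obs)
    diff_abs = abs(late_mean - early_mean)
    if se_q == 0.0:  # degenerate: zero residual variance
        q = 0.0 if diff_abs == 0.0 else np.inf
    else:
        q = diff_abs / se_q
    p = float(sps.studentized_range.sf(q, 2, res.df_error))
    per_subject = late.mean(axis=1) - early.mean(axis=1)
    return PeriodComparison(
        early_mean=early_mean,
        late_mean=late_mean,
        early_sd=float(early.std(ddof=1)),
        late_sd=float(late.std(ddof=1)),
        early_se=float(early.std(ddof=1) / np.sqrt(early.size)),
        late_se=float(late.std(ddof=1) / np.sqrt(late.size)),
        per_subject_diff=per_subject,
        mean_diff=float(per_subject.mean()),
        anova=res,
        tukey_q=float(q),
        tukey_p=p,
        n_group=n_group,
    )
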