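"""Agreement statistics for validating estimated gait parameters against a
reference.

Implements the usual concurrent-validity toolkit: Bland-Altman bias and
95% limits of agreement, Pearson's r, two-way mixed consistency ICC in
both single-rating ICC(3,1) and mean-of-k ICC(3,k) forms, mean absolute
error, a 1.96*SE confidence interval for the bias, paired t-test and
Cohen's d for method comparison, and an informational Shapiro-Wilk
normality check.

The difference direction is fixed as reference - estimate throughout.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats


def bland_altman(ref: np.ndarray, est: np.ndarray):
    """Bias, SD of differences (ddof=1) and 95% limits of agreement
    ``bias -/+ 1.96 SD`` for differences d = ref - est."""
    ref = np.asarray(ref, dtype=float)
    est = np.asarray(est, dtype=float)
    if ref.shape != est.shape:
        raise ValueError("reference and estimate lengths differ")
    if len(ref) < 3:
        raise ValueError("need at least 3 paired values")
    d = ref - est
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return bias, sd, (bias - 1.96 * sd, bias + 1.96 * sd)


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; errors on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or x.shape != y.shape:
        raise ValueError("need two equal-length series with n >= 3")
    if (x == x[0]).all() or (y == y[0]).all():
        raise ValueError("zero variance: correlation undefined")
    return float(stats.pearsonr(x, y)[0])


def icc(ratings: np.ndarray, form: str = "3,1") -> float:
    """Two-way mixed, consistency ICC from the ANOVA mean squares of a
    subjects x raters matrix (no missing cells).

    ICC(3,1) = (BMS - EMS) / (BMS + (k-1) EMS);
    ICC(3,k) = (BMS - EMS) / BMS.
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2:
        raise ValueError("ratings must be a 2-D subjects x raters matrix")
    if np.isnan(m).any():
        raise ValueError("missing cells are not supported (no imputation)")
    n, k = m.shape
    if n < 3 or k < 2:
        raise ValueError("need at least 3 subjects and 2 raters")
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    bms = ss_rows / (n - 1)
    ems = ss_err / ((n - 1) * (k - 1))
    if form == "3,1":
        return float((bms - ems) / (bms + (k - 1) * ems))
    if form == "3,k":
        return float((bms - ems) / bms)
    raise ValueError("form must be '3,1' or '3,k'")


def paired_t_and_cohens_d(err_a: np.ndarray, err_b: np.ndarray):
    """Paired t-test on err_a - err_b and the paired Cohen's d
    ``mean(diff) / SD(diff)``."""
    a = np.asarray(err_a, dtype=float)
    b = np.asarray(err_b, dtype=float)
    if a.shape != b.shape or len(a) < 3:
        raise ValueError("need two equal-length series with n >= 3")
    d = a - b
    sd = np.std(d, ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return 0.0, 1.0, 0.0
        raise ValueError("zero variance of paired differences")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p), float(np.mean(d) / sd)


@dataclass
class AgreementReport:
    n: int
    bias: float
    sd_diff: float
    mae: float
    loa_low: float
    loa_high: float
    ci95_low: float
    ci95_high: float
    pearson_r: float
    icc_3_1: float
    icc_3_k: float
    t_stat: float
    p_value: float
    cohens_d: float
    shapiro_p: float

    def to_dict(self) -> dict:
        return asdict(self)


def agreement_report(ref: np.ndarray, est: np.ndarray) -> AgreementReport:
    """Full agreement analysis of one parameter against its reference.

    The ICC treats the two methods as the k=2 raters of a two-way mixed
    design. The paired t tests ref vs est; Shapiro-Wilk on the
    differences is reported informationally and never gates anything.
    """
    ref = np.asarray(ref, dtype=float)
    est = np.asarray(est, dtype=float)
    bias, sd, (lo, hi) = bland_altman(ref, est)
    d = ref - est
    n = len(d)
    se = sd / np.sqrt(n)
    r = pearson_r(ref, est)
    mat = np.column_stack([ref, est])
    t, p, cd = paired_t_and_cohens_d(ref, est)
    return AgreementReport(
        n=n,
        bias=bias,
        sd_diff=sd,
        mae=float(np.mean(np.abs(d))),
        loa_low=lo,
        loa_high=hi,
        ci95_low=bias - 1.96 * se,
        ci95_high=bias + 1.96 * se,
        pearson_r=r,
        icc_3_1=icc(mat, "3,1"),
        icc_3_k=icc(mat, "3,k"),
        t_stat=t,
        p_value=p,
        cohens_d=cd,
        shapiro_p=float(stats.shapiro(d)[1]) if (d != d[0]).any() else float("nan"),
    )


def bland_altman_plot(ref, est, ax=None, label: str | None = None):
    """Bland-Altman scatter with bias and LoA lines (matplotlib axes)."""
    import matplotlib.pyplot as plt

    ref = np.asarray(ref, dtype=float)
    est = np.asarray(est, dtype=float)
    bias, sd, (lo, hi) = bland_altman(ref, est)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter((ref + est) / 2, ref - est, s=14, alpha=0.7)
    ax.axhline(bias, color="k", lw=1.2)
    for y in (lo, hi):
        ax.axhline(y, color="k", ls="--", lw=1.0)
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("reference - estimate")
    if label:
        ax.set_title(label)
    return ax
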