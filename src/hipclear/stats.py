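"""Validation statistics: LSQE, accuracy summaries, correlations, inclusion rule.

LSQE (least-squares error in hip angles) is the Euclidean norm of the three
angle differences between two postures; it is both the frame-matching cost
and the goodness-of-match covariate in the inclusion procedure. All
statistics are computed on unrounded values; rounding to one decimal happens
only in human-readable reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps

from .errors import DegenerateGeometryError, InputError
from .frames import HipJointAngles


def lsqe(a: HipJointAngles, b: HipJointAngles) -> float:
    """Euclidean norm of the (flexion, ab/adduction, rotation) differences, degrees."""
    if a.side != b.side:
        raise InputError("LSQE compares angles on the same side")
    return float(np.linalg.norm(a.as_array() - b.as_array()))


@dataclass(frozen=True)
class AccuracySummary:
    n: int
    mean_abs_error: float
    sd: float
    rmse: float
    per_subject: tuple = ()

    def rounded(self, decimals: int = 1) -> dict:
        return {
            "n": self.n,
            "mean_abs_error": round(self.mean_abs_error, decimals),
            "sd": round(self.sd, decimals),
            "rmse": round(self.rmse, decimals),
        }


def accuracy_summary(pairs, ids=None) -> AccuracySummary:
    """Absolute-error summary of (beta_model, beta_reference) pairs.

    SD uses the sample (n-1) denominator; RMSE is the quadratic mean of the
    absolute errors, so RMSE >= mean always (power-mean inequality).
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.size == 0:
        raise InputError("accuracy summary needs at least one pair")
    arr = arr.reshape(-1, 2)
    errors = np.abs(arr[:, 0] - arr[:, 1])
    n = len(errors)
    if ids is None:
        ids = list(range(n))
    per_subject = tuple(
        (i, float(m), float(r), float(e)) for i, (m, r), e in zip(ids, arr, errors)
    )
    sd = float(np.std(errors, ddof=1)) if n > 1 else 0.0
    return AccuracySummary(
        n=n,
        mean_abs_error=float(np.mean(errors)),
        sd=sd,
        rmse=float(np.sqrt(np.mean(errors**2))),
        per_subject=per_subject,
    )


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation with the two-sided t-distribution p-value
    (t = r sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InputError("pearson_r needs matched samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateGeometryError("correlation undefined for zero-variance input")
    res = _sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def icc_agreement(x, y) -> float:
    """Two-way, single-measure, absolute-agreement ICC -- ICC(2,1) -- treating
    (x, y) as two raters scoring the same subjects.

    Computed from the two-way ANOVA mean squares:
    ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n).
    Unlike Pearson's r it penalises systematic offset between the raters.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InputError("icc_agreement needs matched samples with n >= 3")
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if abs(denom) < 1e-300:
        raise DegenerateGeometryError("ICC undefined: degenerate variance")
    return float((msr - mse) / denom)


@dataclass(frozen=True)
class InclusionResult:
    threshold_rank: int
    included_ids: tuple
    r: float
    p: float
    icc: float
    non_significant: bool = True


def threshold_inclusion(records, alpha: float = 0.05) -> InclusionResult:
    """Largest low-LSQE prefix with no significant LSQE-accuracy correlation.

    `records` are (id, lsqe, abs_error) triples. They are sorted by ascending
    LSQE and the largest prefix of size >= 3 whose Pearson correlation between
    LSQE and absolute error has p >= alpha is returned (an undefined
    correlation -- zero variance -- counts as non-significant). If even the
    full set is non-significant the full set is returned; if no prefix of
    size >= 3 qualifies, the smallest (size 3) prefix is returned flagged
    ``non_significant=False``.
    """
    recs = sorted(list(records), key=lambda r: float(r[1]))
    if len(recs) < 3:
        raise InputError("threshold inclusion needs at least 3 records")

    def corr(prefix):
        l = [float(r[1]) for r in prefix]
        e = [float(r[2]) for r in prefix]
        try:
            return pearson_r(l, e)
        except DegenerateGeometryError:
            return float("nan"), 1.0  # zero variance: treated as non-significant

    for m in range(len(recs), 2, -1):
        prefix = recs[:m]
        r, p = corr(prefix)
        if p >= alpha:
            l = [float(x[1]) for x in prefix]
            e = [float(x[2]) for x in prefix]
            try:
                icc = icc_agreement(l, e)
            except DegenerateGeometryError:
                icc = float("nan")
            return InclusionResult(
                threshold_rank=m,
                included_ids=tuple(x[0] for x in prefix),
                r=r,
                p=p,
                icc=icc,
                non_significant=True,
            )
    prefix = recs[:3]
    r, p = corr(prefix)
    return InclusionResult(
        threshold_rank=3,
        included_ids=tuple(x[0] for x in prefix),
        r=r,
        p=p,
        icc=icc_agreement([float(x[1]) for x in prefix], [float(x[2]) for x in prefix]),
        non_significant=False,
    )
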