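"""Test-retest statistics for ROI-wise FC-IVIM parameter estimates.

Covers the in-vivo analysis chain: linear signal-drift detection/correction on
the b = 0 acquisitions, within-subject coefficient of variation (wCV),
two-way absolute-agreement average-measures ICC, protocol bias relative to a
reference protocol, and the two-compartment T2 rescaling of the perfusion
fraction to a different echo time.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .model import AcquisitionScheme


@dataclass
class ROISeries:
    """ROI-median signal per acquisition of one subject/organ/occasion."""

    subject: str
    organ: str
    occasion: str
    signals: np.ndarray
    times_s: np.ndarray
    scheme: AcquisitionScheme

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, float)
        self.times_s = np.asarray(self.times_s, float)
        if self.signals.size != len(self.scheme) or self.times_s.size != len(self.scheme):
            raise ValueError("signals/times must have one entry per scheme row")
        if np.any(np.diff(self.times_s) < 0):
            raise ValueError("timestamps must be non-decreasing")
        if np.count_nonzero(self.scheme.b == 0) < 2:
            raise ValueError("need >= 2 b = 0 acquisitions for drift testing")


@dataclass(frozen=True)
class DriftFit:
    """OLS drift test report: S(b=0) ~ a + b * t."""

    a: float
    b_slope: float
    p_value: float
    corrected: bool


def drift_correct(series: ROISeries, alpha: float = 0.05) -> tuple:
    """Detect and, if significant, remove a linear signal drift.

    Ordinary least squares of the b = 0 signals against acquisition time; if
    the slope differs from zero at level ``alpha`` (two-sided t-test), every
    signal is divided by (a + b * t).  Returns (series, DriftFit); the series
    is returned unchanged when no correction is applied.
    """
    mask = series.scheme.b == 0
    t, s = series.times_s[mask], series.signals[mask]
    if t.size < 3:
        raise ValueError("need >= 3 b = 0 points for a slope test")
    if np.ptp(t) == 0:
        raise ValueError("degenerate timestamps: all b = 0 acquisitions coincide")
    fit = stats.linregress(t, s)
    if not np.isfinite(fit.pvalue):
        # zero residual variance: treat an exactly nonzero slope as significant
        p = 0.0 if abs(fit.slope) > 1e-12 * max(abs(fit.intercept), 1.0) else 1.0
    else:
        p = float(fit.pvalue)
    if p < alpha:
        gain = fit.intercept + fit.slope * series.times_s
        corrected = replace(series, signals=series.signals / gain)
        return corrected, DriftFit(float(fit.intercept), float(fit.slope), p, True)
    return series, DriftFit(float(fit.intercept), float(fit.slope), p, False)


def wcv(values, method: str = "rms") -> float:
    """Within-subject coefficient of variation, percent.

    ``values`` is (subjects x repeats): an array, or a list of per-subject
    arrays (>= 2 measurements each).  Default estimator: root mean square over
    subjects of (within-subject SD / within-subject mean).  ``method='pooled'``
    uses sqrt(mean within-subject variance) / grand mean instead.
    """
    rows = [np.asarray(r, float) for r in values]
    if len(rows) < 2:
        raise ValueError("need >= 2 subjects")
    if any(r.size < 2 for r in rows):
        raise ValueError("need >= 2 measurements per subject")
    means = np.array([r.mean() for r in rows])
    if np.any(means == 0):
        raise ValueError("zero within-subject mean")
    sds = np.array([r.std(ddof=1) for r in rows])
    if method == "rms":
        return float(100.0 * np.sqrt(np.mean((sds / means) ** 2)))
    if method == "pooled":
        return float(100.0 * np.sqrt(np.mean(sds**2)) / np.mean([r.mean() for r in rows]))
    raise ValueError("method must be 'rms' or 'pooled'")


@dataclass(frozen=True)
class IccResult:
    """Absolute-agreement average-measures ICC with reliability flag."""

    icc: float
    reliability: str  # 'good' | 'poor' | 'n.a.' (negative ICC)
    ms_rows: float
    ms_cols: float
    ms_err: float
    n_subjects: int
    n_occasions: int


def icc_a_k(matrix, good_threshold: float = 0.75) -> IccResult:
    """Two-way absolute-agreement, average-of-k-measurements ICC.

    ``matrix`` is subjects x occasions with no missing cells.  Uses the
    two-way ANOVA decomposition (subjects random, occasions fixed):
    ICC(A,k) = (MS_R - MS_E) / (MS_R + (MS_C - MS_E) / n).  Negative values
    are reported with reliability 'n.a.' (dominant within-subject variance).
    """
    X = np.asarray(matrix, float)
    if X.ndim != 2:
        raise ValueError("matrix must be subjects x occasions")
    n, k = X.shape
    if n < 3 or k < 2:
        raise ValueError("need >= 3 subjects and >= 2 occasions")
    if not np.all(np.isfinite(X)):
        raise ValueError("missing cells are not allowed (no imputation)")
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_err = np.sum((X - row_means[:, None] - col_means[None, :] + grand) ** 2)
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (ms_c - ms_e) / n
    icc = (ms_r - ms_e) / denom if denom != 0 else np.nan
    # a negative estimate (within-subject variance dominates) or a negative
    # denominator makes the coefficient meaningless: flagged unreliable
    if not np.isfinite(icc) or icc < 0 or denom <= 0:
        flag = "n.a."
    else:
        flag = "good" if icc >= good_threshold else "poor"
    return IccResult(float(icc), flag, float(ms_r), float(ms_c), float(ms_e), n, k)


def protocol_bias(ref, test) -> float:
    """Mean percent deviation of ``test`` from the reference protocol.

    100 * mean over paired measurements of (theta_ref - theta_test) / theta_ref.
    """
    ref = np.asarray(ref, float)
    test = np.asarray(test, float)
    if ref.shape != test.shape:
        raise ValueError("ref and test must be paired (same length)")
    if np.any(ref == 0):
        raise ValueError("reference values must be nonzero")
    return float(100.0 * np.mean((ref - test) / ref))


def t2_adjust_f(
    f_obs: float,
    te_obs: float,
    te_target: float,
    t2_tissue: float,
    t2_blood: float,
) -> float:
    """Rescale a perfusion fraction between echo times via compartment T2s.

    The measured f is a signal fraction; both compartments decay as
    exp(-TE/T2), so the compartment odds f/(1-f) scale by
    exp((TE_target - TE_obs) * (1/T2_tissue - 1/T2_blood)).  All times in ms.
    """
    if not 0.0 < f_obs < 1.0:
        raise ValueError("f_obs must lie strictly between 0 and 1")
    if min(te_obs, te_target, t2_tissue, t2_blood) <= 0:
        raise ValueError("echo times and T2 values must be positive")
    odds = f_obs / (1.0 - f_obs)
    odds *= np.exp((te_target - te_obs) * (1.0 / t2_tissue - 1.0 / t2_blood))
    return float(odds / (1.0 + odds))


# -- tidy-table helpers ------------------------------------------------------

PARAM_COLS = ("D", "f_pct", "tau_ms", "v_mm_s")


def wcv_table(table: pd.DataFrame, occasions, params=PARAM_COLS, method="rms") -> pd.DataFrame:
    """wCV per organ and parameter from a tidy estimates table.

    ``table`` columns: subject, organ, occasion plus parameter columns;
    ``occasions`` selects the repeated measurements to compare.
    """
    sub = table[table["occasion"].isin(list(occasions))]
    rows = []
    for organ, g in sub.groupby("organ"):
        row = {"organ": organ}
        for p in params:
            piv = g.pivot_table(index="subject", columns="occasion", values=p)
            piv = piv.dropna()
            row[p] = wcv(piv.to_numpy(), method=method)
        rows.append(row)
    return pd.DataFrame(rows).set_index("organ")


def icc_table(table: pd.DataFrame, occasions, params=PARAM_COLS) -> pd.DataFrame:
    """ICC(A,k) per organ and parameter from a tidy estimates table."""
    sub = table[table["occasion"].isin(list(occasions))]
    rows = []
    for organ, g in sub.groupby("organ"):
        row = {"organ": organ}
        for p in params:
            piv = g.pivot_table(index="subject", columns="occasion", values=p).dropna()
            res = icc_a_k(piv.to_numpy())
            row[p] = res.icc
            row[f"{p}_reliability"] = res.reliability
        rows.append(row)
    return pd.DataFrame(rows).set_index("organ")


def bias_table(ref_table: pd.DataFrame, test_table: pd.DataFrame, params=PARAM_COLS) -> pd.DataFrame:
    """Per-organ protocol bias of ``test`` vs ``ref`` estimates (paired on
    subject and occasion)."""
    merged = ref_table.merge(
        test_table, on=["subject", "organ", "occasion"], suffixes=("_ref", "_test")
    )
    rows = []
    for organ, g in merged.groupby("organ"):
        row = {"organ": organ}
        for p in params:
            row[p] = protocol_bias(g[f"{p}_ref"].to_numpy(), g[f"{p}_test"].to_numpy())
        rows.append(row)
    return pd.DataFrame(rows).set_index("organ")
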