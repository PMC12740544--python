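"""Accuracy and precision statistics for estimated time-integrated activities.

Accuracy of an estimation method k is summarised over subjects m by the
relative deviation RD_{k,m} = (eTIA_{k,m} - rTIA_m) / rTIA_m, its
root-mean-square error RMSE_k = sqrt(SD(RD)^2 + mean(RD)^2) (population
SD, so identically sqrt(mean(RD^2))), and the mean absolute percentage
error MAPE_k = (100/N) sum |RD_{k,m}|.  Per-subject RD uncertainties are
propagated first-order from the TIA SDs (eTIA and rTIA treated as
uncorrelated) and carried into SDs of RMSE and MAPE by the delta method.
Precision of an individual TIA is its coefficient of variation
CV = SD(TIA) / TIA.

Conventions: RD, RMSE and CV are stored as dimensionless fractions;
MAPE is in percent.  Threshold counts use strict inequality on |RD|.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AccuracyReport",
    "CVSummary",
    "relative_deviation",
    "rd_sd",
    "rmse",
    "mape",
    "rmse_sd",
    "mape_sd",
    "threshold_counts",
    "cv",
    "cv_summary",
    "ols_slope_test",
    "build_accuracy_report",
]

log = logging.getLogger(__name__)


def relative_deviation(etia, rtia):
    """(eTIA - rTIA) / rTIA; vectorised."""
    etia = np.asarray(etia, dtype=float)
    rtia = np.asarray(rtia, dtype=float)
    if np.any(rtia <= 0):
        raise ValueError("reference TIA must be > 0")
    out = (etia - rtia) / rtia
    return float(out) if out.ndim == 0 else out


def rd_sd(etia, sd_e, rtia, sd_r):
    """First-order SD of the relative deviation (uncorrelated eTIA, rTIA)."""
    etia = np.asarray(etia, dtype=float)
    rtia = np.asarray(rtia, dtype=float)
    sd_e = np.asarray(sd_e, dtype=float)
    sd_r = np.asarray(sd_r, dtype=float)
    if np.any(rtia <= 0):
        raise ValueError("reference TIA must be > 0")
    if np.any(sd_e < 0) or np.any(sd_r < 0):
        raise ValueError("SDs must be >= 0")
    out = np.sqrt((sd_e / rtia) ** 2 + (etia * sd_r / rtia**2) ** 2)
    return float(out) if out.ndim == 0 else out


def _check_nonempty(rd) -> np.ndarray:
    rd = np.asarray(rd, dtype=float)
    if rd.size == 0:
        raise ValueError("empty RD vector")
    return rd


def rmse(rd) -> float:
    """sqrt(SD^2 + mean^2) with the N-denominator SD == sqrt(mean(rd^2))."""
    rd = _check_nonempty(rd)
    return float(np.sqrt(np.mean(rd * rd)))


def mape(rd) -> float:
    """Mean absolute RD in percent."""
    rd = _check_nonempty(rd)
    return float(100.0 * np.mean(np.abs(rd)))


def rmse_sd(rd, rd_sds) -> float:
    """Delta-method SD of the RMSE from per-subject RD SDs."""
    rd = _check_nonempty(rd)
    sds = np.asarray(rd_sds, dtype=float)
    if sds.shape != rd.shape:
        raise ValueError("rd and rd_sds must have the same length")
    n = rd.size
    r = rmse(rd)
    if r == 0.0:
        if np.any(sds > 0):
            log.warning("RMSE is zero with nonzero RD SDs; reporting upper bound")
        # |dRMSE/drd_m| <= 1/sqrt(N), so this bounds the propagated SD
        return float(np.sqrt(np.sum(sds**2)) / np.sqrt(n))
    grad = rd / (n * r)
    return float(np.sqrt(np.sum((grad * sds) ** 2)))


def mape_sd(rd, rd_sds) -> float:
    """Delta-method SD of the MAPE (percent); sign of rd enters only as +-1."""
    rd = _check_nonempty(rd)
    sds = np.asarray(rd_sds, dtype=float)
    if sds.shape != rd.shape:
        raise ValueError("rd and rd_sds must have the same length")
    return float(100.0 / rd.size * np.sqrt(np.sum(sds**2)))


def threshold_counts(rd, thresholds=(0.10, 0.20)):
    """Counts (and integer-rounded %) of subjects with |RD| strictly above each threshold."""
    rd = _check_nonempty(rd)
    out = {}
    for thr in thresholds:
        count = int(np.sum(np.abs(rd) > thr))
        out[thr] = (count, int(round(100.0 * count / rd.size)))
    return out


def cv(tia, sd):
    """Coefficient of variation SD/TIA of an individual TIA estimate."""
    tia = np.asarray(tia, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if np.any(tia <= 0):
        raise ValueError("TIA must be > 0")
    if np.any(sd < 0):
        raise ValueError("SD must be >= 0")
    out = sd / tia
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class CVSummary:
    """Cohort summary of per-subject CVs for one method (fractions)."""

    method: str
    n: int
    mean: float
    sd: float
    median: float
    min: float
    max: float


def cv_summary(method: str, cvs) -> CVSummary:
    cvs = _check_nonempty(cvs)
    return CVSummary(
        method=method,
        n=int(cvs.size),
        mean=float(np.mean(cvs)),
        sd=float(np.std(cvs)),
        median=float(np.median(cvs)),
        min=float(np.min(cvs)),
        max=float(np.max(cvs)),
    )


def ols_slope_test(etia, rtia):
    """OLS of eTIA on rTIA with a two-sided t-test of slope != 0.

    Returns (slope, intercept, p_slope).
    """
    etia = np.asarray(etia, dtype=float)
    rtia = np.asarray(rtia, dtype=float)
    if etia.shape != rtia.shape or etia.ndim != 1:
        raise ValueError("etia and rtia must be 1-d arrays of equal length")
    if etia.size < 3:
        raise ValueError("regression needs at least 3 points")
    if np.ptp(rtia) == 0.0:
        raise ValueError("reference TIAs have zero variance")
    res = stats.linregress(rtia, etia)
    return float(res.slope), float(res.intercept), float(res.pvalue)


@dataclass
class AccuracyReport:
    """Cohort accuracy summary of one estimation method against the reference."""

    method: str
    n: int
    rd: np.ndarray
    rd_sds: np.ndarray
    rd_median: float
    rd_min: float
    rd_max: float
    rmse: float
    rmse_sd: float
    mape: float  # percent
    mape_sd: float  # percent
    rd10_count: int
    rd10_pct: int
    rd20_count: int
    rd20_pct: int
    slope: float | None = None
    intercept: float | None = None
    p_slope: float | None = None


def build_accuracy_report(method, etia, sd_e, rtia, sd_r) -> AccuracyReport:
    """Assemble the full accuracy report for one method.

    All inputs are per-subject vectors aligned on the same subject order.
    """
    etia = np.asarray(etia, dtype=float)
    rtia = np.asarray(rtia, dtype=float)
    rd = relative_deviation(etia, rtia)
    rd = np.atleast_1d(rd)
    sds = np.atleast_1d(rd_sd(etia, sd_e, rtia, sd_r))
    counts = threshold_counts(rd)
    slope = intercept = p = None
    if rd.size >= 3 and np.ptp(rtia) > 0:
        slope, intercept, p = ols_slope_test(etia, rtia)
    return AccuracyReport(
        method=method,
        n=int(rd.size),
        rd=rd,
        rd_sds=sds,
        rd_median=float(np.median(rd)),
        rd_min=float(np.min(rd)),
        rd_max=float(np.max(rd)),
        rmse=rmse(rd),
        rmse_sd=rmse_sd(rd, sds),
        mape=mape(rd),
        mape_sd=mape_sd(rd, sds),
        rd10_count=counts[0.10][0],
        rd10_pct=counts[0.10][1],
        rd20_count=counts[0.20][0],
        rd20_pct=counts[0.20][1],
        slope=slope,
        intercept=intercept,
        p_slope=p,
    )
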