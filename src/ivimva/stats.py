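"""Repeatability, outlier handling, SNR estimation and validation statistics.

Scan-rescan repeatability uses the within-subject coefficient of
variation

    CoV(%) = 100 * sigma / mu,
    sigma  = sqrt( sum_i (x_i1 - x_i2)^2 / (2n) ),
    mu     = sum_i (x_i1 + x_i2) / (2n),

over n subjects measured twice.  Outliers are removed beforehand by the
unscaled 3-MAD rule (|x - median| <= 3 * median(|x - median|)).  SNR is
estimated by the two-acquisition difference method,
SNR = mean(r1 + r2) / (sqrt(2) * sd(r1 - r2)), which reduces to mu/sigma
for i.i.d. additive noise.  MRI segment lengths are validated against
reference (micro-CT) lengths by ordinary least-squares regression with
Pearson correlation, slope test p-value and SSE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "RepeatabilityResult",
    "ValidationResult",
    "SNREstimate",
    "RegionSummary",
    "mad_filter",
    "cov_repeatability",
    "snr_difference",
    "validate_lengths",
    "region_summary",
]


def mad_filter(values) -> tuple[np.ndarray, np.ndarray]:
    """Keep values within three median absolute deviations of the median.

    MAD here is the raw median(|x - median|), with no normal-consistency
    scaling.  Values exactly at the cut (including the all-equal case
    where MAD = 0) are kept.  NaNs are removed first.

    Returns
    -------
    (kept, removed_indices)
        ``kept`` in original order; ``removed_indices`` indexes the
        input array (NaN positions are reported as removed).
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if not finite.any():
        raise ValueError("mad_filter requires at least one finite value")
    med = np.median(x[finite])
    mad = np.median(np.abs(x[finite] - med))
    keep = finite & (np.abs(x - med) <= 3.0 * mad)
    return x[keep], np.flatnonzero(~keep)


@dataclass
class RepeatabilityResult:
    """Within-subject repeatability of one parameter in one region."""

    sigma: float          # within-subject SD, parameter units
    mu: float             # mean, parameter units
    cov_percent: float    # 100*sigma/mu; NaN when mu == 0
    n: int                # subject pairs used
    x1: np.ndarray
    x2: np.ndarray
    n_dropped: int = 0    # pairs removed for missing values
    flags: list = field(default_factory=list)


def cov_repeatability(x1, x2) -> RepeatabilityResult:
    """Scan-rescan coefficient of variation from paired estimates.

    Pairs containing NaN are dropped (count reported).  CoV is flagged
    undefined when the mean is zero.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError("x1 and x2 must be paired (equal length)")
    ok = np.isfinite(x1) & np.isfinite(x2)
    n_dropped = int((~ok).sum())
    x1, x2 = x1[ok], x2[ok]
    n = len(x1)
    if n < 1:
        raise ValueError("need at least one complete pair")
    sigma = math.sqrt(float(np.sum((x1 - x2) ** 2)) / (2.0 * n))
    mu = float(np.sum(x1 + x2)) / (2.0 * n)
    flags = []
    if mu == 0.0:
        cov = float("nan")
        flags.append("undefined_cov_mu_zero")
    else:
        cov = 100.0 * sigma / mu
    return RepeatabilityResult(sigma=sigma, mu=mu, cov_percent=cov, n=n,
                               x1=x1, x2=x2, n_dropped=n_dropped, flags=flags)


@dataclass
class SNREstimate:
    """Difference-method SNR from two repeats of the same acquisition."""

    snr: float
    mean_sum: float       # mean of r1 + r2
    sd_diff: float        # sd of r1 - r2 (ddof=1)
    n: int
    flags: list = field(default_factory=list)


def snr_difference(repeat1, repeat2) -> SNREstimate:
    """SNR = mean(r1 + r2) / (sqrt(2) * sd(r1 - r2)).

    For i.i.d. additive noise of SD sigma on a signal of mean mu this
    reduces to mu/sigma.  Identical repeats give flagged infinite SNR.
    """
    r1 = np.asarray(repeat1, dtype=float)
    r2 = np.asarray(repeat2, dtype=float)
    if r1.shape != r2.shape:
        raise ValueError("repeats must be paired")
    if r1.size < 2:
        raise ValueError("need at least two paired samples")
    mean_sum = float(np.mean(r1 + r2))
    sd_diff = float(np.std(r1 - r2, ddof=1))
    flags = []
    if sd_diff == 0.0:
        snr = float("inf")
        flags.append("identical_repeats")
    else:
        snr = mean_sum / (math.sqrt(2.0) * sd_diff)
    return SNREstimate(snr=snr, mean_sum=mean_sum, sd_diff=sd_diff,
                       n=r1.size, flags=flags)


@dataclass
class ValidationResult:
    """Agreement of MR segment lengths with reference lengths."""

    rho: float            # Pearson correlation
    p_value: float        # two-sided t test on the regression slope
    slope: float
    intercept: float
    sse: float            # sum of squared errors, squared length units
    n: int
    sse_about: str = "regression"   # or "identity"
    flags: list = field(default_factory=list)


def validate_lengths(l_mr, l_ref, sse_about: str = "regression") -> ValidationResult:
    """Regress MR segment lengths on reference lengths (reference as abscissa).

    ``sse_about`` selects whether SSE is measured about the fitted
    regression line (default) or the identity line.
    """
    y = np.asarray(l_mr, dtype=float)
    x = np.asarray(l_ref, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired region vectors required")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 paired regions")
    flags = []
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        flags.append("zero_variance")
        slope, intercept, rho, p = float("nan"), float("nan"), float("nan"), float("nan")
    else:
        fit = sps.linregress(x, y)
        slope, intercept, rho, p = fit.slope, fit.intercept, fit.rvalue, fit.pvalue
    if sse_about == "identity":
        sse = float(np.sum((y - x) ** 2))
    elif sse_about == "regression":
        if flags:
            sse = float("nan")
        else:
            sse = float(np.sum((y - (slope * x + intercept)) ** 2))
    else:
        raise ValueError("sse_about must be 'regression' or 'identity'")
    return ValidationResult(rho=float(rho), p_value=float(p), slope=float(slope),
                            intercept=float(intercept), sse=sse, n=len(x),
                            sse_about=sse_about, flags=flags)


@dataclass
class RegionSummary:
    """Mean and SEM of surviving (post-MAD-filter) estimates."""

    mean: float
    sem: float            # sd/sqrt(n); NaN when n < 2
    n: int
    n_removed: int
    flags: list = field(default_factory=list)


def region_summary(estimates, apply_mad: bool = True) -> RegionSummary:
    """Outlier-filtered mean with standard error for one region/parameter."""
    x = np.asarray(estimates, dtype=float)
    if apply_mad:
        kept, removed = mad_filter(x)
    else:
        kept, removed = x[np.isfinite(x)], np.flatnonzero(~np.isfinite(x))
    n = len(kept)
    flags = []
    if n == 0:
        flags.append("empty_after_filter")
        return RegionSummary(mean=float("nan"), sem=float("nan"), n=0,
                             n_removed=len(removed), flags=flags)
    mean = float(np.mean(kept))
    if n < 2:
        sem = float("nan")
        flags.append("sem_undefined_single_value")
    else:
        sem = float(np.std(kept, ddof=1) / math.sqrt(n))
    return RegionSummary(mean=mean, sem=sem, n=n, n_removed=len(removed), flags=flags)
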