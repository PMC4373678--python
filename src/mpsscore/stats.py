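"""Statistical characterization of mutation-score distributions.

Implements the descriptive toolbox used to characterize the 86 SGSH
mutation totals: sample-adjusted skewness (G1) and excess kurtosis (G2)
with their small-sample standard errors (SES, SEK), the D'Agostino-Pearson
omnibus normality statistic K2 (D'Agostino's skewness transform plus the
Anscombe-Glynn kurtosis transform, chi-square with 2 df), an integer-bin
histogram, an amplitude-form Gaussian least-squares fit to that histogram,
and Spearman rank correlation with mean-rank tie handling.

The moment transforms are written out from the published formulas rather
than delegated, so they can be cross-validated against an independent
implementation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats as sps

__all__ = [
    "DistributionSummary",
    "GaussianFitResult",
    "SpearmanResult",
    "describe",
    "ses",
    "sek",
    "histogram",
    "fit_gaussian",
    "spearman",
]


def ses(n: int) -> float:
    """Standard error of skewness: sqrt(6n(n-1) / ((n-2)(n+1)(n+3)))."""
    if n < 3:
        raise ValueError("SES requires n >= 3")
    return math.sqrt(6.0 * n * (n - 1) / ((n - 2) * (n + 1) * (n + 3)))


def sek(n: int) -> float:
    """Standard error of kurtosis: 2*SES(n)*sqrt((n^2-1) / ((n-3)(n+5)))."""
    if n < 4:
        raise ValueError("SEK requires n >= 4")
    return 2.0 * ses(n) * math.sqrt((n * n - 1) / ((n - 3.0) * (n + 5.0)))


@dataclass(frozen=True)
class DistributionSummary:
    n: int
    mean: float
    sd: float
    skewness: float          # G1, sample-adjusted
    ses: float
    kurtosis: float          # G2, sample-adjusted excess
    sek: float
    k2: float
    p_value: float
    skew_significant: bool   # |G1| > 2 SES
    kurt_significant: bool   # |G2| > 2 SEK


def _central_moments(x: np.ndarray) -> tuple[float, float, float]:
    d = x - x.mean()
    return float((d**2).mean()), float((d**3).mean()), float((d**4).mean())


def _skewness_z(b1: float, n: int) -> float:
    """D'Agostino (1970) normalizing transform of sample skewness sqrt(b1)."""
    y = b1 * math.sqrt((n + 1.0) * (n + 3.0) / (6.0 * (n - 2.0)))
    beta2 = (
        3.0 * (n * n + 27.0 * n - 70.0) * (n + 1.0) * (n + 3.0)
        / ((n - 2.0) * (n + 5.0) * (n + 7.0) * (n + 9.0))
    )
    w2 = -1.0 + math.sqrt(2.0 * (beta2 - 1.0))
    delta = 1.0 / math.sqrt(0.5 * math.log(w2))
    alpha = math.sqrt(2.0 / (w2 - 1.0))
    if y == 0:
        return 0.0
    return delta * math.log(y / alpha + math.sqrt((y / alpha) ** 2 + 1.0))


def _kurtosis_z(b2: float, n: int) -> float:
    """Anscombe-Glynn (1983) normalizing transform of sample kurtosis b2."""
    e_b2 = 3.0 * (n - 1.0) / (n + 1.0)
    var_b2 = 24.0 * n * (n - 2.0) * (n - 3.0) / ((n + 1.0) ** 2 * (n + 3.0) * (n + 5.0))
    x = (b2 - e_b2) / math.sqrt(var_b2)
    sqrt_beta1 = (
        6.0 * (n * n - 5.0 * n + 2.0) / ((n + 7.0) * (n + 9.0))
        * math.sqrt(6.0 * (n + 3.0) * (n + 5.0) / (n * (n - 2.0) * (n - 3.0)))
    )
    a = 6.0 + (8.0 / sqrt_beta1) * (
        2.0 / sqrt_beta1 + math.sqrt(1.0 + 4.0 / sqrt_beta1**2)
    )
    term = (1.0 - 2.0 / a) / (1.0 + x * math.sqrt(2.0 / (a - 4.0)))
    return (
        (1.0 - 2.0 / (9.0 * a)) - math.copysign(abs(term) ** (1.0 / 3.0), term)
    ) / math.sqrt(2.0 / (9.0 * a))


def describe(values) -> DistributionSummary:
    """Moments, G1/G2 with SES/SEK significance, and the omnibus K2 test."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 8:
        raise ValueError("omnibus normality test requires n >= 8")
    m2, m3, m4 = _central_moments(x)
    if m2 == 0:
        raise ValueError("constant input: moments undefined")
    b1 = m3 / m2**1.5                 # biased sample skewness sqrt(b1)
    b2 = m4 / m2**2                   # biased sample kurtosis (not excess)
    g1 = b1 * math.sqrt(n * (n - 1.0)) / (n - 2.0)
    g2 = ((n + 1.0) * (b2 - 3.0) + 6.0) * (n - 1.0) / ((n - 2.0) * (n - 3.0))
    z1 = _skewness_z(b1, n)
    z2 = _kurtosis_z(b2, n)
    k2 = z1 * z1 + z2 * z2
    p = float(sps.chi2.sf(k2, 2))
    se_s, se_k = ses(n), sek(n)
    return DistributionSummary(
        n=n,
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)),
        skewness=g1,
        ses=se_s,
        kurtosis=g2,
        sek=se_k,
        k2=k2,
        p_value=p,
        skew_significant=abs(g1) > 2.0 * se_s,
        kurt_significant=abs(g2) > 2.0 * se_k,
    )


def histogram(values, bin_lo: int = 0, bin_hi: int = 11) -> np.ndarray:
    """Counts at the integer centres ``bin_lo..bin_hi`` (inclusive)."""
    counts = np.zeros(bin_hi - bin_lo + 1, dtype=int)
    for v in values:
        iv = int(v)
        if iv != v or not bin_lo <= iv <= bin_hi:
            raise ValueError(f"value {v} outside integer bins {bin_lo}..{bin_hi}")
        counts[iv - bin_lo] += 1
    return counts


@dataclass(frozen=True)
class GaussianFitResult:
    amplitude: float
    mean: float
    sd: float
    se_amplitude: float
    se_mean: float
    se_sd: float
    ci_amplitude: tuple[float, float]
    ci_mean: tuple[float, float]
    ci_sd: tuple[float, float]
    degrees_of_freedom: int
    r_squared: float
    ss_res: float
    sy_x: float


def _gauss(x, a, mu, sigma):
    return a * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def fit_gaussian(counts, centers=None) -> GaussianFitResult:
    """Unweighted least-squares fit of ``A*exp(-(x-mu)^2 / (2 sigma^2))``.

    Initialized at the count maximum / count-weighted mean and SD;
    asymptotic standard errors and t-based 95% CIs; ordinary R^2 about the
    mean of the counts (GraphPad-style for nonlinear fits).
    """
    y = np.asarray(counts, dtype=float)
    x = np.arange(len(y), dtype=float) if centers is None else np.asarray(centers, dtype=float)
    if len(x) != len(y):
        raise ValueError("counts and centers differ in length")
    if len(y) < 4:
        raise ValueError("need at least 4 points for a 3-parameter fit")
    if not y.any():
        raise ValueError("all-zero counts")
    total = y.sum()
    mu0 = float((x * y).sum() / total)
    sd0 = float(math.sqrt(((x - mu0) ** 2 * y).sum() / total)) or 1.0
    p0 = [float(y.max()), mu0, sd0]
    try:
        popt, pcov = optimize.curve_fit(_gauss, x, y, p0=p0, maxfev=10000)
    except RuntimeError as exc:
        raise RuntimeError(f"Gaussian fit did not converge: {exc}") from exc
    a, mu, sigma = popt
    sigma = abs(float(sigma))
    residuals = y - _gauss(x, a, mu, sigma)
    ss_res = float((residuals**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    df = len(y) - 3
    se = np.sqrt(np.diag(pcov))
    tcrit = float(sps.t.ppf(0.975, df))
    ci = [(float(p - tcrit * s), float(p + tcrit * s)) for p, s in zip((a, mu, sigma), se)]
    return GaussianFitResult(
        amplitude=float(a),
        mean=float(mu),
        sd=sigma,
        se_amplitude=float(se[0]),
        se_mean=float(se[1]),
        se_sd=float(se[2]),
        ci_amplitude=ci[0],
        ci_mean=ci[1],
        ci_sd=ci[2],
        degrees_of_freedom=df,
        r_squared=1.0 - ss_res / ss_tot,
        ss_res=ss_res,
        sy_x=math.sqrt(ss_res / df),
    )


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    n: int


def _ranks(x: np.ndarray) -> np.ndarray:
    """Mean ranks with ties averaged (1-based)."""
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=float)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i: j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman(x, y) -> SpearmanResult:
    """Spearman rank correlation with mean-rank ties; two-sided p via the
    t-distribution approximation with n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    rx, ry = _ranks(x), _ranks(y)
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("zero rank variance")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return SpearmanResult(rho=rho, p_value=p, n=n)
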