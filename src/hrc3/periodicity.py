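"""Fixed-period periodogram power, Fisher-type significance, and window scans.

The statistic is the classical Schuster periodogram at one fixed period T,
normalized by the (divisor-n) sample variance of the mean-centered signal:

    c = Σ_j x̃_j cos(2πj/T),  s = Σ_j x̃_j sin(2πj/T),  j = 1..n
    σ̂² = (1/n) Σ_j x̃_j²
    P = (c² + s²) / (n σ̂²)

Under i.i.d. Gaussian noise at a Fourier period, P is exponentially distributed
with unit mean, so Fisher's single-frequency test applies:
exact p = (1 − P/n)^(n−1), approximate p = exp(−P). For a pure cosine of
period T with n a multiple of T, P = n/2 regardless of amplitude.

"HRC3" refers to this power at T = 3 bp evaluated on the HRC profile of a
180-bp window (P_HRC180(3)) or a centered 100-bp window (P_HRC100(3)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .hrc_model import HRCProfile
from .sequence_io import GenomicInterval

__all__ = [
    "PeriodogramResult",
    "GeneScore",
    "ScanResult",
    "periodogram_power",
    "fisher_p",
    "score_window",
    "scan_gene",
    "call_periodic_intervals",
]

DEFAULT_WINDOW = 180
DEFAULT_PERIOD = 3.0


@dataclass(frozen=True)
class PeriodogramResult:
    """Power of the best-fitting harmonic at a fixed period on one interval."""

    period_T: float
    n: int
    power_P: float
    amplitude_R: float
    phase: float
    variance_sigma2: float
    p_exact: float
    p_approx: float
    start: int = 0  # interval start in profile/sequence coordinates, if known


@dataclass(frozen=True)
class GeneScore:
    """Per-gene HRC3 score: periodogram power at T=3 on a 180-bp window."""

    gene_id: str
    P_HRC3: float
    p_value: float
    window_start: int
    source: str  # {"homeobox_window", "max_over_gene"}


@dataclass
class ScanResult:
    """Per-center powers of a sliding-window scan plus the called intervals."""

    window_length: int
    period: float
    centers: np.ndarray  # sequence coordinates of window centers
    powers: np.ndarray
    called_intervals: list[GenomicInterval]


def fisher_p(P: float, n: Optional[int] = None, mode: str = "approx") -> float:
    """Significance of periodogram power P at a single fixed frequency.

    exact: (1 − P/n)^(n−1) for P < n (0 beyond); approx: exp(−P).
    """
    if P < 0:
        raise ValueError("power must be non-negative")
    if mode == "approx":
        return math.exp(-P)
    if mode == "exact":
        if n is None or n < 2:
            raise ValueError("exact mode requires n >= 2")
        if P >= n:
            return 0.0
        return min(1.0, max(0.0, (1.0 - P / n) ** (n - 1)))
    raise ValueError(f"unknown mode {mode!r}")


def periodogram_power(values, T: float = DEFAULT_PERIOD, start: int = 0) -> PeriodogramResult:
    """Periodogram power at period T over one interval of n values.

    Raises on fewer than 4 points or a degenerate (constant) signal. Masked
    (NaN) values are not permitted here; handle them upstream.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError(f"need at least 4 points, got {n}")
    if np.any(~np.isfinite(x)):
        raise ValueError("non-finite values in periodogram input")
    xt = x - x.mean()
    sigma2 = float(np.mean(xt**2))
    if sigma2 == 0.0:
        raise ValueError("degenerate signal: zero variance")
    j = np.arange(1, n + 1)
    c = float(np.dot(xt, np.cos(2 * np.pi * j / T)))
    s = float(np.dot(xt, np.sin(2 * np.pi * j / T)))
    sq = c * c + s * s
    P = sq / (n * sigma2)
    # Cauchy–Schwarz bound at Fourier periods; tiny slack for float rounding
    assert P <= n * (1 + 1e-9), "power exceeds Cauchy-Schwarz bound"
    R = (2.0 / n) * math.sqrt(sq)
    phase = math.atan2(s, c) % (2 * math.pi)
    return PeriodogramResult(
        period_T=float(T),
        n=n,
        power_P=P,
        amplitude_R=R,
        phase=phase,
        variance_sigma2=sigma2,
        p_exact=fisher_p(P, n, "exact"),
        p_approx=fisher_p(P, mode="approx"),
        start=start,
    )


def _window_values(profile: HRCProfile, start: int, window: int) -> np.ndarray:
    if start < profile.offset_in_sequence or start + window > profile.end_in_sequence:
        raise ValueError(
            f"window [{start}, {start + window}) outside profiled range "
            f"[{profile.offset_in_sequence}, {profile.end_in_sequence})"
        )
    a = start - profile.offset_in_sequence
    if profile.mask[a : a + window].any():
        raise ValueError("window contains masked positions")
    return profile.values[a : a + window]


def score_window(
    profile: HRCProfile,
    start: int,
    window: int = DEFAULT_WINDOW,
    T: float = DEFAULT_PERIOD,
    gene_id: Optional[str] = None,
    source: str = "homeobox_window",
) -> GeneScore:
    """Score one window (sequence coordinates [start, start+window)) at period T."""
    res = periodogram_power(_window_values(profile, start, window), T, start=start)
    return GeneScore(
        gene_id=gene_id if gene_id is not None else profile.sequence_id,
        P_HRC3=res.power_P,
        p_value=res.p_approx,
        window_start=start,
        source=source,
    )


def windowed_powers(values: np.ndarray, window: int, T: float = DEFAULT_PERIOD) -> np.ndarray:
    """Periodogram power for every full window (step 1) over a value array.

    Returns powers[k] for the window starting at index k; windows containing
    NaN or with zero variance yield NaN.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < window:
        raise ValueError(f"profile length {n} < window {window}")
    j = np.arange(1, window + 1)
    cosv = np.cos(2 * np.pi * j / T)
    sinv = np.sin(2 * np.pi * j / T)
    # correlate(x, kernel, 'valid')[k] = sum_u x[k+u] * kernel[u]
    c_raw = np.correlate(x, cosv, mode="valid")
    s_raw = np.correlate(x, sinv, mode="valid")
    ones = np.ones(window)
    sums = np.correlate(x, ones, mode="valid")
    sqs = np.correlate(x * x, ones, mode="valid")
    means = sums / window
    # mean-centering corrections (Σcos, Σsin vanish only when T divides window)
    c = c_raw - means * cosv.sum()
    s = s_raw - means * sinv.sum()
    var = sqs / window - means**2
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(var > 0, (c * c + s * s) / (window * var), np.nan)
    # windows touching NaN input propagate NaN through the correlations already
    return P


def scan_gene(
    profile: HRCProfile,
    window: int = DEFAULT_WINDOW,
    T: float = DEFAULT_PERIOD,
    step: int = 1,
    gene_id: Optional[str] = None,
) -> GeneScore:
    """Maximum windowed power over all window start positions (step 1 by default).

    This is the gene-level P_HRC3 used with fixed thresholds (6 and 10) in
    genome-wide searches. Ties are broken by the smallest start coordinate.
    """
    x = np.where(profile.mask, np.nan, profile.values)
    P = windowed_powers(x, window, T)[::step]
    if np.all(np.isnan(P)):
        raise ValueError("no scorable window (all windows masked or degenerate)")
    k = int(np.nanargmax(P))
    start = profile.offset_in_sequence + k * step
    return GeneScore(
        gene_id=gene_id if gene_id is not None else profile.sequence_id,
        P_HRC3=float(P[k]),
        p_value=fisher_p(float(P[k]), mode="approx"),
        window_start=start,
        source="max_over_gene",
    )


def call_periodic_intervals(
    profile: HRCProfile,
    window: int = 100,
    T: float = DEFAULT_PERIOD,
    power_min: float = 1.8,
    run_min: int = 80,
    chrom: Optional[str] = None,
) -> ScanResult:
    """Call periodic intervals: runs of >= run_min consecutive centers whose
    centered window power is >= power_min.

    The power at center i uses the window [i − window//2, i − window//2 + window);
    positions without a full centered window (sequence ends) are excluded. A
    qualifying run [first, last] of centers is emitted as the half-open interval
    [first, last+1) in sequence coordinates.
    """
    x = np.where(profile.mask, np.nan, profile.values)
    if len(x) < window:
        raise ValueError(f"profile length {len(x)} < window {window}")
    P = windowed_powers(x, window, T)
    half = window // 2
    centers = profile.offset_in_sequence + half + np.arange(len(P))
    ok = np.nan_to_num(P, nan=-np.inf) >= power_min
    intervals: list[GenomicInterval] = []
    name = chrom if chrom is not None else profile.sequence_id
    run_start = None
    padded = np.concatenate([ok, [False]])
    for i, q in enumerate(padded):
        if q and run_start is None:
            run_start = i
        elif not q and run_start is not None:
            if i - run_start >= run_min:
                intervals.append(
                    GenomicInterval(name, int(centers[run_start]), int(centers[i - 1]) + 1)
                )
            run_start = None
    return ScanResult(
        window_length=window, period=T, centers=centers, powers=P, called_intervals=intervals
    )
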