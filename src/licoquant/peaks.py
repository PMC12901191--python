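"""Chromatographic peak processing.

Turns raw MRM chromatogram traces into per-transition peak measurements:
robust noise estimation, apex detection with parabolic interpolation,
trapezoidal integration over a linear local baseline, and signal-to-noise
estimation from a flanking baseline window.

S/N is defined as baseline-corrected peak height divided by the standard
deviation of the linearly detrended flanking baseline. The classical
3:1 / 10:1 thresholds classify a peak as detectable / quantifiable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "Chromatogram",
    "PeakApex",
    "PeakMeasurement",
    "detect_peaks",
    "integrate_peak",
    "signal_to_noise",
    "classify_sn",
]


@dataclass(frozen=True)
class Chromatogram:
    """Uniformly sampled intensity trace for one MRM transition."""

    transition: str
    time: np.ndarray       # minutes, strictly increasing, uniform
    intensity: np.ndarray  # detector counts

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        if t.ndim != 1 or t.shape != y.shape:
            raise ValueError("time and intensity must be 1-D arrays of equal length")
        if t.size >= 2:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if np.max(np.abs(dt - dt[0])) > 1e-9:
                raise ValueError("sampling grid must be uniform (within 1e-9)")
        if not np.all(np.isfinite(y)):
            raise ValueError("intensities must be finite")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "intensity", y)

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass(frozen=True)
class PeakApex:
    index: int
    rt: float       # parabolically interpolated apex time, min
    intensity: float


@dataclass(frozen=True)
class PeakMeasurement:
    """Integrated peak: the atom of calibration and quantification."""

    transition: str
    rt: float
    area: float          # counts * s
    height: float        # baseline-corrected counts
    baseline: float      # baseline level at apex
    noise_sd: float = float("nan")
    s_n: float = float("nan")

    def __post_init__(self) -> None:
        if self.area < 0 or self.height < 0:
            raise ValueError("area and height must be >= 0")


def _robust_noise_sd(y: np.ndarray) -> float:
    """MAD-based sd estimate, insensitive to sparse peaks."""
    med = np.median(y)
    mad = np.median(np.abs(y - med))
    return 1.4826 * float(mad)


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y
    kernel = np.ones(window) / window
    return np.convolve(y, kernel, mode="same")


def detect_peaks(
    chrom: Chromatogram,
    threshold_sigma: float = 3.0,
    smooth_window: int = 5,
) -> list[PeakApex]:
    """Find candidate apexes above baseline + threshold_sigma * noise.

    Baseline and noise sd are estimated robustly (median / MAD) from the
    raw trace; detection runs on a lightly moving-average-smoothed copy
    so that single-sample noise excursions do not register as peaks. A
    flat or empty-looking trace returns an empty list. Apex retention
    time refines the sample maximum by parabolic interpolation of the
    top three raw samples; ties between equal-height adjacent samples
    resolve to the earlier time.
    """
    y = chrom.intensity
    if y.size < 20:
        raise ValueError("need at least 20 samples")
    baseline = float(np.median(y))
    noise_sd = _robust_noise_sd(y)
    ys = _smooth(y, smooth_window)
    height_min = baseline + threshold_sigma * noise_sd
    idx, _ = find_peaks(ys, height=height_min if noise_sd > 0 else baseline + 1e-12)

    apexes: list[PeakApex] = []
    for i in idx:
        # re-locate on the raw trace near the smoothed maximum
        lo = max(0, i - smooth_window)
        hi = min(y.size, i + smooth_window + 1)
        j = lo + int(np.argmax(y[lo:hi]))  # argmax ties -> earlier sample
        rt = _parabolic_rt(chrom, j)
        apexes.append(PeakApex(index=j, rt=rt, intensity=float(y[j])))
    # merge duplicates that re-located to the same raw sample
    seen: dict[int, PeakApex] = {}
    for a in apexes:
        seen.setdefault(a.index, a)
    return sorted(seen.values(), key=lambda a: a.rt)


def _parabolic_rt(chrom: Chromatogram, j: int) -> float:
    y = chrom.intensity
    if j == 0 or j == y.size - 1:
        return float(chrom.time[j])
    y0, y1, y2 = y[j - 1], y[j], y[j + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(chrom.time[j])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    return float(chrom.time[j] + delta * chrom.dt)


def integrate_peak(
    chrom: Chromatogram,
    apex: PeakApex,
    window: tuple[float, float],
) -> PeakMeasurement:
    """Trapezoidal area above a straight baseline between window endpoints.

    The window is (start min, end min) within the trace span; the
    baseline is the chord joining the endpoint intensities. Height is
    apex intensity minus the baseline at the apex. Area is reported in
    counts*s (time axis converted from minutes).
    """
    t, y = chrom.time, chrom.intensity
    lo, hi = window
    if lo < t[0] - 1e-12 or hi > t[-1] + 1e-12 or hi <= lo:
        raise ValueError("window outside trace span")
    mask = (t >= lo) & (t <= hi)
    if mask.sum() < 3:
        raise ValueError("window narrower than 3 samples")
    tw, yw = t[mask], y[mask]
    slope = (yw[-1] - yw[0]) / (tw[-1] - tw[0])
    base = yw[0] + slope * (tw - tw[0])
    corrected = yw - base
    area = float(np.trapezoid(corrected, tw)) * 60.0  # min -> s
    base_at_apex = float(yw[0] + slope * (apex.rt - tw[0]))
    height = apex.intensity - base_at_apex
    return PeakMeasurement(
        transition=chrom.transition,
        rt=apex.rt,
        area=max(area, 0.0),
        height=max(height, 0.0),
        baseline=base_at_apex,
    )


def signal_to_noise(
    peak: PeakMeasurement,
    chrom: Chromatogram,
    noise_window: tuple[float, float],
) -> PeakMeasurement:
    """Attach an S/N estimate from a peak-free flanking baseline window.

    The flanking segment is linearly detrended; S/N = height / sd of the
    residuals. A zero-variance window yields an infinite S/N (flagged by
    the value itself).
    """
    t, y = chrom.time, chrom.intensity
    lo, hi = noise_window
    mask = (t >= lo) & (t <= hi)
    if mask.sum() < 4:
        raise ValueError("noise window too narrow")
    tw, yw = t[mask], y[mask]
    coef = np.polyfit(tw, yw, 1)
    resid = yw - np.polyval(coef, tw)
    sd = float(np.std(resid, ddof=2))
    if sd == 0.0:
        return replace(peak, noise_sd=0.0, s_n=math.inf)
    return replace(peak, noise_sd=sd, s_n=peak.height / sd)


def classify_sn(s_n: float) -> str:
    """Classify by the 3:1 / 10:1 convention."""
    if s_n < 3.0:
        return "not detectable"
    if s_n < 10.0:
        return "detectable, not quantifiable"
    return "quantifiable"
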