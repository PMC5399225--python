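"""Heart-rate-variability and Baevsky stress-index features from interbeat intervals.

The interbeat-interval (IBI) series is the raw cardiac input: beat onset
times (ms since session start) paired with the beat-to-beat interval that
ended at each onset.  From a cleaned series this module computes

* time-domain HRV (mean/median RR, mean HR, SDNN, RMSSD, NN50, pNN50),
* frequency-domain HRV (VLF/LF/HF band powers from a Welch periodogram of
  the evenly resampled RR tachogram, with percent and normalized-unit
  variants), and
* the Baevsky stress index SI = AMo / (2 * Mo * MxDMn), a sympathetic
  dominance summary of the IBI histogram.

All window arguments are half-open ``[start, end)`` intervals in ms; an
interval belongs to a window when its onset falls inside it.  Features that
cannot be computed (too few beats, empty window, degenerate histogram) are
returned as NaN together with a machine-readable reason code rather than
raised, so downstream feature tables can carry missingness explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import signal as _signal
from scipy.interpolate import CubicSpline
from scipy.ndimage import median_filter

__all__ = [
    "IbiSeries",
    "HrvTimeFeatures",
    "HrvFreqFeatures",
    "BayevskyInputs",
    "clean_ibi",
    "hrv_time",
    "hrv_freq",
    "bayevsky_si",
    "VLF_BAND",
    "LF_BAND",
    "HF_BAND",
]

# Task Force band conventions (Hz)
VLF_BAND = (0.0033, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)

# Artifact rule: physiologically plausible interval range (ms) and maximum
# relative deviation from the running median of 5 neighbours.
ARTIFACT_MIN_MS = 300.0
ARTIFACT_MAX_MS = 2000.0
ARTIFACT_REL_DEV = 0.25

BAYEVSKY_BIN_MS = 50.0


@dataclass(frozen=True)
class IbiSeries:
    """Timestamped interbeat intervals for one session.

    ``onsets`` are beat times in ms since session start, strictly
    increasing; ``intervals`` are the beat-to-beat gaps in ms, one per
    onset (``onsets[i+1] - onsets[i] ~= intervals[i+1]``).
    """

    onsets: np.ndarray
    intervals: np.ndarray

    def __post_init__(self):
        onsets = np.asarray(self.onsets, dtype=float)
        intervals = np.asarray(self.intervals, dtype=float)
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "intervals", intervals)
        if onsets.shape != intervals.shape:
            raise ValueError("onsets and intervals must have equal length")
        if onsets.size and np.any(np.diff(onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if np.any(intervals <= 0):
            raise ValueError("intervals must be positive")

    def __len__(self) -> int:
        return self.onsets.size

    @classmethod
    def from_intervals(cls, intervals, start_ms: float = 0.0) -> "IbiSeries":
        """Build a series from consecutive intervals; onsets are cumulative."""
        intervals = np.asarray(intervals, dtype=float)
        onsets = start_ms + np.cumsum(intervals)
        return cls(onsets=onsets, intervals=intervals)

    def in_window(self, window: Optional[Tuple[float, float]]) -> "IbiSeries":
        """Intervals whose onset lies in the half-open window [start, end)."""
        if window is None:
            return self
        start, end = window
        mask = (self.onsets >= start) & (self.onsets < end)
        return IbiSeries(onsets=self.onsets[mask], intervals=self.intervals[mask])


@dataclass(frozen=True)
class HrvTimeFeatures:
    mean_rr: float = np.nan   # ms
    median_rr: float = np.nan  # ms
    mean_hr: float = np.nan   # beats/min
    sdnn: float = np.nan      # ms, sample SD (n-1)
    rmssd: float = np.nan     # ms
    nn50: float = np.nan      # count of successive diffs > 50 ms
    pnn50: float = np.nan     # percent
    reason: Optional[str] = None


@dataclass(frozen=True)
class HrvFreqFeatures:
    vlf_power: float = np.nan  # ms^2
    lf_power: float = np.nan
    hf_power: float = np.nan
    lf_pct: float = np.nan     # percent of total (VLF+LF+HF) power
    hf_pct: float = np.nan
    lf_nu: float = np.nan      # LF/(LF+HF) * 100
    hf_nu: float = np.nan
    lf_hf_ratio: float = np.nan
    reason: Optional[str] = None


@dataclass(frozen=True)
class BayevskyInputs:
    mo: float = np.nan      # mode of the IBI histogram, seconds
    amo: float = np.nan     # modal-bin share, percent
    mxdmn: float = np.nan   # max - min interval, seconds
    si: float = np.nan      # stress index = amo / (2 * mo * mxdmn)
    reason: Optional[str] = None


def clean_ibi(raw: IbiSeries) -> Tuple[IbiSeries, int]:
    """Remove artifact intervals; returns (cleaned series, n removed).

    An interval is an artifact when it lies outside [300, 2000] ms or
    deviates more than 25% from the running median of its 5-interval
    neighbourhood (edges replicate the boundary value).
    """
    if len(raw) == 0:
        raise ValueError("cannot clean an empty IBI series")
    iv = raw.intervals
    n = iv.size
    if n >= 5:
        med = median_filter(iv, size=5, mode="nearest")
    else:
        med = np.full(n, np.median(iv))
    ok = (iv >= ARTIFACT_MIN_MS) & (iv <= ARTIFACT_MAX_MS)
    with np.errstate(divide="ignore", invalid="ignore"):
        ok &= np.abs(iv - med) <= ARTIFACT_REL_DEV * med
    cleaned = IbiSeries(onsets=raw.onsets[ok], intervals=raw.intervals[ok])
    return cleaned, int(n - ok.sum())


def hrv_time(ibi: IbiSeries, window: Optional[Tuple[float, float]] = None) -> HrvTimeFeatures:
    """Time-domain HRV on the intervals whose onset lies in ``window``."""
    w = ibi.in_window(window)
    iv = w.intervals
    if iv.size == 0:
        return HrvTimeFeatures(reason="empty_window")
    mean_rr = float(np.mean(iv))
    median_rr = float(np.median(iv))
    mean_hr = 60000.0 / mean_rr
    if iv.size < 2:
        return HrvTimeFeatures(mean_rr=mean_rr, median_rr=median_rr,
                               mean_hr=mean_hr, reason="too_few_intervals")
    sdnn = float(np.std(iv, ddof=1))
    d = np.diff(iv)
    rmssd = float(np.sqrt(np.mean(d ** 2)))
    nn50 = int(np.sum(np.abs(d) > 50.0))
    pnn50 = 100.0 * nn50 / d.size
    return HrvTimeFeatures(mean_rr=mean_rr, median_rr=median_rr, mean_hr=mean_hr,
                           sdnn=sdnn, rmssd=rmssd, nn50=nn50, pnn50=pnn50)


_RESAMPLE_HZ = 4.0


def hrv_freq(ibi: IbiSeries, window: Optional[Tuple[float, float]] = None,
             min_duration_s: float = 30.0) -> HrvFreqFeatures:
    """Frequency-domain HRV via spline-resampled tachogram + Welch periodogram.

    The RR tachogram (interval vs onset) is cubic-spline resampled at 4 Hz,
    linearly detrended, and its Welch power spectrum integrated over the
    VLF/LF/HF bands.  Requires at least ``min_duration_s`` of valid beats.
    """
    w = ibi.in_window(window)
    if len(w) < 4:
        return HrvFreqFeatures(reason="too_few_intervals")
    span_s = (w.onsets[-1] - w.onsets[0]) / 1000.0
    if span_s < min_duration_s:
        return HrvFreqFeatures(reason="window_too_short")
    t = w.onsets / 1000.0
    spline = CubicSpline(t, w.intervals)
    ts = np.arange(t[0], t[-1], 1.0 / _RESAMPLE_HZ)
    x = spline(ts)
    x = _signal.detrend(x, type="linear")
    nperseg = min(256, x.size)
    freqs, psd = _signal.welch(x, fs=_RESAMPLE_HZ, nperseg=nperseg,
                               detrend=False, scaling="density")

    def band_power(lo, hi):
        m = (freqs >= lo) & (freqs < hi)
        return float(np.trapezoid(psd[m], freqs[m])) if m.sum() > 1 else 0.0

    vlf = band_power(*VLF_BAND)
    lf = band_power(*LF_BAND)
    hf = band_power(*HF_BAND)
    total = vlf + lf + hf
    lf_pct = 100.0 * lf / total if total > 0 else np.nan
    hf_pct = 100.0 * hf / total if total > 0 else np.nan
    denom = lf + hf
    lf_nu = 100.0 * lf / denom if denom > 0 else np.nan
    hf_nu = 100.0 * hf / denom if denom > 0 else np.nan
    ratio = lf / hf if hf > 0 else np.nan
    return HrvFreqFeatures(vlf_power=vlf, lf_power=lf, hf_power=hf,
                           lf_pct=lf_pct, hf_pct=hf_pct,
                           lf_nu=lf_nu, hf_nu=hf_nu, lf_hf_ratio=ratio)


def bayevsky_si(ibi: IbiSeries, window: Optional[Tuple[float, float]] = None,
                bin_ms: float = BAYEVSKY_BIN_MS) -> BayevskyInputs:
    """Baevsky stress index from the IBI histogram.

    Histogram bins are ``bin_ms`` wide and aligned at 0 ms; Mo is the modal
    bin midpoint in seconds, AMo the percent of intervals in the modal bin,
    MxDMn the interval range in seconds.  SI = AMo / (2 * Mo * MxDMn).
    Modal-bin ties break toward the lower bin.
    """
    w = ibi.in_window(window)
    iv = w.intervals
    if iv.size < 5:
        return BayevskyInputs(reason="too_few_intervals")
    idx = np.floor(iv / bin_ms).astype(int)
    counts = np.bincount(idx)
    modal = int(np.argmax(counts))  # argmax takes the first (lower) tie
    mo = (modal + 0.5) * bin_ms / 1000.0
    amo = 100.0 * counts[modal] / iv.size
    mxdmn = float(iv.max() - iv.min()) / 1000.0
    if mxdmn == 0.0:
        return BayevskyInputs(mo=mo, amo=amo, mxdmn=0.0, reason="zero_range")
    si = amo / (2.0 * mo * mxdmn)
    return BayevskyInputs(mo=mo, amo=amo, mxdmn=mxdmn, si=si)
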