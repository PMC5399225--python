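"""Electrodermal activity: tonic/phasic decomposition and SCR detection.

Skin conductance (µS) is modelled as a slow tonic level plus transient
skin-conductance responses (SCRs).  The decomposition here is a smoothing
surrogate: the tonic estimate is a long moving median of a lightly smoothed
signal, and the phasic component is defined as the raw signal minus tonic,
so tonic + phasic reconstructs the input exactly.  SCRs are then detected
trough-to-peak on the phasic component with a minimum-amplitude gate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage
from scipy import signal as _signal

__all__ = ["EdaTrace", "EdaFeatures", "decompose_eda", "detect_scr"]

DEFAULT_MIN_AMPLITUDE_US = 0.01  # common SCR amplitude threshold
SMOOTH_S = 0.5    # moving-average width used before tonic estimation
TONIC_S = 30.0    # moving-median width of the tonic estimate


@dataclass(frozen=True)
class EdaTrace:
    """Uniformly sampled skin-conductance signal (µS)."""

    sample_rate: float  # Hz
    values: np.ndarray
    start: float = 0.0  # ms since session start

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("EDA values must be finite")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times_ms(self) -> np.ndarray:
        return self.start + np.arange(self.values.size) * 1000.0 / self.sample_rate

    def window_slice(self, window: Tuple[float, float]) -> slice:
        """Sample-index slice for the half-open ms window [start, end)."""
        lo = int(np.ceil((window[0] - self.start) * self.sample_rate / 1000.0))
        hi = int(np.ceil((window[1] - self.start) * self.sample_rate / 1000.0))
        return slice(max(lo, 0), max(min(hi, len(self)), 0))


@dataclass(frozen=True)
class EdaFeatures:
    scr_sum: float = np.nan     # µS, sum of detected response amplitudes
    scr_count: float = np.nan
    phasic_max: float = np.nan  # µS
    tonic_level: float = np.nan  # µS, median tonic in window
    reason: Optional[str] = None


def _odd(n: int) -> int:
    return n if n % 2 == 1 else n + 1


def decompose_eda(trace: EdaTrace) -> Tuple[EdaTrace, EdaTrace]:
    """Split a trace into (tonic, phasic) with tonic + phasic == raw exactly.

    Tonic = 30 s moving median of the 0.5 s moving-average-smoothed signal;
    the median window is long relative to a single SCR (a 1 s rise / 4 s
    decay response spans roughly 15 s), so isolated responses stay in the
    phasic component.  Phasic = raw - tonic.
    """
    if len(trace) / trace.sample_rate < 10.0:
        raise ValueError("EDA decomposition requires at least 10 s of signal")
    x = trace.values
    smooth_n = _odd(max(1, int(round(SMOOTH_S * trace.sample_rate))))
    smoothed = ndimage.uniform_filter1d(x, size=smooth_n, mode="nearest")
    tonic_n = _odd(max(3, int(round(TONIC_S * trace.sample_rate))))
    tonic = ndimage.median_filter(smoothed, size=tonic_n, mode="nearest")
    phasic = x - tonic
    mk = lambda v: EdaTrace(sample_rate=trace.sample_rate, values=v, start=trace.start)
    return mk(tonic), mk(phasic)


def detect_scr(phasic: EdaTrace, window: Tuple[float, float],
               min_amplitude: float = DEFAULT_MIN_AMPLITUDE_US,
               tonic: Optional[EdaTrace] = None) -> EdaFeatures:
    """Trough-to-peak SCR detection on the phasic signal within a window.

    A response is a local maximum of the phasic component whose rise from
    the preceding trough is at least ``min_amplitude`` µS.  ``scr_sum`` is
    the sum of those rise amplitudes, ``phasic_max`` the largest positive
    phasic excursion in the window, and ``tonic_level`` the median of the
    tonic component there (NaN when no tonic trace is supplied).
    """
    sl = phasic.window_slice(window)
    x = phasic.values[sl]
    if x.size == 0:
        return EdaFeatures(reason="empty_window")
    peaks, _ = _signal.find_peaks(x)
    troughs, _ = _signal.find_peaks(-x)
    amplitudes = []
    for p in peaks:
        prior = troughs[troughs < p]
        base = x[prior[-1]] if prior.size else x[0]
        amp = x[p] - base
        if amp >= min_amplitude:
            amplitudes.append(amp)
    tonic_level = np.nan
    if tonic is not None:
        tv = tonic.values[tonic.window_slice(window)]
        if tv.size:
            tonic_level = float(np.median(tv))
    return EdaFeatures(
        scr_sum=float(np.sum(amplitudes)) if amplitudes else 0.0,
        scr_count=len(amplitudes),
        phasic_max=float(max(x.max(), 0.0)),
        tonic_level=tonic_level,
    )
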