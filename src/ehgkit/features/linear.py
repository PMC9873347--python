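"""Linear (time- and frequency-domain) window features.

Five features per window: peak-PSD frequency (MaxFreq), median frequency
(MedFreq, the 50%-power frequency), root mean square (RMS), zero-crossing
rate (ZCR) and peak-to-peak amplitude (Amp).  The spectral features are
evaluated inside the window's subband on a Welch periodogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from ..records import BandDefinition

#: Welch settings: 512-sample Hann segments with 50% overlap give >= 8
#: averages on a 2400-sample window at a 0.039-Hz frequency step, enough to
#: resolve the 0.3-Hz lower band edge.
WELCH_NPERSEG = 512


@dataclass(frozen=True)
class PSDEstimate:
    """One-sided Welch power spectral density."""

    frequencies: np.ndarray
    power: np.ndarray
    nperseg: int
    fs_hz: float


def rms(window: np.ndarray) -> float:
    """Root mean square, sqrt(mean(x^2))."""
    x = np.asarray(window, dtype=float)
    if x.size == 0:
        raise ValueError("empty window")
    return float(np.sqrt(np.mean(x * x)))


def amplitude(window: np.ndarray) -> float:
    """Peak-to-peak amplitude, max(x) - min(x)."""
    x = np.asarray(window, dtype=float)
    if x.size == 0:
        raise ValueError("empty window")
    return float(x.max() - x.min())


def zero_crossing_rate(window: np.ndarray, fs_hz: float) -> float:
    """Strict sign changes per second.

    An exact zero inherits the sign of the previous sample so that a
    touch-and-go zero is not counted twice.
    """
    x = np.asarray(window, dtype=float)
    if x.size == 0:
        raise ValueError("empty window")
    # an exact zero inheriting the previous sign is equivalent to dropping
    # zeros and counting sign changes among the remaining samples
    s = np.sign(x)
    s = s[s != 0]
    crossings = int(np.count_nonzero(s[1:] != s[:-1]))
    return crossings / (x.size / fs_hz)


def psd_welch(window: np.ndarray, fs_hz: float,
              nperseg: int = WELCH_NPERSEG) -> PSDEstimate:
    x = np.asarray(window, dtype=float)
    nperseg = min(nperseg, x.size)
    f, p = sps.welch(x, fs=fs_hz, window="hann", nperseg=nperseg,
                     noverlap=nperseg // 2, detrend=False)
    return PSDEstimate(frequencies=f, power=p, nperseg=nperseg, fs_hz=fs_hz)


def _band_slice(psd: PSDEstimate, band: BandDefinition) -> np.ndarray:
    mask = (psd.frequencies >= band.low_hz) & (psd.frequencies <= band.high_hz)
    if not mask.any():
        raise ValueError(
            f"PSD (df={psd.frequencies[1] - psd.frequencies[0]:.4f} Hz) has "
            f"no bins inside band {band.name}")
    return mask


def max_frequency(psd: PSDEstimate, band: BandDefinition) -> float:
    """Frequency of maximal PSD within the band (ties -> lowest frequency)."""
    mask = _band_slice(psd, band)
    f = psd.frequencies[mask]
    p = psd.power[mask]
    return float(f[int(np.argmax(p))])  # argmax takes the first (lowest) tie


def medium_frequency(psd: PSDEstimate, band: BandDefinition) -> float:
    """Median (50%-power) frequency within the band, linearly interpolated.

    The smallest frequency at which the cumulative in-band power reaches
    half the total in-band power; the crossing is interpolated between the
    two straddling PSD bins.
    """
    mask = _band_slice(psd, band)
    f = psd.frequencies[mask]
    p = psd.power[mask]
    total = p.sum()
    if total <= 0:
        raise ValueError(f"zero power inside band {band.name}")
    cum = np.cumsum(p)
    half = total / 2.0
    i = int(np.searchsorted(cum, half))
    if i == 0:
        return float(f[0])
    # linear interpolation between cum[i-1] and cum[i]
    frac = (half - cum[i - 1]) / (cum[i] - cum[i - 1])
    return float(f[i - 1] + frac * (f[i] - f[i - 1]))
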