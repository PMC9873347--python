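"""Time-frequency window features.

Continuous wavelet transform (CWT) scalogram features — Energy and Flux at
0/45/90 degrees — and discrete wavelet transform (DWT) adjacent-level
log-energy differences.

The CWT uses the analytic generalized Morse wavelet with symmetry parameter
gamma = 3 and time-bandwidth product P^2 = 60 (hence beta = P^2/gamma = 20),
evaluated in the frequency domain:

    psi_hat(omega) = 2 * exp(beta * ln(omega/omega_p) - omega^gamma
                             + omega_p^gamma),   omega > 0,

with peak frequency omega_p = (beta/gamma)^(1/gamma).  The peak value 2
realizes L1 normalization for an analytic wavelet: unit-amplitude tones at
any frequency attain unit ridge magnitude.  Scales sit on a dyadic grid with
10 voices per octave.

The DWT uses the order-12 Daubechies wavelet over 7 levels with
periodization extension, so the level energies satisfy Parseval's identity
exactly (orthogonal family).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt

#: Flux direction -> (k1, k2) offsets along (time, frequency).
FLUX_OFFSETS = {0: (0, 1), 45: (1, 1), 90: (1, 0)}


@dataclass(frozen=True)
class WaveletParams:
    """CWT and DWT settings."""

    gamma: float = 3.0
    time_bandwidth: float = 60.0
    voices_per_octave: int = 10
    dwt_wavelet: str = "db12"
    dwt_levels: int = 7

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.time_bandwidth <= self.gamma:
            raise ValueError("require gamma > 0 and time_bandwidth > gamma")
        if self.voices_per_octave < 4:
            raise ValueError("voices_per_octave must be >= 4")
        if self.dwt_levels < 1:
            raise ValueError("dwt_levels must be >= 1")

    @property
    def beta(self) -> float:
        return self.time_bandwidth / self.gamma

    @property
    def peak_omega(self) -> float:
        return (self.beta / self.gamma) ** (1.0 / self.gamma)


@dataclass
class Scalogram:
    """CWT magnitude over the time-frequency plane (frequency x time)."""

    magnitude: np.ndarray   # (n_freqs, n_times), descending frequency
    frequencies: np.ndarray  # Hz, descending
    times: np.ndarray        # s

    def __post_init__(self) -> None:
        if self.magnitude.shape != (self.frequencies.size, self.times.size):
            raise ValueError("axes do not match magnitude shape")


def _scale_frequencies(fs_hz: float, n: int, params: WaveletParams
                       ) -> np.ndarray:
    """Dyadic frequency grid (Hz, descending) covering the valid range.

    The lowest frequency is set so roughly two wavelet half-widths
    (P cycles each side) fit inside the window.
    """
    p_cycles = math.sqrt(params.time_bandwidth)
    f_min = 2.0 * p_cycles * fs_hz / n
    f_max = fs_hz / 2.0
    n_octaves = math.log2(f_max / f_min)
    n_voices = int(math.floor(n_octaves * params.voices_per_octave)) + 1
    return f_max * 2.0 ** (-np.arange(n_voices) / params.voices_per_octave)


def cwt_scalogram(window: np.ndarray, fs_hz: float,
                  params: WaveletParams | None = None) -> Scalogram:
    """Analytic Morse CWT magnitude of one window.

    L1-normalized: equal-amplitude tones at different frequencies attain
    equal ridge magnitude (within the dyadic-grid discretization).
    """
    params = params or WaveletParams()
    x = np.asarray(window, dtype=np.float64)
    n = x.size
    if n < 64:
        raise ValueError(f"window of {n} samples too short for the CWT")
    freqs = _scale_frequencies(fs_hz, n, params)

    spectrum = np.fft.fft(x)
    omega = 2.0 * np.pi * np.fft.fftfreq(n)  # rad/sample, signed
    pos = omega > 0
    beta, gamma, omega_p = params.beta, params.gamma, params.peak_omega

    mag = np.empty((freqs.size, n), dtype=np.float64)
    filt = np.zeros(n, dtype=np.float64)
    for i, f in enumerate(freqs):
        s = omega_p / (2.0 * np.pi * f / fs_hz)
        so = s * omega[pos]
        filt[:] = 0.0
        filt[pos] = np.exp(beta * np.log(so / omega_p)
                           - so ** gamma + omega_p ** gamma)
        w = np.fft.ifft(spectrum * (2.0 * filt))
        mag[i] = np.abs(w)
    return Scalogram(magnitude=mag, frequencies=freqs,
                     times=np.arange(n) / fs_hz)


def tf_energy(s: Scalogram) -> float:
    """Total scalogram energy, sum of squared magnitudes."""
    return float(np.sum(s.magnitude ** 2))


def tf_flux(s: Scalogram, angle: int) -> float:
    """Mean absolute scalogram difference at offsets (k1, k2) along
    (time, frequency) for angle in {0, 45, 90} degrees."""
    if angle not in FLUX_OFFSETS:
        raise ValueError(f"angle must be one of {sorted(FLUX_OFFSETS)}")
    k1, k2 = FLUX_OFFSETS[angle]
    m = s.magnitude
    if m.shape[0] <= k2 or m.shape[1] <= k1:
        raise ValueError("scalogram too small for the requested offsets")
    shifted = m[k2:, k1:]
    base = m[: m.shape[0] - k2, : m.shape[1] - k1]
    return float(np.mean(np.abs(shifted - base)))


def dwt_level_energies(window: np.ndarray,
                       params: WaveletParams | None = None
                       ) -> tuple[np.ndarray, float]:
    """Detail-coefficient energies E_1..E_L (finest first) plus the
    approximation energy.  With periodization extension the energies sum to
    the signal energy (Parseval)."""
    params = params or WaveletParams()
    x = np.asarray(window, dtype=np.float64)
    min_len = 2 ** params.dwt_levels
    if x.size < min_len:
        raise ValueError(
            f"window of {x.size} samples too short for {params.dwt_levels} "
            "decomposition levels")
    # zero-pad to a multiple of 2^levels: appended zeros leave the signal
    # energy unchanged while keeping every decimation stage even-length, so
    # the periodized orthogonal transform preserves energy exactly
    block = 2 ** params.dwt_levels
    if x.size % block:
        x = np.concatenate([x, np.zeros(block - x.size % block)])
    with warnings.catch_warnings():
        # decomposing past pywt's boundary-effect heuristic is intentional
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(x, params.dwt_wavelet, mode="periodization",
                              level=params.dwt_levels)
    approx, details = coeffs[0], coeffs[1:]  # details: coarsest..finest
    energies = np.array([float(np.sum(d ** 2)) for d in reversed(details)])
    return energies, float(np.sum(approx ** 2))


def dwt_adjacent_differences(energies: np.ndarray) -> dict[str, float]:
    """Log-energy differences of adjacent levels:
    DWT_dj = ln(E_{j+1}) - ln(E_j), j = 1..L-1.

    Energies are floored at 1e-300, so an all-zero level yields a large but
    finite value rather than an infinity.
    """
    e = np.maximum(np.asarray(energies, dtype=np.float64), 1e-300)
    return {f"DWT_d{j + 1}": float(np.log(e[j + 1]) - np.log(e[j]))
            for j in range(e.size - 1)}
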