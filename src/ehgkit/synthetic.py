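"""Synthetic EHG cohort generator.

Emulates the statistical structure the downstream analysis relies on, without
claiming physiological fidelity: a 1/f^alpha baseline, intermittent uterine
contraction bursts whose energy, spectral spread and regularity differ
between the preterm (P) and term (T) classes, and an optional maternal-ECG
interference component (a Gaussian-pulse train at 84 beats/min, i.e. 1.4 Hz,
whose harmonics fall in the 1-2 and 2-3 Hz subbands).

Design choices:

* Burst envelope is a Hann window — smooth onset/offset, no edge artifacts.
* Burst carrier is a mixture ``regularity * sine(f0) + (1 - regularity) *
  band-limited noise``, with f0 drawn uniformly from the carrier band, so a
  single knob controls the regular-vs-irregular contrast that entropy
  features pick up.
* Channels share burst timing (a contraction is a whole-uterus event) but
  have independent noise and per-channel burst gain jitter.
* All randomness flows from one seeded :class:`numpy.random.Generator` per
  record, derived deterministically from ``(config.seed, record_index)``,
  so a cohort is a pure function of its profiles and config.

Default class profiles encode the phenomenology the analysis assumes:
preterm records carry stronger, more regular contraction bursts, while term
records show weaker bursts and more prominent maternal-ECG interference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import write_wfdb_record
from .records import CHANNEL_NAMES, EHGRecord


@dataclass(frozen=True)
class ClassProfile:
    """Generative parameters for one delivery class (P or T)."""

    label: str
    burst_rate: float = 10.0           # expected contractions per 30 min
    burst_duration_s: float = 45.0     # mean burst length, seconds
    burst_duration_sd_s: float = 10.0
    burst_gain: float = 3.0            # burst-to-baseline RMS ratio
    carrier_band_hz: tuple[float, float] = (0.3, 1.0)
    regularity: float = 0.8            # 1 = pure tone carrier, 0 = band noise
    ecg_interference_gain: float = 0.05  # pulse-train RMS / baseline RMS
    baseline_noise_exponent: float = 1.0  # spectral slope of 1/f^alpha
    baseline_rms: float = 1.0

    def __post_init__(self) -> None:
        if self.label not in ("P", "T"):
            raise ValueError("label must be 'P' or 'T'")
        if self.burst_rate < 0:
            raise ValueError("burst_rate must be >= 0")
        if not 0.0 <= self.regularity <= 1.0:
            raise ValueError("regularity must lie in [0, 1]")
        lo, hi = self.carrier_band_hz
        if not 0.0 < lo < hi:
            raise ValueError("carrier band must satisfy 0 < low < high")
        if min(self.burst_gain, self.ecg_interference_gain,
               self.baseline_rms) < 0:
            raise ValueError("gains must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation settings."""

    n_P: int = 20
    n_T: int = 20
    fs_hz: float = 20.0
    duration_s: float = 1800.0
    n_channels: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1 or self.n_channels > len(CHANNEL_NAMES):
            raise ValueError(f"n_channels must be in 1..{len(CHANNEL_NAMES)}")
        if self.fs_hz <= 0 or self.duration_s <= 0:
            raise ValueError("fs_hz and duration_s must be positive")


def preterm_profile(**overrides) -> ClassProfile:
    """Default preterm profile: strong, regular contraction bursts."""
    return ClassProfile(label="P", burst_gain=3.0, regularity=0.8,
                        ecg_interference_gain=0.05, **overrides)


def term_profile(**overrides) -> ClassProfile:
    """Default term profile: weaker, irregular bursts, stronger maternal-ECG
    interference (closed-uterus volume conduction)."""
    return ClassProfile(label="T", burst_gain=1.5, regularity=0.3,
                        ecg_interference_gain=0.3, **overrides)


def _one_over_f_noise(rng: np.random.Generator, n: int, exponent: float,
                      fs: float) -> np.ndarray:
    """Gaussian noise with a 1/f^alpha amplitude spectrum, unit RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC
    x = np.fft.irfft(spec * shaping, n)
    return x / np.std(x)


def _bandlimited_noise(rng: np.random.Generator, n: int,
                       band: tuple[float, float], fs: float) -> np.ndarray:
    """Unit-RMS white noise restricted to ``band`` by FFT masking."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    x = np.fft.irfft(spec * mask, n)
    sd = np.std(x)
    return x / sd if sd > 0 else x


def _ecg_pulse_train(t: np.ndarray, rng: np.random.Generator,
                     rate_hz: float = 1.4, width_s: float = 0.04) -> np.ndarray:
    """Periodic Gaussian-pulse train (fundamental + harmonics), unit RMS.

    Built in the frequency domain from the fundamental and its first two
    harmonics of the pulse train's Fourier series, which keeps the component
    strictly band-limited below Nyquist at fs = 20 Hz.
    """
    phase = rng.uniform(0, 2 * np.pi)
    x = np.zeros_like(t)
    for h in (1, 2, 3):
        f = h * rate_hz
        # Fourier coefficient of a Gaussian pulse train decays as a Gaussian
        amp = np.exp(-2 * (np.pi * f * width_s) ** 2)
        x += amp * np.cos(2 * np.pi * f * t + h * phase)
    sd = np.std(x)
    return x / sd if sd > 0 else x


def _draw_bursts(profile: ClassProfile, config: SimulationConfig,
                 rng: np.random.Generator) -> list[dict]:
    expected = profile.burst_rate * config.duration_s / 1800.0
    n_bursts = rng.poisson(expected)
    bursts = []
    for _ in range(n_bursts):
        dur = rng.normal(profile.burst_duration_s, profile.burst_duration_sd_s)
        dur = float(np.clip(dur, 5.0, config.duration_s))
        mid = float(rng.uniform(0, config.duration_s))
        f0 = float(rng.uniform(*profile.carrier_band_hz))
        bursts.append({"midpoint_s": mid, "duration_s": dur, "carrier_hz": f0,
                       "phase": float(rng.uniform(0, 2 * np.pi))})
    return bursts


def generate_record(profile: ClassProfile, config: SimulationConfig,
                    record_index: int) -> EHGRecord:
    """Generate one synthetic EHG record.

    Deterministic in ``(profile, config, record_index)``.  Burst timing is
    shared across channels; noise (baseline and irregular carrier component)
    and small per-channel burst-gain jitter are channel-independent.
    Ground truth (burst midpoints/durations/per-channel gains) is stored in
    ``record.annotations``.
    """
    nyq = config.fs_hz / 2.0
    if profile.carrier_band_hz[1] >= nyq:
        raise ValueError(
            f"carrier band upper edge {profile.carrier_band_hz[1]} Hz is at "
            f"or above Nyquist ({nyq} Hz)"
        )
    rng = np.random.default_rng([int(config.seed) % (2**31), record_index])
    n = int(round(config.duration_s * config.fs_hz))
    t = np.arange(n) / config.fs_hz

    bursts = _draw_bursts(profile, config, rng)
    channel_names = CHANNEL_NAMES[: config.n_channels]
    channels: dict[str, np.ndarray] = {}
    gains_per_channel: dict[str, list[float]] = {c: [] for c in channel_names}

    for ch in channel_names:
        x = profile.baseline_rms * _one_over_f_noise(
            rng, n, profile.baseline_noise_exponent, config.fs_hz)
        for b in bursts:
            half = b["duration_s"] / 2.0
            i0 = max(0, int((b["midpoint_s"] - half) * config.fs_hz))
            i1 = min(n, int((b["midpoint_s"] + half) * config.fs_hz))
            if i1 - i0 < 4:
                gains_per_channel[ch].append(0.0)
                continue
            seg_t = t[i0:i1]
            tone = np.sqrt(2.0) * np.sin(
                2 * np.pi * b["carrier_hz"] * seg_t + b["phase"])
            noise = _bandlimited_noise(rng, i1 - i0, profile.carrier_band_hz,
                                       config.fs_hz)
            carrier = (profile.regularity * tone
                       + (1.0 - profile.regularity) * noise)
            sd = np.std(carrier)
            if sd > 0:
                carrier = carrier / sd
            gain = profile.burst_gain * profile.baseline_rms * float(
                rng.lognormal(0.0, 0.1))
            env = np.hanning(i1 - i0)
            x[i0:i1] += gain * env * carrier
            gains_per_channel[ch].append(gain)
        if profile.ecg_interference_gain > 0:
            x += (profile.ecg_interference_gain * profile.baseline_rms
                  * _ecg_pulse_train(t, rng))
        channels[ch] = x

    record_id = f"syn{profile.label.lower()}{record_index:03d}"
    return EHGRecord(
        record_id=record_id,
        channels=channels,
        fs_hz=config.fs_hz,
        label=profile.label,
        gestational_age_rec_weeks=float(
            np.round(rng.normal(30.2, 2.0), 1)),
        gestational_age_del_weeks=float(
            np.round(rng.normal(34.7 if profile.label == "P" else 39.3, 1.5), 1)),
        annotations={
            "bursts": bursts,
            "burst_gains": gains_per_channel,
            "profile": asdict(profile),
        },
    )


def generate_cohort(p_profile: ClassProfile, t_profile: ClassProfile,
                    config: SimulationConfig,
                    out_dir: Optional[str | Path] = None
                    ) -> tuple[list[EHGRecord], pd.DataFrame]:
    """Generate a labeled cohort of ``n_P + n_T`` records.

    Returns the records (P first, then T) and a ground-truth manifest.  When
    ``out_dir`` is given, records are written as WFDB header/signal pairs,
    mirrored per-channel CSVs, and the manifest as ``manifest.csv``.
    """
    if config.n_P < 1 or config.n_T < 1:
        raise ValueError("n_P and n_T must both be >= 1")
    if p_profile.label != "P" or t_profile.label != "T":
        raise ValueError("profiles must carry labels P and T respectively")

    records = []
    rows = []
    for i in range(config.n_P + config.n_T):
        profile = p_profile if i < config.n_P else t_profile
        rec = generate_record(profile, config, i)
        records.append(rec)
        rows.append({
            "record_id": rec.record_id,
            "label": rec.label,
            "n_bursts": len(rec.annotations["bursts"]),
            "gestational_age_rec_weeks": rec.gestational_age_rec_weeks,
            "gestational_age_del_weeks": rec.gestational_age_del_weeks,
            **{f"profile_{k}": v for k, v in asdict(profile).items()
               if not isinstance(v, tuple)},
        })
    manifest = pd.DataFrame(rows)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for rec in records:
            write_wfdb_record(rec, out_dir)
            pd.DataFrame(rec.channels).to_csv(
                out_dir / f"{rec.record_id}.csv", index=False)
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return records, manifest
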