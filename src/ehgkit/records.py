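"""Core containers for electrohysterogram (EHG) records and derived segments.

An :class:`EHGRecord` holds the three bipolar abdominal channels (S1, S2, S3)
of one ~30-minute recording together with its delivery label (P = preterm,
T = term) and gestational-age metadata.  Records are the unit of train /
validation / test splitting; :class:`WindowSegment` (one 120-s, single-channel,
single-subband window) is the unit of feature extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

CHANNEL_NAMES = ("S1", "S2", "S3")
BAND_NAMES = ("F1", "F2", "F3")
LABELS = ("P", "T")
SPLITS = ("train", "validation", "test")


@dataclass
class EHGRecord:
    """One multichannel EHG recording plus its metadata."""

    record_id: str
    channels: dict[str, np.ndarray]
    fs_hz: float
    label: Optional[str] = None
    gestational_age_rec_weeks: Optional[float] = None
    gestational_age_del_weeks: Optional[float] = None
    excluded: bool = False
    exclusion_reason: str = ""
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be positive")
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise ValueError("all channels must have equal length")
        if self.label is not None and self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


@dataclass(frozen=True)
class BandDefinition:
    """A frequency subband used for IIR band-pass filtering."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError(f"invalid band edges ({self.low_hz}, {self.high_hz})")

    def validate_for_fs(self, fs_hz: float) -> None:
        if self.high_hz >= fs_hz / 2:
            raise ValueError(
                f"band {self.name} upper edge {self.high_hz} Hz is at or above "
                f"Nyquist ({fs_hz / 2} Hz)"
            )


#: The three subbands partitioning the conventional fast-wave EHG range.
DEFAULT_BANDS = (
    BandDefinition("F1", 0.3, 1.0),
    BandDefinition("F2", 1.0, 2.0),
    BandDefinition("F3", 2.0, 3.0),
)


def band_by_name(name: str) -> BandDefinition:
    for band in DEFAULT_BANDS:
        if band.name == name:
            return band
    raise KeyError(f"unknown band {name!r}")


@dataclass
class WindowSegment:
    """One 120-s window of a single channel in a single subband."""

    record_id: str
    channel: str
    band: str
    window_index: int
    samples: np.ndarray
    label: Optional[str] = None
    split: Optional[str] = None

    def __post_init__(self) -> None:
        if self.channel not in CHANNEL_NAMES:
            raise ValueError(f"channel must be one of {CHANNEL_NAMES}")
        if self.split is not None and self.split not in SPLITS:
            raise ValueError(f"split must be one of {SPLITS}")
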