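"""Record curation, normalization, subband filtering, windowing and splitting.

The pipeline order is fixed: z-score the raw per-channel record, band-pass
into one of the F1/F2/F3 subbands, then cut 120-s windows with 50% overlap.
Normalization happens at the record level (before filtering) so the natural
F1 > F2 > F3 energy ordering of EHG is preserved within each record.

Splitting into train / validation / test is done at the record level —
every window of a record inherits the record's split — so the held-out test
set always consists of independent recordings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .records import BandDefinition, EHGRecord

#: Default analysis window: 120 s at 20 Hz with 50% overlap.
WINDOW_S = 120.0
OVERLAP = 0.5


class DegenerateSignalError(ValueError):
    """Raised when a signal has no variance and cannot be normalized."""


def zscore(x: np.ndarray) -> np.ndarray:
    """Z-score with the population standard deviation (divide by N)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("signal must have at least 2 samples")
    sd = x.std()
    if sd == 0:
        raise DegenerateSignalError("cannot z-score a constant signal")
    return (x - x.mean()) / sd


def design_bandpass(band: BandDefinition, fs_hz: float, order: int = 4
                    ) -> np.ndarray:
    """4th-order Butterworth band-pass in second-order sections.

    Applied forward-backward (:func:`scipy.signal.sosfiltfilt`), the
    effective magnitude response is the square of the design, i.e. an
    8th-order zero-phase filter.
    """
    band.validate_for_fs(fs_hz)
    return sps.butter(order, [band.low_hz, band.high_hz], btype="bandpass",
                      fs=fs_hz, output="sos")


def bandpass(x: np.ndarray, band: BandDefinition, fs_hz: float) -> np.ndarray:
    """Zero-phase band-pass of ``x`` into ``band``; same length as input."""
    sos = design_bandpass(band, fs_hz)
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def segment_windows(x: np.ndarray, fs_hz: float, window_s: float = WINDOW_S,
                    overlap: float = OVERLAP) -> list[np.ndarray]:
    """Cut ``x`` into fully contained windows of ``window_s`` seconds.

    Hop is ``window_s * (1 - overlap)``; the trailing remainder shorter than
    one window is dropped, so the count is ``floor((N - L) / hop) + 1``.
    """
    x = np.asarray(x, dtype=float)
    length = int(round(window_s * fs_hz))
    hop = int(round(length * (1.0 - overlap)))
    if hop < 1:
        raise ValueError("overlap too large: hop collapses to zero")
    if x.size < length:
        raise ValueError(
            f"signal of {x.size} samples is shorter than one window ({length})")
    n_windows = (x.size - length) // hop + 1
    return [x[i * hop: i * hop + length] for i in range(n_windows)]


def filter_records_by_ga(records: list[EHGRecord], low_weeks: float,
                         high_weeks: float) -> list[EHGRecord]:
    """Keep records recorded between ``low_weeks`` and ``high_weeks``
    gestation (inclusive).  Out-of-range or metadata-less records are
    flagged ``excluded`` (with a reason) rather than removed from memory;
    only non-excluded records are returned.
    """
    kept = []
    for rec in records:
        ga = rec.gestational_age_rec_weeks
        if ga is None:
            rec.excluded = True
            rec.exclusion_reason = "no-metadata"
        elif not (low_weeks <= ga <= high_weeks):
            rec.excluded = True
            rec.exclusion_reason = (
                f"gestational age {ga} outside [{low_weeks}, {high_weeks}]")
        else:
            kept.append(rec)
    return kept


def apply_manual_exclusions(records: list[EHGRecord],
                            exclusions: dict[str, str]) -> list[EHGRecord]:
    """Flag records listed in ``exclusions`` (id -> reason), e.g. visually
    identified motion artifacts; returns the non-excluded records."""
    kept = []
    for rec in records:
        if rec.record_id in exclusions:
            rec.excluded = True
            rec.exclusion_reason = exclusions[rec.record_id]
        else:
            kept.append(rec)
    return kept


def balance_by_subsampling(records: list[EHGRecord], per_class: int,
                           seed: int) -> list[EHGRecord]:
    """Randomly keep exactly ``per_class`` records of each class (seeded)."""
    rng = np.random.default_rng(seed)
    out: list[EHGRecord] = []
    for label in ("P", "T"):
        group = [r for r in records if r.label == label]
        if len(group) < per_class:
            raise ValueError(
                f"class {label} has only {len(group)} records, "
                f"cannot subsample {per_class}")
        idx = rng.choice(len(group), size=per_class, replace=False)
        out.extend(group[i] for i in sorted(idx))
    return out


@dataclass
class SplitAssignment:
    """Record-level train/validation/test partition."""

    assignment: dict[str, str]
    fractions: tuple[float, float, float]
    seed: int
    degenerate: bool = False

    def __getitem__(self, record_id: str) -> str:
        return self.assignment[record_id]

    def ids(self, split: str) -> list[str]:
        return sorted(k for k, v in self.assignment.items() if v == split)


def split_records(records: list[EHGRecord],
                  fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
                  seed: int = 0) -> SplitAssignment:
    """Stratified record-level split into train/validation/test.

    Per class, validation and test sizes are ``round(fraction * n)`` and
    training takes the remainder — deterministic given the seed.  A class
    with fewer than 3 records triggers a degenerate all-train assignment
    with a warning.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    degenerate = False
    for label in ("P", "T"):
        ids = sorted(r.record_id for r in records if r.label == label)
        if not ids:
            continue
        if len(ids) < 3:
            warnings.warn(
                f"class {label} has {len(ids)} records (< 3); assigning all "
                "to train", stacklevel=2)
            degenerate = True
            for rid in ids:
                assignment[rid] = "train"
            continue
        perm = rng.permutation(len(ids))
        n_val = int(round(fractions[1] * len(ids)))
        n_test = int(round(fractions[2] * len(ids)))
        for k, pi in enumerate(perm):
            if k < n_val:
                assignment[ids[pi]] = "validation"
            elif k < n_val + n_test:
                assignment[ids[pi]] = "test"
            else:
                assignment[ids[pi]] = "train"
    return SplitAssignment(assignment=assignment, fractions=fractions,
                           seed=seed, degenerate=degenerate)
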