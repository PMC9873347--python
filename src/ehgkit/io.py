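"""WFDB-compatible record I/O.

Reads and writes the subset of the WFDB format the EHG databases use: a
plain-text ``.hea`` header plus a binary ``.dat`` signal file with
interleaved 16-bit little-endian samples (WFDB format 16).  Physical units
are recovered as ``(adc - baseline) / gain``.

Metadata is carried in header comment lines (``# Key value``).  The keys
``Gestation`` (gestational age at recording, weeks), ``Delivery``
(gestational age at delivery) and ``Label`` (P/T) are written by this
package; ``Rectime``/``Delivery`` style keys found in Physionet headers are
also understood and take precedence.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .records import CHANNEL_NAMES, EHGRecord

_FMT = 16  # the only signal format supported (int16, little-endian)


class WFDBError(IOError):
    """Raised when a header or signal file cannot be read as expected."""


def write_wfdb_record(
    record: EHGRecord,
    directory: str | Path,
    gain: float = 1000.0,
    units: str = "mV",
) -> Path:
    """Write ``record`` as a WFDB header/signal pair; returns the header path.

    Signals are quantized with the given ``gain`` (ADC units per physical
    unit), so the round-trip error is at most half a quantization step,
    ``0.5 / gain``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = record.record_id
    dat_name = f"{name}.dat"

    channels = [record.channels[c] for c in CHANNEL_NAMES if c in record.channels]
    ch_names = [c for c in CHANNEL_NAMES if c in record.channels]
    adc = np.empty((record.n_samples, len(channels)), dtype=np.int16)
    for j, x in enumerate(channels):
        q = np.round(np.asarray(x, dtype=float) * gain)
        if np.any(np.abs(q) > 32767):
            raise WFDBError(
                f"record {name}: signal exceeds int16 range at gain {gain}"
            )
        adc[:, j] = q.astype(np.int16)

    lines = [f"{name} {len(channels)} {record.fs_hz:g} {record.n_samples}"]
    for j, ch in enumerate(ch_names):
        checksum = int(np.sum(adc[:, j], dtype=np.int64) % 65536)
        if checksum >= 32768:
            checksum -= 65536
        lines.append(
            f"{dat_name} {_FMT} {gain:g}(0)/{units} 16 0 "
            f"{int(adc[0, j])} {checksum} 0 {ch}"
        )
    if record.label is not None:
        lines.append(f"# Label {record.label}")
    if record.gestational_age_rec_weeks is not None:
        lines.append(f"# Gestation {record.gestational_age_rec_weeks:g}")
    if record.gestational_age_del_weeks is not None:
        lines.append(f"# Delivery {record.gestational_age_del_weeks:g}")

    (directory / f"{name}.hea").write_text("\n".join(lines) + "\n")
    (directory / dat_name).write_bytes(adc.reshape(-1).tobytes())
    return directory / f"{name}.hea"


def _parse_comments(lines: list[str]) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in lines:
        body = line.lstrip("#").strip()
        m = re.match(r"(\w+)\s+(.+)", body)
        if m:
            out[m.group(1).lower()] = m.group(2).strip()
    return out


def read_wfdb_record(
    path: str | Path,
    expected_channels: int = 3,
    expected_fs: float | None = 20.0,
) -> EHGRecord:
    """Read a WFDB header (``.hea``) and its format-16 signal file.

    Raises :class:`WFDBError` on a missing file, an unexpected channel
    count, an unexpected sampling rate, or an unsupported signal format.
    """
    path = Path(path)
    if path.suffix != ".hea":
        path = path.with_suffix(".hea")
    if not path.exists():
        raise WFDBError(f"header file not found: {path}")

    raw_lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    comments = [ln for ln in raw_lines if ln.startswith("#")]
    spec_lines = [ln for ln in raw_lines if not ln.startswith("#")]
    if not spec_lines:
        raise WFDBError(f"empty header: {path}")

    head = spec_lines[0].split()
    if len(head) < 4:
        raise WFDBError(f"malformed record line in {path}: {spec_lines[0]!r}")
    name, n_sig, fs, n_samp = head[0], int(head[1]), float(head[2]), int(head[3])
    if expected_channels is not None and n_sig != expected_channels:
        raise WFDBError(
            f"record {name}: expected {expected_channels} channels, header "
            f"declares {n_sig}"
        )
    if expected_fs is not None and fs != expected_fs:
        raise WFDBError(
            f"record {name}: expected fs={expected_fs} Hz, header declares {fs}"
        )

    gains, baselines, ch_names, dat_files = [], [], [], []
    for j, line in enumerate(spec_lines[1 : 1 + n_sig]):
        parts = line.split()
        dat_files.append(parts[0])
        if int(parts[1]) != _FMT:
            raise WFDBError(f"record {name}: unsupported signal format {parts[1]}")
        gain_field = parts[2].split("/")[0]
        m = re.match(r"([-\d.eE+]+)(?:\(([-\d]+)\))?", gain_field)
        gains.append(float(m.group(1)) if m.group(1) else 200.0)
        baselines.append(int(m.group(2)) if m.group(2) else 0)
        ch_names.append(parts[-1] if len(parts) >= 9 else CHANNEL_NAMES[j])
    if len(gains) != n_sig:
        raise WFDBError(f"record {name}: header declares {n_sig} signals but "
                        f"lists {len(gains)}")
    if len(set(dat_files)) != 1:
        raise WFDBError(f"record {name}: multi-file records are not supported")

    dat_path = path.parent / dat_files[0]
    if not dat_path.exists():
        raise WFDBError(f"signal file not found: {dat_path}")
    adc = np.frombuffer(dat_path.read_bytes(), dtype="<i2")
    if adc.size != n_sig * n_samp:
        raise WFDBError(
            f"record {name}: signal file holds {adc.size} samples, header "
            f"declares {n_sig * n_samp}"
        )
    adc = adc.reshape(n_samp, n_sig)

    channels = {
        CHANNEL_NAMES[j]: (adc[:, j].astype(float) - baselines[j]) / gains[j]
        for j in range(n_sig)
    }

    meta = _parse_comments(comments)
    ga_rec = meta.get("rectime", meta.get("gestation"))
    ga_del = meta.get("delivery")
    label = meta.get("label")
    if label is not None:
        label = label.upper()[:1]
        if label not in ("P", "T"):
            label = None

    return EHGRecord(
        record_id=name,
        channels=channels,
        fs_hz=fs,
        label=label,
        gestational_age_rec_weeks=float(ga_rec) if ga_rec is not None else None,
        gestational_age_del_weeks=float(ga_del) if ga_del is not None else None,
    )


def read_cohort(directory: str | Path, **kwargs) -> list[EHGRecord]:
    """Read every ``.hea`` record in a directory, sorted by record id."""
    directory = Path(directory)
    headers = sorted(directory.glob("*.hea"))
    if not headers:
        raise WFDBError(f"no .hea files found in {directory}")
    return [read_wfdb_record(h, **kwargs) for h in headers]
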