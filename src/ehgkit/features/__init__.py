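"""Window feature extraction: 33 named features per 120-s subband window.

The canonical registry lists 5 linear, 18 entropy-based, and 10
time-frequency features (4 CWT + 6 DWT log-energy differences).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..preprocessing import OVERLAP, WINDOW_S, bandpass, segment_windows, zscore
from ..records import BandDefinition, DEFAULT_BANDS, EHGRecord, WindowSegment
from . import entropy as ent
from . import linear as lin
from . import timefrequency as tf
from .entropy import EntropyParams, PHEN_KS
from .timefrequency import WaveletParams

LINEAR_FEATURES = ("MaxFreq", "MedFreq", "RMS", "ZCR", "Amp")
ENTROPY_FEATURES = ("SampEn", "FuzzEnLoc", "FuzzEnGlob", "PerEn", "DispEn",
                    "bEn") + tuple(f"PhEn_k{k}" for k in PHEN_KS)
TF_FEATURES = ("Energy", "Flux0", "Flux45", "Flux90") + tuple(
    f"DWT_d{j}" for j in range(1, 7))

#: The 33 canonical feature names, in registry order.
FEATURE_NAMES: tuple[str, ...] = LINEAR_FEATURES + ENTROPY_FEATURES + TF_FEATURES

PROVENANCE_COLUMNS = ("record_id", "channel", "band", "window_index",
                      "label", "split")


def compute_features(window: np.ndarray, fs_hz: float, band: BandDefinition,
                     entropy_params: EntropyParams | None = None,
                     wavelet_params: WaveletParams | None = None
                     ) -> dict[str, float]:
    """All 33 features of one single-channel, single-subband window."""
    ep = entropy_params or EntropyParams()
    wp = wavelet_params or WaveletParams()
    x = np.asarray(window, dtype=np.float64)

    out: dict[str, float] = {}
    psd = lin.psd_welch(x, fs_hz)
    out["MaxFreq"] = lin.max_frequency(psd, band)
    out["MedFreq"] = lin.medium_frequency(psd, band)
    out["RMS"] = lin.rms(x)
    out["ZCR"] = lin.zero_crossing_rate(x, fs_hz)
    out["Amp"] = lin.amplitude(x)

    out["SampEn"] = ent.sample_entropy(x, ep.sampen_m, ep.sampen_r)
    out["FuzzEnLoc"] = ent.fuzzy_entropy(x, ep.fuzzen_m, ep.fuzzen_r,
                                         ep.fuzzen_n, "local")
    out["FuzzEnGlob"] = ent.fuzzy_entropy(x, ep.fuzzen_m, ep.fuzzen_r,
                                          ep.fuzzen_n, "global")
    out["PerEn"] = ent.permutation_entropy(x, ep.peren_order, ep.peren_delay)
    out["DispEn"] = ent.dispersion_entropy(x, ep.dispen_m, ep.dispen_c)
    out["bEn"] = ent.bubble_entropy(x, ep.ben_m)
    out.update(ent.phen_profile(x, ep.phen_ks))

    scal = tf.cwt_scalogram(x, fs_hz, wp)
    out["Energy"] = tf.tf_energy(scal)
    out["Flux0"] = tf.tf_flux(scal, 0)
    out["Flux45"] = tf.tf_flux(scal, 45)
    out["Flux90"] = tf.tf_flux(scal, 90)
    energies, _ = tf.dwt_level_energies(x, wp)
    out.update(tf.dwt_adjacent_differences(energies))
    return out


def extract_feature_table(records: list[EHGRecord],
                          channels: tuple[str, ...] | None = None,
                          bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
                          window_s: float = WINDOW_S,
                          overlap: float = OVERLAP,
                          split_assignment=None,
                          entropy_params: EntropyParams | None = None,
                          wavelet_params: WaveletParams | None = None
                          ) -> pd.DataFrame:
    """Run the fixed pipeline (z-score -> band-pass -> window -> features)
    over a cohort and return one row per (record, channel, band, window).

    Provenance columns precede the 33 feature columns; ``split`` is filled
    from ``split_assignment`` when given.
    """
    rows = []
    for rec in records:
        if rec.excluded:
            continue
        split = (split_assignment[rec.record_id]
                 if split_assignment is not None else None)
        ch_names = channels or tuple(rec.channels)
        for ch in ch_names:
            normalized = zscore(rec.channels[ch])
            for band in bands:
                filtered = bandpass(normalized, band, rec.fs_hz)
                for w_idx, w in enumerate(
                        segment_windows(filtered, rec.fs_hz, window_s,
                                        overlap)):
                    feats = compute_features(w, rec.fs_hz, band,
                                             entropy_params, wavelet_params)
                    rows.append({
                        "record_id": rec.record_id, "channel": ch,
                        "band": band.name, "window_index": w_idx,
                        "label": rec.label, "split": split, **feats,
                    })
    table = pd.DataFrame(rows)
    return table[list(PROVENANCE_COLUMNS) + list(FEATURE_NAMES)]
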