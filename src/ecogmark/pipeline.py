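"""Per-situation biomarker computation and cohort-level table assembly.

Every situation is reduced to one value per derived channel per biomarker:
univariate measures are averaged over the twelve 5 s segments, connectivity
matrices are first reduced to per-channel strengths and then averaged over
segments — except Granger causality, whose VAR is fitted once on all
segments pooled.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from . import connectivity as conn
from .config import RunConfig
from .io import Cohort, SituationRecording
from .preprocess import (EpochSet, bandpass_fir, design_fir, make_bipolar,
                         make_common_average, segment_and_normalize)
from .univariate import arrm, mean_vector_length

logger = logging.getLogger(__name__)

TABLE_COLUMNS = ["patient", "situation", "phase", "channel", "biomarker",
                 "value", "resected", "mesiotemporal", "n_epochs"]


def _pac_values(epochs: EpochSet, cfg: RunConfig,
                taps: dict[str, np.ndarray]) -> np.ndarray:
    """PAC per channel per segment, vectorised across channels/segments."""
    phase_band = cfg.bands[cfg.pac_phase_band]
    amp_band = cfg.bands[cfg.pac_amp_band]
    lo = bandpass_fir(epochs.data, phase_band, epochs.fs,
                      taps=taps[cfg.pac_phase_band])
    hi = bandpass_fir(epochs.data, amp_band, epochs.fs,
                      taps=taps[cfg.pac_amp_band])
    phase = np.angle(hilbert(lo, axis=-1))
    amp = np.abs(hilbert(hi, axis=-1))
    trim = taps[cfg.pac_phase_band].size
    if epochs.data.shape[-1] <= 2 * trim:
        raise ValueError("segments too short to trim phase-filter edges")
    phase, amp = phase[..., trim:-trim], amp[..., trim:-trim]
    vec = np.abs((amp * np.exp(1j * phase)).mean(axis=-1))
    return vec / amp.mean(axis=-1)


def compute_situation_table(rec: SituationRecording, cfg: RunConfig
                            ) -> pd.DataFrame:
    """All requested biomarkers for one situation; one row per channel and
    biomarker."""
    cfg.validate()
    montage = make_bipolar if cfg.montage == "bipolar" else make_common_average
    derived = montage(rec)
    epochs = segment_and_normalize(derived, cfg.epoch_seconds)
    n_ch, n_ep, _ = epochs.data.shape
    taps = {name: design_fir(band, rec.fs) for name, band in cfg.bands.items()}
    gamma = cfg.bands[cfg.connectivity_band]

    values: dict[str, tuple[list, np.ndarray]] = {}  # name -> (channels, per-ch)

    def channel_values(name, chans, vals):
        values[name] = (chans, np.asarray(vals, dtype=float))

    if "ARR" in cfg.biomarkers:
        v = [np.mean([arrm(epochs.data[c, e], cfg.arrm_window,
                           cfg.arrm_overlap, cfg.arrm_order)
                      for e in range(n_ep)]) for c in range(n_ch)]
        channel_values("ARR", epochs.channels, v)
    if "PAC" in cfg.biomarkers:
        channel_values("PAC", epochs.channels,
                       _pac_values(epochs, cfg, taps).mean(axis=-1))

    need_phases = {"PLV", "PLI"} & set(cfg.biomarkers)
    need_filtered = need_phases or "H2" in cfg.biomarkers
    if need_filtered:
        filt = bandpass_fir(epochs.data, gamma, rec.fs,
                            taps=taps[cfg.connectivity_band])
    if need_phases:
        phases = np.angle(hilbert(filt, axis=-1))
        if "PLV" in cfg.biomarkers:
            s = [conn.node_strength(conn.plv_matrix(phases[:, e]), False)
                 for e in range(n_ep)]
            channel_values("PLV", epochs.channels, np.mean(s, axis=0))
        if "PLI" in cfg.biomarkers:
            s = [conn.node_strength(conn.pli_matrix(phases[:, e]), False)
                 for e in range(n_ep)]
            channel_values("PLI", epochs.channels, np.mean(s, axis=0))
    if "H2" in cfg.biomarkers:
        s = [conn.node_strength(
                conn.h2_matrix(filt[:, e], cfg.h2_delays, cfg.h2_n_bins), True)
             for e in range(n_ep)]
        channel_values("H2", epochs.channels, np.mean(s, axis=0))
    if "GC" in cfg.biomarkers:
        diff_epochs = segment_and_normalize(derived, cfg.epoch_seconds,
                                            first_difference=True)
        m, order = conn.gc_pooled(diff_epochs.data, cfg.gc_p_max)
        logger.debug("situation %s/%s: GC VAR order %d", rec.patient_id,
                     rec.situation_id, order)
        channel_values("GC", diff_epochs.channels,
                       conn.node_strength(m, True))
    if "sdDTF" in cfg.biomarkers:
        s = [conn.node_strength(
                conn.sddtf(epochs.data[:, e], rec.fs, cfg.sddtf_order, gamma),
                True)
             for e in range(n_ep)]
        channel_values("sdDTF", epochs.channels, np.mean(s, axis=0))

    rows = []
    for name, (chans, vals) in values.items():
        for ch, v in zip(chans, vals):
            rows.append({
                "patient": rec.patient_id, "situation": rec.situation_id,
                "phase": rec.phase, "channel": ch.name, "biomarker": name,
                "value": float(v), "resected": ch.resected,
                "mesiotemporal": ch.mesiotemporal, "n_epochs": n_ep,
            })
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def compute_biomarker_table(cohort: Cohort, cfg: RunConfig) -> pd.DataFrame:
    """Biomarker table for every situation of a cohort."""
    parts = []
    for rec in cohort.situations:
        try:
            parts.append(compute_situation_table(rec, cfg))
        except ValueError as e:
            logger.warning("skipping situation %s/%s: %s", rec.patient_id,
                           rec.situation_id, e)
    if not parts:
        raise ValueError("no situation could be processed")
    return pd.concat(parts, ignore_index=True)
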